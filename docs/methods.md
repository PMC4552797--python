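# Methods

## Scope and model

`cohortkin` analyses complete (uncensored) cohort mortality data: every
individual in an age-synchronized cohort is followed to death, with deaths
censused once per recording interval. The parametric core is the
two-parameter Weibull survival model — density
f(t) = (β/α)(t/α)^(β−1) exp{−(t/α)^β}, survivorship S = exp{−(t/α)^β},
hazard h = (β/α)(t/α)^(β−1). Its assumptions, stated plainly:

- individual ages at death are independent and identically distributed
  within a condition;
- the hazard is a power of age (monotone: rising for β > 1, constant at
  β = 1, falling for β < 1) — no late-life plateau or non-monotone
  mortality can be represented;
- conditions (temperature regimes) are fitted independently, with no
  shared or pooled parameters;
- observation times are treated as exact, even though a daily census makes
  them interval-valued (see "Recording convention").

The exponential distribution is the β = 1 special case, which is why the
fitted shape doubles as a test of whether a cohort "ages" at all.

Three printed-form ambiguities in the source material for the model were
resolved on algebraic necessity: the variance uses the canonical
α²[Γ(1+2/β) − Γ(1+1/β)²] (the only form that is nonnegative and reproduces
the published variance values); the cdf is 1 − exp{−(t/α)^β} (the only
bracket placement under which hazard = pdf/survival); and the log-hazard
intercept is log β − β log α (the unique constant making
intercept + (β−1)·log t equal log h(t) identically).

## Life tables

`build_life_table` censuses a cohort on a regular grid of width
`bin_width` (default one recording interval): `alive[j]` counts
individuals whose age at death exceeds `ages[j]`, so an individual
recorded dead at the day-d census is assigned age d and counted as having
died in (d−1, d]. Deaths at day 1 are kept at t = 1 rather than shifted to
an interval midpoint so log t stays defined; the ceiling convention in the
simulator matches this. The empirical cumulative hazard is −log lx,
emitted only over the support lx > 0 with a `truncated` flag once the
cohort is exhausted. Right-censored entries are rejected outright rather
than silently mishandled — the supported design follows everyone to death.

`normalize_time` divides ages by the cohort maximum (dimensionless scale,
maximum mapped to 1). It is an explicit opt-in, never automatic: the
published parameter magnitudes (α between 0.26 and 0.71, means well below
one "day") imply the original analysis worked on some rescaled time axis
that is not documented, so the package leaves the choice to the user and
the fitted-parameter presets live on that dimensionless scale.

## Maximum likelihood

The log-likelihood of a sample x₁..xₙ expands to
n log β − nβ log α + (β−1)Σ log xᵢ − Σ(xᵢ/α)^β. Score and Hessian are the
exact analytic derivatives of this expression (unit-tested against central
finite differences and, for the resulting optimum, against
`lifelines.WeibullFitter` and a dense grid search).

Numerical choices:

- **Parameterisation.** Newton–Raphson runs in (log α, log β) with the
  chain rule applied to score and Hessian, so iterates can never cross
  zero and no constraints are needed. Reported quantities (estimates,
  SEs, Hessian) are transformed back to the (α, β) scale.
- **Safeguards.** A Newton step is accepted only if it increases the
  log-likelihood; otherwise it is halved, up to 30 times. When the
  Hessian is not negative definite the direction falls back to (scaled)
  steepest ascent. Plain Newton iteration diverges from poor starts on
  this likelihood; with these safeguards all tested starts converge.
- **Convergence.** Gradient max-norm < 1e-8 on the log-parameter scale,
  or relative parameter change < 1e-10; at most 100 iterations, after
  which an *unconverged* result is returned (flagged, not raised).
- **Starting values.** The cumulative hazard is (t/α)^β, so
  log(−log lx) is linear in log age with slope β; a least-squares line
  over the interior life-table points (binned at 1/30 of the observed
  range) seeds both parameters. With fewer than two usable points the
  seed falls back to moments (shape from the coefficient of variation via
  the standard reliability-engineering approximation β ≈ CV^−1.086).
- **Standard errors.** Square roots of the diagonal of the inverse
  observed information (negative Hessian) at the optimum — the
  conventional companion of Newton–Raphson. Wald coverage of these SEs is
  checked by simulation (about 95% at n = 5000).
- **Ties.** Daily recording produces tied ages; they are accepted as
  exact times. An interval-censored likelihood would be the rigorous
  treatment but is out of scope.
- **Surfaces.** `nll_surface` and `profile_nll` evaluate the negative
  log-likelihood on parameter lattices, row-vectorized so a 200×200 grid
  over a few thousand observations stays in milliseconds; the recorded
  argmin doubles as an optimizer-free check on the Newton fit.

## Hazard-regime classification

Two classifiers are deliberately distinct. The exact-arithmetic one
(`log_hazard_line`, and `classify_regime` without a standard error) calls
|β − 1| ≤ 1e-6 "constant" — a pure sign test for known parameters. The
inferential one (`classify_regime(beta, se_beta)`) calls a fitted shape
"constant" when the two-sided 99% Wald interval β̂ ± 2.5758·SE covers 1,
i.e. when the data cannot distinguish the hazard from constant at that
level. The 99% level is a deliberate, conservative choice: the scientific
claim at stake is usually "this regime shows no ageing", and a
classification that flips to "increasing" on sampling noise for a shape a
fraction of a percent from 1 would be misleading. Reports always carry β̂
and its SE alongside the label so users can apply their own criterion.

## Synthetic study design

The generator emulates the motivating experiment: five regimes, cohort
sizes drawn uniformly from 30–50, Weibull ages at death on the
dimensionless fitted-parameter scale, daily census. Defaults:

- **Regime parameters** are the published fitted pairs per temperature.
  The 30 °C pair as printed (β = 0.0027) is internally inconsistent — it
  implies an infinite mean, contradicting that row's own printed moments —
  so the presets carry it verbatim but flagged `suspect`, alongside a
  moment-matched alternative (α ≈ 0.4421, β ≈ 1.2508) obtained by
  inverting the moment equations against the printed mean 0.4117 and
  variance 0.1097 (`params_from_moments`). Simulable defaults use the
  alternative.
- **Recording.** Daily recording applies a *ceiling* to each latent age
  (a death observed at census d occurred in (d−1, d]), matching the
  life-table convention; the census width defaults to 1/30 of a time unit,
  standing in for "one day" on the dimensionless scale where a long-lived
  cohort spans roughly 30 census intervals. The induced upward bias of
  the sample mean is bounded by one bin width (asserted in tests).
  Continuous recording returns the latent draws.
- **Seeding.** One master seed is spawned into per-regime
  `numpy.random.SeedSequence` substreams, so any single cohort is
  reproducible in isolation and regimes are independent by construction.
  Sampling is by inverse transform, α(−log U)^(1/β).
- **`days_per_unit`** optionally rescales ages to a day axis for
  exercising `normalize_time`.

What the generator does *not* emulate: sex structure, rearing mortality,
measurement error in the census, between-individual frailty, or any
deviation from Weibull-distributed deaths. Passing tests therefore show
the pipeline is correct and well-calibrated *when the model holds*; they
say nothing about model adequacy for real cohorts, which must be judged
from the life-table diagnostics (e.g. curvature in the log(−log lx) plot).

## Problem sizes in the test suite

Distributional checks run at n = 10⁵ draws; moment/Monte-Carlo agreement
at 2×10⁵ per preset; parameter recovery and regime classification at 200
replicates of n = 5000 (the large-sample scale at which shape SEs are
~1%); optimizer-vs-grid checks on 200×200 lattices over cohorts of 200.
These sizes make the stochastic assertions sharp while keeping the whole
suite in a few seconds.

## Known limitations

- No censoring, truncation, staggered entry or competing risks.
- No Gompertz or logistic-mortality alternatives, mixture/frailty
  extensions, or three-parameter (location-shifted) Weibull; the published
  log-likelihood values per regime are not reproducible targets because
  the raw ages and their time normalization were never deposited.
- Wald (SE-based) inference only; no likelihood-ratio confidence regions.
- The life-table hazard is the crude conditional death rate per interval,
  without variance estimates (no Greenwood bands).
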