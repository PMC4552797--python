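# cohortkin

Weibull failure-kinetics analysis of cohort mortality data.

`cohortkin` is for demographers and entomologists who follow age-synchronized
cohorts (the motivating case: adult moths held at five constant temperatures,
15–35 °C, with deaths censused daily) and want to know *how* the force of
mortality changes with age under each condition — not just how long
individuals live. It builds actuarial life tables from ages at death, fits
the two-parameter Weibull survival model by Newton–Raphson maximum
likelihood with analytic score and Hessian, explores the likelihood surface,
and classifies each condition's hazard kinetics.

## The model

Ages at death follow the Weibull distribution with scale α > 0 and shape
β > 0:

    f(t) = (β/α) (t/α)^(β−1) exp{−(t/α)^β}
    S(t) = exp{−(t/α)^β}          survivorship
    h(t) = (β/α) (t/α)^(β−1)      hazard (force of mortality)
    H(t) = (t/α)^β = −log S(t)    cumulative hazard

log h(t) is exactly linear in log t with slope β − 1, so the shape parameter
is the hazard-kinetics verdict: β > 1 means death rates accelerate with age
(wear-out), β = 1 is the memoryless exponential limit (a constant chance of
dying, independent of age), β < 1 means early deaths dominate. The moments
are μ = α·Γ(1 + 1/β) and σ² = α²·[Γ(1 + 2/β) − Γ(1 + 1/β)²].

Fitting maximizes log L(α, β) = Σ log f(xᵢ) via the Newton–Raphson
recurrence θₖ₊₁ = θₖ − H⁻¹(θₖ) g(θₖ) on hand-derived gradient g (score) and
Hessian H, run on the (log α, log β) scale with step halving for global
stability. Standard errors come from the observed information (inverse
negative Hessian) at the optimum.

## Worked example

Simulate the five-regime study design (cohorts of 40, continuous recording)
and run the full analysis:

```sh
cohortkin simulate --seed 11 --n-range 40,40 --recording continuous --out ages.csv
cohortkin report --ages ages.csv --out-csv report.csv
```

The report (one row per condition) comes out as:

```
             label  n  alpha  se_alpha   beta  se_beta   mean hazard_regime  converged
               15C 40 0.4080    0.0551 1.2345   0.1532 0.3811      constant       True
               20C 40 0.7132    0.0357 3.3191   0.4213 0.6400    increasing       True
               25C 40 0.7565    0.0363 3.4644   0.4274 0.6803    increasing       True
30C-moment-matched 40 0.4656    0.0563 1.3880   0.1637 0.4250      constant       True
               35C 40 0.2703    0.0415 1.0882   0.1303 0.2618      constant       True
```

Reading it: at the favourable temperatures (20/25 °C) the fitted shape is
far above 1 — the death rate accelerates as the cohort ages — while at
35 °C the shape is statistically indistinguishable from 1: each individual
faces an age-independent risk of dying, the signature of purely extrinsic
mortality. `mean` is recomputed from the fitted (α, β) through the
gamma-function formula, never from the raw ages. Note that at cohort sizes
of 40 the shape standard errors are wide enough that mildly ageing regimes
(15 °C, true β ≈ 1.36) also classify "constant"; the regime label is a
statistical statement at the achieved precision, and grows sharper with n.

The same analysis is available as a library:

```python
from cohortkin import CohortData, newton_raphson_fit, log_hazard_line

fit = newton_raphson_fit(CohortData(ages, "25C"))
fit.params, fit.std_errors, log_hazard_line(fit.params).regime
```

Other subcommands: `cohortkin lifetable` (age/alive/lx/H tables),
`cohortkin surface` (negative log-likelihood grids for plotting),
`cohortkin fit`, `cohortkin presets`.

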