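"""Synthetic cohort mortality data with the structure the analysis assumes.

Emulates a laboratory life-span study: several age-synchronized insect
cohorts, each held at a constant temperature, followed until every
individual dies, with deaths censused once per recording interval.  Ages at
death are Weibull-distributed with temperature-specific scale and shape;
daily recording rounds each latent age *up* to the next census boundary
(a death observed at the day-d census occurred somewhere in (d-1, d]).

Reproducibility: a single master seed is spawned into one independent
substream per regime via `numpy.random.SeedSequence`, so any cohort can be
regenerated in isolation from (master seed, regime index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .lifetable import CohortData
from .weibull import WeibullParams, params_from_moments, sample

__all__ = [
    "StudyDesign",
    "simulate_cohort",
    "simulate_study",
    "table1_presets",
    "write_study_csv",
    "write_survivorship_txt",
]

# Fitted (scale, shape) per temperature regime on the normalized time scale.
# The 30C shape as printed is inconsistent with its own printed moments
# (it implies an infinite mean); it is kept verbatim but flagged suspect,
# and a moment-matched alternative is derived at call time.
_PRESET_TABLE = [
    ("15C", 0.391, 1.3645, False),
    ("20C", 0.6904, 2.82, False),
    ("25C", 0.7118, 3.4663, False),
    ("30C", 0.442, 0.0027, True),
    ("35C", 0.2594, 0.9926, False),
]
_MOMENTS_30C = (0.4117, 0.1097)  # printed mean, variance at 30C


def table1_presets(include_suspect: bool = True) -> list[tuple[str, WeibullParams, bool]]:
    """The five fitted (label, params, suspect) triples, plus a
    moment-consistent alternative for the internally inconsistent 30C row
    (labelled ``30C-moment-matched``).

    With ``include_suspect=False`` the printed 30C row is dropped and only
    the moment-matched alternative is kept.
    """
    out = []
    for label, a, b, suspect in _PRESET_TABLE:
        if suspect:
            alt = params_from_moments(*_MOMENTS_30C)
            if include_suspect:
                out.append((label, WeibullParams(a, b), True))
            out.append((f"{label}-moment-matched", alt, False))
        else:
            out.append((label, WeibullParams(a, b), False))
    return out


def default_regimes() -> list[tuple[str, WeibullParams]]:
    """The five-temperature study design with simulable parameters
    (moment-matched 30C in place of the suspect printed shape)."""
    return [(lab, p) for lab, p, s in table1_presets(include_suspect=False)]


@dataclass(frozen=True)
class StudyDesign:
    """A multi-regime cohort life-span experiment.

    Defaults mirror the motivating design: five temperature regimes,
    cohorts of 30-50 individuals drawn uniformly, daily death census on the
    dimensionless time scale of the fitted parameters (bin width of one
    census interval).  ``days_per_unit`` rescales ages to days for
    exercising explicit time normalization.
    """

    regimes: list = field(default_factory=default_regimes)
    cohort_size_range: tuple[int, int] = (30, 50)
    recording: Literal["daily", "continuous"] = "daily"
    bin_width: float = 1.0 / 30.0
    normalize: bool = False
    seed: int = 0
    days_per_unit: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.cohort_size_range
        if lo < 2 or hi < lo:
            raise ValueError("cohort sizes must satisfy 2 <= lo <= hi")
        labels = [lab for lab, _ in self.regimes]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate regime labels: {labels}")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


def simulate_cohort(
    params: WeibullParams,
    n: int,
    recording: Literal["daily", "continuous"] = "daily",
    seed=0,
    bin_width: float = 1.0 / 30.0,
    label: str = "cohort",
) -> CohortData:
    """Draw one cohort's ages at death.

    Continuous recording returns the latent Weibull draws; daily recording
    rounds each up to the next census boundary (ceiling), so every recorded
    age is a positive multiple of ``bin_width``.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 individuals")
    ages = sample(params, n, seed)
    if recording == "daily":
        ages = np.ceil(ages / bin_width - 1e-12) * bin_width
        ages = np.maximum(ages, bin_width)
    elif recording != "continuous":
        raise ValueError(f"unknown recording mode {recording!r}")
    return CohortData(ages, label)


def simulate_study(design: StudyDesign) -> dict[str, CohortData]:
    """One cohort per regime from independent substreams of the master seed.

    Returns an ordered mapping label -> CohortData; generation parameters
    are recoverable via :func:`study_manifest`.
    """
    master = np.random.SeedSequence(design.seed)
    streams = master.spawn(len(design.regimes))
    out: dict[str, CohortData] = {}
    for (label, params), ss in zip(design.regimes, streams):
        rng = np.random.default_rng(ss)
        lo, hi = design.cohort_size_range
        n = int(rng.integers(lo, hi + 1))
        cohort = simulate_cohort(
            params,
            n,
            recording=design.recording,
            seed=rng,
            bin_width=design.bin_width,
            label=label,
        )
        if design.days_per_unit is not None:
            cohort = CohortData(
                cohort.ages_at_death * design.days_per_unit, label, "days"
            )
        out[label] = cohort
    return out


def study_manifest(design: StudyDesign) -> dict:
    """JSON-serializable record of every generation parameter."""
    return {
        "regimes": [
            {"label": lab, "alpha": p.alpha, "beta": p.beta}
            for lab, p in design.regimes
        ],
        "cohort_size_range": list(design.cohort_size_range),
        "recording": design.recording,
        "bin_width": design.bin_width,
        "normalize": design.normalize,
        "seed": design.seed,
        "days_per_unit": design.days_per_unit,
    }


def write_study_csv(cohorts: dict[str, CohortData], path, manifest: dict | None = None) -> None:
    """Long-format ``label,age`` CSV; optional JSON manifest alongside."""
    rows = [
        {"label": lab, "age": age}
        for lab, c in cohorts.items()
        for age in c.ages_at_death
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    if manifest is not None:
        with open(str(path) + ".manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def write_survivorship_txt(cohorts: dict[str, CohortData], kx_path, lx_path, bin_width: float) -> None:
    """Paired Kx / lx tables, one whitespace-delimited column per regime,
    padded with zeros to the longest-lived cohort."""
    from .lifetable import build_life_table

    tables = {lab: build_life_table(c, bin_width) for lab, c in cohorts.items()}
    n_rows = max(t.ages.size for t in tables.values())
    kx = pd.DataFrame(
        {lab: np.pad(t.alive, (0, n_rows - t.alive.size)) for lab, t in tables.items()}
    )
    lx = pd.DataFrame(
        {lab: np.pad(t.lx, (0, n_rows - t.lx.size)) for lab, t in tables.items()}
    )
    kx.to_csv(kx_path, sep="\t", index=False)
    lx.to_csv(lx_path, sep="\t", index=False, float_format="%.6f")
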