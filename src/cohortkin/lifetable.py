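"""Actuarial life tables from cohort ages-at-death.

A cohort is followed from age-synchronized emergence until every individual
has died, with deaths censused once per recording interval (daily in the
motivating moth experiments).  The life table tabulates, on the census grid,
the number still alive Kx, the proportion surviving lx = Kx / K0, the
per-interval conditional death rate, and the empirical cumulative hazard
H = -log lx.

Censoring is deliberately unsupported: the design follows all individuals to
death, and a right-censored entry would silently bias every downstream
quantity, so it is rejected instead.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "CohortData",
    "LifeTable",
    "build_life_table",
    "empirical_survivorship",
    "empirical_cumulative_hazard",
    "normalize_time",
    "read_life_table_txt",
    "read_ages",
    "write_life_table_tsv",
]


@dataclass(frozen=True)
class CohortData:
    """Ages at death for one experimental condition.

    ``ages_at_death`` are strictly positive times (days, or dimensionless
    after :func:`normalize_time`); ``label`` names the condition, e.g. a
    temperature regime.
    """

    ages_at_death: np.ndarray
    label: str
    time_unit: Literal["days", "normalized"] = "days"

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages_at_death, dtype=float)
        object.__setattr__(self, "ages_at_death", ages)
        if ages.size == 0:
            raise ValueError("cohort has no individuals")
        if not np.all(np.isfinite(ages)):
            raise ValueError("ages at death must be finite")
        if np.any(ages <= 0):
            raise ValueError("every age at death must be strictly positive")
        if not self.label or not self.label.strip():
            raise ValueError("cohort label must be nonblank")
        if self.time_unit not in ("days", "normalized"):
            raise ValueError(f"unknown time unit {self.time_unit!r}")

    @property
    def n(self) -> int:
        return int(self.ages_at_death.size)


@dataclass(frozen=True)
class LifeTable:
    """Census-grid survivorship of one cohort.

    ``ages`` is the strictly increasing grid starting at 0; ``alive[j]`` is
    the number of individuals whose age at death exceeds ``ages[j]``;
    ``lx = alive / alive[0]``; ``interval_hazard[j]`` is the conditional
    probability of dying in interval j per unit time given alive at its
    start (NaN once nobody is left).
    """

    ages: np.ndarray
    alive: np.ndarray
    label: str = "cohort"
    lx: np.ndarray = field(init=False)
    interval_hazard: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        alive = np.asarray(self.alive)
        if ages.size != alive.size or ages.size < 2:
            raise ValueError("ages and alive must be equal length >= 2")
        if ages[0] != 0 or np.any(np.diff(ages) <= 0):
            raise ValueError("age grid must start at 0 and strictly increase")
        if np.any(alive != np.round(alive)) or np.any(alive < 0):
            raise ValueError("alive counts must be nonnegative integers")
        alive = alive.astype(np.int64)
        if np.any(np.diff(alive) > 0):
            raise ValueError("alive counts must be nonincreasing")
        if alive[0] <= 0:
            raise ValueError("cohort size (alive[0]) must be positive")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "alive", alive)
        lx = alive / alive[0]
        widths = np.diff(ages)
        deaths = -np.diff(alive)
        with np.errstate(divide="ignore", invalid="ignore"):
            haz = deaths / (alive[:-1] * widths)
        haz = np.append(haz, np.nan)  # last grid point opens no interval
        object.__setattr__(self, "lx", lx)
        object.__setattr__(self, "interval_hazard", haz)

    @property
    def cohort_size(self) -> int:
        return int(self.alive[0])

    def to_frame(self) -> pd.DataFrame:
        H = np.where(self.lx > 0, -np.log(np.maximum(self.lx, 1e-300)), np.nan)
        return pd.DataFrame(
            {"age": self.ages, "alive": self.alive, "lx": self.lx, "H": H}
        )


def build_life_table(cohort: CohortData, bin_width: float = 1.0) -> LifeTable:
    """Census the cohort on a regular grid of width ``bin_width``.

    ``alive[j]`` counts individuals with age at death strictly greater than
    ``ages[j]``, matching a census where an individual recorded dead on day d
    died in (d-1, d].  Interval deaths always sum to the cohort size.
    """
    if not (np.isfinite(bin_width) and bin_width > 0):
        raise ValueError("bin_width must be a positive real")
    ages = cohort.ages_at_death
    n_bins = int(np.ceil(ages.max() / bin_width - 1e-12))
    grid = np.arange(n_bins + 1) * bin_width
    alive = np.array([(ages > t).sum() for t in grid])
    if alive[-1] != 0:  # death exactly on the last grid point already counted
        grid = np.append(grid, grid[-1] + bin_width)
        alive = np.append(alive, 0)
    return LifeTable(grid, alive, label=cohort.label)


def empirical_survivorship(table: LifeTable, t: float) -> float:
    """Step-function lx at the last census age <= t."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    j = int(np.searchsorted(table.ages, t, side="right")) - 1
    return float(table.lx[j])


def empirical_cumulative_hazard(table: LifeTable) -> pd.DataFrame:
    """H(age) = -log lx over the support (lx > 0).

    Returns columns ``age`` and ``H``; census points where the cohort is
    exhausted (lx == 0, H undefined) are dropped, and the result carries the
    flag ``attrs['truncated']`` saying whether any were.
    """
    mask = table.lx > 0
    out = pd.DataFrame({"age": table.ages[mask], "H": -np.log(table.lx[mask])})
    out.attrs["truncated"] = bool((~mask).any())
    return out


def normalize_time(cohort: CohortData) -> CohortData:
    """Rescale ages by the maximum observed age (dimensionless, max -> 1).

    Idempotent after the first application; an explicit opt-in, never
    applied automatically.
    """
    m = cohort.ages_at_death.max()
    return replace(
        cohort, ages_at_death=cohort.ages_at_death / m, time_unit="normalized"
    )


def read_ages(path, label: str | None = None) -> list[CohortData]:
    """Read ages at death from text.

    Two layouts: one age per line (single anonymous cohort, named by
    ``label`` or the file stem), or long-format CSV with header
    ``label,age`` (one cohort per distinct label, in order of appearance).
    """
    raw = pd.read_csv(path, sep=r"[,\t ]+", engine="python", header=None)
    first = raw.iloc[0]
    if not pd.to_numeric(first, errors="coerce").notna().all():
        cols = [str(v).strip().lower() for v in first]
        if cols != ["label", "age"]:
            raise ValueError(
                f"expected numeric ages or a 'label,age' header, got {cols}"
            )
        body = raw.iloc[1:]
        out = []
        for lab, grp in body.groupby(body.columns[0], sort=False):
            out.append(CohortData(grp.iloc[:, 1].to_numpy(float), str(lab)))
        return out
    ages = raw.to_numpy(float).ravel()
    name = label or getattr(path, "stem", None) or str(path)
    return [CohortData(ages, str(name))]


def read_life_table_txt(
    path, dialect: Literal["kx", "lx", "auto"] = "auto", bin_width: float = 1.0
) -> list[LifeTable]:
    """Parse a deposited survivorship table, one LifeTable per column.

    Kx columns hold integer counts alive at successive census ages; lx
    columns hold proportions in [0, 1] starting at 1.  ``dialect='auto'``
    treats a table whose first row is all 1.0 and whose entries never exceed
    1 as lx.  Columns may carry a header row of condition labels.  Parse
    errors name the offending row and column.
    """
    if isinstance(path, (str, bytes)) or hasattr(path, "read"):
        raw = pd.read_csv(path, sep=r"\s+|\t|,", engine="python", header=None)
    else:
        raw = pd.read_csv(str(path), sep=r"\s+|\t|,", engine="python", header=None)
    first = raw.iloc[0]
    has_header = not pd.to_numeric(first, errors="coerce").notna().all()
    if has_header:
        labels = [str(v) for v in first]
        body = raw.iloc[1:].reset_index(drop=True)
    else:
        labels = [f"col{j}" for j in range(raw.shape[1])]
        body = raw
    tables: list[LifeTable] = []
    for j in range(body.shape[1]):
        col = pd.to_numeric(body.iloc[:, j], errors="coerce")
        if col.isna().any():
            row = int(col.isna().idxmax()) + 1 + int(has_header)
            raise ValueError(
                f"non-numeric cell at row {row}, column {labels[j]!r}"
            )
        vals = col.to_numpy(float)
        if np.any(np.diff(vals) > 1e-12):
            row = int(np.argmax(np.diff(vals) > 1e-12)) + 2 + int(has_header)
            raise ValueError(
                f"survivorship increases at row {row}, column {labels[j]!r}"
            )
        is_lx = dialect == "lx" or (
            dialect == "auto" and vals.max() <= 1.0 + 1e-12
        )
        if is_lx:
            if vals.max() > 1.0 + 1e-12 or vals.min() < 0:
                bad = int(np.argmax((vals > 1) | (vals < 0))) + 1 + int(has_header)
                raise ValueError(
                    f"lx outside [0, 1] at row {bad}, column {labels[j]!r}"
                )
            if abs(vals[0] - 1.0) > 1e-9:
                raise ValueError(
                    f"lx must start at 1.0 in column {labels[j]!r}"
                )
            # recover counts: smallest cohort size under which every lx is
            # a whole number of individuals (exact for deposited tables)
            for scale in range(1, 1001):
                if np.allclose(vals * scale, np.round(vals * scale), atol=1e-6):
                    break
            else:
                scale = 10**6
            alive = np.round(vals * scale)
        else:
            if np.any(vals < 0) or np.any(vals != np.round(vals)):
                bad = int(np.argmax((vals < 0) | (vals != np.round(vals)))) + 1 + int(has_header)
                raise ValueError(
                    f"Kx must be nonnegative integers; bad cell at row {bad}, "
                    f"column {labels[j]!r}"
                )
            alive = vals
        ages = np.arange(len(alive)) * bin_width
        tables.append(LifeTable(ages, alive, label=labels[j]))
    return tables


def write_life_table_tsv(table: LifeTable, path) -> None:
    """Write columns age, alive, lx, H as TSV."""
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
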