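"""Coverage normalization and abundance contrasts across a 2x2 design.

The study design crossed operating temperature (mesophilic 35 C vs
thermophilic 55 C) with H2 injection (before vs after), giving four
conditions:

    C1  mesophilic, pre-H2       C2  mesophilic, post-H2
    C3  thermophilic, pre-H2     C4  thermophilic, post-H2

Per-PG mean read coverage in each condition is the abundance proxy.  After
depth normalization (scaling every sample to the read total of the
shallowest sample), abundance change is expressed as six pairwise log2
ratios:

    (i)   mean_thermo_meso  = log2((C3+C4)/(C1+C2))
    (ii)  mean_post_pre     = log2((C2+C4)/(C1+C3))
    (iii) meso_post_pre     = log2(C2/C1)
    (iv)  thermo_post_pre   = log2(C4/C3)
    (v)   pre_thermo_meso   = log2(C3/C1)
    (vi)  post_thermo_meso  = log2(C4/C2)

Base 2 makes the printed contrasts directly interpretable as fold changes
(a contrast of -4.65 is a 25-fold drop).  A small pseudocount keeps ratios
defined when a PG is absent from a condition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ValidationError

__all__ = [
    "CONTRAST_NAMES",
    "CONDITIONS",
    "CoverageMatrix",
    "ContrastVector",
    "Chi2Result",
    "normalize_coverage",
    "compute_contrasts",
    "contrast_table",
    "fold_change",
    "classify_sd_bands",
    "band_table",
    "flag_abundant",
    "temperature_partition",
    "chi_square_or",
]

CONDITIONS = ("C1", "C2", "C3", "C4")

#: The six contrast variables, in the conventional (i)-(vi) order.
CONTRAST_NAMES = (
    "mean_thermo_meso",
    "mean_post_pre",
    "meso_post_pre",
    "thermo_post_pre",
    "pre_thermo_meso",
    "post_thermo_meso",
)

DEFAULT_PSEUDOCOUNT = 0.01
ABUNDANCE_THRESHOLD = 5.0


@dataclass
class CoverageMatrix:
    """PG x sample coverage with per-sample read totals.

    `values` is a DataFrame indexed by pg_id with one column per sample;
    `read_totals` a Series over the same samples.  `normalized` records
    whether depth normalization has been applied.
    """

    values: pd.DataFrame
    read_totals: pd.Series
    normalized: bool = False

    def __post_init__(self) -> None:
        self.read_totals = self.read_totals.reindex(self.values.columns)
        if self.read_totals.isna().any():
            missing = list(self.read_totals.index[self.read_totals.isna()])
            raise ValidationError(f"read totals missing for samples {missing}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("coverage values must be non-negative")

    @property
    def pg_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def normalize_coverage(m: CoverageMatrix) -> CoverageMatrix:
    """Depth-normalize: scale each sample to the shallowest sample's reads.

    Each column is multiplied by min(read_totals) / its own read total, so
    the reference (lowest-total) sample is unchanged and within-column ranks
    are preserved.
    """
    if m.normalized:
        raise ValidationError("coverage matrix is already normalized")
    totals = m.read_totals.astype(float)
    if (totals <= 0).any():
        raise ValidationError("read totals must be positive")
    scale = totals.min() / totals
    return CoverageMatrix(
        values=m.values.mul(scale, axis=1),
        read_totals=m.read_totals.copy(),
        normalized=True,
    )


@dataclass(frozen=True)
class ContrastVector:
    """The six log2 contrast variables for one PG, plus signed SD bands."""

    pg_id: str
    v: tuple[float, float, float, float, float, float]
    bands: tuple[int, int, int, int, int, int] | None = None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CONTRAST_NAMES, self.v))


def compute_contrasts(
    c1: float,
    c2: float,
    c3: float,
    c4: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    pg_id: str = "",
) -> ContrastVector:
    """Six log2 coverage ratios for one PG across the four conditions.

    The pseudocount (> 0) is added to each of the four coverages before any
    ratio is formed, keeping every contrast finite.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    cov = np.array([c1, c2, c3, c4], dtype=float)
    if (cov < 0).any():
        raise ValidationError("coverages must be non-negative")
    a1, a2, a3, a4 = cov + pseudocount
    v = (
        math.log2((a3 + a4) / (a1 + a2)),
        math.log2((a2 + a4) / (a1 + a3)),
        math.log2(a2 / a1),
        math.log2(a4 / a3),
        math.log2(a3 / a1),
        math.log2(a4 / a2),
    )
    return ContrastVector(pg_id=pg_id, v=v)


def contrast_table(
    m: CoverageMatrix,
    design: dict[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-PG contrast variables for a whole coverage matrix.

    `design` maps sample_id -> condition label in {C1..C4}; exactly one
    sample per condition.  Returns a DataFrame indexed by pg_id with the six
    contrast columns.
    """
    by_cond: dict[str, str] = {}
    for sample, cond in design.items():
        if cond not in CONDITIONS:
            raise ValidationError(f"unknown condition {cond!r} for sample {sample!r}")
        if cond in by_cond:
            raise ValidationError(f"condition {cond} assigned to multiple samples")
        by_cond[cond] = sample
    missing = [c for c in CONDITIONS if c not in by_cond]
    if missing:
        raise ValidationError(f"design lacks samples for conditions {missing}")
    rows = {}
    for pg in m.values.index:
        cv = compute_contrasts(
            *(float(m.values.at[pg, by_cond[c]]) for c in CONDITIONS),
            pseudocount=pseudocount,
            pg_id=str(pg),
        )
        rows[pg] = cv.v
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(CONTRAST_NAMES)
    ).rename_axis("pg_id")


def fold_change(v: float) -> tuple[str, float]:
    """Convert one log2 contrast to (direction, linear fold magnitude).

    direction is 'increase', 'decrease' or 'none'; magnitude is 2**|v|
    (so -2.98 becomes an ~8-fold decrease).
    """
    if not math.isfinite(v):
        raise ValidationError("contrast must be finite")
    if v == 0:
        return ("none", 1.0)
    return ("increase" if v > 0 else "decrease", 2.0 ** abs(v))


def classify_sd_bands(values) -> np.ndarray:
    """Signed SD-exceedance band for each value of one contrast variable.

    Band = sign(v - mean) * min(3, floor(|v - mean| / SD)) with the sample
    (n-1) standard deviation over the whole PG population; roughly 68% of a
    normal population lands in band 0, and bands saturate at +/-3.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2 or not np.isfinite(arr).all():
        raise ValidationError("need >= 2 finite values to band")
    sd = arr.std(ddof=1)
    if sd == 0:
        warnings.warn("zero standard deviation: all bands set to 0", stacklevel=2)
        return np.zeros(arr.size, dtype=int)
    dev = arr - arr.mean()
    return (np.sign(dev) * np.minimum(3, np.floor(np.abs(dev) / sd))).astype(int)


def band_table(contrasts: pd.DataFrame) -> pd.DataFrame:
    """SD bands per contrast variable (banded per column, not pooled)."""
    return pd.DataFrame(
        {col: classify_sd_bands(contrasts[col].to_numpy()) for col in contrasts.columns},
        index=contrasts.index,
    )


def flag_abundant(coverages, threshold: float = ABUNDANCE_THRESHOLD) -> bool:
    """A PG is abundant when its normalized coverage exceeds the threshold
    (strictly) in at least one condition."""
    return bool((np.asarray(coverages, dtype=float) > threshold).any())


def temperature_partition(
    mean_thermo_meso, threshold: float = 1.0
) -> np.ndarray:
    """Label each PG meso / thermo / neither by its temperature contrast.

    A PG prefers one temperature when its |mean_thermo_meso| contrast exceeds
    the threshold (default 1 log2 unit, i.e. a > 2-fold change; strict).
    """
    v = np.asarray(mean_thermo_meso, dtype=float)
    labels = np.full(v.shape, "neither", dtype=object)
    labels[v > threshold] = "thermo"
    labels[v < -threshold] = "meso"
    return labels


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe 0.5 applied to OR/CI (some zero cell)


def chi_square_or(a: float, b: float, c: float, d: float) -> Chi2Result:
    """Pearson chi-square (no continuity correction) with odds ratio and CI.

    For the 2x2 table [[a, b], [c, d]]: OR = ad/bc, 95% CI by Woolf's
    log-OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d).  A zero cell triggers the
    Haldane-Anscombe correction (0.5 added to every cell) for the OR and CI
    only; the chi-square itself uses the raw counts.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValidationError("counts must be non-negative")
    if table.sum() == 0:
        raise ValidationError("all-zero 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("2x2 table has an empty row or column")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    corrected = bool((table == 0).any())
    t = table + 0.5 if corrected else table
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    se = math.sqrt((1.0 / t).sum())
    log_or = math.log(odds)
    return Chi2Result(
        chi2=float(chi2),
        p=float(p),
        odds_ratio=float(odds),
        ci_low=math.exp(log_or - 1.96 * se),
        ci_high=math.exp(log_or + 1.96 * se),
        corrected=corrected,
    )
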