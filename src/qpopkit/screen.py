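"""Screening-arm and ancillary statistics.

Covers the single-dose library screen (median-viability ranking with hit
calling), xenograft tumor-volume geometry and growth rates, and the
basal-pathway-score vs drug-sensitivity correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenResult",
    "TumorMeasurement",
    "GrowthRateFit",
    "screen_rank",
    "tumor_volume",
    "growth_rate",
    "pathway_score",
    "pathway_sensitivity_correlation",
]


@dataclass(frozen=True)
class ScreenResult:
    """Per-drug median viability across lines, ascending, with hit calls."""

    medians: pd.Series  # index: drug, sorted ascending (ties by name)
    hits: tuple[str, ...]
    hit_threshold: float


def screen_rank(
    viability_matrix: pd.DataFrame, hit_threshold: float = 0.5
) -> ScreenResult:
    """Rank drugs by median viability over cell lines (rows: drugs,
    columns: lines); hits reduce median viability below the threshold.

    Medians over an even number of lines use the standard midpoint of the
    two central values.
    """
    if viability_matrix.empty:
        raise ValueError("viability matrix is empty")
    if not np.isfinite(viability_matrix.to_numpy(dtype=float)).all():
        raise ValueError("viability matrix must be finite")
    med = viability_matrix.median(axis=1)
    # stable sort after name-ordering breaks median ties by drug name
    med = med.sort_index(kind="mergesort").sort_values(kind="mergesort")
    hits = tuple(med.index[med < hit_threshold])
    return ScreenResult(medians=med, hits=hits, hit_threshold=hit_threshold)


@dataclass(frozen=True)
class TumorMeasurement:
    """One caliper measurement; volume from V = pi/6 * A^2 * B."""

    day: float
    A: float  # smallest superficial diameter, mm
    B: float  # largest superficial diameter, mm

    def __post_init__(self) -> None:
        tumor_volume(self.A, self.B)  # validates ordering/positivity

    @property
    def volume(self) -> float:
        return tumor_volume(self.A, self.B)


def tumor_volume(A: float, B: float) -> float:
    """Ellipsoid-approximation volume in mm^3 from the two superficial
    diameters, A the smallest and B the largest."""
    if A <= 0 or B <= 0:
        raise ValueError("diameters must be positive")
    if A > B:
        raise ValueError(
            f"A ({A}) must be the smallest diameter; got A > B ({B})"
        )
    return float(np.pi / 6.0 * A**2 * B)


@dataclass(frozen=True)
class GrowthRateFit:
    slope: float  # mm^3/day, or 1/day on the log scale
    stderr: float
    ci_low: float
    ci_high: float
    log_scale: bool


def growth_rate(
    measurements: list[TumorMeasurement], log_scale: bool = False
) -> GrowthRateFit:
    """OLS slope of (log-)volume against day with a 95% CI."""
    if len(measurements) < 3:
        raise ValueError("growth rate needs >= 3 time points")
    days = np.array([m.day for m in measurements], dtype=float)
    vols = np.array([m.volume for m in measurements], dtype=float)
    y = np.log(vols) if log_scale else vols
    res = stats.linregress(days, y)
    tcrit = stats.t.ppf(0.975, len(days) - 2)
    return GrowthRateFit(
        slope=float(res.slope),
        stderr=float(res.stderr),
        ci_low=float(res.slope - tcrit * res.stderr),
        ci_high=float(res.slope + tcrit * res.stderr),
        log_scale=log_scale,
    )


def pathway_score(
    pjnk_over_jnk: float,
    cjun: float,
    ref_pjnk_over_jnk: float = 1.0,
    ref_cjun: float = 1.0,
    per_component: bool = True,
) -> float:
    """Basal JNK-pathway activity: sum of p-JNK/JNK and c-Jun abundance,
    normalized to a reference line (per component by default, or by the
    summed reference)."""
    if per_component:
        return pjnk_over_jnk / ref_pjnk_over_jnk + cjun / ref_cjun
    return (pjnk_over_jnk + cjun) / (ref_pjnk_over_jnk + ref_cjun)


def pathway_sensitivity_correlation(
    table: pd.DataFrame,
    score_col: str = "pathway_score",
    ic50_col: str = "ic50_uM",
    exclusions: list[str] | None = None,
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between per-line pathway score and
    combination IC50.  ``exclusions`` drops named lines explicitly —
    never automatically — from the indexed table."""
    data = table.drop(index=exclusions or [], errors="raise")
    if len(data) < 3:
        raise ValueError("correlation needs >= 3 paired observations")
    x = data[score_col].to_numpy(dtype=float)
    y = data[ic50_col].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
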