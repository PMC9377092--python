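"""Chou-Talalay combination-index and dose-reduction-index profiles.

Given median-effect fits for two single agents and for the fixed-ratio
combination (on total dose), the combination index at a fraction
affected fa is

    CI(fa) = D1/Dx1 + D2/Dx2          (mutually exclusive form)

where (D1, D2) are the component doses of the combination producing fa
and Dx_i the isoeffective single-agent dose.  CI < 1 indicates synergy,
CI = 1 additivity, CI > 1 antagonism.  The dose reduction index
DRI_i = Dx_i / D_i (> 1 favorable) satisfies CI = 1/DRI1 + 1/DRI2
identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_response import (
    DoseResponsePoint,
    MedianEffectCurve,
    fit_median_effect,
    inhibitory_concentration,
)

__all__ = [
    "CIProfile",
    "fit_fixed_ratio_combo",
    "combination_index",
    "dose_reduction_index",
    "summarize_ci_across_lines",
    "ci_dose_ladder",
    "ratio_from_concentrations",
    "DEFAULT_FA_GRID",
]

DEFAULT_FA_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))

_RATIO_TOL = 1e-8


@dataclass(frozen=True)
class CIProfile:
    """CI and per-drug DRI indexed by fraction affected, for one line."""

    cell_line: str
    fa_grid: np.ndarray
    ci_values: np.ndarray
    dri_a: np.ndarray
    dri_b: np.ndarray
    ratio: tuple[float, float]
    curve_a: MedianEffectCurve
    curve_b: MedianEffectCurve
    curve_combo: MedianEffectCurve

    def ci_at(self, fa: float) -> float:
        idx = int(np.argmin(np.abs(self.fa_grid - fa)))
        if abs(self.fa_grid[idx] - fa) > 1e-9:
            raise KeyError(f"fa={fa} not on the profile grid")
        return float(self.ci_values[idx])


def _check_ratio(ratio: tuple[float, float]) -> tuple[float, float]:
    ra, rb = (float(r) for r in ratio)
    if ra <= 0 or rb <= 0:
        raise ValueError("ratio components must be positive")
    if abs(ra + rb - 1.0) > _RATIO_TOL:
        raise ValueError(f"ratio must sum to 1, got {ra + rb}")
    return ra, rb


def fit_fixed_ratio_combo(
    points: list[DoseResponsePoint], ratio: tuple[float, float]
) -> MedianEffectCurve:
    """Median-effect fit of a fixed-ratio combination on its total dose."""
    _check_ratio(ratio)
    return fit_median_effect(points)


def ci_dose_ladder(
    center_dose: float, n_doses: int = 7, factor: float = 2.0
) -> np.ndarray:
    """Serial-dilution doses bracketing an anticipated median-effect dose.

    The classic combination-index assay doses by ``factor``-fold serial
    dilution around the expected IC50 (default 7 doses, Dm/8 .. 8*Dm), so
    every point carries fractional effects well inside (0, 1).  Doses far
    above the IC50 measure mostly noise (viability near zero) and
    destabilize the linearized median-effect fit.
    """
    if center_dose <= 0:
        raise ValueError("center dose must be positive")
    if n_doses < 2:
        raise ValueError("need at least 2 doses")
    lo = -((n_doses - 1) // 2)
    exponents = np.arange(lo, lo + n_doses)
    return center_dose * factor**exponents.astype(float)


def ratio_from_concentrations(conc_a: float, conc_b: float) -> tuple[float, float]:
    """Normalize a concentration pair (e.g. a ranking's optimum doses) to a
    dose ratio summing to 1."""
    if conc_a <= 0 or conc_b <= 0:
        raise ValueError("both concentrations must be positive to define a ratio")
    total = conc_a + conc_b
    return conc_a / total, conc_b / total


def _doses_at(curve: MedianEffectCurve, fa: np.ndarray) -> np.ndarray:
    return np.array([inhibitory_concentration(curve, 100.0 * f) for f in fa])


def combination_index(
    curve_a: MedianEffectCurve,
    curve_b: MedianEffectCurve,
    combo_curve: MedianEffectCurve,
    ratio: tuple[float, float],
    fa_grid=DEFAULT_FA_GRID,
    cell_line: str = "",
) -> CIProfile:
    """CI(fa) over a grid, mutually exclusive (two-term) form."""
    ra, rb = _check_ratio(ratio)
    fa = np.asarray(fa_grid, dtype=float)
    if np.any((fa <= 0) | (fa >= 1)):
        raise ValueError("fa grid must lie strictly in (0, 1)")
    d_tot = _doses_at(combo_curve, fa)
    d_a, d_b = d_tot * ra, d_tot * rb
    dx_a = _doses_at(curve_a, fa)
    dx_b = _doses_at(curve_b, fa)
    ci = d_a / dx_a + d_b / dx_b
    return CIProfile(
        cell_line=cell_line,
        fa_grid=fa,
        ci_values=ci,
        dri_a=dx_a / d_a,
        dri_b=dx_b / d_b,
        ratio=(ra, rb),
        curve_a=curve_a,
        curve_b=curve_b,
        curve_combo=combo_curve,
    )


def dose_reduction_index(
    curve_a: MedianEffectCurve,
    curve_b: MedianEffectCurve,
    combo_curve: MedianEffectCurve,
    ratio: tuple[float, float],
    fa_grid=DEFAULT_FA_GRID,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-drug DRI(fa) = isoeffective single dose / combination dose."""
    profile = combination_index(curve_a, curve_b, combo_curve, ratio, fa_grid)
    return profile.dri_a, profile.dri_b


def summarize_ci_across_lines(profiles: list[CIProfile]):
    """Per-fa median, min and max CI across a cohort of lines.

    Returns a record array-like dict of columns: fa, median_ci, min_ci,
    max_ci — the table behind a median-and-range Fa-CI plot.
    """
    if not profiles:
        raise ValueError("need at least one CI profile")
    grid = profiles[0].fa_grid
    for p in profiles[1:]:
        if not np.allclose(p.fa_grid, grid):
            raise ValueError("profiles must share a common fa grid")
    ci = np.vstack([p.ci_values for p in profiles])
    return {
        "fa": grid.copy(),
        "median_ci": np.median(ci, axis=0),
        "min_ci": ci.min(axis=0),
        "max_ci": ci.max(axis=0),
    }
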