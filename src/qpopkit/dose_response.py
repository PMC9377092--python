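"""Dose-response curve fitting: median-effect and four-parameter logistic.

The median-effect equation fa/fu = (D/Dm)^m (fa = fraction affected,
fu = 1 - fa) is linear in log-log coordinates, so the canonical fit is
ordinary least squares of log(fa/fu) on log(D).  Dm is the dose giving
half-maximal effect and m the sigmoidicity.  ICx anchors used by the
combinatorial design (IC0/IC10/IC20) and the Chou-Talalay module both
come from this curve.  A 4-parameter logistic is provided for screen-style
IC50 extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DoseResponsePoint",
    "MedianEffectCurve",
    "FourParamLogisticFit",
    "normalize_viability",
    "fit_median_effect",
    "inhibitory_concentration",
    "fit_four_param_logistic",
]

_FA_CLIP = 1e-4


class InsufficientDataError(ValueError):
    """Too few informative points to fit a curve."""


@dataclass(frozen=True)
class DoseResponsePoint:
    dose: float  # uM
    viability: float  # vehicle-normalized fraction
    replicate: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.viability):
            raise ValueError("viability must be finite")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


@dataclass(frozen=True)
class MedianEffectCurve:
    """Median-effect parameters with linearized-fit diagnostics."""

    Dm: float  # median-effect dose, uM
    m: float  # slope
    r2: float
    n_points: int

    def fraction_affected(self, dose: float) -> float:
        """fa(D) = 1 / (1 + (Dm/D)^m); fa(0) = 0."""
        dose = float(dose)
        if dose < 0:
            raise ValueError("dose must be >= 0")
        if dose == 0:
            return 0.0
        return 1.0 / (1.0 + (self.Dm / dose) ** self.m)

    def viability(self, dose: float) -> float:
        return 1.0 - self.fraction_affected(dose)


def normalize_viability(raw_signal: float, vehicle_mean: float) -> float:
    """Vehicle-normalized viability; values above 1 are deliberately kept."""
    if vehicle_mean <= 0:
        raise ValueError(f"vehicle mean must be > 0, got {vehicle_mean}")
    return raw_signal / vehicle_mean


def _informative_mask(doses: np.ndarray, fa: np.ndarray) -> np.ndarray:
    # points whose fa would be clipped at either end carry no slope
    # information in logit coordinates and are excluded
    return (doses > 0) & (fa > _FA_CLIP) & (fa < 1 - _FA_CLIP)


def fit_median_effect(points: list[DoseResponsePoint]) -> MedianEffectCurve:
    """OLS of log(fa/fu) on log(dose) over informative points.

    Replicates are fitted pooled rather than pre-averaged, preserving
    error degrees of freedom in r2.
    """
    doses = np.array([p.dose for p in points], dtype=float)
    fa = 1.0 - np.array([p.viability for p in points], dtype=float)
    mask = _informative_mask(doses, fa)
    if np.unique(doses[mask]).size < 2:
        raise InsufficientDataError(
            "median-effect fit needs >= 2 distinct informative doses "
            f"(got {np.unique(doses[mask]).size})"
        )
    x = np.log(doses[mask])
    y = np.log(fa[mask] / (1.0 - fa[mask]))
    res = stats.linregress(x, y)
    m = res.slope
    Dm = float(np.exp(-res.intercept / m))
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return MedianEffectCurve(Dm=Dm, m=float(m), r2=r2, n_points=int(mask.sum()))


def inhibitory_concentration(curve: MedianEffectCurve, x_percent: float) -> float:
    """ICx from the median-effect equation: Dm * (x/(100-x))^(1/m).

    IC0 is 0 by convention (no measurable inhibition = drug absent).
    """
    if not 0 <= x_percent < 100:
        raise ValueError(f"x_percent must be in [0, 100), got {x_percent}")
    if x_percent == 0:
        return 0.0
    return float(curve.Dm * (x_percent / (100.0 - x_percent)) ** (1.0 / curve.m))


@dataclass(frozen=True)
class FourParamLogisticFit:
    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    r2: float
    warnings: tuple[str, ...] = field(default_factory=tuple)


def fit_four_param_logistic(points: list[DoseResponsePoint]) -> FourParamLogisticFit:
    """Nonlinear least squares of v = bottom + (top-bottom)/(1+(D/IC50)^hill).

    Bounds 0 <= bottom <= top <= 1.5 mirror vehicle-normalized viability;
    a non-positive fitted hill (viability rising with dose) is flagged in
    ``warnings`` rather than rejected.
    """
    doses = np.array([p.dose for p in points], dtype=float)
    v = np.array([p.viability for p in points], dtype=float)
    if np.unique(doses).size < 4:
        raise InsufficientDataError("4PL fit needs >= 4 distinct doses")

    def model(d, top, bottom, ic50, hill):
        with np.errstate(divide="ignore", over="ignore"):
            ratio = np.where(d > 0, (d / ic50) ** hill, 0.0)
        return bottom + (top - bottom) / (1.0 + ratio)

    pos = doses[doses > 0]
    ic50_guess = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
    p0 = (min(float(v.max()), 1.5), max(float(v.min()), 0.0), ic50_guess, 1.0)
    try:
        popt, _ = optimize.curve_fit(
            model,
            doses,
            v,
            p0=p0,
            bounds=([0.0, 0.0, 1e-12, -10.0], [1.5, 1.5, 1e6, 10.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"4PL fit did not converge: {exc}") from exc
    top, bottom, ic50, hill = (float(x) for x in popt)
    resid = v - model(doses, *popt)
    rss = float(resid @ resid)
    tss = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    warns: list[str] = []
    if bottom > top:
        top, bottom = bottom, top
        warns.append("top/bottom swapped to restore ordering")
    if hill <= 0:
        warns.append("non-positive hill slope: viability increases with dose")
    return FourParamLogisticFit(
        top=top, bottom=bottom, ic50=ic50, hill=hill, rss=rss, r2=r2,
        warnings=tuple(warns),
    )
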