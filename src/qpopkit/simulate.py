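"""Synthetic tumor-organoid cohorts with known pharmacology.

Ground truth per cell line: Hill-type single-drug survival
s_i(D) = 1 / (1 + (D/Dm_i)^m_i), Bliss-independent baseline
v0 = prod_i s_i, and a pairwise interaction multiplier

    M = exp(-sum_{i<j} gamma_ij * (1 - s_i) * (1 - s_j)),

so gamma > 0 plants synergy that vanishes whenever either drug is absent
(required for IC0-anchored designs).  Measurement noise is additive
Gaussian on viability, truncated at 0.  The default cohort emulates an
18-line tumor-organoid panel plus one less-sensitive non-tumorigenic
reference line, with log-normal between-line jitter on (Dm, m).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DrugDoseSpec, OACDDesign, map_design_to_concentrations
from .dose_response import MedianEffectCurve, inhibitory_concentration
from .qpop import QuadraticSurface

__all__ = [
    "GroundTruthModel",
    "DEFAULT_DRUG_PANEL",
    "simulate_viability",
    "simulate_oacd_experiment",
    "simulate_quadratic_truth",
    "simulate_dose_response_series",
    "default_dose_ladder",
    "make_cohort",
    "dose_specs_from_panel",
]

# Nine-drug panel: proteasome inhibitors, a CDK inhibitor, multi-kinase
# inhibitors and chemotherapy agents, with order-of-magnitude realistic
# potencies (Dm in uM) and Hill slopes.
DEFAULT_DRUG_PANEL: dict[str, tuple[float, float]] = {
    "ixazomib": (0.1, 1.5),
    "carfilzomib": (0.03, 1.8),
    "dinaciclib": (0.01, 1.5),
    "sorafenib": (4.0, 1.2),
    "regorafenib": (5.0, 1.2),
    "lenvatinib": (8.0, 1.0),
    "cabozantinib": (6.0, 1.1),
    "oxaliplatin": (10.0, 1.0),
    "fluorouracil": (15.0, 0.9),
}


@dataclass(frozen=True)
class GroundTruthModel:
    """Known pharmacology of one simulated cell line."""

    cell_line: str
    per_drug: dict[str, tuple[float, float]]  # drug -> (Dm uM, m)
    gamma: np.ndarray  # symmetric pairwise interaction, zero diagonal
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        k = len(self.per_drug)
        if g.shape != (k, k):
            raise ValueError(f"gamma must be {k}x{k}")
        if not np.allclose(g, g.T) or np.any(np.diag(g) != 0):
            raise ValueError("gamma must be symmetric with zero diagonal")
        for drug, (dm, m) in self.per_drug.items():
            if dm <= 0 or m <= 0:
                raise ValueError(f"Dm and m must be positive for {drug!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "gamma", g)

    @property
    def drugs(self) -> list[str]:
        return list(self.per_drug)


def simulate_viability(model: GroundTruthModel, doses: dict[str, float] | np.ndarray) -> float:
    """Expected (noise-free) viability at the given per-drug doses (uM)."""
    names = model.drugs
    if isinstance(doses, dict):
        d = np.array([doses.get(name, 0.0) for name in names], dtype=float)
    else:
        d = np.asarray(doses, dtype=float)
        if d.shape != (len(names),):
            raise ValueError(f"expected {len(names)} doses")
    if np.any(d < 0):
        raise ValueError("doses must be >= 0")
    dm = np.array([model.per_drug[n][0] for n in names])
    m = np.array([model.per_drug[n][1] for n in names])
    with np.errstate(divide="ignore"):
        s = 1.0 / (1.0 + (d / dm) ** m)
    v0 = float(np.prod(s))
    effect = 1.0 - s
    interaction = 0.0
    for i, j in itertools.combinations(range(len(names)), 2):
        interaction += model.gamma[i, j] * effect[i] * effect[j]
    return float(np.clip(v0 * np.exp(-interaction), 0.0, 1.0))


def simulate_oacd_experiment(
    model: GroundTruthModel,
    concentrations: pd.DataFrame,
    replicates: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Plate records for a concentration-mapped design.

    Columns: run_id, cell_line, replicate, viability.  Noise is additive
    N(0, noise_sd) truncated at 0; seeded and reproducible.
    """
    rng = np.random.default_rng(seed)
    expected = np.array(
        [
            simulate_viability(model, row[model.drugs].to_dict())
            for _, row in concentrations.iterrows()
        ]
    )
    rows = []
    for rep in range(replicates):
        noisy = expected + rng.normal(0.0, model.noise_sd, size=expected.size)
        noisy = np.clip(noisy, 0.0, None)
        for run_id, v in zip(concentrations.index, noisy):
            rows.append(
                {
                    "run_id": run_id,
                    "cell_line": model.cell_line,
                    "replicate": rep,
                    "viability": v,
                }
            )
    return pd.DataFrame(rows)


def simulate_quadratic_truth(
    surface: QuadraticSurface, design: OACDDesign, noise_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Evaluate a known polynomial on the design and add Gaussian noise —
    the round-trip oracle for the surface fitter."""
    if surface.n_factors != design.n_factors:
        raise ValueError("surface and design dimensions differ")
    rng = np.random.default_rng(seed)
    y = surface.predict(design.runs.astype(float))
    return y + rng.normal(0.0, noise_sd, size=y.size)


def default_dose_ladder(n: int = 9) -> np.ndarray:
    """Log-spaced doses from 1e-4 to 100 uM, the standard screen range."""
    return np.logspace(-4, 2, n)


def simulate_dose_response_series(
    model: GroundTruthModel,
    drug: str | tuple[str, str],
    doses: np.ndarray | None = None,
    ratio: tuple[float, float] | None = None,
    replicates: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-agent or fixed-ratio-combination viability series.

    For a pair, ``doses`` are total doses split by ``ratio``.  Columns:
    cell_line, drug, dose_uM, replicate, viability, ratio_a.
    """
    if doses is None:
        doses = default_dose_ladder()
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(drug, str):
        name = drug
        dose_maps = [{name: d} for d in doses]
        ratio_a = np.nan
    else:
        drug_a, drug_b = drug
        if ratio is None:
            raise ValueError("fixed-ratio series needs a ratio")
        ra, rb = ratio
        if abs(ra + rb - 1.0) > 1e-8:
            raise ValueError("ratio must sum to 1")
        name = f"{drug_a}+{drug_b}"
        if drug_a == drug_b:
            # sham self-combination: component doses add up
            dose_maps = [{drug_a: d * (ra + rb)} for d in doses]
        else:
            dose_maps = [{drug_a: d * ra, drug_b: d * rb} for d in doses]
        ratio_a = ra
    expected = np.array([simulate_viability(model, dm) for dm in dose_maps])
    rows = []
    for rep in range(replicates):
        noisy = np.clip(
            expected + rng.normal(0.0, model.noise_sd, size=expected.size), 0.0, None
        )
        for d, v in zip(doses, noisy):
            rows.append(
                {
                    "cell_line": model.cell_line,
                    "drug": name,
                    "dose_uM": d,
                    "replicate": rep,
                    "viability": v,
                    "ratio_a": ratio_a,
                }
            )
    return pd.DataFrame(rows)


def make_cohort(
    n_tumor_lines: int = 18,
    drug_panel: dict[str, tuple[float, float]] | None = None,
    planted_pair: tuple[str, str] = ("ixazomib", "dinaciclib"),
    gamma_strength: float = 2.0,
    heterogeneity_cv: float = 0.0,
    noise_sd: float = 0.05,
    normal_resistance: float = 5.0,
    seed: int = 0,
) -> tuple[list[GroundTruthModel], GroundTruthModel]:
    """Tumor cohort plus one normal reference line.

    The default cohort is pharmacologically homogeneous, so the planted
    pair's interaction is the only systematic between-pair signal — the
    setting in which ground truth unambiguously ranks the planted pair
    first in every line and recovery checks are well-posed.  Set
    ``heterogeneity_cv`` > 0 to jitter per-line (Dm, m) log-normally with
    that coefficient of variation (beyond roughly 0.05 the jitter itself
    reorders pairs line by line, which is realistic cohort behaviour but
    no longer a pure recovery setting).  The planted pair receives
    interaction gamma_strength in tumor lines only.  The normal line's Dm
    values are uniformly ``normal_resistance``-fold larger (less
    drug-sensitive), emulating the tumor-selectivity premise of the delta
    output.
    """
    panel = dict(drug_panel or DEFAULT_DRUG_PANEL)
    names = list(panel)
    for drug in planted_pair:
        if drug not in panel:
            raise ValueError(f"planted drug {drug!r} not in the panel")
    if heterogeneity_cv < 0:
        raise ValueError("heterogeneity_cv must be >= 0")
    rng = np.random.default_rng(seed)
    k = len(names)
    ia, ib = names.index(planted_pair[0]), names.index(planted_pair[1])
    sigma = np.sqrt(np.log1p(heterogeneity_cv**2))  # log-normal with given CV

    tumor_lines = []
    for li in range(n_tumor_lines):
        per_drug = {}
        for name in names:
            dm, m = panel[name]
            per_drug[name] = (
                dm * np.exp(rng.normal(0.0, sigma)),
                m * np.exp(rng.normal(0.0, sigma)),
            )
        gamma = np.zeros((k, k))
        gamma[ia, ib] = gamma[ib, ia] = gamma_strength
        tumor_lines.append(
            GroundTruthModel(
                cell_line=f"PDXO{li + 1}",
                per_drug=per_drug,
                gamma=gamma,
                noise_sd=noise_sd,
                seed=seed,
            )
        )
    normal = GroundTruthModel(
        cell_line="THLE-2",
        per_drug={n: (dm * normal_resistance, m) for n, (dm, m) in panel.items()},
        gamma=np.zeros((k, k)),
        noise_sd=noise_sd,
        seed=seed,
    )
    return tumor_lines, normal


def dose_specs_from_panel(
    panel: dict[str, tuple[float, float]] | None = None,
) -> list[DrugDoseSpec]:
    """IC0/IC10/IC20 dose specs from panel-level median-effect parameters.

    Mirrors anchoring the coded levels on cohort-wide dose-response
    curves: level -1 -> 0 uM (IC0), level 0 -> IC10, level +1 -> IC20.
    """
    panel = dict(panel or DEFAULT_DRUG_PANEL)
    specs = []
    for name, (dm, m) in panel.items():
        curve = MedianEffectCurve(Dm=dm, m=m, r2=1.0, n_points=0)
        specs.append(
            DrugDoseSpec(
                drug_name=name,
                conc_at_level={
                    -1: 0.0,
                    0: inhibitory_concentration(curve, 10.0),
                    1: inhibitory_concentration(curve, 20.0),
                },
                source_curve=curve,
            )
        )
    return specs


def simulate_cohort_plates(
    tumor_lines: list[GroundTruthModel],
    normal: GroundTruthModel,
    design: OACDDesign,
    specs: list[DrugDoseSpec],
    replicates: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Plate table for every cohort line over one concentration-mapped design.

    Each line gets an independent noise stream (seed offset by its cohort
    position); the normal line is measured once, so its plate noise is
    shared by every tumor line's therapeutic output, as in a real screen
    with a single control line.
    """
    conc = map_design_to_concentrations(design, specs)
    frames = []
    for i, model in enumerate([*tumor_lines, normal]):
        frames.append(
            simulate_oacd_experiment(model, conc, replicates=replicates, seed=seed + i)
        )
    return pd.concat(frames, ignore_index=True)
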