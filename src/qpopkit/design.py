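"""Orthogonal array composite designs (OACD) for combinatorial dosing.

An OACD concatenates a three-level orthogonal array (here the L27(3^13)
strength-2 array) with a regular two-level fractional factorial.  The
composite supports estimation of a full second-order polynomial in the
coded dose levels with far fewer runs than a full 3^k factorial: for nine
drugs the design has 27 + 128 = 155 runs against 55 model coefficients.

Coded levels are -1 / 0 / +1 and, for dosing applications, map to the
IC0 / IC10 / IC20 concentrations of each drug (IC0 conventionally 0 uM,
i.e. drug absent).
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OACDDesign",
    "DrugDoseSpec",
    "build_three_level_oa",
    "build_two_level_fraction",
    "compose_oacd",
    "second_order_model_matrix",
    "map_design_to_concentrations",
    "read_design_csv",
    "write_design_csv",
    "read_dose_specs_json",
]


class DesignCapacityError(ValueError):
    """Requested factor count exceeds what the design family supports."""


# The 13 columns of L27(3^13) as representatives (up to scalar multiples)
# of the non-zero linear forms over GF(3)^3.  Any two distinct forms are
# linearly independent, which yields the strength-2 property.
_L27_GENERATORS = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, 2, 0),
    (1, 0, 1), (1, 0, 2),
    (0, 1, 1), (0, 1, 2),
    (1, 1, 1), (1, 1, 2), (1, 2, 1), (1, 2, 2),
)

# GF(3) digits {0,1,2} -> coded dose levels.  Digit 0 maps to the centre
# (level 0) so the all-centre run appears as row 0 of the array, anchoring
# the pure-quadratic terms.
_DIGIT_TO_LEVEL = np.array([0, -1, 1], dtype=int)

# Regular 2^(k-p) generator tables, 1-indexed into the basic columns.
# Chosen for maximal resolution at a run size compatible with a
# second-order composite fit; k=9 gives the 128-run resolution-VI
# fraction so the composite has 155 runs.
_TWO_LEVEL_GENERATORS: dict[int, tuple[int, list[tuple[int, ...]]]] = {
    2: (2, []),
    3: (3, []),
    4: (4, []),
    5: (4, [(1, 2, 3, 4)]),
    6: (5, [(1, 2, 3, 4, 5)]),
    7: (6, [(1, 2, 3, 4, 5, 6)]),
    8: (6, [(1, 2, 3, 4), (1, 2, 5, 6)]),
    9: (7, [(1, 3, 4, 6, 7), (2, 3, 5, 6, 7)]),
    10: (7, [(1, 2, 3, 7), (2, 3, 4, 5), (1, 3, 4, 6)]),
}


@dataclass(frozen=True)
class DrugDoseSpec:
    """Concentrations (uM) assigned to the coded levels of one drug.

    The levels carry IC0/IC10/IC20 semantics: level -1 is conventionally
    0 uM (no measurable inhibition), level 0 the IC10 and level +1 the
    IC20 of the drug across the cohort.
    """

    drug_name: str
    conc_at_level: dict[int, float]
    source_curve: object | None = None

    def __post_init__(self) -> None:
        missing = {-1, 0, 1} - set(self.conc_at_level)
        if missing:
            raise ValueError(
                f"dose spec for {self.drug_name!r} lacks level(s) {sorted(missing)}"
            )
        if self.conc_at_level[-1] < 0:
            raise ValueError("concentration at level -1 must be >= 0")
        lo, mid, hi = (self.conc_at_level[v] for v in (-1, 0, 1))
        if not (lo <= mid <= hi):
            raise ValueError(
                f"concentrations for {self.drug_name!r} must be non-decreasing in level"
            )

    def concentration(self, level: int) -> float:
        try:
            return self.conc_at_level[int(level)]
        except KeyError as exc:
            raise ValueError(
                f"dose spec for {self.drug_name!r} lacks level {level}"
            ) from exc


@dataclass(frozen=True)
class OACDDesign:
    """A composite coded design: L27 block stacked on a two-level fraction."""

    n_factors: int
    runs: np.ndarray
    block_labels: tuple[str, ...]
    design_hash: str = field(default="")

    def __post_init__(self) -> None:
        runs = np.asarray(self.runs, dtype=int)
        if runs.shape[1] != self.n_factors:
            raise ValueError("runs column count must equal n_factors")
        if not np.isin(runs, (-1, 0, 1)).all():
            raise ValueError("coded levels must be in {-1, 0, +1}")
        if len(self.block_labels) != runs.shape[0]:
            raise ValueError("one block label per run required")
        object.__setattr__(self, "runs", runs)
        if not self.design_hash:
            object.__setattr__(self, "design_hash", _hash_design(runs, self.block_labels))

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    def model_matrix(self) -> np.ndarray:
        return second_order_model_matrix(self.runs)


def _hash_design(runs: np.ndarray, labels: tuple[str, ...]) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(runs, dtype=np.int8).tobytes())
    h.update("|".join(labels).encode())
    return h.hexdigest()


def build_three_level_oa(n_factors: int) -> np.ndarray:
    """First ``n_factors`` columns of the L27(3^13) array, coded {-1,0,+1}.

    The array is built as the evaluation of 13 pairwise independent linear
    forms over all 27 points of GF(3)^3; strength 2 (every ordered level
    pair appears exactly 3 times in every column pair) follows from the
    independence of the forms.
    """
    if not 1 <= n_factors <= 13:
        raise DesignCapacityError(
            f"L27 supports 1..13 three-level factors, got {n_factors}"
        )
    points = np.array(list(itertools.product(range(3), repeat=3)), dtype=int)
    gens = np.array(_L27_GENERATORS[:n_factors], dtype=int)
    digits = points @ gens.T % 3
    return _DIGIT_TO_LEVEL[digits]


def build_two_level_fraction(n_factors: int) -> np.ndarray:
    """Regular 2^(k-p) fractional factorial with entries in {-1,+1}.

    Uses a fixed generator table giving the highest resolution attainable
    at the chosen run size (full factorials for k <= 4; e.g. the 128-run
    resolution-VI fraction for k = 9).
    """
    if n_factors < 2:
        raise ValueError(f"need at least 2 factors, got {n_factors}")
    if n_factors not in _TWO_LEVEL_GENERATORS:
        raise DesignCapacityError(
            f"no fractional-factorial generators tabulated for k={n_factors} "
            f"(supported: 2..{max(_TWO_LEVEL_GENERATORS)})"
        )
    n_basic, gens = _TWO_LEVEL_GENERATORS[n_factors]
    basic = np.array(list(itertools.product((-1, 1), repeat=n_basic)), dtype=int)
    cols = [basic[:, i] for i in range(n_basic)]
    for gen in gens:
        col = np.prod([basic[:, i - 1] for i in gen], axis=0)
        cols.append(col)
    return np.column_stack(cols)


def compose_oacd(n_factors: int) -> OACDDesign:
    """Stack the L27 block and the two-level fraction into one design."""
    oa = build_three_level_oa(n_factors)
    ff = build_two_level_fraction(n_factors)
    runs = np.vstack([oa, ff])
    labels = ("three_level",) * oa.shape[0] + ("two_level",) * ff.shape[0]
    design = OACDDesign(n_factors=n_factors, runs=runs, block_labels=labels)
    p = 1 + 2 * n_factors + n_factors * (n_factors - 1) // 2
    rank = np.linalg.matrix_rank(design.model_matrix())
    if rank < p:
        raise ValueError(
            f"composite design model matrix is rank deficient ({rank} < {p})"
        )
    return design


def second_order_model_matrix(runs: np.ndarray) -> np.ndarray:
    """Columns: intercept, k linear, k quadratic, k(k-1)/2 interactions (i<j)."""
    runs = np.asarray(runs, dtype=float)
    n, k = runs.shape
    inter = [runs[:, i] * runs[:, j] for i, j in itertools.combinations(range(k), 2)]
    return np.column_stack([np.ones(n), runs, runs**2] + inter)


def map_design_to_concentrations(
    design: OACDDesign, specs: list[DrugDoseSpec]
) -> pd.DataFrame:
    """Replace coded levels with concentrations, one column per drug (uM).

    Rows keep the design order; the index is the run id (0-based).
    """
    if len(specs) != design.n_factors:
        raise ValueError(
            f"need one dose spec per factor: {design.n_factors} factors, "
            f"{len(specs)} specs"
        )
    names = [s.drug_name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("drug names in dose specs must be unique")
    data = {
        spec.drug_name: [spec.concentration(v) for v in design.runs[:, j]]
        for j, spec in enumerate(specs)
    }
    out = pd.DataFrame(data, columns=names)
    out.index.name = "run_id"
    return out


def write_design_csv(design: OACDDesign, path, drug_names: list[str] | None = None) -> None:
    names = drug_names or [f"drug_{i + 1}" for i in range(design.n_factors)]
    df = pd.DataFrame(design.runs, columns=names)
    df.insert(0, "run_id", np.arange(design.n_runs))
    df["block"] = design.block_labels
    df.to_csv(path, index=False)


def read_design_csv(path) -> OACDDesign:
    """Load a user-supplied coded design (e.g. a transcribed published layout)."""
    df = pd.read_csv(path)
    drug_cols = [c for c in df.columns if c not in ("run_id", "block")]
    runs = df[drug_cols].to_numpy(dtype=int)
    labels = tuple(df["block"]) if "block" in df else ("three_level",) * len(df)
    return OACDDesign(n_factors=len(drug_cols), runs=runs, block_labels=labels)


def read_dose_specs_json(path) -> list[DrugDoseSpec]:
    """Read per-drug dose specs: [{"drug": name, "levels": {"-1": uM, ...}}, ...]."""
    with open(path) as fh:
        raw = json.load(fh)
    return [
        DrugDoseSpec(
            drug_name=entry["drug"],
            conc_at_level={int(k): float(v) for k, v in entry["levels"].items()},
        )
        for entry in raw
    ]
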