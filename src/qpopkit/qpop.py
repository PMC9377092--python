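"""Quadratic response-surface fitting and exhaustive two-drug ranking.

The central idea: the therapeutic response of a cell population to a
k-drug dosing combination is well approximated by a second-order
polynomial in the coded dose levels,

    y = b0 + sum_i bi*xi + sum_i bii*xi^2 + sum_{i<j} bij*xi*xj,

so a small composite design (the OACD) suffices to estimate all
1 + 2k + k(k-1)/2 coefficients.  The fitted surface is then queried over
all unordered drug pairs — the remaining drugs held at level -1 (absent)
— to rank pairs by projected output, and pair rankings from a cohort of
cell lines are aggregated by top-N frequency analysis and hierarchical
clustering of the rank profiles.

The therapeutic output used in tumor-vs-normal screens is
delta = viability(normal reference) - viability(tumor line): larger delta
means more tumor-selective killing.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import linkage

from .design import DrugDoseSpec, OACDDesign, second_order_model_matrix

__all__ = [
    "TherapeuticOutput",
    "QuadraticSurface",
    "CombinationRanking",
    "FrequencyTable",
    "therapeutic_output",
    "aggregate_plate_outputs",
    "fit_quadratic_surface",
    "score_two_drug_combinations",
    "rank_frequency",
    "cluster_rank_profiles",
    "export_response_surface",
    "polygonogram_edges",
]

_OBJECTIVES = ("delta", "pdxo_kill", "thle2_kill")


@dataclass(frozen=True)
class TherapeuticOutput:
    delta: float
    viability_thle2: float
    viability_pdxo: float


def therapeutic_output(v_thle2: float, v_pdxo: float) -> TherapeuticOutput:
    """delta = viability of the normal reference minus the tumor line."""
    if not (np.isfinite(v_thle2) and np.isfinite(v_pdxo)):
        raise ValueError("viabilities must be finite")
    return TherapeuticOutput(
        delta=v_thle2 - v_pdxo, viability_thle2=v_thle2, viability_pdxo=v_pdxo
    )


@dataclass(frozen=True)
class QuadraticSurface:
    """Second-order polynomial over coded levels, with OLS diagnostics.

    ``f_stat``/``f_pvalue`` are NaN when the overall F-test is undefined
    (e.g. constant outputs).
    """

    n_factors: int
    beta0: float
    beta_lin: np.ndarray  # (k,)
    beta_quad: np.ndarray  # (k,)
    beta_int: np.ndarray  # (k*(k-1)/2,) ordered by (i, j), i < j
    adj_r2: float
    f_stat: float
    f_pvalue: float
    residual_ss: float
    df_resid: int
    dropped_terms: tuple[str, ...] = ()

    @property
    def n_coefficients(self) -> int:
        k = self.n_factors
        return 1 + 2 * k + k * (k - 1) // 2

    def interaction(self, i: int, j: int) -> float:
        """beta_ij for an unordered factor pair."""
        i, j = sorted((i, j))
        pairs = list(itertools.combinations(range(self.n_factors), 2))
        return float(self.beta_int[pairs.index((i, j))])

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the surface at coded points (rows of ``x``)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_factors:
            raise ValueError(
                f"expected {self.n_factors} coded levels per point, got {x.shape[1]}"
            )
        beta = np.concatenate(
            [[self.beta0], self.beta_lin, self.beta_quad, self.beta_int]
        )
        return second_order_model_matrix(x) @ beta


def aggregate_plate_outputs(
    plates: pd.DataFrame, tumor_line: str, normal_line: str
) -> pd.Series:
    """Per-run therapeutic output from a long plate table.

    ``plates`` columns: run_id, cell_line, replicate, viability.  Replicate
    viabilities are averaged per run and line before differencing, giving
    one delta per experimental combination.
    """
    means = plates.groupby(["run_id", "cell_line"])["viability"].mean().unstack()
    for line in (tumor_line, normal_line):
        if line not in means.columns:
            raise ValueError(f"cell line {line!r} absent from plate table")
    return (means[normal_line] - means[tumor_line]).sort_index()


def _term_names(k: int) -> list[str]:
    names = ["intercept"]
    names += [f"x{i + 1}" for i in range(k)]
    names += [f"x{i + 1}^2" for i in range(k)]
    names += [f"x{i + 1}*x{j + 1}" for i, j in itertools.combinations(range(k), 2)]
    return names


def fit_quadratic_surface(
    design: OACDDesign,
    outputs: np.ndarray | pd.Series,
    backward_eliminate: bool = False,
    alpha: float = 0.05,
) -> QuadraticSurface:
    """OLS fit of the full second-order model to per-run outputs.

    With ``backward_eliminate`` the least significant non-intercept term
    (largest t-test p-value above ``alpha``) is dropped iteratively and
    the model re-fit; removed terms are reported with zero coefficients.
    """
    y = np.asarray(outputs, dtype=float)
    X = design.model_matrix()
    n, p = X.shape
    k = design.n_factors
    if n < p:
        raise ValueError(f"insufficient runs: {n} runs for {p} coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design model matrix is rank deficient")
    if y.shape[0] != n:
        raise ValueError(f"outputs length {y.shape[0]} != {n} runs")

    names = _term_names(k)
    if np.ptp(y) == 0.0:
        # constant response: intercept only; F-test not applicable
        beta = np.zeros(p)
        beta[0] = y[0]
        return _pack_surface(k, beta, adj_r2=0.0, f_stat=np.nan, f_pvalue=np.nan,
                             residual_ss=0.0, df_resid=n - 1, dropped=())

    keep = list(range(p))
    dropped: list[str] = []
    while True:
        fit = sm.OLS(y, X[:, keep]).fit()
        if not backward_eliminate:
            break
        pvals = fit.pvalues.copy()
        cand = [
            (pv, idx)
            for pv, idx in zip(pvals, keep)
            if idx != 0 and pv > alpha
        ]
        if not cand or len(keep) <= 2:
            break
        worst = max(cand)[1]
        dropped.append(names[worst])
        keep.remove(worst)

    beta = np.zeros(p)
    beta[keep] = fit.params
    return _pack_surface(
        k,
        beta,
        adj_r2=float(fit.rsquared_adj),
        f_stat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        residual_ss=float(fit.ssr),
        df_resid=int(fit.df_resid),
        dropped=tuple(dropped),
    )


def _pack_surface(k, beta, adj_r2, f_stat, f_pvalue, residual_ss, df_resid, dropped):
    n_int = k * (k - 1) // 2
    return QuadraticSurface(
        n_factors=k,
        beta0=float(beta[0]),
        beta_lin=beta[1 : 1 + k].copy(),
        beta_quad=beta[1 + k : 1 + 2 * k].copy(),
        beta_int=beta[1 + 2 * k : 1 + 2 * k + n_int].copy(),
        adj_r2=adj_r2,
        f_stat=f_stat,
        f_pvalue=f_pvalue,
        residual_ss=residual_ss,
        df_resid=df_resid,
        dropped_terms=dropped,
    )


@dataclass(frozen=True)
class CombinationRanking:
    """All unordered drug pairs of one cell line, sorted by projected output."""

    cell_line: str
    objective: str
    entries: pd.DataFrame  # rank, drug_a, drug_b, level_a, level_b,
    #                        conc_a_uM, conc_b_uM, projected_output

    def top(self, n: int) -> list[tuple[str, str]]:
        head = self.entries.nsmallest(n, "rank")
        return [tuple(r) for r in head[["drug_a", "drug_b"]].itertuples(index=False)]

    def rank_of(self, drug_a: str, drug_b: str) -> int:
        a, b = sorted((drug_a, drug_b))
        row = self.entries[
            (self.entries.drug_a == a) & (self.entries.drug_b == b)
        ]
        if row.empty:
            raise KeyError(f"pair ({a}, {b}) not in ranking")
        return int(row["rank"].iloc[0])


def score_two_drug_combinations(
    surface: QuadraticSurface,
    specs: list[DrugDoseSpec],
    objective: str = "delta",
    cell_line: str = "",
    continuous: bool = False,
    grid_points: int = 41,
) -> CombinationRanking:
    """Rank all unordered drug pairs by the surface's projected output.

    For each pair the other drugs sit at level -1 (absent) and the surface
    is evaluated at the four coded points {0,1} x {0,1}; the pair's score
    is the best prediction under the objective's orientation (``delta``
    maximizes; the two ``*_kill`` objectives minimize viability).  With
    ``continuous`` the search extends over a fine grid on [-1,1]^2.
    Ties break lexicographically by drug-name pair.
    """
    if objective not in _OBJECTIVES:
        raise ValueError(f"objective must be one of {_OBJECTIVES}")
    if len(specs) != surface.n_factors:
        raise ValueError(
            f"surface has {surface.n_factors} factors but {len(specs)} specs given"
        )
    maximize = objective == "delta"
    if continuous:
        axis = np.linspace(-1.0, 1.0, grid_points)
    else:
        axis = np.array([0.0, 1.0])
    cand_levels = np.array(list(itertools.product(axis, axis)))

    rows = []
    for i, j in itertools.combinations(range(surface.n_factors), 2):
        pts = np.full((len(cand_levels), surface.n_factors), -1.0)
        pts[:, i] = cand_levels[:, 0]
        pts[:, j] = cand_levels[:, 1]
        preds = surface.predict(pts)
        best = int(np.argmax(preds) if maximize else np.argmin(preds))
        la, lb = cand_levels[best]
        name_i, name_j = specs[i].drug_name, specs[j].drug_name
        if name_i <= name_j:
            a, b, lev_a, lev_b, spec_a, spec_b = name_i, name_j, la, lb, specs[i], specs[j]
        else:
            a, b, lev_a, lev_b, spec_a, spec_b = name_j, name_i, lb, la, specs[j], specs[i]
        rows.append(
            {
                "drug_a": a,
                "drug_b": b,
                "level_a": lev_a,
                "level_b": lev_b,
                "conc_a_uM": _conc_at(spec_a, lev_a),
                "conc_b_uM": _conc_at(spec_b, lev_b),
                "projected_output": float(preds[best]),
            }
        )
    df = pd.DataFrame(rows)
    ascending = not maximize
    df = df.sort_values(
        ["projected_output", "drug_a", "drug_b"],
        ascending=[ascending, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return CombinationRanking(cell_line=cell_line, objective=objective, entries=df)


def _conc_at(spec: DrugDoseSpec, level: float) -> float:
    if float(level) in (-1.0, 0.0, 1.0):
        return spec.concentration(int(level))
    # continuous levels: log-linear interpolation is meaningless with IC0=0,
    # so interpolate linearly between the bracketing coded concentrations
    lo = int(np.floor(level))
    hi = lo + 1
    frac = level - lo
    return (1 - frac) * spec.concentration(lo) + frac * spec.concentration(hi)


@dataclass(frozen=True)
class FrequencyTable:
    top_n: int
    n_lines: int
    pair_counts: dict[tuple[str, str], int]
    drug_counts: dict[str, int]

    def modal_pair(self) -> tuple[str, str]:
        return max(self.pair_counts, key=lambda p: (self.pair_counts[p], p))


def rank_frequency(
    rankings: list[CombinationRanking], top_n: int = 25
) -> FrequencyTable:
    """Count how often each pair (and each drug) enters a line's top-N."""
    if not rankings:
        raise ValueError("need at least one ranking")
    drug_sets = {
        frozenset(r.entries.drug_a) | frozenset(r.entries.drug_b) for r in rankings
    }
    if len(drug_sets) != 1:
        raise ValueError("all rankings must share the same drug set")
    n_pairs = len(rankings[0].entries)
    if top_n > n_pairs:
        raise ValueError(f"top_n={top_n} exceeds the {n_pairs} pairs available")
    pair_counts: Counter = Counter()
    drug_counts: Counter = Counter()
    for r in rankings:
        for a, b in r.top(top_n):
            pair_counts[(a, b)] += 1
            drug_counts[a] += 1
            drug_counts[b] += 1
    return FrequencyTable(
        top_n=top_n,
        n_lines=len(rankings),
        pair_counts=dict(pair_counts),
        drug_counts=dict(drug_counts),
    )


def rank_matrix(rankings: list[CombinationRanking]) -> pd.DataFrame:
    """Lines x pairs matrix of ranks, pairs ordered lexicographically."""
    pairs = sorted(
        (a, b)
        for a, b in rankings[0].entries[["drug_a", "drug_b"]].itertuples(index=False)
    )
    data = {
        r.cell_line: [r.rank_of(a, b) for a, b in pairs] for r in rankings
    }
    return pd.DataFrame(data, index=[f"{a}+{b}" for a, b in pairs]).T


def cluster_rank_profiles(rank_mat: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Average-linkage tree over lines, distance = 1 - Spearman correlation.

    Returns a scipy linkage matrix.  Rank profiles are already ranks, so
    Spearman reduces to Pearson on the rows.
    """
    if isinstance(rank_mat, pd.DataFrame):
        labels = list(rank_mat.index)
        mat = rank_mat.to_numpy(dtype=float)
    else:
        mat = np.asarray(rank_mat, dtype=float)
        labels = [str(i) for i in range(mat.shape[0])]
    if mat.shape[0] < 2:
        raise ValueError("clustering needs >= 2 lines")
    for row, label in zip(mat, labels):
        if np.ptp(row) == 0:
            raise ValueError(
                f"rank profile of line {label!r} is constant; correlation undefined"
            )
    n = mat.shape[0]
    dist = []
    for i in range(n):
        for j in range(i + 1, n):
            rho = stats.spearmanr(mat[i], mat[j]).statistic
            dist.append(1.0 - rho)
    return linkage(np.array(dist), method="average")


def export_response_surface(
    surface: QuadraticSurface,
    pair: tuple[int, int],
    grid_points_per_axis: int = 21,
) -> pd.DataFrame:
    """Surface values over [-1,1]^2 for one pair, other drugs at level -1.

    Columns: level_a, level_b, output — the long-form table behind a
    parabolic response-surface map.
    """
    i, j = pair
    k = surface.n_factors
    if not (0 <= i < k and 0 <= j < k and i != j):
        raise ValueError(f"invalid pair {pair} for {k} factors")
    axis = np.linspace(-1.0, 1.0, grid_points_per_axis)
    aa, bb = np.meshgrid(axis, axis, indexing="ij")
    pts = np.full((aa.size, k), -1.0)
    pts[:, i] = aa.ravel()
    pts[:, j] = bb.ravel()
    return pd.DataFrame(
        {"level_a": aa.ravel(), "level_b": bb.ravel(), "output": surface.predict(pts)}
    )


def polygonogram_edges(
    surface: QuadraticSurface,
    ranking: CombinationRanking,
    drug_names: list[str],
) -> pd.DataFrame:
    """Edge list for a polygonogram: each pair's interaction coefficient
    beta_ij (the edge weight) alongside its ranked score."""
    idx = {name: i for i, name in enumerate(drug_names)}
    rows = []
    for rec in ranking.entries.itertuples(index=False):
        rows.append(
            {
                "drug_a": rec.drug_a,
                "drug_b": rec.drug_b,
                "interaction_beta": surface.interaction(idx[rec.drug_a], idx[rec.drug_b]),
                "score": rec.projected_output,
                "rank": rec.rank,
            }
        )
    return pd.DataFrame(rows)
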