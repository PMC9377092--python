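"""Quadratic surface fitting, pair ranking, frequency and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qpopkit.design import OACDDesign, compose_oacd
from qpopkit.qpop import (
    QuadraticSurface,
    aggregate_plate_outputs,
    cluster_rank_profiles,
    export_response_surface,
    fit_quadratic_surface,
    polygonogram_edges,
    rank_frequency,
    rank_matrix,
    score_two_drug_combinations,
    therapeutic_output,
)
from qpopkit.simulate import simulate_quadratic_truth

from conftest import make_specs


def make_surface(k, beta0=0.0, lin=None, quad=None, inter=None):
    n_int = k * (k - 1) // 2
    return QuadraticSurface(
        n_factors=k,
        beta0=beta0,
        beta_lin=np.zeros(k) if lin is None else np.asarray(lin, float),
        beta_quad=np.zeros(k) if quad is None else np.asarray(quad, float),
        beta_int=np.zeros(n_int) if inter is None else np.asarray(inter, float),
        adj_r2=1.0,
        f_stat=np.nan,
        f_pvalue=np.nan,
        residual_ss=0.0,
        df_resid=0,
    )


class TestTherapeuticOutput:
    @pytest.mark.parametrize(
        "vt,vp,expected", [(1.0, 0.2, 0.8), (0.5, 0.5, 0.0), (0.2, 1.0, -0.8)]
    )
    def test_delta(self, vt, vp, expected):
        assert therapeutic_output(vt, vp).delta == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            therapeutic_output(np.nan, 0.5)


class TestAggregatePlates:
    def test_replicates_averaged_before_differencing(self):
        plates = pd.DataFrame(
            {
                "run_id": [0, 0, 0, 0],
                "cell_line": ["T", "T", "N", "N"],
                "replicate": [0, 1, 0, 1],
                "viability": [0.2, 0.4, 0.9, 1.1],
            }
        )
        delta = aggregate_plate_outputs(plates, "T", "N")
        assert delta.loc[0] == pytest.approx(1.0 - 0.3)

    def test_missing_line_rejected(self):
        plates = pd.DataFrame(
            {"run_id": [0], "cell_line": ["T"], "replicate": [0], "viability": [0.5]}
        )
        with pytest.raises(ValueError, match="absent"):
            aggregate_plate_outputs(plates, "T", "N")


class TestFitQuadraticSurface:
    def test_exact_recovery_on_oacd(self, oacd9, random_surface9):
        y = simulate_quadratic_truth(random_surface9, oacd9, noise_sd=0.0)
        fit = fit_quadratic_surface(oacd9, y)
        err = max(
            abs(fit.beta0 - random_surface9.beta0),
            np.abs(fit.beta_lin - random_surface9.beta_lin).max(),
            np.abs(fit.beta_quad - random_surface9.beta_quad).max(),
            np.abs(fit.beta_int - random_surface9.beta_int).max(),
        )
        assert err <= 1e-8
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_outputs_degenerate(self, oacd9):
        fit = fit_quadratic_surface(oacd9, np.full(155, 0.7))
        assert fit.beta0 == pytest.approx(0.7)
        assert np.all(fit.beta_lin == 0) and np.all(fit.beta_int == 0)
        assert fit.adj_r2 == 0.0
        assert np.isnan(fit.f_stat) and np.isnan(fit.f_pvalue)

    def test_insufficient_runs(self, oacd9):
        small = OACDDesign(
            n_factors=9, runs=oacd9.runs[:10], block_labels=oacd9.block_labels[:10]
        )
        with pytest.raises(ValueError, match="nsufficient"):
            fit_quadratic_surface(small, np.zeros(10))

    def test_f_test_significant_on_structured_data(self, oacd9, random_surface9):
        rng = np.random.default_rng(5)
        y = simulate_quadratic_truth(random_surface9, oacd9, noise_sd=0.05, seed=5)
        fit = fit_quadratic_surface(oacd9, y)
        assert fit.f_pvalue < 1e-6
        assert fit.df_resid == 100

    def test_backward_elimination_drops_null_terms(self):
        d = compose_oacd(4)
        truth = make_surface(4, beta0=1.0, lin=[2.0, 0, 0, 0])
        y = simulate_quadratic_truth(truth, d, noise_sd=0.01, seed=3)
        fit = fit_quadratic_surface(d, y, backward_eliminate=True)
        assert len(fit.dropped_terms) > 0
        assert abs(fit.beta_lin[0] - 2.0) < 0.05


class TestScoring:
    def test_single_interaction_surface(self):
        k = 4
        inter = np.zeros(6)
        pairs = list(itertools.combinations(range(k), 2))
        inter[pairs.index((1, 2))] = 0.5
        surface = make_surface(k, inter=inter)
        specs = make_specs(["a", "b", "c", "d"])
        ranking = score_two_drug_combinations(surface, specs, "delta")
        # at the all-absent reference the product (-1)*(-1) also activates
        # beta_bc, so uninvolved pairs can tie; the interacting pair must
        # attain the top score with its optimum at the (+1,+1) corner
        row = ranking.entries[
            (ranking.entries.drug_a == "b") & (ranking.entries.drug_b == "c")
        ].iloc[0]
        assert row.projected_output == pytest.approx(0.5)
        assert row.projected_output == pytest.approx(
            ranking.entries.projected_output.max()
        )
        assert row.level_a == 1.0 and row.level_b == 1.0

    def test_label_permutation_equivariance(self, oacd9, random_surface9):
        y = simulate_quadratic_truth(random_surface9, oacd9, noise_sd=0.0)
        fit = fit_quadratic_surface(oacd9, y)
        names = [f"d{i}" for i in range(9)]
        specs = make_specs(names)
        base = score_two_drug_combinations(fit, specs, "delta")
        # permute columns of the design/output consistently
        perm = np.array([3, 1, 4, 0, 2, 5, 8, 6, 7])
        runs_p = oacd9.runs[:, perm]
        d_p = OACDDesign(n_factors=9, runs=runs_p, block_labels=oacd9.block_labels)
        fit_p = fit_quadratic_surface(d_p, y)
        specs_p = make_specs([names[i] for i in perm])
        permuted = score_two_drug_combinations(fit_p, specs_p, "delta")
        for r in range(36):
            a = base.entries.iloc[r]
            b = permuted.entries.iloc[r]
            assert {a.drug_a, a.drug_b} == {b.drug_a, b.drug_b}
            assert a.projected_output == pytest.approx(b.projected_output, abs=1e-9)

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_matches_exhaustive_grid_oracle(self, k):
        """Scores equal brute-force evaluation of the polynomial over all
        coded points with at most two drugs above level -1."""
        rng = np.random.default_rng(k)
        n_int = k * (k - 1) // 2
        surface = make_surface(
            k,
            beta0=rng.normal(),
            lin=rng.normal(size=k),
            quad=rng.normal(size=k),
            inter=rng.normal(size=n_int),
        )
        names = [f"d{i}" for i in range(k)]
        ranking = score_two_drug_combinations(surface, make_specs(names), "delta")

        def poly(x):
            # independent evaluation: direct polynomial arithmetic
            val = surface.beta0
            for i in range(k):
                val += surface.beta_lin[i] * x[i] + surface.beta_quad[i] * x[i] ** 2
            for idx, (i, j) in enumerate(itertools.combinations(range(k), 2)):
                val += surface.beta_int[idx] * x[i] * x[j]
            return val

        best = {}
        for point in itertools.product((-1, 0, 1), repeat=k):
            active = tuple(i for i, v in enumerate(point) if v > -1)
            if len(active) == 2:
                key = active
                best[key] = max(best.get(key, -np.inf), poly(point))
        for (i, j), oracle_score in best.items():
            a, b = sorted((names[i], names[j]))
            row = ranking.entries[
                (ranking.entries.drug_a == a) & (ranking.entries.drug_b == b)
            ]
            assert row.projected_output.iloc[0] == pytest.approx(oracle_score, abs=1e-12)

    def test_ranking_invariant_to_output_shift(self, oacd9, random_surface9):
        y = simulate_quadratic_truth(random_surface9, oacd9, noise_sd=0.0)
        specs = make_specs([f"d{i}" for i in range(9)])
        r1 = score_two_drug_combinations(fit_quadratic_surface(oacd9, y), specs)
        r2 = score_two_drug_combinations(fit_quadratic_surface(oacd9, y + 5.0), specs)
        assert (
            r1.entries[["drug_a", "drug_b", "rank"]]
            .reset_index(drop=True)
            .equals(r2.entries[["drug_a", "drug_b", "rank"]].reset_index(drop=True))
        )

    def test_kill_objective_minimizes(self):
        surface = make_surface(2, beta0=1.0, lin=[-0.5, -0.1])
        specs = make_specs(["a", "b"])
        r = score_two_drug_combinations(surface, specs, "pdxo_kill")
        assert r.entries.iloc[0].projected_output == pytest.approx(1.0 - 0.6)

    def test_ranks_are_contiguous(self, oacd9, random_surface9, specs9):
        r = score_two_drug_combinations(random_surface9, specs9)
        assert list(r.entries["rank"]) == list(range(1, 37))


class TestFrequency:
    def _ranking_from_surface(self, surface, names, line):
        return score_two_drug_combinations(
            surface, make_specs(names), "delta", cell_line=line
        )

    def test_identical_rankings_count_n_lines(self):
        k = 9
        rng = np.random.default_rng(0)
        surface = make_surface(k, inter=rng.normal(size=36))
        names = [f"d{i}" for i in range(k)]
        rankings = [self._ranking_from_surface(surface, names, f"L{i}") for i in range(4)]
        ft = rank_frequency(rankings, top_n=25)
        assert all(v == 4 for v in ft.pair_counts.values())
        assert sum(ft.pair_counts.values()) == 25 * 4

    def test_drug_counts_sum_over_member_pairs(self):
        rng = np.random.default_rng(1)
        surface = make_surface(9, inter=rng.normal(size=36))
        names = [f"d{i}" for i in range(9)]
        rankings = [self._ranking_from_surface(surface, names, "L")]
        ft = rank_frequency(rankings, top_n=25)
        for drug in names:
            expected = sum(c for p, c in ft.pair_counts.items() if drug in p)
            assert ft.drug_counts.get(drug, 0) == expected

    def test_top_n_exceeding_pairs_rejected(self):
        surface = make_surface(3)
        rankings = [self._ranking_from_surface(surface, list("abc"), "L")]
        with pytest.raises(ValueError, match="exceeds"):
            rank_frequency(rankings, top_n=4)

    def test_inconsistent_drug_sets_rejected(self):
        s = make_surface(3)
        r1 = self._ranking_from_surface(s, list("abc"), "L1")
        r2 = self._ranking_from_surface(s, list("abd"), "L2")
        with pytest.raises(ValueError, match="same drug set"):
            rank_frequency([r1, r2], top_n=2)


class TestClustering:
    def test_identical_lines_merge_at_zero(self):
        mat = np.array([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]], dtype=float)
        Z = cluster_rank_profiles(mat)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_reversed_rankings_distance_two(self):
        mat = np.array([[1, 2, 3, 4], [4, 3, 2, 1]], dtype=float)
        Z = cluster_rank_profiles(mat)
        assert Z[0, 2] == pytest.approx(2.0)

    def test_matches_naive_average_linkage(self):
        """Four-line toy matrix versus an independently coded agglomerator."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(8)
        mat = np.array([rng.permutation(6) + 1 for _ in range(4)], dtype=float)
        Z = cluster_rank_profiles(mat)

        # naive O(n^3) average-linkage on 1 - spearman
        n = 4
        dist = {
            frozenset((i, j)): 1 - spearmanr(mat[i], mat[j]).statistic
            for i in range(n)
            for j in range(i + 1, n)
        }
        clusters = {i: [i] for i in range(n)}
        next_id = n
        merges = []
        while len(clusters) > 1:
            pairs = sorted(clusters)
            best, bd = None, np.inf
            for ai in range(len(pairs)):
                for bi in range(ai + 1, len(pairs)):
                    a, b = pairs[ai], pairs[bi]
                    d_ab = np.mean(
                        [dist[frozenset((x, y))] for x in clusters[a] for y in clusters[b]]
                    )
                    if d_ab < bd - 1e-12:
                        best, bd = (a, b), d_ab
            a, b = best
            merges.append((a, b, bd, len(clusters[a]) + len(clusters[b])))
            clusters[next_id] = clusters.pop(a) + clusters.pop(b)
            next_id += 1
        for (za, zb, zd, zn), (na, nb, nd, nn) in zip(Z, merges):
            assert sorted((za, zb)) == sorted((na, nb))
            assert zd == pytest.approx(nd, abs=1e-12)
            assert zn == nn

    def test_constant_profile_names_line(self):
        mat = pd.DataFrame(
            [[1, 1, 1], [1, 2, 3]], index=["FLAT", "OK"], dtype=float
        )
        with pytest.raises(ValueError, match="FLAT"):
            cluster_rank_profiles(mat)

    def test_rank_matrix_layout(self):
        s = make_surface(3, inter=[0.5, 0.1, -0.2])
        rankings = [
            score_two_drug_combinations(s, make_specs(list("abc")), cell_line=f"L{i}")
            for i in range(2)
        ]
        rm = rank_matrix(rankings)
        assert rm.shape == (2, 3)
        assert list(rm.columns) == ["a+b", "a+c", "b+c"]


class TestExport:
    def test_grid_shape_and_corners(self):
        surface = make_surface(3, beta0=0.2, lin=[0.1, -0.3, 0.0], inter=[0.4, 0, 0])
        grid = export_response_surface(surface, (0, 1), grid_points_per_axis=21)
        assert len(grid) == 441
        corner = grid[(grid.level_a == 1.0) & (grid.level_b == 1.0)].output.iloc[0]
        # direct arithmetic with drug 2 at level -1
        expected = 0.2 + 0.1 - 0.3 + 0.4 * 1 * 1 + 0.0 * (-1)
        assert corner == pytest.approx(expected)

    def test_interaction_only_surface_is_saddle_with_ridge_at_upper_corner(self):
        surface = make_surface(2, inter=[0.6])
        grid = export_response_surface(surface, (0, 1), grid_points_per_axis=11)
        upper = grid[(grid.level_a == 1.0) & (grid.level_b == 1.0)].output.iloc[0]
        assert upper == pytest.approx(grid.output.max())
        # saddle shape: the mixed corners are the minima
        mixed = grid[(grid.level_a == -1.0) & (grid.level_b == 1.0)].output.iloc[0]
        assert mixed == pytest.approx(grid.output.min())

    def test_polygonogram_edges_carry_interaction(self):
        inter = [0.5, -0.1, 0.2]
        surface = make_surface(3, inter=inter)
        specs = make_specs(list("abc"))
        ranking = score_two_drug_combinations(surface, specs)
        edges = polygonogram_edges(surface, ranking, list("abc"))
        ab = edges[(edges.drug_a == "a") & (edges.drug_b == "b")]
        assert ab.interaction_beta.iloc[0] == pytest.approx(0.5)
        assert len(edges) == 3
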