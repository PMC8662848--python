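import numpy as np
import pytest
from scipy import stats

from snsvd.diffcoexpr import (
    DifferentialCorrelation,
    MatchedExpressionSet,
    adPCC_permutation_test,
    de_filter,
    differential_matrix,
    find_diff_modules,
    knn_impute,
    sigma_sweep,
)
from snsvd.io import ExpressionMatrix, ModuleRecord
from snsvd.simulation import generate_matched_set, generate_planted_differential
from snsvd.solver import SolverConfig


def _expr(values, prefix="f", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"{prefix}{i + 1}" for i in range(values.shape[0])],
        [f"{sample_prefix}{j + 1}" for j in range(values.shape[1])],
    )


class TestDEFilter:
    def test_identical_feature_not_selected_shifted_feature_selected(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 10, size=(2, 20))
        case = _expr(np.vstack([base[0], base[1] + 10]))
        control = ExpressionMatrix(
            base.copy(), case.gene_ids, [f"t{j}" for j in range(20)]
        )
        res = de_filter(case, control, alpha=0.05)
        assert res.features == ["f2"]
        assert res.p_values["f1"] == 1.0
        # oracle: rank-sum p for complete separation, Bonferroni x2
        a = np.log2(case.values[1] + 1)
        b = np.log2(base[1] + 1)
        expected = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        assert res.p_values["f2"] == pytest.approx(expected)
        assert expected * 2 < 0.05

    def test_bonferroni_multiplication_rule(self):
        # with k features a raw p just under alpha/k passes, just over fails
        rng = np.random.default_rng(1)
        k = 10
        case_rows = [rng.uniform(1, 2, 12) for _ in range(k)]
        ctrl_rows = [r.copy() for r in case_rows]
        case_rows[0] = case_rows[0] + 5.0  # strongly separated
        res = de_filter(_expr(np.array(case_rows)), _expr(np.array(ctrl_rows)))
        assert "f1" in res.features and len(res.features) == 1

    def test_low_expression_features_are_dropped(self):
        case = _expr([[0.0] * 10, [5.0] * 10])
        control = _expr([[0.0] * 9 + [1.0], [1.0] * 10])
        res = de_filter(case, control, alpha=0.5)
        assert "f1" not in res.features

    def test_all_identical_raises(self):
        vals = np.ones((2, 5))
        with pytest.raises(ValueError):
            de_filter(_expr(vals), _expr(vals.copy()))


class TestKnnImpute:
    def test_no_missing_is_identity(self, small_expression):
        out = knn_impute(small_expression)
        np.testing.assert_array_equal(out.values, small_expression.values)

    def test_identical_rows_fill_with_common_value(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], (5, 1))
        vals[2, 1] = np.nan
        out = knn_impute(_expr(vals), k=2)
        assert out.values[2, 1] == pytest.approx(2.0)
        assert out.n_missing == 0

    def test_hand_computed_neighbor_mean(self):
        # row 1 is missing col 0; its 2 nearest rows (by the complete
        # columns) are rows 0 and 2 -> fill = mean(10, 20) = 15
        vals = np.array(
            [
                [10.0, 1.0, 1.0, 1.0],
                [np.nan, 1.1, 1.0, 1.0],
                [20.0, 0.9, 1.0, 1.0],
                [90.0, 9.0, 9.0, 9.0],
                [80.0, 9.1, 9.0, 9.0],
            ]
        )
        out = knn_impute(_expr(vals), k=2)
        assert out.values[1, 0] == pytest.approx(15.0)

    def test_fully_missing_row_rejected(self):
        vals = np.ones((3, 3))
        vals[1] = np.nan
        with pytest.raises(ValueError, match="fully missing"):
            knn_impute(_expr(vals))


class TestDifferentialMatrix:
    def test_self_correlation_diagonal(self):
        rng = np.random.default_rng(2)
        a1 = rng.standard_normal((4, 30))
        a2 = rng.standard_normal((4, 25))
        mset = MatchedExpressionSet(
            A1=_expr(a1, "g"), A2=_expr(a2, "g", "t"),
            B1=_expr(a1.copy(), "m"), B2=_expr(a2.copy(), "m", "t"),
        )
        dc = differential_matrix(mset)
        np.testing.assert_allclose(np.diag(dc.X1), 1.0, atol=1e-12)
        assert np.all(np.abs(dc.X1) <= 1 + 1e-12)
        assert np.all(np.abs(dc.X) <= 2 + 1e-12)

    def test_independent_noise_correlations_concentrate_near_zero(self):
        rng = np.random.default_rng(3)
        n = 500
        mset = MatchedExpressionSet(
            A1=_expr(rng.standard_normal((6, n)), "g"),
            A2=_expr(rng.standard_normal((6, n)), "g", "t"),
            B1=_expr(rng.standard_normal((4, n)), "m"),
            B2=_expr(rng.standard_normal((4, n)), "m", "t"),
        )
        dc = differential_matrix(mset)
        assert np.max(np.abs(dc.X2)) < 0.2

    def test_pearson_invariant_under_row_affine_maps(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((3, 40))
        b = rng.standard_normal((2, 40))
        a2 = rng.standard_normal((3, 40))
        b2 = rng.standard_normal((2, 40))
        base = differential_matrix(
            MatchedExpressionSet(
                A1=_expr(a, "g"), A2=_expr(a2, "g", "t"),
                B1=_expr(b, "m"), B2=_expr(b2, "m", "t"),
            )
        )
        scaled = differential_matrix(
            MatchedExpressionSet(
                A1=_expr(a * 7.0 - 3.0, "g"), A2=_expr(a2, "g", "t"),
                B1=_expr(b * 0.1 + 5.0, "m"), B2=_expr(b2, "m", "t"),
            )
        )
        np.testing.assert_allclose(base.X1, scaled.X1, atol=1e-12)

    def test_zero_variance_row_warns_and_gives_zero(self):
        a = np.vstack([np.ones(10), np.arange(10.0)])
        b = np.arange(10.0)[None, :]
        with pytest.warns(UserWarning, match="zero-variance"):
            dc = differential_matrix(
                MatchedExpressionSet(
                    A1=_expr(a, "g"), A2=_expr(a + 1, "g", "t"),
                    B1=_expr(b, "m"), B2=_expr(b + 1, "m", "t"),
                )
            )
        assert dc.X1[0, 0] == 0.0


class TestFindDiffModules:
    def test_planted_block_recovery_and_count(self):
        dc, net, gm, mm = generate_planted_differential(seed=1)
        mods = find_diff_modules(
            dc, net, SolverConfig(sigma=0.5), n_modules=3,
            target_nnz_gene=20, k_v_mirna=5, seed=0,
        )
        assert len(mods) == 3
        m1 = mods[0]
        true_genes = {f"g{i + 1}" for i in np.flatnonzero(gm)}
        true_mirnas = {f"mir{i + 1}" for i in np.flatnonzero(mm)}
        assert len(m1.genes & true_genes) / len(true_genes) >= 0.9
        assert len(m1.samples & true_mirnas) / len(true_mirnas) >= 0.9
        assert m1.stats["adPCC"] > np.abs(dc.X).mean()

    def test_network_weight_increases_induced_edges(self):
        """Paired over seeds: the network-regularized fit should find at
        least as many induced gene edges as the sigma = 0 fit."""
        edges = {0.0: [], 0.8: []}
        for seed in range(6):
            dc, net, _, _ = generate_planted_differential(
                seed=seed, block_value=0.5, noise=0.25
            )
            for sigma in edges:
                mods = find_diff_modules(
                    dc, net, SolverConfig(sigma=sigma), n_modules=1,
                    target_nnz_gene=25, k_v_mirna=5, n_restarts=3, seed=seed,
                )
                edges[sigma].append(mods[0].stats["n_gene_edges"])
        assert np.mean(edges[0.8]) >= np.mean(edges[0.0])

    def test_identical_conditions_give_degenerate_factors(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((30, 20))
        b = rng.standard_normal((8, 20))
        mset = MatchedExpressionSet(
            A1=_expr(a, "g"), A2=_expr(a.copy(), "g", "t"),
            B1=_expr(b, "m"), B2=_expr(b.copy(), "m", "t"),
        )
        dc = differential_matrix(mset)
        assert np.allclose(dc.X, 0.0)
        net_nodes = list(dc.gene_ids)
        from snsvd.io import GeneNetwork

        net = GeneNetwork(net_nodes, {(0, 1)})
        with pytest.warns(UserWarning):
            mods = find_diff_modules(
                dc, net, SolverConfig(sigma=0.0), n_modules=2,
                target_nnz_gene=5, k_v_mirna=2, seed=0,
            )
        assert all(m.d == pytest.approx(0.0, abs=1e-12) for m in mods)


class TestAdPCCPermutation:
    def test_planted_block_module_gets_minimal_p(self):
        dc, net, gm, mm = generate_planted_differential(seed=2)
        module = ModuleRecord(
            1,
            {f"g{i + 1}" for i in np.flatnonzero(gm)},
            {f"mir{i + 1}" for i in np.flatnonzero(mm)},
        )
        p = adPCC_permutation_test(dc, module, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_permutation_statistic_mean_matches_overall_mean(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 20))
        dc = DifferentialCorrelation(
            X1=np.clip(X, -1, 1), X2=np.clip(X, -1, 1) - X, X=X,
            gene_ids=[f"g{i}" for i in range(50)],
            mirna_ids=[f"m{j}" for j in range(20)],
        )
        # sampling consistency: null submatrix means center on mean |X|
        absx = np.abs(X)
        means = []
        for _ in range(300):
            rg = rng.choice(50, 8, replace=False)
            rm = rng.choice(20, 4, replace=False)
            means.append(absx[np.ix_(rg, rm)].mean())
        assert np.mean(means) == pytest.approx(absx.mean(), abs=0.02)

    def test_n_perm_floor(self):
        dc, _, _, _ = generate_planted_differential(seed=4)
        module = ModuleRecord(1, {"g1"}, {"mir1"})
        with pytest.raises(ValueError):
            adPCC_permutation_test(dc, module, n_perm=50)


class TestEndToEndPipeline:
    def test_matched_set_to_modules(self):
        A1, A2, B1, B2, gm, mm = generate_matched_set(seed=5)
        mset = MatchedExpressionSet(A1=A1, A2=A2, B1=B1, B2=B2)
        dc = differential_matrix(mset)
        # planted block is strongly positive in X1, absent in X2
        assert dc.X[:20, :5].mean() > 0.5
        from conftest import random_network

        rng = np.random.default_rng(0)
        net = random_network(len(dc.gene_ids), 0.05, rng)
        net.nodes = list(dc.gene_ids)
        mods = find_diff_modules(
            dc, net, SolverConfig(sigma=0.0), n_modules=2,
            target_nnz_gene=20, k_v_mirna=5, seed=1,
        )
        true_genes = {f"g{i + 1}" for i in np.flatnonzero(gm)}
        assert len(mods[0].genes & true_genes) >= 15

    def test_sigma_sweep_table_layout(self):
        dc, net, _, _ = generate_planted_differential(seed=6)
        table = sigma_sweep(
            dc, net, sigmas=(0, 0.5), n_modules=2, target_nnz_gene=20,
            k_v_mirna=5, n_random=5, n_restarts=2, seed=0,
        )
        assert list(table.columns) == ["sigma", "edge_avg", "fold_change", "d_avg"]
        assert len(table) == 2
        assert table["edge_avg"].notna().all()
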