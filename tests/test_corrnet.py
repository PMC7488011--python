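"""Correlation networks, bootstrap counts and the count-exceedance test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mirnaboot as mb
from mirnaboot.corrnet import (
    CountDistribution,
    bootstrap_correlation_counts,
    correlation_concordance,
    correlation_count_test,
    count_significant,
    iteration_calibration,
    partial_correlation_matrix,
    pearson_matrix,
)


class TestPearson:
    def test_collinear_pair_is_significant(self):
        summ = pearson_matrix(np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]]))
        assert summ.r.iloc[0, 1] == pytest.approx(1.0)
        # p is clamped to the smallest positive float at |r| = 1 and in any
        # case far below alpha at floating-point-limited |r|
        assert 0 < summ.p.iloc[0, 1] < 1e-6
        assert summ.n_significant == 1

    def test_hand_computed_r_and_p(self):
        x = np.array([[1, 1], [2, 3], [3, 2], [4, 4]], dtype=float)
        summ = pearson_matrix(x)
        assert summ.r.iloc[0, 1] == pytest.approx(0.8, abs=1e-12)
        t = 0.8 * np.sqrt(2 / (1 - 0.64))
        assert summ.p.iloc[0, 1] == pytest.approx(2 * stats.t.sf(t, 2), rel=1e-10)
        assert summ.p.iloc[0, 1] == pytest.approx(0.2, abs=5e-4)

    def test_constant_column_pairs_non_significant(self):
        x = np.column_stack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2])
        summ = pearson_matrix(x)
        assert (summ.p.iloc[0, 1:] == 1.0).all()
        assert (summ.r.iloc[0, 1:] == 0.0).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pearson_matrix(np.ones((2, 3)))

    def test_independent_gaussian_count_near_alpha_rate(self):
        rng = np.random.default_rng(0)
        summ = pearson_matrix(rng.normal(size=(25, 150)))
        assert abs(summ.n_significant - 559) <= 70

    def test_count_significant_alpha_zero_is_zero(self):
        rng = np.random.default_rng(1)
        summ = pearson_matrix(rng.normal(size=(10, 8)))
        assert count_significant(summ.p.to_numpy(), 0.0) == 0

    def test_count_invariant_to_orderings(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 9))
        base = pearson_matrix(x).n_significant
        assert pearson_matrix(x[::-1]).n_significant == base
        assert pearson_matrix(x[:, ::-1]).n_significant == base

    def test_edges_lists_significant_pairs_only(self):
        rng = np.random.default_rng(3)
        summ = pearson_matrix(rng.normal(size=(15, 12)))
        edges = summ.edges()
        assert len(edges) == summ.n_significant
        assert (edges["p"] < summ.alpha).all()


class TestPartial:
    def test_orthogonal_covariate_leaves_r_unchanged(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 6))
        cov = rng.normal(size=20)
        # project out x's column space so the covariate is exactly orthogonal
        q, _ = np.linalg.qr(np.column_stack([np.ones(20), x]))
        cov = cov - q @ (q.T @ cov)
        full = pearson_matrix(x).r.to_numpy()
        part = partial_correlation_matrix(x, cov)
        assert np.allclose(part, full, atol=1e-10)

    def test_self_partial_correlation_is_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(15, 3))
        part = partial_correlation_matrix(x, rng.normal(size=15))
        assert np.allclose(np.diag(part), 1.0)

    def test_confounder_removed(self):
        rng = np.random.default_rng(6)
        ga = rng.normal(30, 3, size=30)
        x = np.column_stack(
            [2 * ga + rng.normal(size=30), 2 * ga + rng.normal(size=30)]
        )
        full = pearson_matrix(x).r.iloc[0, 1]
        part = partial_correlation_matrix(x, ga)[0, 1]
        assert full > 0.9
        assert abs(part) < 0.3

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 3))
        cov = np.column_stack([np.arange(12.0), 2 * np.arange(12.0)])
        with pytest.raises(ValueError):
            partial_correlation_matrix(x, cov)


class TestConcordance:
    def test_identical_matrices_give_one(self):
        rng = np.random.default_rng(8)
        r = pearson_matrix(rng.normal(size=(10, 6))).r.to_numpy()
        assert correlation_concordance(r, r) == pytest.approx(1.0)

    def test_ga_driven_cohort_less_concordant(self):
        """Strong GA slopes lower the full-vs-partial R^2 versus a GA-free cohort."""
        scores = {}
        for label, slopes in (("free", {}), ("driven", {i: 0.6 for i in range(30)})):
            cfg = mb.SimConfig(
                seed=13, n_mirnas=60, detect_dropout=0.0, ga_slopes=slopes,
                background_loading=0.0,
            )
            mat, meta, _ = mb.simulate_cohort(cfg)
            expr = mb.preprocess(mat)
            rows = meta.index[(meta.group == "UE") & (meta.time_point == "T3")]
            sub = expr.dct.loc[rows]
            ga = meta.loc[rows, "GA_bd2"].to_numpy()
            full = pearson_matrix(sub).r.to_numpy()
            part = partial_correlation_matrix(sub.to_numpy(), ga)
            scores[label] = correlation_concordance(full, part)
        assert scores["free"] > 0.95
        assert scores["driven"] < scores["free"]


class TestBootstrapCounts:
    def test_constant_data_gives_all_zero_counts(self):
        meta = pd.DataFrame(
            {"group": "UE", "sex": "M", "time_point": "T2"},
            index=[f"S{i}" for i in range(6)],
        )
        expr = mb.NormalizedExpression(
            pd.DataFrame(np.zeros((6, 4)), index=meta.index,
                         columns=[f"m{j}" for j in range(4)])
        )
        dist = bootstrap_correlation_counts(
            expr, meta, mb.BootstrapConfig(50, seed=0), "UE"
        )
        assert (dist.counts == 0).all()

    def test_single_iteration_shape(self, null_expr):
        expr, meta = null_expr
        dist = bootstrap_correlation_counts(
            expr, meta, mb.BootstrapConfig(1, seed=1), "UE", "T2"
        )
        assert dist.n_iterations == 1 and dist.counts[0] >= 0

    def test_small_stratum_rejected(self, null_expr):
        expr, meta = null_expr
        tiny = meta.iloc[:3]
        with pytest.raises(ValueError):
            bootstrap_correlation_counts(
                mb.NormalizedExpression(expr.dct.loc[tiny.index]),
                tiny, mb.BootstrapConfig(5, seed=0), tiny["group"].iloc[0],
                tiny["time_point"].iloc[0],
            )

    def test_planted_block_raises_mean_count_over_matched_null(self):
        """Factor cohort vs same-seed null cohort, same cell: 50 seed pairs."""
        from mirnaboot.simulate import CoSecretionSpec

        wins = 0
        for s in range(50):
            spec = CoSecretionSpec(
                member_indices=tuple(range(20)),
                active_strata={("HEa", "F", "T2"): 0.8},
                baseline_loading=0.0, member_background=0.0,
            )
            means = []
            for cosec in (spec, None):
                cfg = mb.SimConfig(seed=9000 + s, cosecretion=cosec,
                                   background_loading=0.0)
                mat, meta, _ = mb.simulate_cohort(cfg)
                expr = mb.preprocess(mat)
                dist = bootstrap_correlation_counts(
                    expr, meta, mb.BootstrapConfig(200, seed=s), "HEa", "T2", "F"
                )
                means.append(dist.mean_count)
            wins += means[0] > means[1]
        assert wins / 50 >= 0.95


class TestCountTest:
    def _dist(self, counts):
        return CountDistribution(np.asarray(counts), "HEa", "female", "T2")

    def test_all_exceed_gives_zero(self):
        p = correlation_count_test(self._dist([100] * 10), self._dist([50] * 10))
        assert p == 0.0

    def test_none_exceed_gives_one(self):
        p = correlation_count_test(self._dist([10] * 10), self._dist([50] * 10))
        assert p == 1.0

    def test_half_exceed_gives_half(self):
        exp = self._dist([60] * 5 + [40] * 5)
        assert correlation_count_test(exp, self._dist([50] * 10)) == 0.5

    def test_tie_with_reference_mean_counts_as_not_exceeding(self):
        assert correlation_count_test(self._dist([50] * 4), self._dist([50] * 4)) == 1.0

    def test_mismatched_b_rejected(self):
        with pytest.raises(ValueError):
            correlation_count_test(self._dist([1, 2]), self._dist([1, 2, 3]))

    def test_monotone_in_exposed_counts(self):
        rng = np.random.default_rng(9)
        ref = self._dist(rng.integers(40, 60, size=50))
        base = rng.integers(30, 70, size=50)
        p0 = correlation_count_test(self._dist(base), ref)
        p1 = correlation_count_test(self._dist(base + 5), ref)
        assert p1 <= p0


class TestCalibration:
    def test_grid_shape(self, null_expr):
        expr, meta = null_expr
        sub = mb.NormalizedExpression(expr.dct.iloc[:, :30])
        table = iteration_calibration(
            sub, meta, "UE", iteration_grid=[50], n_runs=2, seed=3
        )
        assert len(table) == 2
        assert set(table.columns) == {"n_iterations", "run", "mean_count"}

    def test_monte_carlo_error_shrinks_with_iterations(self, null_expr):
        expr, meta = null_expr
        sub = mb.NormalizedExpression(expr.dct.iloc[:, :60])
        table = iteration_calibration(
            sub, meta, "UE", iteration_grid=[50, 1000], n_runs=10, seed=4
        )
        spread = table.groupby("n_iterations")["mean_count"].std()
        assert spread[1000] < spread[50]

    def test_empty_grid_rejected(self, null_expr):
        expr, meta = null_expr
        with pytest.raises(ValueError):
            iteration_calibration(expr, meta, "UE", iteration_grid=[])


class TestModelFacade:
    def test_network_fit_summarises_all_cells(self, null_expr):
        expr, meta = null_expr
        sub = mb.NormalizedExpression(expr.dct.iloc[:, :40])
        res = mb.CorrelationNetwork(
            sub, meta, mb.BootstrapConfig(60, seed=5), time_points=("T2",),
            sexes=(None,),
        ).fit()
        assert len(res.summaries) == 3
        assert len(res.tests) == 2
        assert set(res.tests["group"]) == {"HEa", "HEua"}
        assert res.tests["p"].between(0, 1).all()
        assert "Correlation-network bootstrap" in res.summary()
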