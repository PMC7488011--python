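"""ANOVA/ANCOVA p-values, stability profiles and sex-specific labels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mirnaboot as mb
from mirnaboot.stability import (
    STRATA,
    ancova_pvalue,
    anova_pvalue,
    classify_profiles,
    classify_sex_specific,
    concordance_r2,
    stability_profile,
)


def _ols_anova_p(values, groups, covs=None):
    """Independent oracle: group-factor p from statsmodels OLS anova_lm."""
    import statsmodels.api as smf
    import statsmodels.formula.api as sm

    df = pd.DataFrame({"y": values, "g": groups})
    rhs = "C(g)"
    if covs is not None:
        for j, c in enumerate(np.atleast_2d(covs)):
            df[f"x{j}"] = c
            rhs = f"x{j} + " + rhs
    model = sm.ols(f"y ~ {rhs}", data=df).fit()
    table = smf.stats.anova_lm(model, typ=2)
    return float(table.loc["C(g)", "PR(>F)"])


class TestAnova:
    def test_equal_group_means_give_p_one(self):
        assert anova_pvalue([[1, 2, 3], [1, 2, 3], [1, 2, 3]]) == 1.0

    def test_hand_computed_f_statistic(self):
        # groups [0,1],[0,1],[4,5]: SSB = 64/3 * SSW/(df ratio) -> F = 64/3
        p = anova_pvalue([[0, 1], [0, 1], [4, 5]])
        assert np.isclose(p, float(stats.f.sf(64 / 3, 2, 3)), rtol=1e-12)
        assert np.isclose(p, _ols_anova_p([0, 1, 0, 1, 4, 5], list("aabbcc")), atol=1e-10)

    def test_all_identical_values_give_p_one(self):
        assert anova_pvalue([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]]) == 1.0

    def test_matches_linear_model_oracle_on_random_data(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            y = rng.normal(size=18)
            g = rng.choice(list("abc"), size=18)
            if min((g == c).sum() for c in "abc") < 2:
                continue
            mine = anova_pvalue([y[g == c] for c in "abc"])
            assert np.isclose(mine, _ols_anova_p(y, g), atol=1e-10)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_pvalue([[1.0], [1, 2], [3, 4]])


class TestAncova:
    def test_matches_linear_model_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = 21
            y = rng.normal(size=n)
            g = rng.choice(list("abc"), size=n)
            if min((g == c).sum() for c in "abc") < 2:
                continue
            cov = rng.normal(size=n)
            assert np.isclose(
                ancova_pvalue(y, g, cov), _ols_anova_p(y, g, cov), atol=1e-10
            )

    def test_covariate_fully_explains_value(self):
        rng = np.random.default_rng(7)
        ga = rng.normal(30, 3, size=24)
        y = 2.0 * ga
        g = np.repeat(list("abc"), 8)
        p = ancova_pvalue(y, g, ga)
        assert np.isclose(p, _ols_anova_p(y, g, ga), atol=1e-8) or p == 1.0

    def test_zero_variance_covariate_rejected(self):
        with pytest.raises(ValueError):
            ancova_pvalue([1, 2, 3, 4], list("aabb"), np.ones(4))


class TestProfiles:
    def test_constant_mirna_never_significant(self):
        meta_rows, vals = [], []
        for g, n in (("UE", 6), ("HEua", 6), ("HEa", 6)):
            for i in range(n):
                meta_rows.append({"group": g, "sex": "M", "time_point": "T2",
                                  "GA_bd1": 18.0 + i, "GA_bd2": 33.0})
                vals.append(0.0)
        meta = pd.DataFrame(meta_rows, index=[f"S{i}" for i in range(18)])
        expr = mb.NormalizedExpression(
            pd.DataFrame({"m": vals}, index=meta.index, dtype=float)
        )
        prof = stability_profile(
            expr, meta, mb.BootstrapConfig(200, seed=0), "T2", "anova",
            strata=("aggregated",),
        )
        assert prof["proportion"].iloc[0] == 0.0

    def test_strong_planted_effect_is_stable(self, null_cohort):
        """g=3 between HEa and the rest: significant in >90% of iterations."""
        cfg = mb.SimConfig(
            seed=31,
            background_loading=0.0,
            planted_effects=[mb.PlantedEffect(0, "HEa", "both", 3.0)],
        )
        mat, meta, annot = mb.simulate_cohort(cfg)
        expr = mb.preprocess(mat)
        prof = stability_profile(
            expr, meta, mb.BootstrapConfig(500, seed=1), "T2", "anova",
            strata=("aggregated",),
        ).set_index("mirna_id")
        assert prof.loc[annot["mirna_id"][0], "proportion"] > 0.9

    def test_null_mirnas_mostly_below_half(self, null_expr):
        expr, meta = null_expr
        prof = stability_profile(
            expr, meta, mb.BootstrapConfig(300, seed=2), "T2", "anova",
            strata=("aggregated",),
        )
        assert prof["proportion"].median() < 0.5

    def test_column_order_invariance_is_exact(self, null_expr):
        expr, meta = null_expr
        cols = list(expr.mirna_ids)[:30]
        sub = mb.NormalizedExpression(expr.dct[cols])
        perm = mb.NormalizedExpression(expr.dct[cols[::-1]])
        boot = mb.BootstrapConfig(100, seed=3)
        a = stability_profile(sub, meta, boot, "T2", strata=("aggregated",))
        b = stability_profile(perm, meta, boot, "T2", strata=("aggregated",))
        merged = a.merge(b, on="mirna_id", suffixes=("_a", "_b"))
        assert (merged["proportion_a"] == merged["proportion_b"]).all()

    def test_row_order_changes_only_monte_carlo_noise(self, null_expr):
        expr, meta = null_expr
        cols = list(expr.mirna_ids)[:40]
        sub = mb.NormalizedExpression(expr.dct[cols])
        shuffled = meta.sample(frac=1.0, random_state=1)
        boot = mb.BootstrapConfig(800, seed=4)
        a = stability_profile(sub, meta, boot, "T2", strata=("aggregated",))
        b = stability_profile(
            mb.NormalizedExpression(sub.dct.loc[shuffled.index]),
            shuffled, boot, "T2", strata=("aggregated",),
        )
        merged = a.merge(b, on="mirna_id", suffixes=("_a", "_b"))
        diff = (merged["proportion_a"] - merged["proportion_b"]).abs()
        assert diff.max() < 0.08  # ~4 binomial SE at B=800

    def test_small_stratum_rejected(self, null_expr):
        expr, meta = null_expr
        tiny = meta[~((meta.group == "UE") & (meta.time_point == "T2"))].iloc[:40]
        with pytest.raises(ValueError):
            stability_profile(
                mb.NormalizedExpression(expr.dct.loc[tiny.index]),
                tiny, mb.BootstrapConfig(10, seed=0), "T2",
            )


class TestClassification:
    @pytest.mark.parametrize(
        "agg,male,female,label",
        [
            (0.30, 0.20, 0.70, "female"),
            (0.30, 0.40, 0.40, "none"),   # fails the 0.5 bar
            (0.55, 0.52, 0.52, "none"),   # not strictly increased... and <=agg
            (0.30, 0.60, 0.70, "both"),
            (0.70, 0.80, 0.10, "male"),   # agg above 0.5 can still be beaten
            (0.50, 0.50, 0.50, "none"),   # ties fail strict rules
        ],
    )
    def test_rule_table(self, agg, male, female, label):
        assert classify_sex_specific(agg, male, female) == label

    def test_agg_cap_option(self):
        assert classify_sex_specific(0.7, 0.9, None, require_agg_below=0.5) == "none"

    def test_classify_profiles_requires_aggregated(self):
        prof = pd.DataFrame(
            {"mirna_id": ["m"], "stratum": ["male"], "proportion": [0.9]}
        )
        with pytest.raises(ValueError):
            classify_profiles(prof)


class TestConcordance:
    def test_identical_profiles_give_one(self):
        assert concordance_r2([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]) == pytest.approx(1.0)

    def test_sign_blind(self):
        assert concordance_r2([0.1, 0.5, 0.9], [0.9, 0.5, 0.1]) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            concordance_r2([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])

    def test_anova_ancova_concordant_without_ga_effects(self, null_expr):
        """GA-independent cohort: ANOVA and ANCOVA profiles agree (R^2 > 0.9)."""
        expr, meta = null_expr
        boot = mb.BootstrapConfig(300, seed=2)
        pa = stability_profile(expr, meta, boot, "T2", "anova", strata=("aggregated",))
        pc = stability_profile(expr, meta, boot, "T2", "ancova", strata=("aggregated",))
        assert concordance_r2(pa["proportion"], pc["proportion"]) > 0.9


class TestModelFacade:
    def test_fit_returns_profiles_labels_and_summary(self, null_expr):
        expr, meta = null_expr
        sub = mb.NormalizedExpression(expr.dct.iloc[:, :25])
        res = mb.StabilityBootstrap(
            sub, meta, "T2", mb.BootstrapConfig(100, seed=6)
        ).fit()
        assert set(res.profiles["stratum"]) == set(STRATA)
        assert len(res.labels) == 25
        assert "Stability bootstrap" in res.summary()
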