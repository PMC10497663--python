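import numpy as np
import pandas as pd
import pytest

from duosync.stats_models import (
    ModelSpec,
    bonferroni_threshold,
    fit_model,
    tukey_contrasts,
)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, m, expected",
        [(0.05, 24, 0.05 / 24), (0.05, 1, 0.05), (0.01, 4, 0.0025)],
    )
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_battery_of_24_models_matches_printed_precision(self):
        assert bonferroni_threshold(0.05, 24) == pytest.approx(0.002083, abs=5e-7)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 3)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def ept_table(rng, n=24, slope=0.0, noise=1.0):
    pianist = rng.integers(13, 29, n)
    singer = rng.integers(13, 29, n)
    phase = slope * (singer - 20.5) + rng.normal(0, noise, n)
    return pd.DataFrame(
        {"duo_id": [f"duo{i}" for i in range(n)], "pianist_ept": pianist,
         "singer_ept": singer, "phase_ms": phase}
    )


class TestFitModel:
    def test_zero_response_gives_null_fit(self):
        table = ept_table(np.random.default_rng(0))
        table["phase_ms"] = 0.0
        fit = fit_model(
            ModelSpec(response="phase_ms", fixed=("singer_ept",)), table
        )
        assert fit.params["singer_ept"] == pytest.approx(0.0, abs=1e-12)
        assert fit.marginal_r2 == 0.0

    def test_planted_slope_recovered_with_ci_excluding_zero(self):
        rng = np.random.default_rng(1)
        table = ept_table(rng, n=24, slope=-10.0, noise=5.0)
        fit = fit_model(
            ModelSpec(response="phase_ms", fixed=("pianist_ept", "singer_ept")),
            table,
        )
        assert fit.params["singer_ept"] < 0
        lo, hi = fit.conf_int.loc["singer_ept"]
        assert hi < 0

    def test_negligible_group_variance_triggers_ols_fallback(self):
        rng = np.random.default_rng(2)
        rows = []
        for d in range(12):
            for _ in range(10):
                for lv, mu in (("half", 10.0), ("four", 5.0)):
                    # no duo-level offset at all: between-duo variance is 0
                    rows.append({"duo_id": f"d{d}", "phrase_level": lv,
                                 "power": mu + rng.normal(0, 0.5)})
        table = pd.DataFrame(rows)
        spec = ModelSpec(response="power", fixed=("phrase_level",),
                         random_intercept="duo_id",
                         baselines={"phrase_level": "four"})
        fit = fit_model(spec, table)
        assert fit.used_ols_fallback

    def test_fallback_matches_mixed_fixed_effects_when_variance_zero(self):
        # deterministic response within level: the OLS fit the fallback
        # produces is the exact solution the mixed model converges to
        rows = []
        for d in range(6):
            for lv, mu in (("half", 10.0), ("four", 5.0)):
                rows.append({"duo_id": f"d{d}", "phrase_level": lv, "power": mu})
        table = pd.DataFrame(rows)
        spec = ModelSpec(response="power", fixed=("phrase_level",),
                         random_intercept="duo_id",
                         baselines={"phrase_level": "four"})
        fit = fit_model(spec, table)
        assert fit.used_ols_fallback
        assert fit.params["Intercept"] == pytest.approx(5.0)
        assert fit.params.iloc[1] == pytest.approx(5.0)

    def test_real_group_variance_keeps_random_intercept(self):
        rng = np.random.default_rng(3)
        rows = []
        for d in range(16):
            offset = rng.normal(0, 5.0)
            for lv, mu in (("half", 10.0), ("one", 8.0), ("four", 5.0)):
                rows.append({"duo_id": f"d{d}", "phrase_level": lv,
                             "power": mu + offset + rng.normal(0, 0.5)})
        table = pd.DataFrame(rows)
        fit = fit_model(
            ModelSpec(response="power", fixed=("phrase_level",),
                      random_intercept="duo_id",
                      baselines={"phrase_level": "four"}),
            table,
        )
        assert not fit.used_ols_fallback
        assert fit.conditional_r2 > fit.marginal_r2

    def test_rank_deficient_design_lists_aliased_terms(self):
        table = ept_table(np.random.default_rng(4))
        table["ept_copy"] = table["singer_ept"]
        with pytest.raises(ValueError, match="aliased"):
            fit_model(
                ModelSpec(response="phase_ms", fixed=("singer_ept", "ept_copy")),
                table,
            )

    def test_nested_term_expands_to_within_factor_dummies(self):
        rng = np.random.default_rng(5)
        rows = []
        for d in range(8):
            for lv in ("half", "four"):
                for take in (0, 2):
                    rows.append({"duo_id": f"d{d}", "phrase_level": lv,
                                 "take": take,
                                 "power": rng.normal(5, 1)})
        table = pd.DataFrame(rows)
        fit = fit_model(
            ModelSpec(response="power", fixed=("phrase_level/take",),
                      categorical=("phrase_level", "take"),
                      baselines={"phrase_level": "four", "take": 0}),
            table,
        )
        # one intercept + 1 level main effect + 2 within-level take terms
        assert len(fit.params) == 4


class TestTukey:
    def test_identical_groups_have_p_one(self):
        table = pd.DataFrame(
            {"g": ["a"] * 3 + ["b"] * 3, "y": [1.0, 2.0, 3.0] * 2}
        )
        fit = fit_model(ModelSpec(response="y", fixed=("g",)), table)
        out = tukey_contrasts(fit, "g")
        assert out.loc[0, "p_adj"] == pytest.approx(1.0, abs=1e-9)

    def test_large_separation_is_significant(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(
            {"g": ["a"] * 10 + ["b"] * 10,
             "y": np.concatenate([rng.normal(0, 1, 10), rng.normal(50, 1, 10)])}
        )
        fit = fit_model(ModelSpec(response="y", fixed=("g",)), table)
        out = tukey_contrasts(fit, "g")
        assert out.loc[0, "p_adj"] < 0.001

    def test_number_of_contrasts_is_choose_2(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(
            {"g": list("abcde") * 4, "y": rng.normal(size=20)}
        )
        fit = fit_model(ModelSpec(response="y", fixed=("g",)), table)
        assert len(tukey_contrasts(fit, "g")) == 10

    def test_single_level_rejected(self):
        table = pd.DataFrame({"g": ["a"] * 4, "y": [1.0, 2.0, 3.0, 4.0]})
        fit = fit_model(ModelSpec(response="y", fixed=("y",)), table)
        with pytest.raises(ValueError, match="2 levels"):
            tukey_contrasts(fit, "g")

    def test_matches_statsmodels_on_separated_groups(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(8)
        y = np.concatenate([rng.normal(m, 1, 8) for m in (0.0, 1.5, 4.0)])
        g = np.repeat(list("abc"), 8)
        table = pd.DataFrame({"g": g, "y": y})
        fit = fit_model(ModelSpec(response="y", fixed=("g",)), table)
        ours = tukey_contrasts(fit, "g")
        ref = pairwise_tukeyhsd(y, g)
        np.testing.assert_allclose(ours["diff"], ref.meandiffs, rtol=1e-10)
        # reference p-values are table-interpolated; compare loosely
        np.testing.assert_allclose(ours["p_adj"], ref.pvalues, atol=0.02)
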