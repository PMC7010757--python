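"""Transforms, VIF screening, OLS, stepwise selection with forced terms,
and hierarchical partitioning against a brute-force all-orderings oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from macrodiv import regression


def orderings_oracle(data, response, terms):
    """Independent contributions via explicit enumeration of all k! orderings."""
    import statsmodels.formula.api as smf

    def r2(subset):
        if not subset:
            return 0.0
        return smf.ols(f"{response} ~ {' + '.join(subset)}", data=data).fit().rsquared

    k = len(terms)
    totals = {t: 0.0 for t in terms}
    for order in itertools.permutations(terms):
        so_far = []
        for t in order:
            before = r2(so_far)
            so_far.append(t)
            totals[t] += r2(so_far) - before
    import math
    return np.array([totals[t] / math.factorial(k) for t in terms])


class TestTransformResponse:
    def test_standardization_contract(self, rng):
        gd = rng.gamma(2.0, 0.005, size=200)
        z = regression.transform_response(gd)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_monotone(self, rng):
        gd = np.sort(rng.gamma(2.0, 0.005, size=50))
        z = regression.transform_response(gd)
        assert np.all(np.diff(z) >= 0)

    def test_zeros_survive_via_epsilon(self):
        z = regression.transform_response(np.array([0.0, 0.01, 0.02]))
        assert np.all(np.isfinite(z))

    def test_constant_input_is_error(self):
        with pytest.raises(ValueError):
            regression.transform_response(np.full(10, 0.02))

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            regression.transform_response(np.zeros(10))


class TestVifScreen:
    def test_near_duplicate_pair_closed_form(self, rng):
        # correlation r gives VIF = 1/(1-r^2); r = 0.98 -> ~25.3 > 5
        x = rng.normal(size=500)
        y = 0.98 * x + np.sqrt(1 - 0.98**2) * rng.normal(size=500)
        df = pd.DataFrame({"a": x, "b": y, "c": rng.normal(size=500)})
        kept, report = regression.vif_screen(df)
        assert len(kept) == 2 and "c" in kept
        assert report["vif"].iloc[0] > 5

    def test_orthogonal_predictors_untouched(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(100, 3)))
        df = pd.DataFrame(q, columns=list("abc"))
        kept, report = regression.vif_screen(df)
        assert kept == list("abc") and report.empty

    def test_duplicated_column_dropped_with_infinite_vif(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        kept, report = regression.vif_screen(df)
        assert len(kept) == 2
        assert np.isinf(report["vif"].iloc[0])


class TestFitLm:
    def test_consistency_small_noise(self, rng):
        x = rng.normal(size=300)
        df = pd.DataFrame({"x": x, "y": 2.0 * x + rng.normal(scale=1e-4, size=300)})
        res = regression.fit_lm(df, "y", ["x"])
        assert res.coef("x") == pytest.approx(2.0, abs=1e-4)
        assert res.conf_int.loc["x", "high"] - res.conf_int.loc["x", "low"] < 1e-4

    def test_cis_contain_estimates_and_adj_r2_below_r2(self, rng):
        df = pd.DataFrame({
            "x1": rng.normal(size=80), "x2": rng.normal(size=80),
            "y": rng.normal(size=80),
        })
        res = regression.fit_lm(df, "y", ["x1", "x2"])
        assert (res.conf_int["low"] <= res.params).all()
        assert (res.params <= res.conf_int["high"]).all()
        assert res.adj_r2 <= res.r2

    def test_null_predictor_coverage(self, rng):
        covered = 0
        for _ in range(200):
            df = pd.DataFrame({"x": rng.normal(size=40), "y": rng.normal(size=40)})
            res = regression.fit_lm(df, "y", ["x"])
            covered += (
                res.conf_int.loc["x", "low"] <= 0 <= res.conf_int.loc["x", "high"]
            )
        assert 0.90 <= covered / 200 <= 0.99

    def test_residuals_orthogonal_to_design(self, rng):
        df = pd.DataFrame({
            "x1": rng.normal(size=60), "x2": rng.normal(size=60),
            "y": rng.normal(size=60),
        })
        res = regression.fit_lm(df, "y", ["x1", "x2"])
        assert df["x1"] @ res.residuals == pytest.approx(0.0, abs=1e-9)
        assert df["x2"] @ res.residuals == pytest.approx(0.0, abs=1e-9)


class TestStepAic:
    def _data(self, rng, n=400):
        df = pd.DataFrame({
            "signal": rng.normal(size=n), "noise": rng.normal(size=n),
            "forced_term": rng.normal(size=n),
        })
        df["y"] = 1.5 * df["signal"] + rng.normal(size=n)
        return df

    def test_zero_effect_predictor_dropped(self, rng):
        dropped = 0
        for _ in range(20):
            df = self._data(rng)
            res = regression.step_aic(
                df, "y", ["signal", "noise", "forced_term"], forced=["forced_term"]
            )
            dropped += "noise" not in res.terms
            assert "signal" in res.terms
        assert dropped >= 16

    def test_forced_zero_effect_term_retained(self, rng):
        df = self._data(rng)
        res = regression.step_aic(
            df, "y", ["signal", "forced_term"], forced=["forced_term"]
        )
        assert "forced_term" in res.terms

    def test_minimal_model_is_fixed_point(self, rng):
        df = self._data(rng)
        res = regression.step_aic(df, "y", ["signal"], forced=["signal"])
        assert res.terms == ["signal"]

    def test_selected_aic_not_above_full(self, rng):
        df = self._data(rng)
        terms = ["signal", "noise", "forced_term"]
        full = regression.fit_lm(df, "y", terms)
        res = regression.step_aic(df, "y", terms, forced=["forced_term"])
        assert res.aic <= full.aic + 1e-9

    def test_categorical_block_moves_whole(self, rng):
        n = 300
        df = pd.DataFrame({
            "g": rng.choice(list("abc"), size=n), "x": rng.normal(size=n),
        })
        df["y"] = df["x"] + rng.normal(size=n)
        res = regression.step_aic(df, "y", ["x", "C(g)"], forced=[])
        assert "C(g)" not in res.terms  # dropped as one block


class TestHierPart:
    def test_single_predictor_equals_simple_r2(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=100)})
        df["y"] = df["x"] + rng.normal(size=100)
        hp = regression.hier_part(df, "y", ["x"])
        assert hp.independent[0] == pytest.approx(hp.full_r2)
        assert hp.relative_pct[0] == pytest.approx(100.0)

    def test_orthogonal_predictors_split_marginally(self, rng):
        raw = rng.normal(size=(200, 2))
        raw -= raw.mean(axis=0)  # centre, then orthogonalize b against a
        raw[:, 1] -= raw[:, 0] * (raw[:, 0] @ raw[:, 1]) / (raw[:, 0] @ raw[:, 0])
        df = pd.DataFrame(raw, columns=["a", "b"])
        df["y"] = 2 * df["a"] + df["b"] + 0.1 * rng.normal(size=200)
        hp = regression.hier_part(df, "y", ["a", "b"])
        import statsmodels.formula.api as smf
        for j, t in enumerate(["a", "b"]):
            marginal = smf.ols(f"y ~ {t}", data=df).fit().rsquared
            assert hp.independent[j] == pytest.approx(marginal, abs=1e-10)

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_matches_all_orderings_oracle(self, rng, k):
        n = 80
        base = rng.normal(size=(n, k))
        base += 0.6 * base[:, [0]]  # induce correlation among predictors
        cols = [f"p{j}" for j in range(k)]
        df = pd.DataFrame(base, columns=cols)
        df["y"] = base @ rng.normal(size=k) + rng.normal(size=n)
        hp = regression.hier_part(df, "y", cols)
        oracle = orderings_oracle(df, "y", cols)
        assert np.allclose(hp.independent, oracle, atol=1e-10)
        assert hp.relative_pct.sum() == pytest.approx(100.0, abs=1e-8)
        assert hp.independent.sum() == pytest.approx(hp.full_r2, abs=1e-8)

    def test_combinatorial_guard(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 14)),
                          columns=[f"p{j}" for j in range(14)])
        df["y"] = rng.normal(size=30)
        with pytest.raises(ValueError, match="12"):
            regression.hier_part(df, "y", [f"p{j}" for j in range(13)])


class TestHabitatLatitudeModel:
    def _cells(self, rng, ratio=1.0, n=150):
        lat = rng.uniform(-60, 60, size=2 * n)
        habitat = np.repeat([1, 0], n)  # marine = 1
        gd = rng.lognormal(mean=np.log(0.005), sigma=0.5, size=2 * n)
        gd[habitat == 0] *= ratio
        return pd.DataFrame({"gd": gd, "latitude": lat, "habitat": habitat})

    def test_identical_distributions_ci_covers_zero(self, rng):
        covered = 0
        for _ in range(40):
            fit, _ = regression.habitat_latitude_model(self._cells(rng, ratio=1.0))
            covered += (
                fit.conf_int.loc["habitat", "low"] <= 0
                <= fit.conf_int.loc["habitat", "high"]
            )
        assert covered >= 33  # ~95% nominal

    def test_doubled_freshwater_diversity_detected(self, rng):
        detected = 0
        for _ in range(20):
            fit, hp = regression.habitat_latitude_model(self._cells(rng, ratio=2.0))
            lo, hi = fit.conf_int.loc["habitat", ["low", "high"]]
            detected += (fit.coef("habitat") < 0) and (hi < 0)
        assert detected >= 18  # freshwater (habitat=0) higher -> negative marine effect

    def test_single_habitat_is_error(self, rng):
        df = self._cells(rng).query("habitat == 1")
        with pytest.raises(ValueError):
            regression.habitat_latitude_model(df)


def test_region_rank_test_orders_groups(rng):
    values = np.concatenate([rng.normal(3, 1, 50), rng.normal(0, 1, 100)])
    regions = np.array(["south_america"] * 50 + ["other"] * 100)
    stat, p = regression.region_rank_test(values, regions, "south_america")
    assert p < 1e-6 and stat > 0
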