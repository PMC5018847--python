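"""Fate coding, Cox fitting, VIF pruning, suite enumeration, AICc
ranking and model averaging."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from nestcam.survival import (
    CoxResult,
    FateCodingError,
    ModelSpec,
    aicc,
    akaike_weights,
    code_fates,
    compute_vif,
    cox_fit,
    enumerate_models,
    km_curve,
    model_average,
    rank_and_weight,
    vif_prune,
)
from nestcam.synthetic import SurvivalTruth, make_null_metric_table, make_survival_table


def _visits(rows):
    return pd.DataFrame(rows, columns=["nest_id", "species", "day", "state"])


class TestFateCoding:
    def test_hatched_nest_censored_at_hatching(self):
        out = code_fates(_visits([("a", "plover", 0, "intact"), ("a", "plover", 25, "hatched")]))
        assert not out.loc[0, "event"]
        assert out.loc[0, "exit_day"] == 25
        assert out.loc[0, "fate_label"] == "hatched"

    def test_predation_event_at_detection_visit(self):
        out = code_fates(
            _visits(
                [
                    ("b", "tern", 0, "intact"),
                    ("b", "tern", 10, "intact"),
                    ("b", "tern", 13, "empty"),
                ]
            )
        )
        assert out.loc[0, "event"]
        assert out.loc[0, "exit_day"] == 13
        assert out.loc[0, "fate_label"] == "predation"

    def test_abandonment_censored_at_last_attended(self):
        out = code_fates(
            _visits(
                [
                    ("c", "plover", 0, "intact"),
                    ("c", "plover", 8, "intact"),
                    ("c", "plover", 11, "abandoned"),
                ]
            )
        )
        assert not out.loc[0, "event"]
        assert out.loc[0, "exit_day"] == 8
        assert out.loc[0, "fate_label"] == "abandonment"

    def test_eggs_reappearing_after_loss_rejected(self):
        with pytest.raises(FateCodingError, match="reappear"):
            code_fates(
                _visits(
                    [
                        ("d", "tern", 0, "intact"),
                        ("d", "tern", 5, "empty"),
                        ("d", "tern", 9, "intact"),
                    ]
                )
            )


class TestVif:
    def test_orthogonal_columns_not_dropped(self, rng):
        n = 60
        df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["x", "y", "z"])
        df["species"] = "plover"
        df["exit_day"] = rng.integers(3, 25, n)
        df["event"] = rng.random(n) < 0.5
        retained, log = vif_prune(df, ["x", "y", "z"])
        assert retained == ["x", "y", "z"] and log == []

    def test_duplicated_column_drops_exactly_one(self, rng):
        n = 60
        x = rng.normal(size=n)
        df = pd.DataFrame({"x": x, "x2": x, "y": rng.normal(size=n)})
        df["species"] = "plover"
        df["exit_day"] = rng.integers(3, 25, n)
        df["event"] = rng.random(n) < 0.5
        retained, log = vif_prune(df, ["x", "x2", "y"])
        assert len(retained) == 2 and "y" in retained
        assert len(log) == 1 and np.isinf(log[0]["vif"])

    def test_vif_matches_explicit_regression_oracle(self, rng):
        n = 200
        z = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "a": z + rng.normal(scale=0.5, size=n),
                "b": z + rng.normal(scale=0.8, size=n),
                "c": rng.normal(size=n),
            }
        )
        vifs = compute_vif(df)
        import statsmodels.api as sm
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        X = sm.add_constant(df.to_numpy())
        for j, col in enumerate(df.columns):
            assert vifs[col] == pytest.approx(variance_inflation_factor(X, j + 1), rel=1e-8)


class TestEnumeration:
    def test_study_scheme_yields_19_models(self):
        metrics = ["DisRat", "VisRat", "CompRat^2", "DeltaE", "PropBgToEggColorMatch"]
        specs = enumerate_models(metrics, ["PropBgToEggColorMatch", "DisRat"])
        assert len(specs) == 19
        names = {s.name for s in specs}
        assert "Species" in names
        assert "Species * DisRat" in names
        assert len({s.key for s in specs}) == 19

    def test_no_metrics_gives_species_only(self):
        specs = enumerate_models([])
        assert len(specs) == 1 and specs[0].terms == ("Species",)

    def test_single_metric_collapses_duplicates(self):
        specs = enumerate_models(["DisRat"])
        assert len(specs) == 4

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError):
            ModelSpec(terms=("Species:DisRat",))


class TestAicc:
    def test_small_sample_formula(self):
        assert aicc(-65.26, 1, 54) == pytest.approx(132.6, abs=0.05)
        assert aicc(-64.59, 2, 54) == pytest.approx(133.4, abs=0.05)

    def test_large_n_limit_is_aic(self):
        assert aicc(-100.0, 3, 10**9) == pytest.approx(206.0, abs=1e-6)

    def test_undefined_below_minimum_n(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestRanking:
    def test_single_model(self):
        out = rank_and_weight([("m", -10.0, 1)], n=50)
        assert out.loc[0, "delta"] == 0.0 and out.loc[0, "weight"] == pytest.approx(1.0)

    def test_equal_models_split_weight(self):
        out = rank_and_weight([("a", -10.0, 1), ("b", -10.0, 1)], n=50)
        assert np.allclose(out["weight"], 0.5)

    def test_weights_sum_to_one_and_best_delta_zero(self, rng):
        rows = [(f"m{i}", float(-rng.uniform(50, 80)), int(rng.integers(1, 5))) for i in range(8)]
        out = rank_and_weight(rows, n=54)
        assert out["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert out.loc[0, "delta"] == 0.0
        assert out["aicc"].is_monotonic_increasing

    def test_ranking_invariant_to_loglik_shift(self, rng):
        rows = [(f"m{i}", float(-rng.uniform(50, 80)), 2) for i in range(5)]
        shifted = [(m, ll + 7.0, k) for m, ll, k in rows]
        r1 = rank_and_weight(rows, n=54)
        r2 = rank_and_weight(shifted, n=54)
        assert list(r1["model"]) == list(r2["model"])
        assert np.allclose(r1["weight"], r2["weight"])


def _fake_fit(name, coefs, ses):
    return CoxResult(
        spec=ModelSpec(terms=tuple(coefs)),
        coefs=pd.Series(coefs),
        ses=pd.Series(ses),
        loglik=0.0,
        k=len(coefs),
    )


class TestModelAverage:
    def test_single_model_identity(self):
        ranking = pd.DataFrame({"model": ["m"], "delta": [0.0], "weight": [1.0]})
        fits = {"m": _fake_fit("m", {"Species": 0.7}, {"Species": 0.2})}
        out = model_average(ranking, fits).set_index("term")
        assert out.loc["Species", "coef"] == pytest.approx(0.7)
        assert out.loc["Species", "se"] == pytest.approx(0.2)
        assert out.loc["Species", "hr"] == pytest.approx(np.exp(0.7))

    def test_opposite_coefficients_cancel(self):
        ranking = pd.DataFrame({"model": ["a", "b"], "delta": [0.0, 0.0], "weight": [0.5, 0.5]})
        fits = {
            "a": _fake_fit("a", {"X": 0.8}, {"X": 0.1}),
            "b": _fake_fit("b", {"X": -0.8}, {"X": 0.1}),
        }
        out = model_average(ranking, fits).set_index("term")
        assert out.loc["X", "coef"] == pytest.approx(0.0)
        assert out.loc["X", "hr"] == pytest.approx(1.0)

    def test_three_model_weighted_sum_oracle(self):
        w = np.array([0.5, 0.3, 0.2])
        b = np.array([0.4, 0.9, -0.1])
        se = np.array([0.2, 0.3, 0.25])
        ranking = pd.DataFrame({"model": list("abc"), "delta": [0.0, 1.0, 1.8], "weight": w})
        fits = {m: _fake_fit(m, {"X": bi}, {"X": si}) for m, bi, si in zip("abc", b, se)}
        out = model_average(ranking, fits).set_index("term")
        b_bar = np.sum(w * b)
        var = np.sum(w * (se**2 + (b - b_bar) ** 2))
        assert out.loc["X", "coef"] == pytest.approx(b_bar)
        assert out.loc["X", "se"] == pytest.approx(np.sqrt(var))
        assert out.loc["X", "hr_upper"] == pytest.approx(np.exp(b_bar + 1.96 * np.sqrt(var)))

    def test_term_weights_renormalized_over_containing_models(self):
        ranking = pd.DataFrame({"model": ["a", "b"], "delta": [0.0, 1.5], "weight": [0.6, 0.4]})
        fits = {
            "a": _fake_fit("a", {"Species": 0.5}, {"Species": 0.1}),
            "b": _fake_fit("b", {"Species": 0.5, "DisRat": 1.0}, {"Species": 0.1, "DisRat": 0.4}),
        }
        out = model_average(ranking, fits).set_index("term")
        # DisRat appears only in model b: conditional average is b's own
        assert out.loc["DisRat", "coef"] == pytest.approx(1.0)
        assert out.loc["DisRat", "n_models"] == 1


class TestCoxFit:
    def _records(self, times, events, x, species=None):
        n = len(times)
        return pd.DataFrame(
            {
                "nest_id": [f"n{i}" for i in range(n)],
                "species": species or ["plover"] * n,
                "exit_day": times,
                "event": events,
                "X": x,
            }
        )

    def test_small_sample_matches_partial_likelihood_maximum(self):
        # 6 nests, one binary covariate, distinct event times
        times = [2.0, 4.0, 5.0, 7.0, 9.0, 11.0]
        events = [True, True, False, True, True, False]
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        rec = self._records(times, events, x)
        res = cox_fit(rec, ModelSpec(terms=("X",)))

        def neg_logpl(beta):
            ll = 0.0
            for i in range(6):
                if not events[i]:
                    continue
                risk = [j for j in range(6) if times[j] >= times[i]]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return -ll

        opt = minimize_scalar(neg_logpl, bounds=(-5, 5), method="bounded")
        assert res.coefs["X"] == pytest.approx(opt.x, abs=1e-4)
        assert res.loglik == pytest.approx(-neg_logpl(opt.x), abs=1e-6)
        assert res.k == 1

    def test_constant_covariate_rejected(self):
        rec = self._records([2, 4, 6, 8], [True, True, False, True], [1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            cox_fit(rec, ModelSpec(terms=("X",)))

    def test_no_events_rejected(self):
        rec = self._records([2, 4, 6], [False, False, False], [0.0, 1.0, 0.5])
        with pytest.raises(ValueError):
            cox_fit(rec, ModelSpec(terms=("X",)))

    def test_planted_continuous_log_hazard_recovered(self):
        cov = make_null_metric_table(1000, 1000, seed=10)
        truth = SurvivalTruth(baseline_hazard=0.01, beta_camouflage={"PropBgToEggColorMatch": 1.0})
        table = make_survival_table(truth, cov, seed=11)
        res = cox_fit(table, ModelSpec(terms=("PropBgToEggColorMatch",)))
        assert 0.9 <= res.coefs["PropBgToEggColorMatch"] <= 1.1

    def test_species_interaction_design(self):
        cov = make_null_metric_table(100, 100, seed=12)
        truth = SurvivalTruth(baseline_hazard=0.02)
        table = make_survival_table(truth, cov, seed=13)
        spec = ModelSpec(terms=("Species", "DisRat", "Species:DisRat"))
        res = cox_fit(table, spec)
        assert res.k == 3
        assert set(res.coefs.index) == {"Species", "DisRat", "Species:DisRat"}


class TestKaplanMeier:
    def _rec(self, times, events, species=None):
        n = len(times)
        return pd.DataFrame(
            {
                "species": species or ["plover"] * n,
                "exit_day": times,
                "event": events,
            }
        )

    def test_no_events_flat_at_one(self):
        out = km_curve(self._rec([5, 10, 25], [False] * 3))
        assert (out["survival"] == 1.0).all()

    def test_single_event_drop(self):
        out = km_curve(self._rec([5, 10, 25, 25], [False, True, False, False]))
        after = out[out["time"] >= 10]["survival"]
        assert after.iloc[0] == pytest.approx(2 / 3)  # 3 at risk at t=10

    def test_matches_hand_product_limit(self):
        # 5 records: events at 3 (5 at risk) and 9 (3 at risk), censor at 6
        out = km_curve(self._rec([3, 6, 9, 12, 15], [True, False, True, False, False]))
        s = out.set_index("time")["survival"]
        assert s.loc[3.0] == pytest.approx(4 / 5)
        assert s.loc[9.0] == pytest.approx(4 / 5 * 2 / 3)
        assert s.loc[15.0] == pytest.approx(4 / 5 * 2 / 3)
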