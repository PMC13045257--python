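"""Kaplan-Meier, log-rank, Cox fitting, screening and risk stratification."""

import numpy as np
import pandas as pd
import pytest

from tcdtyper import (
    CohortConfig,
    InputError,
    cox_fit,
    generate_survival,
    km_estimate,
    logrank_test,
    risk_scores,
    univariate_screen,
    validate_model,
)
from tcdtyper.survival import CoxRiskModel, breslow_partial_loglik
from helpers import breslow_loglik_direct, product_limit


def _surv(times, events, **cov) -> pd.DataFrame:
    df = pd.DataFrame({"os_time": times, "os_event": events})
    for k, v in cov.items():
        df[k] = v
    return df


class TestKaplanMeier:
    def test_all_censored_flat_curve(self):
        curve = km_estimate(_surv([1.0, 2.0, 3.0], [0, 0, 0]))
        assert curve.event_times.size == 0
        assert curve.at(10.0) == 1.0

    def test_hand_product_limit(self):
        curve = km_estimate(_surv([1.0, 2.0, 3.0], [1, 0, 1]))
        assert curve.at(1.0) == pytest.approx(2 / 3)
        assert curve.at(2.5) == pytest.approx(2 / 3)
        assert curve.at(3.0) == pytest.approx(0.0)

    def test_matches_direct_formula(self, rng):
        times = rng.exponential(10.0, size=100).round(1) + 0.1
        events = rng.integers(0, 2, size=100)
        curve = km_estimate(_surv(times, events))
        ref = product_limit(times, events)
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(ref[float(t)], abs=1e-12)

    def test_record_order_invariance(self, rng):
        times = rng.exponential(10.0, size=50) + 0.1
        events = rng.integers(0, 2, size=50)
        a = km_estimate(_surv(times, events))
        perm = rng.permutation(50)
        b = km_estimate(_surv(times[perm], events[perm]))
        assert np.allclose(a.survival, b.survival)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(InputError):
            km_estimate(_surv([0.0, 1.0], [1, 1]))


class TestLogrank:
    def test_identical_groups_no_difference(self):
        g = _surv([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1])
        res = logrank_test([g, g.copy()])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_power_with_planted_hazard(self, seed):
        cfg = CohortConfig(surv_base_hazard=0.05, surv_log_hr_per_severity=1.0,
                           censor_fraction=0.2)
        rng = np.random.default_rng(3000 + seed)
        surv = generate_survival([0] * 200 + [1] * 200, cfg, rng)
        res = logrank_test([surv.iloc[:200], surv.iloc[200:]])
        assert res.p < 0.001

    def test_empty_group_rejected(self):
        g = _surv([1.0], [1])
        with pytest.raises(InputError):
            logrank_test([g, g.iloc[:0]])


class TestCoxFit:
    def test_null_covariate_coverage(self):
        inside = 0
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            times = rng.exponential(10.0, size=150) + 0.01
            events = rng.integers(0, 2, size=150)
            if events.sum() < 2:
                continue
            x = rng.normal(size=150)
            m = cox_fit(_surv(times, events, x=x), ["x"])
            inside += abs(m.beta[0]) < 3 * m.se[0]
        assert inside >= 18

    def test_toy_matches_grid_maximiser(self):
        times = [5.0, 8.0, 2.0, 11.0, 3.0, 7.0]
        events = [1, 0, 1, 1, 1, 0]
        x = [1.0, 0.0, 1.0, 0.0, 0.0, 1.0]
        df = _surv(times, events, x=x)
        model = cox_fit(df, ["x"])
        grid = np.linspace(-4, 4, 80001)
        lls = [
            breslow_loglik_direct(b, np.array(x), np.array(times), np.array(events))
            for b in grid
        ]
        best = grid[int(np.argmax(lls))]
        assert model.beta[0] == pytest.approx(best, abs=1e-4)
        # and the package's own likelihood evaluator agrees at the optimum
        X = df[["x"]].to_numpy()
        assert breslow_partial_loglik(
            model.beta, X, np.array(times), np.array(events)
        ) == pytest.approx(model.loglik, abs=1e-9)

    def test_matches_lifelines_without_ties(self, rng):
        from lifelines import CoxPHFitter

        n = 300
        x1 = rng.normal(size=n)
        x2 = rng.binomial(1, 0.5, size=n).astype(float)
        lam = 0.05 * np.exp(0.7 * x1 - 0.4 * x2)
        times = rng.exponential(1 / lam)
        events = (times < np.quantile(times, 0.8)).astype(int)
        df = _surv(times, events, x1=x1, x2=x2)
        ours = cox_fit(df, ["x1", "x2"])
        cph = CoxPHFitter()
        cph.fit(df.rename(columns={"os_time": "T", "os_event": "E"}), "T", "E")
        assert ours.beta == pytest.approx(cph.params_.to_numpy(), abs=1e-4)
        assert ours.se == pytest.approx(cph.standard_errors_.to_numpy(), abs=1e-4)

    def test_scale_equivariance(self, rng):
        n = 200
        x = rng.normal(size=n)
        times = rng.exponential(1 / (0.05 * np.exp(0.5 * x)))
        df = _surv(times, np.ones(n, dtype=int), x=x)
        base = cox_fit(df, ["x"])
        df2 = df.copy()
        df2["x"] = df2["x"] * 10.0
        scaled = cox_fit(df2, ["x"])
        assert scaled.beta[0] == pytest.approx(base.beta[0] / 10.0, abs=1e-6)

    def test_constant_covariate_rejected(self):
        df = _surv([1.0, 2.0, 3.0], [1, 1, 1], x=[2.0, 2.0, 2.0])
        with pytest.raises(InputError, match="constant"):
            cox_fit(df, ["x"])


class TestUnivariateScreen:
    def test_noise_features_rarely_selected(self):
        selected = 0
        for seed in range(20):
            rng = np.random.default_rng(600 + seed)
            times = rng.exponential(10.0, size=120) + 0.01
            events = rng.integers(0, 2, size=120)
            feats = pd.DataFrame(rng.normal(size=(1, 120)), index=["noise"])
            selected += "noise" in univariate_screen(feats, _surv(times, events))
        assert selected <= 3

    @pytest.mark.parametrize("seed", range(5))
    def test_prognostic_feature_always_selected(self, seed):
        rng = np.random.default_rng(700 + seed)
        n = 500
        x = rng.normal(size=n)
        times = rng.exponential(1 / (0.05 * np.exp(0.8 * x)))
        feats = pd.DataFrame(x[None, :], index=["prog"])
        assert univariate_screen(feats, _surv(times, np.ones(n, dtype=int))) == ["prog"]

    def test_five_of_six_selected(self):
        """Five prognostic features among six are exactly the survivors."""
        rng = np.random.default_rng(11)
        n = 800
        X = rng.normal(size=(6, n))
        eta = 0.6 * X[:5].sum(axis=0) / np.sqrt(5)
        times = rng.exponential(1 / (0.05 * np.exp(eta)))
        feats = pd.DataFrame(X, index=[f"f{i}" for i in range(6)])
        got = univariate_screen(feats, _surv(times, np.ones(n, dtype=int)))
        assert got == [f"f{i}" for i in range(5)]


class TestRiskStratification:
    def _model(self, names, beta):
        b = np.asarray(beta, dtype=float)
        return CoxRiskModel(
            covariates=list(names), beta=b, se=np.ones_like(b),
            p=np.ones_like(b), loglik=0.0, n=0, n_events=0, iterations=0,
        )

    def test_hand_dot_product(self):
        model = self._model(["a", "b"], [1.0, -1.0])
        X = pd.DataFrame({"a": [2.0, 0.0], "b": [3.0, 0.0]}, index=["s1", "s2"])
        strat = risk_scores(model, X)
        assert strat.scores["s1"] == pytest.approx(-1.0)

    def test_zero_coefficients_degenerate(self):
        model = self._model(["a"], [0.0])
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(InputError, match="tie policy|degenerate"):
            risk_scores(model, X)

    def test_median_ties_go_high(self):
        model = self._model(["a"], [1.0])
        X = pd.DataFrame({"a": [1.0, 2.0, 2.0]}, index=["s1", "s2", "s3"])
        strat = risk_scores(model, X)
        assert strat.group["s2"] == "high" and strat.group["s3"] == "high"
        assert strat.group["s1"] == "low"

    def test_positive_coefficient_high_group_has_higher_median(self, rng):
        model = self._model(["a"], [2.0])
        X = pd.DataFrame({"a": rng.normal(size=101)})
        strat = risk_scores(model, X)
        med_high = X.loc[strat.group == "high", "a"].median()
        med_low = X.loc[strat.group == "low", "a"].median()
        assert med_high > med_low

    def test_heldout_stratification_separates_survival(self):
        cfg = CohortConfig(samples_per_subtype=150, seed=21)
        rng = np.random.default_rng(21)
        n = 600
        x = rng.normal(size=n)
        times = rng.exponential(1 / (0.05 * np.exp(1.0 * x)))
        df = _surv(times, np.ones(n, dtype=int), x=x)
        train, test = df.iloc[:300], df.iloc[300:].reset_index(drop=True)
        model = cox_fit(train, ["x"])
        res = validate_model(model, test, test[["x"]])
        assert res.logrank.p < 0.001


class TestValidateModel:
    def _model_and_data(self, seed, effect=1.0, n=300):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        times = rng.exponential(1 / (0.05 * np.exp(effect * x)))
        return _surv(times, np.ones(n, dtype=int), x=x)

    def test_training_data_reproduces_stratification(self):
        df = self._model_and_data(31)
        model = cox_fit(df, ["x"])
        strat = risk_scores(model, df[["x"]])
        res = validate_model(model, df, df[["x"]])
        pd.testing.assert_series_equal(strat.group, res.stratification.group)

    def test_transfer_to_external_cohort(self):
        model = cox_fit(self._model_and_data(32), ["x"])
        external = self._model_and_data(33)
        res = validate_model(model, external, external[["x"]])
        assert res.logrank.p < 0.01

    def test_null_transfer_rejects_at_alpha(self):
        model = cox_fit(self._model_and_data(34), ["x"])
        rejections = 0
        for seed in range(100):
            external = self._model_and_data(4000 + seed, effect=0.0, n=120)
            res = validate_model(model, external, external[["x"]])
            rejections += res.logrank.p < 0.05
        assert abs(rejections / 100 - 0.05) <= 0.07
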