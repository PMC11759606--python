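"""Ridge Cox fitting, concordance, log-rank KM stratification and nomogram."""

import numpy as np
import pandas as pd
import pytest

from pathomil.survival import (apply_stratification, build_nomogram,
                               concordance_index, fit_cox, km_stratify,
                               logrank_test)
from pathomil.synth import simulate_survival


def brute_force_cindex(risk, times, events):
    """Exhaustive pair enumeration under right censoring (higher risk = earlier death)."""
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                num += 1.0 if risk[i] > risk[j] else (0.5 if risk[i] == risk[j] else 0.0)
    return num / den


class TestCox:
    def test_constant_covariate_rejected(self):
        df = simulate_survival(30, seed=0)
        df["flat"] = 1.0
        with pytest.raises(ValueError):
            fit_cox(df[["time_months", "event", "flat"]], covariates=["flat"])

    def test_no_events_rejected(self):
        df = simulate_survival(20, seed=0)
        df["event"] = 0
        with pytest.raises(ValueError):
            fit_cox(df[["time_months", "event", "risk_score"]], covariates=["risk_score"])

    def test_planted_unit_beta_recovered(self):
        df = simulate_survival(200, hazard_coefs=(1.0, 0.0, 0.0),
                               censoring_rate=0.3, seed=0)
        fit = fit_cox(df[["time_months", "event", "risk_score"]],
                      covariates=["risk_score"])
        beta = fit.coefficients["risk_score"]
        assert beta > 0
        assert abs(beta - 1.0) < 0.35

    def test_null_beta_stays_small(self):
        df = simulate_survival(200, hazard_coefs=(0.0, 0.0, 0.0),
                               censoring_rate=0.3, seed=1)
        fit = fit_cox(df[["time_months", "event", "risk_score"]],
                      covariates=["risk_score"])
        assert abs(fit.coefficients["risk_score"]) < 0.25

    def test_sign_agreement_across_simulated_cohorts(self):
        signs = []
        for seed in range(50):
            df = simulate_survival(200, hazard_coefs=(0.8, 0.0, 0.0),
                                   censoring_rate=0.3, seed=100 + seed)
            fit = fit_cox(df[["time_months", "event", "risk_score"]],
                          covariates=["risk_score"])
            signs.append(fit.coefficients["risk_score"] > 0)
        assert all(signs)


class TestCindex:
    def test_perfect_anti_ordering_gives_one(self):
        times = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        risk = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert concordance_index(risk, times, np.ones(5, int)) == 1.0

    def test_constant_risk_gives_half(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index(np.ones(4), times, np.ones(4, int)) == 0.5

    def test_matches_exhaustive_pair_enumeration_with_censoring(self):
        risk = np.array([2.0, 1.0, 3.0, 0.5, 2.5])
        times = np.array([3.0, 8.0, 1.0, 9.0, 4.0])
        events = np.array([1, 1, 1, 0, 1])
        ours = concordance_index(risk, times, events)
        assert ours == pytest.approx(brute_force_cindex(risk, times, events))

    def test_matches_brute_force_on_random_instances(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 12))
            times = rng.exponential(10, n) + 0.1  # continuous: no tied times
            events = rng.integers(0, 2, n)
            risk = rng.normal(size=n).round(2)    # risk ties still exercised
            if events.sum() == 0:
                continue
            try:
                ours = concordance_index(risk, times, events)
            except ValueError:
                continue  # no comparable pairs
            assert ours == pytest.approx(brute_force_cindex(risk, times, events))

    def test_monotone_transform_invariance(self, rng):
        risk = rng.normal(size=30)
        times = rng.exponential(10, 30)
        events = rng.integers(0, 2, 30)
        events[0] = 1
        a = concordance_index(risk, times, events)
        b = concordance_index(np.exp(2 * risk), times, events)
        assert a == pytest.approx(b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            concordance_index(np.ones(3), np.ones(2), np.ones(3))


class TestLogrank:
    def test_maximal_separation_is_significant(self):
        times = np.array([1.0] * 10 + [10.0] * 10)
        groups = np.array([0] * 10 + [1] * 10)
        stat, p = logrank_test(groups, times, np.ones(20, int))
        assert p < 0.001

    def test_single_shared_event_time_statistic_zero(self):
        times = np.ones(8)
        groups = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        stat, _ = logrank_test(groups, times, np.ones(8, int))
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(np.zeros(5), np.ones(5), np.ones(5, int))

    def test_supports_three_groups(self, rng):
        stat, p = logrank_test(rng.integers(0, 3, 60), rng.exponential(10, 60),
                               np.ones(60, int))
        assert 0.0 <= p <= 1.0


class TestKMStratify:
    def test_recovers_planted_split_within_one_grid_step(self):
        rng = np.random.default_rng(0)
        risk = np.where(np.arange(200) < 120, -1.0, 1.0) + rng.normal(0, 0.01, 200)
        df = simulate_survival(200, hazard_coefs=(2.0, 0.0, 0.0),
                               censoring_rate=0.2, risk=risk, seed=3)
        res = km_stratify(df["risk_score"].to_numpy(), df["time_months"].to_numpy(),
                          df["event"].to_numpy())
        assert abs(res["percentile"] - 60) <= 5  # planted boundary at the 60th pct

    def test_deterministic_given_inputs(self):
        df = simulate_survival(100, seed=4)
        args = (df["risk_score"].to_numpy(), df["time_months"].to_numpy(),
                df["event"].to_numpy())
        a, b = km_stratify(*args), km_stratify(*args)
        assert a["percentile"] == b["percentile"] and a["logrank_p"] == b["logrank_p"]

    def test_frozen_threshold_application(self):
        risk = np.array([0.1, 0.5, 0.9])
        np.testing.assert_array_equal(apply_stratification(risk, 0.5), [0, 0, 1])

    def test_degenerate_risk_rejected(self):
        df = simulate_survival(20, seed=5)
        with pytest.raises(ValueError):
            km_stratify(np.ones(20), df["time_months"].to_numpy(),
                        df["event"].to_numpy(), min_group_size=5)


class TestNomogram:
    @staticmethod
    def _fit(coefs=(1.0, 0.3, 0.5), seed=0):
        df = simulate_survival(300, hazard_coefs=coefs, censoring_rate=0.2, seed=seed)
        return fit_cox(df[["time_months", "event", "risk_score", "age", "ki67"]],
                       covariates=["risk_score", "age", "ki67"]), df

    def test_single_covariate_spans_full_axis(self):
        df = simulate_survival(200, hazard_coefs=(1.0, 0.0, 0.0), seed=1)
        fit = fit_cox(df[["time_months", "event", "risk_score"]],
                      covariates=["risk_score"])
        spec = build_nomogram(fit, {"risk_score": (-2.0, 2.0)})
        pts = [spec.points("risk_score", x) for x in (-2.0, 0.0, 2.0)]
        assert pts[0] == pytest.approx(0.0)
        assert pts[2] == pytest.approx(100.0)
        assert pts[1] == pytest.approx(50.0)  # affine in the covariate

    def test_equal_effect_covariates_both_span_100(self):
        fit, _ = self._fit()
        fit.coefficients[:] = [0.5, 0.5, 0.5]
        spec = build_nomogram(fit, {"risk_score": (0.0, 2.0), "age": (30.0, 32.0)})
        assert spec.points("risk_score", 2.0) == pytest.approx(100.0)
        assert spec.points("age", 32.0) == pytest.approx(100.0)

    def test_positive_hazard_covariates_decrease_predicted_survival(self):
        fit, df = self._fit()
        ranges = {"risk_score": (df["risk_score"].min(), df["risk_score"].max()),
                  "age": (df["age"].min(), df["age"].max()),
                  "ki67": (0.01, 0.9)}
        spec = build_nomogram(fit, ranges)
        lo = spec.survival_at(10.0, 60.0)
        hi = spec.survival_at(200.0, 60.0)
        assert hi < lo  # more points (higher hazard) -> lower survival
        for name in ranges:
            assert spec.points(name, ranges[name][1]) >= spec.points(name, ranges[name][0])

    def test_survival_mapping_matches_cox_prediction(self):
        fit, df = self._fit()
        ranges = {"risk_score": (-3.0, 3.0), "age": (27.0, 89.0), "ki67": (0.01, 0.9)}
        spec = build_nomogram(fit, ranges)
        subject = {"risk_score": 1.0, "age": 60.0, "ki67": 0.5}
        total = spec.total_points(subject)
        lp = sum(fit.coefficients[k] * (v - fit.fitter._norm_mean[k])
                 for k, v in subject.items())
        expected = spec.baseline[60.0] ** np.exp(lp)
        assert spec.survival_at(total, 60.0) == pytest.approx(expected, rel=1e-6)

    def test_zero_scale_rejected(self):
        fit, _ = self._fit()
        fit.coefficients[:] = 0.0
        with pytest.raises(ValueError):
            build_nomogram(fit, {"risk_score": (-1.0, 1.0)})

    def test_json_export(self, tmp_path):
        fit, _ = self._fit()
        spec = build_nomogram(fit, {"risk_score": (-2.0, 2.0), "age": (27.0, 89.0),
                                    "ki67": (0.01, 0.9)})
        spec.to_json(tmp_path / "nomogram.json")
        assert (tmp_path / "nomogram.json").stat().st_size > 100
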