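"""Cox fits, logrank, stratification, and the CV permutation scheme."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test
from scipy.stats import kstest

from spathet import (
    bivariate_group,
    km_curves,
    logrank_statistic,
    multiple_cox_stepwise,
    quantile_stratify,
    repeated_cv_permutation,
    simulate_survival,
    univariate_cox,
)
from spathet.survival import _logrank_oev, _logrank_oev_numpy


class TestLogrank:
    def test_matches_lifelines_on_random_data(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 120))
            t = rng.exponential(10, n)
            tie_mask = rng.uniform(size=n) < 0.3
            t[tie_mask] = np.ceil(t[tie_mask])  # introduce tied event times
            e = rng.integers(0, 2, n)
            g = rng.uniform(size=n) < 0.4
            if g.all() or not g.any() or e.sum() == 0:
                continue
            stat, p = logrank_statistic(t, e, g)
            ref = logrank_test(t[g], t[~g], e[g], e[~g])
            assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_numba_kernel_equals_numpy_fallback(self, rng):
        t = np.sort(rng.exponential(10, 80))
        e = rng.integers(0, 2, 80).astype(float)
        g = (rng.uniform(size=80) < 0.5).astype(float)
        assert np.allclose(_logrank_oev(t, e, g), _logrank_oev_numpy(t, e, g))

    def test_degenerate_inputs_return_null(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 1, 1])
        assert logrank_statistic(t, e, np.array([True, True, True])) == (0.0, 1.0)
        assert logrank_statistic(t, np.zeros(3), np.array([True, False, True])) == (0.0, 1.0)


class TestUnivariateCox:
    def test_recovers_protective_hazard_ratio(self, rng):
        z = rng.normal(size=500)
        t, e = simulate_survival(z, np.log(0.5), censoring_rate=0.2, rng=rng)
        res = univariate_cox(z, t, e)
        assert res.ok
        assert 0.4 < res.hr < 0.62
        assert res.ci_low < res.hr < res.ci_high

    def test_null_p_values_approximately_uniform(self):
        pvals = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            z = r.normal(size=80)
            t, e = simulate_survival(np.zeros(80), 0.0, 0.2, rng=r)
            pvals.append(univariate_cox(z, t, e).p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_score_flagged(self):
        t = np.arange(1, 21, dtype=float)
        e = np.ones(20)
        res = univariate_cox(np.full(20, 2.0), t, e)
        assert not res.ok
        assert "constant" in res.message

    def test_too_few_events_flagged(self):
        res = univariate_cox(np.arange(5.0), np.arange(1.0, 6.0), np.zeros(5))
        assert not res.ok


def _clinical_frame(rng, n, time, event, avg=None):
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "os_time": time,
        "os_event": event,
        "age": rng.integers(45, 85, n),
        "gender": rng.choice(["f", "m"], n),
        "grade": rng.choice(["G1", "G2", "G3"], n),
        "avg_expression": rng.normal(15, 3, n) if avg is None else avg,
    })


class TestStepwiseCox:
    def test_pure_noise_candidates_leave_base_model(self, rng):
        n = 120
        t, e = simulate_survival(np.zeros(n), 0.0, 0.2, rng=rng)
        clinical = _clinical_frame(rng, n, t, e)
        # constant-hazard data: noise candidates rarely beat the AIC penalty
        scores = pd.DataFrame({"sample_id": clinical["sample_id"],
                               "noise": rng.normal(size=n)})
        res = multiple_cox_stepwise(scores, clinical)
        if not res.selected_scores:
            assert res.lr_p == 1.0
            assert res.final_loglik == res.base_loglik

    def test_planted_additive_signal_detected(self):
        detections = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 150
            driver = r.normal(size=n)
            t, e = simulate_survival(driver, np.log(2.5), 0.2, rng=r)
            clinical = _clinical_frame(r, n, t, e)
            scores = pd.DataFrame({"sample_id": clinical["sample_id"],
                                   "driver": driver,
                                   "noise": r.normal(size=n)})
            res = multiple_cox_stepwise(scores, clinical)
            if "driver" in res.selected_scores and res.lr_p < 0.05:
                detections += 1
        assert detections >= 8

    def test_collinear_candidate_screened_out(self, rng):
        n = 100
        t, e = simulate_survival(np.zeros(n), 0.0, 0.2, rng=rng)
        avg = rng.normal(15, 3, n)
        clinical = _clinical_frame(rng, n, t, e, avg=avg)
        scores = pd.DataFrame({"sample_id": clinical["sample_id"],
                               "shadow": avg * 2 + 1})  # Spearman rho = 1
        res = multiple_cox_stepwise(scores, clinical)
        assert "shadow" in res.screened_out
        assert "shadow" not in res.selected_scores


class TestQuantileStratify:
    def test_balanced_null_not_small(self, rng):
        pvals = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            n = 80
            score = np.tile([0.0, 1.0], n // 2)
            t, e = simulate_survival(np.zeros(n), 0.0, 0.2, rng=r)
            res = quantile_stratify(score, t, e)
            pvals.append(res.best_p)
        # best-of-quantiles selection inflates small p's, but under the null
        # most cohorts still do not reach significance
        assert np.mean(np.array(pvals) < 0.01) < 0.2

    def test_strong_signal_detected(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            z = r.normal(size=100)
            t, e = simulate_survival(z, np.log(3), 0.2, rng=r)
            res = quantile_stratify(z, t, e)
            if res.best_p < 0.01:
                hits += 1
        assert hits >= 18

    def test_reports_all_valid_cutoffs(self, rng):
        z = rng.normal(size=60)
        t, e = simulate_survival(z, 0.5, 0.2, rng=rng)
        res = quantile_stratify(z, t, e)
        assert len(res.cutoffs) == 3
        assert res.best_cutoff in set(res.cutoffs["cutoff"])
        assert set(res.median_survival) == {"high", "low"}

    def test_constant_score_flagged(self, rng):
        t, e = simulate_survival(np.zeros(30), 0.0, 0.2, rng=rng)
        res = quantile_stratify(np.full(30, 1.0), t, e)
        assert not res.ok


class TestRepeatedCvPermutation:
    def test_single_permutation_p_floor(self, rng):
        z = rng.normal(size=40)
        t, e = simulate_survival(z, 0.0, 0.2, rng=rng)
        res = repeated_cv_permutation(z, t, e, n_repeats=3, k=4, m=1, seed=0)
        assert set(np.unique(res.p_values)) <= {0.5, 1.0}

    def test_empirical_p_never_zero(self, rng):
        z = rng.normal(size=50)
        t, e = simulate_survival(z, np.log(4), 0.1, rng=rng)
        res = repeated_cv_permutation(z, t, e, n_repeats=3, k=5, m=50, seed=0)
        assert np.all(res.p_values >= 1 / 51)

    def test_strong_signal_small_median_p(self, rng):
        z = rng.normal(size=60)
        t, e = simulate_survival(z, np.log(3), 0.3, rng=rng)
        res = repeated_cv_permutation(z, t, e, n_repeats=5, k=5, m=200, seed=1)
        assert res.median_p <= 0.05

    def test_deterministic_under_seed(self, rng):
        z = rng.normal(size=40)
        t, e = simulate_survival(z, 0.5, 0.2, rng=rng)
        a = repeated_cv_permutation(z, t, e, n_repeats=2, k=4, m=30, seed=9)
        b = repeated_cv_permutation(z, t, e, n_repeats=2, k=4, m=30, seed=9)
        np.testing.assert_array_equal(a.p_values, b.p_values)
        np.testing.assert_array_equal(a.statistics, b.statistics)


class TestBivariateGroup:
    def test_orthogonal_balanced_features_four_equal_groups(self, rng):
        n = 80
        score = np.tile([0.0, 1.0], n // 2)
        avg = np.repeat([0.0, 1.0], n // 2)
        t, e = simulate_survival(np.zeros(n), 0.0, 0.2, rng=rng)
        groups = bivariate_group(score, avg, 0.5, 0.5, t, e)
        assert list(groups["n"]) == [20, 20, 20, 20]

    def test_constant_feature_warns_with_two_groups(self, rng):
        n = 40
        score = np.tile([0.0, 1.0], n // 2)
        t, e = simulate_survival(np.zeros(n), 0.0, 0.2, rng=rng)
        with pytest.warns(UserWarning, match="fewer than 4"):
            groups = bivariate_group(score, np.full(n, 1.0), 0.5, 0.5, t, e)
        assert (groups["n"] > 0).sum() == 2

    def test_planted_interaction_orders_group_medians(self, rng):
        """Hazard rises only when expression is high AND heterogeneity is low."""
        n = 200
        score = np.tile([0.0, 1.0], n // 2)
        avg = np.repeat([0.0, 1.0], n // 2)
        lin = np.where((avg >= 0.5) & (score < 0.5), 1.5, 0.0)
        t, e = simulate_survival(lin, 1.0, 0.1, rng=rng)
        groups = bivariate_group(score, avg, 0.5, 0.5, t, e).set_index(
            ["score", "avg_expression"])
        worst = groups.loc[("low", "high"), "median_survival"]
        others = groups.drop(index=("low", "high"))["median_survival"]
        assert (worst < others).all()


class TestKmCurves:
    def test_curves_start_at_one_and_decrease(self, rng):
        z = rng.normal(size=60)
        t, e = simulate_survival(z, np.log(2), 0.2, rng=rng)
        curves = km_curves(t, e, z > 0)
        for name, curve in curves.items():
            s = curve["survival"].to_numpy()
            assert s[0] == 1.0
            assert np.all(np.diff(s) <= 1e-12)
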