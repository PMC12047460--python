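"""Scoring: matching, beat/patient metrics, GEE adjustment, agreement."""

import math

import networkx as nx
import numpy as np
import pytest

from ectopy.errors import InvalidInputError
from ectopy.evaluation import (beat_metrics, burden_agreement, f1_score,
                               gee_adjusted, match, patient_average,
                               threshold_metrics, MetricSet)


def optimal_match_oracle(det, ref, tol):
    """Independent maximum-cardinality, minimum-|Δt| matching via networkx."""
    g = nx.Graph()
    g.add_nodes_from((("d", i) for i in range(len(det))))
    g.add_nodes_from((("r", j) for j in range(len(ref))))
    for i, d in enumerate(det):
        for j, r in enumerate(ref):
            if abs(d - r) <= tol:
                g.add_edge(("d", i), ("r", j), weight=10.0 * tol - abs(d - r))
    pairs = nx.max_weight_matching(g, maxcardinality=True)
    total = sum(abs(det[a[1]] - ref[b[1]]) if a[0] == "d"
                else abs(det[b[1]] - ref[a[1]]) for a, b in pairs)
    return len(pairs), total


class TestMatch:
    def test_detection_within_tolerance_is_tp(self):
        m = match([10.10], [10.00], 0.150)
        assert m.n_tp == 1 and m.n_fp == 0 and m.n_fn == 0

    def test_detection_outside_tolerance_is_fp_plus_fn(self):
        m = match([10.20], [10.00], 0.150)
        assert m.n_tp == 0 and m.n_fp == 1 and m.n_fn == 1

    def test_two_detections_one_reference_keeps_closer(self):
        m = match([9.94, 10.05], [10.00], 0.150)
        assert m.n_tp == 1 and m.n_fp == 1
        assert m.tp[0][0] == 10.05  # the closer detection

    def test_detection_near_excluded_reference_not_counted_as_fp(self):
        m = match([10.0, 20.0], [10.0], 0.150, excluded_references=[20.05])
        assert m.n_tp == 1 and m.n_fp == 0
        assert m.excluded == [20.0]

    def test_blocking_configuration_still_matches_both(self):
        # the nearest pairing for the first detection would strand the second
        m = match([0.01, -0.10], [0.00, 0.14], 0.150)
        assert m.n_tp == 2

    def test_equals_optimal_assignment_on_random_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(300):
            nd, nr = rng.integers(0, 7, size=2)
            det = sorted(rng.uniform(0, 3, nd))
            ref = sorted(rng.uniform(0, 3, nr))
            m = match(det, ref, 0.150)
            n_opt, dt_opt = optimal_match_oracle(det, ref, 0.150)
            assert m.n_tp == n_opt
            total = sum(abs(d - r) for d, r in m.tp)
            assert total <= dt_opt + 1e-9


class TestBeatMetrics:
    def test_printed_benchmark_arithmetic(self):
        """Counts chosen to reproduce 87.9 / 96.4 / 91.9 to print precision."""
        m = match([], [], 0.150)
        m.tp = [(0.0, 0.0)] * 879
        m.fp = [0.0] * 33
        m.fn = [0.0] * 121
        ms = beat_metrics(m, n_detected_beats=20000)
        assert round(100 * ms.sensitivity, 1) == 87.9
        assert round(100 * ms.ppv, 1) == 96.4
        assert round(100 * ms.f1, 1) == 91.9

    def test_no_tp_gives_zero_sensitivity_and_f1(self):
        m = match([], [1.0, 2.0], 0.150)
        ms = beat_metrics(m, 100)
        assert ms.sensitivity == 0.0 and ms.f1 == 0.0

    def test_no_fp_gives_perfect_ppv_and_specificity(self):
        m = match([1.0], [1.0], 0.150)
        ms = beat_metrics(m, 100)
        assert ms.ppv == 1.0 and ms.specificity == 1.0

    def test_zero_denominator_is_undefined(self):
        m = match([], [], 0.150)
        ms = beat_metrics(m, 100)
        assert math.isnan(ms.sensitivity) and math.isnan(ms.ppv)


class TestF1:
    def test_symmetric_and_idempotent(self):
        assert f1_score(0.6, 0.9) == f1_score(0.9, 0.6)
        assert f1_score(0.7, 0.7) == pytest.approx(0.7)

    def test_bounded_by_components(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s, p = rng.uniform(0.01, 1, 2)
            f = f1_score(s, p)
            assert min(s, p) <= f <= max(s, p)


class TestPatientAverage:
    def test_unweighted_mean(self):
        ms = patient_average([MetricSet(sensitivity=0.8),
                              MetricSet(sensitivity=0.6)])
        assert ms.sensitivity == pytest.approx(0.7)

    def test_single_patient_identity(self):
        ms = patient_average([MetricSet(sensitivity=0.55, ppv=0.9)])
        assert ms.sensitivity == 0.55 and ms.ppv == 0.9

    def test_undefined_patients_excluded_from_mean(self):
        ms = patient_average([MetricSet(sensitivity=0.8), MetricSet()])
        assert ms.sensitivity == pytest.approx(0.8)

    def test_gross_differs_from_patient_average_with_dominant_patient(self):
        # patient A: 900/1000; patient B: 1/10 — recount both levels directly
        per = [MetricSet(sensitivity=0.9), MetricSet(sensitivity=0.1)]
        gross = (900 + 1) / (1000 + 10)
        assert patient_average(per).sensitivity == pytest.approx(0.5)
        assert gross == pytest.approx(0.8920792079)


def _gee_moment_oracle(data, tol=1e-13, max_iter=1000):
    """Intercept-only exchangeable-GEE fixed point (moment estimator)."""
    ys = [np.r_[np.ones(s), np.zeros(t - s)] for s, t in data]
    n_obs = sum(len(y) for y in ys)
    p = 1
    mu = sum(y.sum() for y in ys) / n_obs
    rho = 0.0
    for _ in range(max_iter):
        v = mu * (1 - mu)
        res = [(y - mu) / np.sqrt(v) for y in ys]
        scale = sum((r ** 2).sum() for r in res) / (n_obs - p)
        num = sum((r.sum() ** 2 - (r ** 2).sum()) / 2 for r in res)
        den = sum(len(r) * (len(r) - 1) / 2 for r in res) - p
        rho_new = num / den / scale
        w_num = w_den = 0.0
        for y in ys:
            n = len(y)
            w = 1 / (1 + (n - 1) * rho_new)
            w_num += w * y.sum()
            w_den += w * n
        mu_new = w_num / w_den
        if abs(mu_new - mu) < tol and abs(rho_new - rho) < tol:
            return mu_new
        mu, rho = mu_new, rho_new
    return mu


class TestGeeAdjusted:
    def test_equal_proportions_recovered(self):
        g = gee_adjusted([(5, 10), (50, 100), (10, 20)])
        assert g.estimate == pytest.approx(0.5, abs=1e-9)

    def test_degenerate_all_success(self):
        g = gee_adjusted([(10, 10), (5, 5)])
        assert g.degenerate and g.estimate == 1.0
        assert math.isnan(g.ci95[0])

    def test_matches_moment_oracle_on_clustered_binomial(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            data = []
            for _ in range(10):
                p = rng.beta(4, 4)
                t = int(rng.integers(20, 120))
                s = int(np.clip(rng.binomial(t, p), 1, t - 1))
                data.append((s, t))
            g = gee_adjusted(data)
            assert abs(g.estimate - _gee_moment_oracle(data)) < 1e-6

    def test_needs_two_clusters(self):
        with pytest.raises(InvalidInputError):
            gee_adjusted([(3, 10)])


class TestBurdenAgreement:
    def test_identity_gives_perfect_agreement(self):
        est = [1.0, 5.0, 10.0, 20.0]
        r, bias, _ = burden_agreement(est, est)
        assert r == pytest.approx(1.0)
        assert bias == pytest.approx(0.0)

    def test_constant_underestimate_shows_as_bias(self):
        ref = np.array([2.0, 7.5, 12.0, 25.0, 40.0])
        r, bias, loa = burden_agreement(ref - 1.83, ref)
        assert bias == pytest.approx(-1.83)
        assert r == pytest.approx(1.0)
        assert loa[0] == pytest.approx(-1.83) and loa[1] == pytest.approx(-1.83)

    def test_r_matches_independent_correlation(self):
        rng = np.random.default_rng(9)
        est, ref = rng.uniform(0, 30, 40), rng.uniform(0, 30, 40)
        r, _, _ = burden_agreement(est, ref)
        assert r == pytest.approx(float(np.corrcoef(est, ref)[0, 1]), abs=1e-12)

    def test_zero_variance_r_undefined(self):
        r, bias, _ = burden_agreement([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        assert math.isnan(r)


class TestThresholdMetrics:
    def test_38_positive_patients_32_detected_none_false(self):
        ref = [15.0] * 38 + [2.0] * 51
        est = [15.0] * 32 + [5.0] * 6 + [2.0] * 51
        sens, spec, ppv = threshold_metrics(est, ref, 10.0)
        assert round(100 * sens) == 84
        assert spec == 1.0 and ppv == 1.0

    def test_identity_estimates_are_perfect(self):
        ref = [1.0, 12.0, 30.0]
        assert threshold_metrics(ref, ref, 10.0) == (1.0, 1.0, 1.0)

    def test_zero_threshold_degenerates_to_full_sensitivity(self):
        sens, _, _ = threshold_metrics([0.0, 0.0], [20.0, 1.0], 0.0)
        assert sens == 1.0

    def test_lower_threshold_compensates_systematic_underestimation(self):
        # a detector that underestimates by ~1.8 ppt misses borderline
        # patients at 10% but recovers them at 5% (hand-checked: 3/4 -> 5/6)
        ref = np.array([3.0, 6.0, 8.0, 11.0, 14.0, 20.0, 30.0])
        est = ref - 1.8
        sens10, _, _ = threshold_metrics(est, ref, 10.0)
        sens5, _, _ = threshold_metrics(est, ref, 5.0)
        assert sens10 == pytest.approx(3 / 4)
        assert sens5 == pytest.approx(5 / 6)
        assert sens5 >= sens10
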