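"""Evaluation statistics: delta vectors, mu/sigma, Wilcoxon, regression, boxplots."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from dvhgru.dvh import DoseVolumeHistogram, compute_eud, default_oar_config
from dvhgru.evaluation import (
    boxplot_stats,
    evaluate_predictions,
    mu_sigma,
    pooled_regression,
    prediction_errors,
    wilcoxon_signed_rank,
)

CORD = default_oar_config("spinal_cord")
PAROTID = default_oar_config("parotid_l")


def _exact_wilcoxon_oracle(da, db):
    """Independent route: DP over the signed-rank distribution (scaled ranks)."""
    d = np.asarray(da, float) - np.asarray(db, float)
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    scaled = np.round(ranks * 2).astype(int)  # tie-averaged ranks -> integers
    w_obs = int(round(scaled[d > 0].sum()))
    total = scaled.sum()
    # distribution of W+ by dynamic programming over rank inclusion
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in scaled:
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    dist /= dist.sum()
    p_le = dist[: w_obs + 1].sum()
    p_ge = dist[w_obs:].sum()
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestPredictionErrors:
    def _case(self, doses, name="spinal_cord"):
        from dvhgru.cohort import PatientCase
        from dvhgru.dvh import BeamDVHSet

        dvh = DoseVolumeHistogram(doses)
        beams = BeamDVHSet((dvh,) * 9)
        return PatientCase("P000", {name: (beams, dvh)})

    def test_perfect_predictions_give_zero_delta(self):
        case = self._case(np.linspace(40, 2, 100))
        errs = prediction_errors([case.oars["spinal_cord"][1]], [case], CORD)
        np.testing.assert_allclose(errs["eud"], 0.0)
        np.testing.assert_allclose(errs["dmax"], 0.0)

    def test_delta_is_predicted_minus_plan(self):
        case = self._case(np.full(100, 50.0))
        pred = DoseVolumeHistogram(np.full(100, 52.0))
        errs = prediction_errors([pred], [case], CORD)
        assert errs["eud"][0] == pytest.approx(2.0)
        assert errs["dmax"][0] == pytest.approx(2.0)

    def test_parallel_organ_has_no_dmax(self):
        case = self._case(np.full(100, 20.0), name="parotid_l")
        errs = prediction_errors([case.oars["parotid_l"][1]], [case], PAROTID)
        assert set(errs) == {"eud"}

    def test_missing_prediction_named(self):
        case = self._case(np.full(100, 20.0))
        with pytest.raises(ValueError, match="P000"):
            prediction_errors({}, [case], CORD)


class TestMuSigma:
    def test_plus_minus_one(self):
        mu, sigma = mu_sigma([1.0, -1.0])
        assert mu == 0.0
        assert sigma == 1.0  # population denominator n

    def test_single_value(self):
        mu, sigma = mu_sigma([3.2])
        assert (mu, sigma) == (3.2, 0.0)

    def test_translation_invariance_of_sigma(self, rng):
        d = rng.normal(size=20)
        mu0, sd0 = mu_sigma(d)
        mu1, sd1 = mu_sigma(d + 5.0)
        assert mu1 == pytest.approx(mu0 + 5.0)
        assert sd1 == pytest.approx(sd0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mu_sigma([])


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_n3_same_sign_exact(self):
        # all 2^3 sign assignments: P(W=6)=1/8, two-sided p = 0.25
        p = wilcoxon_signed_rank([1.0, 2.0, 3.0], [0.5, 1.0, 2.0])
        assert p == pytest.approx(0.25)

    def test_symmetric_under_method_swap(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(size=9)
        assert wilcoxon_signed_rank(a, b) == pytest.approx(
            wilcoxon_signed_rank(b, a)
        )

    @given(st.integers(0, 100_000))
    @settings(max_examples=60, deadline=None)
    def test_exact_mode_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        a = rng.normal(size=n)
        # mix of continuous values and ties
        b = a + rng.choice([-1.0, 0.5, 1.0, 2.0], size=n)
        p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(_exact_wilcoxon_oracle(a, b), abs=1e-12)

    def test_agrees_with_scipy_exact_when_tie_free(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 15))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            ours = wilcoxon_signed_rank(a, b)
            ref = sps.wilcoxon(a - b, method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_large_n_normal_approximation(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(loc=0.3, size=40)
        ours = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a - b, method="approx", correction=False).pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_absolute_error_pairing_flag(self):
        a = np.array([3.0, -3.0, 2.0, -2.0])
        b = np.array([1.0, -1.0, 0.5, -0.5])
        p_signed = wilcoxon_signed_rank(a, b)
        p_abs = wilcoxon_signed_rank(a, b, use_absolute=True)
        assert p_signed != p_abs  # signs matter only in the signed pairing


class TestPooledRegression:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept, r = pooled_regression(x, x)
        assert (slope, intercept, r) == pytest.approx((1.0, 0.0, 1.0))

    def test_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0])
        _, _, r = pooled_regression(-x, x)
        assert r == pytest.approx(-1.0)

    def test_closed_form_example(self):
        # pairs (plan, predicted): (1,2), (2,3), (3,5)
        _, _, r = pooled_regression([2.0, 3.0, 5.0], [1.0, 2.0, 3.0])
        assert r == pytest.approx(0.981980506, abs=1e-6)

    def test_scale_invariance_of_r(self, rng):
        x = rng.uniform(10, 60, size=25)
        y = x + rng.normal(size=25)
        _, _, r0 = pooled_regression(y, x)
        _, _, r1 = pooled_regression(2.5 * y + 7.0, 0.5 * x - 3.0)
        assert r1 == pytest.approx(r0, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pooled_regression([1.0, 2.0], [3.0, 3.0])


class TestBoxplotStats:
    def test_one_to_seven(self):
        s = boxplot_stats(np.arange(1.0, 8.0))
        assert s["median"] == 4.0
        assert s["q1"] == 2.5
        assert s["q3"] == 5.5
        assert len(s["outliers"]) == 0
        assert s["whisker_lo"] == 1.0 and s["whisker_hi"] == 7.0

    def test_constant_vector(self):
        s = boxplot_stats(np.full(5, 2.0))
        assert s["iqr"] == 0.0
        assert len(s["outliers"]) == 0

    def test_far_point_becomes_single_outlier(self):
        base = np.arange(1.0, 8.0)
        s0 = boxplot_stats(base)
        spiked = np.append(base, s0["q3"] + 10 * s0["iqr"])
        s1 = boxplot_stats(spiked)
        assert len(s1["outliers"]) == 1


def test_report_assembly_and_linearity(small_cohort):
    """mu of delta equals difference of endpoint means; report fields coherent."""
    cases = small_cohort.test_cases
    plans = [c.oars["spinal_cord"][1] for c in cases]
    shifted = [DoseVolumeHistogram(p.doses + 1.5) for p in plans]
    report = evaluate_predictions(
        {"spinal_cord": shifted}, cases, {"spinal_cord": CORD},
        comparison_by_oar={"spinal_cord": plans},
    )
    by_ep = {s.endpoint: s for s in report.summaries}
    pred_euds = [compute_eud(p, 8) for p in shifted]
    plan_euds = [compute_eud(p, 8) for p in plans]
    assert by_ep["eud"].mu == pytest.approx(np.mean(pred_euds) - np.mean(plan_euds))
    assert by_ep["dmax"].mu == pytest.approx(1.5)
    assert by_ep["eud"].p_value is not None
    assert report.pooled_r > 0.99  # constant shift keeps perfect correlation
    assert "pooled OLS" in report.summary()
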