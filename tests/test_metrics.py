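import numpy as np
import pytest
from scipy.stats import rankdata

from wriststep.io import NONWALK, WALK
from wriststep.metrics import (EvalReport, bland_altman,
                               classification_metrics, icc_agreement, mape,
                               mean_bias_percent, spearman)


class TestMAPEAndBias:
    def test_perfect_agreement(self):
        assert mape([100, 200], [100, 200]) == 0.0
        assert mean_bias_percent([100, 200], [100, 200]) == 0.0

    def test_hand_arithmetic(self):
        assert mape([100, 200], [90, 220]) == pytest.approx(10.0)
        assert mape([863], [971]) == pytest.approx(108 / 863 * 100)

    def test_bias_cancellation_unlike_mape(self):
        assert mean_bias_percent([100, 100], [90, 110]) == pytest.approx(0.0)
        assert mape([100, 100], [90, 110]) == pytest.approx(10.0)

    def test_uniform_overcount(self):
        assert mean_bias_percent([100, 300], [110, 330]) == pytest.approx(10.0)

    def test_zero_true_count_errors(self):
        with pytest.raises(ValueError):
            mape([0, 100], [10, 100])

    def test_bias_bounded_by_mape(self, rng):
        for _ in range(50):
            t = rng.integers(1, 5000, 10).astype(float)
            p = np.maximum(0, t + rng.normal(0, 300, 10))
            assert abs(mean_bias_percent(t, p)) <= mape(t, p) + 1e-12


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        t = np.array([100.0, 400, 900, 1600])
        assert spearman(t, np.sqrt(t)) == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        assert spearman([1, 2, 3, 4], [9, 7, 5, 3]) == pytest.approx(-1.0)

    def test_tied_table_matches_rank_pearson(self):
        t = np.array([1.0, 2, 3, 4])
        p = np.array([10.0, 20, 20, 40])
        rt, rp = rankdata(t), rankdata(p)
        expected = np.corrcoef(rt, rp)[0, 1]
        assert spearman(t, p) == pytest.approx(expected)

    def test_constant_vector_warns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(spearman([1, 2, 3], [5, 5, 5]))


class TestBlandAltman:
    def test_perfect_agreement_zero_limits(self):
        ba = bland_altman([100, 200, 300], [100, 200, 300])
        assert (ba.mean_diff, ba.lower, ba.upper) == (0.0, 0.0, 0.0)

    def test_hand_sd_computation(self):
        ba = bland_altman([100, 100], [90, 110])
        sd = np.std([-10, 10], ddof=1)  # = sqrt(200)
        assert ba.mean_diff == pytest.approx(0.0)
        assert ba.upper == pytest.approx(1.96 * sd)
        assert ba.lower == pytest.approx(-1.96 * sd)

    def test_limits_symmetric_about_mean(self, rng):
        t = rng.integers(100, 5000, 20).astype(float)
        p = t + rng.normal(0, 200, 20)
        ba = bland_altman(t, p)
        assert ba.upper - ba.mean_diff == pytest.approx(ba.mean_diff - ba.lower)


def _icc2_hand(a, b):
    """Two-way absolute-agreement single-rater ICC from ANOVA mean squares."""
    Y = np.column_stack([a, b]).astype(float)
    n, k = Y.shape
    mean_r = Y.mean(axis=1)
    mean_c = Y.mean(axis=0)
    grand = Y.mean()
    msr = k * np.sum((mean_r - grand) ** 2) / (n - 1)
    msc = n * np.sum((mean_c - grand) ** 2) / (k - 1)
    sse = np.sum((Y - mean_r[:, None] - mean_c[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_annotations_give_one(self):
        assert icc_agreement([100, 250, 980], [100, 250, 980]) == pytest.approx(1.0)

    def test_constant_rater_near_zero(self):
        a = [1.0, 2.0, 3.0]
        b = [2.0, 2.0, 2.0]
        got = icc_agreement(a, b)
        assert got == pytest.approx(_icc2_hand(a, b), abs=1e-9)
        assert abs(got) < 0.3

    def test_four_pair_table_matches_anova_formula(self):
        a = [100.0, 220, 310, 440]
        b = [110.0, 200, 330, 420]
        assert icc_agreement(a, b) == pytest.approx(_icc2_hand(a, b), abs=1e-9)

    def test_zero_variance_both_raters_flagged(self):
        with pytest.warns(UserWarning):
            assert icc_agreement([5, 5, 5], [5, 5, 5]) == 1.0


class TestClassification:
    def test_perfect_predictions(self):
        t = np.array([WALK] * 10 + [NONWALK] * 30)
        m = classification_metrics(t, t)
        assert (m.precision, m.recall, m.f1, m.kappa, m.accuracy) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_hand_confusion_arithmetic(self):
        # TP 40, FN 10, FP 20, TN 130
        t = np.array([WALK] * 50 + [NONWALK] * 150)
        p = np.array([WALK] * 40 + [NONWALK] * 10 +
                     [WALK] * 20 + [NONWALK] * 130)
        m = classification_metrics(t, p)
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(0.8)
        assert m.f1 == pytest.approx(2 * (2 / 3) * 0.8 / (2 / 3 + 0.8))
        assert m.accuracy == pytest.approx(0.85)
        # po=0.85, pe=0.25*0.3 + 0.75*0.7 = 0.6
        assert m.kappa == pytest.approx((0.85 - 0.6) / 0.4)

    def test_random_predictions_have_near_zero_kappa(self, rng):
        t = (rng.random(20000) < 0.1).astype(int)
        p = (rng.random(20000) < 0.1).astype(int)
        assert abs(classification_metrics(t, p).kappa) < 0.03

    def test_no_positive_predictions_warns(self):
        t = np.array([WALK, NONWALK, NONWALK, WALK])
        p = np.array([NONWALK] * 4)
        with pytest.warns(UserWarning, match="precision"):
            m = classification_metrics(t, p)
        assert np.isnan(m.precision)


def test_eval_report_round_trip_and_order_invariance():
    ids = ["a", "b", "c"]
    t = [1000.0, 2000, 500]
    p = [950.0, 2100, 510]
    r1 = EvalReport.from_counts(ids, t, p)
    r2 = EvalReport.from_counts(ids[::-1], t[::-1], p[::-1])
    assert r1.mape == pytest.approx(r2.mape)
    assert r1.mean_bias == pytest.approx(r2.mean_bias)
    d = r1.to_dict()
    assert d["n_participants"] == 3
    assert "mape_pct" in d and "bland_altman" in d
    assert "MAPE" in r1.summary()
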