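import numpy as np
import pytest

from wriststep.io import NONWALK, WALK
from wriststep.peaks import (PeakGrid, PeakParams, find_step_peaks,
                             hybrid_count, tune_peak_params)
from wriststep.preprocess import ConditionedSignal
from wriststep.reference import naive_find_peaks
from wriststep.simulate import Bout, GaitScenario, simulate_recording


def _sig(values, fs=100.0):
    return ConditionedSignal(np.asarray(values, float), fs)


def test_constant_signal_has_no_peaks():
    idx = find_step_peaks(_sig(np.full(500, 0.3)), PeakParams(0.1, 0.2, 1.0))
    assert len(idx) == 0


def test_sinusoid_peak_count_closed_form():
    # small phase offset keeps crests off exact two-sample plateaus
    t = np.arange(1000) / 100.0
    v = 0.5 * np.sin(2 * np.pi * 2.0 * t + 0.3)
    params = PeakParams(0.3, 0.3, 0.5)
    idx = find_step_peaks(_sig(v), params)
    assert len(idx) == 20  # 2 Hz over 10 s
    np.testing.assert_array_equal(
        idx, naive_find_peaks(v, 100.0, 0.3, 0.3, 0.5))


def test_distance_pruning_keeps_higher_peak():
    # two triangular peaks 1.0 and 0.8 g, 8 samples apart (0.08 s at 100 Hz)
    v = np.zeros(20)
    v[5] = 1.0
    v[4] = v[6] = 0.5
    v[13] = 0.8
    v[12] = v[14] = 0.4
    idx = find_step_peaks(_sig(v), PeakParams(0.1, 0.2, 1.0))
    assert idx.tolist() == [5]
    assert naive_find_peaks(v, 100.0, 0.1, 0.2, 1.0).tolist() == [5]


def test_oracle_equivalence_random_signals(rng):
    for _ in range(100):
        n = int(rng.integers(20, 800))
        fs = float(rng.choice([15.0, 25.0, 50.0, 100.0]))
        v = rng.normal(0, 0.3, n)
        if rng.random() < 0.5:
            k = int(rng.integers(2, 8))
            v = np.convolve(v, np.ones(k) / k, "same")
        p = PeakParams(float(rng.uniform(0.05, 0.6)),
                       float(rng.uniform(0.05, 1.0)),
                       float(rng.uniform(0.05, 1.0)))
        fast = find_step_peaks(_sig(v, fs), p)
        slow = naive_find_peaks(v, fs, p.prominence, p.distance, p.width_max)
        np.testing.assert_array_equal(fast, slow)


def test_monotone_in_prominence_and_distance(rng):
    v = np.convolve(rng.normal(0, 0.4, 600), np.ones(4) / 4, "same")
    base = len(find_step_peaks(_sig(v), PeakParams(0.1, 0.2, 1.0)))
    for prom in (0.2, 0.3, 0.5):
        n = len(find_step_peaks(_sig(v), PeakParams(prom, 0.2, 1.0)))
        assert n <= base
        base = n
    base = len(find_step_peaks(_sig(v), PeakParams(0.1, 0.2, 1.0)))
    for dist in (0.4, 0.8, 1.5):
        n = len(find_step_peaks(_sig(v), PeakParams(0.1, dist, 1.0)))
        assert n <= base
        base = n


def test_gated_count_recovers_synthetic_steps():
    sc = GaitScenario(duration=400.0,
                      bouts=[Bout(10.0, 100.0, 250), Bout(200.0, 110.0, 250)],
                      arm_noise_sd=0.02, seed=2)
    rec, steps, epochs = simulate_recording(sc)
    assert len(steps) == 500
    from wriststep.peaks import count_gated_steps, precompute_peaks
    from wriststep.preprocess import condition_signal
    cand = precompute_peaks(condition_signal(rec))
    # oracle classification: gate with the true labels
    _, counts = count_gated_steps(cand, PeakParams(0.2, 0.4, 0.5),
                                  epochs.true_label == WALK,
                                  epochs.samples_per_epoch)
    assert abs(counts.sum() - 500) / 500 < 0.05


def test_all_nonwalk_prediction_yields_zero_steps(clean_walk_recording):
    rec, _, epochs = clean_walk_recording
    from wriststep.peaks import count_gated_steps, precompute_peaks
    from wriststep.preprocess import condition_signal
    cand = precompute_peaks(condition_signal(rec))
    _, counts = count_gated_steps(cand, PeakParams(0.1, 0.2, 1.0),
                                  np.zeros(len(epochs), dtype=bool),
                                  epochs.samples_per_epoch)
    assert counts.sum() == 0


def test_spurious_peaks_bounded_by_distance(rng):
    # noise-only signal: the spacing constraint caps the possible peak count
    v = rng.normal(0, 0.3, 3000)  # 30 s at 100 Hz
    params = PeakParams(0.1, 0.5, 1.0)
    idx = find_step_peaks(_sig(v), params)
    assert len(idx) <= 30.0 / 0.5 + 1
    if len(idx) > 1:
        assert np.diff(idx).min() >= 0.5 * 100


def test_gated_count_conserves_and_respects_distance():
    sc = GaitScenario(duration=200.0, bouts=[Bout(10.0, 100.0, 150)], seed=4)
    rec, _, epochs = simulate_recording(sc)
    from wriststep.peaks import count_gated_steps, precompute_peaks
    from wriststep.preprocess import condition_signal
    params = PeakParams(0.2, 0.4, 0.5)
    cand = precompute_peaks(condition_signal(rec))
    idx, counts = count_gated_steps(cand, params,
                                    np.ones(len(epochs), dtype=bool),
                                    epochs.samples_per_epoch)
    assert len(idx) == counts.sum()
    if len(idx) > 1:
        assert np.diff(idx).min() >= params.distance * rec.sample_rate


def test_hybrid_count_short_recording_warns():
    from wriststep.io import RawRecording
    from wriststep.peaks import hybrid_count
    rec = RawRecording(np.tile([0, 0, 1.0], (300, 1)), 100.0)  # 3 s
    with pytest.warns(UserWarning, match="shorter than one epoch"):
        ev = hybrid_count(rec, None, None, PeakParams(0.2, 0.4, 0.5))
    assert ev.total == 0


class TestTuning:
    def _val_set(self, n=3, seed=0):
        from wriststep.simulate import simulate_cohort
        return simulate_cohort(n, seed=seed, duration=120.0)

    def test_single_cell_grid_returned(self):
        grid = PeakGrid(np.array([0.25]), np.array([0.5]), np.array([0.4]))
        got = tune_peak_params(self._val_set(), grid)
        assert (got.prominence, got.distance, got.width_max) == (0.25, 0.5, 0.4)

    def test_tuned_params_respect_constructed_optimum(self):
        # pulses have conditioned-signal prominence ~0.4 g and cadence
        # 80-120 steps/min, so tuning must not exceed those scales
        grid = PeakGrid(np.array([0.1, 0.2, 0.3, 0.4, 0.6, 0.8, 1.0]),
                        np.array([0.2, 0.4, 0.6, 0.8, 1.0, 1.5]),
                        np.array([0.5]))
        got = tune_peak_params(self._val_set(4, seed=2), grid)
        assert got.prominence <= 0.4
        assert got.distance <= 0.6

    def test_default_grid_matches_tuning_ranges(self):
        g = PeakGrid()
        assert g.prominences.min() == pytest.approx(0.1)
        assert g.prominences.max() == pytest.approx(0.95, abs=0.051)
        assert g.distances.min() == pytest.approx(0.2)
        assert g.distances.max() == pytest.approx(2.0)
        assert g.widths.min() == pytest.approx(0.01)
        assert g.widths.max() <= 1.0
        g.validate()

    def test_participant_order_invariance(self):
        grid = PeakGrid(np.array([0.2, 0.4]), np.array([0.3, 0.6]),
                        np.array([0.5]))
        val = self._val_set(4, seed=5)
        a = tune_peak_params(val, grid)
        b = tune_peak_params(val[::-1], grid)
        assert vars(a) == vars(b)

    def test_empty_validation_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            tune_peak_params([], PeakGrid())

    def test_out_of_range_grid_rejected(self):
        with pytest.raises(ValueError):
            PeakGrid(np.array([0.05]), np.array([0.5]), np.array([0.5])).validate()
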