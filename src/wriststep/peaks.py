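"""Step counting by heuristic peak detection on the conditioned signal.

Peaks are strict local maxima screened by three tunable heuristics:

* ``prominence`` (g) - minimum vertical distance from the peak to its lowest
  bounding contour line (minimum peak height);
* ``width_max`` (s) - maximum peak width, measured at half prominence;
* ``distance`` (s) - minimum spacing between retained peaks; among closer
  peaks the lower ones are removed greedily in descending height order.

Prominences and widths do not depend on the heuristic values, so they are
precomputed once per signal (:func:`precompute_peaks`); parameter selection
and grid tuning are then cheap filters over the precomputed candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import peak_prominences, peak_widths

from .io import WALK, EpochSet, RawRecording, window_epochs
from .preprocess import ConditionedSignal, condition_signal

# Tuning ranges for the heuristics.
PROMINENCE_RANGE = (0.1, 1.0)   # g
DISTANCE_RANGE = (0.2, 2.0)     # s
WIDTH_RANGE = (0.01, 1.0)       # s


@dataclass
class PeakParams:
    """Peak-detection heuristics: prominence (g), distance (s), width_max (s)."""

    prominence: float
    distance: float
    width_max: float

    def validate_in_tuning_range(self) -> None:
        if not (PROMINENCE_RANGE[0] <= self.prominence <= PROMINENCE_RANGE[1]):
            raise ValueError("prominence outside tuning range 0.1-1 g")
        if not (DISTANCE_RANGE[0] <= self.distance <= DISTANCE_RANGE[1]):
            raise ValueError("distance outside tuning range 0.2-2 s")
        if not (WIDTH_RANGE[0] <= self.width_max <= WIDTH_RANGE[1]):
            raise ValueError("width outside tuning range 0.01-1 s")


@dataclass
class PeakCandidates:
    """All strict local maxima of a signal with precomputed prominence/width."""

    idx: np.ndarray          # sample indices
    height: np.ndarray       # signal value at the peak
    prominence: np.ndarray   # g
    width_s: np.ndarray      # s, at half prominence
    sample_rate: float


@dataclass
class StepEvents:
    """Detected steps: event times plus per-epoch counts."""

    step_times: np.ndarray            # s from recording start, increasing
    epoch_counts: np.ndarray          # per-epoch detected step counts
    params: PeakParams | None = None
    epochs: EpochSet | None = field(default=None, repr=False)

    @property
    def total(self) -> int:
        return int(len(self.step_times))


def precompute_peaks(signal: ConditionedSignal) -> PeakCandidates:
    """Locate strict local maxima and their prominences and half-prominence widths."""
    v = np.asarray(signal.values, dtype=float)
    if len(v) < 3:
        empty = np.zeros(0)
        return PeakCandidates(np.zeros(0, int), empty, empty, empty,
                              signal.sample_rate)
    interior = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    idx = np.flatnonzero(interior) + 1
    if len(idx) == 0:
        empty = np.zeros(0)
        return PeakCandidates(idx, empty, empty, empty, signal.sample_rate)
    prom, lb, rb = peak_prominences(v, idx)
    w, *_ = peak_widths(v, idx, rel_height=0.5, prominence_data=(prom, lb, rb))
    return PeakCandidates(idx, v[idx], prom, w / signal.sample_rate,
                          signal.sample_rate)


def _greedy_distance_prune(idx: np.ndarray, height: np.ndarray,
                           min_samples: float) -> np.ndarray:
    """Keep highest peaks first; drop any peak closer than min_samples to a kept one.

    Only the nearest kept neighbour on each side can violate the spacing,
    so a sorted insertion point check suffices.
    """
    from bisect import bisect_left, insort

    order = np.lexsort((idx, -height))  # height desc, index asc on ties
    keep = np.zeros(len(idx), dtype=bool)
    kept_positions: list[int] = []
    for j in order:
        pos = int(idx[j])
        i = bisect_left(kept_positions, pos)
        left_ok = i == 0 or pos - kept_positions[i - 1] >= min_samples
        right_ok = i == len(kept_positions) or kept_positions[i] - pos >= min_samples
        if left_ok and right_ok:
            keep[j] = True
            insort(kept_positions, pos)
    return keep


def select_peaks(cand: PeakCandidates, params: PeakParams) -> np.ndarray:
    """Apply the prominence/width/distance heuristics to precomputed candidates.

    Returns retained peak sample indices, sorted ascending.
    """
    mask = (cand.prominence >= params.prominence) & \
           (cand.width_s <= params.width_max)
    idx = cand.idx[mask]
    height = cand.height[mask]
    keep = _greedy_distance_prune(idx, height,
                                  params.distance * cand.sample_rate)
    return np.sort(idx[keep])


def find_step_peaks(signal: ConditionedSignal, params: PeakParams) -> np.ndarray:
    """Detect step-candidate peaks in a conditioned signal (sample indices)."""
    return select_peaks(precompute_peaks(signal), params)


def count_gated_steps(cand: PeakCandidates, params: PeakParams,
                      walk_mask: np.ndarray, samples_per_epoch: int,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Select peaks, keep those inside walking epochs, return (indices, per-epoch counts)."""
    idx = select_peaks(cand, params)
    n_epochs = len(walk_mask)
    ep = idx // samples_per_epoch
    in_range = ep < n_epochs
    idx, ep = idx[in_range], ep[in_range]
    keep = walk_mask[ep]
    idx, ep = idx[keep], ep[keep]
    counts = np.bincount(ep, minlength=n_epochs).astype(int)
    return idx, counts


def hybrid_count(rec: RawRecording, model, hmm_params, params: PeakParams,
                 epoch_length: float = 10.0) -> StepEvents:
    """Hybrid step counting: classify epochs, smooth labels, count peaks in walk epochs.

    ``model`` is a trained epoch classifier (see :mod:`wriststep.classifier`)
    and ``hmm_params`` the fitted label smoother; either may be ``None`` to
    skip that stage (``model=None`` uses the epochs' existing predicted
    labels).  Non-walk epochs contribute exactly zero steps.
    """
    from .classifier import predict_epochs
    from .hmm import smooth_epoch_labels

    epochs = window_epochs(rec, epoch_length)
    if len(epochs) == 0:
        warnings.warn("recording shorter than one epoch; zero steps")
        return StepEvents(np.zeros(0), np.zeros(0, int), params, epochs)
    if model is not None:
        prob, labels = predict_epochs(model, rec, epochs)
        epochs.walk_prob = prob
        epochs.pred_label = labels
    if hmm_params is not None:
        epochs.pred_label = smooth_epoch_labels(hmm_params, epochs.pred_label,
                                                epochs.valid)
    signal = condition_signal(rec)
    cand = precompute_peaks(signal)
    walk_mask = epochs.pred_label == WALK
    idx, counts = count_gated_steps(cand, params, walk_mask,
                                    epochs.samples_per_epoch)
    epochs.step_count = counts
    return StepEvents(idx / rec.sample_rate, counts, params, epochs)


@dataclass
class PeakGrid:
    """Exhaustive tuning grid over the three heuristics.

    Defaults span prominence 0.1-1 g in 0.05 g steps, distance 0.2-2 s in
    0.1 s steps and width 10 ms-1 s in 50 ms steps.
    """

    prominences: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.10, 1.0 + 1e-9, 0.05), 3))
    distances: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.2, 2.0 + 1e-9, 0.1), 3))
    widths: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.01, 1.0 + 1e-9, 0.05), 3))

    def validate(self) -> None:
        if (len(self.prominences) == 0 or len(self.distances) == 0
                or len(self.widths) == 0):
            raise ValueError("tuning grid must be non-empty")
        for p in self.prominences:
            if not PROMINENCE_RANGE[0] <= p <= PROMINENCE_RANGE[1]:
                raise ValueError("grid prominence outside 0.1-1 g")
        for d in self.distances:
            if not DISTANCE_RANGE[0] <= d <= DISTANCE_RANGE[1]:
                raise ValueError("grid distance outside 0.2-2 s")
        for w in self.widths:
            if not WIDTH_RANGE[0] <= w <= WIDTH_RANGE[1]:
                raise ValueError("grid width outside 0.01-1 s")


def tune_peak_params(participants, grid: PeakGrid | None = None,
                     epoch_length: float = 10.0) -> PeakParams:
    """Exhaustive grid search minimising per-participant step-count MAE.

    ``participants`` is a sequence of objects with ``recording``,
    ``step_times`` and ``epochs`` (ground-truth labels); gating during tuning
    uses the true walking labels so that peak parameters are not confounded
    by classifier error.  Ties are broken toward higher prominence, then
    longer distance, then smaller width (conservative counting).
    """
    if grid is None:
        grid = PeakGrid()
    grid.validate()
    participants = list(participants)
    if not participants:
        raise ValueError("tuning requires a non-empty validation set")
    pre = []
    for p in participants:
        cand = precompute_peaks(condition_signal(p.recording))
        walk_mask = p.epochs.true_label == WALK
        pre.append((cand, walk_mask, p.epochs.samples_per_epoch,
                    float(len(p.step_times))))
    if not any(w.any() for _, w, _, _ in pre):
        raise ValueError("validation set contains no walking epochs")

    best: tuple[float, float, float, float] | None = None
    best_params: PeakParams | None = None
    for prom in grid.prominences:
        for dist in grid.distances:
            for wid in grid.widths:
                params = PeakParams(float(prom), float(dist), float(wid))
                errs = [abs(count_gated_steps(cand, params, wm, spe)[1].sum()
                            - true_total)
                        for cand, wm, spe, true_total in pre]
                mae = float(np.mean(errs))
                key = (mae, -params.prominence, -params.distance,
                       params.width_max)
                if best is None or key < best:
                    best, best_params = key, params
    assert best_params is not None
    return best_params
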