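"""Reference open-source wrist step-counting algorithms.

Two widely used baselines for comparison with the hybrid model:

* :func:`ducharme_steps` - an acceleration-threshold method: one step per
  upward crossing of a fixed threshold on the lowpassed gravity-removed
  magnitude.
* :func:`verisense_steps` - a peak-detection method operating at 15 Hz on
  the raw vector magnitude, with magnitude, periodicity, similarity and
  continuity screening of candidate peaks.

Every constant is exposed through the config dataclasses so alternative
published parameterisations can be dropped in without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RawRecording, resample, window_epochs
from .peaks import StepEvents
from .preprocess import enmo_signal, lowpass


@dataclass
class DucharmeConfig:
    """Threshold-crossing parameters (config-exposed published constants)."""

    threshold_g: float = 0.1    # crossing threshold on lowpassed ENMO
    cutoff_hz: float = 5.0      # lowpass cutoff before crossing detection
    epoch_length: float = 10.0


@dataclass
class VerisenseConfig:
    """Peak-screening parameters at the algorithm's native 15 Hz."""

    native_hz: float = 15.0
    half_window: int = 3        # candidate peak = max of +/- half_window samples
    mag_threshold_g: float = 1.2   # on raw vector magnitude (gravity included)
    period_min_samples: int = 5    # ~0.33 s at 15 Hz
    period_max_samples: int = 15   # ~1.0 s at 15 Hz
    similarity_g: float = 0.5      # max height difference of consecutive steps
    continuity_window_s: float = 3.0
    continuity_min_peaks: int = 4
    epoch_length: float = 10.0


def _epoch_counts(idx: np.ndarray, rec: RawRecording,
                  epoch_length: float) -> np.ndarray:
    epochs = window_epochs(rec, epoch_length)
    n_per = epochs.samples_per_epoch
    ep = idx // n_per
    ep = ep[ep < len(epochs)]
    return np.bincount(ep, minlength=len(epochs)).astype(int)


def ducharme_steps(rec: RawRecording,
                   cfg: DucharmeConfig | None = None) -> StepEvents:
    """Count steps as upward threshold crossings of the smoothed magnitude."""
    cfg = cfg or DucharmeConfig()
    v = enmo_signal(rec)
    v[rec.missing] = 0.0
    v = lowpass(v, rec.sample_rate, cfg.cutoff_hz)
    above = v > cfg.threshold_g
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    counts = _epoch_counts(crossings, rec, cfg.epoch_length)
    return StepEvents(crossings / rec.sample_rate, counts)


def verisense_steps(rec: RawRecording,
                    cfg: VerisenseConfig | None = None) -> StepEvents:
    """Peak-detection step counting with periodicity/similarity/continuity screens.

    The recording is resampled internally to the native 15 Hz when needed
    (the screening constants are sample-count based).  A candidate peak is a
    sample that is the strict maximum of its +/- ``half_window``
    neighbourhood with raw magnitude above ``mag_threshold_g``.  A candidate
    becomes a step when its gap to the previous accepted peak lies in the
    periodicity band, its height is within ``similarity_g`` of the previous
    accepted peak, and at least ``continuity_min_peaks`` candidates fall in
    the centred continuity window (isolated impacts are rejected).
    """
    cfg = cfg or VerisenseConfig()
    if rec.sample_rate < cfg.native_hz:
        raise ValueError(
            f"sample rate {rec.sample_rate} Hz is below the algorithm's "
            f"native {cfg.native_hz} Hz; resample upstream")
    work = rec
    if not np.isclose(rec.sample_rate, cfg.native_hz):
        work = resample(rec, cfg.native_hz)
    mag = np.sqrt(np.nansum(np.nan_to_num(work.data, nan=0.0) ** 2, axis=1))
    n = len(mag)
    k = cfg.half_window
    cand = []
    for i in range(k, n - k):
        w = mag[i - k:i + k + 1]
        if mag[i] == w.max() and np.sum(w == mag[i]) == 1 \
                and mag[i] > cfg.mag_threshold_g:
            cand.append(i)
    cand_arr = np.asarray(cand, dtype=int)

    # continuity: candidates supported by enough nearby candidates
    win = cfg.continuity_window_s * cfg.native_hz / 2
    supported = np.array([
        np.sum(np.abs(cand_arr - c) <= win) >= cfg.continuity_min_peaks
        for c in cand_arr], dtype=bool) if len(cand_arr) else np.zeros(0, bool)

    steps = []
    prev_idx, prev_height = None, None
    for i, ok in zip(cand_arr, supported):
        if not ok:
            continue
        if prev_idx is not None:
            gap = i - prev_idx
            if gap < cfg.period_min_samples:
                continue
            if gap <= cfg.period_max_samples and \
                    abs(mag[i] - prev_height) > cfg.similarity_g:
                continue
        steps.append(i)
        prev_idx, prev_height = i, mag[i]

    idx = np.asarray(steps, dtype=int)
    counts = _epoch_counts(idx, work, cfg.epoch_length)
    return StepEvents(idx / cfg.native_hz, counts)
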