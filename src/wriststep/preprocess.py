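"""Signal conditioning for peak detection.

The univariate detection signal is the Euclidean norm of triaxial
acceleration minus 1 g (removing static gravity), clipped to +/-2 g and
zero-phase lowpass filtered at 5 Hz.  The filter is a 4th-order Butterworth
applied forward-backward with odd-symmetric edge extension, so peak
positions are not phase-shifted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .io import RawRecording

DEFAULT_CLIP_G = 2.0
DEFAULT_CUTOFF_HZ = 5.0
FILTER_ORDER = 4


@dataclass
class ConditionedSignal:
    """Gravity-removed, clipped, lowpassed magnitude signal in g."""

    values: np.ndarray
    sample_rate: float
    clip_limit: float = DEFAULT_CLIP_G
    cutoff: float = DEFAULT_CUTOFF_HZ

    def __len__(self) -> int:
        return len(self.values)


def enmo_signal(rec: RawRecording | np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of (x, y, z) minus 1 g; not floored at zero."""
    data = rec.data if isinstance(rec, RawRecording) else np.asarray(rec, float)
    return np.sqrt(np.sum(data**2, axis=-1)) - 1.0


def clip(signal: np.ndarray, limit: float = DEFAULT_CLIP_G) -> np.ndarray:
    """Saturate the signal to [-limit, +limit]."""
    if not limit > 0:
        raise ValueError("clip limit must be positive")
    return np.clip(np.asarray(signal, dtype=float), -limit, limit)


def lowpass(signal: np.ndarray, sample_rate: float,
            cutoff: float = DEFAULT_CUTOFF_HZ) -> np.ndarray:
    """Zero-phase Butterworth lowpass with unit DC gain."""
    if not 0 < cutoff < sample_rate / 2:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist={sample_rate / 2:g}) Hz")
    b, a = butter(FILTER_ORDER, cutoff, btype="low", fs=sample_rate)
    return filtfilt(b, a, np.asarray(signal, dtype=float))


def condition_signal(rec: RawRecording, clip_limit: float = DEFAULT_CLIP_G,
                     cutoff: float = DEFAULT_CUTOFF_HZ) -> ConditionedSignal:
    """Full conditioning pipeline: ENMO -> clip -> lowpass.

    Missing samples enter the filter as 0 g (resting magnitude); the epochs
    they belong to are invalid downstream, so any artefactual peaks there are
    never counted.
    """
    v = enmo_signal(rec)
    v[rec.missing] = 0.0
    v = clip(v, clip_limit)
    v = lowpass(v, rec.sample_rate, cutoff)
    return ConditionedSignal(v, rec.sample_rate, clip_limit, cutoff)
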