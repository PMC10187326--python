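"""Reading, resampling and windowing of raw triaxial accelerometer recordings.

A :class:`RawRecording` holds calibrated acceleration in units of g on a
nominally uniform time grid.  Non-wear or unparseable samples are represented
by a per-sample missing mask (values are NaN where missing), which survives
resampling and drives epoch validity downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Epoch label codes used throughout the package.
NONWALK = 0
WALK = 1
UNKNOWN = -1

#: Minimum number of true steps inside a 10 s epoch for it to count as walking.
WALK_MIN_STEPS = 4

#: Fraction of non-missing samples an epoch needs to be usable.
EPOCH_VALID_FRACTION = 0.5


@dataclass
class RawRecording:
    """Timestamped triaxial acceleration in g at a nominal sampling rate.

    Parameters
    ----------
    data : ndarray, shape (n, 3)
        Acceleration in g.  NaN entries mark missing samples.
    sample_rate : float
        Sampling rate in Hz; samples are assumed uniformly spaced.
    start_time : pandas.Timestamp, optional
        Wall-clock time of the first sample (needed for diurnal bookkeeping).
    missing : ndarray of bool, shape (n,), optional
        Per-sample missing mask; defaults to rows containing NaN.
    """

    data: np.ndarray
    sample_rate: float
    start_time: pd.Timestamp | None = None
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValueError("data must have shape (n, 3)")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if self.missing is None:
            self.missing = np.isnan(self.data).any(axis=1)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape[0] != self.data.shape[0]:
                raise ValueError("missing mask length mismatch")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Recording span in seconds (n samples at ``sample_rate``)."""
        return len(self) / self.sample_rate

    def times(self) -> np.ndarray:
        """Elapsed time of each sample in seconds from the recording start."""
        return np.arange(len(self)) / self.sample_rate

    def write_csv(self, path) -> None:
        """Write as CSV with columns time (elapsed s or ISO-8601), x, y, z."""
        t: np.ndarray | pd.Index
        if self.start_time is not None:
            t = self.start_time + pd.to_timedelta(self.times(), unit="s")
        else:
            t = self.times()
        df = pd.DataFrame({"time": t, "x": self.data[:, 0],
                           "y": self.data[:, 1], "z": self.data[:, 2]})
        df.loc[self.missing, ["x", "y", "z"]] = np.nan
        df.to_csv(path, index=False)


def read_recording(path, format: str = "csv",
                   sample_rate: float | None = None) -> RawRecording:
    """Read a recording from a CSV with columns time, x, y, z.

    The time column may hold elapsed seconds or ISO-8601 timestamps.  The
    sampling rate is taken from ``sample_rate`` when given, otherwise inferred
    from the median time step.  Rows with unparseable acceleration values are
    kept in place and flagged missing.
    """
    if format != "csv":
        raise ValueError(f"unsupported format: {format!r}")
    df = pd.read_csv(path)
    for col in ("time", "x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"recording file {path} is missing column {col!r}")
    start_time = None
    try:
        t = pd.to_numeric(df["time"], errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError):
        stamps = pd.to_datetime(df["time"], format="ISO8601")
        start_time = stamps.iloc[0]
        t = (stamps - start_time).dt.total_seconds().to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps are not strictly increasing")
    xyz = np.column_stack([
        pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        for c in ("x", "y", "z")
    ])
    if sample_rate is None:
        if len(t) < 2:
            raise ValueError("cannot infer sample rate from fewer than 2 samples")
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    return RawRecording(xyz, sample_rate, start_time=start_time)


def resample(rec: RawRecording, target_hz: float) -> RawRecording:
    """Linearly interpolate a recording onto a uniform grid at ``target_hz``.

    Missing spans stay missing: any output sample whose interpolation window
    touches a missing source sample is NaN/masked.  Duration is preserved to
    within one sample period.
    """
    if not target_hz > 0:
        raise ValueError("target_hz must be positive")
    if len(rec) < 2:
        raise ValueError("cannot resample a recording shorter than 2 samples")
    t_src = rec.times()
    n_out = int(np.floor(t_src[-1] * target_hz + 1e-9)) + 1
    t_out = np.arange(n_out) / target_hz
    t_out = np.minimum(t_out, t_src[-1])
    vals = rec.data.copy()
    vals[rec.missing] = np.nan  # NaN poisons any interpolation using it
    out = np.column_stack([np.interp(t_out, t_src, vals[:, i]) for i in range(3)])
    # exact grid hits adjacent to a missing neighbour are fine; recover them
    exact = np.isclose(t_out[:, None], t_src[None, :], rtol=0, atol=1e-12)
    hit_out, hit_src = np.nonzero(exact)
    out[hit_out] = vals[hit_src]
    start = rec.start_time
    return RawRecording(out, target_hz, start_time=start)


@dataclass
class EpochSet:
    """Non-overlapping fixed-length windows tiling a recording.

    Labels use the module-level codes ``WALK``/``NONWALK``/``UNKNOWN``.
    ``step_count`` is filled by the hybrid counter and is 0 for epochs whose
    (smoothed) predicted label is non-walk.
    """

    epoch_length: float
    samples_per_epoch: int
    start_idx: np.ndarray
    valid: np.ndarray
    true_label: np.ndarray
    pred_label: np.ndarray
    walk_prob: np.ndarray
    step_count: np.ndarray

    def __len__(self) -> int:
        return len(self.start_idx)

    def copy(self) -> "EpochSet":
        return EpochSet(self.epoch_length, self.samples_per_epoch,
                        self.start_idx.copy(), self.valid.copy(),
                        self.true_label.copy(), self.pred_label.copy(),
                        self.walk_prob.copy(), self.step_count.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "start_idx": self.start_idx,
            "start_s": self.start_idx.astype(float) / (self.samples_per_epoch / self.epoch_length),
            "valid": self.valid,
            "true_label": self.true_label,
            "pred_label": self.pred_label,
            "walk_prob": self.walk_prob,
            "step_count": self.step_count,
        })


def window_epochs(rec: RawRecording, epoch_length: float = 10.0) -> EpochSet:
    """Tile a recording into epochs of ``epoch_length`` seconds.

    The trailing partial epoch is discarded.  An epoch is valid when at least
    half of its samples are non-missing.  Epoch intervals are half-open
    ``[start, start + epoch_length)``.
    """
    if not epoch_length > 0:
        raise ValueError("epoch_length must be positive")
    n_per = int(round(epoch_length * rec.sample_rate))
    n_epochs = len(rec) // n_per
    start_idx = np.arange(n_epochs) * n_per
    if n_epochs:
        nonmiss = (~rec.missing[: n_epochs * n_per]).reshape(n_epochs, n_per)
        valid = nonmiss.mean(axis=1) >= EPOCH_VALID_FRACTION
    else:
        valid = np.zeros(0, dtype=bool)
    fill = lambda v, dt: np.full(n_epochs, v, dtype=dt)  # noqa: E731
    return EpochSet(epoch_length, n_per, start_idx, valid,
                    fill(UNKNOWN, np.int8), fill(UNKNOWN, np.int8),
                    fill(np.nan, float), fill(0, int))


def label_epochs_from_steps(epochs: EpochSet, step_times: np.ndarray,
                            sample_rate: float,
                            min_steps: int = WALK_MIN_STEPS) -> EpochSet:
    """Set ground-truth walk labels from known step-event times.

    An epoch is labelled walking when it contains at least ``min_steps`` steps
    (half-open interval), otherwise non-walking.
    """
    out = epochs.copy()
    edges = np.append(out.start_idx, out.start_idx[-1] + out.samples_per_epoch
                      if len(out) else 0) / sample_rate
    counts, _ = np.histogram(np.asarray(step_times, dtype=float), bins=edges) \
        if len(out) else (np.zeros(0, int), None)
    # histogram's last bin is closed on the right; drop a step landing exactly
    # on the final edge to keep intervals half-open
    if len(out) and len(step_times):
        last_edge = edges[-1]
        counts[-1] -= int(np.sum(np.asarray(step_times) == last_edge))
    out.true_label = np.where(counts >= min_steps, WALK, NONWALK).astype(np.int8)
    return out


def true_epoch_step_counts(epochs: EpochSet, step_times: np.ndarray,
                           sample_rate: float) -> np.ndarray:
    """Number of true step events falling in each epoch (half-open bins)."""
    if not len(epochs):
        return np.zeros(0, dtype=int)
    edges = np.append(epochs.start_idx,
                      epochs.start_idx[-1] + epochs.samples_per_epoch) / sample_rate
    counts, _ = np.histogram(np.asarray(step_times, dtype=float), bins=edges)
    if len(step_times):
        counts[-1] -= int(np.sum(np.asarray(step_times) == edges[-1]))
    return counts.astype(int)

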