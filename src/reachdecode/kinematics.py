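"""Wrist-trajectory processing and movement-onset detection.

Optical-tracking wrist positions (120 Hz, meters) are gap-interpolated,
low-pass smoothed with a zero-lag 4th-order 5 Hz filter, differentiated to
velocity, and downsampled to 50 Hz.  Movement onset is the first time the
3D wrist speed reaches 0.01 m/s and remains at or above that threshold
for more than 0.5 s; trials with no such time have no onset, which the
trial-rejection logic consumes as a value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Trajectory",
    "VelocityTrace",
    "interpolate_gaps",
    "smooth_lowpass",
    "differentiate_and_downsample",
    "detect_onset",
    "process_trajectory",
    "onset_table",
]


@dataclass
class Trajectory:
    """3D wrist position samples on a uniform time grid."""

    time: np.ndarray  # s
    position: np.ndarray  # (n, 3) m
    rate: float  # Hz
    missing: np.ndarray = field(default=None)  # bool mask of missing samples

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(len(self.time), dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.position.ndim != 2 or self.position.shape[1] != 3:
            raise ValueError("position must be an (n, 3) array")
        if len(self.time) != len(self.position):
            raise ValueError("time and position lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class VelocityTrace:
    """3D wrist velocity with Euclidean speed."""

    time: np.ndarray  # s
    velocity: np.ndarray  # (n, 3) m/s
    rate: float  # Hz

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity, axis=1)


def interpolate_gaps(traj: Trajectory, max_gap: float = 0.5) -> Trajectory:
    """Linearly interpolate missing samples per coordinate.

    Gaps longer than ``max_gap`` seconds, or gaps touching the trace ends,
    cannot be bridged and raise :class:`ValueError`.
    """
    missing = traj.missing
    if not missing.any():
        return Trajectory(traj.time.copy(), traj.position.copy(), traj.rate)
    if missing[0] or missing[-1]:
        raise ValueError("leading or trailing gap cannot be interpolated")
    # longest run of consecutive missing samples
    padded = np.concatenate([[0], missing.astype(int), [0]])
    edges = np.diff(padded)
    run_lengths = np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)
    if run_lengths.size and run_lengths.max() / traj.rate > max_gap:
        raise ValueError(
            f"gap of {run_lengths.max() / traj.rate:.3f} s exceeds the "
            f"{max_gap} s interpolation limit"
        )
    good = ~missing
    pos = traj.position.copy()
    for axis in range(3):
        pos[missing, axis] = np.interp(
            traj.time[missing], traj.time[good], traj.position[good, axis]
        )
    return Trajectory(traj.time.copy(), pos, traj.rate)


def smooth_lowpass(traj: Trajectory, cutoff: float = 5.0, order: int = 4) -> Trajectory:
    """Zero-lag low-pass smoothing (forward-backward Butterworth).

    The forward-backward pass cancels the phase response at all
    frequencies and doubles the effective magnitude order.
    """
    if traj.missing.any():
        raise ValueError("interpolate gaps before smoothing")
    if traj.rate <= 2 * cutoff:
        raise ValueError("sampling rate must exceed twice the cutoff")
    b, a = signal.butter(order, cutoff, fs=traj.rate)
    padlen = 3 * max(len(a), len(b))
    if len(traj.time) <= padlen:
        raise ValueError(f"trace too short for stable filtering (need > {padlen} samples)")
    pos = signal.filtfilt(b, a, traj.position, axis=0)
    return Trajectory(traj.time.copy(), pos, traj.rate)


def differentiate_and_downsample(traj: Trajectory, out_rate: float = 50.0) -> VelocityTrace:
    """Central-difference velocity, polyphase-resampled to 50 Hz.

    The 120 -> 50 Hz ratio is non-integer, so resampling uses
    :func:`scipy.signal.resample_poly` (up 5, down 12) rather than sample
    picking.
    """
    if traj.missing.any():
        raise ValueError("interpolate gaps before differentiating")
    vel = np.gradient(traj.position, axis=0) * traj.rate
    from fractions import Fraction

    frac = Fraction(out_rate / traj.rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    vel_ds = signal.resample_poly(vel, up, down, axis=0)
    time = traj.time[0] + np.arange(len(vel_ds)) / out_rate
    return VelocityTrace(time=time, velocity=vel_ds, rate=out_rate)


def detect_onset(
    vel: VelocityTrace, threshold: float = 0.01, sustain: float = 0.5
) -> Optional[float]:
    """First time speed reaches ``threshold`` and stays there for more
    than ``sustain`` seconds; ``None`` if no qualifying run exists.

    A run of consecutive supra-threshold samples qualifies when the time
    from its first to its last sample strictly exceeds ``sustain``;
    comparisons at the threshold use ``>=``.
    """
    speed = vel.speed
    above = speed >= threshold
    if not above.any():
        return None
    padded = np.concatenate([[0], above.astype(int), [0]])
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)  # exclusive
    for s, e in zip(starts, ends):
        if vel.time[e - 1] - vel.time[s] > sustain:
            return float(vel.time[s])
    return None


def process_trajectory(
    traj: Trajectory,
    cutoff: float = 5.0,
    order: int = 4,
    out_rate: float = 50.0,
    threshold: float = 0.01,
    sustain: float = 0.5,
) -> Optional[float]:
    """Full kinematic pipeline: interpolate, smooth, differentiate,
    downsample, detect onset.  Returns the onset time or ``None``."""
    traj = interpolate_gaps(traj)
    traj = smooth_lowpass(traj, cutoff=cutoff, order=order)
    vel = differentiate_and_downsample(traj, out_rate=out_rate)
    return detect_onset(vel, threshold=threshold, sustain=sustain)


def onset_table(trajectories: Sequence[Trajectory], trial_ids: Optional[Iterable[int]] = None,
                **kwargs) -> pd.DataFrame:
    """Detected onsets for a list of trial trajectories.

    Returns a table with columns ``trial`` and ``t_onset`` (NaN when no
    onset was found).
    """
    if trial_ids is None:
        trial_ids = range(len(trajectories))
    rows = []
    for trial, traj in zip(trial_ids, trajectories):
        onset = process_trajectory(traj, **kwargs)
        rows.append({"trial": trial, "t_onset": np.nan if onset is None else onset})
    return pd.DataFrame(rows, columns=["trial", "t_onset"])
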