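"""EEG preprocessing: reference, filter, downsample, de-artifact, epoch,
and reject trials on movement criteria.

The continuous 500 Hz record is common-average referenced over the 30
montage channels, band-pass filtered 0.3-4 Hz with a zero-phase
Hamming-windowed sinc FIR kernel, and decimated to 50 Hz.  Ocular
artifacts are removed by least-squares regression of the HEOG/VEOG
channels out of every EEG channel (a pass-through mode exists for
artifact-free synthetic data).  Two epoch sets of [-1, 2] s at 50 Hz are
cut: *planning* epochs locked to the Task cue and *execution* epochs
locked to the kinematic movement onset.  Trials are rejected from the
planning set when movement onset precedes the Go cue by more than 0.5 s,
and from the execution set additionally when onset precedes Go at all or
no movement was detected — so execution rejections always contain the
planning rejections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from . import kinematics as kin
from .decoding import STANDARD_MONTAGE
from .task_model import TrialCondition, parse_condition_code

__all__ = [
    "EpochSet",
    "RejectionReport",
    "common_average_reference",
    "design_bandpass",
    "bandpass_lowfreq",
    "downsample_eeg",
    "regress_out_eog",
    "epoch",
    "reject_trials",
    "preprocess_session",
    "PreprocessResult",
]

EPOCH_START = -1.0  # s relative to the alignment event
EPOCH_END = 2.0
EPOCH_RATE = 50.0
EPOCH_SAMPLES = int(round((EPOCH_END - EPOCH_START) * EPOCH_RATE))  # 150


@dataclass
class EpochSet:
    """Trials x 30 channels x 150 samples at 50 Hz on [-1, 2] s."""

    data: np.ndarray
    alignment: str  # "task_cue" | "movement_onset"
    conditions: Tuple[TrialCondition, ...]
    trial_ids: np.ndarray
    rate: float = EPOCH_RATE
    t_start: float = EPOCH_START
    ch_names: Tuple[str, ...] = STANDARD_MONTAGE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[1] != len(self.ch_names):
            raise ValueError("data must be (trials, 30, samples)")
        if self.data.shape[2] != EPOCH_SAMPLES:
            raise ValueError(f"epochs must have {EPOCH_SAMPLES} samples")
        if self.alignment not in ("task_cue", "movement_onset"):
            raise ValueError(f"unknown alignment {self.alignment!r}")
        if len(self.conditions) != len(self.data):
            raise ValueError("one condition per trial required")

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.data.shape[2]) / self.rate

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, conditions: Sequence[TrialCondition]) -> "EpochSet":
        mask = np.array([c in conditions for c in self.conditions])
        return EpochSet(
            data=self.data[mask],
            alignment=self.alignment,
            conditions=tuple(c for c in self.conditions if c in conditions),
            trial_ids=self.trial_ids[mask],
            rate=self.rate,
            t_start=self.t_start,
            ch_names=self.ch_names,
        )


@dataclass
class RejectionReport:
    """Per-trial movement-based rejection flags and dataset rates."""

    flags: pd.DataFrame  # trial, early_planning, pre_go_onset, no_movement

    @property
    def planning_reject(self) -> np.ndarray:
        return self.flags["early_planning"].to_numpy()

    @property
    def execution_reject(self) -> np.ndarray:
        f = self.flags
        return (
            f["early_planning"] | f["pre_go_onset"] | f["no_movement"]
        ).to_numpy()

    @property
    def planning_rate(self) -> float:
        return float(self.planning_reject.mean())

    @property
    def execution_rate(self) -> float:
        return float(self.execution_reject.mean())


def common_average_reference(eeg: np.ndarray, n_eeg: Optional[int] = None) -> np.ndarray:
    """Subtract the instantaneous mean of the EEG channels.

    ``eeg`` is channels x samples; only the first ``n_eeg`` rows (default:
    all but trailing EOG rows when the array has 32 rows, otherwise all)
    enter the average and are re-referenced.  EOG rows pass through.
    """
    eeg = np.asarray(eeg)
    if not np.issubdtype(eeg.dtype, np.floating):
        eeg = eeg.astype(float)
    if n_eeg is None:
        n_eeg = 30 if eeg.shape[0] == 32 else eeg.shape[0]
    if n_eeg < 2:
        raise ValueError("common average reference needs at least 2 EEG channels")
    out = eeg.copy()
    out[:n_eeg] -= out[:n_eeg].mean(axis=0, keepdims=True)
    return out


def design_bandpass(
    rate: float = 500.0,
    l_freq: float = 0.3,
    h_freq: float = 4.0,
    l_trans: float = 0.6,
    h_trans: float = 1.0,
) -> np.ndarray:
    """Zero-phase band-pass kernel: Hamming-windowed sinc high-pass and
    low-pass stages convolved together.

    Each stage's length follows the Hamming transition-width rule
    (~3.3 / transition in normalized frequency); the -6 dB points sit at
    the cutoffs.  The combined kernel is symmetric, hence exactly
    zero-phase when applied with a centered convolution.
    """
    def _taps(trans: float) -> int:
        n = int(np.ceil(3.3 * rate / trans))
        return n + 1 if n % 2 == 0 else n

    hp = signal.firwin(_taps(l_trans), l_freq, fs=rate, window="hamming", pass_zero=False)
    lp = signal.firwin(_taps(h_trans), h_freq, fs=rate, window="hamming")
    return np.convolve(hp, lp)


def bandpass_lowfreq(eeg: np.ndarray, rate: float = 500.0, kernel: Optional[np.ndarray] = None,
                     **design_kwargs) -> np.ndarray:
    """Apply the 0.3-4 Hz zero-phase FIR to channels x samples data."""
    eeg = np.atleast_2d(np.asarray(eeg))
    if not np.issubdtype(eeg.dtype, np.floating):
        eeg = eeg.astype(float)
    if kernel is None:
        kernel = design_bandpass(rate=rate, **design_kwargs)
    if eeg.shape[-1] < len(kernel):
        raise ValueError(
            f"record ({eeg.shape[-1]} samples) shorter than the filter kernel ({len(kernel)})"
        )
    return signal.oaconvolve(eeg, kernel[None, :].astype(eeg.dtype), mode="same", axes=-1)


def downsample_eeg(eeg: np.ndarray, rate: float = 500.0, out_rate: float = 50.0) -> np.ndarray:
    """Integer decimation of already low-passed data; event times stay in
    seconds and need no adjustment."""
    ratio = rate / out_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"non-integer decimation ratio {ratio}")
    return np.asarray(eeg)[..., :: int(round(ratio))]


def regress_out_eog(eeg: np.ndarray, heog: np.ndarray, veog: np.ndarray) -> np.ndarray:
    """Remove each channel's least-squares projection onto the EOG pair.

    Stands in for ICA-based ocular artifact removal; the generator's
    known leakage coefficients make it verifiable against ground truth.
    Degenerate (near-constant) EOG regressors skip the step with a
    warning.
    """
    eeg = np.asarray(eeg, dtype=float)
    regs = np.column_stack([np.asarray(heog, dtype=float), np.asarray(veog, dtype=float)])
    sds = regs.std(axis=0)
    if np.any(sds < 1e-12):
        warnings.warn("degenerate EOG regressor; skipping ocular regression", stacklevel=2)
        return eeg.copy()
    x = np.column_stack([regs, np.ones(len(regs))])
    beta, *_ = np.linalg.lstsq(x, eeg.T, rcond=None)
    return eeg - (x @ beta).T


def epoch(
    eeg50: np.ndarray,
    align_times: Sequence[float],
    conditions: Sequence[TrialCondition],
    trial_ids: Sequence[int],
    alignment: str,
    rate: float = EPOCH_RATE,
) -> EpochSet:
    """Cut [-1, 2] s epochs around alignment events from 30-channel data.

    Trials whose window exceeds the record bounds are dropped with a
    warning.
    """
    eeg50 = np.asarray(eeg50)
    keep_data, keep_conds, keep_ids = [], [], []
    dropped = []
    for t, cond, tid in zip(align_times, conditions, trial_ids):
        i0 = int(round((t + EPOCH_START) * rate))
        i1 = i0 + EPOCH_SAMPLES
        if i0 < 0 or i1 > eeg50.shape[-1]:
            dropped.append(tid)
            continue
        keep_data.append(eeg50[:, i0:i1])
        keep_conds.append(cond)
        keep_ids.append(tid)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} trial(s) outside record bounds: {dropped}",
                      stacklevel=2)
    data = np.stack(keep_data) if keep_data else np.empty((0, eeg50.shape[0], EPOCH_SAMPLES))
    return EpochSet(
        data=data,
        alignment=alignment,
        conditions=tuple(keep_conds),
        trial_ids=np.asarray(keep_ids, dtype=int),
    )


def reject_trials(
    onsets: Sequence[float],
    go_times: Sequence[float],
    trial_ids: Optional[Sequence[int]] = None,
    early_margin: float = 0.5,
) -> RejectionReport:
    """Movement-based trial rejection.

    Planning: reject iff onset occurred strictly before ``Go - 0.5`` s
    (movement too early contaminates planning activity; onset exactly at
    the boundary is kept).  Execution: additionally reject trials whose
    onset precedes the Go cue at all, and trials without any detected
    movement.  ``onsets`` may contain NaN for absent movement.
    """
    onsets = np.asarray(onsets, dtype=float)
    go = np.asarray(go_times, dtype=float)
    if trial_ids is None:
        trial_ids = np.arange(len(onsets))
    no_move = np.isnan(onsets)
    early = (~no_move) & (onsets < go - early_margin)
    pre_go = (~no_move) & (onsets < go)
    flags = pd.DataFrame(
        {
            "trial": np.asarray(trial_ids, dtype=int),
            "early_planning": early,
            "pre_go_onset": pre_go,
            "no_movement": no_move,
        }
    )
    return RejectionReport(flags=flags)


@dataclass
class PreprocessResult:
    planning: EpochSet
    execution: EpochSet
    report: RejectionReport
    onsets: pd.DataFrame  # detected onsets (absolute s; NaN = none)


def preprocess_session(session, eog_mode: str = "regress") -> PreprocessResult:
    """Full deterministic preprocessing of a session.

    Reference -> band-pass -> decimate -> (optional) EOG regression ->
    kinematic onset detection -> movement-based rejection -> planning and
    execution epoch sets.  ``eog_mode`` is ``"regress"`` or ``"none"``
    (pass-through for artifact-free data).
    """
    if eog_mode not in ("regress", "none"):
        raise ValueError(f"eog_mode must be 'regress' or 'none', got {eog_mode!r}")
    if session.eeg is None:
        raise ValueError("session has no EEG record")
    data = common_average_reference(session.eeg, n_eeg=30)
    data = bandpass_lowfreq(data, rate=session.rate)
    data = downsample_eeg(data, rate=session.rate, out_rate=EPOCH_RATE)
    if eog_mode == "regress":
        data[:30] = regress_out_eog(data[:30], data[30], data[31])
    eeg30 = data[:30]

    table = session.trial_table
    onsets = kin.onset_table(session.kinematics, table["trial"].tolist())
    onset_times = onsets["t_onset"].to_numpy()
    go_times = table["t_go"].to_numpy()
    report = reject_trials(onset_times, go_times, table["trial"].to_numpy())

    conds = [parse_condition_code(c) for c in table["code"]]
    trial_ids = table["trial"].to_numpy()

    keep_plan = ~report.planning_reject
    planning = epoch(
        eeg30,
        table["t_task"].to_numpy()[keep_plan],
        [c for c, k in zip(conds, keep_plan) if k],
        trial_ids[keep_plan],
        alignment="task_cue",
    )
    keep_exec = ~report.execution_reject
    execution = epoch(
        eeg30,
        onset_times[keep_exec],
        [c for c, k in zip(conds, keep_exec) if k],
        trial_ids[keep_exec],
        alignment="movement_onset",
    )
    return PreprocessResult(planning=planning, execution=execution, report=report, onsets=onsets)
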