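"""Synthetic reach-to-grasp sessions with a known coordinate encoding.

The generator reproduces the study design: 8 blocks of 40 trials, hands
alternating by block, each block a seeded permutation of 10 repeats of the
four task conditions; per trial a Ready cue, a Task cue 1 s later, and a
Go cue 2 s after that; 30+2-channel EEG at 500 Hz; 120 Hz 3D wrist
trajectories with the characteristic grasp/touch velocity structure
(single vertical-velocity peak for touch, double peak for grasp, object
contact near 0.8 s after movement onset).

The EEG is a forward-mixed sum of three low-frequency (<= 4 Hz) sources
whose spatial patterns encode the decoding hypotheses:

* an *action* source (grasp = +, touch = -) with a midline-symmetric
  scalp pattern, so montage mirroring leaves it untouched;
* an *extrinsic direction* source (right handle = +, left = -) with a
  fixed, lateralized pattern identical for both hands;
* an *intrinsic direction* source (contralateral reach = +, ipsilateral
  = -) whose pattern mirrors across the midline between hands.

Each source is a smooth raised-cosine envelope with a cue-locked planning
bump and a larger movement-onset-locked execution bump; the direction
envelope peaks 0.15 s earlier than the action envelope.  Pink+white
channel noise and frontal EOG leakage with known coefficients complete
the record.  Amplitudes (``w_act``, ``w_ext``, ``w_int``) are dials for
the *encoding*, not the design: setting one to zero removes that source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .decoding import STANDARD_MONTAGE, mirror_permutation
from .kinematics import Trajectory
from .task_model import Action, Direction, Hand, TrialCondition, parse_condition_code

__all__ = [
    "SynthConfig",
    "SpatialPatternSet",
    "Session",
    "make_trial_schedule",
    "simulate_kinematics",
    "simulate_eeg_trial",
    "simulate_session",
    "VEOG_LEAK",
    "HEOG_LEAK",
]

EOG_CHANNELS = ("HEOG", "VEOG")

# --- timing constants (s) ---------------------------------------------------
READY_TO_TASK = 1.0
TASK_TO_GO = 2.0
# source envelope geometry
ENVELOPE_WIDTH = 1.0  # full raised-cosine support
PLAN_ACT_CENTER = 0.7  # s after Task cue
EXEC_ACT_CENTER = 0.8  # s after movement onset
DIRECTION_LEAD = 0.15  # direction envelope peaks earlier than action
PLAN_AMP = 0.6
EXEC_AMP = 1.0
# reach geometry: handles 19 cm apart, start centered between them
HANDLE_HALF_SEPARATION = 0.095  # m
REACH_DURATION = 0.8  # s, onset to object contact
LIFT_START, LIFT_END = 0.9, 1.5  # s post-onset, grasp-only second pulse


@dataclass
class SynthConfig:
    """Session-generator parameters.

    Defaults follow the study design (8 blocks x 40 trials, 10 repeats of
    each of the 4 task conditions per block, 500 Hz EEG, 120 Hz
    kinematics) and its observed movement-onset latency distribution
    (mean 0.3385 s, SD 0.1137 s after the Go cue).  Source amplitudes are
    in microvolts; ``noise_sd`` is the per-channel broadband noise SD.
    """

    n_blocks: int = 8
    trials_per_block: int = 40
    per_condition_per_block: int = 10
    eeg_rate: float = 500.0
    kin_rate: float = 120.0
    w_act: float = 1.0
    w_ext: float = 1.0
    w_int: float = 1.0
    noise_sd: float = 0.7
    noise_model: str = "pink+white"
    eog_amp: float = 15.0
    onset_mean: float = 0.3385
    onset_sd: float = 0.1137
    early_mover_frac: float = 0.0
    no_move_frac: float = 0.0
    trial_period: float = 6.5
    session_pad: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.eeg_rate <= 0 or self.kin_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if min(self.w_act, self.w_ext, self.w_int, self.noise_sd, self.eog_amp) < 0:
            raise ValueError("amplitudes must be non-negative")
        for name in ("early_mover_frac", "no_move_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.early_mover_frac + self.no_move_frac > 1:
            raise ValueError("early_mover_frac + no_move_frac must not exceed 1")
        if self.trials_per_block != 4 * self.per_condition_per_block:
            raise ValueError("trials_per_block must equal 4 * per_condition_per_block")
        if self.noise_model not in ("white", "pink+white"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


def _pattern_vector(weights: Dict[str, float]) -> np.ndarray:
    v = np.array([weights.get(ch, 0.0) for ch in STANDARD_MONTAGE], dtype=float)
    return v / np.linalg.norm(v)


# Action pattern: midline-adjacent fronto-central pairs, exactly symmetric.
_ACT_WEIGHTS = {
    "FC1": 1.0, "FC2": 1.0, "C1": 1.0, "C2": 1.0,
    "FC3": 0.5, "FC4": 0.5, "C3": 0.5, "C4": 0.5,
    "F1": 0.3, "F2": 0.3, "CP1": 0.3, "CP2": 0.3,
}
# Extrinsic direction pattern: right-hemisphere parietal, fixed across hands.
_EXT_WEIGHTS = {
    "P2": 1.0, "P4": 1.0, "P6": 0.8,
    "CP2": 0.7, "CP4": 0.7, "CP6": 0.5,
    "C2": 0.3, "C4": 0.3,
}
# Intrinsic direction pattern for the right hand: central/centro-parietal
# electrodes over the contralateral (left) hemisphere.
_INT_RIGHT_WEIGHTS = {
    "C1": 1.0, "C3": 1.0, "C5": 0.8,
    "CP1": 0.7, "CP3": 0.7, "CP5": 0.5,
    "FC1": 0.3, "FC3": 0.3,
}


@dataclass
class SpatialPatternSet:
    """Unit-norm scalp patterns of the three generative sources."""

    s_act: np.ndarray
    s_ext: np.ndarray
    s_int_right: np.ndarray

    @classmethod
    def default(cls) -> "SpatialPatternSet":
        return cls(
            s_act=_pattern_vector(_ACT_WEIGHTS),
            s_ext=_pattern_vector(_EXT_WEIGHTS),
            s_int_right=_pattern_vector(_INT_RIGHT_WEIGHTS),
        )

    @property
    def s_int_left(self) -> np.ndarray:
        """Left-hand intrinsic pattern: the midline mirror of the right's."""
        return self.s_int_right[mirror_permutation()]

    def s_int(self, hand: Hand) -> np.ndarray:
        return self.s_int_right if hand is Hand.RIGHT else self.s_int_left

    def validate(self) -> None:
        perm = mirror_permutation()
        if not np.array_equal(self.s_act[perm], self.s_act):
            raise ValueError("s_act must be midline-symmetric")
        for name in ("s_act", "s_ext", "s_int_right"):
            v = getattr(self, name)
            if v.shape != (len(STANDARD_MONTAGE),):
                raise ValueError(f"{name} must be a 30-vector")
            if not np.isclose(np.linalg.norm(v), 1.0):
                raise ValueError(f"{name} must have unit norm")


def _row_prefix(ch: str) -> str:
    return ch.rstrip("0123456789")


# EOG leakage coefficients (unitless multipliers of the EOG traces),
# strongest frontally; horizontal leakage changes sign across the midline.
_VEOG_ROW = {"F": 0.30, "FC": 0.15, "C": 0.08, "CP": 0.04, "P": 0.02}
VEOG_LEAK = np.array([_VEOG_ROW[_row_prefix(ch)] for ch in STANDARD_MONTAGE])
HEOG_LEAK = 0.5 * VEOG_LEAK * np.array(
    [1.0 if int(ch[-1]) % 2 == 0 else -1.0 for ch in STANDARD_MONTAGE]
)


@dataclass
class Session:
    """One continuous event-marked recording with per-trial kinematics."""

    eeg: Optional[np.ndarray]  # (32, n_samples) microvolts, or None
    rate: float
    ch_names: Tuple[str, ...]
    events: pd.DataFrame  # columns: trial, type, time, code
    kinematics: List[Trajectory]  # one per trial, absolute time axis
    trial_table: pd.DataFrame  # trial, block, hand, code, t_ready, t_task, t_go, t_onset
    config: SynthConfig = None
    patterns: SpatialPatternSet = None

    @property
    def n_trials(self) -> int:
        return len(self.trial_table)

    def event_times(self, kind: str) -> np.ndarray:
        sub = self.events[self.events["type"] == kind].sort_values("trial")
        return sub["time"].to_numpy()


def make_trial_schedule(config: SynthConfig, seed=None) -> pd.DataFrame:
    """Block/trial schedule with cue times.

    Hands alternate between blocks (starting hand seeded); each block is
    a random permutation of 10 repeats of the four task conditions.  The
    ``t_onset`` column is NaN until a session is simulated.
    """
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    start_hand = int(rng.integers(2))
    task_conds = [(d, a) for d in Direction for a in Action]
    rows = []
    for b in range(config.n_blocks):
        hand = list(Hand)[(start_hand + b) % 2]
        order = np.repeat(np.arange(4), config.per_condition_per_block)
        order = rng.permutation(order)
        for i, task_idx in enumerate(order):
            d, a = task_conds[task_idx]
            trial = b * config.trials_per_block + i
            t_ready = config.session_pad + trial * config.trial_period
            rows.append(
                {
                    "trial": trial,
                    "block": b,
                    "hand": hand.value,
                    "code": TrialCondition(d, a, hand).code,
                    "t_ready": t_ready,
                    "t_task": t_ready + READY_TO_TASK,
                    "t_go": t_ready + READY_TO_TASK + TASK_TO_GO,
                    "t_onset": np.nan,
                }
            )
    return pd.DataFrame(rows)


def _halfsine_pulse(t: np.ndarray, start: float, end: float) -> np.ndarray:
    """Half-sine velocity pulse on [start, end] (sinusoidal point-to-point
    profile; integral = 2(end-start)/pi)."""
    out = np.zeros_like(t)
    m = (t >= start) & (t <= end)
    out[m] = np.sin(np.pi * (t[m] - start) / (end - start))
    return out


def simulate_kinematics(
    cond: TrialCondition,
    onset_latency: Optional[float],
    config: SynthConfig,
    seed=None,
) -> Trajectory:
    """Noise-free wrist trajectory for one trial, time zero at the Go cue.

    The trace spans [-3, 3.5) s around Go.  The wrist is still until
    ``Go + onset_latency``; the reach moves the wrist 9.5 cm toward the
    target handle (handles 19 cm apart, start centered) with peak speed
    near 0.4 s and object contact (a speed minimum) near 0.8 s after
    onset.  Grasp trials add a second vertical-velocity pulse (the lift)
    peaking near 1.2 s post-onset; touch trials have a single vertical
    peak.  ``onset_latency=None`` yields a no-movement trial.
    """
    dt = 1.0 / config.kin_rate
    t = np.arange(-3.0, 3.5, dt)
    vel = np.zeros((len(t), 3))
    if onset_latency is not None:
        tp = t - onset_latency  # time since movement onset
        reach = _halfsine_pulse(tp, 0.0, REACH_DURATION)
        dir_sign = 1.0 if cond.direction is Direction.RIGHT else -1.0
        # half-sine pulse: displacement = amp * 2 * duration / pi
        vel[:, 0] = dir_sign * (HANDLE_HALF_SEPARATION * np.pi / (2 * REACH_DURATION)) * reach
        vel[:, 1] = 0.75 * reach  # forward toward the object (~0.38 m)
        vel[:, 2] = 0.30 * reach  # up to the handle top
        if cond.action is Action.GRASP:
            vel[:, 2] += 0.40 * _halfsine_pulse(tp, LIFT_START, LIFT_END)
    pos = np.concatenate(
        [np.zeros((1, 3)), np.cumsum(0.5 * (vel[1:] + vel[:-1]) * dt, axis=0)]
    )
    return Trajectory(time=t, position=pos, rate=config.kin_rate)


def _envelope(t: np.ndarray, t_task: float, t_onset: Optional[float], center_plan: float,
              center_exec: float) -> np.ndarray:
    """Cue-locked planning bump plus larger onset-locked execution bump."""
    env = PLAN_AMP * _raised_cosine(t - t_task, center_plan)
    if t_onset is not None:
        env = env + EXEC_AMP * _raised_cosine(t - t_onset, center_exec)
    return env


def _raised_cosine(t: np.ndarray, center: float, width: float = ENVELOPE_WIDTH) -> np.ndarray:
    x = (t - center) / width
    out = np.zeros_like(t)
    m = np.abs(x) < 0.5
    out[m] = 0.5 * (1.0 + np.cos(2.0 * np.pi * x[m]))
    return out


def _trial_sources(
    cond: TrialCondition,
    t: np.ndarray,
    t_task: float,
    t_onset: Optional[float],
    patterns: SpatialPatternSet,
    config: SynthConfig,
) -> np.ndarray:
    """Clean 30-channel source mixture of one trial on the time grid ``t``."""
    a = 1.0 if cond.action is Action.GRASP else -1.0
    d_ext = 1.0 if cond.direction is Direction.RIGHT else -1.0
    d_int = 1.0 if cond.direction.value != cond.hand.value else -1.0  # + contralateral
    e_act = _envelope(t, t_task, t_onset, PLAN_ACT_CENTER, EXEC_ACT_CENTER)
    e_dir = _envelope(
        t, t_task, t_onset, PLAN_ACT_CENTER - DIRECTION_LEAD, EXEC_ACT_CENTER - DIRECTION_LEAD
    )
    spatial_dir = config.w_ext * d_ext * patterns.s_ext + config.w_int * d_int * patterns.s_int(
        cond.hand
    )
    return np.outer(config.w_act * a * patterns.s_act, e_act) + np.outer(spatial_dir, e_dir)


def _slow_process(rng: np.random.Generator, n: int, rate: float, cutoff: float = 3.0) -> np.ndarray:
    """Unit-SD random process band-limited below ``cutoff`` Hz."""
    from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

    m = next_fast_len(n)
    white = rng.standard_normal(m, dtype=np.float32)
    f = rfftfreq(m, 1.0 / rate)
    gain = (0.5 * (1.0 + np.cos(np.pi * np.clip(f / cutoff, 0, 1)))).astype(np.float32)
    x = irfft(rfft(white) * gain, m)[:n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _eog_traces(rng: np.random.Generator, n: int, rate: float, amp: float) -> Tuple[np.ndarray, np.ndarray]:
    """Horizontal and vertical EOG: slow drift plus blink pulses on VEOG."""
    heog = amp * _slow_process(rng, n, rate)
    veog = amp * _slow_process(rng, n, rate)
    duration = n / rate
    n_blinks = rng.poisson(0.15 * duration)
    for bt in np.sort(rng.uniform(0.5, duration - 0.5, size=n_blinks)):
        i0 = max(0, int((bt - 0.5) * rate))
        i1 = min(n, int((bt + 0.5) * rate))
        t_local = np.arange(i0, i1) / rate
        veog[i0:i1] += 3.0 * amp * np.exp(-0.5 * ((t_local - bt) / 0.08) ** 2)
    return heog, veog


def _channel_noise(
    rng: np.random.Generator, n_ch: int, n: int, rate: float, sd: float, model: str
) -> np.ndarray:
    """Independent per-channel noise, pink (1/f, flattened below 0.1 Hz)
    plus white by default."""
    if model == "white":
        return sd * rng.standard_normal((n_ch, n), dtype=np.float32)
    from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

    m = next_fast_len(n)
    white_for_pink = rng.standard_normal((n_ch, m), dtype=np.float32)
    f = rfftfreq(m, 1.0 / rate)
    scale = (1.0 / np.sqrt(np.maximum(f, 0.1))).astype(np.float32)
    scale[0] = 0.0
    pink = irfft(rfft(white_for_pink, axis=1) * scale, m, axis=1)[:, :n]
    pink /= pink.std(axis=1, keepdims=True)
    pink += np.float32(np.sqrt(0.3 / 0.7)) * rng.standard_normal((n_ch, n), dtype=np.float32)
    pink *= np.float32(sd * np.sqrt(0.7))
    return pink


def simulate_eeg_trial(
    cond: TrialCondition,
    onset_time: Optional[float],
    patterns: SpatialPatternSet,
    config: SynthConfig,
    seed: Optional[int] = None,
) -> np.ndarray:
    """One trial's 32-channel EEG segment on a trial-local timeline.

    Time runs from 0 (Ready cue) to ``config.trial_period``; the Task cue
    is at 1 s and Go at 3 s.  ``onset_time`` is the movement onset on
    this local timeline (``None`` for a no-movement trial).  Returns
    channels x samples (30 montage channels, then HEOG, VEOG) in
    microvolts.
    """
    patterns.validate()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    n = int(round(config.trial_period * config.eeg_rate))
    t = np.arange(n) / config.eeg_rate
    data = np.zeros((len(STANDARD_MONTAGE) + 2, n))
    data[:30] = _trial_sources(cond, t, READY_TO_TASK, onset_time, patterns, config)
    if config.eog_amp > 0:
        heog, veog = _eog_traces(rng, n, config.eeg_rate, config.eog_amp)
        data[30], data[31] = heog, veog
        data[:30] += HEOG_LEAK[:, None] * heog
        data[:30] += VEOG_LEAK[:, None] * veog
    if config.noise_sd > 0:
        data[:30] += _channel_noise(rng, 30, n, config.eeg_rate, config.noise_sd, config.noise_model)
        data[30:] += 0.05 * config.noise_sd * rng.standard_normal((2, n))
    return data


def _draw_trial_fates(
    rng: np.random.Generator, n_trials: int, config: SynthConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-trial onset latency (s after Go, NaN = no movement).

    Regular latencies are Normal(onset_mean, onset_sd) truncated at 0.
    Early movers get onsets more than 0.5 s before Go; no-move trials get
    NaN.  Returns (latency, is_early) arrays.
    """
    u = rng.uniform(size=n_trials)
    latency = np.maximum(rng.normal(config.onset_mean, config.onset_sd, n_trials), 0.0)
    early_lat = -(0.55 + np.abs(rng.normal(0.15, 0.07, n_trials)))
    early_lat = np.clip(early_lat, -1.4, None)
    no_move = u < config.no_move_frac
    early = (~no_move) & (u < config.no_move_frac + config.early_mover_frac)
    latency = np.where(early, early_lat, latency)
    latency[no_move] = np.nan
    return latency, early


def simulate_session(
    config: SynthConfig,
    patterns: Optional[SpatialPatternSet] = None,
    include_eeg: bool = True,
) -> Session:
    """Assemble a full event-marked session from the generative model.

    Deterministic: the same config (including seed) yields a bit-identical
    session.  ``include_eeg=False`` skips the EEG forward model (the
    schedule, latencies, and kinematics are unchanged), which is useful
    for rejection-logic studies.
    """
    config.validate()
    patterns = patterns or SpatialPatternSet.default()
    patterns.validate()
    ss = np.random.SeedSequence(config.seed)
    r_sched, r_fate, r_eog, r_noise = [np.random.default_rng(s) for s in ss.spawn(4)]

    table = make_trial_schedule(config, seed=r_sched)
    latency, _ = _draw_trial_fates(r_fate, len(table), config)
    table = table.copy()
    table["t_onset"] = table["t_go"].to_numpy() + latency  # NaN propagates for no-move

    conds = [parse_condition_code(c) for c in table["code"]]

    # events
    ev_rows = []
    for row, cond in zip(table.itertuples(), conds):
        chime_delay = 3.0 if cond.action is Action.GRASP else 2.0
        ev_rows += [
            {"trial": row.trial, "type": "Ready", "time": row.t_ready, "code": row.code},
            {"trial": row.trial, "type": "Task", "time": row.t_task, "code": row.code},
            {"trial": row.trial, "type": "Go", "time": row.t_go, "code": row.code},
            {"trial": row.trial, "type": "Chime", "time": row.t_go + chime_delay, "code": row.code},
        ]
    events = pd.DataFrame(ev_rows)

    # kinematics (absolute time axes)
    kin: List[Trajectory] = []
    for row, cond, lat in zip(table.itertuples(), conds, latency):
        traj = simulate_kinematics(cond, None if np.isnan(lat) else float(lat), config)
        kin.append(Trajectory(time=traj.time + row.t_go, position=traj.position, rate=traj.rate))

    eeg = None
    ch_names = STANDARD_MONTAGE + EOG_CHANNELS
    if include_eeg:
        n = int(round((config.session_pad * 2 + len(table) * config.trial_period) * config.eeg_rate))
        t_axis_rate = config.eeg_rate
        # float32: ample for microvolt signals, halves the memory traffic
        eeg = np.zeros((32, n), dtype=np.float32)
        for row, cond in zip(table.itertuples(), conds):
            t_onset = None if np.isnan(row.t_onset) else float(row.t_onset)
            lo = row.t_task - 0.6
            hi = (t_onset if t_onset is not None else row.t_task) + 1.5
            i0 = max(0, int(np.floor(lo * t_axis_rate)))
            i1 = min(n, int(np.ceil(hi * t_axis_rate)))
            t = np.arange(i0, i1) / t_axis_rate
            eeg[:30, i0:i1] += _trial_sources(cond, t, row.t_task, t_onset, patterns, config)
        if config.eog_amp > 0:
            heog, veog = _eog_traces(r_eog, n, t_axis_rate, config.eog_amp)
            eeg[30], eeg[31] = heog, veog
            eeg[:30] += HEOG_LEAK.astype(np.float32)[:, None] * heog
            eeg[:30] += VEOG_LEAK.astype(np.float32)[:, None] * veog
        if config.noise_sd > 0:
            eeg[:30] += _channel_noise(r_noise, 30, n, t_axis_rate, config.noise_sd, config.noise_model)
            eeg[30:] += np.float32(0.05 * config.noise_sd) * r_noise.standard_normal(
                (2, n), dtype=np.float32
            )

    return Session(
        eeg=eeg,
        rate=config.eeg_rate,
        ch_names=ch_names,
        events=events,
        kinematics=kin,
        trial_table=table,
        config=config,
        patterns=patterns,
    )
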