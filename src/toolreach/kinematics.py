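"""Extraction of spatio-temporal reach parameters from fingertip trajectories.

Seven parameters are scored per trial, all referred to the going phase
(movement onset to target arrival): movement time (s), mean and peak
velocity (m/s), mean and peak acceleration over the acceleration phase
(onset to velocity peak, m/s^2), and mean and peak deceleration over the
deceleration phase (velocity peak to offset, signed, negative).

Processing chain: zero-phase Butterworth low-pass (6 Hz default),
central-difference differentiation of the 3D position to tangential
speed and of speed to acceleration, onset/offset segmentation by a
5%-of-peak speed threshold with hysteresis, refined by walking outward
while speed keeps falling (so the detected span reaches the true rest
plateau rather than stopping at the 5% crossing, which for a bell-shaped
profile would shorten the movement by ~12%).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import MarkerTrajectory

__all__ = [
    "GoingPhase",
    "KinematicParameters",
    "NoMovementError",
    "smooth_trajectory",
    "differentiate",
    "detect_going_phase",
    "extract_parameters",
    "extract_trial",
    "collapse_trials",
    "extract_cohort",
    "read_trial_csv",
]

PARAMETER_ORDER = [
    "movement_time",
    "mean_velocity",
    "peak_velocity",
    "mean_acceleration",
    "peak_acceleration",
    "mean_deceleration",
    "peak_deceleration",
]

SPEED_FLOOR = 1e-3  # m/s; below this there is no movement to segment


class NoMovementError(ValueError):
    """Raised when a speed profile never rises above the detection floor."""


@dataclass(frozen=True)
class GoingPhase:
    onset_index: int
    offset_index: int
    peak_velocity_index: int

    def __post_init__(self) -> None:
        if not self.onset_index < self.peak_velocity_index < self.offset_index:
            raise ValueError("phase indices must satisfy onset < peak < offset")


@dataclass(frozen=True)
class KinematicParameters:
    movement_time: float
    mean_velocity: float
    peak_velocity: float
    mean_acceleration: float
    peak_acceleration: float
    mean_deceleration: float
    peak_deceleration: float

    def __post_init__(self) -> None:
        if self.movement_time <= 0:
            raise ValueError("movement_time must be > 0")
        if not 0 < self.mean_velocity <= self.peak_velocity * (1 + 1e-9):
            raise ValueError("need 0 < mean_velocity <= peak_velocity")
        if not (self.peak_acceleration > 0 >= self.mean_deceleration >= self.peak_deceleration):
            raise ValueError("acceleration sign convention violated")


def smooth_trajectory(traj: MarkerTrajectory, cutoff: float = 6.0) -> MarkerTrajectory:
    """Zero-phase low-pass filter of the marker positions.

    A 2nd-order Butterworth applied forward and backward (net 4th-order,
    zero lag).  Timestamps and length are unchanged.
    """
    nyq = traj.sample_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({nyq} Hz)")
    b, a = signal.butter(2, cutoff / nyq)
    smoothed = signal.filtfilt(b, a, traj.positions, axis=0)
    return MarkerTrajectory(
        times=traj.times,
        positions=smoothed,
        sample_rate=traj.sample_rate,
        participant_id=traj.participant_id,
        group=traj.group,
        session=traj.session,
        hand=traj.hand,
        trial_index=traj.trial_index,
    )


def differentiate(traj: MarkerTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Tangential speed and its time derivative.

    Speed is the Euclidean norm of the central-difference 3D velocity
    (one-sided at the ends); acceleration is the same scheme applied to
    the speed series.  Both are frame-independent.
    """
    if traj.times.size < 3:
        raise ValueError("need >= 3 samples to differentiate")
    vel = np.gradient(traj.positions, traj.times, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    accel = np.gradient(speed, traj.times)
    return speed, accel


def _runs_below(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Boolean mask of samples belonging to a below-threshold run >= min_len."""
    out = np.zeros_like(mask)
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_len:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def detect_going_phase(
    speed: np.ndarray,
    threshold_frac: float = 0.05,
    sample_rate: float = 100.0,
    hysteresis_s: float = 0.05,
    refine: bool = True,
) -> GoingPhase:
    """Segment the going phase of a speed profile.

    The velocity peak is the global speed maximum (earliest index on
    ties).  Onset is located at the last sample before the peak inside a
    below-threshold run of at least ``hysteresis_s`` (tremor-resistant),
    offset symmetrically after the peak.  With ``refine=True`` both are
    then pushed outward while speed keeps strictly decreasing, stopping
    at a local minimum or the rest plateau, which removes the span bias
    of a pure threshold rule.
    """
    speed = np.asarray(speed, dtype=float)
    peak = int(np.argmax(speed))
    vmax = speed[peak]
    if vmax <= SPEED_FLOOR:
        raise NoMovementError("no movement detected: speed never exceeds 1 mm/s")
    min_len = max(1, int(round(hysteresis_s * sample_rate)))
    below = _runs_below(speed < threshold_frac * vmax, min_len)

    pre = np.flatnonzero(below[:peak])
    onset = int(pre[-1]) if pre.size else 0
    post_rel = np.flatnonzero(below[peak + 1 :])
    offset = int(peak + 1 + post_rel[0]) if post_rel.size else speed.size - 1

    if refine:
        # sub-threshold tails of a bell-shaped reach are < ~7% of the
        # detected span, so cap the walk to stop noise-driven runaways
        allow = max(3, int(round(0.12 * (offset - onset))))
        floor_on, cap_off = onset - allow, offset + allow
        while onset > max(0, floor_on) and speed[onset - 1] < speed[onset]:
            onset -= 1
        while offset < min(speed.size - 1, cap_off) and speed[offset + 1] < speed[offset]:
            offset += 1
        # the walk stops one sample into the rest plateau (central
        # differences smear the first moving sample); step back inside
        onset += 1
        offset -= 1
    onset = min(onset, peak - 1)
    offset = max(offset, peak + 1)
    return GoingPhase(onset_index=onset, offset_index=offset, peak_velocity_index=peak)


def extract_parameters(
    traj: MarkerTrajectory,
    phase: GoingPhase,
    speed: np.ndarray | None = None,
    accel: np.ndarray | None = None,
) -> KinematicParameters:
    """Score the seven parameters over a segmented going phase.

    Mean velocity is path length over the phase divided by movement
    time.  Acceleration parameters are taken over [onset, peak], the
    deceleration ones over [peak, offset] as signed mean and signed
    minimum, so deceleration values are negative as printed conventions
    require.
    """
    if speed is None or accel is None:
        speed, accel = differentiate(traj)
    on, pk, off = phase.onset_index, phase.peak_velocity_index, phase.offset_index
    if not (0 <= on < pk < off < traj.times.size):
        raise ValueError("phase does not fit inside the trajectory")
    if pk - on < 2 or off - pk < 2:
        raise ValueError("degenerate phase: need >= 3 samples per sub-phase")
    t = traj.times
    dt = float(np.median(np.diff(t)))
    # sub-sample timing of the velocity peak by parabolic interpolation;
    # the correction is clamped to half a sample
    t_pk, v_pk = t[pk], speed[pk]
    curv = speed[pk - 1] - 2.0 * speed[pk] + speed[pk + 1]
    if curv < 0:
        delta = float(np.clip(0.5 * (speed[pk - 1] - speed[pk + 1]) / curv, -0.5, 0.5))
        t_pk = t[pk] + delta * dt
        v_pk = speed[pk] - 0.25 * (speed[pk - 1] - speed[pk + 1]) * delta

    t_on, t_off = t[on], t[off]
    mt = t_off - t_on
    seg = traj.positions[on : off + 1]
    path = float(np.sum(np.linalg.norm(np.diff(seg, axis=0), axis=1)))
    # signed means are the time-average of tangential acceleration over
    # each sub-phase, i.e. net speed change / sub-phase duration
    mean_acc = (v_pk - speed[on]) / (t_pk - t_on)
    mean_dec = (speed[off] - v_pk) / (t_off - t_pk)
    return KinematicParameters(
        movement_time=float(mt),
        mean_velocity=path / float(mt),
        peak_velocity=float(max(v_pk, speed[on : off + 1].max())),
        mean_acceleration=float(mean_acc),
        peak_acceleration=float(accel[on : pk + 1].max()),
        mean_deceleration=float(min(mean_dec, 0.0)),
        peak_deceleration=float(accel[pk : off + 1].min()),
    )


def extract_trial(
    traj: MarkerTrajectory,
    cutoff: float = 6.0,
    threshold_frac: float = 0.05,
    smooth: bool = True,
) -> KinematicParameters:
    """Full per-trial chain: smooth, differentiate, segment, score."""
    if smooth:
        traj = smooth_trajectory(traj, cutoff)
    speed, accel = differentiate(traj)
    phase = detect_going_phase(speed, threshold_frac, sample_rate=traj.sample_rate)
    return extract_parameters(traj, phase, speed, accel)


def collapse_trials(params: pd.DataFrame, per_hand: bool = False) -> pd.DataFrame:
    """Mean of each parameter per participant x session (hands pooled).

    ``params`` is the tidy per-trial table produced by
    :func:`extract_cohort`.  With ``per_hand=True`` the hand column is
    kept as a grouping key instead of pooled.
    """
    if params.empty:
        raise ValueError("no trials to collapse")
    keys = ["participant_id", "session"]
    if "group" in params.columns:
        keys.insert(1, "group")
    if per_hand:
        keys.append("hand")
    return params.groupby(keys, as_index=False, sort=True)[PARAMETER_ORDER].mean()


def extract_cohort(
    trials, cutoff: float = 6.0, threshold_frac: float = 0.05
) -> pd.DataFrame:
    """Tidy per-trial parameter table for an iterable of trajectories."""
    rows = []
    for traj in trials:
        p = extract_trial(traj, cutoff=cutoff, threshold_frac=threshold_frac)
        rows.append(
            {
                "participant_id": traj.participant_id,
                "group": traj.group,
                "session": traj.session,
                "hand": traj.hand,
                "trial": traj.trial_index,
                **asdict(p),
            }
        )
    return pd.DataFrame(rows)


def read_trial_csv(path, **meta) -> MarkerTrajectory:
    """Read a `time,x,y,z` trial CSV (seconds, meters)."""
    return MarkerTrajectory.from_frame(pd.read_csv(path), **meta)
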