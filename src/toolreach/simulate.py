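"""Synthetic reach-to-point cohorts with known kinematic ground truth.

The generative model is a minimum-jerk point-to-point movement: the
fingertip travels a straight line of length ``D`` in time ``T`` following
the quintic profile ``x(t) = D (10 tau^3 - 15 tau^4 + 6 tau^5)``,
``tau = t/T``.  This is the standard closed-form model for self-paced
reaching: its speed profile is bell-shaped and single-peaked, the
acceleration crosses zero exactly at the velocity peak, and every
spatio-temporal parameter a kinematic pipeline should recover has a
closed form:

========================  =======================================
peak velocity             ``1.875 * D / T``
mean velocity             ``D / T``
peak acceleration         ``(10/sqrt(3)) * D / T**2`` (5.7735...)
peak deceleration         ``-(10/sqrt(3)) * D / T**2``
========================  =======================================

A cohort generator layers the structure of a pre/post tool-use
experiment on top: two groups (Parkinson's disease and healthy
controls), two recorded sessions (pre- and post-tool-use) of six trials
per hand, bradykinetic slowing and peak attenuation for the patient
group, a tool-use effect (longer movements, stronger deceleration)
applied per group, optional 4-6 Hz rest tremor, and tactile estimates of
a fixed 7 cm caliper gap after each of the three experimental sessions.

To let the tool-use effect raise deceleration magnitude independently
of total duration, trials are generated from a two-half minimum-jerk
profile with an acceleration phase of length ``Ta`` and a deceleration
phase of length ``Td`` (``Ta + Td = T``); the symmetric case
``Ta = Td = T/2`` reduces to the classic polynomial.  Speed and
acceleration are continuous at the junction and the peak speed
``1.875 D/T`` is invariant to the split, while the peak deceleration is
``-(10/sqrt(3)) * D / (2 T Td)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PEAK_SPEED_COEF",
    "PEAK_ACC_COEF",
    "ReachSpec",
    "CohortDesign",
    "TrialTruth",
    "MarkerTrajectory",
    "minimum_jerk_position",
    "reach_position",
    "generate_trial",
    "generate_cohort",
    "session_scores",
    "write_cohort",
]

#: max of d/dtau [10 tau^3 - 15 tau^4 + 6 tau^5] (attained at tau = 1/2)
PEAK_SPEED_COEF = 1.875
#: max of the second derivative, 10/sqrt(3), attained at tau = (3 - sqrt(3))/6
PEAK_ACC_COEF = 10.0 / np.sqrt(3.0)

SESSIONS = ("pre", "post")
TACTILE_SESSIONS = ("I", "II", "III")
HANDS = ("left", "right")
TRUE_GAP_CM = 7.0


@dataclass(frozen=True)
class ReachSpec:
    """Parameters of one simulated reach.

    amplitude_D : straight-line start-to-target distance (m).
    duration_T : movement time (s); the task is self-paced so this is a
        per-trial draw upstream, fixed here.
    decel_fraction : fraction of ``duration_T`` spent in the deceleration
        phase (0.5 = symmetric minimum jerk).
    tremor_amplitude / tremor_freq : additive sinusoid on the movement
        axis (m, Hz), present for the whole recording as rest tremor is.
    noise_sd : i.i.d. Gaussian positional noise per axis (m).
    rest_s / hold_s : stationary padding before onset and after offset.
    """

    amplitude_D: float = 0.33
    duration_T: float = 0.7
    sample_rate: float = 100.0
    decel_fraction: float = 0.5
    tremor_amplitude: float = 0.0
    tremor_freq: float = 5.0
    noise_sd: float = 0.0
    rest_s: float = 0.5
    hold_s: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.amplitude_D <= 0:
            raise ValueError("amplitude_D must be > 0")
        if self.duration_T <= 0:
            raise ValueError("duration_T must be > 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if not 0.05 <= self.decel_fraction <= 0.95:
            raise ValueError("decel_fraction must lie in [0.05, 0.95]")
        if self.tremor_amplitude < 0:
            raise ValueError("tremor_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TrialTruth:
    """Closed-form parameter values implied by a ReachSpec."""

    movement_time: float
    mean_velocity: float
    peak_velocity: float
    mean_acceleration: float
    peak_acceleration: float
    mean_deceleration: float
    peak_deceleration: float

    @classmethod
    def from_spec(cls, spec: ReachSpec) -> "TrialTruth":
        D, T = spec.amplitude_D, spec.duration_T
        Td = spec.decel_fraction * T
        Ta = T - Td
        return cls(
            movement_time=T,
            mean_velocity=D / T,
            peak_velocity=PEAK_SPEED_COEF * D / T,
            mean_acceleration=PEAK_SPEED_COEF * D / (T * Ta),
            peak_acceleration=PEAK_ACC_COEF * D / (2.0 * T * Ta),
            mean_deceleration=-PEAK_SPEED_COEF * D / (T * Td),
            peak_deceleration=-PEAK_ACC_COEF * D / (2.0 * T * Td),
        )


@dataclass
class MarkerTrajectory:
    """One trial's time-stamped 3D fingertip positions."""

    times: np.ndarray
    positions: np.ndarray  # (n, 3), meters
    sample_rate: float
    participant_id: str = ""
    group: str = ""
    session: str = ""
    hand: str = ""
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.positions.shape != (self.times.size, 3):
            raise ValueError("positions must be (n, 3) matching times")
        if self.times.size < 20:
            raise ValueError("trajectory needs >= 20 samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0) or np.ptp(dt) > 1e-6:
            raise ValueError("times must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **meta) -> "MarkerTrajectory":
        t = df["time"].to_numpy(float)
        rate = 1.0 / float(np.median(np.diff(t)))
        pos = df[["x", "y", "z"]].to_numpy(float)
        return cls(times=t, positions=pos, sample_rate=rate, **meta)


def _unit_minimum_jerk(tau: np.ndarray) -> np.ndarray:
    return 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5


def minimum_jerk_position(t, spec: ReachSpec):
    """Position along the movement axis at time ``t`` of the symmetric profile.

    Raises ValueError if any ``t`` lies outside ``[0, duration_T]``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > spec.duration_T):
        raise ValueError("t must lie in [0, duration_T]")
    return spec.amplitude_D * _unit_minimum_jerk(t / spec.duration_T)


def reach_position(t, D: float, T: float, decel_fraction: float = 0.5):
    """Two-half minimum-jerk position, asymmetric in time.

    The acceleration phase (duration ``Ta = (1 - decel_fraction) T``) is
    the first half of a minimum jerk of duration ``2 Ta`` and amplitude
    ``2 D Ta / T``; the deceleration phase is the mirror construction.
    Position, velocity and acceleration are continuous at the junction
    and the junction velocity is the global peak ``1.875 D / T``.
    """
    t = np.asarray(t, dtype=float)
    Td = decel_fraction * T
    Ta = T - Td
    Da = D * Ta / T
    Dd = D * Td / T
    out = np.empty_like(t)
    first = t <= Ta
    out[first] = 2.0 * Da * _unit_minimum_jerk(t[first] / (2.0 * Ta))
    tau = 0.5 + (t[~first] - Ta) / (2.0 * Td)
    out[~first] = D - 2.0 * Dd * (1.0 - _unit_minimum_jerk(tau))
    return out


def generate_trial(spec: ReachSpec, rng: np.random.Generator | None = None) -> MarkerTrajectory:
    """Simulate one trial: rest, going phase, terminal hold.

    With ``noise_sd = 0`` and ``tremor_amplitude = 0`` the sampled
    positions equal the analytic profile at the sample instants.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sample_rate
    total = spec.rest_s + spec.duration_T + spec.hold_s
    n = int(round(total / dt)) + 1
    times = np.arange(n) * dt
    x = np.empty(n)
    pre = times < spec.rest_s
    post = times > spec.rest_s + spec.duration_T
    mov = ~(pre | post)
    x[pre] = 0.0
    x[post] = spec.amplitude_D
    x[mov] = reach_position(
        times[mov] - spec.rest_s, spec.amplitude_D, spec.duration_T, spec.decel_fraction
    )
    if spec.tremor_amplitude > 0:
        x = x + spec.tremor_amplitude * np.sin(2.0 * np.pi * spec.tremor_freq * times)
    pos = np.column_stack([x, np.zeros(n), np.zeros(n)])
    if spec.noise_sd > 0:
        pos = pos + rng.normal(0.0, spec.noise_sd, size=pos.shape)
    return MarkerTrajectory(times=times, positions=pos, sample_rate=spec.sample_rate)


@dataclass(frozen=True)
class CohortDesign:
    """Structure and effect sizes of a simulated pre/post tool-use cohort.

    Defaults follow the study conditions this package targets: groups of
    14 patients and 18 controls, six trials per session and hand,
    baseline reach of 0.33 m (an 80%-of-arm-length target) in 0.66 s for
    controls, bradykinetic slowing x1.25 and amplitude attenuation x0.95
    for patients, a tool-use effect (movement time +0.06 s and
    deceleration-magnitude factor 1.15) present only in controls, 1 mm /
    5 Hz rest tremor in patients, and tactile estimates of the 7 cm gap
    biased by (+1.1, +1.0, +0.9) cm over the three measurement sessions.
    ``n_tactile_missing`` patients contribute no tactile data (the
    mixed-design tactile analysis then runs on 31 participants, the
    study's effective sample).
    """

    n_pd: int = 14
    n_control: int = 18
    trials_per_session: int = 6
    hands: int = 2
    amplitude_D: float = 0.33
    duration_T: float = 0.66
    pd_slowing: float = 1.25
    pd_attenuation: float = 0.95
    time_effect_T: tuple[float, float] = (0.0, 0.06)  # (PD, control) delta T post (s)
    time_effect_decel: tuple[float, float] = (1.0, 1.15)  # decel magnitude factor post
    subject_T_sd: float = 0.08
    trial_T_sd: float = 0.03
    tremor_amplitude_pd: float = 0.001
    tremor_freq: float = 5.0
    noise_sd: float = 0.0005
    sample_rate: float = 100.0
    tactile_trials: int = 7
    tactile_bias_by_session: tuple[float, float, float] = (1.1, 1.0, 0.9)
    tactile_subject_sd: float = 0.8
    tactile_noise_sd: float = 1.0
    n_tactile_missing: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pd < 2 or self.n_control < 2:
            raise ValueError("need >= 2 participants per group")
        if self.trials_per_session < 1:
            raise ValueError("trials_per_session must be >= 1")
        for name in ("pd_slowing", "pd_attenuation", "amplitude_D", "duration_T"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive and finite")
        if not 0 <= self.n_tactile_missing <= self.n_pd:
            raise ValueError("n_tactile_missing must lie in [0, n_pd]")

    @classmethod
    def null(cls, **overrides) -> "CohortDesign":
        """A design with every group and time effect switched off."""
        base = dict(
            pd_slowing=1.0,
            pd_attenuation=1.0,
            time_effect_T=(0.0, 0.0),
            time_effect_decel=(1.0, 1.0),
            tremor_amplitude_pd=0.0,
            tactile_bias_by_session=(0.0, 0.0, 0.0),
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "CohortDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown design fields: {sorted(unknown)}")
        for key in ("time_effect_T", "time_effect_decel", "tactile_bias_by_session"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class Cohort:
    """Everything one simulated experiment produces."""

    design: CohortDesign
    participants: pd.DataFrame  # participant_id, group, age, education, side, duration, updrs
    trials: list[MarkerTrajectory]
    truth: pd.DataFrame  # per-trial closed-form parameter values
    tactile: pd.DataFrame  # participant_id, group, session_measurement, hand, trial, estimate_cm


def _simulate_participants(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(design.n_pd):
        rows.append(
            {
                "participant_id": f"PD{i + 1:02d}",
                "group": "PD",
                "age": int(np.clip(round(rng.normal(66, 8)), 40, 90)),
                "education": int(np.clip(round(rng.normal(9, 3)), 3, 20)),
                "side": "L" if i % 2 == 0 else "R",
                "duration": int(np.clip(round(rng.normal(7, 3)), 1, 30)),
                "updrs": int(np.clip(round(rng.normal(30, 13)), 5, 100)),
            }
        )
    for i in range(design.n_control):
        rows.append(
            {
                "participant_id": f"HC{i + 1:02d}",
                "group": "control",
                "age": int(np.clip(round(rng.normal(48, 14)), 20, 85)),
                "education": int(np.clip(round(rng.normal(15, 3)), 5, 22)),
                "side": "",
                "duration": np.nan,
                "updrs": np.nan,
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(design: CohortDesign) -> Cohort:
    """Simulate the full experiment for one cohort.

    Per participant: ``trials_per_session * hands`` reaches in each of
    the pre and post sessions, plus ``tactile_trials`` tactile estimates
    per hand after each of the three experimental sessions.  Closed-form
    ground-truth parameter values are emitted per trial for recovery
    testing.  Identical design (including seed) gives identical output.
    """
    rng = np.random.default_rng(design.seed)
    participants = _simulate_participants(design, rng)
    trials: list[MarkerTrajectory] = []
    truth_rows = []
    tactile_rows = []
    no_tactile = set(
        participants.loc[participants.group == "PD", "participant_id"].iloc[
            : design.n_tactile_missing
        ]
    )
    g_index = {"PD": 0, "control": 1}
    for _, prow in participants.iterrows():
        pid, group = prow.participant_id, prow.group
        gi = g_index[group]
        slow = design.pd_slowing if group == "PD" else 1.0
        atten = design.pd_attenuation if group == "PD" else 1.0
        tremor = design.tremor_amplitude_pd if group == "PD" else 0.0
        subj_dT = rng.normal(0.0, design.subject_T_sd)
        for session in SESSIONS:
            base_T = design.duration_T * slow + subj_dT
            if session == "post":
                base_T += design.time_effect_T[gi]
                decel_factor = design.time_effect_decel[gi]
            else:
                decel_factor = 1.0
            decel_fraction = np.clip(0.5 / decel_factor, 0.05, 0.95)
            for hand in HANDS[: design.hands]:
                for k in range(design.trials_per_session):
                    T = max(0.25, base_T + rng.normal(0.0, design.trial_T_sd))
                    spec = ReachSpec(
                        amplitude_D=design.amplitude_D * atten,
                        duration_T=T,
                        sample_rate=design.sample_rate,
                        decel_fraction=float(decel_fraction),
                        tremor_amplitude=tremor,
                        tremor_freq=design.tremor_freq,
                        noise_sd=design.noise_sd,
                    )
                    traj = generate_trial(spec, rng)
                    traj.participant_id = pid
                    traj.group = group
                    traj.session = session
                    traj.hand = hand
                    traj.trial_index = k
                    trials.append(traj)
                    truth_rows.append(
                        {
                            "participant_id": pid,
                            "group": group,
                            "session": session,
                            "hand": hand,
                            "trial": k,
                            **dataclasses.asdict(TrialTruth.from_spec(spec)),
                        }
                    )
        # tactile estimation: 7 trials after each of the three sessions, per hand
        subj_tact = rng.normal(0.0, design.tactile_subject_sd)
        if pid not in no_tactile:
            for si, sess in enumerate(TACTILE_SESSIONS):
                for hand in HANDS[: design.hands]:
                    est = (
                        TRUE_GAP_CM
                        + design.tactile_bias_by_session[si]
                        + subj_tact
                        + rng.normal(0.0, design.tactile_noise_sd, design.tactile_trials)
                    )
                    est = np.clip(est, 0.0, None)
                    for k, e in enumerate(est):
                        tactile_rows.append(
                            {
                                "participant_id": pid,
                                "group": group,
                                "session_measurement": sess,
                                "hand": hand,
                                "trial": k,
                                "estimate_cm": float(e),
                            }
                        )
        else:
            # burn the same number of draws so other participants' data
            # do not depend on who is missing
            rng.normal(0.0, design.tactile_noise_sd,
                       3 * design.hands * design.tactile_trials)
    truth = pd.DataFrame(truth_rows)
    tactile = pd.DataFrame(tactile_rows)
    return Cohort(design=design, participants=participants, trials=trials,
                  truth=truth, tactile=tactile)


def session_scores(
    n_pd: int,
    n_control: int,
    n_sessions: int = 2,
    cell_effects: np.ndarray | None = None,
    icc: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Participant x session outcomes drawn at the response level.

    Statistical shortcut of :func:`generate_cohort` for calibration
    studies: each participant-session mean outcome is a random subject
    intercept (variance ``icc``) plus independent session noise
    (variance ``1 - icc``), shifted by ``cell_effects[group, session]``
    expressed in total-SD units.  Row order and column names match what
    the ANOVA front end expects.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if cell_effects is None:
        cell_effects = np.zeros((2, n_sessions))
    cell_effects = np.asarray(cell_effects, dtype=float)
    if cell_effects.shape != (2, n_sessions):
        raise ValueError("cell_effects must be (2, n_sessions)")
    rows = []
    for gi, (gname, n) in enumerate((("PD", n_pd), ("control", n_control))):
        subj = rng.normal(0.0, np.sqrt(icc), n)
        eps = rng.normal(0.0, np.sqrt(1.0 - icc), (n, n_sessions))
        for i in range(n):
            for j in range(n_sessions):
                rows.append(
                    {
                        "participant_id": f"{gname}{i}",
                        "group": gname,
                        "session": f"s{j}",
                        "value": subj[i] + eps[i, j] + cell_effects[gi, j],
                    }
                )
    return pd.DataFrame(rows)


def write_cohort(cohort: Cohort, outdir) -> pd.DataFrame:
    """Write trials as per-trial CSVs plus manifest, truth, and tactile CSVs.

    Returns the manifest (one row per trial CSV written).
    """
    outdir = Path(outdir)
    trialdir = outdir / "trials"
    trialdir.mkdir(parents=True, exist_ok=True)
    meta = cohort.participants.set_index("participant_id")
    manifest_rows = []
    for traj in cohort.trials:
        fname = f"{traj.participant_id}_{traj.session}_{traj.hand}_{traj.trial_index:02d}.csv"
        traj.to_frame().to_csv(trialdir / fname, index=False, float_format="%.9g")
        m = meta.loc[traj.participant_id]
        manifest_rows.append(
            {
                "participant_id": traj.participant_id,
                "group": m.group,
                "age": m.age,
                "education": m.education,
                "side": m.side,
                "duration": m.duration,
                "updrs": m.updrs,
                "hand": traj.hand,
                "session": traj.session,
                "trial": traj.trial_index,
                "file": f"trials/{fname}",
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(outdir / "manifest.csv", index=False, float_format="%.9g")
    cohort.truth.to_csv(outdir / "ground_truth.csv", index=False, float_format="%.9g")
    cohort.tactile.to_csv(outdir / "tactile.csv", index=False, float_format="%.9g")
    return manifest
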