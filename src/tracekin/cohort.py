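"""Synthetic study generator: participants, questionnaires, stylus traces.

Emulates a three-group cohort (autistic, Parkinson's, control; N = 31/32/31)
tracing the four pure-frequency shapes over two testing days, plus a
reaction-time task and the questionnaire battery.  The generative kinematic
model is the speed-curvature power law

    v(s) = c * kappa(s)^(-beta) * exp(eta_slow(s)) * exp(g * z(s)),

with ``beta`` the group's speed-modulation exponent, ``eta_slow`` a slow
multiplicative speed drift, and ``z`` band-limited zero-mean noise with
~150 ms correlation time whose gain ``g`` injects intermittent
acceleration-sign alternations (sub-movements).  The normalisation ``c`` is
chosen so the time-averaged speed equals the group's base speed.  A
low-frequency normal offset models imperfect tracing.

Questionnaire scores are drawn from zero-truncated normals with the cohort
summary means/SDs; reaction times are shifted lognormals.  Everything is
driven by one seeded generator: a fixed seed reproduces the dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter1d
from scipy.stats import truncnorm

from .preprocessing import RawTrajectory
from .shapes import IdealCurve, SHAPE_NAMES, all_task_shapes

__all__ = [
    "GroupProfile",
    "CohortConfig",
    "TrialScheduleEntry",
    "CohortDataset",
    "DEFAULT_PROFILES",
    "simulate_task_schedule",
    "simulate_trial_trajectory",
    "simulate_reaction_times",
    "simulate_questionnaires",
    "simulate_cohort",
]

QUESTIONNAIRES = ("aq", "raads", "updrs", "phq", "gad", "nvr")


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one participant group.

    Questionnaire/age means and SDs default to the cohort summary table;
    the kinematic knobs (speed-modulation exponent, sub-movement gain,
    reaction-time shift) encode the qualitative group ordering reported for
    the task — their magnitudes are simulator calibration, not measurements.
    """

    group: str
    beta_gen: float  # speed-modulation exponent
    base_speed: float  # time-averaged tracing speed, px/s
    submovement_gain: float  # log-speed perturbation amplitude
    rt_shift: float  # s
    rt_mu_log: float = float(np.log(0.12))  # lognormal location (log s)
    rt_sigma: float = 0.30  # lognormal scale
    beta_between_sd: float = 0.04  # between-participant SD of beta
    speed_between_sd: float = 0.10  # between-participant SD of log base speed
    gain_between_sd: float = 0.03
    questionnaire_params: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    age_params: tuple[float, float] = (60.0, 9.0)
    gender_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.beta_gen < 0:
            raise ValueError("beta_gen must be >= 0")
        if self.base_speed <= 0:
            raise ValueError("base_speed must be > 0")
        for name, (_, sd) in self.questionnaire_params.items():
            if sd < 0:
                raise ValueError(f"negative SD for {name}")


DEFAULT_PROFILES: dict[str, GroupProfile] = {
    "ASD": GroupProfile(
        group="ASD",
        beta_gen=0.40,
        base_speed=500.0,
        submovement_gain=0.26,
        rt_shift=0.44,
        questionnaire_params={
            "aq": (37.61, 7.06),
            "raads": (32.97, 8.05),
            "updrs": (3.7, 3.76),
            "phq": (8.2, 5.59),
            "gad": (9.9, 5.89),
            "nvr": (0.57, 0.15),
        },
        age_params=(55.52, 8.01),
        gender_counts={"M": 14, "F": 16, "O": 1},
    ),
    "PD": GroupProfile(
        group="PD",
        beta_gen=0.30,
        base_speed=500.0,
        submovement_gain=0.20,
        rt_shift=0.50,
        questionnaire_params={
            "aq": (19.19, 7.72),
            "raads": (10.7, 9.43),
            "updrs": (11.91, 6.93),
            "phq": (7.87, 4.56),
            "gad": (5.1, 4.39),
            "nvr": (0.55, 0.13),
        },
        age_params=(63.16, 7.60),
        gender_counts={"M": 19, "F": 13},
    ),
    "CTRL": GroupProfile(
        group="CTRL",
        beta_gen=0.33,
        base_speed=500.0,
        submovement_gain=0.20,
        rt_shift=0.45,
        questionnaire_params={
            "aq": (16.03, 5.95),
            "raads": (6.32, 6.46),
            "updrs": (0.94, 1.69),
            "phq": (3.0, 2.58),
            "gad": (3.6, 4.90),
            "nvr": (0.58, 0.16),
        },
        age_params=(59.00, 9.96),
        gender_counts={"M": 15, "F": 16},
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the simulated cohort."""

    n_per_group: tuple[int, int, int] = (31, 32, 31)
    n_days: int = 2
    seed: int = 0
    sampling_rate_hz: float = 60.0
    timestamp_jitter_sd: float = 0.001  # s
    shapes: tuple[str, ...] = SHAPE_NAMES
    n_cycles: int = 10
    successes_per_block: int = 4
    max_attempts: int = 7
    failure_prob: float = 0.08
    rt_trials: int = 40
    rt_practice: int = 8
    # noise structure of the trajectory generator
    speed_noise_sd: float = 0.08  # slow log-speed drift
    speed_noise_corr_s: float = 1.0
    submovement_corr_s: float = 0.15
    error_sd_px: float = 2.5  # normal-offset tracing error
    error_corr_s: float = 0.5
    deviation_boundary_frac: float = 0.15  # of the shape's larger dimension

    def __post_init__(self) -> None:
        if self.n_days not in (1, 2):
            raise ValueError("n_days must be 1 or 2")
        if not 0.0 <= self.failure_prob < 1.0:
            raise ValueError("failure_prob must be in [0, 1)")


@dataclass
class TrialScheduleEntry:
    day: int
    block: int  # presentation order within the day, 1-based
    shape: str
    attempt: int  # 1-based within block
    success: bool
    trial: int  # successful-trial counter within the day (0 for failures)


@dataclass
class CohortDataset:
    """In-memory simulated study (see ``tracekin.io`` for the file layout)."""

    trajectories: pd.DataFrame
    covariates: pd.DataFrame
    reaction_times: pd.DataFrame
    schedule: pd.DataFrame
    config: CohortConfig


def simulate_task_schedule(
    config: CohortConfig, failure_prob: float, rng: np.random.Generator
) -> list[TrialScheduleEntry]:
    """Block scheduler for one participant.

    Per day: two blocks per shape in a random order; within each block,
    attempts are drawn until ``successes_per_block`` successes or
    ``max_attempts`` attempts, each attempt failing independently with
    ``failure_prob``.
    """
    if not 0.0 <= failure_prob < 1.0:
        raise ValueError("failure_prob must be in [0, 1)")
    entries: list[TrialScheduleEntry] = []
    for day in range(1, config.n_days + 1):
        block_shapes = list(config.shapes) * 2
        rng.shuffle(block_shapes)
        trial_counter = 0
        for block_idx, shape in enumerate(block_shapes, start=1):
            successes = 0
            attempt = 0
            while successes < config.successes_per_block and attempt < config.max_attempts:
                attempt += 1
                ok = rng.random() >= failure_prob
                if ok:
                    successes += 1
                    trial_counter += 1
                entries.append(
                    TrialScheduleEntry(
                        day=day,
                        block=block_idx,
                        shape=shape,
                        attempt=attempt,
                        success=ok,
                        trial=trial_counter if ok else 0,
                    )
                )
    return entries


def _smooth_noise(n: int, sigma_samples: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited zero-mean Gaussian noise with target marginal SD."""
    if sd <= 0 or n < 4:
        return np.zeros(n)
    raw = gaussian_filter1d(rng.standard_normal(n), max(sigma_samples, 1e-6), mode="wrap")
    raw_sd = raw.std()
    if raw_sd < 1e-12:
        return np.zeros(n)
    return raw * (sd / raw_sd)


def simulate_trial_trajectory(
    curve: IdealCurve,
    profile: GroupProfile,
    n_cycles: float,
    config: CohortConfig,
    rng: np.random.Generator,
    meta: Optional[dict] = None,
) -> RawTrajectory:
    """Generate one stylus trace of ``n_cycles`` counter-clockwise cycles."""
    if n_cycles < 0.1:
        raise ValueError("n_cycles must be >= 0.1")
    per = curve.perimeter
    n_curve = len(curve.s) - 1  # closing point duplicated
    full = int(np.floor(n_cycles))
    frac_pts = int(np.floor((n_cycles - full) * n_curve))
    s_dense = np.concatenate(
        [curve.s[:-1] + k * per for k in range(full)]
        + ([curve.s[:frac_pts] + full * per] if frac_pts else [])
        + [[n_cycles * per]]
    )
    kappa = curve.kappa_at_s(s_dense)
    ds = np.diff(s_dense).mean()

    # target speed: power law x slow drift x band-limited sub-movement noise
    v = kappa ** (-profile.beta_gen) if profile.beta_gen > 0 else np.ones_like(kappa)
    corr_px_slow = config.speed_noise_corr_s * profile.base_speed
    v = v * np.exp(_smooth_noise(len(v), corr_px_slow / ds, config.speed_noise_sd, rng))
    corr_px_sub = config.submovement_corr_s * profile.base_speed
    v = v * np.exp(
        _smooth_noise(len(v), corr_px_sub / ds, 1.0, rng) * profile.submovement_gain
    )
    # normalise so the time-averaged speed equals base_speed
    t_unnorm = cumulative_trapezoid(1.0 / v, s_dense, initial=0.0)
    c = profile.base_speed * t_unnorm[-1] / s_dense[-1]
    v = v * c
    t_dense = t_unnorm / c

    # low-frequency normal-offset tracing error
    corr_px_err = config.error_corr_s * profile.base_speed
    offset = _smooth_noise(len(s_dense), corr_px_err / ds, config.error_sd_px, rng)
    boundary = config.deviation_boundary_frac * max(*curve.bbox)
    success = bool(np.all(np.abs(offset) < boundary))

    # sample near the device rate with timestamp jitter
    dt = 1.0 / config.sampling_rate_hz
    n_samp = int(np.floor(t_dense[-1] / dt)) + 1
    t_samp = np.arange(n_samp) * dt
    if config.timestamp_jitter_sd > 0:
        jitter = rng.normal(0.0, config.timestamp_jitter_sd, n_samp)
        jitter[0] = 0.0
        t_samp = np.maximum.accumulate(np.clip(t_samp + jitter, 0.0, t_dense[-1]))
    s_samp = np.interp(t_samp, t_dense, s_dense)
    x, y = curve.position_at_s(s_samp)
    theta = curve.theta_at_s(s_samp)
    e_samp = np.interp(s_samp, s_dense, offset)
    x = x - np.sin(theta) * e_samp
    y = y + np.cos(theta) * e_samp

    meta = meta or {}
    return RawTrajectory(
        participant=meta.get("participant", "SIM"),
        group=meta.get("group", profile.group),
        day=meta.get("day", 1),
        block=meta.get("block", 1),
        shape=meta.get("shape", curve.spec.name),
        trial=meta.get("trial", 1),
        attempt=meta.get("attempt", 1),
        t=t_samp,
        x=x,
        y=y,
        success=success and meta.get("success", True),
    )


def simulate_reaction_times(
    profile: GroupProfile, n_trials: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-trial reaction times: shift + lognormal(mu, sigma), seconds."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if profile.rt_sigma == 0:
        return np.full(n_trials, profile.rt_shift + np.exp(profile.rt_mu_log))
    return profile.rt_shift + rng.lognormal(profile.rt_mu_log, profile.rt_sigma, n_trials)


def _truncated_normal(
    mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Zero-truncated normal draws (degenerate at the mean when sd = 0)."""
    if sd == 0:
        return np.full(n, float(mean))
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_questionnaires(
    profiles: Mapping[str, GroupProfile],
    n_per_group: Sequence[int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Covariate table: age, gender and questionnaire scores per participant.

    Scores and age are zero-truncated normals with the group means/SDs;
    gender labels reproduce the group counts (padded proportionally when a
    non-default group size is requested) in a shuffled order.
    """
    rows = []
    for (name, profile), n in zip(profiles.items(), n_per_group):
        for inst in QUESTIONNAIRES:
            if inst not in profile.questionnaire_params:
                raise ValueError(f"profile {name} missing mean/SD for {inst!r}")
        scores = {
            inst: _truncated_normal(*profile.questionnaire_params[inst], n, rng)
            for inst in QUESTIONNAIRES
        }
        age = _truncated_normal(*profile.age_params, n, rng)
        genders: list[str] = []
        labels = list(profile.gender_counts) or ["M", "F"]
        counts = np.array([profile.gender_counts.get(g, 1) for g in labels], float)
        quota = np.floor(counts / counts.sum() * n).astype(int)
        for g, k in zip(labels, quota):
            genders.extend([g] * int(k))
        while len(genders) < n:
            genders.append(labels[int(rng.integers(len(labels)))])
        genders = genders[:n]
        rng.shuffle(genders)
        for i in range(n):
            rows.append(
                {
                    "participant": f"{name}{i + 1:03d}",
                    "group": name,
                    "age": age[i],
                    "gender": genders[i],
                    **{inst: scores[inst][i] for inst in QUESTIONNAIRES},
                }
            )
    return pd.DataFrame(rows)


def _trajectory_rows(traj: RawTrajectory) -> pd.DataFrame:
    n = len(traj.t)
    return pd.DataFrame(
        {
            "participant_id": [traj.participant] * n,
            "group": [traj.group] * n,
            "day": traj.day,
            "block": traj.block,
            "shape": [traj.shape] * n,
            "trial": traj.trial,
            "attempt": traj.attempt,
            "success": traj.success,
            "t_s": traj.t,
            "x_px": traj.x,
            "y_px": traj.y,
        }
    )


def simulate_cohort(
    config: CohortConfig,
    profiles: Mapping[str, GroupProfile] = DEFAULT_PROFILES,
    curves: Optional[Mapping[str, IdealCurve]] = None,
) -> CohortDataset:
    """Simulate the full study for every participant.

    Failed attempts produce short partial traces (0.3-2.4 cycles) flagged
    unsuccessful; practice reaction-time trials are generated but flagged.
    """
    rng = np.random.default_rng(config.seed)
    if curves is None:
        curves = all_task_shapes(config.shapes)
    covariates = simulate_questionnaires(
        profiles, list(config.n_per_group), rng
    )
    traj_frames: list[pd.DataFrame] = []
    sched_rows: list[dict] = []
    rt_rows: list[dict] = []
    for _, person in covariates.iterrows():
        pid = person["participant"]
        profile = profiles[person["group"]]
        # participant-level kinematic parameters
        p_profile = replace(
            profile,
            beta_gen=max(rng.normal(profile.beta_gen, profile.beta_between_sd), 0.0),
            base_speed=float(
                profile.base_speed * np.exp(rng.normal(0.0, profile.speed_between_sd))
            ),
            submovement_gain=max(
                rng.normal(profile.submovement_gain, profile.gain_between_sd), 0.0
            ),
        )
        schedule = simulate_task_schedule(config, config.failure_prob, rng)
        for entry in schedule:
            meta = {
                "participant": pid,
                "group": person["group"],
                "day": entry.day,
                "block": entry.block,
                "shape": entry.shape,
                "trial": entry.trial,
                "attempt": entry.attempt,
                "success": entry.success,
            }
            cycles = (
                float(config.n_cycles)
                if entry.success
                else float(rng.uniform(0.3, 2.4))
            )
            traj = simulate_trial_trajectory(
                curves[entry.shape], p_profile, cycles, config, rng, meta
            )
            traj_frames.append(_trajectory_rows(traj))
            sched_rows.append({"participant_id": pid, **vars(entry), "kept": traj.success})
        for day in range(1, config.n_days + 1):
            rts = simulate_reaction_times(
                p_profile, config.rt_practice + config.rt_trials, rng
            )
            for i, rt in enumerate(rts, start=1):
                rt_rows.append(
                    {
                        "participant_id": pid,
                        "group": person["group"],
                        "day": day,
                        "trial": i,
                        "practice": i <= config.rt_practice,
                        "rt_s": float(rt),
                    }
                )
    return CohortDataset(
        trajectories=pd.concat(traj_frames, ignore_index=True),
        covariates=covariates,
        reaction_times=pd.DataFrame(rt_rows),
        schedule=pd.DataFrame(sched_rows),
        config=config,
    )
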