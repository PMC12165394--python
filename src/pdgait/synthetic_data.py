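"""Synthetic trajectories and cohorts with analytic ground truth.

Three generators stand in for undeposited participant recordings:

* :func:`simulate_tug_trajectory` — a COM trajectory through the full
  Timed-Up-and-Go cycle whose eight event-rule crossing times are known in
  closed form (half-cosine vertical transitions; monotone PCHIP horizontal
  excursion through the 1 m / 3 m thresholds at exactly the programmed
  times).
* :func:`simulate_walking_trial` — a cyclic overground walking trial
  (sinusoidal heel/toe excursion relative to the COM, quartic swing-phase
  toe-height valley, sinusoidal joint flexion) with closed-form foot
  strike/off times, stride length, double support, minimum toe clearance
  and joint ROM.
* :func:`simulate_cohort` — a Gaussian-copula cohort whose marginal
  means/SDs, shapes (normal or positively skewed) and latent correlation
  matrix are the generating truth.

The waveform family is chosen for exact ground truth, not biomechanical
realism; every generator is seed-deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from statsmodels.stats.correlation_tools import corr_nearest

from .gait_metrics import GaitEvents, compose_cardan_xyz, symmetry_angle
from .io_model import (
    COGNITIVE_COLUMNS,
    DT_COLUMNS,
    ParameterError,
    REGISTRY_COLUMNS,
    ST_COLUMNS,
    TUG_COLUMNS,
    TrialRecording,
)
from .tug_phases import TUGEvents

logger = logging.getLogger(__name__)

__all__ = [
    "TUGSimParams",
    "WalkSimParams",
    "CohortSimParams",
    "WalkTruth",
    "CohortTruth",
    "COHORT_MARGINALS",
    "SKEWED_COLUMNS",
    "default_correlation_matrix",
    "simulate_tug_trajectory",
    "simulate_walking_trial",
    "simulate_cohort",
]

_MAX_WALK_SPEED = 3.0  # physical cap used for feasibility checks (m/s)


# --------------------------------------------------------------------------
# TUG trajectory
# --------------------------------------------------------------------------


@dataclass
class TUGSimParams:
    """Programmed TUG phase structure (defaults follow the cohort means)."""

    phase_durations: tuple = (1.13, 0.59, 1.73, 2.98, 1.89, 1.32, 1.33)
    seated_com_z: float = 0.55
    standing_com_z: float = 0.95
    walk_speed: float = 1.2
    turn_extra_m: float = 0.4  # COM excursion beyond the 3 m mark mid-turn
    detect_tol_m: float = 0.005  # matches the detector's z noise tolerance
    pre_hold_s: float = 1.0
    post_hold_s: float = 0.8
    noise_sd_m: float = 0.0
    rate_hz: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.phase_durations) != 7:
            raise ParameterError("phase_durations must have 7 entries")
        if any(d <= 0 for d in self.phase_durations):
            raise ParameterError("phase durations must be positive")
        if self.standing_com_z <= self.seated_com_z:
            raise ParameterError("standing COM height must exceed seated height")
        if self.noise_sd_m < 0:
            raise ParameterError("noise must be non-negative")
        if self.pre_hold_s < 0.6:
            raise ParameterError("pre_hold_s must cover the seated baseline window")

    @classmethod
    def randomized(cls, seed: int, noise_sd_m: float = 0.0) -> "TUGSimParams":
        """Phase durations jittered +/-15 % around the defaults."""
        rng = np.random.default_rng(seed)
        base = np.array(cls.__dataclass_fields__["phase_durations"].default)
        durations = tuple(base * rng.uniform(0.85, 1.15, size=7))
        return cls(
            phase_durations=durations,
            seated_com_z=float(rng.uniform(0.52, 0.60)),
            standing_com_z=float(rng.uniform(0.90, 1.00)),
            noise_sd_m=noise_sd_m,
            seed=seed,
        )


def simulate_tug_trajectory(params: TUGSimParams) -> tuple[TrialRecording, TUGEvents]:
    """Build a TUG COM trajectory plus its exact rule-crossing event times.

    The vertical channel rises through a half-cosine to a standing peak
    (with a curvature-matched overshoot so the peak is locally symmetric),
    plateaus, and descends through the 95 % threshold exactly at the
    programmed sit_begin.  The horizontal channel is a monotone PCHIP
    through knots placed at the programmed 1 m / 3 m crossing times, so the
    excursion rules fire exactly at the knots.
    """
    d1, d2, d3, d4, d5, d6, d7 = params.phase_durations
    if (params.standing_com_z - params.seated_com_z) <= 4 * params.detect_tol_m:
        raise ParameterError("stand height change too small for the stand_init rule")
    # walk 1 must span from 1 m to 3 m within its duration
    if 2.0 / d3 > _MAX_WALK_SPEED:
        raise ParameterError(
            f"walk1 of {d3:.2f} s cannot span 2 m at a feasible speed "
            f"(requires {2.0 / d3:.1f} m/s)"
        )
    if 2.0 / d5 > _MAX_WALK_SPEED:
        raise ParameterError(f"walk2 of {d5:.2f} s cannot span 2 m at a feasible speed")

    t0 = params.pre_hold_s
    stand_end = t0 + d1
    gait_init_end = stand_end + d2
    turn_begin = gait_init_end + d3
    turn_end = turn_begin + d4
    walk2_end = turn_end + d5
    sit_begin = walk2_end + d6
    sit_end = sit_begin + d7
    total = sit_end + params.post_hold_s

    z_seat = params.seated_com_z
    z_stand = params.standing_com_z
    # overshoot with matched curvature on both sides of the peak so the
    # peak is locally symmetric (keeps quadratic refinement unbiased)
    d_dec = 0.3 * d1
    r2 = (d_dec / d1) ** 2
    overshoot = (z_stand - z_seat) * r2 / (1.0 - r2)
    z_peak = z_stand + overshoot
    if params.standing_com_z <= 0.95 * z_peak + 0.002:
        raise ParameterError("standing plateau would dip below the 95 % sit threshold")
    rise_amp = z_peak - z_seat

    # stand_init ground truth: analytic crossing of the detection threshold
    tau = (d1 / np.pi) * np.arccos(1.0 - 2.0 * params.detect_tol_m / rise_amp)
    stand_init = t0 + tau

    # descent solved so z crosses 0.95 * z_peak exactly at sit_begin
    f_cross = (z_stand - 0.95 * z_peak) / (z_stand - z_seat)
    s_star = float(np.arccos(1.0 - 2.0 * f_cross) / np.pi)
    descent = min(1.2, 0.9 * d6 / s_star, (total - sit_begin) / max(1e-9, 1 - s_star) * 0.95)
    if descent <= 0.05:
        raise ParameterError("slow-down phase too short to fit the sitting descent")
    t_desc = sit_begin - s_star * descent
    if t_desc < walk2_end:
        raise ParameterError("sitting descent would begin before walk 2 ends")

    n = int(round(total * params.rate_hz)) + 1
    t = np.arange(n) / params.rate_hz

    z = np.full(n, z_seat)
    rise = (t >= t0) & (t < stand_end)
    z[rise] = z_seat + rise_amp * 0.5 * (1 - np.cos(np.pi * (t[rise] - t0) / d1))
    dec = (t >= stand_end) & (t < stand_end + d_dec)
    z[dec] = z_stand + overshoot * 0.5 * (1 + np.cos(np.pi * (t[dec] - stand_end) / d_dec))
    plat = (t >= stand_end + d_dec) & (t < t_desc)
    z[plat] = z_stand
    down = (t >= t_desc) & (t < t_desc + descent)
    z[down] = z_seat + (z_stand - z_seat) * 0.5 * (
        1 + np.cos(np.pi * (t[down] - t_desc) / descent)
    )
    z[t >= t_desc + descent] = z_seat

    apex_t = turn_begin + d4 / 2.0
    # the COM keeps drifting backward over the chair after sit_end so the
    # x <= start crossing has a firm slope at the knot
    knots_t = np.array(
        [0.0, stand_end, gait_init_end, turn_begin, apex_t, turn_end, walk2_end,
         sit_begin, sit_end, total]
    )
    knots_x = np.array(
        [0.0, 0.0, 1.0, 3.0, 3.0 + params.turn_extra_m, 3.0, 1.0, 0.3, 0.0, -0.08]
    )
    if np.any(np.diff(knots_t) <= 0):
        raise ParameterError("phase durations produce non-increasing trajectory knots")
    x = PchipInterpolator(knots_t, knots_x)(t)

    y = np.zeros(n)
    com = np.column_stack([x, y, z])
    if params.noise_sd_m > 0:
        rng = np.random.default_rng(params.seed)
        com = com + rng.normal(0.0, params.noise_sd_m, size=com.shape)

    trial = TrialRecording(
        trial_id=f"tug-sim-{params.seed}",
        condition="TUG",
        rate_hz=params.rate_hz,
        t=t,
        com=com,
    )
    events = TUGEvents(
        stand_init=stand_init,
        stand_end=stand_end,
        gait_init_end=gait_init_end,
        turn_begin=turn_begin,
        turn_end=turn_end,
        walk2_end=walk2_end,
        sit_begin=sit_begin,
        sit_end=sit_end,
        start_x=0.0,
        start_z=z_seat,
        standing_z=z_peak,
    )
    events.validate()
    return trial, events


# --------------------------------------------------------------------------
# Walking trial
# --------------------------------------------------------------------------


@dataclass
class WalkSimParams:
    """Programmed spatiotemporal/kinematic panel for one walking trial."""

    velocity: float = 1.32
    stride_length: float = 1.36
    double_support: float = 0.34
    toe_clearance: float = 0.034
    hip_rom_left: float = 50.4
    hip_rom_right: float = 50.4
    shoulder_rom_left: float = 24.0
    shoulder_rom_right: float = 20.0
    trial_length_m: float = 15.0
    impaired_side: str = "left"
    condition: str = "WALK_ST"
    swing_peak_extra_m: float = 0.03  # toe lift above the mid-swing minimum
    noise_sd_m: float = 0.0
    rate_hz: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.velocity, self.stride_length, self.toe_clearance) <= 0:
            raise ParameterError("velocity, stride length and toe clearance must be positive")
        if min(self.hip_rom_left, self.hip_rom_right,
               self.shoulder_rom_left, self.shoulder_rom_right) <= 0:
            raise ParameterError("ROM values must be positive")
        if self.trial_length_m < 15.0:
            raise ParameterError("trial length must be at least 15 m")
        if self.double_support <= 0 or self.double_support >= self.stride_time:
            raise ParameterError(
                f"double support ({self.double_support:.2f} s) must lie in "
                f"(0, stride time = {self.stride_time:.2f} s)"
            )
        if self.noise_sd_m < 0:
            raise ParameterError("noise must be non-negative")

    @property
    def stride_time(self) -> float:
        return self.stride_length / self.velocity

    @classmethod
    def randomized(cls, seed: int, noise_sd_m: float = 0.0,
                   condition: str = "WALK_ST") -> "WalkSimParams":
        rng = np.random.default_rng(seed)
        v = float(rng.uniform(1.0, 1.4))
        sl = float(rng.uniform(1.1, 1.4))
        ts = sl / v
        return cls(
            velocity=v,
            stride_length=sl,
            double_support=float(rng.uniform(0.28, min(0.45, 0.45 * ts))),
            toe_clearance=float(rng.uniform(0.025, 0.045)),
            hip_rom_left=float(rng.uniform(42.0, 55.0)),
            hip_rom_right=float(rng.uniform(42.0, 55.0)),
            shoulder_rom_left=float(rng.uniform(15.0, 30.0)),
            shoulder_rom_right=float(rng.uniform(15.0, 30.0)),
            impaired_side=["left", "right", "bilateral", "none"][int(rng.integers(4))],
            noise_sd_m=noise_sd_m,
            condition=condition,
            seed=seed,
        )


@dataclass
class WalkTruth:
    """Closed-form ground truth emitted alongside a simulated walking trial."""

    events: GaitEvents
    velocity: float
    stride_length: float
    double_support: float
    toe_clearance: float
    hip_rom_left: float
    hip_rom_right: float
    shoulder_rom_left: float
    shoulder_rom_right: float
    shoulder_symmetry: float
    stance_time: float


def _swing_profile_coeffs(tc: float, peak: float) -> tuple[float, float]:
    """Quartic swing toe-height q(s) = s(1-s)(a - b s(1-s)) with q(1/2)=tc.

    The curve is zero at both swing boundaries, peaks at ~17 % and ~83 % of
    swing at height ``peak``, and has its interior minimum tc at mid-swing.
    """
    disc = (4 * peak - 2 * tc) ** 2 - 4 * tc * tc
    if disc <= 0:
        raise ParameterError("swing peak must exceed the programmed toe clearance")
    b = ((4 * peak - 2 * tc) + np.sqrt(disc)) / 0.125
    a = 4 * tc + 0.25 * b
    if not a < b / 2:
        raise ParameterError("degenerate swing profile; increase swing_peak_extra_m")
    return a, b


def simulate_walking_trial(params: WalkSimParams) -> tuple[TrialRecording, WalkTruth]:
    """Cyclic walking trial with closed-form events and metric panel.

    com_x advances uniformly at the programmed velocity; heel/toe anterior
    positions oscillate sinusoidally about the COM at the stride frequency
    (anti-phase sides), with the toe phase offset chosen so foot-off lags
    the contralateral strike by exactly half the programmed double-support
    time; toe height follows a quartic swing valley whose interior minimum
    is the programmed clearance; hip and shoulder flexion are sinusoids
    with the programmed ranges of motion.
    """
    v, sl = params.velocity, params.stride_length
    T_s = params.stride_time
    f = 1.0 / T_s
    delta = params.double_support / 2.0
    stance = T_s / 2.0 + delta
    stance_frac = stance / T_s

    total = params.trial_length_m / v
    n = int(round(total * params.rate_hz)) + 1
    t = np.arange(n) / params.rate_hz

    first_strike_L = 0.8
    phi_L = np.pi / 2 - 2 * np.pi * f * first_strike_L
    phi = {"left": phi_L, "right": phi_L - np.pi}
    psi = -2 * np.pi * f * delta  # toe phase lag realizing the programmed DS

    com_x = v * t
    com_y = 0.02 * np.sin(2 * np.pi * f * t + phi_L)
    com_z = 0.95 + 0.012 * np.sin(4 * np.pi * f * t)
    com = np.column_stack([com_x, com_y, com_z])

    amp = sl / 4.0
    a_sw, b_sw = _swing_profile_coeffs(
        params.toe_clearance, params.toe_clearance + params.swing_peak_extra_m
    )

    def strikes_for(side: str) -> np.ndarray:
        t_first = (np.pi / 2 - phi[side]) / (2 * np.pi * f) % T_s
        k = np.arange(int(np.ceil((total - t_first) / T_s)) + 1)
        s = t_first + k * T_s
        return s[(s >= 0) & (s <= total)]

    markers: dict[str, np.ndarray] = {}
    truth_strikes: dict[str, np.ndarray] = {}
    truth_offs: dict[str, np.ndarray] = {}
    for side, suffix, y_off in (("left", "L", 0.10), ("right", "R", -0.10)):
        ph = 2 * np.pi * f * t + phi[side]
        heel_x = com_x + amp * np.sin(ph)
        toe_x = com_x + amp * np.sin(ph + psi)
        s_all = strikes_for(side)
        truth_strikes[side] = s_all
        offs = s_all + stance
        truth_offs[side] = offs[offs <= total]
        # gait-cycle phase with strike at 0; swing occupies [stance_frac, 1)
        p = ((t - s_all[0]) * f) % 1.0
        swing = p >= stance_frac
        s_norm = (p - stance_frac) / (1.0 - stance_frac)
        u = s_norm * (1 - s_norm)
        toe_z = np.where(swing, u * (a_sw - b_sw * u), 0.0)
        heel_z = np.where(swing, 0.05 * np.sin(np.pi * np.clip(s_norm, 0, 1)) ** 2, 0.0)
        markers[f"heel_{suffix}"] = np.column_stack([heel_x, np.full(n, y_off), heel_z])
        markers[f"toe_{suffix}"] = np.column_stack(
            [toe_x, np.full(n, y_off * 1.2), toe_z]
        )

    rots: dict[str, np.ndarray] = {}
    for joint, rom_L, rom_R, offset, arm_phase in (
        ("hip", params.hip_rom_left, params.hip_rom_right, 20.0, 0.0),
        ("shoulder", params.shoulder_rom_left, params.shoulder_rom_right, -5.0, np.pi),
    ):
        for side, suffix, rom in (("left", "L", rom_L), ("right", "R", rom_R)):
            flex = offset + rom / 2.0 * np.sin(2 * np.pi * f * t + phi[side] + arm_phase)
            rots[f"{joint}_rot_{suffix}"] = compose_cardan_xyz(
                flex, np.full(n, 3.0), np.full(n, -2.0)
            )

    if params.noise_sd_m > 0:
        rng = np.random.default_rng(params.seed)
        com = com + rng.normal(0.0, params.noise_sd_m, size=com.shape)
        for key in markers:
            markers[key] = markers[key] + rng.normal(0.0, params.noise_sd_m,
                                                     size=markers[key].shape)

    trial = TrialRecording(
        trial_id=f"walk-sim-{params.seed}",
        condition=params.condition,
        rate_hz=params.rate_hz,
        t=t,
        com=com,
        impaired_side=params.impaired_side,
        **markers,
        **rots,
    )
    events = GaitEvents(
        strikes_L=truth_strikes["left"],
        offs_L=truth_offs["left"],
        strikes_R=truth_strikes["right"],
        offs_R=truth_offs["right"],
    )
    _, sym = symmetry_angle(params.shoulder_rom_left, params.shoulder_rom_right)
    truth = WalkTruth(
        events=events,
        velocity=v,
        stride_length=sl,
        double_support=params.double_support,
        toe_clearance=params.toe_clearance,
        hip_rom_left=params.hip_rom_left,
        hip_rom_right=params.hip_rom_right,
        shoulder_rom_left=params.shoulder_rom_left,
        shoulder_rom_right=params.shoulder_rom_right,
        shoulder_symmetry=sym,
        stance_time=stance,
    )
    return trial, truth


# --------------------------------------------------------------------------
# Cohort
# --------------------------------------------------------------------------

#: marginal (mean, SD) per registry column for the study-sized cohort
COHORT_MARGINALS: dict[str, tuple[float, float]] = {
    "response_inhibition": (13.0, 13.9),
    "working_memory": (4.7, 1.2),
    "mental_rotation": (54.1, 31.3),
    "tug_sit_to_stand": (1.13, 0.30),
    "tug_gait_initiation": (0.59, 0.19),
    "tug_walk1": (1.73, 0.27),
    "tug_turn": (2.98, 0.68),
    "tug_walk2": (1.89, 0.38),
    "tug_slow_down_turn": (1.32, 0.44),
    "tug_sit_down": (1.33, 0.56),
    "st_velocity": (1.32, 0.21),
    "st_stride_length": (1.36, 0.19),
    "st_double_support": (0.34, 0.03),
    "st_toe_clearance": (0.034, 0.011),
    "st_hip_rom": (50.38, 6.11),
    "st_shoulder_asymmetry": (9.03, 8.30),
    "dt_velocity": (1.12, 0.28),
    "dt_stride_length": (1.22, 0.22),
    "dt_double_support": (0.40, 0.05),
    "dt_toe_clearance": (0.030, 0.012),
    "dt_hip_rom": (46.42, 8.37),
    "dt_shoulder_asymmetry": (12.85, 13.25),
}

#: columns whose marginals are positively skewed (non-normal) in the cohort
SKEWED_COLUMNS = frozenset(
    {
        "response_inhibition",
        "tug_sit_down",
        "st_shoulder_asymmetry",
        "dt_double_support",
        "dt_shoulder_asymmetry",
    }
)

# printed cognitive-by-gait correlations used as the default targets:
# predictors x TUG phases and predictors x dual-task metrics
_TUG_CORR = {
    "response_inhibition": (-0.4704, 0.0705, -0.4861, -0.4366, -0.5114, -0.2148, -0.4102),
    "working_memory": (-0.613, 0.1025, -0.5186, -0.5592, -0.682, -0.4619, -0.4191),
    "mental_rotation": (-0.5401, -0.1389, -0.6458, -0.6377, -0.6755, -0.4989, -0.2917),
}
_DT_CORR = {
    "response_inhibition": (0.4179, 0.3555, -0.1477, 0.3413, 0.5632, 0.1337),
    "working_memory": (0.6524, 0.6758, -0.3145, 0.5234, 0.6803, 0.2411),
    "mental_rotation": (0.3583, 0.5178, -0.1418, 0.3514, 0.4886, 0.5894),
}


def default_correlation_matrix() -> pd.DataFrame:
    """Cognitive-by-TUG and cognitive-by-DT default correlation targets.

    All other off-diagonal entries are zero; the resulting matrix is not in
    general positive semi-definite and is repaired at generation time.
    """
    cols = list(REGISTRY_COLUMNS)
    C = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for pred, vals in _TUG_CORR.items():
        for col, r in zip(TUG_COLUMNS, vals):
            C.loc[pred, col] = C.loc[col, pred] = r
    for pred, vals in _DT_CORR.items():
        for col, r in zip(DT_COLUMNS, vals):
            C.loc[pred, col] = C.loc[col, pred] = r
    return C


@dataclass
class CohortSimParams:
    """Gaussian-copula cohort generator parameters."""

    n: int = 19
    marginals: dict = field(default_factory=lambda: dict(COHORT_MARGINALS))
    correlation: Optional[pd.DataFrame] = None  # None: default targets
    skewed: frozenset = SKEWED_COLUMNS
    min_skewness: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError("cohort needs n >= 2")
        for col, (mean, sd) in self.marginals.items():
            if sd <= 0:
                raise ParameterError(f"{col}: SD must be positive")


@dataclass
class CohortTruth:
    """Exact generating parameters of a simulated cohort."""

    correlation: pd.DataFrame  # actual (repaired) latent correlation
    requested_correlation: pd.DataFrame
    marginals: dict
    skewed: frozenset
    skewness: dict
    n: int
    seed: int
    repaired: bool


def _skewed_marginal_params(mean: float, sd: float, min_skew: float) -> tuple[float, float, float]:
    """Shifted-lognormal parameters (shift, scale, sigma) matching mean/SD.

    Target skewness is the 2-parameter lognormal's implied skewness, floored
    at ``min_skew`` so mildly-dispersed variables still fail normality
    checks at study sample sizes.
    """
    cv = sd / mean if mean > 0 else 1.0
    w_natural = 1.0 + cv * cv
    skew_natural = (w_natural + 2.0) * np.sqrt(w_natural - 1.0)
    gamma = max(skew_natural, min_skew)
    # solve (w + 2)^2 (w - 1) = gamma^2  <=>  w^3 + 3 w^2 - (4 + gamma^2) = 0
    roots = np.roots([1.0, 3.0, 0.0, -(4.0 + gamma * gamma)])
    w = float(max(r.real for r in roots if abs(r.imag) < 1e-9 and r.real > 1.0))
    sigma = float(np.sqrt(np.log(w)))
    scale = sd / np.sqrt(w - 1.0)  # mean of the lognormal part
    shift = mean - scale
    return shift, scale, sigma


from functools import lru_cache


@lru_cache(maxsize=8)
def _repaired_correlation(c_bytes: bytes, dim: int) -> np.ndarray:
    """Nearest-correlation repair with an exact PSD projection.

    The result (not the request) is the correlation actually generated, so
    it is what gets recorded as truth.  Cached: the repair is iterative and
    replicate draws reuse the same target matrix.
    """
    import warnings

    C = np.frombuffer(c_bytes, dtype=float).reshape(dim, dim)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # iteration-limit chatter; residue clipped below
        C_fixed = np.asarray(corr_nearest(C, threshold=1e-7, n_fact=200))
    w, V = np.linalg.eigh(C_fixed)
    S = (V * np.clip(w, 1e-12, None)) @ V.T
    d = np.sqrt(np.diag(S))
    C_psd = S / np.outer(d, d)
    logger.warning(
        "target correlation matrix not PSD (min eigenvalue %.3g); "
        "nearest-correlation repair shifted entries by up to %.3f",
        float(np.linalg.eigvalsh(C).min()), float(np.abs(C_psd - C).max()),
    )
    return C_psd


def simulate_cohort(params: CohortSimParams) -> tuple[pd.DataFrame, CohortTruth]:
    """Draw a cohort table via a Gaussian copula with known truth.

    A multivariate normal with the target latent correlations is drawn and
    each column is pushed through its marginal transform (affine for normal
    columns, shifted lognormal for skewed ones), preserving the programmed
    means and SDs.  Non-PSD target matrices are repaired to the nearest
    correlation matrix and the repair is logged; the repaired matrix is the
    returned generating truth.
    """
    cols = list(params.marginals.keys())
    if params.correlation is None:
        requested = default_correlation_matrix().loc[cols, cols]
    else:
        requested = params.correlation.loc[cols, cols].astype(float)
    C = requested.to_numpy()
    if not np.allclose(C, C.T, atol=1e-12):
        raise ParameterError("correlation matrix must be symmetric")
    if np.any(np.abs(np.diag(C) - 1.0) > 1e-12):
        raise ParameterError("correlation matrix must have unit diagonal")

    min_eig = float(np.linalg.eigvalsh(C).min())
    repaired = False
    if min_eig < -1e-10:
        C = _repaired_correlation(C.tobytes(), C.shape[0])
        repaired = True
    eigval, eigvec = np.linalg.eigh(C)
    root = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))

    rng = np.random.default_rng(params.seed)
    latent = rng.standard_normal((params.n, len(cols))) @ root.T

    data = {}
    skewness: dict[str, float] = {}
    for j, col in enumerate(cols):
        mean, sd = params.marginals[col]
        u = latent[:, j]
        if col in params.skewed:
            shift, scale, sigma = _skewed_marginal_params(mean, sd, params.min_skewness)
            data[col] = shift + scale * np.exp(sigma * u - sigma * sigma / 2.0)
            w = float(np.exp(sigma * sigma))
            skewness[col] = float((w + 2.0) * np.sqrt(w - 1.0))
        else:
            data[col] = mean + sd * u
            skewness[col] = 0.0
    index = pd.Index([f"P{i + 1:03d}" for i in range(params.n)], name="participant_id")
    cohort = pd.DataFrame(data, index=index)
    truth = CohortTruth(
        correlation=pd.DataFrame(C, index=cols, columns=cols),
        requested_correlation=requested,
        marginals=dict(params.marginals),
        skewed=params.skewed,
        skewness=skewness,
        n=params.n,
        seed=params.seed,
        repaired=repaired,
    )
    return cohort, truth
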