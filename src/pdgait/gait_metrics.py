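"""Gait-event detection and the walking metric panel.

Foot strikes are local maxima of the anterior heel-minus-COM distance and
foot offs are local minima of the toe-minus-COM distance, the standard
coordinate-based event family for optical gait data.  From those events the
module derives walking velocity over a central capture zone, stride length,
double-support time, minimum toe clearance during swing, hip and shoulder
flexion-extension range of motion from XYZ Cardan angles, and the bilateral
shoulder symmetry angle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .io_model import AnalysisConfig, DetectionError, TrialRecording, ValidationError
from .preprocess import FilterSpec, lowpass_series

logger = logging.getLogger(__name__)

__all__ = [
    "GaitEvents",
    "GaitMetrics",
    "detect_gait_events",
    "capture_zone_velocity",
    "stride_length",
    "double_support_time",
    "min_toe_clearance",
    "cardan_xyz_angles",
    "compose_cardan_xyz",
    "joint_rom",
    "symmetry_angle",
    "impaired_side_value",
    "summarize_walking_trial",
    "average_walking_metrics",
]


@dataclass
class GaitEvents:
    """Per-side foot-strike and foot-off times (s), alternation-validated."""

    strikes_L: np.ndarray
    offs_L: np.ndarray
    strikes_R: np.ndarray
    offs_R: np.ndarray

    def strikes(self, side: str) -> np.ndarray:
        return self.strikes_L if side == "left" else self.strikes_R

    def offs(self, side: str) -> np.ndarray:
        return self.offs_L if side == "left" else self.offs_R

    def cycles(self, side: str) -> list[tuple[float, float]]:
        s = self.strikes(side)
        return list(zip(s[:-1], s[1:]))

    def validate(self) -> None:
        for side in ("left", "right"):
            s, o = self.strikes(side), self.offs(side)
            for off in o:
                k = np.searchsorted(s, off)
                if k == 0 or k == len(s):
                    continue  # offs outside the strike span were trimmed upstream
                if not (s[k - 1] < off < s[k]):
                    raise ValidationError(f"{side} foot-off at {off:.3f} s breaks alternation")
            inter = np.searchsorted(s, o)
            if len(np.unique(inter)) != len(inter):
                raise ValidationError(f"two {side} foot-offs within one stride")


@dataclass
class GaitMetrics:
    """Trial-level walking metric panel (missing channels leave None)."""

    velocity: Optional[float] = None
    stride_length: Optional[float] = None
    double_support: Optional[float] = None
    toe_clearance_left: Optional[float] = None
    toe_clearance_right: Optional[float] = None
    toe_clearance: Optional[float] = None  # impaired-side value
    hip_rom_left: Optional[float] = None
    hip_rom_right: Optional[float] = None
    hip_rom: Optional[float] = None  # impaired-side value
    shoulder_rom_left: Optional[float] = None
    shoulder_rom_right: Optional[float] = None
    shoulder_symmetry: Optional[float] = None  # magnitude, %
    shoulder_symmetry_signed: Optional[float] = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _refine_extremum(t: np.ndarray, y: np.ndarray, idx: int) -> float:
    """Three-point parabolic sub-frame refinement of an extremum time."""
    if idx == 0 or idx == len(y) - 1:
        return float(t[idx])
    denom = y[idx - 1] - 2 * y[idx] + y[idx + 1]
    if denom == 0:
        return float(t[idx])
    delta = 0.5 * (y[idx - 1] - y[idx + 1]) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    return float(t[idx] + delta * (t[1] - t[0]))


def _filtered(trial: TrialRecording, series: np.ndarray, config: AnalysisConfig) -> np.ndarray:
    spec = FilterSpec(config.filter_cutoff_hz, trial.rate_hz, method=config.filter_method,
                      max_nan_gap_s=config.max_nan_gap_s)
    return lowpass_series(series, spec)


def detect_gait_events(
    trial: TrialRecording, config: Optional[AnalysisConfig] = None
) -> GaitEvents:
    """Coordinate-based foot-strike / foot-off detection.

    Per side: strikes are maxima of (heel_x - com_x) and offs are minima of
    (toe_x - com_x), with a minimum peak separation and prominence guard to
    suppress noise peaks; alternation (one off strictly between consecutive
    same-side strikes) is enforced.
    """
    config = config or AnalysisConfig()
    for name in ("heel_L", "heel_R", "toe_L", "toe_R"):
        if trial.marker(name) is None:
            raise ValidationError(f"gait-event detection needs marker {name}")
    t = trial.t
    com_x = _filtered(trial, trial.com[:, 0], config)
    distance = max(1, int(round(config.min_peak_separation_s * trial.rate_hz)))

    def extrema(series: np.ndarray, kind: str) -> np.ndarray:
        rel = _filtered(trial, series, config) - com_x
        y = rel if kind == "max" else -rel
        idx, _ = find_peaks(y, distance=distance, prominence=config.peak_prominence_m)
        return np.array([_refine_extremum(t, y, i) for i in idx])

    out = {}
    for side, heel, toe in (("L", trial.heel_L, trial.toe_L), ("R", trial.heel_R, trial.toe_R)):
        strikes = extrema(heel[:, 0], "max")
        if len(strikes) < 2:
            raise DetectionError(
                f"insufficient strides on side {side}: {len(strikes)} foot strike(s) detected"
            )
        offs = extrema(toe[:, 0], "min")
        # alternation cleaning: keep exactly one off per stride interval
        kept = []
        for s0, s1 in zip(strikes[:-1], strikes[1:]):
            inside = offs[(offs > s0) & (offs < s1)]
            if len(inside) == 0:
                raise DetectionError(
                    f"alternation violation on side {side}: no foot-off between "
                    f"strikes at {s0:.3f} and {s1:.3f} s"
                )
            kept.append(inside[0] if len(inside) == 1 else float(np.median(inside)))
        out[side] = (strikes, np.array(kept))

    events = GaitEvents(
        strikes_L=out["L"][0], offs_L=out["L"][1],
        strikes_R=out["R"][0], offs_R=out["R"][1],
    )
    events.validate()
    return events


def capture_zone_velocity(
    trial: TrialRecording, config: Optional[AnalysisConfig] = None
) -> float:
    """Walking velocity over the central capture zone.

    velocity = zone length / (t_exit - t_enter) with sub-frame interpolated
    crossing times; the zone is centered on the midpoint of the COM x range
    unless ``config.zone_center_x`` overrides it.
    """
    config = config or AnalysisConfig()
    t = trial.t
    x = _filtered(trial, trial.com[:, 0], config)
    center = config.zone_center_x
    if center is None:
        center = 0.5 * (float(x.min()) + float(x.max()))
    half = config.capture_zone_m / 2.0
    lo, hi = center - half, center + half

    def crossing(threshold: float) -> Optional[float]:
        above = x > threshold
        hits = np.flatnonzero(above)
        if len(hits) == 0 or hits[0] == 0:
            return None if len(hits) == 0 else float(t[hits[0]])
        i = hits[0]
        frac = (threshold - x[i - 1]) / (x[i] - x[i - 1])
        return float(t[i - 1] + frac * (t[i] - t[i - 1]))

    t_enter = crossing(lo)
    t_exit = crossing(hi)
    if t_enter is None or t_exit is None or x.max() < hi:
        raise DetectionError(
            f"capture zone [{lo:.2f}, {hi:.2f}] m not fully traversed "
            f"(COM x spans [{x.min():.2f}, {x.max():.2f}] m)"
        )
    inside = (t >= t_enter) & (t <= t_exit)
    if np.any(np.diff(x[inside]) < -1e-3):
        raise DetectionError("direction reversal inside the capture zone")
    if config.velocity_mode == "com_displacement":
        return float((x[inside][-1] - x[inside][0]) / (t_exit - t_enter))
    return float(config.capture_zone_m / (t_exit - t_enter))


def stride_length(
    events: GaitEvents, trial: TrialRecording, config: Optional[AnalysisConfig] = None
) -> float:
    """Mean anterior heel displacement between consecutive same-side strikes."""
    config = config or AnalysisConfig()
    strides = []
    for side, heel in (("left", trial.heel_L), ("right", trial.heel_R)):
        if heel is None:
            continue
        hx = _filtered(trial, heel[:, 0], config)
        s = events.strikes(side)
        if len(s) < 2:
            continue
        pos = np.interp(s, trial.t, hx)
        strides.extend(np.abs(np.diff(pos)))
    if not strides:
        raise DetectionError("no complete stride on either side")
    return float(np.mean(strides))


def double_support_time(events: GaitEvents) -> float:
    """Mean total double-support time per stride.

    Each stride (ipsilateral strike to the next ipsilateral strike)
    contributes two double-limb intervals: ipsilateral strike to the
    contralateral foot-off, and contralateral strike to the ipsilateral
    foot-off.  Strides missing a contralateral event are skipped; an error
    is raised only if no stride can be matched.
    """
    totals = []
    for side, other in (("left", "right"), ("right", "left")):
        s_i = events.strikes(side)
        s_c = events.strikes(other)
        o_i = events.offs(side)
        o_c = events.offs(other)
        for s0, s1 in zip(s_i[:-1], s_i[1:]):
            # inclusive lower bounds: a foot-off coincident with the
            # opposite strike is a zero-length double-support interval
            c_off = o_c[(o_c >= s0) & (o_c < s1)]
            c_strike = s_c[(s_c > s0) & (s_c < s1)]
            if len(c_off) == 0 or len(c_strike) == 0:
                continue
            i_off = o_i[(o_i >= c_strike[0]) & (o_i < s1)]
            if len(i_off) == 0:
                continue
            totals.append((c_off[0] - s0) + (i_off[0] - c_strike[0]))
    if not totals:
        raise DetectionError("no stride with matched contralateral events")
    return float(np.mean(totals))


def _floor_reference(
    toe_z: np.ndarray, t: np.ndarray, events: GaitEvents, side: str, config: AnalysisConfig
) -> float:
    if config.floor_mode == "constant":
        return config.floor_constant_m
    if config.floor_mode == "min":
        return float(toe_z.min())
    # stance_median: median toe height over the central 60 % of each stance
    # (strike -> next same-side off); unbiased for a flat stance plateau.
    samples = []
    strikes, offs = events.strikes(side), events.offs(side)
    for s in strikes:
        nxt = offs[offs > s]
        if len(nxt) == 0:
            continue
        dur = nxt[0] - s
        mask = (t >= s + 0.2 * dur) & (t <= nxt[0] - 0.2 * dur)
        samples.append(toe_z[mask])
    if not samples or sum(len(s) for s in samples) == 0:
        return float(toe_z.min())
    return float(np.median(np.concatenate(samples)))


def min_toe_clearance(
    trial: TrialRecording, events: GaitEvents, config: Optional[AnalysisConfig] = None
) -> dict[str, float]:
    """Mean minimum toe clearance (m) during swing, per side.

    Per swing (foot off to the next same-side foot strike) the minimum of
    toe height above the floor reference is taken within the middle
    (1 - 2 * trim) of the swing; the per-side values are swing means.
    """
    config = config or AnalysisConfig()
    result = {}
    trim = config.swing_trim_fraction
    for side, toe in (("left", trial.toe_L), ("right", trial.toe_R)):
        if toe is None:
            continue
        tz = _filtered(trial, toe[:, 2], config)
        floor = _floor_reference(tz, trial.t, events, side, config)
        minima = []
        offs, strikes = events.offs(side), events.strikes(side)
        for off in offs:
            nxt = strikes[strikes > off]
            if len(nxt) == 0:
                continue
            dur = nxt[0] - off
            mask = (trial.t >= off + trim * dur) & (trial.t <= nxt[0] - trim * dur)
            if not mask.any():
                continue
            seg = tz[mask]
            k = int(np.argmin(seg))
            if k == 0 or k == len(seg) - 1:
                logger.warning(
                    "%s swing at %.3f s: toe height monotone within the trimmed "
                    "window; taking the window-edge minimum", side, off
                )
            minima.append(seg[k] - floor)
        if not minima:
            raise DetectionError(f"no complete swing on side {side}")
        result[side] = float(np.mean(minima))
    if not result:
        raise DetectionError("toe markers absent; cannot compute toe clearance")
    return result


# --------------------------------------------------------------------------
# Cardan angles and ROM
# --------------------------------------------------------------------------


def compose_cardan_xyz(alpha_deg, beta_deg, gamma_deg) -> np.ndarray:
    """Compose rotation matrices R = Rx(alpha) @ Ry(beta) @ Rz(gamma)."""
    a, b, g = (np.deg2rad(np.asarray(v, dtype=float)) for v in (alpha_deg, beta_deg, gamma_deg))
    ca, sa, cb, sb, cg, sg = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(g), np.sin(g)
    R = np.empty(np.broadcast(a, b, g).shape + (3, 3))
    R[..., 0, 0] = cb * cg
    R[..., 0, 1] = -cb * sg
    R[..., 0, 2] = sb
    R[..., 1, 0] = ca * sg + sa * sb * cg
    R[..., 1, 1] = ca * cg - sa * sb * sg
    R[..., 1, 2] = -sa * cb
    R[..., 2, 0] = sa * sg - ca * sb * cg
    R[..., 2, 1] = sa * cg + ca * sb * sg
    R[..., 2, 2] = ca * cb
    return R


def cardan_xyz_angles(rot: np.ndarray, unwrap: bool = True) -> np.ndarray:
    """Decompose rotation matrices as Rx(a) @ Ry(b) @ Rz(g), degrees.

    The first angle is flexion-extension by the joint coordinate system
    convention.  Angles are continuity-unwrapped across frames; gimbal
    proximity (|beta| > 89 deg) is logged.
    """
    R = np.asarray(rot, dtype=float)
    single = R.ndim == 2
    if single:
        R = R[None]
    if R.shape[-2:] != (3, 3):
        raise ValidationError("expected 3x3 rotation matrices")
    gram_dev = np.abs(np.einsum("...ij,...kj->...ik", R, R) - np.eye(3)).max()
    if gram_dev > 1e-6 or np.any(np.linalg.det(R) < 0):
        raise ValidationError(
            f"non-orthonormal rotation input (deviation {gram_dev:.2e})"
        )
    beta = np.arcsin(np.clip(R[..., 0, 2], -1.0, 1.0))
    alpha = np.arctan2(-R[..., 1, 2], R[..., 2, 2])
    gamma = np.arctan2(-R[..., 0, 1], R[..., 0, 0])
    angles = np.rad2deg(np.stack([alpha, beta, gamma], axis=-1))
    n_gimbal = int(np.sum(np.abs(angles[..., 1]) > 89.0))
    if n_gimbal:
        logger.warning("%d frame(s) within 1 deg of gimbal lock (|beta| > 89 deg)", n_gimbal)
    if unwrap and len(angles) > 1:
        angles = np.unwrap(angles, period=360.0, axis=0)
    return angles[0] if single else angles


def joint_rom(
    flexion_deg: np.ndarray, t: np.ndarray, events: GaitEvents, side: str
) -> float:
    """Mean flexion-extension range of motion per gait cycle (deg).

    A cycle spans consecutive same-side foot strikes; ROM is max - min of
    the flexion angle within the cycle, averaged across cycles.
    """
    flexion_deg = np.asarray(flexion_deg, dtype=float)
    cycles = events.cycles(side)
    roms = []
    for s0, s1 in cycles:
        mask = (t >= s0) & (t <= s1)
        if mask.sum() < 2:
            continue
        roms.append(float(np.ptp(flexion_deg[mask])))
    if not roms:
        raise DetectionError(f"no complete gait cycle on side {side}")
    rom = float(np.mean(roms))
    if rom < 1e-6:
        logger.warning("degenerate ROM (constant angle) on side %s", side)
    return rom


def symmetry_angle(x_left: float, x_right: float) -> tuple[float, float]:
    """Bilateral symmetry angle as (signed %, magnitude %).

    theta = arctan(left/right); SA = (45 deg - theta) / 90 deg * 100, with
    the 180-degree wrap applied when |45 - theta| exceeds 90.  0 % means
    perfect symmetry; the magnitude is what gets tabulated.
    """
    if x_left == 0 and x_right == 0:
        raise ValidationError("symmetry angle undefined for (0, 0)")
    theta = np.degrees(np.arctan2(x_left, x_right))
    dev = 45.0 - theta
    if dev > 90.0:
        dev -= 180.0
    elif dev < -90.0:
        dev += 180.0
    signed = dev / 90.0 * 100.0
    return float(signed), float(abs(signed))


def impaired_side_value(
    left: Optional[float], right: Optional[float], impaired_side: str
) -> float:
    """Select the analysis value by clinical impairment side.

    Unilateral impairment uses that side; bilateral or no impairment uses
    the across-side mean.
    """
    if impaired_side == "left":
        if left is None:
            raise ValidationError("impaired_side=left but left value missing")
        return float(left)
    if impaired_side == "right":
        if right is None:
            raise ValidationError("impaired_side=right but right value missing")
        return float(right)
    if impaired_side in ("bilateral", "none"):
        if left is None or right is None:
            raise ValidationError(f"impaired_side={impaired_side} needs both side values")
        return float((left + right) / 2.0)
    raise ValidationError(f"unknown impaired_side {impaired_side!r}")


# --------------------------------------------------------------------------
# Trial-level panel
# --------------------------------------------------------------------------


def summarize_walking_trial(
    trial: TrialRecording, config: Optional[AnalysisConfig] = None
) -> GaitMetrics:
    """Compose the full walking metric panel for one overground trial.

    Channels that are absent leave their metrics as None (logged); errors in
    individual components are annotated with the metric name and re-raised
    only for the core spatiotemporal set.
    """
    config = config or AnalysisConfig()
    metrics = GaitMetrics()
    events = detect_gait_events(trial, config)

    try:
        metrics.velocity = capture_zone_velocity(trial, config)
    except DetectionError as exc:
        raise DetectionError(f"velocity: {exc}") from exc
    metrics.stride_length = stride_length(events, trial, config)
    metrics.double_support = double_support_time(events)

    tc = min_toe_clearance(trial, events, config)
    metrics.toe_clearance_left = tc.get("left")
    metrics.toe_clearance_right = tc.get("right")
    metrics.toe_clearance = impaired_side_value(
        metrics.toe_clearance_left, metrics.toe_clearance_right, trial.impaired_side
    )

    def rom_of(rot: Optional[np.ndarray], side: str, joint: str) -> Optional[float]:
        if rot is None:
            logger.info("%s %s rotations absent; ROM left missing", side, joint)
            return None
        flex = cardan_xyz_angles(rot)[:, 0]
        return joint_rom(flex, trial.t, events, side)

    metrics.hip_rom_left = rom_of(trial.hip_rot_L, "left", "hip")
    metrics.hip_rom_right = rom_of(trial.hip_rot_R, "right", "hip")
    if metrics.hip_rom_left is not None and metrics.hip_rom_right is not None:
        metrics.hip_rom = impaired_side_value(
            metrics.hip_rom_left, metrics.hip_rom_right, trial.impaired_side
        )
    metrics.shoulder_rom_left = rom_of(trial.shoulder_rot_L, "left", "shoulder")
    metrics.shoulder_rom_right = rom_of(trial.shoulder_rot_R, "right", "shoulder")
    if metrics.shoulder_rom_left is not None and metrics.shoulder_rom_right is not None:
        signed, mag = symmetry_angle(metrics.shoulder_rom_left, metrics.shoulder_rom_right)
        metrics.shoulder_symmetry_signed = signed
        metrics.shoulder_symmetry = mag
    return metrics


def average_walking_metrics(panels: Sequence[GaitMetrics]) -> GaitMetrics:
    """Equal-weight field-wise mean across repeated trials.

    A trial missing a metric leaves that metric as the mean of the trials
    that have it (logged).
    """
    if len(panels) == 0:
        raise ValidationError("cannot average zero trials")
    out = {}
    for f in fields(GaitMetrics):
        vals = [getattr(p, f.name) for p in panels if getattr(p, f.name) is not None]
        if len(vals) != len(panels) and vals:
            logger.warning("metric %s missing in %d of %d trials; averaging the rest",
                           f.name, len(panels) - len(vals), len(panels))
        out[f.name] = float(np.mean(vals)) if vals else None
    return GaitMetrics(**out)
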