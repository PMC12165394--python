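"""Timed Up and Go phase segmentation from COM trajectories.

Eight event markers are detected from the filtered whole-body COM x
(direction of travel) and z (vertical) coordinates:

====================  =====================================================
stand_init            z rises above the seated baseline (+ noise tolerance)
stand_end             first local maximum of z after stand_init
gait_init_end         x exceeds 1 m beyond the starting position
turn_begin            x exceeds 3 m
turn_end              x falls back below 3 m
walk2_end             x falls below 1 m
sit_begin             z falls below 95 % of standing height
sit_end               x returns to (or behind) the starting position
====================  =====================================================

The seven phase durations telescope between consecutive events, so they
partition [stand_init, sit_end] exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .io_model import AnalysisConfig, DetectionError, TrialRecording, ValidationError
from .preprocess import FilterSpec, baseline_stat, lowpass_series

logger = logging.getLogger(__name__)

__all__ = [
    "TUGEvents",
    "TUGPhaseResult",
    "EVENT_ORDER",
    "detect_tug_events",
    "compute_phase_times",
    "average_tug_trials",
    "segment_tug",
]

EVENT_ORDER = (
    "stand_init",
    "stand_end",
    "gait_init_end",
    "turn_begin",
    "turn_end",
    "walk2_end",
    "sit_begin",
    "sit_end",
)

#: phase name -> (start event, end event)
PHASE_BOUNDS = {
    "sit_to_stand": ("stand_init", "stand_end"),
    "gait_initiation": ("stand_end", "gait_init_end"),
    "walk1": ("gait_init_end", "turn_begin"),
    "turn": ("turn_begin", "turn_end"),
    "walk2": ("turn_end", "walk2_end"),
    "slow_down_turn": ("walk2_end", "sit_begin"),
    "sit_down": ("sit_begin", "sit_end"),
}


@dataclass
class TUGEvents:
    """The eight detected event times (s) plus the reference scalars."""

    stand_init: float
    stand_end: float
    gait_init_end: float
    turn_begin: float
    turn_end: float
    walk2_end: float
    sit_begin: float
    sit_end: float
    start_x: float = 0.0
    start_z: float = 0.0
    standing_z: float = 0.0

    def times(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in EVENT_ORDER])

    def validate(self) -> None:
        t = self.times()
        if np.any(np.diff(t) <= 0):
            order = ", ".join(f"{n}={v:.3f}" for n, v in zip(EVENT_ORDER, t))
            raise ValidationError(f"event times not strictly increasing: {order}")


@dataclass
class TUGPhaseResult:
    """The seven TUG phase durations (s)."""

    sit_to_stand: float
    gait_initiation: float
    walk1: float
    turn: float
    walk2: float
    slow_down_turn: float
    sit_down: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    @property
    def total(self) -> float:
        return float(self.as_array().sum())


def _first_crossing(
    t: np.ndarray, x: np.ndarray, threshold: float, direction: str, start_idx: int
) -> Optional[float]:
    """Sub-frame time of the first threshold crossing at/after start_idx."""
    seg = x[start_idx:]
    above = seg > threshold if direction == "up" else seg < threshold
    hits = np.flatnonzero(above)
    if len(hits) == 0:
        return None
    i = hits[0] + start_idx
    if i == start_idx or x[i] == x[i - 1]:
        return float(t[i])
    # linear interpolation between the bracketing frames
    frac = (threshold - x[i - 1]) / (x[i] - x[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def _refine_peak(t: np.ndarray, x: np.ndarray, idx: int, half_window: int) -> tuple[float, float]:
    """Quadratic least-squares refinement of a local-max time and height."""
    lo = max(0, idx - half_window)
    hi = min(len(x), idx + half_window + 1)
    tt = t[lo:hi] - t[idx]
    coef = np.polyfit(tt, x[lo:hi], 2)
    if coef[0] >= 0:  # not concave; keep the frame peak
        return float(t[idx]), float(x[idx])
    t_peak = -coef[1] / (2 * coef[0])
    t_peak = float(np.clip(t_peak, tt[0], tt[-1]))
    return float(t[idx] + t_peak), float(np.polyval(coef, t_peak))


def detect_tug_events(trial: TrialRecording, config: Optional[AnalysisConfig] = None) -> TUGEvents:
    """Apply the eight COM-coordinate event rules to a filtered TUG trial.

    Crossings are located with linear sub-frame interpolation on the
    filtered series and reported at sub-frame resolution in seconds.  Raises
    :class:`DetectionError` naming the first rule that cannot fire.
    """
    config = config or AnalysisConfig()
    if trial.condition != "TUG":
        raise ValidationError(f"expected a TUG trial, got condition {trial.condition!r}")
    rate = trial.rate_hz
    spec = FilterSpec(config.filter_cutoff_hz, rate, method=config.filter_method,
                      max_nan_gap_s=config.max_nan_gap_s)
    x = lowpass_series(trial.com[:, 0], spec)
    z = lowpass_series(trial.com[:, 2], spec)
    t = trial.t
    tol = config.z_noise_tol_m

    nb = int(round(config.baseline_window_s * rate))
    if nb < 1 or nb > len(t):
        raise ValidationError("baseline window does not fit the trial")
    start_x = baseline_stat(x, config.baseline_window_s, rate)
    start_z = baseline_stat(z, config.baseline_window_s, rate)
    if np.ptp(z[:nb]) > 2 * tol:
        raise DetectionError(
            "trial does not begin seated: COM z moves "
            f"{np.ptp(z[:nb]) * 1000:.1f} mm within the first "
            f"{config.baseline_window_s:g} s baseline window"
        )

    # 1. stand initiation: z exceeds the seated baseline (+ tolerance)
    t_stand_init = _first_crossing(t, z, start_z + tol, "up", 0)
    if t_stand_init is None:
        raise DetectionError(
            f"stand_init not reached: max COM z rise {(z.max() - start_z) * 1000:.1f} mm"
        )
    i_stand = int(np.searchsorted(t, t_stand_init))

    # 2. stand end: first local maximum of z after stand initiation
    peaks, _ = find_peaks(z[i_stand:], prominence=tol)
    if len(peaks) == 0:
        raise DetectionError("stand_end not found: no COM z peak after stand initiation")
    half_w = max(2, int(round(config.peak_refine_window_s * rate)))
    t_stand_end, standing_z = _refine_peak(t, z, peaks[0] + i_stand, half_w)

    i_after_stand = int(np.searchsorted(t, t_stand_init))

    # 3. gait initiation end: x > start + 1 m
    thr1 = start_x + config.gait_init_distance_m
    t_gait_init_end = _first_crossing(t, x, thr1, "up", i_after_stand)
    if t_gait_init_end is None:
        raise DetectionError(
            f"gait_init_end not reached: max excursion {x.max() - start_x:.1f} m"
        )

    # 4. turn begin: x > start + 3 m
    thr3 = start_x + config.turn_distance_m
    i_gie = int(np.searchsorted(t, t_gait_init_end))
    t_turn_begin = _first_crossing(t, x, thr3, "up", i_gie)
    if t_turn_begin is None:
        raise DetectionError(
            f"turn_begin not reached: max excursion {x.max() - start_x:.1f} m"
        )

    # 5/6. turn end and walk-2 end: falling crossings after the apex
    i_apex = int(np.argmax(x))
    t_turn_end = _first_crossing(t, x, thr3, "down", i_apex)
    if t_turn_end is None:
        raise DetectionError("turn_end not reached: COM x never returns below 3 m")
    i_te = int(np.searchsorted(t, t_turn_end))
    t_walk2_end = _first_crossing(t, x, thr1, "down", i_te)
    if t_walk2_end is None:
        raise DetectionError("walk2_end not reached: COM x never returns below 1 m")

    # 7. sit begin: z < 95 % of standing height
    i_w2 = int(np.searchsorted(t, t_walk2_end))
    t_sit_begin = _first_crossing(t, z, config.sit_z_fraction * standing_z, "down", i_w2)
    if t_sit_begin is None:
        raise DetectionError(
            f"sit_begin not reached: min COM z after walk 2 is "
            f"{z[i_w2:].min():.3f} m vs threshold "
            f"{config.sit_z_fraction * standing_z:.3f} m"
        )

    # 8. sit end: x back at/behind the starting position
    i_sb = int(np.searchsorted(t, t_sit_begin))
    t_sit_end = _first_crossing(t, x, start_x, "down", i_sb)
    if t_sit_end is None:
        # realistic sitting placement can stop slightly forward of start
        i_min = int(np.argmin(x[i_sb:])) + i_sb
        t_sit_end = float(t[i_min])
        logger.warning(
            "sit_end rule (x <= start) never fired; falling back to the "
            "x-minimum after sit_begin at t=%.3f s", t_sit_end
        )

    events = TUGEvents(
        stand_init=t_stand_init,
        stand_end=t_stand_end,
        gait_init_end=t_gait_init_end,
        turn_begin=t_turn_begin,
        turn_end=t_turn_end,
        walk2_end=t_walk2_end,
        sit_begin=t_sit_begin,
        sit_end=t_sit_end,
        start_x=start_x,
        start_z=start_z,
        standing_z=standing_z,
    )
    events.validate()
    return events


def compute_phase_times(events: TUGEvents) -> TUGPhaseResult:
    """Telescoping phase durations between consecutive event markers."""
    events.validate()
    durations = {
        phase: getattr(events, end) - getattr(events, start)
        for phase, (start, end) in PHASE_BOUNDS.items()
    }
    for phase, d in durations.items():
        if d <= 0:
            raise ValidationError(f"phase {phase!r} has non-positive duration {d:.4f} s")
    return TUGPhaseResult(**durations)


def average_tug_trials(results: Sequence[TUGPhaseResult]) -> TUGPhaseResult:
    """Arithmetic mean of phase durations across repeated TUG trials."""
    if len(results) == 0:
        raise ValidationError("cannot average zero TUG trials")
    stacked = np.vstack([r.as_array() for r in results])
    mean = stacked.mean(axis=0)
    names = [f.name for f in fields(TUGPhaseResult)]
    return TUGPhaseResult(**dict(zip(names, mean)))


def segment_tug(
    trial: TrialRecording, config: Optional[AnalysisConfig] = None
) -> tuple[TUGEvents, TUGPhaseResult]:
    """Detect events and derive phase durations in one call."""
    events = detect_tug_events(trial, config)
    return events, compute_phase_times(events)
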