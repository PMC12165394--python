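"""Data model, file formats, and configuration.

Trajectory trials are stored as wide CSV: a block of ``# key: value``
metadata lines followed by one row per frame.  Column names follow
``<series>_<axis>`` (``com_x``, ``heel_L_z``, ...); rotation-matrix series
are stored row-major as nine columns (``hip_rot_L_r00`` ... ``_r22``).
Cohorts are delimited tables keyed by ``participant_id`` whose analysis
columns come from a fixed registry (three cognitive scores, seven TUG phase
times, six single-task and six dual-task walking metrics).

All in-memory positions are metres, all times seconds; the readers convert
declared ``mm``/``ms`` units on ingest and nothing else.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "FormatError",
    "ValidationError",
    "DetectionError",
    "ParameterError",
    "AnalysisConfig",
    "TrialRecording",
    "CognitiveScores",
    "COGNITIVE_COLUMNS",
    "TUG_PHASE_NAMES",
    "TUG_COLUMNS",
    "WALK_METRIC_NAMES",
    "ST_COLUMNS",
    "DT_COLUMNS",
    "REGISTRY_COLUMNS",
    "read_trial",
    "write_trial",
    "read_cohort",
    "write_cohort",
    "write_report",
]


class SchemaError(ValueError):
    """A required column or metadata key is missing."""


class FormatError(ValueError):
    """The file parses but violates the format contract (units, time axis)."""


class ValidationError(ValueError):
    """Numerically invalid content (e.g. a reflection where a rotation is required)."""


class DetectionError(RuntimeError):
    """An event-detection rule could not be satisfied on the given trial."""


class ParameterError(ValueError):
    """Simulator or configuration parameters are infeasible."""


# --------------------------------------------------------------------------
# Cohort column registry
# --------------------------------------------------------------------------

COGNITIVE_COLUMNS = ("response_inhibition", "working_memory", "mental_rotation")

TUG_PHASE_NAMES = (
    "sit_to_stand",
    "gait_initiation",
    "walk1",
    "turn",
    "walk2",
    "slow_down_turn",
    "sit_down",
)
TUG_COLUMNS = tuple(f"tug_{p}" for p in TUG_PHASE_NAMES)

WALK_METRIC_NAMES = (
    "velocity",
    "stride_length",
    "double_support",
    "toe_clearance",
    "hip_rom",
    "shoulder_asymmetry",
)
ST_COLUMNS = tuple(f"st_{m}" for m in WALK_METRIC_NAMES)
DT_COLUMNS = tuple(f"dt_{m}" for m in WALK_METRIC_NAMES)

#: every analysis column of a cohort table, in canonical order
REGISTRY_COLUMNS = COGNITIVE_COLUMNS + TUG_COLUMNS + ST_COLUMNS + DT_COLUMNS

CONDITIONS = ("TUG", "WALK_ST", "WALK_DT")
IMPAIRED_SIDES = ("left", "right", "bilateral", "none")

_MARKER_SERIES = ("heel_L", "heel_R", "toe_L", "toe_R")
_ROT_SERIES = ("hip_rot_L", "hip_rot_R", "shoulder_rot_L", "shoulder_rot_R")
_AXES = ("x", "y", "z")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Tunable constants of the whole pipeline.

    Defaults encode the protocol constants: a 12 Hz low-pass cutoff, the
    3.3 m walking capture zone, the 1 m / 3 m TUG excursion thresholds, the
    95 % standing-height sit threshold, and alpha = 0.05.
    """

    filter_cutoff_hz: float = 12.0
    filter_method: str = "butterworth"  # or "spline" (GCV smoothing spline)
    capture_zone_m: float = 3.3
    zone_center_x: Optional[float] = None  # None: midpoint of the COM x range
    gait_init_distance_m: float = 1.0
    turn_distance_m: float = 3.0
    sit_z_fraction: float = 0.95
    baseline_window_s: float = 0.5
    z_noise_tol_m: float = 0.005
    min_peak_separation_s: float = 0.6
    peak_prominence_m: float = 0.01
    peak_refine_window_s: float = 0.125
    max_nan_gap_s: float = 0.1
    swing_trim_fraction: float = 0.1
    floor_mode: str = "stance_median"  # or "min", "constant"
    floor_constant_m: float = 0.0
    velocity_mode: str = "zone"  # or "com_displacement"
    alpha: float = 0.05
    multiple_testing: Optional[str] = None  # None or "benjamini-hochberg"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "filter_cutoff_hz",
            "capture_zone_m",
            "gait_init_distance_m",
            "turn_distance_m",
            "baseline_window_s",
            "z_noise_tol_m",
            "min_peak_separation_s",
            "peak_prominence_m",
            "peak_refine_window_s",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0.0 < self.sit_z_fraction < 1.0:
            raise ParameterError("sit_z_fraction must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")
        if not 0.0 <= self.swing_trim_fraction < 0.5:
            raise ParameterError("swing_trim_fraction must lie in [0, 0.5)")
        if self.floor_mode not in ("stance_median", "min", "constant"):
            raise ParameterError(f"unknown floor_mode {self.floor_mode!r}")
        if self.filter_method not in ("butterworth", "spline"):
            raise ParameterError(f"unknown filter_method {self.filter_method!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# Trial recording
# --------------------------------------------------------------------------


@dataclass
class TrialRecording:
    """One trial's synchronized kinematic time series.

    Axes are canonical: x = direction of travel, y = mediolateral,
    z = superior-inferior.  ``com`` and the four foot markers are T x 3
    position arrays (m); the optional rotation series are T x 3 x 3
    proximal-to-distal rotation matrices.
    """

    trial_id: str
    condition: str
    rate_hz: float
    t: np.ndarray
    com: np.ndarray
    heel_L: Optional[np.ndarray] = None
    heel_R: Optional[np.ndarray] = None
    toe_L: Optional[np.ndarray] = None
    toe_R: Optional[np.ndarray] = None
    hip_rot_L: Optional[np.ndarray] = None
    hip_rot_R: Optional[np.ndarray] = None
    shoulder_rot_L: Optional[np.ndarray] = None
    shoulder_rot_R: Optional[np.ndarray] = None
    impaired_side: str = "none"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.com = np.asarray(self.com, dtype=float)
        self.validate()

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def marker(self, name: str) -> Optional[np.ndarray]:
        return getattr(self, name)

    def validate(self, rot_tol: float = 1e-6) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.impaired_side not in IMPAIRED_SIDES:
            raise ValidationError(f"unknown impaired_side {self.impaired_side!r}")
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be positive")
        T = len(self.t)
        if T < 2:
            raise ValidationError("a trial needs at least two frames")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise FormatError("time vector is not strictly increasing")
        if np.any(np.abs(dt - 1.0 / self.rate_hz) > 1e-9):
            raise FormatError(
                f"time spacing deviates from 1/{self.rate_hz} Hz by more than 1e-9 s"
            )
        if self.com.shape != (T, 3):
            raise ValidationError(f"com must be ({T}, 3), got {self.com.shape}")
        for name in _MARKER_SERIES:
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                setattr(self, name, arr)
                if arr.shape != (T, 3):
                    raise ValidationError(f"{name} must be ({T}, 3), got {arr.shape}")
        for name in _ROT_SERIES:
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                setattr(self, name, arr)
                if arr.shape != (T, 3, 3):
                    raise ValidationError(f"{name} must be ({T}, 3, 3), got {arr.shape}")
                _check_rotations(arr, name, tol=rot_tol)


def _check_rotations(R: np.ndarray, name: str, tol: float = 1e-6) -> None:
    """Every matrix must be orthonormal with determinant +1 (tolerance tol)."""
    gram = np.einsum("tij,tkj->tik", R, R)
    dev = np.abs(gram - np.eye(3)).max()
    if dev > tol:
        raise ValidationError(
            f"{name}: rotation matrices deviate from orthonormality by {dev:.2e} (> {tol:.0e})"
        )
    det = np.linalg.det(R)
    if np.any(det < 0):
        raise ValidationError(f"{name}: determinant -1 found; reflections are not rotations")
    if np.abs(det - 1.0).max() > 10 * tol:
        raise ValidationError(f"{name}: determinants deviate from +1")


def _reorthonormalize(R: np.ndarray) -> np.ndarray:
    """Project near-rotations onto SO(3) via SVD (polar decomposition)."""
    U, _, Vt = np.linalg.svd(R)
    out = U @ Vt
    # keep determinant +1 (sign flips are rejected elsewhere)
    neg = np.linalg.det(out) < 0
    if np.any(neg):
        U[neg, :, -1] *= -1.0
        out = U @ Vt
    return out


@dataclass
class CognitiveScores:
    """Per-participant cognitive test scores (all finite)."""

    participant_id: str
    response_inhibition: float
    working_memory: float
    mental_rotation: float

    def __post_init__(self) -> None:
        for name in COGNITIVE_COLUMNS:
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")


# --------------------------------------------------------------------------
# Trajectory file reader / writer
# --------------------------------------------------------------------------

_READER_ROT_TOL = 1e-3  # near-rotations within this are re-orthonormalized


def _parse_header(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, value = body.split(":", 1)
                meta[key.strip()] = value.strip()
    return meta


def read_trial(path: str | Path, config: Optional[AnalysisConfig] = None) -> TrialRecording:
    """Read a trajectory CSV into a validated :class:`TrialRecording`.

    The header block declares ``rate_hz``, ``condition`` and optionally
    ``units`` (m|mm), ``time_units`` (s|ms), ``axis_order`` (a permutation of
    ``xyz`` mapping file axes to canonical forward/mediolateral/vertical),
    ``trial_id`` and ``impaired_side``.  Rotation series may be stored as
    nine (3x3) or sixteen (4x4 pose; translation discarded) columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _parse_header(path)
    for key in ("rate_hz", "condition"):
        if key not in meta:
            raise SchemaError(f"missing required header key {key!r}")
    rate_hz = float(meta["rate_hz"])
    condition = meta["condition"]
    units = meta.get("units", "m")
    time_units = meta.get("time_units", "s")
    axis_order = meta.get("axis_order", "xyz")
    if sorted(axis_order) != ["x", "y", "z"]:
        raise FormatError(f"axis_order must be a permutation of 'xyz', got {axis_order!r}")
    if units not in ("m", "mm"):
        raise FormatError(f"units must be 'm' or 'mm', got {units!r}")
    if time_units not in ("s", "ms"):
        raise FormatError(f"time_units must be 's' or 'ms', got {time_units!r}")

    df = pd.read_csv(path, comment="#")
    if "time" not in df.columns:
        raise SchemaError("missing mandatory column 'time'")
    t = df["time"].to_numpy(dtype=float)
    if time_units == "ms":
        t = t / 1000.0
    pos_scale = 0.001 if units == "mm" else 1.0
    if np.any(np.diff(t) <= 0):
        raise FormatError("non-monotone time column")

    # file axis -> canonical axis permutation: column <series>_<file axis>
    # holds the canonical axis axis_order[i] where file axis index i.
    perm = {file_ax: canon_ax for file_ax, canon_ax in zip("xyz", axis_order)}

    def read_vec(series: str, required: bool) -> Optional[np.ndarray]:
        cols = {}
        for file_ax in _AXES:
            col = f"{series}_{file_ax}"
            if col in df.columns:
                cols[perm[file_ax]] = df[col].to_numpy(dtype=float) * pos_scale
        if not cols:
            if required:
                raise SchemaError(f"missing mandatory columns {series}_x/{series}_y/{series}_z")
            return None
        if set(cols) != set(_AXES):
            raise SchemaError(f"incomplete axis columns for series {series!r}")
        return np.column_stack([cols["x"], cols["y"], cols["z"]])

    def read_rot(series: str) -> Optional[np.ndarray]:
        cols9 = [f"{series}_r{i}{j}" for i in range(3) for j in range(3)]
        cols16 = [f"{series}_r{i}{j}" for i in range(4) for j in range(4)]
        if all(c in df.columns for c in cols16):
            flat = df[cols16].to_numpy(dtype=float).reshape(-1, 4, 4)
            R = flat[:, :3, :3]  # 4x4 pose: keep the rotation block
        elif all(c in df.columns for c in cols9):
            R = df[cols9].to_numpy(dtype=float).reshape(-1, 3, 3)
        elif any(c in df.columns for c in cols9):
            raise SchemaError(f"incomplete rotation columns for series {series!r}")
        else:
            return None
        det = np.linalg.det(R)
        if np.any(det <= 0):
            raise ValidationError(
                f"{series}: rotation rows with non-positive determinant (reflection or singular)"
            )
        gram_dev = np.abs(np.einsum("tij,tkj->tik", R, R) - np.eye(3)).max()
        if gram_dev > _READER_ROT_TOL:
            raise ValidationError(
                f"{series}: matrices deviate from orthonormality by {gram_dev:.2e}, "
                f"beyond the reader tolerance {_READER_ROT_TOL:.0e}"
            )
        if gram_dev > 1e-9:
            R = _reorthonormalize(R)
            logger.info("%s: re-orthonormalized rotations (max deviation %.2e)", series, gram_dev)
        return R

    kwargs = {name: read_vec(name, required=False) for name in _MARKER_SERIES}
    kwargs.update({name: read_rot(name) for name in _ROT_SERIES})
    return TrialRecording(
        trial_id=meta.get("trial_id", path.stem),
        condition=condition,
        rate_hz=rate_hz,
        t=t,
        com=read_vec("com", required=True),
        impaired_side=meta.get("impaired_side", "none"),
        **kwargs,
    )


def write_trial(trial: TrialRecording, path: str | Path) -> None:
    """Write a trial to the wide-CSV dialect (always metres / seconds)."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {"time": trial.t}
    for series in ("com",) + _MARKER_SERIES:
        arr = getattr(trial, series)
        if arr is not None:
            for i, ax in enumerate(_AXES):
                cols[f"{series}_{ax}"] = arr[:, i]
    for series in _ROT_SERIES:
        arr = getattr(trial, series)
        if arr is not None:
            flat = arr.reshape(len(trial.t), 9)
            for k in range(9):
                cols[f"{series}_r{k // 3}{k % 3}"] = flat[:, k]
    header = (
        f"# trial_id: {trial.trial_id}\n"
        f"# condition: {trial.condition}\n"
        f"# rate_hz: {trial.rate_hz:g}\n"
        f"# impaired_side: {trial.impaired_side}\n"
        f"# units: m\n# time_units: s\n# axis_order: xyz\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(cols).to_csv(fh, index=False, lineterminator="\n")


# --------------------------------------------------------------------------
# Cohort reader / writer
# --------------------------------------------------------------------------


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort table (TSV/CSV by extension) indexed by participant_id.

    Unknown columns are preserved but ignored by the statistical battery;
    missing cells become NaN.  Duplicate participant ids are an error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise SchemaError("missing mandatory column 'participant_id'")
    dup = df["participant_id"][df["participant_id"].duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate participant_id values: {', '.join(map(str, dup))}")
    df = df.set_index("participant_id")
    for col in df.columns:
        if col in REGISTRY_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    n_missing = int(df[[c for c in df.columns if c in REGISTRY_COLUMNS]].isna().sum().sum())
    if n_missing:
        logger.warning("cohort has %d missing analysis value(s)", n_missing)
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    cohort.to_csv(path, sep=sep, index=True, index_label="participant_id", lineterminator="\n")


# --------------------------------------------------------------------------
# Statistical report writer
# --------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        if np.isnan(v):
            return "nan"
        if np.isinf(v):
            return "inf" if v > 0 else "-inf"
        return _FLOAT_FMT % v
    return str(v)


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    lines = ["\t".join(header)]
    lines += ["\t".join(_fmt(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


def write_report(report, out_dir: str | Path) -> list[Path]:
    """Write a :class:`~pdgait.stats_battery.StatReport` as TSV tables + JSON.

    Emits ``normality.tsv``, ``correlations.tsv``, ``ols.tsv``,
    ``manova.tsv``, ``vif.tsv`` and ``report.json``.  Output is byte-stable
    for identical inputs (fixed float formatting and ordering).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = out_dir / "normality.tsv"
    _write_tsv(
        p,
        ["variable", "W", "p_value", "normal"],
        [(r.variable, r.W, r.p_value, r.normal) for r in report.normality],
    )
    written.append(p)

    p = out_dir / "correlations.tsv"
    _write_tsv(
        p,
        ["predictor", "dependent", "method", "r", "p_value", "ci_lower", "ci_upper",
         "n", "significant"],
        [
            (r.predictor, r.dependent, r.method, r.r, r.p_value, r.ci_lower,
             r.ci_upper, r.n, r.significant)
            for r in report.correlations
        ],
    )
    written.append(p)

    ols_rows = []
    for fit in report.ols:
        for term in fit.terms:
            ols_rows.append(
                (fit.dependent, term.term, term.B, term.SE, term.t, term.p_value,
                 term.ci_lower, term.ci_upper, fit.r_squared, fit.adj_r_squared)
            )
    p = out_dir / "ols.tsv"
    _write_tsv(
        p,
        ["dependent", "predictor", "B", "SE", "t", "p", "ci_lower", "ci_upper",
         "r_squared", "adj_r_squared"],
        ols_rows,
    )
    written.append(p)

    manova_rows = []
    for block in report.manova:
        for term in block.terms:
            for stat in term.statistics:
                manova_rows.append(
                    (block.block, term.term, stat.name, stat.value, stat.F,
                     stat.df_num, stat.df_den, stat.p_value)
                )
    p = out_dir / "manova.tsv"
    _write_tsv(
        p,
        ["block", "predictor", "statistic", "value", "F", "df_num", "df_den", "p"],
        manova_rows,
    )
    written.append(p)

    p = out_dir / "vif.tsv"
    _write_tsv(p, ["predictor", "vif"], [(r.predictor, r.vif) for r in report.vif])
    written.append(p)

    p = out_dir / "report.json"

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    p.write_text(json.dumps(dataclasses.asdict(report), default=default,
                            indent=2, sort_keys=True) + "\n")
    written.append(p)
    return written
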