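"""Normality-gated correlation, OLS, MANOVA, and VIF battery.

The pipeline mirrors standard motor-cognitive correlation practice: every
cohort variable is first checked for normality (Shapiro-Wilk); each
cognitive-gait pair is then correlated with Pearson when both members are
normal and Spearman otherwise, with 95 % confidence intervals from the
Fisher z transform; each gait variable is regressed on the three cognitive
scores by OLS; each response block (TUG phases, single-task metrics,
dual-task metrics) gets a one-way MANOVA with the four classical
multivariate statistics; and predictor collinearity is screened with
variance inflation factors.  No multiplicity correction is applied by
default (a Benjamini-Hochberg flag exists).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import eigh
import statsmodels.api as sm

from .io_model import (
    AnalysisConfig,
    COGNITIVE_COLUMNS,
    DT_COLUMNS,
    REGISTRY_COLUMNS,
    ST_COLUMNS,
    TUG_COLUMNS,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NormalityResult",
    "CorrelationResult",
    "OLSTerm",
    "OLSResult",
    "ManovaStatistic",
    "ManovaTerm",
    "MANOVAResult",
    "VIFResult",
    "StatReport",
    "shapiro_wilk",
    "choose_method",
    "correlate",
    "run_correlation_battery",
    "ols_fit",
    "vif",
    "manova",
    "run_full_battery",
]


@dataclass
class NormalityResult:
    variable: str
    W: float
    p_value: float
    normal: bool


@dataclass
class CorrelationResult:
    predictor: str
    dependent: str
    method: str  # "pearson" | "spearman"
    r: float
    p_value: float
    ci_lower: float
    ci_upper: float
    n: int
    significant: bool
    note: str = ""


@dataclass
class OLSTerm:
    term: str
    B: float
    SE: float
    t: float
    p_value: float
    ci_lower: float
    ci_upper: float


@dataclass
class OLSResult:
    dependent: str
    terms: list[OLSTerm]
    r_squared: float
    adj_r_squared: float
    n: int


@dataclass
class ManovaStatistic:
    name: str
    value: float
    F: float
    df_num: float
    df_den: float
    p_value: float


@dataclass
class ManovaTerm:
    term: str
    statistics: list[ManovaStatistic]
    eigenvalues: list[float]


@dataclass
class MANOVAResult:
    block: str
    terms: list[ManovaTerm]
    n: int
    df_error: int


@dataclass
class VIFResult:
    predictor: str
    vif: float


@dataclass
class StatReport:
    normality: list[NormalityResult] = field(default_factory=list)
    correlations: list[CorrelationResult] = field(default_factory=list)
    ols: list[OLSResult] = field(default_factory=list)
    manova: list[MANOVAResult] = field(default_factory=list)
    vif: list[VIFResult] = field(default_factory=list)
    config: Optional[dict] = None


# --------------------------------------------------------------------------
# Normality and gating
# --------------------------------------------------------------------------


def shapiro_wilk(x: np.ndarray, variable: str = "", alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk W and p (Royston approximation via scipy)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValidationError("Shapiro-Wilk needs n >= 3")
    if len(x) > 5000:
        raise ValidationError("Shapiro-Wilk approximation only valid for n <= 5000")
    if np.ptp(x) == 0:
        raise ValidationError("Shapiro-Wilk undefined for a constant sample")
    W, p = sps.shapiro(x)
    return NormalityResult(variable=variable, W=float(W), p_value=float(p), normal=bool(p > alpha))


def choose_method(nx: NormalityResult, ny: NormalityResult) -> str:
    """Pearson only when both variables are normal; Spearman otherwise."""
    return "pearson" if (nx.normal and ny.normal) else "spearman"


# --------------------------------------------------------------------------
# Correlations
# --------------------------------------------------------------------------


def _fisher_ci(r: float, n: int, se_scale: float, alpha: float) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (float("nan"), float("nan"))
    z = np.arctanh(r)
    se = np.sqrt(se_scale / (n - 3))
    crit = sps.norm.ppf(1 - alpha / 2)
    return float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se))


def correlate(
    x: np.ndarray,
    y: np.ndarray,
    method: str,
    predictor: str = "x",
    dependent: str = "y",
    alpha: float = 0.05,
) -> CorrelationResult:
    """Pairwise-complete correlation with a Fisher-z 95 % CI.

    Pearson uses SE = 1/sqrt(n-3); Spearman uses the Fieller-corrected
    SE = sqrt(1.06/(n-3)) on the rank correlation, with the usual
    t-approximation p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 4:
        raise ValidationError(f"correlation needs n >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a zero-variance sample")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
        lo, hi = _fisher_ci(float(r), n, 1.0, alpha)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
        lo, hi = _fisher_ci(float(r), n, 1.06, alpha)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return CorrelationResult(
        predictor=predictor, dependent=dependent, method=method, r=float(r),
        p_value=float(p), ci_lower=lo, ci_upper=hi, n=n,
        significant=bool(p < alpha),
    )


def _bh_adjust(results: list[CorrelationResult], alpha: float) -> None:
    """Benjamini-Hochberg significance flags (off by default)."""
    ps = np.array([r.p_value for r in results])
    order = np.argsort(ps)
    m = len(ps)
    passed = np.zeros(m, dtype=bool)
    thresh = alpha * (np.arange(1, m + 1)) / m
    ok = np.flatnonzero(ps[order] <= thresh)
    if len(ok):
        passed[order[: ok[-1] + 1]] = True
    for r, sig in zip(results, passed):
        r.significant = bool(sig)


def run_correlation_battery(
    cohort: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
    normality: Optional[dict[str, NormalityResult]] = None,
) -> list[CorrelationResult]:
    """All cognitive-predictor x gait-metric correlations (3 x 19 rows).

    The method per pair follows the normality gate; row-level failures are
    recorded (NaN row with a note) without aborting the battery.
    """
    config = config or AnalysisConfig()
    dependents = [c for c in TUG_COLUMNS + ST_COLUMNS + DT_COLUMNS if c in cohort.columns]
    predictors = [c for c in COGNITIVE_COLUMNS if c in cohort.columns]
    if normality is None:
        normality = {}
        for col in predictors + dependents:
            normality[col] = shapiro_wilk(cohort[col].to_numpy(), col, config.alpha)
    results: list[CorrelationResult] = []
    for pred in predictors:
        for dep in dependents:
            method = choose_method(normality[pred], normality[dep])
            try:
                results.append(
                    correlate(
                        cohort[pred].to_numpy(), cohort[dep].to_numpy(), method,
                        predictor=pred, dependent=dep, alpha=config.alpha,
                    )
                )
            except ValidationError as exc:
                logger.warning("correlation %s ~ %s failed: %s", pred, dep, exc)
                results.append(
                    CorrelationResult(
                        predictor=pred, dependent=dep, method=method,
                        r=float("nan"), p_value=float("nan"),
                        ci_lower=float("nan"), ci_upper=float("nan"),
                        n=0, significant=False, note=str(exc),
                    )
                )
    if config.multiple_testing == "benjamini-hochberg":
        _bh_adjust([r for r in results if np.isfinite(r.p_value)], config.alpha)
    return results


# --------------------------------------------------------------------------
# OLS and VIF
# --------------------------------------------------------------------------


def ols_fit(X: pd.DataFrame, y: np.ndarray, dependent: str = "y",
            alpha: float = 0.05) -> OLSResult:
    """Multivariable OLS of one gait metric on the cognitive scores."""
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y) & np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    Xc, yc = X.loc[mask], y[mask]
    n = len(yc)
    if n <= X.shape[1] + 1:
        raise ValidationError(f"OLS needs n > {X.shape[1] + 1}, got {n}")
    design = sm.add_constant(Xc.to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = np.corrcoef(Xc.to_numpy(dtype=float), rowvar=False)
        pairs = [
            f"{a} ~ {b}"
            for i, a in enumerate(Xc.columns)
            for j, b in enumerate(Xc.columns)
            if i < j and abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValidationError(
            "design matrix is rank deficient"
            + (f" (collinear: {', '.join(pairs)})" if pairs else "")
        )
    fit = sm.OLS(yc, design).fit()
    names = ["intercept"] + list(Xc.columns)
    ci = fit.conf_int(alpha=alpha)
    terms = [
        OLSTerm(
            term=names[i], B=float(fit.params[i]), SE=float(fit.bse[i]),
            t=float(fit.tvalues[i]), p_value=float(fit.pvalues[i]),
            ci_lower=float(ci[i, 0]), ci_upper=float(ci[i, 1]),
        )
        for i in range(len(names))
    ]
    return OLSResult(
        dependent=dependent, terms=terms, r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj), n=n,
    )


def vif(X: pd.DataFrame) -> list[VIFResult]:
    """Variance inflation factor per predictor: 1/(1 - R^2_aux).

    Perfect collinearity is reported as infinite.
    """
    if X.shape[1] < 2:
        raise ValidationError("VIF needs at least two predictors")
    out = []
    arr = X.to_numpy(dtype=float)
    mask = np.isfinite(arr).all(axis=1)
    arr = arr[mask]
    for j, name in enumerate(X.columns):
        others = np.delete(arr, j, axis=1)
        design = sm.add_constant(others, has_constant="add")
        r2 = sm.OLS(arr[:, j], design).fit().rsquared
        v = float("inf") if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        out.append(VIFResult(predictor=str(name), vif=float(v)))
    return out


# --------------------------------------------------------------------------
# MANOVA
# --------------------------------------------------------------------------


def _manova_f_stats(eigs: np.ndarray, a: int, p: int, v: int) -> list[ManovaStatistic]:
    """Classical F approximations from the eigenvalues of H E^-1.

    a = hypothesis df, p = number of responses, v = error df.  Rao's F for
    Wilks, the Pillai-trace F, the classical Hotelling-Lawley F, and an
    upper-bound F for Roy's greatest root; for a = 1 all four coincide.
    """
    eigs = np.clip(np.asarray(eigs, dtype=float), 0.0, None)
    s = min(a, p)
    m = (abs(a - p) - 1) / 2.0
    n_ = (v - p - 1) / 2.0
    out: list[ManovaStatistic] = []

    wilks = float(np.prod(1.0 / (1.0 + eigs)))
    t = 1.0
    if p * p + a * a - 5 > 0:
        t = np.sqrt((p * p * a * a - 4.0) / (p * p + a * a - 5.0))
    r_ = v - (p - a + 1) / 2.0
    df1 = p * a
    df2 = r_ * t - (p * a - 2) / 2.0
    lam_t = wilks ** (1.0 / t)
    F_w = (1 - lam_t) / lam_t * df2 / df1 if lam_t > 0 else np.inf
    out.append(ManovaStatistic("wilks_lambda", wilks, float(F_w), float(df1), float(df2),
                               float(sps.f.sf(F_w, df1, df2))))

    pillai = float(np.sum(eigs / (1.0 + eigs)))
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n_ + s + 1)
    denom = s - pillai
    F_p = ((2 * n_ + s + 1) / (2 * m + s + 1)) * pillai / denom if denom > 0 else np.inf
    out.append(ManovaStatistic("pillai_trace", pillai, float(F_p), float(df1), float(df2),
                               float(sps.f.sf(F_p, df1, df2))))

    hl = float(np.sum(eigs))
    df1 = s * (2 * m + s + 1)
    df2 = 2 * (s * n_ + 1)
    F_h = hl * df2 / (s * df1) if df1 > 0 else np.inf
    out.append(ManovaStatistic("hotelling_lawley_trace", hl, float(F_h), float(df1), float(df2),
                               float(sps.f.sf(F_h, df1, df2))))

    roy = float(eigs.max(initial=0.0))
    r_roy = max(a, p)
    df1 = r_roy
    df2 = v - r_roy + a
    F_r = roy * df2 / df1
    out.append(ManovaStatistic("roys_greatest_root", roy, float(F_r), float(df1), float(df2),
                               float(sps.f.sf(F_r, df1, df2))))
    return out


def manova(X: pd.DataFrame, Y: pd.DataFrame, block: str = "") -> MANOVAResult:
    """Multivariate linear model Y ~ intercept + X, one test per term.

    For each single-df term the hypothesis SSCP is tested against the
    residual SSCP via the eigenvalues of H E^-1.
    """
    Xa = X.to_numpy(dtype=float)
    Ya = Y.to_numpy(dtype=float)
    mask = np.isfinite(Xa).all(axis=1) & np.isfinite(Ya).all(axis=1)
    Xa, Ya = Xa[mask], Ya[mask]
    n = len(Xa)
    k = Xa.shape[1] + 1
    p = Ya.shape[1]
    if p == 0 or X.shape[1] == 0:
        raise ValidationError("MANOVA needs at least one predictor and one response")
    if n <= k + p - 1:
        raise ValidationError(
            f"MANOVA needs n > predictors + responses for an invertible error matrix "
            f"(n={n}, k={k}, p={p})"
        )
    design = np.column_stack([np.ones(n), Xa])
    XtX = design.T @ design
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ design.T @ Ya
    resid = Ya - design @ B
    E = resid.T @ resid
    v = n - k
    # guard: E must be positive definite
    try:
        np.linalg.cholesky(E)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("singular error SSCP matrix") from exc

    names = ["intercept"] + list(X.columns)
    terms = []
    for j, name in enumerate(names):
        L = np.zeros((1, k))
        L[0, j] = 1.0
        LB = L @ B  # 1 x p
        M = L @ XtX_inv @ L.T  # 1 x 1
        H = LB.T @ np.linalg.inv(M) @ LB
        eigs = eigh(H, E, eigvals_only=True)
        eigs = np.clip(eigs, 0.0, None)
        stats = _manova_f_stats(eigs, a=1, p=p, v=v)
        terms.append(ManovaTerm(term=name, statistics=stats,
                                eigenvalues=[float(e) for e in np.sort(eigs)[::-1][:min(1, p)]]))
    return MANOVAResult(block=block, terms=terms, n=n, df_error=v)


# --------------------------------------------------------------------------
# Full battery
# --------------------------------------------------------------------------


def run_full_battery(
    cohort: pd.DataFrame, config: Optional[AnalysisConfig] = None
) -> StatReport:
    """Normality table, correlation battery, per-metric OLS, per-block
    MANOVA, and VIF screen — deterministic given cohort and config.

    Missing data: pairwise-complete for correlations, listwise for
    OLS/MANOVA.  All-missing columns are dropped with a warning.
    """
    import dataclasses

    config = config or AnalysisConfig()
    present = [c for c in REGISTRY_COLUMNS if c in cohort.columns]
    dropped = [c for c in present if cohort[c].isna().all()]
    for c in dropped:
        logger.warning("column %s is entirely missing; dropped from the battery", c)
    present = [c for c in present if c not in dropped]
    data = cohort[present]

    normality = {
        col: shapiro_wilk(data[col].to_numpy(), col, config.alpha) for col in present
    }
    report = StatReport(config=dataclasses.asdict(config))
    report.normality = [normality[col] for col in present]
    report.correlations = run_correlation_battery(data, config, normality)

    predictors = [c for c in COGNITIVE_COLUMNS if c in present]
    dependents = [c for c in TUG_COLUMNS + ST_COLUMNS + DT_COLUMNS if c in present]
    X = data[predictors]
    for dep in dependents:
        try:
            report.ols.append(ols_fit(X, data[dep].to_numpy(), dep, config.alpha))
        except ValidationError as exc:
            logger.warning("OLS for %s failed: %s", dep, exc)

    for block, cols in (
        ("tug", [c for c in TUG_COLUMNS if c in present]),
        ("walk_st", [c for c in ST_COLUMNS if c in present]),
        ("walk_dt", [c for c in DT_COLUMNS if c in present]),
    ):
        if not cols:
            continue
        try:
            report.manova.append(manova(X, data[cols], block=block))
        except ValidationError as exc:
            logger.warning("MANOVA block %s failed: %s", block, exc)

    if len(predictors) >= 2:
        report.vif = vif(X)
    return report
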