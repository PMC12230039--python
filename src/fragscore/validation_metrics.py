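"""Discrimination, calibration, classification, and risk-stratification statistics.

All statistics are implemented directly (rank-based AUC with DeLong variance,
the paired DeLong test on placement values, Hosmer-Lemeshow with explicit
tie handling, calibration slope by Newton-Raphson logistic regression) so the
arithmetic is fully specified and testable against independent oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .risk_scores import ScoreModelSpec, ScorePanel

__all__ = [
    "ValidationReport",
    "StratumResult",
    "CalibrationResult",
    "ConfusionMetrics",
    "roc_auc",
    "delong_test",
    "hosmer_lemeshow",
    "calibration_slope",
    "confusion_metrics",
    "stratum_table",
    "stratum_accuracy",
    "hanley_mcneil_n",
    "build_report",
]


def _as_arrays(scores, outcomes) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(int)
    if s.shape != y.shape:
        raise ValueError(f"length mismatch: {s.shape} vs {y.shape}")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    return s, y


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: per-death and per-survivor mean win fractions."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    # pairwise comparison matrix with ties counting 1/2
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)


def roc_auc(scores, outcomes, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """AUC via the Mann-Whitney rank statistic (ties count 1/2) with DeLong CI.

    Higher score is taken to predict death.  The confidence interval uses the
    DeLong placement-value variance with a normal approximation, truncated to
    [0, 1].
    """
    s, y = _as_arrays(scores, outcomes)
    v10, v01 = _placements(s, y)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) + (v01.var(ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def delong_test(scores_a, scores_b, outcomes) -> tuple[float, float, float, float]:
    """Paired DeLong test comparing two correlated AUCs on the same patients.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided p-value.  Identical
    score vectors give z = 0, p = 1.
    """
    sa, y = _as_arrays(scores_a, outcomes)
    sb, y2 = _as_arrays(scores_b, outcomes)
    va10, va01 = _placements(sa, y)
    vb10, vb01 = _placements(sb, y)
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    m, n = len(va10), len(va01)

    def _cov(u, v):
        if len(u) < 2:
            return 0.0
        return float(np.cov(u, v, ddof=1)[0, 1])

    var = (
        (_cov(va10, va10) + _cov(vb10, vb10) - 2 * _cov(va10, vb10)) / m
        + (_cov(va01, va01) + _cov(vb01, vb01) - 2 * _cov(va01, vb01)) / n
    )
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else math.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
        return auc_a, auc_b, z, p
    z = diff / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


def hosmer_lemeshow(
    predicted,
    outcomes,
    groups: int = 10,
    df_style: str = "validation",
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit test on quantile bins of predicted risk.

    Patients are binned into ``groups`` quantiles of predicted probability;
    tied predictions stay in one bin (piecewise-constant risk scores produce
    heavy ties, so the effective number of bins can be smaller).  Bins whose
    expected deaths or expected survivors are zero are collapsed into their
    neighbor.  The statistic sums ``(O-E)^2/E`` over deaths and survivors.

    ``df_style="validation"`` (default) uses df = effective bins, appropriate
    when the probabilities were NOT fitted to these data (external
    validation); ``"development"`` uses the classic df = bins - 2.
    Returns ``(statistic, df, p)``.
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcomes).astype(int)
    if p.shape != y.shape:
        raise ValueError("length mismatch")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if len(p) < groups:
        raise ValueError(f"need at least {groups} observations")
    if df_style not in ("validation", "development"):
        raise ValueError("df_style must be 'validation' or 'development'")

    distinct = np.unique(p)
    if len(distinct) <= groups:
        # piecewise-constant predictions: one bin per distinct risk value
        bins = np.searchsorted(distinct, p)
    else:
        bins = pd.qcut(p, groups, duplicates="drop", labels=False)
    tab = pd.DataFrame({"p": p, "y": y, "bin": bins}).groupby("bin").agg(
        n=("y", "size"), o1=("y", "sum"), e1=("p", "sum")
    )
    n_b = tab["n"].to_numpy(dtype=float)
    o1 = tab["o1"].to_numpy(dtype=float)
    e1 = tab["e1"].to_numpy(dtype=float)

    # collapse bins with zero expected deaths or survivors into a neighbor
    i = 0
    while len(n_b) > 1 and i < len(n_b):
        if e1[i] <= 0 or (n_b[i] - e1[i]) <= 0:
            j = i - 1 if i > 0 else i + 1
            n_b[j] += n_b[i]
            o1[j] += o1[i]
            e1[j] += e1[i]
            n_b = np.delete(n_b, i)
            o1 = np.delete(o1, i)
            e1 = np.delete(e1, i)
            i = 0
        else:
            i += 1

    e0 = n_b - e1
    o0 = n_b - o1
    statistic = float(np.sum((o1 - e1) ** 2 / e1) + np.sum((o0 - e0) ** 2 / e0))
    g = len(n_b)
    df = g if df_style == "validation" else g - 2
    if df < 1:
        return statistic, df, float("nan")
    return statistic, df, float(stats.chi2.sf(statistic, df))


@dataclass(frozen=True)
class CalibrationResult:
    slope: Optional[float]
    slope_ci: Optional[tuple[float, float]]
    intercept: Optional[float]
    intercept_ci: Optional[tuple[float, float]]
    converged: bool
    degenerate: bool = False
    message: str = ""


def calibration_slope(
    predicted,
    outcomes,
    tol: float = 1e-8,
    max_iter: int = 50,
    clip: float = 1e-6,
) -> CalibrationResult:
    """Calibration slope/intercept: logistic regression of outcome on logit(p).

    Fit by Newton-Raphson with Wald 95% intervals.  A slope of 1 with
    intercept 0 is perfect calibration; slope < 1 indicates predictions more
    extreme than observed risk.  Degenerate inputs (constant predictions) and
    non-convergence/separation are flagged, not raised.
    """
    p = np.clip(np.asarray(predicted, dtype=float), clip, 1 - clip)
    y = np.asarray(outcomes).astype(float)
    x = np.log(p / (1 - p))
    if np.ptp(x) < 1e-12:
        return CalibrationResult(None, None, None, None, False, True,
                                 "constant predictions: slope undefined")
    X = np.column_stack([np.ones_like(x), x])

    def loglik(b):
        eta = X @ b
        return float(y @ eta - np.sum(np.log1p(np.exp(eta))))

    beta = np.zeros(2)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return CalibrationResult(None, None, None, None, False, False,
                                     "singular Hessian (separation?)")
        # backtracking: Newton can overshoot when the starting point is far
        ll0 = loglik(beta)
        scale = 1.0
        while scale > 1e-8 and loglik(beta + scale * step) < ll0:
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    hess = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return CalibrationResult(float(beta[1]), None, float(beta[0]), None,
                                 False, False, "singular Hessian at optimum")
    se = np.sqrt(np.diag(cov))
    if not converged or not np.all(np.isfinite(se)) or np.max(np.abs(beta)) > 1e3:
        return CalibrationResult(float(beta[1]), None, float(beta[0]), None,
                                 False, False, "did not converge (separation?)")
    z = stats.norm.ppf(0.975)
    return CalibrationResult(
        slope=float(beta[1]),
        slope_ci=(float(beta[1] - z * se[1]), float(beta[1] + z * se[1])),
        intercept=float(beta[0]),
        intercept_ci=(float(beta[0] - z * se[0]), float(beta[0] + z * se[0])),
        converged=True,
    )


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]
    threshold: float


def confusion_metrics(scores, outcomes, threshold: float | str = "youden") -> ConfusionMetrics:
    """Sensitivity/specificity/PPV/NPV at a threshold (score >= t predicts death).

    ``threshold="youden"`` chooses the cutoff maximizing sensitivity +
    specificity - 1 over observed score values, breaking ties toward higher
    specificity.
    """
    s, y = _as_arrays(scores, outcomes)
    if threshold == "youden":
        best = None
        for t in np.unique(s):
            m = _confusion_at(s, y, t)
            j = m.sensitivity + m.specificity - 1
            if best is None or j > best[0] + 1e-12 or (
                abs(j - best[0]) <= 1e-12 and m.specificity > best[1].specificity
            ):
                best = (j, m)
        return best[1]
    return _confusion_at(s, y, float(threshold))


def _confusion_at(s: np.ndarray, y: np.ndarray, t: float) -> ConfusionMetrics:
    pred = s >= t
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    return ConfusionMetrics(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ppv=tp / (tp + fp) if tp + fp else None,
        npv=tn / (tn + fn) if tn + fn else None,
        threshold=float(t),
    )


def stratum_accuracy(predicted_pct: float, observed_pct: float) -> float:
    """Symmetric ratio agreement between predicted and observed mortality, %.

    ``100 * min(p, o) / max(p, o)``; 100 when both are zero, 0 when exactly
    one is zero.  Symmetric, bounded by 100, equal to 100 iff p = o.
    """
    if predicted_pct < 0 or observed_pct < 0:
        raise ValueError("mortality percentages must be non-negative")
    lo, hi = sorted((predicted_pct, observed_pct))
    if hi == 0 or lo == hi:
        return 100.0
    return 100.0 * lo / hi


@dataclass(frozen=True)
class StratumResult:
    """One risk stratum's predicted vs observed mortality."""

    label: str
    n: int
    predicted_pct: Optional[float]
    observed_pct: Optional[float]
    accuracy_pct: Optional[float]


def stratum_table(
    panels: Sequence[ScorePanel],
    outcomes: Mapping[str, bool],
    spec: ScoreModelSpec,
    interval_mode: str = "upper",
) -> list[StratumResult]:
    """Per-stratum n, predicted %, observed %, and accuracy for one model.

    ``outcomes`` maps patient_id to one-year death.  Interval-valued predicted
    mortalities are summarized by their upper bound by default
    (``interval_mode="lower"`` switches).  Empty strata yield n = 0 rows with
    missing observed/accuracy (rendered as "None" downstream).
    """
    if interval_mode not in ("upper", "lower"):
        raise ValueError("interval_mode must be 'upper' or 'lower'")
    by_stratum: dict[str, list[ScorePanel]] = {}
    for pan in panels:
        by_stratum.setdefault(pan.stratum, []).append(pan)
    out: list[StratumResult] = []
    for st in spec.strata:
        members = by_stratum.get(st.label, [])
        pred = st.representative_predicted(use_upper=interval_mode == "upper")
        if not members:
            out.append(StratumResult(st.label, 0, pred, None, None))
            continue
        deaths = sum(bool(outcomes[m.patient_id]) for m in members)
        obs = 100.0 * deaths / len(members)
        acc = stratum_accuracy(pred, obs) if pred is not None else None
        out.append(StratumResult(st.label, len(members), pred, obs, acc))
    return out


def hanley_mcneil_n(
    auc: float,
    ci_halfwidth: float,
    prevalence: float,
    z: float = 1.96,
    max_n: int = 10_000_000,
) -> int:
    """Minimum total sample size for an AUC confidence interval, Hanley & McNeil.

    Smallest N such that ``z * SE(auc; n1, n2) <= ci_halfwidth`` with
    n1 = prevalence*N events and n2 = (1-prevalence)*N non-events, where
    ``SE^2 = [A(1-A) + (n1-1)(Q1-A^2) + (n2-1)(Q2-A^2)] / (n1*n2)``,
    Q1 = A/(2-A), Q2 = 2A^2/(1+A).
    """
    if not 0.5 < auc < 1:
        raise ValueError("auc must be in (0.5, 1)")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    if ci_halfwidth <= 0:
        raise ValueError("ci_halfwidth must be positive")
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)

    def se(n_total: float) -> float:
        n1 = prevalence * n_total
        n2 = (1 - prevalence) * n_total
        var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n2 - 1) * (q2 - a * a)) / (n1 * n2)
        return math.sqrt(max(var, 0.0))

    lo, hi = 2, max_n
    if z * se(hi) > ci_halfwidth:
        raise ValueError("infeasible: requested halfwidth unreachable below max_n")
    while lo < hi:
        mid = (lo + hi) // 2
        if z * se(mid) <= ci_halfwidth:
            hi = mid
        else:
            lo = mid + 1
    return lo


@dataclass
class ValidationReport:
    """Full external-validation summary for one model."""

    model: str
    auc: float
    auc_ci: tuple[float, float]
    auc_oriented: float
    auc_oriented_ci: tuple[float, float]
    orientation: int
    delong_p_vs: dict[str, float]
    hl_statistic: Optional[float]
    hl_df: Optional[int]
    hl_p: Optional[float]
    calibration: Optional[CalibrationResult]
    confusion: ConfusionMetrics
    n: int
    n_events: int
    probability_source: str
    notes: list[str] = field(default_factory=list)


def build_report(
    model: str,
    spec: ScoreModelSpec,
    raw_scores: Sequence[float],
    predicted_probs: Sequence[Optional[float]],
    outcomes: Sequence[bool],
    threshold: float | str = "youden",
    hl_groups: int = 10,
    hl_df_style: str = "validation",
) -> ValidationReport:
    """Assemble discrimination/calibration/classification metrics for one model.

    Oriented metrics (threshold search, oriented AUC) use
    ``orientation * score`` so that higher always means higher predicted
    mortality; the as-published AUC is reported alongside.
    """
    y = np.asarray(outcomes).astype(int)
    s = np.asarray(raw_scores, dtype=float)
    auc, ci = roc_auc(s, y)
    oriented = spec.orientation * s
    auc_o, ci_o = roc_auc(oriented, y)
    conf = confusion_metrics(oriented, y, threshold)

    notes: list[str] = []
    if getattr(spec, "orientation", 1) == -1:
        notes.append("score orientation inverted for threshold/oriented AUC")
    adaptation = spec.transform.get("adaptation") if isinstance(spec.transform, dict) else None
    if adaptation:
        notes.append(str(adaptation))

    probs = np.array([np.nan if p is None else float(p) for p in predicted_probs])
    have_probs = np.all(np.isfinite(probs))
    hl_stat = hl_df = hl_p = None
    calib = None
    source = "none"
    if have_probs:
        t = spec.transform.get("type", "none")
        source = {"logistic_percent": "published formula",
                  "logistic": "published formula (configured intercept)",
                  "stratum_table": "stratum-level predicted mortality"}.get(t, t)
        hl_stat, hl_df, hl_p = hosmer_lemeshow(probs, y, hl_groups, hl_df_style)
        calib = calibration_slope(probs, y)
    return ValidationReport(
        model=model,
        auc=auc,
        auc_ci=ci,
        auc_oriented=auc_o,
        auc_oriented_ci=ci_o,
        orientation=spec.orientation,
        delong_p_vs={},
        hl_statistic=hl_stat,
        hl_df=hl_df,
        hl_p=hl_p,
        calibration=calib,
        confusion=conf,
        n=int(len(y)),
        n_events=int(y.sum()),
        probability_source=source,
    )
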