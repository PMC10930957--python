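"""Survival-biomarker engine, implemented from first principles:

- empirical ROC with trapezoid AUC cross-checked against the
  Mann–Whitney formulation, DeLong 95% CI;
- Youden-index optimal cutoff with Wilson-score CIs for
  sensitivity/specificity;
- Kaplan–Meier product-limit estimator;
- two-group log-rank (Mantel–Cox) test with hypergeometric variance;
- univariate Cox proportional hazards (Newton–Raphson, Efron ties);
- the five-year survivor labelling rule and the end-to-end report
  that chains them on a cohort table.

Orientation throughout: higher biomarker values predict the positive
class (survival), and ``value >= cutoff`` means predicted positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

_Z95 = 1.959963984540054


class SingleClassError(ValueError):
    """ROC is undefined when only one class is present."""


class SurvivalInputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ROC / AUC / Youden


@dataclass
class RocCurve:
    thresholds: np.ndarray  # ascending unique score values
    sensitivity: np.ndarray  # P(score >= t | positive), per threshold
    specificity: np.ndarray  # P(score <  t | negative), per threshold
    auc: float
    auc_ci_95: tuple[float, float]
    auc_se: float
    n_positive: int
    n_negative: int
    orientation: str = "higher_positive"


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """Empirical ROC over all distinct thresholds (rule: score >= t positive).

    The trapezoid AUC over the step curve and the Mann–Whitney U
    probability (ties credited 1/2) are both computed and must agree; the
    95% CI is DeLong's.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise SingleClassError("both classes must be present")

    m, n = pos.size, neg.size
    thresholds = np.unique(s)
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # counts of pos >= t and neg >= t per threshold, via binary search
    tp = m - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = n - np.searchsorted(neg_sorted, thresholds, side="left")
    sens = tp / m
    spec = 1.0 - fp / n

    # trapezoid over the step curve in integer count space (exact):
    # 2*m*n*AUC = sum (fp_i - fp_{i+1}) * (tp_i + tp_{i+1})
    fp_pts = np.concatenate([[n], fp, [0]])
    tp_pts = np.concatenate([[m], tp, [0]])
    num2 = int(np.sum((fp_pts[:-1] - fp_pts[1:]) * (tp_pts[:-1] + tp_pts[1:])))
    auc_trap = num2 / (2 * m * n)

    auc_mw = _mann_whitney_auc(pos, neg)
    if abs(auc_trap - auc_mw) > 1e-12:  # internal consistency guard
        raise AssertionError(
            f"trapezoid AUC {auc_trap!r} != Mann-Whitney AUC {auc_mw!r}"
        )
    se = _delong_se(pos, neg)
    lo = max(0.0, auc_mw - _Z95 * se)
    hi = min(1.0, auc_mw + _Z95 * se)
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc_mw,
        auc_ci_95=(lo, hi),
        auc_se=se,
        n_positive=m,
        n_negative=n,
    )


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    combined = np.concatenate([pos, neg])
    ranks = sps.rankdata(combined)  # midranks handle ties with 1/2 credit
    r_pos = ranks[: pos.size].sum()
    m, n = pos.size, neg.size
    return float((r_pos - m * (m + 1) / 2.0) / (m * n))


def _delong_se(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong structural-components standard error of the AUC."""
    m, n = pos.size, neg.size
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    neg_lt = np.searchsorted(neg_sorted, pos, side="left")
    neg_le = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (neg_lt + 0.5 * (neg_le - neg_lt)) / n
    pos_le = np.searchsorted(pos_sorted, neg, side="right")
    pos_lt = np.searchsorted(pos_sorted, neg, side="left")
    v01 = ((m - pos_le) + 0.5 * (pos_le - pos_lt)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def wilson_ci(successes: int, total: int, z: float = _Z95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if total == 0:
        return (0.0, 1.0)
    p = successes / total
    denom = 1.0 + z**2 / total
    center = (p + z**2 / (2 * total)) / denom
    half = z * np.sqrt(p * (1 - p) / total + z**2 / (4 * total**2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


@dataclass
class CutoffResult:
    cutoff: float  # observed score; rule: value >= cutoff => predicted positive
    youden_j: float
    sensitivity: float
    sensitivity_ci_95: tuple[float, float]
    specificity: float
    specificity_ci_95: tuple[float, float]


def youden_cutoff(roc: RocCurve) -> CutoffResult:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties broken by higher specificity, then by lower cutoff value.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = 0
    for i in range(1, roc.thresholds.size):
        if j[i] > j[best] + 1e-12 or (
            abs(j[i] - j[best]) <= 1e-12
            and (
                roc.specificity[i] > roc.specificity[best] + 1e-12
                # lower cutoff at equal J and spec never occurs later in the
                # ascending sweep, so no third clause is needed
            )
        ):
            best = i
    cut = float(roc.thresholds[best])
    sens = float(roc.sensitivity[best])
    spec = float(roc.specificity[best])
    m, n = roc.n_positive, roc.n_negative
    return CutoffResult(
        cutoff=cut,
        youden_j=float(j[best]),
        sensitivity=sens,
        sensitivity_ci_95=wilson_ci(round(sens * m), m),
        specificity=spec,
        specificity_ci_95=wilson_ci(round(spec * n), n),
    )


# ---------------------------------------------------------------------------
# Kaplan–Meier / log-rank / Cox


@dataclass
class KmCurve:
    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    censor_times: np.ndarray

    def at(self, t: float) -> float:
        """S(t) — survival probability at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KmCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t < 0):
        raise SurvivalInputError("negative survival times")
    if t.shape != e.shape:
        raise SurvivalInputError("times/events length mismatch")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times, d = np.unique(t[e == 1], return_counts=True)
    at_risk = t.size - np.searchsorted(t, event_times, side="left")
    surv = np.cumprod(1.0 - d / at_risk)
    return KmCurve(
        times=event_times,
        at_risk=at_risk,
        n_events=d,
        survival=surv,
        censor_times=np.sort(t[e == 0]),
    )


def km_by_group(
    times: Sequence[float], events: Sequence[int], groups: Sequence
) -> dict[object, KmCurve]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    return {lv: km_estimate(t[g == lv], e[g == lv]) for lv in np.unique(g)}


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def log_rank(
    times: Sequence[float], events: Sequence[int], groups: Sequence
) -> LogRankResult:
    """Two-group Mantel–Cox test: ((sum O1-E1)^2) / (sum V), chi2 df=1."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    levels = np.unique(g)
    if levels.size != 2:
        raise SurvivalInputError(f"log-rank needs exactly 2 groups, got {levels.size}")
    if e.sum() < 1:
        raise SurvivalInputError("log-rank needs at least one event")
    in1 = g == levels[0]
    t_sorted = np.sort(t)
    t1_sorted = np.sort(t[in1])
    event_times, d = np.unique(t[e == 1], return_counts=True)
    d1 = np.zeros(event_times.size)
    g1_times, g1_counts = np.unique(t[(e == 1) & in1], return_counts=True)
    d1[np.searchsorted(event_times, g1_times)] = g1_counts
    n_i = t.size - np.searchsorted(t_sorted, event_times, side="left")
    n1_i = t1_sorted.size - np.searchsorted(t1_sorted, event_times, side="left")
    frac1 = n1_i / n_i
    o1 = float(d1.sum())
    e1 = float((d * frac1).sum())
    o2 = float(d.sum() - o1)
    e2 = float(d.sum() - e1)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = d * frac1 * (1.0 - frac1) * (n_i - d) / (n_i - 1.0)
    v = float(terms[n_i > 1].sum())
    if v == 0.0:
        return LogRankResult(0.0, 1, 1.0, (o1, o2), (e1, e2))
    stat = (o1 - e1) ** 2 / v
    return LogRankResult(
        float(stat), 1, float(sps.chi2.sf(stat, 1)), (float(o1), float(o2)), (float(e1), float(e2))
    )


@dataclass
class CoxResult:
    beta: float
    hazard_ratio: float
    se: float
    z: float
    p_value: float
    hr_ci_95: tuple[float, float]
    converged: bool
    n_iterations: int


def _cox_derivatives(
    beta: float, t: np.ndarray, e: np.ndarray, x: np.ndarray
) -> tuple[float, float, float]:
    """Log partial likelihood, gradient and negative Hessian (information)
    for a single covariate under Efron tie handling."""
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    eta = beta * x
    w = np.exp(eta)
    wx = w * x
    wx2 = wx * x
    # suffix sums give the risk-set sums S0/S1/S2 at any event time
    rs0 = np.cumsum(w[::-1])[::-1]
    rs1 = np.cumsum(wx[::-1])[::-1]
    rs2 = np.cumsum(wx2[::-1])[::-1]

    ev = np.flatnonzero(e == 1)
    ev_times = t[ev]
    uniq, starts, d = np.unique(ev_times, return_index=True, return_counts=True)
    k = np.searchsorted(t, uniq, side="left")
    s0, s1, s2 = rs0[k], rs1[k], rs2[k]
    ts0 = np.add.reduceat(w[ev], starts)
    ts1 = np.add.reduceat(wx[ev], starts)
    ts2 = np.add.reduceat(wx2[ev], starts)

    loglik = float(eta[ev].sum())
    grad = float(x[ev].sum())
    info = 0.0
    single = d == 1
    if single.any():
        z0, z1, z2 = s0[single], s1[single], s2[single]
        loglik -= float(np.log(z0).sum())
        grad -= float((z1 / z0).sum())
        info += float((z2 / z0 - (z1 / z0) ** 2).sum())
    for j in np.flatnonzero(~single):  # Efron correction at tied event times
        dj = int(d[j])
        for l in range(dj):
            f = l / dj
            z0 = s0[j] - f * ts0[j]
            z1 = s1[j] - f * ts1[j]
            z2 = s2[j] - f * ts2[j]
            loglik -= np.log(z0)
            grad -= z1 / z0
            info += z2 / z0 - (z1 / z0) ** 2
    return loglik, grad, info


def cox_univariate(
    times: Sequence[float],
    events: Sequence[int],
    covariate: Sequence[float],
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Univariate Cox PH fit by Newton–Raphson with Efron tie handling.

    Convergence when |delta beta| < tol; monotone likelihood (separation)
    is flagged as non-convergence and no estimate should be trusted.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if np.ptp(x) == 0.0:
        raise SurvivalInputError("covariate does not vary")
    if e.sum() < 1:
        raise SurvivalInputError("need at least one event")

    beta = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, grad, info = _cox_derivatives(beta, t, e, x)
        if info <= 0:
            break
        step = grad / info
        # dampen wild steps (near-separation)
        if abs(step) > 5.0:
            step = np.sign(step) * 5.0
        beta += step
        if abs(beta) > 30.0:  # monotone likelihood
            break
        if abs(step) < tol:
            converged = True
            break
    _, _, info = _cox_derivatives(beta, t, e, x)
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf
    z = beta / se if np.isfinite(se) and se > 0 else np.nan
    p = float(2.0 * sps.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    if np.isfinite(se):
        with np.errstate(over="ignore"):  # near-separation: CI may hit inf
            ci = (float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se)))
    else:
        ci = (0.0, np.inf)
    return CoxResult(
        beta=float(beta),
        hazard_ratio=float(np.exp(beta)),
        se=se,
        z=float(z),
        p_value=p,
        hr_ci_95=ci,
        converged=converged,
        n_iterations=it,
    )


def cox_score_test(
    times: Sequence[float], events: Sequence[int], covariate: Sequence[float]
) -> float:
    """Score (Rao) chi-square at beta = 0; equals the log-rank statistic for
    a binary covariate without tied event times."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = np.asarray(covariate, dtype=float)
    _, grad, info = _cox_derivatives(0.0, t, e, x)
    return float(grad**2 / info)


# ---------------------------------------------------------------------------
# Five-year labelling and the end-to-end report


def five_year_label(
    times: Sequence[float], events: Sequence[int], horizon: float = 60.0
) -> tuple[np.ndarray, np.ndarray]:
    """Binary survivor labels at the horizon (months).

    Returns (labels, included): survivor (1) if time >= horizon;
    nonsurvivor (0) if the event occurred before the horizon; subjects
    censored before the horizon are excluded (included == False, label 0).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    labels = (t >= horizon).astype(int)
    included = (t >= horizon) | (e == 1)
    return labels, included


@dataclass
class BiomarkerReport:
    gene: str
    n_total: int
    n_classified: int
    n_excluded_censored: int
    roc: RocCurve
    cutoff: CutoffResult
    km_high: KmCurve
    km_low: KmCurve
    n_high: int
    n_low: int
    log_rank: LogRankResult
    cox: CoxResult

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "n_total": self.n_total,
            "n_classified": self.n_classified,
            "n_excluded_censored": self.n_excluded_censored,
            "auc": self.roc.auc,
            "auc_ci_95": list(self.roc.auc_ci_95),
            "cutoff": self.cutoff.cutoff,
            "youden_j": self.cutoff.youden_j,
            "sensitivity": self.cutoff.sensitivity,
            "sensitivity_ci_95": list(self.cutoff.sensitivity_ci_95),
            "specificity": self.cutoff.specificity,
            "specificity_ci_95": list(self.cutoff.specificity_ci_95),
            "n_high": self.n_high,
            "n_low": self.n_low,
            "log_rank_chi_square": self.log_rank.chi_square,
            "log_rank_p": self.log_rank.p_value,
            "cox_beta": self.cox.beta,
            "cox_hazard_ratio": self.cox.hazard_ratio,
            "cox_hr_ci_95": list(self.cox.hr_ci_95),
            "cox_p": self.cox.p_value,
            "cox_converged": self.cox.converged,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def biomarker_report(
    cohort: pd.DataFrame,
    gene: str,
    value_col: str | None = None,
    time_col: str = "time_months",
    event_col: str = "event",
    horizon: float = 60.0,
) -> BiomarkerReport:
    """Full biomarker evaluation of one gene on a cohort table.

    Chains five-year labelling, ROC/AUC, Youden cutoff, dichotomization at
    the cutoff (value >= cutoff is "high"), Kaplan–Meier curves per group,
    log-rank, and univariate Cox on the high/low indicator.  Deterministic:
    equal inputs yield identical reports.
    """
    value_col = value_col or f"{gene}_rpkm"
    values = cohort[value_col].to_numpy(dtype=float)
    times = cohort[time_col].to_numpy(dtype=float)
    events = cohort[event_col].to_numpy(dtype=int)

    labels, included = five_year_label(times, events, horizon)
    roc = roc_curve(values[included], labels[included])
    cut = youden_cutoff(roc)

    high = values >= cut.cutoff
    groups = np.where(high, "high", "low")
    km = km_by_group(times, events, groups)
    lr = log_rank(times, events, groups)
    # covariate 1 = low expressor, so HR > 1 means low expression is harmful
    cox = cox_univariate(times, events, (~high).astype(float))

    return BiomarkerReport(
        gene=gene,
        n_total=len(cohort),
        n_classified=int(included.sum()),
        n_excluded_censored=int((~included).sum()),
        roc=roc,
        cutoff=cut,
        km_high=km["high"],
        km_low=km["low"],
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        log_rank=lr,
        cox=cox,
    )
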