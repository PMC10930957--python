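"""Group-comparison statistics: one-way ANOVA, Sidak and Benjamini–Hochberg
adjustments, Welch's t, and Pearson chi-square on 2x2 tables.

Test statistics are computed from first principles (sums of squares,
Satterthwaite df, step-up ordering); p-values come from scipy reference
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateInputError(ValueError):
    """All values identical where a variance is required."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    method: str
    adjusted_p: float | None = None


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Classical equal-variance one-way ANOVA F test."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1 = len(arrays) - 1
    df2 = n_total - len(arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            # all values identical everywhere: no evidence against the null
            return TestResult(0.0, (df1, df2), 1.0, "one-way ANOVA")
        raise DegenerateInputError("zero within-group variance with unequal means")
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    return TestResult(float(f), (df1, df2), p, "one-way ANOVA")


def sidak_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Sidak adjustment: p_adj = 1 - (1 - p)^m, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be >= number of comparisons")
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t test with Satterthwaite df."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return TestResult(0.0, np.nan, 1.0, "Welch t")
        raise DegenerateInputError("zero variance in both groups with unequal means")
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(float(t), float(df), p, "Welch t")


def chi_square(table: Sequence[Sequence[float]], correction: bool = False) -> TestResult:
    """Pearson chi-square on a contingency table, no continuity correction
    by default."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total == 0:
        raise DegenerateInputError("empty contingency table")
    expected = row @ col / total
    if np.any(expected == 0):
        raise DegenerateInputError("zero expected count in contingency table")
    diff = np.abs(obs - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return TestResult(stat, df, p, "Pearson chi-square")


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Fisher's exact test (2x2), delegated to scipy."""
    odds, p = sps.fisher_exact(np.asarray(table))
    return TestResult(float(odds), None, float(p), "Fisher exact")


def compare_groups(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    group_col: str = "group",
    adjust: str = "sidak",
) -> pd.DataFrame:
    """Per-gene group comparison producing a tidy results table.

    ``expression`` is samples x genes with a ``sample_id`` column (or
    index); ``metadata`` maps sample_id to a group label.  Two groups use
    Welch's t, more use one-way ANOVA; p-values are adjusted across genes.
    """
    expr = expression.set_index("sample_id") if "sample_id" in expression else expression
    meta = metadata.set_index("sample_id") if "sample_id" in metadata else metadata
    labels = meta.loc[expr.index, group_col]
    level_names = sorted(labels.unique())
    rows = []
    for gene in expr.columns:
        by_group = [expr.loc[labels == lv, gene].to_numpy() for lv in level_names]
        if len(by_group) == 2:
            res = welch_t(by_group[0], by_group[1])
        else:
            res = one_way_anova(by_group)
        rows.append(
            {
                "contrast": gene,
                "statistic": res.statistic,
                "p": res.p_value,
                "method": res.method,
            }
        )
    out = pd.DataFrame(rows)
    if adjust == "sidak":
        out["p_adj"] = sidak_adjust(out["p"].to_numpy())
    elif adjust == "bh":
        out["p_adj"] = bh_fdr(out["p"].to_numpy())
    elif adjust == "none":
        out["p_adj"] = out["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["adjust_method"] = adjust
    return out[["contrast", "statistic", "p", "p_adj", "method", "adjust_method"]]
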