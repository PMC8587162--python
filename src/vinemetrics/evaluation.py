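"""Model accuracy and group-comparison statistics.

Accuracy of a regression model is summarized per stage (training /
validation / testing / overall) by the Pearson correlation R between
predictions and targets, the least-squares slope b of predictions on
targets, and the mean squared error — all computed on observations
flattened across targets, so a two-target model on 432 samples is scored
on 864 observations.

Outliers are counted against the 95% (t-based) prediction bounds of the
ordinary least-squares fit of predictions on targets, the standard
interval including leverage. Group comparisons use one-way ANOVA followed
by Tukey's HSD with a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionDiagnostics",
    "OutlierReport",
    "GroupComparison",
    "diagnostics",
    "prediction_bound_outliers",
    "outlier_percent",
    "anova_tukey",
]


@dataclass
class RegressionDiagnostics:
    stage: str  # training | validation | testing | overall
    n_samples: int
    n_observations: int
    r: float
    slope: float
    mse: float

    def as_dict(self) -> dict:
        return {"stage": self.stage, "n_samples": self.n_samples,
                "n_observations": self.n_observations, "r": self.r,
                "slope": self.slope, "mse": self.mse}


@dataclass
class OutlierReport:
    n_total: int
    n_outliers: int
    percent: float
    level: float = 0.95
    outlier_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class GroupComparison:
    groups: list[str]
    means: np.ndarray
    standard_errors: np.ndarray
    f_statistic: float
    p_value: float
    letters: dict[str, str]
    tukey_table: pd.DataFrame
    alpha: float = 0.05


def diagnostics(pred: np.ndarray, target: np.ndarray, stage: str = "overall") -> RegressionDiagnostics:
    """R, slope and MSE of predictions vs targets, flattened across targets.

    The slope is the least-squares coefficient b in ``pred = a + b*target``.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError("pred and target must have equal shapes")
    n_samples = pred.shape[0]
    n_targets = 1 if pred.ndim == 1 else int(np.prod(pred.shape[1:]))
    p, t = pred.ravel(), target.ravel()
    if np.var(t) == 0:
        raise ValueError("target has zero variance; correlation undefined")
    r = float(np.corrcoef(p, t)[0, 1])
    slope = float(np.cov(p, t, bias=True)[0, 1] / np.var(t))
    mse = float(np.mean((p - t) ** 2))
    return RegressionDiagnostics(stage=stage, n_samples=n_samples,
                                 n_observations=n_samples * n_targets,
                                 r=r, slope=slope, mse=mse)


def outlier_percent(n_outliers: int, n_total: int) -> float:
    """Outlier bookkeeping: percentage at 2 dp, e.g. 43/864 -> 4.98."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_outliers / n_total, 2)


def prediction_bound_outliers(pred: np.ndarray, target: np.ndarray,
                              level: float = 0.95) -> OutlierReport:
    """Count observations outside the t-based OLS prediction bounds.

    Fits ``pred = a + b*target`` by OLS; an observation is an outlier iff
    its prediction falls outside the two-sided prediction interval at the
    requested level (residual variance inflated by leverage,
    ``s * sqrt(1 + 1/n + (x - xbar)^2 / Sxx)``, t quantile with n - 2 df).
    """
    y = np.asarray(pred, dtype=float).ravel()
    x = np.asarray(target, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("degenerate fit: target has zero variance")
    b = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    a = float(y.mean() - b * x.mean())
    resid = y - (a + b * x)
    s2 = float(resid @ resid) / (n - 2)
    if s2 == 0:
        outliers = np.array([], dtype=int)
    else:
        se = np.sqrt(s2 * (1.0 + 1.0 / n + (x - x.mean()) ** 2 / sxx))
        tcrit = stats.t.ppf(0.5 + level / 2.0, n - 2)
        outliers = np.flatnonzero(np.abs(resid) > tcrit * se)
    return OutlierReport(n_total=n, n_outliers=len(outliers),
                         percent=outlier_percent(len(outliers), n),
                         level=level, outlier_index=outliers)


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD with compact letter display
# ---------------------------------------------------------------------------

def anova_tukey(values_by_group: dict[str, Sequence[float]],
                alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA and Tukey HSD pairwise comparisons with letters.

    Groups that share a letter are not significantly different at ``alpha``.
    If every value in every group is identical the comparison is vacuous and
    p = 1 by convention.
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    means = np.array([a.mean() for a in arrays])
    ses = np.array([a.std(ddof=1) / np.sqrt(len(a)) for a in arrays])

    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:
        letters = {g: "a" for g in names}
        table = pd.DataFrame(columns=["group1", "group2", "meandiff", "p-adj", "reject"])
        return GroupComparison(names, means, ses, 0.0, 1.0, letters, table, alpha)

    f_stat, p_val = stats.f_oneway(*arrays)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = np.concatenate([[g] * len(a) for g, a in zip(names, arrays)])
    tuk = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    table = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
    not_different = {
        frozenset((row["group1"], row["group2"]))
        for _, row in table.iterrows() if not row["reject"]
    }
    letters = _compact_letter_display(names, means, not_different)
    return GroupComparison(names, means, ses, float(f_stat), float(p_val),
                           letters, table, alpha)


def _compact_letter_display(names, means, not_different) -> dict[str, str]:
    """Letter each maximal clique of the not-different graph.

    Letters are assigned in order of the best (highest) group mean within
    the clique, so the top-performing homogeneous subset gets 'a' — the
    usual presentation in agronomy tables. Group counts here are small, so
    maximal cliques are found by subset enumeration.
    """
    from itertools import combinations

    def is_clique(subset):
        return all(frozenset(p) in not_different for p in combinations(subset, 2))

    cliques = [frozenset(c)
               for r in range(len(names), 0, -1)
               for c in combinations(names, r) if is_clique(c)]
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    mean_of = dict(zip(names, np.asarray(means)))
    maximal.sort(key=lambda c: -max(mean_of[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in names}
    for letter, clique in zip(alphabet, maximal):
        for g in clique:
            out[g] += letter
    return {g: "".join(sorted(out[g])) for g in names}
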