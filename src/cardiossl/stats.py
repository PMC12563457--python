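"""Classifier metric battery and the comparison statistics.

Confusion-matrix metrics (sensitivity, specificity, precision, F1) follow
their textbook definitions with explicit NA markers for zero denominators.
AUC uses the rank (Mann-Whitney) formulation with midrank tie handling.
Group comparison uses a one-way fixed-effects ANOVA and Tukey's HSD
post-hoc test; unbalanced designs fall back to the Tukey-Kramer standard
error.  Studentized-range probabilities come from the numerical
distribution in :mod:`scipy.stats`, not from table lookups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConfusionCounts",
    "MetricsRow",
    "AnovaResult",
    "TukeyResult",
    "confusion_metrics",
    "confusion_from_predictions",
    "roc_auc",
    "one_way_anova",
    "tukey_hsd",
    "build_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsRow:
    """Metric battery; undefined ratios are NaN (never silently zero)."""

    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    auc: float = np.nan

    def to_dict(self) -> dict:
        return {"sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "precision": self.precision,
                "f_score": self.f_score,
                "auc": self.auc}


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NA",
                      stacklevel=3)
        return np.nan
    return num / den


def confusion_metrics(c: ConfusionCounts) -> MetricsRow:
    """Sensitivity, specificity, precision and F1 from raw counts."""
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = _ratio(c.tn, c.tn + c.fp, "specificity")
    prec = _ratio(c.tp, c.tp + c.fp, "precision")
    if np.isnan(sens) or np.isnan(prec) or (prec + sens) == 0:
        if not (np.isnan(sens) or np.isnan(prec)):
            warnings.warn("f_score undefined (zero denominator); reporting NA",
                          stacklevel=2)
        f1 = np.nan
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return MetricsRow(sens, spec, prec, f1)


def confusion_from_predictions(y_true, scores,
                               threshold: float = 0.5) -> ConfusionCounts:
    y = np.asarray(y_true).astype(int)
    pred = (np.asarray(scores) >= threshold).astype(int)
    return ConfusionCounts(tp=int(((pred == 1) & (y == 1)).sum()),
                           fp=int(((pred == 1) & (y == 0)).sum()),
                           tn=int(((pred == 0) & (y == 0)).sum()),
                           fn=int(((pred == 0) & (y == 1)).sum()))


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC via midranks plus the ROC polyline over all score thresholds."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = sps.rankdata(scores, method="average")
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)) , len(scores) - 1]
    tp = np.cumsum(sorted_labels)[distinct]
    fp = (distinct + 1) - tp
    points = pd.DataFrame({
        "threshold": np.r_[np.inf, sorted_scores[distinct]],
        "fpr": np.r_[0.0, fp / n_neg],
        "tpr": np.r_[0.0, tp / n_pos],
    })
    return float(auc), points


@dataclass(frozen=True)
class AnovaResult:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    f: float
    p: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("ss_between", "ss_within", "ss_total", "df_between",
                 "df_within", "ms_between", "ms_within", "f", "p")}


def one_way_anova(groups: list) -> AnovaResult:
    """Fixed-effects one-way ANOVA decomposition with an F-distribution p."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within == 0:
        raise ValueError("zero within-group variance: F is degenerate")
    df_between = len(groups) - 1
    df_within = len(allv) - len(groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f = ms_between / ms_within
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(ss_between, ss_within, ss_between + ss_within,
                       df_between, df_within, ms_between, ms_within,
                       float(f), p)


@dataclass(frozen=True)
class TukeyResult:
    table: pd.DataFrame
    q_critical: dict[float, float]
    hsd_thresholds: dict[float, float]
    ms_within: float
    df_within: int

    def to_dict(self) -> dict:
        return {"table": self.table.to_dict(orient="records"),
                "q_critical": {str(a): v for a, v in self.q_critical.items()},
                "hsd_thresholds": {str(a): v
                                   for a, v in self.hsd_thresholds.items()},
                "ms_within": self.ms_within,
                "df_within": self.df_within}


def tukey_hsd(groups: list, alphas: tuple[float, ...] = (0.05, 0.01),
              names: list[str] | None = None) -> TukeyResult:
    """Tukey's HSD pairwise comparison after a one-way ANOVA.

    Balanced designs use ``Q = |mean_i - mean_j| / sqrt(MSW / n)``;
    unbalanced pairs use the Tukey-Kramer standard error
    ``sqrt(MSW/2 * (1/n_i + 1/n_j))``.  p-values and critical points come
    from the studentized-range distribution with (k, df_within).
    """
    anova = one_way_anova(groups)
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    k = len(groups)
    names = names or [f"g{i}" for i in range(k)]
    msw, dfw = anova.ms_within, anova.df_within
    balanced = len({len(g) for g in groups}) == 1
    n_ref = len(groups[0])
    q_crit = {a: float(sps.studentized_range.ppf(1.0 - a, k, dfw))
              for a in alphas}
    hsd = {a: q_crit[a] * np.sqrt(msw / n_ref) if balanced else np.nan
           for a in alphas}
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(msw / 2.0 * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            q = abs(groups[i].mean() - groups[j].mean()) / se
            p = float(np.clip(sps.studentized_range.sf(q, k, dfw), 0.0, 1.0))
            row = {"group_i": names[i], "group_j": names[j],
                   "mean_i": groups[i].mean(), "mean_j": groups[j].mean(),
                   "q": float(q), "p": p}
            for a in alphas:
                row[f"significant_{a}"] = bool(q > q_crit[a])
            rows.append(row)
    return TukeyResult(pd.DataFrame(rows), q_crit, hsd, msw, dfw)


METRIC_NAMES = ("sensitivity", "specificity", "precision", "f_score", "auc")


def build_report(cells: pd.DataFrame,
                 group_by: str = "reduction") -> dict:
    """Assemble the benchmark tables and the statistics block.

    ``cells`` is one row per (task, reduction, seed) with accuracy columns,
    robustness columns, and the five-metric battery.  The statistics block
    groups the metric observations by ``group_by`` (reduction level by
    default) and runs ANOVA + Tukey over those groups.
    """
    required = {"task", "reduction", "seed"}
    if not required <= set(cells.columns):
        raise ValueError(f"cells must contain columns {sorted(required)}")
    summary_cols = [c for c in ("train_acc", "val_acc", "test_acc",
                                "fgsm_drop", "pgd_drop", "fgsm_category",
                                "pgd_category", "ood_score")
                    if c in cells.columns]
    summary = (cells.groupby(["task", "reduction"], as_index=False)
               [summary_cols]
               .agg(lambda s: s.median() if s.dtype.kind in "fci"
                    else s.mode().iloc[0]))
    metric_cols = [m for m in METRIC_NAMES if m in cells.columns]
    metrics = cells[["task", "reduction", "seed"] + metric_cols].copy()

    stats_block: dict = {"grouping": group_by}
    levels = sorted(cells[group_by].unique())
    groups, names = [], []
    for lev in levels:
        obs = cells.loc[cells[group_by] == lev, metric_cols].to_numpy().ravel()
        obs = obs[np.isfinite(obs)]
        if len(obs) >= 2:
            groups.append(obs)
            names.append(str(lev))
    if len(groups) >= 2:
        try:
            anova = one_way_anova(groups)
            tukey = tukey_hsd(groups, names=names)
            stats_block["anova"] = anova.to_dict()
            stats_block["tukey"] = tukey.to_dict()
        except ValueError as exc:
            stats_block["error"] = str(exc)
    else:
        stats_block["error"] = "not enough groups with observations"
    return {"summary": summary, "metrics": metrics, "stats": stats_block}
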