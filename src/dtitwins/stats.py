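"""Evaluation metrics and replicate-comparison statistics.

Classification is scored by ROC AUC and PR AUC (average precision);
regression by Pearson's rho and mean absolute error.  Replicate runs of
competing model configurations are compared metric-by-metric with a
two-sided Welch's t-test, the family of p-values is corrected by
Benjamini-Hochberg, and a configuration is flagged the winner on a metric
only when it is both the best on average and significantly different from
every competitor after correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

#: Metrics where larger is better; MAE is the only loss-type metric.
_HIGHER_BETTER = {"roc_auc": True, "pr_auc": True, "pearson": True, "mae": False}


def roc_auc(labels, scores) -> float:
    """Probability that a random positive outscores a random negative, ties
    counting one half (Mann-Whitney statistic)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC needs both classes")
    return float(roc_auc_score(labels, scores))


def pr_auc(labels, scores) -> float:
    """Average precision: sum of precision at each positive's recall step."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("PR AUC needs at least one positive")
    return float(average_precision_score(labels, scores))


def pearson(y_true, y_pred) -> float:
    return float(sps.pearsonr(np.asarray(y_true, float),
                              np.asarray(y_pred, float)).statistic)


def mae(y_true, y_pred) -> float:
    return float(np.mean(np.abs(np.asarray(y_true, float)
                                - np.asarray(y_pred, float))))


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test (unequal variances, two-sided).

    Returns (t, Welch-Satterthwaite df, p).  When both samples are constant
    with equal means the test is vacuous and (0, df, 1) is returned by
    convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        df = float(len(x) + len(y) - 2)
        if np.isclose(x.mean(), y.mean()):
            return 0.0, df, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), df, 0.0
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def benjamini_hochberg(pvals, alpha: float = 0.05
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Step-up false-discovery-rate control.

    Returns (reject flags, adjusted p-values).  Rejections are monotone in
    alpha: raising alpha never un-rejects a hypothesis.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    pvals = np.asarray(pvals, float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject, p_adj


@dataclass
class MetricsReport:
    """Metric values for one replicate of one model configuration."""

    model: str
    replicate: int
    metrics: dict[str, float] = field(default_factory=dict)


def classification_report(model: str, replicate: int, labels, scores
                          ) -> MetricsReport:
    return MetricsReport(model, replicate,
                         {"roc_auc": roc_auc(labels, scores),
                          "pr_auc": pr_auc(labels, scores)})


def regression_report(model: str, replicate: int, y_true, y_pred
                      ) -> MetricsReport:
    return MetricsReport(model, replicate,
                         {"pearson": pearson(y_true, y_pred),
                          "mae": mae(y_true, y_pred)})


def compare_models(reports: list[MetricsReport], alpha: float = 0.001
                   ) -> pd.DataFrame:
    """Pairwise Welch tests per metric with BH correction over the family.

    One row per (metric, model pair) with means, t, df, raw and adjusted p
    and the rejection flag, plus a ``winner`` column naming the flagged
    winner of that metric ('' when the best model is not significantly
    better than every competitor).
    """
    models = sorted({r.model for r in reports})
    metric_names = sorted({m for r in reports for m in r.metrics})
    by_model = {m: [r for r in reports if r.model == m] for m in models}
    for m, rs in by_model.items():
        if len(rs) < 2:
            raise ValueError(f"model {m!r} has fewer than 2 replicates")
        if any(set(r.metrics) != set(metric_names) for r in rs):
            raise ValueError(f"model {m!r} reports a mismatched metric set")
    rows = []
    for metric in metric_names:
        for a, b in combinations(models, 2):
            xa = [r.metrics[metric] for r in by_model[a]]
            xb = [r.metrics[metric] for r in by_model[b]]
            t, df, p = welch_t_test(xa, xb)
            rows.append({"metric": metric, "model_a": a, "model_b": b,
                         "mean_a": float(np.mean(xa)), "mean_b": float(np.mean(xb)),
                         "mean_diff": float(np.mean(xa) - np.mean(xb)),
                         "t": t, "df": df, "p": p})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    reject, p_adj = benjamini_hochberg(table["p"].to_numpy(), alpha)
    table["p_adj"] = p_adj
    table["significant"] = reject
    winners = []
    for metric in metric_names:
        sub = table[table["metric"] == metric]
        means = {m: np.mean([r.metrics[metric] for r in by_model[m]])
                 for m in models}
        best = (max if _HIGHER_BETTER.get(metric, True) else min)(means, key=means.get)
        beats_all = all(
            row.significant
            for row in sub.itertuples()
            if best in (row.model_a, row.model_b)
        )
        winners.append(best if beats_all and len(models) > 1 else "")
    table["winner"] = table["metric"].map(dict(zip(metric_names, winners)))
    return table
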