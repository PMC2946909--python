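"""ROC/AUC analysis, score summaries and between-group score comparison.

The ROC curve plots sensitivity (true-positive fraction) against
1 - specificity (false-positive fraction) over all score thresholds; the
area under it equals the Mann-Whitney concordance probability with ties
counted half, and is the threshold-free accuracy measure reported for every
panel. Confidence intervals use the DeLong covariance estimator of the AUC
variance with a normal-theory interval clipped to [0, 1] (Hanley-McNeil
available as an alternative). Score distributions are summarized as median
and interquartile range with the linear-interpolation quartile convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

from .biomarker_discovery import mann_whitney_p

__all__ = [
    "ROCResult",
    "roc_curve",
    "auc_confidence_interval",
    "summarize_scores",
    "compare_score_groups",
    "plot_roc",
]


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray  # sensitivity
    fpr: np.ndarray  # 1 - specificity
    auc: float
    n_pos: int
    n_neg: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    scores: np.ndarray = field(default_factory=lambda: np.array([]))
    labels: np.ndarray = field(default_factory=lambda: np.array([]))


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    uniq = np.unique(y)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, got {list(uniq)}")
    return (y == uniq[1]).astype(int)


def roc_curve(scores, labels) -> ROCResult:
    """ROC over all distinct thresholds, AUC as tie-aware concordance.

    ``labels`` may be any two values; the larger (sorted order) is the
    positive class, and larger scores are taken to indicate it.
    """
    s = np.asarray(scores, float)
    y = _as_binary(labels)
    fpr, tpr, thr = skm.roc_curve(y, s, drop_intermediate=False)
    auc = float(skm.roc_auc_score(y, s))
    return ROCResult(
        thresholds=thr,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        n_pos=int(y.sum()),
        n_neg=int((1 - y).sum()),
        scores=s,
        labels=y,
    )


def _delong_variance(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """DeLong variance of the AUC via placement values."""
    m, n = len(pos_scores), len(neg_scores)
    # V10_i: fraction of negatives each positive beats (ties half)
    diff = pos_scores[:, None] - neg_scores[None, :]
    win = (diff > 0) + 0.5 * (diff == 0)
    v10 = win.mean(axis=1)
    v01 = win.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def _hanley_mcneil_variance(auc: float, m: int, n: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    return (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)


def auc_confidence_interval(
    roc: ROCResult, level: float = 0.95, method: str = "delong"
) -> tuple[float, float]:
    """Normal-theory AUC confidence interval, clipped to [0, 1].

    ``method`` is ``"delong"`` (nonparametric covariance estimator,
    default) or ``"hanley_mcneil"`` (binormal-exponential approximation).
    Degenerate score vectors (all equal) yield the uninformative [0, 1]
    interval with a warning. Updates ``roc.ci_low`` / ``roc.ci_high``.
    """
    if roc.n_pos < 1 or roc.n_neg < 1:
        raise ValueError("need at least one sample per class")
    s, y = roc.scores, roc.labels
    if len(s) and np.all(s == s[0]):
        warnings.warn("all scores identical; AUC CI is uninformative")
        roc.ci_low, roc.ci_high = 0.0, 1.0
        return 0.0, 1.0
    if method == "delong":
        var = _delong_variance(s[y == 1], s[y == 0])
    elif method == "hanley_mcneil":
        var = _hanley_mcneil_variance(roc.auc, roc.n_pos, roc.n_neg)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    zq = stats.norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(max(var, 0.0))
    lo = float(np.clip(roc.auc - half, 0.0, 1.0))
    hi = float(np.clip(roc.auc + half, 0.0, 1.0))
    roc.ci_low, roc.ci_high = lo, hi
    return lo, hi


def summarize_scores(scores, group) -> pd.DataFrame:
    """Per-group median and quartiles (linear interpolation convention)."""
    df = pd.DataFrame({"score": np.asarray(scores, float), "group": np.asarray(group)})
    rows = []
    for g, sub in df.groupby("group", sort=True):
        q1, med, q3 = np.percentile(sub["score"], [25, 50, 75])
        rows.append({"group": g, "median": med, "q1": q1, "q3": q3, "n": len(sub)})
    return pd.DataFrame(rows).set_index("group")


def compare_score_groups(scores_a, scores_b) -> float:
    """Two-sided Mann-Whitney p for a difference in score distributions
    (same engine as panel-peptide validation)."""
    return mann_whitney_p(np.asarray(scores_a, float), np.asarray(scores_b, float))


def plot_roc(roc: ROCResult, path=None, title: str = "ROC"):
    """Plot the ROC curve; saves to ``path`` when given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc.fpr, roc.tpr, drawstyle="steps-post", label=f"AUC = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity (false positive fraction)")
    ax.set_ylabel("sensitivity (true positive fraction)")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
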