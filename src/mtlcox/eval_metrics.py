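"""Evaluation metrics for censored risk predictions.

Five metrics — concordance index, ROC AUC, sensitivity, specificity, Youden
index — plus the paired Wilcoxon signed-rank protocol used to compare methods
across disease x fold cells.

Comparable pairs for the C-index follow the usual right-censoring rule: the
pair (i, j) is comparable when subject i has an observed event and
time_i < time_j; censored-first pairs carry no ordering information and are
skipped.  The AUC path converts survival outcomes to binary labels at a fixed
horizon, excluding subjects censored before the horizon (their label is
unknown).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "c_index",
    "binarize_at_horizon",
    "roc_auc",
    "confusion_metrics",
    "paired_wilcoxon",
    "WilcoxonResult",
]


def c_index(scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's concordance index of risk scores against censored outcomes.

    Over comparable pairs (i has the event and time_i < time_j), the fraction
    with score_i > score_j; tied scores count 1/2.  Higher scores must mean
    higher risk (e.g. the Cox linear predictor x'beta).

    Raises
    ------
    ValueError
        If no pair is comparable.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).ravel().astype(int)
    n = len(scores)
    if not (len(time) == n == len(event)):
        raise ValueError("scores, time, event must have equal length")
    ev_idx = np.flatnonzero(event == 1)
    # pairwise, vectorized over event subjects; O(m * n) memory in blocks
    concordant = 0.0
    comparable = 0
    block = max(1, int(2e6 // max(n, 1)))
    for start in range(0, len(ev_idx), block):
        ii = ev_idx[start : start + block]
        comp = time[ii][:, None] < time[None, :]  # (m, n)
        s_i = scores[ii][:, None]
        concordant += np.sum(comp & (s_i > scores[None, :]))
        concordant += 0.5 * np.sum(comp & (s_i == scores[None, :]))
        comparable += int(comp.sum())
    if comparable == 0:
        raise ValueError("no comparable pairs; C-index undefined")
    return float(concordant / comparable)


def binarize_at_horizon(
    time: np.ndarray, event: np.ndarray, horizon: float
) -> tuple[np.ndarray, np.ndarray]:
    """Convert censored outcomes to binary labels at a fixed horizon.

    Positive: event observed at or before the horizon.  Negative: followed
    beyond the horizon without the event by then.  Censored before the horizon
    without an event: excluded (mask False) — their horizon status is unknown.

    Returns
    -------
    labels : int array (0/1), meaningful only where ``mask`` is True
    mask : boolean inclusion mask
    """
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).ravel().astype(int)
    positive = (event == 1) & (time <= horizon)
    negative = time > horizon
    mask = positive | negative
    labels = positive.astype(int)
    return labels, mask


@dataclass
class RocResult:
    auc: float
    cutoff: float
    youden_at_cutoff: float


def roc_auc(risk: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC AUC via the rank (Mann-Whitney) formulation, with the
    Youden-optimal cutoff.

    AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg) where R_pos is the sum
    of mid-ranks of the positive risks — identical to trapezoidal integration
    of the empirical ROC.  The cutoff is the risk threshold maximizing
    sensitivity + specificity - 1, scanning every observed risk value as a
    ">= threshold -> positive" rule.

    Raises
    ------
    ValueError
        If only one class is present.
    """
    risk = np.asarray(risk, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc undefined: only one class present")
    ranks = stats.rankdata(risk)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    thresholds = np.unique(risk)
    best_youden, best_cut = -np.inf, thresholds[0]
    for thr in thresholds:
        pred = risk >= thr
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        y = sens + spec - 1.0
        if y > best_youden:
            best_youden, best_cut = y, thr
    return RocResult(auc=float(auc), cutoff=float(best_cut), youden_at_cutoff=float(best_youden))


def confusion_metrics(
    risk: np.ndarray, labels: np.ndarray, cutoff: float
) -> dict[str, float]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP) and the Youden index
    (sensitivity + specificity - 1) of the rule risk >= cutoff -> positive."""
    risk = np.asarray(risk, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    pred = risk >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return {
        "sensitivity": sens,
        "specificity": spec,
        "youden": sens + spec - 1.0,
        "tp": tp,
        "fn": fn,
        "tn": tn,
        "fp": fp,
    }


@dataclass
class WilcoxonResult:
    p_value: float
    statistic: float
    n_pairs: int
    n_nonzero: int
    better: str  # which side has the larger values on average, or "none"
    all_zero: bool = False


def paired_wilcoxon(
    values_a: np.ndarray, values_b: np.ndarray, *, label_a: str = "A", label_b: str = "B"
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test on matched metric values.

    Pairs are matched cells (e.g. disease x fold).  Zero differences are
    dropped; the exact null distribution is used for small samples and the
    normal approximation with continuity correction otherwise (scipy's
    ``method='auto'``).  If every difference is zero the test is undefined and
    reported as p = 1 with ``all_zero=True``.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        return WilcoxonResult(
            p_value=1.0,
            statistic=np.nan,
            n_pairs=len(d),
            n_nonzero=0,
            better="none",
            all_zero=True,
        )
    res = stats.wilcoxon(
        nz, alternative="two-sided", zero_method="wilcox", correction=True, method="auto"
    )
    median_diff = float(np.median(nz))
    better = label_a if median_diff > 0 else (label_b if median_diff < 0 else "none")
    return WilcoxonResult(
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        n_pairs=len(d),
        n_nonzero=len(nz),
        better=better,
    )
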