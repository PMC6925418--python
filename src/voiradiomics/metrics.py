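"""ROC metrics: rank-statistic AUC, DeLong variance/CI and the DeLong test
for two correlated ROC curves.

The DeLong machinery uses placement values (structural components): for
scores ``s`` with positives P and negatives N, the placement of a positive
is the fraction of negatives it outscores (ties count half), and vice versa.
The AUC is the mean placement; its variance and the covariance between two
markers measured on the same subjects follow from the empirical covariance
of the placements.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    if not np.all(pos | neg):
        raise ValueError("labels must be binary 0/1")
    return pos, neg


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney U statistic (ties counted half)."""
    scores = np.asarray(scores, dtype=np.float64)
    pos, neg = _check_labels(labels)
    sp, sn = scores[pos], scores[neg]
    diff = sp[:, None] - sn[None, :]
    return float((np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0))
                 / (sp.size * sn.size))


def _placements(scores, pos, neg):
    """Placement values V10 (per positive) and V01 (per negative)."""
    sp, sn = scores[pos], scores[neg]
    diff = sp[:, None] - sn[None, :]
    win = (diff > 0).astype(np.float64) + 0.5 * (diff == 0)
    return win.mean(axis=1), 1.0 - win.mean(axis=0)


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC) for a single marker."""
    scores = np.asarray(scores, dtype=np.float64)
    pos, neg = _check_labels(labels)
    v10, v01 = _placements(scores, pos, neg)
    auc = float(v10.mean())
    m, n = v10.size, v01.size
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) + (v01.var(ddof=1) / n if n > 1 else 0.0)
    return auc, float(var)


def auc_confidence_interval(scores, labels, alpha: float = 0.05) -> tuple[float, float, float]:
    """(AUC, lower, upper): normal-approximation CI from the DeLong variance,
    clipped to [0, 1]."""
    auc, var = delong_variance(scores, labels)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return auc, float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def delong_test(scores_a, scores_b, labels) -> dict:
    """Two-sided DeLong test comparing two correlated AUCs on the same
    subjects.

    Returns a dict with ``auc_a``, ``auc_b``, ``z``, ``p`` and a
    ``degenerate`` flag; when the variance of the AUC difference vanishes
    (e.g. identical score vectors) the test is undefined and ``p = 1`` is
    reported with ``degenerate=True``.
    """
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    if scores_a.shape != scores_b.shape:
        raise ValueError("score vectors must cover the same subjects")
    pos, neg = _check_labels(labels)
    va10, va01 = _placements(scores_a, pos, neg)
    vb10, vb01 = _placements(scores_b, pos, neg)
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    m, n = va10.size, va01.size

    def cov(u, v, size):
        if size < 2:
            return 0.0
        return float(np.cov(u, v, ddof=1)[0, 1]) / size

    var_diff = (
        cov(va10, va10, m) + cov(vb10, vb10, m) - 2 * cov(va10, vb10, m)
        + cov(va01, va01, n) + cov(vb01, vb01, n) - 2 * cov(va01, vb01, n)
    )
    if var_diff <= 1e-16:
        return {"auc_a": auc_a, "auc_b": auc_b, "z": 0.0, "p": 1.0, "degenerate": True}
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return {"auc_a": auc_a, "auc_b": auc_b, "z": float(z), "p": float(p), "degenerate": False}


def classification_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Sensitivity, specificity and accuracy at a probability threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    pos, neg = _check_labels(labels)
    pred = scores >= threshold
    sens = float(pred[pos].mean())
    spec = float((~pred[neg]).mean())
    acc = float((pred == np.asarray(labels).astype(bool)).mean())
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc}


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity - 1 on the given data."""
    scores = np.asarray(scores, dtype=np.float64)
    pos, neg = _check_labels(labels)
    best_t, best_j = 0.5, -np.inf
    for t in np.unique(scores):
        sens = float((scores[pos] >= t).mean())
        spec = float((scores[neg] < t).mean())
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t
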