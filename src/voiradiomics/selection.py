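"""Two-stage feature selection on the training cohort.

Stage 1 — mRMR (maximum relevance, minimum redundancy) greedily ranks
features by mutual information with the class label, penalized by the mean
mutual information with the already-selected set (the MID criterion).
Mutual information is computed on features discretized to 3 levels at
mean +/- SD, in bits.

Stage 2 — the shortlist is ranked by maximizing the 0.632+ bootstrap AUC of
an incrementally grown feature set (default) or by the single-feature 0.632+
AUC ("univariate" mode).  The bootstrap draws class-stratified 63.2%
subsamples of the training cohort without replacement (the classic
with-replacement bootstrap, whose expected unique fraction is the same
0.632, is available behind ``with_replacement=True``); the internal
classifier is a fast ridge-regularized linear discriminant.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SelectionConfig:
    shortlist_size: int = 100
    final_size: int = 20
    n_bootstrap: int = 1000
    resample_fraction: float = 0.632
    mrmr_criterion: str = "MID"
    ranking_mode: str = "stepwise"  # {"stepwise", "univariate"}
    with_replacement: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.final_size <= self.shortlist_size):
            raise ValueError("need 0 < final_size <= shortlist_size")
        if not (0.0 < self.resample_fraction < 1.0):
            raise ValueError("resample_fraction must lie in (0, 1)")
        if self.ranking_mode not in ("stepwise", "univariate"):
            raise ValueError(f"unknown ranking mode {self.ranking_mode!r}")


@dataclass(frozen=True)
class SelectionResult:
    shortlist: tuple[str, ...]
    ranked: tuple[str, ...]
    step_scores: tuple[float, ...]  # 0.632+ AUC after each ranking step
    config: SelectionConfig

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "shortlist": list(self.shortlist),
            "ranked": list(self.ranked),
            "step_scores": list(self.step_scores),
            "config": asdict(self.config),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    def overlap_with(self, other: "SelectionResult") -> float:
        """Fraction of this result's final features shared with another's."""
        if not self.ranked:
            return 0.0
        return len(set(self.ranked) & set(other.ranked)) / len(self.ranked)


# ---------------------------------------------------------------------------
# mRMR
# ---------------------------------------------------------------------------

def _discretize_3level(x: np.ndarray) -> np.ndarray:
    """3-level discretization at mean +/- SD (inclusive boundaries, so a
    binary feature maps onto the outer levels rather than collapsing)."""
    mu, sd = x.mean(), x.std()
    out = np.ones(x.shape, dtype=np.int64)
    out[x <= mu - sd] = 0
    out[x >= mu + sd] = 2
    return out


def mutual_information_bits(a: np.ndarray, b: np.ndarray) -> float:
    """MI between two small discrete variables, in bits."""
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb) / a.size
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])))


def mrmr_rank(table: pd.DataFrame, labels, m: int = 100,
              feature_names: list[str] | None = None) -> list[str]:
    """Greedy MID-criterion mRMR ranking of the top ``m`` features.

    The first pick maximizes I(f; class); each later pick maximizes
    I(f; class) - mean_{g in selected} I(f; g).  Ties break toward the
    earlier column.  Constant features have I = 0 and are eligible but never
    preferred over informative ones.
    """
    if feature_names is None:
        feature_names = [c for c in table.columns if c not in ("label", "split")]
    y = np.asarray(labels).astype(np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = table[feature_names].to_numpy(dtype=np.float64)
    n_feat = X.shape[1]
    if n_feat < m:
        import warnings
        warnings.warn(f"only {n_feat} features available; returning all")
        m = n_feat

    disc = np.stack([_discretize_3level(X[:, j]) for j in range(n_feat)], axis=1)
    relevance = np.array([mutual_information_bits(disc[:, j], y) for j in range(n_feat)])

    selected: list[int] = []
    redundancy_sum = np.zeros(n_feat)
    remaining = np.ones(n_feat, dtype=bool)
    mi_cache: dict[int, np.ndarray] = {}
    for step in range(m):
        if step == 0:
            scores = relevance.copy()
        else:
            scores = relevance - redundancy_sum / step
        scores[~remaining] = -np.inf
        pick = int(np.argmax(scores))  # argmax takes the first max: stable tie-break
        selected.append(pick)
        remaining[pick] = False
        if step < m - 1:
            mi_with_pick = np.array([
                mutual_information_bits(disc[:, j], disc[:, pick]) if remaining[j] else 0.0
                for j in range(n_feat)
            ])
            redundancy_sum += mi_with_pick
    return [feature_names[j] for j in selected]


# ---------------------------------------------------------------------------
# 0.632+ bootstrap AUC
# ---------------------------------------------------------------------------

class _RidgeLda:
    """Ridge-regularized linear discriminant scorer (selection stage only;
    the final model is always the random forest)."""

    def __init__(self, ridge: float = 1e-3):
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_RidgeLda":
        X0, X1 = X[y == 0], X[y == 1]
        mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
        n0, n1 = len(X0), len(X1)
        d = X.shape[1]
        cov = np.zeros((d, d))
        if n0 > 1:
            cov += (n0 - 1) * np.cov(X0, rowvar=False).reshape(d, d)
        if n1 > 1:
            cov += (n1 - 1) * np.cov(X1, rowvar=False).reshape(d, d)
        cov /= max(n0 + n1 - 2, 1)
        lam = self.ridge * max(np.trace(cov) / d, 1e-12)
        try:
            self.w_ = np.linalg.solve(cov + lam * np.eye(d), mu1 - mu0)
        except np.linalg.LinAlgError:
            self.w_ = mu1 - mu0  # degenerate covariance: fall back to mean difference
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return X @ self.w_


def _fast_auc(scores: np.ndarray, y: np.ndarray) -> float:
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores))
    ranks[order] = np.arange(1, len(scores) + 1)
    # midranks for ties
    s_sorted = scores[order]
    i = 0
    while i < len(s_sorted):
        j = i
        while j + 1 < len(s_sorted) and s_sorted[j + 1] == s_sorted[i]:
            j += 1
        if j > i:
            ranks[order[i : j + 1]] = 0.5 * (i + j) + 1
        i = j + 1
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        return 0.5
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def _stratified_subsample(y: np.ndarray, fraction: float, rng: np.random.Generator,
                          with_replacement: bool) -> np.ndarray:
    """Class-stratified draw of ~fraction of the indices; remainder = test."""
    idx = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(y == cls)
        k = max(int(np.ceil(fraction * len(cls_idx))), 1)
        k = min(k, len(cls_idx) - 1) if len(cls_idx) > 1 else 1
        if with_replacement:
            idx.append(rng.choice(cls_idx, size=len(cls_idx), replace=True))
        else:
            idx.append(rng.choice(cls_idx, size=k, replace=False))
    return np.concatenate(idx)


def bootstrap_auc_632plus(X: np.ndarray, y: np.ndarray, config: SelectionConfig,
                          rng: np.random.Generator | None = None,
                          splits: list[np.ndarray] | None = None) -> float:
    """The 0.632+ bootstrap AUC of a feature subset.

    AUC_app is the apparent AUC (train = score = full training set);
    AUC_boot averages the held-out AUC over class-stratified resamples.
    With AUC' = max(AUC_boot, 0.5), the relative overfitting rate is
    R = clip((AUC_app - AUC') / (AUC_app - 0.5), 0, 1) (R = 0 when
    AUC_app <= 0.5), the weight w = 0.632 / (1 - 0.368 R), and the estimate
    is (1 - w) AUC_app + w AUC'.

    ``splits`` allows reusing one set of bootstrap index draws across many
    candidate subsets (common random numbers for fair stepwise comparison).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y).astype(np.int64)

    clf = _RidgeLda().fit(X, y)
    auc_app = _fast_auc(clf.decision_function(X), y)

    if splits is None:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        splits = [
            _stratified_subsample(y, config.resample_fraction, rng, config.with_replacement)
            for _ in range(config.n_bootstrap)
        ]
    all_idx = np.arange(len(y))
    aucs = []
    for train_idx in splits:
        test_idx = np.setdiff1d(all_idx, train_idx)
        if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
            aucs.append(0.5)  # degenerate split; stratification makes this rare
            continue
        fit = _RidgeLda().fit(X[train_idx], y[train_idx])
        aucs.append(_fast_auc(fit.decision_function(X[test_idx]), y[test_idx]))
    auc_boot = float(np.mean(aucs))

    return combine_632plus(auc_app, auc_boot)


def combine_632plus(auc_app: float, auc_boot: float) -> float:
    """The 0.632+ combination of apparent and bootstrap AUCs."""
    auc_prime = max(auc_boot, 0.5)
    if auc_app <= 0.5:
        r = 0.0
    else:
        r = np.clip((auc_app - auc_prime) / (auc_app - 0.5), 0.0, 1.0)
    w = 0.632 / (1.0 - 0.368 * r)
    return float((1.0 - w) * auc_app + w * auc_prime)


def rank_top_features(shortlist: list[str], table: pd.DataFrame, labels,
                      config: SelectionConfig) -> SelectionResult:
    """Rank the mRMR shortlist down to the final top-predictive set.

    Stepwise (default): grow the set greedily, at each step adding the
    shortlist feature that maximizes the 0.632+ AUC of the augmented set.
    Univariate: rank features by their single-feature 0.632+ AUC.  Ties break
    by shortlist (mRMR) order.  Fully deterministic given ``config.seed``.
    """
    y = np.asarray(labels).astype(np.int64)
    X_all = table[shortlist].to_numpy(dtype=np.float64)
    n_final = min(config.final_size, len(shortlist))
    ss = np.random.SeedSequence(config.seed)

    if config.ranking_mode == "univariate":
        rng = np.random.default_rng(ss)
        splits = [
            _stratified_subsample(y, config.resample_fraction, rng, config.with_replacement)
            for _ in range(config.n_bootstrap)
        ]
        scores = [
            bootstrap_auc_632plus(X_all[:, j], y, config, splits=splits)
            for j in range(len(shortlist))
        ]
        order = sorted(range(len(shortlist)), key=lambda j: (-scores[j], j))[:n_final]
        return SelectionResult(
            shortlist=tuple(shortlist),
            ranked=tuple(shortlist[j] for j in order),
            step_scores=tuple(scores[j] for j in order),
            config=config,
        )

    selected: list[int] = []
    step_scores: list[float] = []
    step_seeds = ss.spawn(n_final)
    for step in range(n_final):
        rng = np.random.default_rng(step_seeds[step])
        splits = [
            _stratified_subsample(y, config.resample_fraction, rng, config.with_replacement)
            for _ in range(config.n_bootstrap)
        ]
        best_j, best_score = -1, -np.inf
        for j in range(len(shortlist)):
            if j in selected:
                continue
            cols = selected + [j]
            score = bootstrap_auc_632plus(X_all[:, cols], y, config, splits=splits)
            if score > best_score:  # strict: ties keep the earlier shortlist index
                best_score, best_j = score, j
        selected.append(best_j)
        step_scores.append(best_score)
    return SelectionResult(
        shortlist=tuple(shortlist),
        ranked=tuple(shortlist[j] for j in selected),
        step_scores=tuple(step_scores),
        config=config,
    )
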