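"""Radiomics classification models, statsmodels-style.

:class:`RadiomicsModel` is built from a cohort feature table (training
split); ``fit()`` runs the full modeling chain — mRMR shortlist, 0.632+
bootstrap ranking, then 20 incremental random-forest models whose feature
count is chosen by stratified 10-fold cross-validated AUC — and returns a
:class:`RadiomicsResults` carrying the estimates, their uncertainties and a
``summary()`` table.  Evaluation on an independent validation table yields
AUC with DeLong 95% CI, sensitivity/specificity/accuracy and DeLong
comparisons between variants; :func:`transfer_matrix` crosses models and
validation delineations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from . import metrics
from .selection import SelectionConfig, SelectionResult, mrmr_rank, rank_top_features


@dataclass(frozen=True)
class ModelSpec:
    """Random-forest modeling settings: 150 trees, stratified 10-fold CV,
    incremental feature counts 1..max_features."""

    n_trees: int = 150
    cv_folds: int = 10
    max_features: int = 20
    threshold: str | float = 0.5  # probability cutoff, or "youden" (training-set)
    seed: int = 0


class RadiomicsModel:
    """A delineation-variant radiomics classifier specification.

    Parameters
    ----------
    endog : array-like of {0, 1}
        Class labels of the training subjects.
    exog : DataFrame
        Training feature table (subjects x features).
    selection : SelectionConfig, optional
    spec : ModelSpec, optional
    variant : str
        Delineation-variant tag carried into reports.
    """

    def __init__(self, endog, exog: pd.DataFrame,
                 selection: SelectionConfig | None = None,
                 spec: ModelSpec | None = None,
                 variant: str = "baseline"):
        self.endog = np.asarray(endog).astype(np.int64)
        if set(np.unique(self.endog)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(self.endog)) < 2:
            raise ValueError("both classes must be present in training data")
        self.exog = exog
        self.selection = selection or SelectionConfig()
        self.spec = spec or ModelSpec()
        self.variant = variant

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, label_col: str = "label",
                       split_col: str = "split", **kwargs) -> "RadiomicsModel":
        """Build from a cohort table with label/split columns, using the
        training split only."""
        train = table[table[split_col] == "training"] if split_col in table else table
        feats = [c for c in table.columns if c not in (label_col, split_col)]
        return cls(train[label_col].to_numpy(), train[feats], **kwargs)

    def fit(self) -> "RadiomicsResults":
        """Run selection and incremental modeling; returns the results."""
        names = list(self.exog.columns)
        shortlist = mrmr_rank(self.exog, self.endog,
                              m=min(self.selection.shortlist_size, len(names)),
                              feature_names=names)
        sel = rank_top_features(shortlist, self.exog, self.endog, self.selection)
        ranked = list(sel.ranked)

        cv_trace = self._incremental_cv(ranked)
        chosen_k = int(np.argmax(cv_trace)) + 1  # first max: ties favor smaller k

        features = ranked[:chosen_k]
        forest = RandomForestClassifier(
            n_estimators=self.spec.n_trees, random_state=self.spec.seed & 0x7FFFFFFF
        )
        forest.fit(self.exog[features].to_numpy(dtype=np.float64), self.endog)

        threshold = self.spec.threshold
        if threshold == "youden":
            train_scores = forest.predict_proba(
                self.exog[features].to_numpy(dtype=np.float64))[:, 1]
            threshold = metrics.youden_threshold(train_scores, self.endog)

        return RadiomicsResults(
            model=self, selection_result=sel, cv_auc_trace=tuple(cv_trace),
            chosen_k=chosen_k, features=tuple(features), forest=forest,
            threshold=float(threshold),
        )

    def _incremental_cv(self, ranked: list[str]) -> list[float]:
        """Mean stratified-CV AUC of the top-k feature forest, k = 1..K."""
        y = self.endog
        n_min_class = int(min(np.bincount(y)))
        folds = self.spec.cv_folds
        if n_min_class < folds:
            import warnings
            warnings.warn(f"smallest class has {n_min_class} subjects; "
                          f"reducing CV folds from {folds}")
            folds = max(n_min_class, 2)
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=self.spec.seed & 0x7FFFFFFF)
        splits = list(skf.split(np.zeros(len(y)), y))
        trace = []
        for k in range(1, min(self.spec.max_features, len(ranked)) + 1):
            X = self.exog[ranked[:k]].to_numpy(dtype=np.float64)
            fold_aucs = []
            for f, (tr, te) in enumerate(splits):
                if len(np.unique(y[te])) < 2:
                    continue
                rf = RandomForestClassifier(
                    n_estimators=self.spec.n_trees,
                    random_state=(self.spec.seed + 1000 * k + f) & 0x7FFFFFFF,
                )
                rf.fit(X[tr], y[tr])
                fold_aucs.append(metrics.auc_mann_whitney(rf.predict_proba(X[te])[:, 1], y[te]))
            trace.append(float(np.mean(fold_aucs)))
        return trace


@dataclass(frozen=True)
class EvaluationRow:
    """One Table-style evaluation line: AUC with 95% CI plus operating-point
    metrics on the validation cohort."""

    variant: str
    k: int
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_validation: int


@dataclass(frozen=True)
class RadiomicsResults:
    """Fitted radiomics model: selected features, CV trace and final forest."""

    model: RadiomicsModel
    selection_result: SelectionResult
    cv_auc_trace: tuple[float, ...]
    chosen_k: int
    features: tuple[str, ...]
    forest: RandomForestClassifier
    threshold: float

    @property
    def variant(self) -> str:
        return self.model.variant

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in table.columns]
        if missing:
            raise KeyError(f"validation table lacks model features: {missing[:5]}")
        return self.forest.predict_proba(table[list(self.features)].to_numpy(dtype=np.float64))[:, 1]

    def evaluate(self, table: pd.DataFrame, labels=None) -> EvaluationRow:
        """Evaluate on an independent validation table."""
        if labels is None:
            labels = table["label"].to_numpy()
        labels = np.asarray(labels).astype(np.int64)
        if len(np.unique(labels)) < 2:
            raise ValueError("validation cohort must contain both classes")
        scores = self.predict_proba(table)
        auc, lo, hi = metrics.auc_confidence_interval(scores, labels)
        cls = metrics.classification_metrics(scores, labels, self.threshold)
        return EvaluationRow(
            variant=self.variant, k=self.chosen_k, auc=auc, ci_low=lo, ci_high=hi,
            sensitivity=cls["sensitivity"], specificity=cls["specificity"],
            accuracy=cls["accuracy"], n_validation=len(labels),
        )

    def compare(self, other: "RadiomicsResults", table: pd.DataFrame,
                other_table: pd.DataFrame | None = None, labels=None) -> dict:
        """DeLong test of this model's validation AUC against another model's
        on the same subjects (tables may come from different delineations)."""
        if other_table is None:
            other_table = table
        if labels is None:
            labels = table["label"].to_numpy()
        return metrics.delong_test(
            self.predict_proba(table), other.predict_proba(other_table),
            np.asarray(labels).astype(np.int64),
        )

    def summary(self) -> str:
        """Human-readable fit summary in the spirit of statsmodels results."""
        lines = [
            "Radiomics random-forest model",
            "=" * 46,
            f"variant:             {self.variant}",
            f"training subjects:   {len(self.model.endog)}"
            f" ({int(self.model.endog.sum())} positive)",
            f"candidate features:  {self.model.exog.shape[1]}",
            f"mRMR shortlist:      {len(self.selection_result.shortlist)}",
            f"ranked features:     {len(self.selection_result.ranked)}"
            f" ({self.model.selection.ranking_mode} 0.632+ ranking)",
            f"chosen k (CV AUC):   {self.chosen_k}"
            f"  (mean CV AUC {self.cv_auc_trace[self.chosen_k - 1]:.3f})",
            f"forest:              {self.model.spec.n_trees} trees,"
            f" threshold {self.threshold:g}",
            "-" * 46,
            "rank  feature                          cv/step",
        ]
        for i, feat in enumerate(self.features):
            step = self.selection_result.step_scores[i]
            lines.append(f"{i + 1:>4}  {feat[:32]:<32} {step:7.3f}")
        return "\n".join(lines)


def fit_variant_models(tables: dict[str, pd.DataFrame],
                       selection: SelectionConfig | None = None,
                       spec: ModelSpec | None = None) -> dict[str, RadiomicsResults]:
    """Fit one model per delineation variant from its cohort table."""
    out = {}
    for variant, table in tables.items():
        model = RadiomicsModel.from_dataframe(table, variant=variant,
                                              selection=selection, spec=spec)
        out[variant] = model.fit()
    return out


def transfer_matrix(results: dict[str, RadiomicsResults],
                    validation_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Variant x variant transfer AUCs.

    Entry (d, d') is the AUC of the model trained on delineation d applied
    to validation features extracted from delineation d' (using d's selected
    feature names).  The diagonal reproduces each model's own validation AUC.
    """
    variants = list(results)
    mat = pd.DataFrame(index=variants, columns=variants, dtype=np.float64)
    for d, res in results.items():
        for d2 in variants:
            table = validation_tables[d2]
            labels = table["label"].to_numpy().astype(np.int64)
            mat.loc[d, d2] = metrics.auc_mann_whitney(res.predict_proba(table), labels)
    mat.index.name = "model_variant"
    return mat
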