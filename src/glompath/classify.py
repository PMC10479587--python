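"""Feature selection and glomerulus-level classification.

Feature importance is the mean decrease in Gini impurity from a random
forest (500 trees, sqrt(p) features per split, fixed seed); the top-k
features (k = 10 by default) then feed a linear discriminant analysis (LDA)
classifier whose posterior probabilities drive both the glomerulus label
(argmax) and the downstream patient-level aggregation.

Model selection follows the patient-grouped protocol: data are split by
patient (never splitting one patient's glomeruli across folds or across the
train/test boundary), with five-fold cross-validation on the training
portion and a stratified 67/33 patient-level holdout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.pipeline import Pipeline

BFE_CLASSES = ("MCD", "MN", "TBMN")

META_COLUMNS = ("patient_id", "glom_id", "label")


class GiniImportanceSelector(SelectorMixin, BaseEstimator):
    """Select the top-k features by random-forest Gini importance.

    Parameters
    ----------
    k : int — number of features to keep (<= n_features).
    n_estimators : int — forest size used to estimate importances.
    random_state : int — forest seed; fixed seed => deterministic ranking.

    Attributes
    ----------
    importances_ : ndarray (n_features,) — normalized (sum 1) importances.
    ranking_ : ndarray (n_features,) — column indices in descending
        importance; ties broken by column (registry) order.
    selected_idx_ : ndarray (k,) — the selected columns, ranking order.
    """

    def __init__(self, k: int = 10, n_estimators: int = 500, random_state: int = 0):
        self.k = k
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.k > X.shape[1]:
            raise ValueError(f"k={self.k} exceeds n_features={X.shape[1]}")
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 classes")
        forest = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features="sqrt",
            random_state=self.random_state,
            n_jobs=1,
        ).fit(X, y)
        imp = forest.feature_importances_
        s = imp.sum()
        self.importances_ = imp / s if s > 0 else imp
        # stable sort on negated importances -> ties keep column order
        self.ranking_ = np.argsort(-self.importances_, kind="stable")
        self.selected_idx_ = self.ranking_[: self.k]
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_idx_] = True
        return mask

    def transform(self, X):
        # keep ranking order (not column order) so downstream models see
        # features ordered by importance
        return np.asarray(X)[:, self.selected_idx_]


def make_lda() -> LinearDiscriminantAnalysis:
    """LDA with a least-squares pooled-covariance solve.

    The lsqr solver is robust to singular pooled covariance (few samples vs
    many features after selection), while producing standard posterior
    probabilities.
    """
    return LinearDiscriminantAnalysis(solver="lsqr")


def make_bfe_classifier(top_k: int = 10, seed: int = 0) -> Pipeline:
    """Gini-importance selection -> LDA, as one sklearn Pipeline."""
    return Pipeline(
        [
            ("select", GiniImportanceSelector(k=top_k, random_state=seed)),
            ("lda", make_lda()),
        ]
    )


# ---------------------------------------------------------------------------
# thin functional wrappers


def gini_rank(X: pd.DataFrame, y, seed: int = 0) -> pd.Series:
    """Feature names ranked by descending Gini importance.

    Returns a Series (index = feature name, value = normalized importance)
    in ranking order; ties break by column order for reproducibility.
    """
    sel = GiniImportanceSelector(k=X.shape[1], random_state=seed).fit(X.to_numpy(), y)
    names = np.asarray(X.columns)[sel.ranking_]
    return pd.Series(sel.importances_[sel.ranking_], index=names)


def select_top_k(ranking: pd.Series, k: int = 10) -> list[str]:
    """First k feature names of a ranking."""
    if k <= 0:
        raise ValueError("k must be positive")
    return list(ranking.index[:k])


def fit_lda(X, labels) -> LinearDiscriminantAnalysis:
    """Fit the LDA classifier on an already-selected feature subset."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("LDA needs at least 2 classes")
    return make_lda().fit(np.asarray(X, dtype=np.float64), labels)


def predict_proba(model: LinearDiscriminantAnalysis, rows) -> np.ndarray:
    return model.predict_proba(np.asarray(rows, dtype=np.float64))


# ---------------------------------------------------------------------------
# data handling


def split_feature_table(table: pd.DataFrame):
    """(X DataFrame, y labels, groups patient ids) from a feature table."""
    feature_cols = [c for c in table.columns if c not in META_COLUMNS]
    return table[feature_cols], table["label"].to_numpy(), table["patient_id"].to_numpy()


def patient_grouped_cv(
    table: pd.DataFrame, n_folds: int = 5, seed: int = 0, top_k: int = 10
) -> dict:
    """Patient-grouped k-fold CV of the selection + LDA pipeline.

    Folds partition patients; feature ranking and selection are re-fit on
    each training fold only (no leakage of held-out labels into selection).
    Returns per-fold glomerulus-level accuracies and their mean and sd.
    """
    X, y, groups = split_feature_table(table)
    n_patients = len(np.unique(groups))
    if n_patients < n_folds:
        raise ValueError(f"{n_patients} patients < {n_folds} folds")
    Xa = X.to_numpy(dtype=np.float64)
    # grouped by patient AND stratified by disease, so every training fold
    # sees all three classes even in small cohorts
    cv = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_acc = []
    fold_info = []
    for tr, te in cv.split(Xa, y, groups):
        clf = make_bfe_classifier(top_k=top_k, seed=seed)
        clf.fit(Xa[tr], y[tr])
        acc = float((clf.predict(Xa[te]) == y[te]).mean())
        fold_acc.append(acc)
        fold_info.append(
            {
                "train_patients": sorted(set(groups[tr])),
                "test_patients": sorted(set(groups[te])),
                "accuracy": acc,
            }
        )
    fold_acc = np.asarray(fold_acc)
    return {
        "fold_accuracies": fold_acc.tolist(),
        "mean_accuracy": float(fold_acc.mean()),
        "sd_accuracy": float(fold_acc.std()),
        "folds": fold_info,
    }


def holdout_split(manifest: pd.DataFrame, test_fraction: float = 1 / 3, seed: int = 0):
    """Stratified patient-level train/test split.

    Patients are split per disease (round(n * test_fraction) to test), so a
    45-patient cohort with 15 per disease yields 30 train / 15 test.
    """
    rng = np.random.default_rng(seed)
    patients = manifest[["patient_id", "label"]].drop_duplicates().sort_values("patient_id")
    train, test = [], []
    for label in sorted(patients["label"].unique()):
        ids = patients.loc[patients["label"] == label, "patient_id"].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        n_test = int(round(len(ids) * test_fraction))
        test.extend(ids[:n_test])
        train.extend(ids[n_test:])
    return sorted(train), sorted(test)


def glomerulus_predictions(
    clf: Pipeline, table: pd.DataFrame, classes=BFE_CLASSES
) -> pd.DataFrame:
    """Per-glomerulus posterior triplets and argmax labels as a DataFrame."""
    X, y, _ = split_feature_table(table)
    proba = clf.predict_proba(X.to_numpy(dtype=np.float64))
    order = [list(clf.classes_).index(c) for c in classes]
    proba = proba[:, order]
    out = table[["glom_id", "patient_id"]].copy()
    for i, c in enumerate(classes):
        out[f"p_{c}"] = proba[:, i]
    out["predicted"] = [classes[i] for i in np.argmax(proba, axis=1)]
    out["true"] = y
    return out
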