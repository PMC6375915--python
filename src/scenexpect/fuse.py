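"""Late fusion of detector confidence scores with predicted context priors.

A detector assigns each scene a confidence score for a target category.
Expectation models fitted on behavioural ratings predict contextual priors
(likelihood, location, scale, aspect) for the same scenes from coarse
features alone. Late fusion concatenates score and priors into a short
feature vector and trains a cross-validated linear discriminant to decide
target presence; gains over the score-only baseline quantify how much
label information the priors carry beyond the detector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .expect import ExpectationResults

__all__ = [
    "PRIOR_RESPONSES",
    "predict_priors",
    "FusedClassifier",
    "FusionResults",
    "roc_curve",
    "auc_score",
    "augmentation_table",
]

PRIOR_RESPONSES = ("likelihood", "x", "y", "area", "aspect")


def predict_priors(models: Mapping[str, ExpectationResults],
                   channels: Mapping[str, pd.DataFrame] | pd.DataFrame,
                   ) -> pd.DataFrame:
    """Predicted contextual priors for novel scenes.

    ``models`` maps response names to fitted expectation results;
    ``channels`` maps channel names to feature frames for the novel scenes
    (a bare DataFrame is treated as the coarse channel ``C``). Returns one
    column per response, indexed by scene.
    """
    if isinstance(channels, pd.DataFrame):
        channels = {"C": channels}
    out = {}
    for resp, res in models.items():
        out[resp] = res.predict(channels)
    return pd.DataFrame(out)


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC points with thresholds at every unique score plus the endpoints."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = metrics.roc_curve(labels, scores, drop_intermediate=False)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal area under the ROC curve."""
    roc = roc_curve(scores, labels)
    return float(np.trapezoid(roc["tpr"], roc["fpr"]))


@dataclass
class FusionResults:
    """Cross-validated fused-classifier performance."""

    feature_cols: tuple[str, ...]
    fold_accuracies: np.ndarray
    oof_score: pd.Series          # out-of-fold discriminant values
    oof_prediction: pd.Series
    labels: pd.Series
    n_folds: int
    seed: int

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    @property
    def roc(self) -> pd.DataFrame:
        return roc_curve(self.oof_score.to_numpy(), self.labels.to_numpy())

    @property
    def auc(self) -> float:
        return auc_score(self.oof_score.to_numpy(), self.labels.to_numpy())

    def tpr_at(self, fpr_grid: np.ndarray) -> np.ndarray:
        """Interpolated true-positive rate at the given false-positive rates."""
        roc = self.roc
        return np.interp(fpr_grid, roc["fpr"].to_numpy(), roc["tpr"].to_numpy())

    def summary(self) -> str:
        return ("Fused linear-discriminant classifier\n"
                f"  features: {', '.join(self.feature_cols)}\n"
                f"  {self.n_folds}-fold CV accuracy: "
                f"{self.accuracy_mean:.4f} +/- {self.accuracy_sd:.4f}\n"
                f"  AUC (out-of-fold discriminant): {self.auc:.4f}")


class FusedClassifier:
    """Linear discriminant on a detector score and optional prior columns.

    Parameters
    ----------
    table : DataFrame
        Evaluation table with a binary label column and the feature columns.
    feature_cols : sequence of str
        Columns entering the classifier; ``("score",)`` is the baseline.
    n_folds, seed : int
        Stratified cross-validation setup; folds and results are
        deterministic under a fixed seed.

    The discriminant uses a pooled covariance with empirical class priors;
    features are z-scored with training-fold statistics (the discriminant is
    affine-invariant, so this is for numerical conditioning). A singular
    pooled covariance is handled by the SVD solver's ridge-like tolerance.
    """

    def __init__(self, table: pd.DataFrame,
                 feature_cols: Sequence[str] = ("score",),
                 label_col: str = "label", n_folds: int = 5, seed: int = 0):
        if not feature_cols:
            raise ValueError("feature_cols must be non-empty")
        missing = [c for c in feature_cols if c not in table.columns]
        if missing:
            raise ValueError(f"table lacks feature columns {missing}")
        labels = table[label_col].to_numpy()
        classes, counts = np.unique(labels, return_counts=True)
        if len(classes) != 2:
            raise ValueError("labels must contain exactly two classes")
        if counts.min() < 10:
            raise ValueError("need at least 10 scenes per class")
        if table[list(feature_cols)].isna().any().any():
            raise ValueError("missing values in feature columns")
        self.table = table
        self.feature_cols = tuple(feature_cols)
        self.label_col = label_col
        self.n_folds = n_folds
        self.seed = seed

    def fit(self) -> FusionResults:
        x = self.table[list(self.feature_cols)].to_numpy(dtype=float)
        y = self.table[self.label_col].to_numpy()
        index = (self.table["scene_id"]
                 if "scene_id" in self.table.columns else self.table.index)
        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                              random_state=self.seed)
        n = len(y)
        oof_score = np.empty(n)
        oof_pred = np.empty(n, dtype=y.dtype)
        accs = []
        for train_idx, test_idx in skf.split(x, y):
            scaler = StandardScaler().fit(x[train_idx])
            lda = LinearDiscriminantAnalysis(solver="svd")
            lda.fit(scaler.transform(x[train_idx]), y[train_idx])
            xt = scaler.transform(x[test_idx])
            oof_score[test_idx] = lda.decision_function(xt)
            pred = lda.predict(xt)
            oof_pred[test_idx] = pred
            accs.append(float(np.mean(pred == y[test_idx])))
        idx = pd.Index(index, name="scene_id")
        return FusionResults(
            feature_cols=self.feature_cols,
            fold_accuracies=np.asarray(accs),
            oof_score=pd.Series(oof_score, index=idx, name="discriminant"),
            oof_prediction=pd.Series(oof_pred, index=idx, name="prediction"),
            labels=pd.Series(y, index=idx, name="label"),
            n_folds=self.n_folds, seed=self.seed)


#: The standard augmentation grid: baseline plus prior combinations.
DEFAULT_CONFIG_GRID: dict[str, tuple[str, ...]] = {
    "baseline": (),
    "+likelihood": ("likelihood",),
    "+y": ("y",),
    "+area": ("area",),
    "+likelihood+y+area": ("likelihood", "y", "area"),
    "+all": PRIOR_RESPONSES,
}


def augmentation_table(table: pd.DataFrame,
                       priors: pd.DataFrame,
                       config_grid: Mapping[str, Sequence[str]] | None = None,
                       detector_cols: Sequence[str] = ("score",),
                       label_col: str = "label",
                       n_folds: int = 5, seed: int = 0,
                       ) -> pd.DataFrame:
    """Accuracy of score-plus-priors classifiers across a config grid.

    ``priors`` is indexed by scene_id with one column per prior response.
    The grid maps config names to tuples of prior columns; the empty tuple
    is the score-only baseline and must be present. Deltas are in
    percentage points versus the baseline of the same detector column.
    """
    grid = dict(config_grid) if config_grid is not None else dict(DEFAULT_CONFIG_GRID)
    if not any(len(v) == 0 for v in grid.values()):
        raise ValueError("config grid must include the score-only baseline")
    merged = table.merge(priors, left_on="scene_id", right_index=True,
                         how="left", validate="one_to_one")
    rows = []
    for det in detector_cols:
        base_acc = None
        for name, prior_cols in grid.items():
            feats = (det, *prior_cols)
            res = FusedClassifier(merged, feature_cols=feats,
                                  label_col=label_col, n_folds=n_folds,
                                  seed=seed).fit()
            if len(prior_cols) == 0:
                base_acc = res.accuracy_mean
            rows.append({
                "detector": det, "config": name,
                "features": "+".join(feats),
                "accuracy_mean": res.accuracy_mean,
                "accuracy_sd": res.accuracy_sd,
                "auc": res.auc,
            })
        for row in rows:
            if row["detector"] == det and "delta_points" not in row:
                row["delta_points"] = 100.0 * (row["accuracy_mean"] - base_acc)
    return pd.DataFrame(rows)
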