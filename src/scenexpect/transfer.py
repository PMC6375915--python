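"""Transfer of car/person priors to other object categories.

Objects that co-occur with cars or people (benches with people, signage
with cars) should benefit from being fused with car/person context priors
even though no human ratings exist for them. Two statistics quantify this:

* the association index ``|p(object | anchor present) - p(object)|``,
  a [0, 1] measure of co-occurrence coupling between an object category and
  an anchor category (car or person), averaged over the two anchors;
* correlations of the fused-accuracy improvement with (a) the object's
  baseline detector accuracy (expected negative: weak detectors gain more)
  and (b) its mean association index (expected positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fuse import FusedClassifier
from .synth import EvalSet

__all__ = [
    "association_index",
    "association_table",
    "benefit_correlation",
    "transfer_experiment",
    "TransferResult",
]

ANCHORS = ("car", "person")


def association_index(presence: pd.DataFrame, obj: str, anchor: str) -> float:
    """``|p(object | anchor present) - p(object)|`` by direct counting."""
    for col in (obj, anchor):
        if col not in presence.columns:
            raise ValueError(f"presence matrix lacks column {col!r}")
    a = presence[anchor].to_numpy()
    o = presence[obj].to_numpy()
    if a.sum() == 0:
        raise ValueError(f"anchor {anchor!r} is never present")
    p_obj = o.mean()
    p_cond = o[a == 1].mean()
    return float(abs(p_cond - p_obj))


def association_table(presence: pd.DataFrame,
                      objects: Sequence[str] | None = None,
                      anchors: Sequence[str] = ANCHORS) -> pd.DataFrame:
    """Per-object association indices for each anchor plus their mean."""
    if objects is None:
        objects = [c for c in presence.columns
                   if c not in anchors and c != "scene_id"]
    rows = {}
    for obj in objects:
        per = {f"assoc_{a}": association_index(presence, obj, a)
               for a in anchors if a in presence.columns}
        per["assoc_mean"] = float(np.mean(list(per.values())))
        rows[obj] = per
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "category"
    return out


def benefit_correlation(summary: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and p of improvement vs baseline accuracy and association.

    ``summary`` needs columns ``improvement_points``, ``baseline_accuracy``
    and ``assoc_mean`` with one row per object category (>= 3 rows).
    p-values are two-sided from the t distribution of the correlation.
    """
    if len(summary) < 3:
        raise ValueError("need at least 3 categories")
    out = {}
    impr = summary["improvement_points"].to_numpy(dtype=float)
    for key, col in (("baseline", "baseline_accuracy"),
                     ("association", "assoc_mean")):
        other = summary[col].to_numpy(dtype=float)
        if np.ptp(impr) == 0 or np.ptp(other) == 0:
            out[key] = {"r": np.nan, "p": np.nan, "constant": True}
        else:
            r, p = stats.pearsonr(impr, other)
            out[key] = {"r": float(r), "p": float(p), "constant": False}
    return pd.DataFrame(out).T


@dataclass
class TransferResult:
    """Per-category augmentation benefit and its correlates."""

    summary: pd.DataFrame       # per category: assoc, baseline, fused, improvement
    correlations: pd.DataFrame  # from benefit_correlation

    def summary_text(self) -> str:
        lines = ["Transfer of car/person priors to other categories",
                 self.summary.to_string(float_format=lambda v: f"{v:.3f}")]
        for key, row in self.correlations.iterrows():
            lines.append(f"  improvement vs {key}: r = {row['r']:.3f}, "
                         f"p = {row['p']:.4g}")
        return "\n".join(lines)


def transfer_experiment(eval_set: EvalSet, priors: pd.DataFrame,
                        objects: Sequence[str] | None = None,
                        n_folds: int = 5, seed: int = 0) -> TransferResult:
    """Fuse each object's detector score with the car/person priors.

    For every object category in the evaluation set, a baseline linear
    discriminant on the object's own detector score is compared with one
    fused with the supplied prior columns; the improvement (percentage
    points) is tabulated against the object's association indices, and the
    benefit correlations are computed across categories.
    """
    presence = eval_set.presence
    if objects is None:
        objects = [c for c in eval_set.object_scores.columns if c != "scene_id"]
    assoc = association_table(presence, objects=objects)
    prior_cols = list(priors.columns)
    rows = []
    for obj in objects:
        table = pd.DataFrame({
            "scene_id": presence["scene_id"],
            "label": presence[obj].to_numpy(),
            "score": eval_set.object_scores[obj].to_numpy(),
        }).merge(priors, left_on="scene_id", right_index=True, how="left")
        base = FusedClassifier(table, feature_cols=("score",),
                               n_folds=n_folds, seed=seed).fit()
        fused = FusedClassifier(table, feature_cols=("score", *prior_cols),
                                n_folds=n_folds, seed=seed).fit()
        rows.append({
            "category": obj,
            "n_scenes": len(table),
            "baseline_accuracy": base.accuracy_mean,
            "augmented_accuracy": fused.accuracy_mean,
            "improvement_points": 100.0 * (fused.accuracy_mean
                                           - base.accuracy_mean),
        })
    summary = pd.DataFrame(rows).set_index("category").join(assoc)
    return TransferResult(summary=summary,
                          correlations=benefit_correlation(summary))
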