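"""Linear expectation models, cross-validation, model comparison, ceilings.

The modelling problem: per-scene, across-subject mean ratings (likelihood,
box x, box y, area, aspect ratio, separately for each target category) are
regressed on feature-channel principal components, ``y = Xb``, with ordinary
least squares. Model quality is the Pearson correlation between
cross-validated predictions and the observed means; channel subsets are
compared over many random 80-20 splits, with significance reported as the
fraction of splits on which a competitor beats the reference model. The
upper bound on any model's correlation is the split-half noise ceiling of
the ratings with the Spearman-Brown correction ``rc = 2r / (1 + r)``.

Public surface follows a statsmodels-like Model / Results convention:
:class:`ExpectationModel` is constructed from data and ``fit()`` /
``cross_validate()`` return result objects carrying estimates, diagnostics
and ``summary()`` tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import ChannelPCA, FeatureChannel, _as_frame, canonical_subset
from .synth import CATEGORIES, CHANNELS, RESPONSES

__all__ = [
    "aggregate_ratings",
    "fit_linear",
    "LinearFit",
    "ExpectationModel",
    "ExpectationResults",
    "CrossValResult",
    "compare_models",
    "ModelComparisonResult",
    "noise_ceiling",
    "NoiseCeilingResult",
    "spearman_brown",
    "nontarget_weight_correlation",
    "ALL_SUBSETS",
]

#: The seven channel subsets of the standard model comparison.
ALL_SUBSETS: dict[str, tuple[str, ...]] = {
    "T": ("T",), "N": ("N",), "C": ("C",),
    "TN": ("T", "N"), "TC": ("T", "C"), "NC": ("N", "C"),
    "TNC": ("T", "N", "C"),
}

_BOX_RESPONSES = ("x", "y", "area", "aspect")


def aggregate_ratings(ratings: pd.DataFrame,
                      scene_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-scene, per-category across-subject aggregates.

    Likelihood is averaged over all raters; box statistics (x, y, area,
    aspect) only over raters who gave a non-zero likelihood (subjects rating
    zero place no box). Box aggregates are NaN when no rater gave a non-zero
    likelihood. Returns a frame indexed by (scene_id, category) with columns
    likelihood, x, y, area, aspect, n_raters, n_nonzero_raters.
    """
    required = {"subject_id", "scene_id", "category", "likelihood"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings table lacks columns {sorted(missing)}")
    if scene_ids is not None:
        absent = set(scene_ids) - set(ratings["scene_id"])
        if absent:
            raise ValueError(
                f"scenes with zero raters: {sorted(absent)[:5]}")
    grouped = ratings.groupby(["scene_id", "category"], sort=True)
    out = grouped.agg(
        likelihood=("likelihood", "mean"),
        n_raters=("likelihood", "size"),
    )
    nonzero = ratings[ratings["likelihood"] > 0]
    box_cols = {"x": "box_x", "y": "box_y", "area": "box_area",
                "aspect": "box_aspect"}
    box = nonzero.groupby(["scene_id", "category"]).agg(
        **{resp: (col, "mean") for resp, col in box_cols.items()},
        n_nonzero_raters=("likelihood", "size"),
    )
    out = out.join(box)
    out["n_nonzero_raters"] = out["n_nonzero_raters"].fillna(0).astype(np.int64)
    return out[["likelihood", *box_cols, "n_raters", "n_nonzero_raters"]]


@dataclass
class LinearFit:
    intercept: float
    weights: np.ndarray
    rank: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(x, dtype=float) @ self.weights


def fit_linear(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """Ordinary least squares with intercept.

    Rank-deficient designs are solved by the minimum-norm convention (SVD
    least squares) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("x must be 2-d with one row per element of y")
    design = np.column_stack([np.ones(len(x)), x])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient design; using minimum-norm solution",
                      RuntimeWarning, stacklevel=2)
    return LinearFit(intercept=float(coef[0]), weights=coef[1:], rank=int(rank))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _design_names(subset: Sequence[str], k: int) -> list[str]:
    return [f"{ch}_pc{j + 1:02d}" for ch in subset for j in range(k)]


class ExpectationModel:
    """Linear expectation model for one response variable.

    Parameters
    ----------
    y : Series
        Per-scene response (an :func:`aggregate_ratings` column for one
        category), indexed by scene_id. Rows with NaN are dropped.
    channels : mapping
        ``channel name -> FeatureChannel or DataFrame`` covering y's index.
    subset : iterable of {"T", "N", "C"}
        Channels entering the design (canonical order enforced).
    pca_k : int
        Components retained per channel.
    """

    def __init__(self, y: pd.Series,
                 channels: Mapping[str, FeatureChannel | pd.DataFrame],
                 subset: Iterable[str] = ("N", "C"),
                 pca_k: int = 20, standardize: bool = True,
                 pca_solver: str = "auto", response: str = "likelihood",
                 category: str | None = None):
        self.subset = canonical_subset(subset)
        y = pd.Series(y).dropna()
        if y.empty:
            raise ValueError("response has no observed values")
        self.y = y
        self.response = response
        self.category = category
        self.pca_k = pca_k
        self.standardize = standardize
        self.pca_solver = pca_solver
        self.channels = {}
        for ch in self.subset:
            if ch not in channels:
                raise ValueError(f"channel {ch!r} not supplied")
            frame = _as_frame(channels[ch])
            missing = y.index.difference(frame.index)
            if len(missing):
                raise ValueError(
                    f"channel {ch} lacks rows for scenes {list(missing[:5])}")
            self.channels[ch] = frame.loc[y.index]
        self.n_obs = len(y)

    # -- internal helpers -------------------------------------------------
    def _fit_pcas(self, rows: np.ndarray | None = None,
                  seed: int = 0) -> dict[str, ChannelPCA]:
        pcas = {}
        for ch, frame in self.channels.items():
            sub = frame if rows is None else frame.iloc[rows]
            pcas[ch] = ChannelPCA(k=self.pca_k, standardize=self.standardize,
                                  solver=self.pca_solver,
                                  random_state=seed).fit(sub)
        return pcas

    def _design(self, pcas: Mapping[str, ChannelPCA],
                rows: np.ndarray | None = None) -> np.ndarray:
        blocks = []
        for ch in self.subset:
            frame = self.channels[ch]
            sub = frame if rows is None else frame.iloc[rows]
            blocks.append(pcas[ch].transform(sub))
        return np.hstack(blocks)

    # -- public API -------------------------------------------------------
    def fit(self) -> "ExpectationResults":
        """Fit PCA on all scenes and the OLS readout on top of it."""
        pcas = self._fit_pcas()
        x = self._design(pcas)
        fit = fit_linear(x, self.y.to_numpy())
        return ExpectationResults(model=self, pcas=pcas, fit=fit)

    def cross_validate(self, k: int = 5, seed: int = 0,
                       pca_global: bool = False) -> "CrossValResult":
        """k-fold cross-validated predictions and their correlation with y.

        Folds are a random near-equal partition. By default the channel PCAs
        are refit on each training fold (leakage-safe); ``pca_global=True``
        fits them once on all scenes.
        """
        n = self.n_obs
        if k < 2:
            raise ValueError("k must be at least 2")
        if n < 2 * k:
            raise ValueError(f"need at least {2 * k} scenes for {k} folds")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        y = self.y.to_numpy()
        preds = np.empty(n)
        assign = np.empty(n, dtype=np.int64)
        global_pcas = self._fit_pcas() if pca_global else None
        for i, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(perm, test_idx)
            pcas = global_pcas if pca_global else self._fit_pcas(train_idx, seed=seed)
            fit = fit_linear(self._design(pcas, train_idx), y[train_idx])
            preds[test_idx] = fit.predict(self._design(pcas, test_idx))
            assign[test_idx] = i
        r = _pearson(preds, y)
        return CrossValResult(
            predictions=pd.Series(preds, index=self.y.index, name="prediction"),
            r=r, fold_assignments=pd.Series(assign, index=self.y.index),
            seed=seed, k=k, r_undefined=bool(np.isnan(r)))


@dataclass
class ExpectationResults:
    """Fitted expectation model: channel PCAs plus the linear readout."""

    model: ExpectationModel
    pcas: dict[str, ChannelPCA]
    fit: LinearFit

    @property
    def intercept(self) -> float:
        return self.fit.intercept

    @property
    def weights(self) -> pd.Series:
        names = _design_names(self.model.subset, self.model.pca_k)
        return pd.Series(self.fit.weights, index=names, name="weight")

    @property
    def fittedvalues(self) -> pd.Series:
        x = self.model._design(self.pcas)
        return pd.Series(self.fit.predict(x), index=self.model.y.index)

    def predict(self, channels: Mapping[str, FeatureChannel | pd.DataFrame]
                ) -> pd.Series:
        """Predict the response for novel scenes from their raw channels."""
        blocks = []
        index = None
        for ch in self.model.subset:
            if ch not in channels:
                raise ValueError(f"channel {ch!r} not supplied")
            frame = _as_frame(channels[ch])
            index = frame.index if index is None else index
            blocks.append(self.pcas[ch].transform(frame))
        return pd.Series(self.fit.predict(np.hstack(blocks)), index=index)

    def channel_weight_block(self, channel: str) -> np.ndarray:
        """Weights of one channel's PCA components within the fitted vector."""
        if channel not in self.model.subset:
            raise ValueError(f"model does not include channel {channel!r}")
        pos = self.model.subset.index(channel)
        k = self.model.pca_k
        return self.fit.weights[pos * k:(pos + 1) * k]

    def nontarget_label_weights(self) -> pd.Series:
        """Back-project the N-component weights to per-label weights."""
        block = self.channel_weight_block("N")
        pca = self.pcas["N"]
        labels = self.model.channels["N"].columns
        return pd.Series(pca.loadings_ @ block, index=labels, name="weight")

    def summary(self) -> str:
        m = self.model
        lines = [
            "Expectation model (OLS on channel principal components)",
            f"  response: {m.response}" +
            (f" ({m.category})" if m.category else ""),
            f"  channels: {'+'.join(m.subset)}  (k = {m.pca_k} per channel)",
            f"  n scenes: {m.n_obs}   design columns: {len(self.fit.weights)}",
            f"  intercept: {self.intercept: .4f}",
            "  variance captured per channel: " + ", ".join(
                f"{ch}={self.pcas[ch].variance_captured_:.3f}" for ch in m.subset),
        ]
        r = _pearson(self.fittedvalues.to_numpy(), m.y.to_numpy())
        lines.append(f"  in-sample r: {r: .4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "response": self.model.response,
            "category": self.model.category,
            "subset": list(self.model.subset),
            "pca_k": self.model.pca_k,
            "intercept": self.intercept,
            "weights": self.fit.weights.tolist(),
            "pcas": {ch: pca.to_dict() for ch, pca in self.pcas.items()},
        }


@dataclass
class LinearExpectationPredictor:
    """A fitted expectation model reloaded from its serialised state.

    Carries only what prediction needs: the per-channel PCA states and the
    linear readout. Produced by :meth:`from_dict` on the output of
    :meth:`ExpectationResults.to_dict`.
    """

    subset: tuple[str, ...]
    intercept: float
    weights: np.ndarray
    pcas: dict[str, ChannelPCA]
    response: str = "likelihood"
    category: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "LinearExpectationPredictor":
        return cls(subset=tuple(d["subset"]), intercept=float(d["intercept"]),
                   weights=np.asarray(d["weights"], dtype=float),
                   pcas={ch: ChannelPCA.from_dict(p)
                         for ch, p in d["pcas"].items()},
                   response=d.get("response", "likelihood"),
                   category=d.get("category"))

    def predict(self, channels: Mapping[str, pd.DataFrame]) -> pd.Series:
        if isinstance(channels, pd.DataFrame):
            channels = {self.subset[0]: channels}
        blocks = []
        index = None
        for ch in self.subset:
            frame = _as_frame(channels[ch])
            index = frame.index if index is None else index
            blocks.append(self.pcas[ch].transform(frame))
        x = np.hstack(blocks)
        return pd.Series(self.intercept + x @ self.weights, index=index)


@dataclass
class CrossValResult:
    predictions: pd.Series
    r: float
    fold_assignments: pd.Series
    seed: int
    k: int
    r_undefined: bool = False


@dataclass
class ModelComparisonResult:
    """Channel-subset comparison over resampled train/test splits."""

    stats: pd.DataFrame              # index subset; columns mean, sd, exceedance
    split_correlations: pd.DataFrame  # n_splits x subsets
    reference: str
    ceiling_mean: float | None = None
    ceiling_sd: float | None = None
    n_splits: int = 0
    seed: int = 0

    def summary(self) -> str:
        lines = ["Model comparison: cross-validated correlation over "
                 f"{self.n_splits} random 80-20 splits",
                 f"  reference (best) model: {self.reference}"]
        if self.ceiling_mean is not None:
            lines.append(f"  noise ceiling: {self.ceiling_mean:.3f} "
                         f"+/- {self.ceiling_sd:.3f}")
        lines.append(f"  {'model':>6} {'mean r':>8} {'sd':>7} {'p(beats ref)':>13}")
        for name, row in self.stats.iterrows():
            frac = ("-" if name == self.reference
                    else f"{row['exceedance']:.3f}")
            lines.append(f"  {name:>6} {row['mean']:8.3f} {row['sd']:7.3f} "
                         f"{frac:>13}")
        return "\n".join(lines)


def compare_models(y: pd.Series,
                   channels: Mapping[str, FeatureChannel | pd.DataFrame],
                   subsets: Mapping[str, Sequence[str]] | None = None,
                   n_splits: int = 1000, train_frac: float = 0.8,
                   seed: int = 0, pca_k: int = 20,
                   pca_global: bool = False,
                   reference: str | None = None,
                   ceiling: tuple[float, float] | None = None,
                   ) -> ModelComparisonResult:
    """Compare channel subsets over random train/test splits.

    Per split every subset is fit on the training portion (channel PCAs are
    refit on the training scenes unless ``pca_global``) and scored by the
    Pearson correlation between predictions and observations on the held-out
    portion; the same splits are shared by all subsets so comparisons are
    paired. The exceedance fraction of a competitor is the fraction of
    splits on which it beats the reference (best-on-average) model, with
    exact ties counting one half.

    Splits whose test responses are constant (correlation undefined) are
    resampled and logged via a warning.
    """
    subsets = dict(subsets) if subsets is not None else dict(ALL_SUBSETS)
    models = {name: ExpectationModel(y, channels, subset=sub, pca_k=pca_k)
              for name, sub in subsets.items()}
    n = next(iter(models.values())).n_obs
    y_arr = next(iter(models.values())).y.to_numpy()
    n_test = max(1, int(round(n * (1.0 - train_frac))))
    if n_test >= n:
        raise ValueError("train_frac leaves no training scenes")
    rng = np.random.default_rng(seed)
    needed = {ch for m in models.values() for ch in m.subset}
    y_index = next(iter(models.values())).y.index
    frames = {ch: _as_frame(channels[ch]).loc[y_index] for ch in needed}

    global_pcas = {
        ch: ChannelPCA(k=pca_k, solver="auto", random_state=seed).fit(frames[ch])
        for ch in needed} if pca_global else None

    split_r = np.empty((n_splits, len(models)))
    names = list(models)
    for s in range(n_splits):
        for attempt in range(100):
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if np.ptp(y_arr[test_idx]) > 0:
                break
            warnings.warn("resampling a degenerate split (constant test y)",
                          RuntimeWarning)
        else:
            raise RuntimeError("could not draw a non-degenerate split")
        # fit PCAs once per split per channel, share across subsets
        scores_train, scores_test = {}, {}
        for ch in needed:
            frame = frames[ch]
            if pca_global:
                pca = global_pcas[ch]
            else:
                pca = ChannelPCA(k=pca_k, solver="auto",
                                 random_state=(seed + s) % (2 ** 31)
                                 ).fit(frame.iloc[train_idx])
            scores_train[ch] = pca.transform(frame.iloc[train_idx])
            scores_test[ch] = pca.transform(frame.iloc[test_idx])
        for j, (name, model) in enumerate(models.items()):
            x_train = np.hstack([scores_train[ch] for ch in model.subset])
            x_test = np.hstack([scores_test[ch] for ch in model.subset])
            fit = fit_linear(x_train, y_arr[train_idx])
            split_r[s, j] = _pearson(fit.predict(x_test), y_arr[test_idx])

    split_df = pd.DataFrame(split_r, columns=names)
    means = split_df.mean()
    ref = reference if reference is not None else means.idxmax()
    if ref not in names:
        raise ValueError(f"reference {ref!r} is not among the subsets")
    ref_r = split_df[ref].to_numpy()
    exceed = {}
    for name in names:
        if name == ref:
            exceed[name] = np.nan
            continue
        r = split_df[name].to_numpy()
        exceed[name] = float(np.mean((r > ref_r) + 0.5 * (r == ref_r)))
    stats_df = pd.DataFrame({
        "mean": means, "sd": split_df.std(ddof=1 if n_splits > 1 else 0),
        "exceedance": pd.Series(exceed),
    })
    if n_splits == 1:
        stats_df["sd"] = 0.0
    return ModelComparisonResult(
        stats=stats_df, split_correlations=split_df, reference=ref,
        ceiling_mean=None if ceiling is None else ceiling[0],
        ceiling_sd=None if ceiling is None else ceiling[1],
        n_splits=n_splits, seed=seed)


def spearman_brown(r: float | np.ndarray) -> float | np.ndarray:
    """Spearman-Brown step-up of a split-half correlation: 2r / (1 + r)."""
    return 2.0 * r / (1.0 + r)


@dataclass
class NoiseCeilingResult:
    mean: float
    sd: float
    samples: np.ndarray
    n_subjects: int
    response: str
    category: str

    def summary(self) -> str:
        return (f"Noise ceiling ({self.response}, {self.category}): "
                f"{self.mean:.3f} +/- {self.sd:.3f} over "
                f"{len(self.samples)} random halvings of "
                f"{self.n_subjects} subjects (Spearman-Brown corrected)")


def noise_ceiling(ratings: pd.DataFrame, response: str = "likelihood",
                  category: str = "car", n_resamples: int = 1000,
                  seed: int = 0) -> NoiseCeilingResult:
    """Corrected split-half reliability of the per-scene mean ratings.

    For each resample the subjects are randomly split into two halves, the
    two groups' per-scene means are correlated across scenes, and the
    correlation is stepped up with the Spearman-Brown formula. Box responses
    use only ratings with non-zero likelihood (the others have no box);
    scenes unobserved in either half are dropped for that resample.
    """
    col = {"likelihood": "likelihood", "x": "box_x", "y": "box_y",
           "area": "box_area", "aspect": "box_aspect"}[response]
    sub = ratings[ratings["category"] == category]
    if response != "likelihood":
        sub = sub[sub["likelihood"] > 0]
    wide = sub.pivot_table(index="scene_id", columns="subject_id",
                           values=col, aggfunc="mean")
    n_subj = wide.shape[1]
    if n_subj < 2:
        raise ValueError("noise ceiling needs at least 2 subjects")
    mat = wide.to_numpy()
    rng = np.random.default_rng(seed)
    half = n_subj // 2
    samples = np.empty(n_resamples)
    for i in range(n_resamples):
        perm = rng.permutation(n_subj)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m1 = np.nanmean(mat[:, perm[:half]], axis=1)
            m2 = np.nanmean(mat[:, perm[half:]], axis=1)
        ok = ~(np.isnan(m1) | np.isnan(m2))
        r = _pearson(m1[ok], m2[ok])
        samples[i] = spearman_brown(r)
    return NoiseCeilingResult(mean=float(np.mean(samples)),
                              sd=float(np.std(samples, ddof=1)),
                              samples=samples, n_subjects=n_subj,
                              response=response, category=category)


def recover_generating_weights(results: ExpectationResults,
                               truth) -> tuple[np.ndarray, np.ndarray, float]:
    """Score a fitted model's parameter recovery against synthetic truth.

    The fitted weights live on PCA-component axes of the observed channels
    while the generating weights live on the generator's latent factors, so
    they are compared by regressing the model's fitted values onto the known
    latent design. Both weight vectors are expressed in standardised units
    (weight times the factor's empirical sd, i.e. the per-factor signal
    amplitude), so that factors carrying no variance cannot dominate the
    comparison. Returns ``(recovered, true, correlation)``.
    """
    subset = results.model.subset
    design = truth.signal_design(subset)
    scene_ids = list(truth.scene_values["scene_id"].unique())
    frame = pd.DataFrame(design, index=pd.Index(scene_ids, name="scene_id"))
    x = frame.loc[results.model.y.index].to_numpy()
    sd = x.std(axis=0)
    sd[sd < 1e-12] = 1.0
    yhat = results.fittedvalues.to_numpy()
    recovered = fit_linear((x - x.mean(axis=0)) / sd, yhat).weights
    true = truth.signal_weights(results.model.category or "car",
                                results.model.response, subset) * sd
    return recovered, true, _pearson(recovered, true)


def nontarget_weight_correlation(car_results: ExpectationResults,
                                 person_results: ExpectationResults,
                                 ) -> tuple[float, float, pd.DataFrame]:
    """Correlate per-label nontarget weights of the car and person models.

    Both fitted models must include the N channel; their component weights
    are back-projected through the channel PCA loadings to one weight per
    nontarget label, and the car and person label weights are correlated
    (Pearson). Returns (r, p, per-label weight table).
    """
    w_car = car_results.nontarget_label_weights()
    w_person = person_results.nontarget_label_weights()
    if not w_car.index.equals(w_person.index):
        raise ValueError("models use different nontarget vocabularies")
    r, p = stats.pearsonr(w_car.to_numpy(), w_person.to_numpy())
    table = pd.DataFrame({"car": w_car, "person": w_person})
    return float(r), float(p), table
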