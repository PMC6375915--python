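"""Synthetic behavioural and evaluation data with known generative structure.

This module emulates the statistical structure of a contextual-expectation
study: a set of target-absent scenes described by three feature channels
(target-detection summaries ``T``, binary nontarget-object labels ``N`` and
coarse scene features ``C``), subject-level likelihood/box ratings driven by a
linear readout of latent channel factors, and class-balanced evaluation sets
pairing detector confidence scores with context features.

Every generator is deterministic under a fixed seed and returns a *truth*
record holding the generating latents, loadings and weights, so downstream
model fits can be scored against known ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "CATEGORIES",
    "RESPONSES",
    "CHANNELS",
    "DEFAULT_VOCABULARY",
    "ConfigError",
    "GeneratorConfig",
    "EvalConfig",
    "SceneSetTruth",
    "EvalSet",
    "generate_scene_set",
    "generate_subject_ratings",
    "generate_eval_set",
]

CATEGORIES = ("car", "person")
RESPONSES = ("likelihood", "x", "y", "area", "aspect")
CHANNELS = ("T", "N", "C")

#: Default nontarget vocabulary: label -> occurrence count out of 650 scenes.
#: A long-tailed distribution typical of outdoor/urban scene datasets.
_VOCABULARY_COUNTS = {
    "window": 332, "tree": 327, "pole": 267, "door": 160, "fence": 149,
    "sign": 147, "roof": 147, "text": 103, "lamppost": 90, "glass": 82,
    "cable": 80, "stripe": 58, "box": 56, "bush": 47, "stair": 45,
    "bench": 42, "rock": 41, "dustbin": 36, "flower-pot": 35, "lamp": 29,
    "flower": 26, "chair": 26, "entrance": 23, "cycle": 22, "table": 20,
    "boat": 19, "statue": 17, "hydrant": 8, "flag": 8, "wheel": 7,
    "animal": 7, "cone": 6, "bird": 6, "manhole-cover": 5, "cloud": 5,
    "bag": 2,
}
DEFAULT_VOCABULARY: dict[str, float] = {
    k: v / 650.0 for k, v in _VOCABULARY_COUNTS.items()
}

# Box geometry of the latent "most likely" rectangle, in a 640x480 frame.
_BOX_SCALE = {
    "x_frac": 0.14,        # sd of latent x-centre as a fraction of width
    "y_frac": 0.145,       # sd of latent y-centre as a fraction of height
    "log_area_mu": np.log(4900.0),
    "log_area_sd": 0.5,
    "log_aspect_sd": 0.3,
}
_ASPECT_BASE = {"car": 0.45, "person": 2.5}  # aspect = height / width
# Per-subject jitter of box placement (px for x/y, log units otherwise).
_BOX_JITTER = {"x": 80.0, "y": 60.0, "log_area": 0.6, "log_aspect": 1.0}


class ConfigError(ValueError):
    """Raised for invalid generator configurations."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the behavioural scene-set generator.

    Defaults reproduce the study conditions the pipeline is meant for:
    650 target-absent scenes of 640x480 px, 11 subjects, two target
    categories, a ~36-label long-tailed nontarget vocabulary, and rating
    noise tuned so the likelihood noise ceiling sits near 0.9.

    Parameters
    ----------
    n_scenes, n_subjects : int
        Number of scenes and raters.
    image_width, image_height : int
        Frame size in pixels; boxes are generated in these coordinates.
    nontarget_vocabulary : mapping
        Label -> marginal occurrence probability in [0, 1].
    t_dim, c_dim : int
        Column counts of the target-summary (T) and coarse (C) channels.
    n_latent : int
        Latent factors per channel; channels are low rank by construction so
        that ``n_latent`` principal components capture most of the variance.
    factor_decay : float
        Geometric decay ratio of the latent factors' variance profile
        (1.0 = flat). Real scene descriptors have strongly decaying spectra
        — a few scene-type dimensions drive most co-occurrence structure —
        and the decay is what lets a binary label channel retain its leading
        factors after binarisation.
    channel_signal_fraction : float
        Fraction of each observed channel column's variance carried by the
        latent factors (the rest is isotropic noise).
    true_weights : mapping or None
        Optional ``{category: {response: {channel: (n_latent,) array}}}``
        generating weights on the latent channel factors, taken literally.
        When None, weights are drawn from the seed (aligned with the factor
        variance profile) and scaled so the response signal has exactly the
        configured variance, split ``nontarget_share`` :
        ``1 - nontarget_share`` between the N and C factors with nothing
        on T.
    likelihood_intercept, signal_sd, nontarget_share : float
        Mean of the latent likelihood, sd of its scene-to-scene signal, and
        the share of signal variance carried by the N channel.
    scene_noise_sd : float
        Scene-level rating noise shared by all subjects (part of the "true"
        scene value, invisible to any feature-based model).
    subject_noise_sd : float
        Independent per-rating subject noise.
    zero_likelihood_rate : float
        Probability that a rating is forced to exactly 0 (its box is then
        absent, as in the behavioural procedure).
    seed : int
        Master seed; identical seeds give bit-identical outputs.
    """

    n_scenes: int = 650
    n_subjects: int = 11
    image_width: int = 640
    image_height: int = 480
    nontarget_vocabulary: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VOCABULARY)
    )
    t_dim: int = 62
    c_dim: int = 512
    n_latent: int = 20
    factor_decay: float = 0.8
    channel_signal_fraction: float = 0.9
    true_weights: Mapping | None = None
    likelihood_intercept: float = 0.5
    signal_sd: float = 0.105
    nontarget_share: float = 0.35
    scene_noise_sd: float = 0.058
    subject_noise_sd: float = 0.12
    zero_likelihood_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_scenes > 0, "n_scenes must be positive")
        _check(self.n_subjects > 0, "n_subjects must be positive")
        _check(self.image_width > 0 and self.image_height > 0,
               "image dimensions must be positive")
        _check(len(self.nontarget_vocabulary) > 0, "vocabulary must be non-empty")
        for label, p in self.nontarget_vocabulary.items():
            _check(0.0 <= p <= 1.0, f"probability for label {label!r} not in [0,1]")
        _check(self.t_dim > 0 and self.c_dim > 0 and self.n_latent > 0,
               "channel dims must be positive")
        _check(0.0 < self.channel_signal_fraction <= 1.0,
               "channel_signal_fraction must be in (0,1]")
        _check(0.0 < self.factor_decay <= 1.0,
               "factor_decay must be in (0,1]")
        _check(0.0 <= self.zero_likelihood_rate <= 1.0,
               "zero_likelihood_rate must be in [0,1]")
        _check(self.subject_noise_sd >= 0 and self.scene_noise_sd >= 0,
               "noise sds must be non-negative")

    @property
    def vocabulary(self) -> list[str]:
        return list(self.nontarget_vocabulary)

    @property
    def channel_dims(self) -> dict[str, int]:
        return {"T": self.t_dim, "N": len(self.nontarget_vocabulary), "C": self.c_dim}


@dataclass
class SceneSetTruth:
    """Generating parameters and latents of one synthetic scene set.

    The generating signal of every response is linear in the latent factor
    scores of the channels; :meth:`signal_design` and :meth:`signal_weights`
    expose that design and its true weights so fitted models can be scored
    for parameter recovery.
    """

    config: GeneratorConfig
    latents: dict[str, np.ndarray]          # channel -> (n_scenes, n_latent)
    loadings: dict[str, np.ndarray]         # channel -> (n_latent, dims)
    label_thresholds: np.ndarray            # Gaussian thresholds per label
    presence: np.ndarray                    # (n_scenes, n_labels) binary
    weights: dict[str, dict[str, dict[str, np.ndarray]]]
    scene_values: pd.DataFrame              # latent per-scene responses
    ratings_seed: np.random.SeedSequence

    def signal_design(self, channels=("N", "C")) -> np.ndarray:
        """Concatenated generating regressors in canonical channel order."""
        order = [ch for ch in CHANNELS if ch in channels]
        return np.hstack([self.latents[ch] for ch in order])

    def signal_weights(self, category: str, response: str,
                       channels=("N", "C")) -> np.ndarray:
        order = [ch for ch in CHANNELS if ch in channels]
        return np.concatenate(
            [self.weights[category][response][ch] for ch in order]
        )

    def params_dict(self) -> dict:
        """JSON-serialisable summary of the generating parameters."""
        cfg = dataclasses.asdict(self.config)
        cfg["nontarget_vocabulary"] = dict(self.config.nontarget_vocabulary)
        cfg.pop("true_weights", None)
        return {
            "config": cfg,
            "weights": {
                cat: {resp: {ch: list(map(float, w)) for ch, w in per_ch.items()}
                      for resp, per_ch in per_resp.items()}
                for cat, per_resp in self.weights.items()
            },
        }


def _unit_columns(rng: np.random.Generator, k: int, d: int) -> np.ndarray:
    """Random (k, d) loading matrix with unit-norm columns."""
    load = rng.normal(size=(k, d))
    return load / np.linalg.norm(load, axis=0, keepdims=True)


def _unit_vector(rng: np.random.Generator, k: int) -> np.ndarray:
    v = rng.normal(size=k)
    return v / np.linalg.norm(v)


def _factor_scales(config: GeneratorConfig) -> np.ndarray:
    """Per-factor sds: geometric variance profile normalised to mean 1."""
    profile = config.factor_decay ** np.arange(config.n_latent)
    return np.sqrt(config.n_latent * profile / profile.sum())


def _draw_weights(rng: np.random.Generator, config: GeneratorConfig,
                  latents: dict[str, np.ndarray]) -> dict:
    """Draw generating weights on the latent factors, aligned with the
    factor variance profile and scaled so each response's signal variance is
    exact: ``nontarget_share`` of it from the N factors, the rest from the
    C factors, none from the target channel."""
    k = config.n_latent
    scales = _factor_scales(config)
    weights: dict = {}
    for cat in CATEGORIES:
        per_resp: dict = {}
        for resp in RESPONSES:
            total_sd = config.signal_sd if resp == "likelihood" else 1.0
            targets = {"N": total_sd * np.sqrt(config.nontarget_share),
                       "C": total_sd * np.sqrt(1.0 - config.nontarget_share)}
            per_ch = {"T": np.zeros(k)}
            for ch, target in targets.items():
                w = rng.normal(size=k) * scales  # weight tracks factor strength
                sd = (latents[ch] @ w).std()
                per_ch[ch] = w * (target / sd) if sd > 0 else w * 0.0
            per_resp[resp] = per_ch
        weights[cat] = per_resp
    return weights


def _signal(latents: dict[str, np.ndarray],
            w: dict[str, np.ndarray]) -> np.ndarray:
    return sum(latents[ch] @ w[ch] for ch in CHANNELS)


def generate_scene_set(config: GeneratorConfig):
    """Generate scenes, observed feature channels and the truth record.

    Returns
    -------
    scenes : DataFrame
        One row per scene: ``scene_id``, frame size and a ``labels`` column
        with the ``|``-joined nontarget labels present in the scene.
    channels : dict of DataFrame
        ``{"T", "N", "C"}`` -> scenes x dims matrices indexed by scene_id,
        each low rank plus isotropic noise. The N matrix is the graded
        label-evidence channel (one column per vocabulary label); the scene
        table's binary labels are its thresholding, so
        :func:`~scenexpect.features.build_nontarget_channel` yields the
        matching binary channel when label presences are all one observes.
    truth : SceneSetTruth
    """
    ss = np.random.SeedSequence(config.seed)
    scene_ss, ratings_ss = ss.spawn(2)
    rng = np.random.default_rng(scene_ss)

    n, k = config.n_scenes, config.n_latent
    f = config.channel_signal_fraction
    labels = config.vocabulary
    dims = config.channel_dims
    scene_ids = [f"scene{i:04d}" for i in range(n)]

    scales = _factor_scales(config)
    latents = {ch: rng.normal(size=(n, k)) * scales for ch in CHANNELS}
    loadings = {ch: _unit_columns(rng, k, dims[ch]) for ch in CHANNELS}

    def observe(ch: str) -> np.ndarray:
        noise = rng.normal(size=(n, dims[ch]))
        return np.sqrt(f) * (latents[ch] @ loadings[ch]) + np.sqrt(1 - f) * noise

    x_t = observe("T")
    x_c = observe("C")
    # N: Gaussian-copula binary labels. Each label's latent is standardised
    # to unit variance and thresholded so the marginal presence probability
    # is exact.
    u = observe("N")
    u_sd = np.sqrt(f * (scales[:, None] ** 2 * loadings["N"] ** 2).sum(axis=0)
                   + (1 - f))
    u = u / u_sd[None, :]
    probs = np.array([config.nontarget_vocabulary[lab] for lab in labels])
    with np.errstate(divide="ignore"):
        thresholds = norm.ppf(1.0 - probs)  # +inf for p=0, -inf for p=1
    presence = (u > thresholds[None, :]).astype(np.int64)

    if config.true_weights is not None:
        weights = {
            cat: {resp: {ch: np.asarray(w, dtype=float)
                         for ch, w in per_ch.items()}
                  for resp, per_ch in per_resp.items()}
            for cat, per_resp in config.true_weights.items()
        }
    else:
        weights = _draw_weights(rng, config, latents)

    rows = []
    w_img, h_img = config.image_width, config.image_height
    for cat in CATEGORIES:
        wc = weights[cat]

        def sig(resp):
            return _signal(latents, wc[resp])

        value = (config.likelihood_intercept + sig("likelihood")
                 + rng.normal(scale=config.scene_noise_sd, size=n))
        x_mu = w_img / 2 + _BOX_SCALE["x_frac"] * w_img * sig("x")
        y_mu = h_img / 2 + _BOX_SCALE["y_frac"] * h_img * sig("y")
        log_area = _BOX_SCALE["log_area_mu"] + _BOX_SCALE["log_area_sd"] * sig("area")
        log_aspect = np.log(_ASPECT_BASE[cat]) + _BOX_SCALE["log_aspect_sd"] * sig("aspect")
        rows.append(pd.DataFrame({
            "scene_id": scene_ids, "category": cat, "value": value,
            "x": np.clip(x_mu, 0, w_img), "y": np.clip(y_mu, 0, h_img),
            "log_area": log_area, "log_aspect": log_aspect,
        }))
    scene_values = pd.concat(rows, ignore_index=True)

    label_strings = ["|".join(lab for lab, p in zip(labels, row) if p)
                     for row in presence]
    scenes = pd.DataFrame({
        "scene_id": scene_ids,
        "width": w_img,
        "height": h_img,
        "labels": label_strings,
    })
    index = pd.Index(scene_ids, name="scene_id")
    channels = {
        "T": pd.DataFrame(x_t, index=index,
                          columns=[f"t{j:02d}" for j in range(dims["T"])]),
        "N": pd.DataFrame(u, index=index, columns=labels),
        "C": pd.DataFrame(x_c, index=index,
                          columns=[f"c{j:03d}" for j in range(dims["C"])]),
    }
    truth = SceneSetTruth(
        config=config, latents=latents, loadings=loadings,
        label_thresholds=thresholds, presence=presence, weights=weights,
        scene_values=scene_values, ratings_seed=ratings_ss,
    )
    return scenes, channels, truth


def generate_subject_ratings(scenes: pd.DataFrame, truth: SceneSetTruth,
                             config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Simulate per-subject likelihood ratings and most-likely boxes.

    Each rating is ``clip(scene value + subject noise, 0, 1)``; with
    probability ``zero_likelihood_rate`` it is forced to 0. Box fields are
    present exactly when the likelihood is non-zero, and equal the latent box
    plus per-subject jitter. Repeated calls with the same truth record return
    bit-identical tables.
    """
    config = config or truth.config
    if list(scenes["scene_id"]) != list(
            truth.scene_values["scene_id"].unique()):
        raise ValueError("scene table does not match the truth record")
    rng = np.random.default_rng(truth.ratings_seed)
    n = len(scenes)
    n_subj = config.n_subjects
    w_img, h_img = config.image_width, config.image_height

    frames = []
    for cat in CATEGORIES:
        sv = truth.scene_values[truth.scene_values["category"] == cat]
        value = sv["value"].to_numpy()
        lik = np.clip(value[None, :] +
                      rng.normal(scale=config.subject_noise_sd, size=(n_subj, n)),
                      0.0, 1.0)
        forced_zero = rng.random(size=(n_subj, n)) < config.zero_likelihood_rate
        lik = np.where(forced_zero, 0.0, lik)
        box_x = np.clip(sv["x"].to_numpy()[None, :] +
                        rng.normal(scale=_BOX_JITTER["x"], size=(n_subj, n)),
                        0, w_img)
        box_y = np.clip(sv["y"].to_numpy()[None, :] +
                        rng.normal(scale=_BOX_JITTER["y"], size=(n_subj, n)),
                        0, h_img)
        box_area = np.exp(sv["log_area"].to_numpy()[None, :] +
                          rng.normal(scale=_BOX_JITTER["log_area"], size=(n_subj, n)))
        box_aspect = np.exp(sv["log_aspect"].to_numpy()[None, :] +
                            rng.normal(scale=_BOX_JITTER["log_aspect"], size=(n_subj, n)))
        has_box = lik > 0
        for arr in (box_x, box_y, box_area, box_aspect):
            arr[~has_box] = np.nan
        subj_ids = np.repeat([f"sub{j:02d}" for j in range(n_subj)], n)
        frames.append(pd.DataFrame({
            "subject_id": subj_ids,
            "scene_id": np.tile(scenes["scene_id"].to_numpy(), n_subj),
            "category": cat,
            "likelihood": lik.ravel(),
            "box_x": box_x.ravel(),
            "box_y": box_y.ravel(),
            "box_area": box_area.ravel(),
            "box_aspect": box_aspect.ravel(),
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["subject_id", "scene_id", "category"],
                           kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class EvalConfig:
    """Configuration of a synthetic detector-evaluation set.

    ``score_separation`` is the standardised distance between the
    class-conditional detector-score means (AUC = Phi(d / sqrt(2)); the
    default 1.466 gives AUC ~ 0.85). ``prior_informativeness`` is the
    correlation between the scene's latent context signal and the true
    presence label; the context signal is independent of the detector score
    given the label, so fusing the two adds information.

    ``associated_objects`` maps object names to coupling strengths in
    [-1, 1] with the anchor category: with a balanced anchor, an object with
    coupling ``g`` has ``p(object | anchor) - p(object) = g / 2``.
    """

    n_pos: int = 3000
    n_neg: int = 3000
    category: str = "car"
    score_separation: float = 1.466
    prior_informativeness: float = 0.45
    associated_objects: Mapping[str, float] = field(default_factory=dict)
    object_base_rate: float = 0.35
    object_score_separation: float | Mapping[str, float] = 1.2
    c_dim: int = 512
    n_latent: int = 20
    channel_signal_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_pos > 0 and self.n_neg > 0,
               "n_pos and n_neg must be positive")
        _check(self.category in CATEGORIES, f"unknown category {self.category!r}")
        _check(-1.0 <= self.prior_informativeness <= 1.0,
               "prior_informativeness must be in [-1,1]")
        for name, g in self.associated_objects.items():
            _check(-1.0 <= g <= 1.0,
                   f"coupling for object {name!r} must be in [-1,1]")
        _check(0.0 < self.object_base_rate < 1.0,
               "object_base_rate must be in (0,1)")

    def separation_for(self, obj: str) -> float:
        if isinstance(self.object_score_separation, Mapping):
            return float(self.object_score_separation[obj])
        return float(self.object_score_separation)


@dataclass
class EvalSet:
    """A synthetic evaluation set and its generating record."""

    table: pd.DataFrame          # scene_id, category, label, score, ctx columns
    presence: pd.DataFrame       # scene_id + anchor/object binary columns
    object_scores: pd.DataFrame  # scene_id + per-object detector scores
    context_signal: np.ndarray   # latent context signal per scene
    config: EvalConfig

    @property
    def context(self) -> pd.DataFrame:
        ctx_cols = [c for c in self.table.columns if c.startswith("c")
                    and c not in ("category",)]
        return self.table.set_index("scene_id")[ctx_cols]


def generate_eval_set(config: EvalConfig,
                      truth: SceneSetTruth | None = None) -> EvalSet:
    """Generate a class-balanced evaluation set with context features.

    When a behavioural-study ``truth`` is supplied, the coarse context
    features use the same latent-to-observed loadings as the behavioural
    scene set and the context signal is injected along the direction the
    true likelihood weights read out, so expectation models fitted on the
    behavioural data produce informative priors on these novel scenes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_pos + config.n_neg
    labels = np.zeros(n, dtype=np.int64)
    labels[:config.n_pos] = 1
    rng.shuffle(labels)
    l_std = 2.0 * labels - 1.0  # unit-variance coding of a balanced label

    scores = rng.normal(size=n) + config.score_separation * labels

    if truth is not None:
        k = truth.config.n_latent
        load_c = truth.loadings["C"]
        w_c = truth.weights[config.category]["likelihood"]["C"]
        direction = w_c / np.linalg.norm(w_c)
        f = truth.config.channel_signal_fraction
        c_dim = load_c.shape[1]
        col_names = [f"c{j:03d}" for j in range(c_dim)]
    else:
        k = config.n_latent
        load_c = _unit_columns(rng, k, config.c_dim)
        direction = _unit_vector(rng, k)
        f = config.channel_signal_fraction
        c_dim = config.c_dim
        col_names = [f"c{j:03d}" for j in range(c_dim)]

    rho = config.prior_informativeness
    g = rho * l_std + np.sqrt(max(0.0, 1.0 - rho ** 2)) * rng.normal(size=n)
    # Latent factors with unit-variance columns whose projection on
    # `direction` equals g.
    e = rng.normal(size=(n, k))
    e_perp = e - np.outer(e @ direction, direction)
    z = np.outer(g, direction) + e_perp
    if truth is not None:
        # match the behavioural scene set's factor variance profile
        z = z * _factor_scales(truth.config)
    ctx = np.sqrt(f) * (z @ load_c) + np.sqrt(1 - f) * rng.normal(size=(n, c_dim))

    scene_ids = [f"eval{i:05d}" for i in range(n)]
    table = pd.DataFrame({"scene_id": scene_ids,
                          "category": config.category,
                          "label": labels,
                          "score": scores})
    table = pd.concat(
        [table, pd.DataFrame(ctx, columns=col_names)], axis=1)

    other_anchor = "person" if config.category == "car" else "car"
    presence = pd.DataFrame({"scene_id": scene_ids,
                             config.category: labels,
                             other_anchor: (rng.random(n) < 0.5).astype(np.int64)})
    obj_scores = pd.DataFrame({"scene_id": scene_ids})
    anchor_rate = labels.mean()
    for obj, g_obj in config.associated_objects.items():
        p = np.clip(config.object_base_rate +
                    g_obj * (labels - anchor_rate), 0.0, 1.0)
        obj_presence = (rng.random(n) < p).astype(np.int64)
        presence[obj] = obj_presence
        obj_scores[obj] = (rng.normal(size=n) +
                           config.separation_for(obj) * obj_presence)
    return EvalSet(table=table, presence=presence, object_scores=obj_scores,
                   context_signal=g, config=config)
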