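"""Feature channels: target-detection summaries, nontarget labels and PCA.

Three per-scene descriptor groups feed the expectation models:

``T``
    A 62-dimensional summary of part-based detector output for the two
    target categories (31 values per category: detection counts at a strong
    threshold, a false-alarm estimate from the strong/weak count difference,
    mean detected area, 16 part-deformation statistics, a 5-bin eccentricity
    histogram, 6 view frequencies and the mean match score).
``N``
    Binary presence/absence of each nontarget-object label.
``C``
    Coarse scene features consumed as ready-made vectors.

Channel complexity is equalised by projecting each channel onto its first
``k`` (default 20) principal components before regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.utils.extmath import randomized_svd

from .synth import CATEGORIES, CHANNELS

__all__ = [
    "DetectionRecord",
    "FeatureChannel",
    "ChannelPCA",
    "N_PARTS",
    "TARGET_FEATURE_NAMES",
    "read_detections",
    "compute_part_means",
    "summarize_detections",
    "build_target_channel",
    "build_nontarget_channel",
    "fit_channel_pca",
    "assemble_design",
]

N_PARTS = 8
_VIEWS = (1, 2, 3)
_N_ECC_BINS = 5

STRONG_THRESHOLD = -0.7
WEAK_THRESHOLD = -1.2


@dataclass(frozen=True)
class DetectionRecord:
    """One part-based detector hit in a scene.

    ``part_offsets`` holds the eight detected part positions expressed in
    unit-square coordinates of the normalised detection box.
    """

    scene_id: str
    category: str
    view: int
    score: float
    x: float
    y: float
    width: float
    height: float
    part_offsets: tuple = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.view not in _VIEWS:
            raise ValueError(f"view must be one of {_VIEWS}, got {self.view}")
        if not (self.width > 0 and self.height > 0):
            raise ValueError("detection box must have positive width and height")
        offsets = tuple((float(dx), float(dy)) for dx, dy in self.part_offsets)
        if len(offsets) != N_PARTS:
            raise ValueError(
                f"part_offsets must contain exactly {N_PARTS} (dx, dy) pairs, "
                f"got {len(offsets)}")
        object.__setattr__(self, "part_offsets", offsets)

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)

    @property
    def area(self) -> float:
        return self.width * self.height


def _per_category_names(cat: str) -> list[str]:
    names = [f"{cat}_n_strong", f"{cat}_false_alarms", f"{cat}_mean_area"]
    names += [f"{cat}_part{p + 1}_{ax}" for p in range(N_PARTS) for ax in ("dx", "dy")]
    names += [f"{cat}_ecc{b + 1}" for b in range(_N_ECC_BINS)]
    names += [f"{cat}_view_{c}{v}" for c in CATEGORIES for v in _VIEWS]
    names += [f"{cat}_mean_score"]
    return names


#: Column labels of the 62-dimensional target feature vector.
TARGET_FEATURE_NAMES: list[str] = (
    _per_category_names("car") + _per_category_names("person")
)


def read_detections(path) -> list[DetectionRecord]:
    """Read detection records from CSV.

    Expected columns: scene_id, category, view, score, x, y, width, height
    and part{1..8}_dx / part{1..8}_dy.
    """
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        offsets = tuple(
            (getattr(row, f"part{p}_dx"), getattr(row, f"part{p}_dy"))
            for p in range(1, N_PARTS + 1))
        records.append(DetectionRecord(
            scene_id=str(row.scene_id), category=row.category,
            view=int(row.view), score=float(row.score),
            x=float(row.x), y=float(row.y),
            width=float(row.width), height=float(row.height),
            part_offsets=offsets))
    return records


def compute_part_means(records: Iterable[DetectionRecord]) -> dict[str, np.ndarray]:
    """Dataset-wide mean location of each part, per category.

    First pass of the two-pass part-deformation computation: the per-scene
    statistics are displacements from these means.
    """
    sums = {cat: np.zeros((N_PARTS, 2)) for cat in CATEGORIES}
    counts = {cat: 0 for cat in CATEGORIES}
    for rec in records:
        sums[rec.category] += np.asarray(rec.part_offsets)
        counts[rec.category] += 1
    return {cat: (sums[cat] / counts[cat] if counts[cat] else np.full((N_PARTS, 2), 0.0))
            for cat in CATEGORIES}


def summarize_detections(records: Sequence[DetectionRecord],
                         part_means: Mapping[str, np.ndarray] | None = None,
                         strong_threshold: float = STRONG_THRESHOLD,
                         weak_threshold: float = WEAK_THRESHOLD,
                         frame_size: tuple[float, float] = (640.0, 480.0),
                         ) -> np.ndarray:
    """Summarise one scene's detection records into the 62-vector.

    Per category: number of strong detections (score above the strong
    threshold), false-alarm estimate (weak minus strong counts), mean area
    of strong detections, mean per-part displacement from the dataset-wide
    part means (16 values), a histogram of detection eccentricity in 5 equal
    annuli from the scene centre (outer radius = half the frame diagonal),
    view frequencies and the mean score over all detections. Empty
    statistics default to 0.

    ``part_means`` should come from :func:`compute_part_means` over the whole
    dataset; when omitted it is computed from the given records alone.
    """
    if not strong_threshold > weak_threshold:
        raise ValueError("strong_threshold must exceed weak_threshold")
    records = list(records)
    if part_means is None:
        part_means = compute_part_means(records)

    w_img, h_img = frame_size
    cx, cy = w_img / 2.0, h_img / 2.0
    max_ecc = np.hypot(w_img, h_img) / 2.0
    bin_edges = np.linspace(0.0, max_ecc, _N_ECC_BINS + 1)

    out = []
    for cat in CATEGORIES:
        recs = [r for r in records if r.category == cat]
        strong = [r for r in recs if r.score > strong_threshold]
        n_weak = sum(r.score > weak_threshold for r in recs)
        n_strong = len(strong)
        mean_area = float(np.mean([r.area for r in strong])) if strong else 0.0

        if recs:
            disp = np.mean(
                [np.asarray(r.part_offsets) - part_means[cat] for r in recs],
                axis=0)
        else:
            disp = np.zeros((N_PARTS, 2))

        ecc = np.array([np.hypot(r.center[0] - cx, r.center[1] - cy)
                        for r in recs])
        if len(ecc):
            bins = np.minimum(
                np.digitize(ecc, bin_edges[1:], right=False), _N_ECC_BINS - 1)
            ecc_hist = np.bincount(bins, minlength=_N_ECC_BINS).astype(float)
        else:
            ecc_hist = np.zeros(_N_ECC_BINS)

        view_freq = np.array(
            [float(sum(1 for r in recs if r.category == c and r.view == v))
             for c in CATEGORIES for v in _VIEWS])
        mean_score = float(np.mean([r.score for r in recs])) if recs else 0.0

        out.append(np.concatenate([
            [float(n_strong), float(n_weak - n_strong), mean_area],
            disp.ravel(), ecc_hist, view_freq, [mean_score]]))
    return np.concatenate(out)


@dataclass
class FeatureChannel:
    """A scenes x dims feature matrix for one channel (T, N or C)."""

    name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.name not in CHANNELS:
            raise ValueError(f"channel name must be one of {CHANNELS}")
        if self.data.isna().any().any():
            raise ValueError(f"channel {self.name} contains missing entries")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate scene ids in channel")

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def dims(self) -> int:
        return self.data.shape[1]


def _as_frame(channel) -> pd.DataFrame:
    return channel.data if isinstance(channel, FeatureChannel) else channel


def build_target_channel(records: Iterable[DetectionRecord],
                         scene_ids: Sequence[str],
                         strong_threshold: float = STRONG_THRESHOLD,
                         weak_threshold: float = WEAK_THRESHOLD,
                         frame_size: tuple[float, float] = (640.0, 480.0),
                         ) -> FeatureChannel:
    """Two-pass construction of the T channel from detection records."""
    records = list(records)
    part_means = compute_part_means(records)
    by_scene: dict[str, list[DetectionRecord]] = {sid: [] for sid in scene_ids}
    for rec in records:
        if rec.scene_id not in by_scene:
            raise ValueError(f"detection references unknown scene {rec.scene_id!r}")
        by_scene[rec.scene_id].append(rec)
    rows = [summarize_detections(by_scene[sid], part_means,
                                 strong_threshold, weak_threshold, frame_size)
            for sid in scene_ids]
    data = pd.DataFrame(rows, index=pd.Index(scene_ids, name="scene_id"),
                        columns=TARGET_FEATURE_NAMES)
    return FeatureChannel("T", data)


def build_nontarget_channel(scenes: pd.DataFrame,
                            vocabulary: Sequence[str]) -> FeatureChannel:
    """Binary presence matrix over the nontarget vocabulary.

    ``scenes`` must have ``scene_id`` and ``labels`` columns (labels
    ``|``-joined, empty string for none). Column order follows the given
    vocabulary; an out-of-vocabulary label raises a ``ValueError`` naming it.
    """
    vocab = list(vocabulary)
    col = {lab: j for j, lab in enumerate(vocab)}
    mat = np.zeros((len(scenes), len(vocab)), dtype=np.int64)
    for i, labels in enumerate(scenes["labels"].fillna("")):
        for lab in str(labels).split("|"):
            if not lab:
                continue
            if lab not in col:
                raise ValueError(f"label {lab!r} is not in the vocabulary")
            mat[i, col[lab]] = 1
    data = pd.DataFrame(mat, columns=vocab,
                        index=pd.Index(scenes["scene_id"], name="scene_id"))
    return FeatureChannel("N", data)


class ChannelPCA:
    """Standardise a feature channel and project onto its top-k components.

    Columns are z-scored before the decomposition because channels mix
    binary and continuous scales; zero-variance columns get unit scale so
    they contribute nothing rather than dividing by zero. The loading matrix
    has orthonormal columns; ``variance_captured_`` is the fraction of total
    (standardised) variance carried by the retained components.
    """

    def __init__(self, k: int = 20, standardize: bool = True,
                 solver: str = "auto", random_state: int = 0):
        self.k = int(k)
        self.standardize = standardize
        self.solver = solver
        self.random_state = random_state

    def fit(self, channel) -> "ChannelPCA":
        x = np.asarray(_as_frame(channel), dtype=float)
        n, d = x.shape
        if self.k > min(n - 1, d):
            raise ValueError(
                f"k={self.k} exceeds min(n_scenes - 1, dims) = {min(n - 1, d)}")
        self.mean_ = x.mean(axis=0)
        if self.standardize:
            scale = x.std(axis=0)
            scale[scale < 1e-12] = 1.0
        else:
            scale = np.ones(d)
        self.scale_ = scale
        xs = (x - self.mean_) / self.scale_
        total_var = float(np.sum(xs ** 2))

        solver = self.solver
        if solver == "auto":
            solver = "randomized" if min(n, d) > 120 else "exact"
        if solver == "exact":
            _, s, vt = np.linalg.svd(xs, full_matrices=False)
            s, vt = s[: self.k], vt[: self.k]
        elif solver == "randomized":
            _, s, vt = randomized_svd(xs, n_components=self.k, n_iter=5,
                                      random_state=self.random_state)
        else:
            raise ValueError(f"unknown solver {solver!r}")
        self.loadings_ = vt.T  # (dims, k)
        self.variance_captured_ = (float(np.sum(s ** 2)) / total_var
                                   if total_var > 0 else 1.0)
        return self

    def transform(self, channel) -> np.ndarray:
        frame = _as_frame(channel)
        x = np.asarray(frame, dtype=float)
        if x.shape[1] != self.loadings_.shape[0]:
            raise ValueError(
                f"channel has {x.shape[1]} columns, PCA was fit on "
                f"{self.loadings_.shape[0]}")
        return ((x - self.mean_) / self.scale_) @ self.loadings_

    def fit_transform(self, channel) -> np.ndarray:
        return self.fit(channel).transform(channel)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "standardize": self.standardize,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "loadings": self.loadings_.tolist(),
            "variance_captured": self.variance_captured_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelPCA":
        obj = cls(k=d["k"], standardize=d["standardize"])
        obj.mean_ = np.asarray(d["mean"], dtype=float)
        obj.scale_ = np.asarray(d["scale"], dtype=float)
        obj.loadings_ = np.asarray(d["loadings"], dtype=float)
        obj.variance_captured_ = float(d["variance_captured"])
        return obj


def fit_channel_pca(channel, k: int = 20, standardize: bool = True,
                    solver: str = "auto", random_state: int = 0) -> ChannelPCA:
    """Fit a :class:`ChannelPCA` on a channel (FeatureChannel or DataFrame)."""
    return ChannelPCA(k=k, standardize=standardize, solver=solver,
                      random_state=random_state).fit(channel)


def canonical_subset(subset: Iterable[str]) -> tuple[str, ...]:
    """Order a channel subset canonically (T, N, C)."""
    subset = set(subset)
    unknown = subset - set(CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}")
    if not subset:
        raise ValueError("channel subset must be non-empty")
    return tuple(ch for ch in CHANNELS if ch in subset)


def assemble_design(subset: Iterable[str],
                    pcas: Mapping[str, ChannelPCA],
                    channels: Mapping[str, object]) -> np.ndarray:
    """Concatenate the per-channel PCA projections for a channel subset.

    Channels always appear in canonical T, N, C order, so the design for a
    nested subset is a column-submatrix of the full TNC design.
    """
    order = canonical_subset(subset)
    blocks = [pcas[ch].transform(channels[ch]) for ch in order]
    return np.hstack(blocks)
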