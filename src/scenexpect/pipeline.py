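"""End-to-end orchestration of the analysis stages with file interchange.

Stages (``simulate``, ``aggregate``, ``fit``, ``compare``, ``ceiling``,
``fuse``, ``transfer``, ``report``) communicate only through plain CSV/JSON
files in a run directory, so any stage can be rerun in isolation. A single
master seed expands deterministically into per-stage seeds, and a manifest
records the resolved configuration, the seeds and a checksum of every
output, making whole runs byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import expect, fuse, synth, transfer

__all__ = ["DEFAULT_CONFIG", "STAGES", "MissingStageError", "load_config",
           "stage_seeds", "run_pipeline", "report"]

STAGES = ("simulate", "aggregate", "fit", "compare", "ceiling", "fuse",
          "transfer", "report")

_FLOAT_FMT = "%.6g"

#: Flat, stage-prefixed configuration with the study-condition defaults.
DEFAULT_CONFIG: dict[str, object] = {
    "simulate.n_scenes": 650,
    "simulate.n_subjects": 11,
    "simulate.zero_likelihood_rate": 0.03,
    "simulate.eval_n_pos": 800,
    "simulate.eval_n_neg": 800,
    "simulate.eval_category": "car",
    "simulate.score_separation": 1.466,
    "simulate.prior_informativeness": 0.45,
    "simulate.n_transfer_objects": 12,
    "fit.pca_k": 20,
    "fit.folds": 5,
    "pca.global": False,
    "compare.n_splits": 200,
    "compare.train_frac": 0.8,
    "ceiling.n_resamples": 1000,
    "fuse.folds": 5,
    "fuse.priors": "all",
    "transfer.folds": 5,
}


class MissingStageError(RuntimeError):
    """An input file produced by an earlier stage is absent."""


def _transfer_objects(n: int) -> tuple[dict[str, float], dict[str, float]]:
    """Default associated-object grid: couplings spread over (0, 0.8], with
    detector separations deliberately decorrelated from coupling order."""
    couplings = np.linspace(0.05, 0.75, n)
    seps = np.array([0.9, 1.8, 1.2, 2.2, 1.0, 1.6, 2.0, 0.8, 1.4, 2.4,
                     1.1, 1.9])
    seps = np.resize(seps, n)
    names = [f"obj{i + 1:02d}" for i in range(n)]
    return (dict(zip(names, couplings)),
            dict(zip(names, map(float, seps))))


def load_config(path=None, overrides: Mapping[str, object] | None = None
                ) -> dict[str, object]:
    """Resolve configuration from defaults, an optional ``key = value`` file
    and explicit overrides (later wins)."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in cfg:
                raise KeyError(f"unknown configuration key {key!r}")
            cfg[key] = _coerce(value.strip(), cfg[key])
    for key, value in (overrides or {}).items():
        if key not in cfg:
            raise KeyError(f"unknown configuration key {key!r}")
        cfg[key] = _coerce(value, cfg[key])
    return cfg


def _coerce(value, template):
    if isinstance(value, str):
        if isinstance(template, bool):
            return value.lower() in ("1", "true", "yes")
        if isinstance(template, int):
            return int(value)
        if isinstance(template, float):
            return float(value)
    return type(template)(value) if not isinstance(value, type(template)) else value


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Expand one master seed into named per-stage seeds (all < 2**31)."""
    names = ("simulate", "eval", "fit", "compare", "ceiling", "fuse",
             "transfer", "cv")
    ss = np.random.SeedSequence(master_seed)
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(names, ss.spawn(len(names)))}


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=index, float_format=_FLOAT_FMT)
    tmp.replace(path)


def _write_json(obj, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(obj, sort_keys=True, indent=1))
    tmp.replace(path)


def _require(out: Path, filename: str, produced_by: str) -> Path:
    path = out / filename
    if not path.exists():
        raise MissingStageError(
            f"{filename} not found; run the {produced_by!r} stage first")
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stage implementations

def _stage_simulate(cfg, out: Path, seeds) -> list[str]:
    gen_cfg = synth.GeneratorConfig(
        n_scenes=cfg["simulate.n_scenes"],
        n_subjects=cfg["simulate.n_subjects"],
        zero_likelihood_rate=cfg["simulate.zero_likelihood_rate"],
        seed=seeds["simulate"])
    scenes, channels, truth = synth.generate_scene_set(gen_cfg)
    ratings = synth.generate_subject_ratings(scenes, truth)
    couplings, seps = _transfer_objects(cfg["simulate.n_transfer_objects"])
    eval_cfg = synth.EvalConfig(
        n_pos=cfg["simulate.eval_n_pos"], n_neg=cfg["simulate.eval_n_neg"],
        category=cfg["simulate.eval_category"],
        score_separation=cfg["simulate.score_separation"],
        prior_informativeness=cfg["simulate.prior_informativeness"],
        associated_objects=couplings, object_score_separation=seps,
        seed=seeds["eval"])
    eval_set = synth.generate_eval_set(eval_cfg, truth=truth)

    _write_csv(scenes, out / "scenes.csv")
    _write_csv(ratings, out / "ratings.csv")
    for ch, frame in channels.items():
        _write_csv(frame, out / f"channels_{ch}.csv", index=True)
    _write_csv(eval_set.table, out / "eval.csv")
    _write_csv(eval_set.presence, out / "presence.csv")
    _write_csv(eval_set.object_scores, out / "object_scores.csv")
    truth_doc = truth.params_dict()
    truth_doc["eval_config"] = {
        **{k: v for k, v in dataclasses.asdict(eval_cfg).items()
           if k not in ("associated_objects", "object_score_separation")},
        "associated_objects": couplings,
        "object_score_separation": seps,
    }
    truth_doc["seeds"] = seeds
    _write_json(truth_doc, out / "truth.json")
    return ["scenes.csv", "ratings.csv", "channels_T.csv", "channels_N.csv",
            "channels_C.csv", "eval.csv", "presence.csv", "object_scores.csv",
            "truth.json"]


def _stage_aggregate(cfg, out: Path, seeds) -> list[str]:
    ratings = pd.read_csv(_require(out, "ratings.csv", "simulate"))
    agg = expect.aggregate_ratings(ratings)
    _write_csv(agg.reset_index(), out / "aggregates.csv")
    return ["aggregates.csv"]


def _read_channels(out: Path) -> dict[str, pd.DataFrame]:
    return {ch: pd.read_csv(_require(out, f"channels_{ch}.csv", "simulate"),
                            index_col="scene_id")
            for ch in synth.CHANNELS}


def _read_aggregates(out: Path) -> pd.DataFrame:
    agg = pd.read_csv(_require(out, "aggregates.csv", "aggregate"))
    return agg.set_index(["scene_id", "category"])


def _stage_fit(cfg, out: Path, seeds) -> list[str]:
    channels = _read_channels(out)
    agg = _read_aggregates(out)
    pca_k = cfg["fit.pca_k"]
    (out / "models").mkdir(exist_ok=True)
    written = []
    model_index = []
    for cat in synth.CATEGORIES:
        sub = agg.xs(cat, level="category")
        fits = {("NC", "likelihood"): ("N", "C")}
        for resp in synth.RESPONSES:
            fits[("C", resp)] = ("C",)
        for (tag, resp), subset in fits.items():
            y = sub[resp]
            res = expect.ExpectationModel(
                y, channels, subset=subset, pca_k=pca_k,
                response=resp, category=cat).fit()
            cv = expect.ExpectationModel(
                y, channels, subset=subset, pca_k=pca_k,
                response=resp, category=cat).cross_validate(
                    k=cfg["fit.folds"], seed=seeds["cv"],
                    pca_global=cfg["pca.global"])
            doc = res.to_dict()
            doc["cv_r"] = None if np.isnan(cv.r) else float(cv.r)
            doc["cv_folds"] = cfg["fit.folds"]
            name = f"models/{cat}_{resp}_{tag}.json"
            _write_json(doc, out / name)
            written.append(name)
            model_index.append({"category": cat, "response": resp,
                                "subset": tag, "file": name,
                                "cv_r": doc["cv_r"]})
    _write_csv(pd.DataFrame(model_index), out / "models_index.csv")
    return written + ["models_index.csv"]


def _stage_compare(cfg, out: Path, seeds) -> list[str]:
    channels = _read_channels(out)
    agg = _read_aggregates(out)
    frames = []
    for cat in synth.CATEGORIES:
        y = agg.xs(cat, level="category")["likelihood"]
        result = expect.compare_models(
            y, channels, n_splits=cfg["compare.n_splits"],
            train_frac=cfg["compare.train_frac"], seed=seeds["compare"],
            pca_k=cfg["fit.pca_k"], pca_global=cfg["pca.global"])
        stats = result.stats.copy()
        stats.insert(0, "category", cat)
        stats.insert(1, "reference", result.reference)
        stats.index.name = "model"
        frames.append(stats.reset_index())
    _write_csv(pd.concat(frames, ignore_index=True),
               out / "comparison_table.csv")
    return ["comparison_table.csv"]


def _stage_ceiling(cfg, out: Path, seeds) -> list[str]:
    ratings = pd.read_csv(_require(out, "ratings.csv", "simulate"))
    rows = []
    for cat in synth.CATEGORIES:
        for resp in synth.RESPONSES:
            res = expect.noise_ceiling(
                ratings, response=resp, category=cat,
                n_resamples=cfg["ceiling.n_resamples"], seed=seeds["ceiling"])
            rows.append({"category": cat, "response": resp,
                         "ceiling_mean": res.mean, "ceiling_sd": res.sd,
                         "n_subjects": res.n_subjects})
    _write_csv(pd.DataFrame(rows), out / "ceiling.csv")
    return ["ceiling.csv"]


def _load_prior_models(cfg, out: Path) -> dict[str, expect.LinearExpectationPredictor]:
    category = cfg["simulate.eval_category"]
    models = {}
    for resp in fuse.PRIOR_RESPONSES:
        path = _require(out, f"models/{category}_{resp}_C.json", "fit")
        models[resp] = expect.LinearExpectationPredictor.from_dict(
            json.loads(path.read_text()))
    return models


def _eval_priors(cfg, out: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    eval_table = pd.read_csv(_require(out, "eval.csv", "simulate"))
    ctx_cols = [c for c in eval_table.columns if c.startswith("c") and
                c not in ("category",)]
    ctx = eval_table.set_index("scene_id")[ctx_cols]
    models = _load_prior_models(cfg, out)
    priors = fuse.predict_priors(models, {"C": ctx})
    return eval_table, priors


def _stage_fuse(cfg, out: Path, seeds) -> list[str]:
    eval_table, priors = _eval_priors(cfg, out)
    if cfg["fuse.priors"] != "all":
        keep = [p.strip() for p in str(cfg["fuse.priors"]).split(",")]
        priors = priors[keep]
    table = fuse.augmentation_table(
        eval_table, priors, n_folds=cfg["fuse.folds"], seed=seeds["fuse"])
    _write_csv(table, out / "fusion_results.csv")

    merged = eval_table.merge(priors, left_on="scene_id", right_index=True)
    roc_frames = []
    for name, feats in (("baseline", ("score",)),
                        ("+likelihood", ("score", "likelihood")),
                        ("+all", ("score", *priors.columns))):
        res = fuse.FusedClassifier(merged, feature_cols=feats,
                                   n_folds=cfg["fuse.folds"],
                                   seed=seeds["fuse"]).fit()
        roc = res.roc
        roc.insert(0, "config", name)
        roc_frames.append(roc)
    _write_csv(pd.concat(roc_frames, ignore_index=True),
               out / "roc_points.csv")
    return ["fusion_results.csv", "roc_points.csv"]


def _stage_transfer(cfg, out: Path, seeds) -> list[str]:
    _, priors = _eval_priors(cfg, out)
    presence = pd.read_csv(_require(out, "presence.csv", "simulate"))
    obj_scores = pd.read_csv(_require(out, "object_scores.csv", "simulate"))
    eval_table = pd.read_csv(out / "eval.csv")
    eval_set = synth.EvalSet(
        table=eval_table, presence=presence, object_scores=obj_scores,
        context_signal=np.zeros(len(presence)),
        config=synth.EvalConfig(n_pos=1, n_neg=1))
    result = transfer.transfer_experiment(
        eval_set, priors, n_folds=cfg["transfer.folds"],
        seed=seeds["transfer"])
    _write_csv(result.summary.reset_index(), out / "transfer_summary.csv")
    _write_csv(result.correlations.reset_index(names="predictor"),
               out / "transfer_correlations.csv")
    return ["transfer_summary.csv", "transfer_correlations.csv"]


def _stage_report(cfg, out: Path, seeds) -> list[str]:
    text = report(out)
    tmp = out / "report.txt.tmp"
    tmp.write_text(text)
    tmp.replace(out / "report.txt")
    return ["report.txt"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "aggregate": _stage_aggregate,
    "fit": _stage_fit,
    "compare": _stage_compare,
    "ceiling": _stage_ceiling,
    "fuse": _stage_fuse,
    "transfer": _stage_transfer,
    "report": _stage_report,
}


def run_pipeline(out_dir, stages=("all",), seed: int = 0,
                 config_path=None,
                 overrides: Mapping[str, object] | None = None) -> dict:
    """Run the requested stages and write a manifest.

    Returns the manifest dict (also written to ``manifest.json``): resolved
    configuration, master and per-stage seeds, and a SHA-256 checksum per
    output file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = load_config(config_path, overrides)
    seeds = stage_seeds(seed)
    stages = list(stages)
    if "all" in stages:
        stages = list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    produced: dict[str, str] = {}
    for stage in STAGES:  # canonical order regardless of request order
        if stage not in stages:
            continue
        for name in _STAGE_FUNCS[stage](cfg, out, seeds):
            produced[name] = _sha256(out / name)
    config_blob = json.dumps(cfg, sort_keys=True)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "master_seed": seed,
        "stage_seeds": seeds,
        "stages_run": stages,
        "outputs": dict(sorted(produced.items())),
    }
    _write_json(manifest, out / "manifest.json")
    return manifest


def report(run_dir) -> str:
    """Render a human-readable summary of a completed run's tables."""
    out = Path(run_dir)
    sections = []
    any_found = False

    def fmt(df: pd.DataFrame) -> str:
        return df.to_string(index=False,
                            float_format=lambda v: f"{v:.6g}")

    for title, filename in (
            ("Model comparison (cross-validated correlation)",
             "comparison_table.csv"),
            ("Noise ceilings (Spearman-Brown corrected split-half)",
             "ceiling.csv"),
            ("Detector augmentation with predicted priors",
             "fusion_results.csv"),
            ("Transfer to associated object categories",
             "transfer_summary.csv"),
            ("Benefit correlations", "transfer_correlations.csv")):
        path = out / filename
        if path.exists():
            any_found = True
            sections.append(f"== {title} ==\n{fmt(pd.read_csv(path))}")
        else:
            sections.append(f"== {title} ==\n(missing: {filename} — "
                            "stage not run)")
    if not any_found:
        raise MissingStageError(f"no pipeline outputs found in {out}")
    return "\n\n".join(sections) + "\n"
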