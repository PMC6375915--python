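# scenexpect

Humans form graded expectations about objects that are *not* in a scene: an
empty highway still "calls for" cars at a particular place and size, a park
bench suggests people. `scenexpect` is a pipeline for measuring, modelling
and exploiting such contextual expectations. It is aimed at visual
psychophysicists and computer-vision researchers who want to

1. model per-scene expectation ratings (likelihood of occurrence, most
   likely x/y position, scale and aspect ratio, for cars and people) from
   scene feature channels,
2. quantify how reliable those ratings are (noise ceilings) and which
   feature channels explain them, and
3. feed the *predicted* expectations into a second-stage classifier to
   improve an object detector's present/absent decisions (late fusion).

A synthetic-data module generates behavioural and evaluation datasets with
the same statistical structure and known ground truth, so the entire
analysis is testable without any image data or human experiments.

## Model

Per-scene, across-subject mean ratings are modelled with ordinary least
squares,

```
y = X b,        X = [ P_T(T) | P_N(N) | P_C(C) ]
```

where `T`, `N`, `C` are three feature channels — a 62-dimensional summary of
part-based detector output, binary (or graded) nontarget-object labels, and
coarse scene features — and `P_k` projects each channel onto its first 20
principal components so channels compete at equal complexity. Performance is
the Pearson correlation between 5-fold cross-validated predictions and the
observed means; the seven channel subsets {T, N, C, TN, TC, NC, TNC} are
compared over 1000 random 80–20 splits, with significance as the fraction of
splits on which a competitor beats the best subset. The attainable ceiling
is the Spearman–Brown corrected split-half reliability of the ratings,
`r_c = 2r / (1 + r)`.

For detection, a scene's detector confidence score `s` and its predicted
priors `p̂ = (likelihood, x, y, area, aspect)` are concatenated and a
5-fold cross-validated linear discriminant decides target presence; gains
over the score-only baseline measure the label information the context
priors carry beyond the detector. Transfer to other object categories is
summarised by the association index
`|p(object | anchor present) − p(object)|` and by correlating per-category
accuracy improvements with baseline accuracy and association strength.

## Worked example

```python
import scenexpect as sx

cfg = sx.GeneratorConfig(seed=7)          # 650 scenes, 11 subjects
scenes, channels, truth = sx.generate_scene_set(cfg)
ratings = sx.generate_subject_ratings(scenes, truth)
agg = sx.aggregate_ratings(ratings)
y = agg.xs("car", level="category")["likelihood"]

model = sx.ExpectationModel(y, channels, subset=("N", "C"),
                            response="likelihood", category="car")
print(model.fit().summary())
print(f"5-fold cross-validated r: {model.cross_validate(k=5, seed=0).r:.3f}")
print(sx.noise_ceiling(ratings, "likelihood", "car",
                       n_resamples=1000, seed=0).summary())
```

prints

```
Expectation model (OLS on channel principal components)
  response: likelihood (car)
  channels: N+C  (k = 20 per channel)
  n scenes: 650   design columns: 40
  intercept:  0.4939
  variance captured per channel: N=0.955, C=0.899
  in-sample r:  0.8202
5-fold cross-validated r: 0.793
Noise ceiling (likelihood, car): 0.873 +/- 0.006 over 1000 random halvings of 11 subjects (Spearman-Brown corrected)
```

The nontarget + coarse-scene model explains most of the explainable
variance: its cross-validated correlation (0.79) approaches the reliability
ceiling of the ratings (0.87) and stays below it, as it must. Fusing the
predicted car likelihood with a detector score on 6000 novel scenes:

```python
from scenexpect.fuse import FusedClassifier, predict_priors

prior_model = sx.ExpectationModel(y, channels, subset=("C",),
                                  category="car").fit()
ev = sx.generate_eval_set(sx.EvalConfig(n_pos=3000, n_neg=3000, seed=21),
                          truth=truth)
priors = predict_priors({"likelihood": prior_model}, {"C": ev.context})
merged = ev.table.merge(priors, left_on="scene_id", right_index=True)
print(FusedClassifier(merged, ("score",), seed=3).fit().summary())
print(FusedClassifier(merged, ("score", "likelihood"), seed=3).fit().summary())
```

```
Fused linear-discriminant classifier
  features: score
  5-fold CV accuracy: 0.7682 +/- 0.0160
  AUC (out-of-fold discriminant): 0.8521
Fused linear-discriminant classifier
  features: score, likelihood
  5-fold CV accuracy: 0.8043 +/- 0.0112
  AUC (out-of-fold discriminant): 0.8897
```

— a 3.6-point accuracy gain from one predicted prior, because the context
signal carries presence information the detector score does not.

The same stages run from the shell:

```bash
scenexpect all --out run --seed 42
scenexpect report --out run
```

which writes `comparison_table.csv`, `ceiling.csv`, `fusion_results.csv`,
`roc_points.csv`, `transfer_summary.csv` and a `manifest.json` recording the
resolved configuration, per-stage seeds and a checksum of every output.

## Layout

| module | contents |
| --- | --- |
| `scenexpect.synth` | generators for behavioural studies and evaluation sets, with truth records |
| `scenexpect.features` | detection-record summaries (T), nontarget labels (N), `ChannelPCA`, design assembly |
| `scenexpect.expect` | `ExpectationModel`/`ExpectationResults`, cross-validation, subset comparison, noise ceilings, label-weight analyses |
| `scenexpect.fuse` | prior prediction, `FusedClassifier`, ROC/AUC, augmentation tables |
| `scenexpect.transfer` | association indices and benefit correlations across categories |
| `scenexpect.pipeline`, `scenexpect.cli` | staged file-based orchestration and the `scenexpect` command |

See `docs/methods.md` for the modelling assumptions, generator calibration
and numerical choices.
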