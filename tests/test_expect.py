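"""Aggregation, OLS, cross-validation, comparison, ceilings, label weights."""

import numpy as np
import pandas as pd
import pytest

import scenexpect as sx
from scenexpect.expect import fit_linear, spearman_brown

from conftest import make_ratings


# -- aggregation -----------------------------------------------------------

def test_aggregate_means_and_nonzero_boxes():
    ratings = make_ratings([
        ("s1", "a", "car", 0.2, 100, 200, 500, 1.0),
        ("s2", "a", "car", 0.4, 300, 100, 700, 2.0),
    ])
    agg = sx.aggregate_ratings(ratings)
    row = agg.loc[("a", "car")]
    assert row["likelihood"] == pytest.approx(0.3)
    assert row["x"] == pytest.approx(200)
    assert row["n_raters"] == 2 and row["n_nonzero_raters"] == 2


def test_aggregate_box_uses_only_nonzero_raters():
    ratings = make_ratings([
        ("s1", "a", "car", 0.0),
        ("s2", "a", "car", 0.6, 100, 200, 400, 1.5),
    ])
    row = sx.aggregate_ratings(ratings).loc[("a", "car")]
    assert row["likelihood"] == pytest.approx(0.3)
    assert row["x"] == pytest.approx(100)  # the single non-zero rater
    assert row["n_nonzero_raters"] == 1


def test_aggregate_all_zero_scene_has_no_box():
    ratings = make_ratings([
        ("s1", "a", "car", 0.0),
        ("s2", "a", "car", 0.0),
    ])
    row = sx.aggregate_ratings(ratings).loc[("a", "car")]
    assert row["likelihood"] == 0.0
    assert np.isnan(row["x"]) and np.isnan(row["aspect"])


def test_aggregate_missing_scene_error():
    ratings = make_ratings([("s1", "a", "car", 0.5, 1, 1, 1, 1)])
    with pytest.raises(ValueError, match="zero raters"):
        sx.aggregate_ratings(ratings, scene_ids=["a", "b"])


# -- linear fitting --------------------------------------------------------

def test_fit_linear_exact_and_constant():
    x = np.arange(10.0)[:, None]
    fit = fit_linear(x, 2.0 * x[:, 0])
    assert fit.intercept == pytest.approx(0.0, abs=1e-10)
    assert fit.weights[0] == pytest.approx(2.0)
    fit_c = fit_linear(x, np.full(10, 3.5))
    assert fit_c.intercept == pytest.approx(3.5)
    assert fit_c.weights[0] == pytest.approx(0.0, abs=1e-10)


def test_fit_linear_matches_normal_equations():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(50, 3))
    y = rng.normal(size=50)
    fit = fit_linear(x, y)
    design = np.column_stack([np.ones(50), x])
    oracle = np.linalg.solve(design.T @ design, design.T @ y)
    np.testing.assert_allclose(np.r_[fit.intercept, fit.weights], oracle,
                               atol=1e-8)


def test_fit_linear_rank_deficient_warns():
    x = np.ones((20, 2))  # duplicated constant columns
    with pytest.warns(RuntimeWarning, match="rank-deficient"):
        fit_linear(x, np.arange(20.0))


# -- cross-validation ------------------------------------------------------

def test_crossval_noiseless_linear():
    rng = np.random.default_rng(1)
    frame = pd.DataFrame(rng.normal(size=(120, 10)),
                         index=[f"s{i}" for i in range(120)])
    y = pd.Series(frame.to_numpy() @ rng.normal(size=10) + 2.0,
                  index=frame.index)
    cv = sx.ExpectationModel(y, {"C": frame}, subset=("C",), pca_k=10
                             ).cross_validate(k=5, seed=0)
    assert cv.r >= 0.999


def test_crossval_determinism(small_study, car_ch=None):
    channels = small_study["channels"]
    y = small_study["agg"].xs("car", level="category")["likelihood"]
    m = sx.ExpectationModel(y, channels, subset=("N", "C"))
    cv1 = m.cross_validate(k=5, seed=42)
    cv2 = m.cross_validate(k=5, seed=42)
    assert cv1.r == cv2.r
    pd.testing.assert_series_equal(cv1.predictions, cv2.predictions)
    pd.testing.assert_series_equal(cv1.fold_assignments, cv2.fold_assignments)


def test_crossval_null_within_permutation_band(small_study):
    """With y independent of the features, the cross-validated correlation
    lies inside the 99% band of the label-permutation null."""
    channels = {"T": small_study["channels"]["T"]}
    rng = np.random.default_rng(5)
    index = channels["T"].index
    y = pd.Series(rng.normal(size=len(index)), index=index)
    r_obs = sx.ExpectationModel(y, channels, subset=("T",), pca_k=10
                                ).cross_validate(k=5, seed=0).r
    null = []
    for i in range(100):
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=index)
        null.append(sx.ExpectationModel(y_perm, channels, subset=("T",),
                                        pca_k=10).cross_validate(k=5, seed=0).r)
    lo, hi = np.quantile(null, [0.005, 0.995])
    assert lo <= r_obs <= hi


def test_out_of_fold_predictions_ignore_test_responses(small_study):
    """Leakage check: perturbing a fold's responses leaves that fold's
    out-of-fold predictions unchanged."""
    channels = small_study["channels"]
    y = small_study["agg"].xs("car", level="category")["likelihood"]
    m = sx.ExpectationModel(y, channels, subset=("N", "C"))
    cv = m.cross_validate(k=5, seed=3)
    fold0 = cv.fold_assignments[cv.fold_assignments == 0].index
    y_pert = y.copy()
    y_pert.loc[fold0] = y_pert.loc[fold0] + 10.0
    cv_pert = sx.ExpectationModel(y_pert, channels, subset=("N", "C")
                                  ).cross_validate(k=5, seed=3)
    pd.testing.assert_series_equal(cv.predictions.loc[fold0],
                                   cv_pert.predictions.loc[fold0])


def test_crossval_input_validation(small_study):
    y = small_study["agg"].xs("car", level="category")["likelihood"]
    m = sx.ExpectationModel(y, small_study["channels"], subset=("C",))
    with pytest.raises(ValueError):
        m.cross_validate(k=1)


# -- model comparison ------------------------------------------------------

def test_identical_subsets_tie_at_half(small_study):
    y = small_study["agg"].xs("car", level="category")["likelihood"]
    res = sx.compare_models(y, small_study["channels"],
                            subsets={"A": ("N",), "B": ("N",)},
                            n_splits=20, seed=1, pca_k=10)
    competitor = [s for s in res.stats.index if s != res.reference][0]
    assert res.stats.loc[competitor, "exceedance"] == pytest.approx(0.5)


def test_single_split_sd_zero(small_study):
    y = small_study["agg"].xs("car", level="category")["likelihood"]
    res = sx.compare_models(y, small_study["channels"],
                            subsets={"N": ("N",), "C": ("C",)},
                            n_splits=1, seed=1, pca_k=10)
    assert (res.stats["sd"] == 0).all()


def test_comparison_summary_renders(small_study):
    y = small_study["agg"].xs("car", level="category")["likelihood"]
    res = sx.compare_models(y, small_study["channels"],
                            subsets={"N": ("N",), "C": ("C",)},
                            n_splits=5, seed=1, pca_k=10,
                            ceiling=(0.9, 0.01))
    text = res.summary()
    assert "noise ceiling" in text and res.reference in text


# -- noise ceiling ---------------------------------------------------------

def test_spearman_brown_values_and_monotonicity():
    assert spearman_brown(0.5) == pytest.approx(2.0 / 3.0)
    grid = np.linspace(0.0, 0.99, 50)
    corrected = spearman_brown(grid)
    assert np.all(np.diff(corrected) > 0)
    assert np.all(corrected >= grid)


def test_noise_ceiling_zero_noise_is_one():
    cfg = sx.GeneratorConfig(n_scenes=40, n_subjects=4, subject_noise_sd=0.0,
                             zero_likelihood_rate=0.0, seed=8)
    scenes, channels, truth = sx.generate_scene_set(cfg)
    ratings = sx.generate_subject_ratings(scenes, truth)
    res = sx.noise_ceiling(ratings, "likelihood", "car", n_resamples=20,
                           seed=0)
    assert res.mean == pytest.approx(1.0)


def test_noise_ceiling_single_subject_error():
    ratings = make_ratings([("s1", "a", "car", 0.5, 1, 1, 1, 1),
                            ("s1", "b", "car", 0.2, 1, 1, 1, 1)])
    with pytest.raises(ValueError, match="2 subjects"):
        sx.noise_ceiling(ratings, "likelihood", "car", n_resamples=5, seed=0)


def test_model_does_not_beat_ceiling(calibrated_study, car_likelihood):
    """On data generated under the assumed model, the cross-validated model
    correlation stays at or below the noise ceiling (up to Monte-Carlo
    error)."""
    cv = sx.ExpectationModel(car_likelihood, calibrated_study["channels"],
                             subset=("N", "C")).cross_validate(k=5, seed=0)
    ceiling = sx.noise_ceiling(calibrated_study["ratings"], "likelihood",
                               "car", n_resamples=200, seed=0)
    assert cv.r <= ceiling.mean + 3 * ceiling.sd


# -- nontarget label weights ----------------------------------------------

def test_opposed_responses_give_anticorrelated_label_weights(small_study):
    channels = small_study["channels"]
    y = small_study["agg"].xs("car", level="category")["likelihood"]
    car = sx.ExpectationModel(y, channels, subset=("N", "C"),
                              category="car").fit()
    person = sx.ExpectationModel(-y, channels, subset=("N", "C"),
                                 category="person").fit()
    r, p, table = sx.nontarget_weight_correlation(car, person)
    assert r == pytest.approx(-1.0)
    assert list(table.index) == list(channels["N"].columns)


def test_nontarget_weight_correlation_requires_n_channel(small_study):
    y = small_study["agg"].xs("car", level="category")["likelihood"]
    c_only = sx.ExpectationModel(y, small_study["channels"],
                                 subset=("C",)).fit()
    with pytest.raises(ValueError):
        c_only.nontarget_label_weights()


def test_results_summary_and_serialisation(small_study):
    y = small_study["agg"].xs("car", level="category")["likelihood"]
    res = sx.ExpectationModel(y, small_study["channels"], subset=("N", "C"),
                              response="likelihood", category="car").fit()
    assert "N+C" in res.summary()
    clone = sx.LinearExpectationPredictor.from_dict(res.to_dict())
    pd.testing.assert_series_equal(
        clone.predict(small_study["channels"]), res.fittedvalues,
        check_names=False)
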