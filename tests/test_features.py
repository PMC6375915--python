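"""Target-summary features, nontarget channel, channel PCA, design assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import scenexpect as sx
from scenexpect.features import (
    N_PARTS, TARGET_FEATURE_NAMES, ChannelPCA, assemble_design,
    build_nontarget_channel, build_target_channel, compute_part_means,
    summarize_detections,
)

NAME_IDX = {name: i for i, name in enumerate(TARGET_FEATURE_NAMES)}


def make_record(scene="s0", category="car", view=1, score=-0.5,
                x=0.0, y=0.0, width=10.0, height=10.0, offsets=None):
    if offsets is None:
        offsets = tuple((0.5, 0.5) for _ in range(N_PARTS))
    return sx.DetectionRecord(scene_id=scene, category=category, view=view,
                              score=score, x=x, y=y, width=width,
                              height=height, part_offsets=offsets)


def test_threshold_counting():
    recs = [make_record(score=s) for s in (-0.5, -1.0, -1.5)]
    vec = summarize_detections(recs)
    assert vec[NAME_IDX["car_n_strong"]] == 1          # only -0.5 > -0.7
    assert vec[NAME_IDX["car_false_alarms"]] == 1      # two above -1.2, one strong
    assert len(vec) == 62


def test_single_record_geometry():
    # 100x50 box centred on the scene centre, strong score
    rec = make_record(score=-0.3, x=320 - 50, y=240 - 25, width=100, height=50)
    vec = summarize_detections([rec], frame_size=(640, 480))
    assert vec[NAME_IDX["car_mean_area"]] == pytest.approx(5000.0)
    assert vec[NAME_IDX["car_ecc1"]] == 1.0
    assert sum(vec[NAME_IDX[f"car_ecc{b}"]] for b in range(1, 6)) == 1.0
    assert vec[NAME_IDX["car_mean_score"]] == pytest.approx(-0.3)
    assert vec[NAME_IDX["car_view_car1"]] == 1.0
    # person half is all zeros
    assert not vec[31:].any()


def test_empty_scene_is_zero_vector():
    vec = summarize_detections([])
    assert vec.shape == (62,)
    assert not vec.any()


def test_eccentricity_histogram_counts_all_detections():
    recs = [make_record(x=float(x), score=-1.0) for x in (0, 100, 200, 300)]
    vec = summarize_detections(recs, frame_size=(640, 480))
    total = sum(vec[NAME_IDX[f"car_ecc{b}"]] for b in range(1, 6))
    assert total == len(recs)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.randoms(use_true_random=False))
def test_summary_is_permutation_invariant(rnd):
    recs = [make_record(score=rnd.uniform(-2, 0), x=rnd.uniform(0, 600),
                        y=rnd.uniform(0, 440), width=rnd.uniform(5, 80),
                        height=rnd.uniform(5, 80), view=rnd.choice([1, 2, 3]),
                        category=rnd.choice(["car", "person"]),
                        offsets=tuple((rnd.random(), rnd.random())
                                      for _ in range(N_PARTS)))
            for _ in range(8)]
    means = compute_part_means(recs)
    base = summarize_detections(recs, means)
    shuffled = list(recs)
    rnd.shuffle(shuffled)
    np.testing.assert_allclose(summarize_detections(shuffled, means), base,
                               rtol=0, atol=1e-12)


def test_part_deformation_two_pass():
    # two scenes; dataset-wide mean part location is the midpoint, so each
    # scene's displacement is +/- the half-offset on part 1 dx
    off_a = tuple((0.4, 0.5) if p == 0 else (0.5, 0.5) for p in range(N_PARTS))
    off_b = tuple((0.6, 0.5) if p == 0 else (0.5, 0.5) for p in range(N_PARTS))
    recs = [make_record(scene="a", offsets=off_a),
            make_record(scene="b", offsets=off_b)]
    means = compute_part_means(recs)
    np.testing.assert_allclose(means["car"][0], [0.5, 0.5])
    vec_a = summarize_detections([recs[0]], means)
    assert vec_a[NAME_IDX["car_part1_dx"]] == pytest.approx(-0.1)
    vec_b = summarize_detections([recs[1]], means)
    assert vec_b[NAME_IDX["car_part1_dx"]] == pytest.approx(0.1)


def test_invalid_records_rejected():
    with pytest.raises(ValueError):
        make_record(offsets=((0.5, 0.5),) * 7)
    with pytest.raises(ValueError):
        make_record(width=-1.0)
    with pytest.raises(ValueError):
        summarize_detections([], strong_threshold=-1.2, weak_threshold=-0.7)


def test_build_target_channel_two_pass_consistency():
    recs = [make_record(scene="a"), make_record(scene="b", score=-1.0)]
    ch = build_target_channel(recs, ["a", "b", "c"])
    assert ch.data.shape == (3, 62)
    assert not ch.data.loc["c"].any()       # no detections -> zeros
    with pytest.raises(ValueError):
        build_target_channel([make_record(scene="zz")], ["a"])


def test_nontarget_channel_rows_and_sums():
    scenes = pd.DataFrame({
        "scene_id": ["a", "b", "c"],
        "labels": ["tree|bench", "", "tree"],
    })
    ch = build_nontarget_channel(scenes, ["tree", "bench", "lamp"])
    assert ch.data.loc["a"].tolist() == [1, 1, 0]
    assert ch.data.loc["b"].tolist() == [0, 0, 0]
    assert ch.data.sum().tolist() == [2, 1, 0]   # counting oracle
    with pytest.raises(ValueError, match="unicorn"):
        build_nontarget_channel(
            pd.DataFrame({"scene_id": ["a"], "labels": ["unicorn"]}),
            ["tree"])


def test_binary_channel_matches_scene_table(small_study):
    """Thresholding the graded label-evidence channel reproduces the scene
    table's binary labels."""
    ch = build_nontarget_channel(small_study["scenes"],
                                 small_study["config"].vocabulary)
    truth = small_study["truth"]
    binary = (small_study["channels"]["N"].to_numpy()
              > truth.label_thresholds[None, :]).astype(int)
    np.testing.assert_array_equal(ch.data.to_numpy(), binary)


def test_pca_rank_one_and_orthonormality():
    rng = np.random.default_rng(0)
    rank1 = np.outer(rng.normal(size=50), rng.normal(size=8))
    pca = ChannelPCA(k=1, standardize=False).fit(pd.DataFrame(rank1))
    assert pca.variance_captured_ == pytest.approx(1.0)
    pca5 = ChannelPCA(k=5).fit(pd.DataFrame(rng.normal(size=(60, 12))))
    np.testing.assert_allclose(pca5.loadings_.T @ pca5.loadings_,
                               np.eye(5), atol=1e-8)


def test_pca_k_too_large_and_zero_variance_column():
    rng = np.random.default_rng(1)
    x = pd.DataFrame(rng.normal(size=(10, 4)))
    with pytest.raises(ValueError):
        ChannelPCA(k=5).fit(x)
    x[3] = 1.0  # constant column
    pca = ChannelPCA(k=2).fit(x)
    assert np.isfinite(pca.transform(x)).all()
    assert pca.scale_[3] == 1.0


def test_reconstruction_error_non_increasing_in_k():
    rng = np.random.default_rng(2)
    x = pd.DataFrame(rng.normal(size=(80, 15)) @ rng.normal(size=(15, 15)))
    errors = []
    for k in (2, 5, 9, 14):
        pca = ChannelPCA(k=k).fit(x)
        xs = (x.to_numpy() - pca.mean_) / pca.scale_
        recon = pca.transform(x) @ pca.loadings_.T
        errors.append(np.linalg.norm(xs - recon))
    assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))


def test_synthetic_channels_reach_variance_target(small_study):
    """The generator's low-rank construction puts >= 85% of (standardised)
    channel variance in the first 20 components."""
    for ch in sx.CHANNELS:
        pca = ChannelPCA(k=20, solver="exact").fit(small_study["channels"][ch])
        assert pca.variance_captured_ >= 0.85, ch


def test_randomized_solver_close_to_exact(small_study):
    frame = small_study["channels"]["C"]
    exact = ChannelPCA(k=20, solver="exact").fit(frame)
    rand = ChannelPCA(k=20, solver="randomized", random_state=0).fit(frame)
    assert abs(exact.variance_captured_ - rand.variance_captured_) < 0.01


def test_design_assembly_widths_and_nesting(small_study):
    channels = small_study["channels"]
    pcas = {ch: ChannelPCA(k=20).fit(channels[ch]) for ch in sx.CHANNELS}
    d_n = assemble_design({"N"}, pcas, channels)
    d_tnc = assemble_design({"T", "N", "C"}, pcas, channels)
    assert d_n.shape[1] == 20 and d_tnc.shape[1] == 60
    # canonical order makes nested designs column-submatrices of TNC
    np.testing.assert_array_equal(d_tnc[:, 20:40], d_n)
    d_nc = assemble_design(["C", "N"], pcas, channels)  # order normalised
    np.testing.assert_array_equal(d_tnc[:, 20:], d_nc)
    with pytest.raises(ValueError):
        assemble_design(set(), pcas, channels)


def test_projecting_mean_row_gives_zero_scores(small_study):
    frame = small_study["channels"]["T"]
    pca = ChannelPCA(k=10).fit(frame)
    mean_row = pd.DataFrame([frame.mean()], columns=frame.columns)
    np.testing.assert_allclose(pca.transform(mean_row), 0.0, atol=1e-10)


def test_pca_round_trip_serialisation(small_study):
    pca = ChannelPCA(k=8).fit(small_study["channels"]["T"])
    clone = ChannelPCA.from_dict(pca.to_dict())
    np.testing.assert_allclose(
        clone.transform(small_study["channels"]["T"]),
        pca.transform(small_study["channels"]["T"]), atol=1e-12)
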