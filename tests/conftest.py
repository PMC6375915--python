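"""Shared fixtures: synthetic studies at two scales.

``small_study`` keeps unit tests fast; ``calibrated_study`` reproduces the
full study conditions (650 scenes, 11 subjects, rating noise placing the
likelihood ceiling near 0.9) for the end-to-end behavioural checks.
"""

import numpy as np
import pandas as pd
import pytest

import scenexpect as sx


@pytest.fixture(scope="session")
def small_study():
    cfg = sx.GeneratorConfig(n_scenes=160, n_subjects=6, seed=123)
    scenes, channels, truth = sx.generate_scene_set(cfg)
    ratings = sx.generate_subject_ratings(scenes, truth)
    agg = sx.aggregate_ratings(ratings)
    return {"config": cfg, "scenes": scenes, "channels": channels,
            "truth": truth, "ratings": ratings, "agg": agg}


@pytest.fixture(scope="session")
def calibrated_study():
    """Full-size study with no forced zeros and subject noise set so the
    closed-form likelihood ceiling is ~0.9."""
    cfg = sx.GeneratorConfig(n_scenes=650, n_subjects=11,
                             subject_noise_sd=0.133,
                             zero_likelihood_rate=0.0, seed=2024)
    scenes, channels, truth = sx.generate_scene_set(cfg)
    ratings = sx.generate_subject_ratings(scenes, truth)
    agg = sx.aggregate_ratings(ratings)
    return {"config": cfg, "scenes": scenes, "channels": channels,
            "truth": truth, "ratings": ratings, "agg": agg}


@pytest.fixture(scope="session")
def car_likelihood(calibrated_study):
    return calibrated_study["agg"].xs("car", level="category")["likelihood"]


def make_ratings(rows):
    """Tiny ratings table from (subject, scene, category, likelihood, box...)."""
    cols = ["subject_id", "scene_id", "category", "likelihood",
            "box_x", "box_y", "box_area", "box_aspect"]
    padded = [list(r) + [np.nan] * (len(cols) - len(r)) for r in rows]
    return pd.DataFrame(padded, columns=cols)
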