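"""Shared fixtures: synthetic recordings and a small labeled cohort.

Session-scoped so the (comparatively) expensive feature extraction for the
20-subject cohort happens once.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gaitfall.feature_table import FeatureMatrix, build_matrix
from gaitfall.gait_events import detect_steps
from gaitfall.preprocess import preprocess_recording
from gaitfall.synthetic import CohortSpec, GaitProfile, generate_cohort, generate_subject


@pytest.fixture(scope="session")
def clean_rec():
    """Perfectly periodic walker: f_step 1.8 Hz, no jitter, no noise, 60 s."""
    profile = GaitProfile(f_step_hz=1.8, timing_jitter=0.0, amp_jitter=0.0, noise_sd=0.0)
    return generate_subject(profile, duration_s=60, fs_hz=100, seed=11, subject_id="clean")


@pytest.fixture(scope="session")
def jittered_rec():
    """Faller-regime walker: 8% timing jitter, 15% amplitude jitter."""
    profile = GaitProfile(f_step_hz=1.8, timing_jitter=0.08, amp_jitter=0.15)
    return generate_subject(profile, duration_s=60, fs_hz=100, seed=12, subject_id="jit")


@pytest.fixture(scope="session")
def clean_pre(clean_rec):
    return preprocess_recording(clean_rec)


@pytest.fixture(scope="session")
def clean_seg(clean_pre):
    return detect_steps(clean_pre.axis_step("V"), clean_pre.fs_hz)


@pytest.fixture(scope="session")
def cohort20():
    """10 fallers / 10 non-fallers, 30 s at 100 Hz."""
    return generate_cohort(CohortSpec(n_fallers=10, n_nonfallers=10, duration_s=30, seed=3))


@pytest.fixture(scope="session")
def matrix20(cohort20) -> FeatureMatrix:
    return build_matrix(cohort20)


def planted_matrix(
    n_per_class: int,
    n_features: int = 30,
    n_informative: int = 5,
    shift: float = 1.5,
    seed: int = 0,
) -> tuple[FeatureMatrix, list[str]]:
    """Feature matrix with known informative columns (class-shifted Gaussians).

    Returns the matrix and the planted column names. Used where ground truth
    about which features carry the class signal is needed.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(size=(n, n_features))
    labels = np.array(["faller"] * n_per_class + ["non_faller"] * n_per_class)
    planted = [f"planted_{j}" for j in range(n_informative)]
    X[labels == "faller", :n_informative] += shift
    cols = planted + [f"noise_{j}" for j in range(n_features - n_informative)]
    ids = [f"S{i:03d}" for i in range(n)]
    return (
        FeatureMatrix(X=pd.DataFrame(X, index=ids, columns=cols), labels=pd.Series(labels, index=ids)),
        planted,
    )
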