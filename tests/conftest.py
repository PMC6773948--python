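"""Shared fixtures: seeded synthetic benchmarks and trained models.

The expensive artefacts (the 400-patch cascade training set, the trained
hand-engineered bundle) are session-scoped so the whole suite builds each
of them exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcquant.benchmark import benchmark_patches, train_cascade, train_hand_engineered
from tcquant.cascade import CascadeConfig
from tcquant.synthetic import NucleusClassParams, SyntheticPatchSpec, generate_patch

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Small-canvas spec for fast unit tests; class morphology matches the
#: full-size default so separability properties carry over.
SMALL_BASE = SyntheticPatchSpec(width_px=128, height_px=128)


def small_spec(**kwargs) -> SyntheticPatchSpec:
    merged = {"width_px": 128, "height_px": 128}
    merged.update(kwargs)
    return SyntheticPatchSpec(**merged)


@pytest.fixture(scope="session")
def bench_train_he():
    """Hand-engineered training patches (40, seeded)."""
    return benchmark_patches(40, seed=11)


@pytest.fixture(scope="session")
def bench_test():
    """Shared held-out benchmark: 100 patches spanning healthy to ~90%."""
    return benchmark_patches(100, seed=22)


@pytest.fixture(scope="session")
def bench_train_cascade():
    """Cascade training patches (400, seeded)."""
    return benchmark_patches(400, seed=1001)


@pytest.fixture(scope="session")
def he_models(bench_train_he):
    return train_hand_engineered(bench_train_he)


@pytest.fixture(scope="session")
def cascade_models(bench_train_cascade):
    return train_cascade(bench_train_cascade, CascadeConfig(seed=0))


@pytest.fixture(scope="session")
def he_scores(he_models, bench_test):
    """Hand-engineered TCScore per test patch, computed once."""
    from tcquant.scoring import score_patch_hand_engineered

    return {
        p.patch_id: score_patch_hand_engineered(p.rgb, he_models, p.patch_id)
        for p in bench_test
    }


@pytest.fixture(scope="session")
def mixed_patch():
    """One full-size patch with all three classes present."""
    spec = SyntheticPatchSpec(
        n_lymphocyte=20, n_epithelial=15, n_malignant=25, seed=7
    )
    return generate_patch(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
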