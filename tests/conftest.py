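"""Shared fixtures: small seeded synthetic cohorts and NIfTI scratch files."""

from __future__ import annotations

import numpy as np
import pytest

from normatlas import (
    CohortSpec,
    CohortStack,
    MaskedVolume,
    VolumeGrid,
    generate_atrophied_subjects,
    generate_normal_cohort,
)


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """Desk-scale cohort spec: 16^3 grid keeps every test fast."""
    return CohortSpec(shape=(16, 16, 16), n_normal=40, n_atrophied=6, seed=20260921)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_normal_cohort(small_spec)


@pytest.fixture(scope="session")
def small_atrophied(small_spec):
    return generate_atrophied_subjects(small_spec)


@pytest.fixture()
def tiny_grid() -> VolumeGrid:
    return VolumeGrid((4, 4, 4), np.eye(4))


def make_cohort(values: np.ndarray) -> CohortStack:
    """Wrap a (n_subjects, n_voxels) array in a CohortStack on a flat grid."""
    values = np.asarray(values, dtype=float)
    n_vox = values.shape[1]
    shape = (n_vox, 1, 1)
    mask = np.ones(shape, dtype=bool)
    g = VolumeGrid(shape, np.eye(4))
    return CohortStack(g, mask, values, [f"s{i}" for i in range(values.shape[0])])


@pytest.fixture()
def flat_cohort_factory():
    return make_cohort
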