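"""Shared fixtures: tiny grids, a small simulated study, helper builders."""

from __future__ import annotations

import numpy as np
import pytest

from lesionnet import (
    BinaryMask,
    Connectome,
    SimulationConfig,
    SubjectTimeSeries,
    VolumeGrid,
    network_value_matrix,
    simulate_connectome,
    simulate_lesion_cohort,
)


@pytest.fixture
def grid8() -> VolumeGrid:
    return VolumeGrid.isotropic((8, 8, 8), 2.0)


@pytest.fixture
def full_mask(grid8) -> BinaryMask:
    return BinaryMask(grid8, np.ones(grid8.shape, bool))


def make_mask(grid: VolumeGrid, voxels: list[tuple[int, int, int]]) -> BinaryMask:
    arr = np.zeros(grid.shape, bool)
    for ijk in voxels:
        arr[ijk] = True
    return BinaryMask(grid, arr)


def make_connectome(
    data_per_subject: list[np.ndarray],
    grid: VolumeGrid,
    brain: BinaryMask,
) -> Connectome:
    return Connectome(
        tuple(SubjectTimeSeries(grid, brain, d) for d in data_per_subject)
    )


#: a scaled-down study configuration used by several inference tests:
#: 12^3 grid, 8-subject connectome, 40 lesions across 5 datasets
SMALL_STUDY = dict(
    shape=(12, 12, 12),
    brain_center=(6.0, 6.0, 6.0),
    brain_radius=5.0,
    node_center=(9.0, 6.0, 6.0),
    node_radius=1.5,
    t_points=100,
    n_subjects=8,
    cohort_size=8,
    lesion_radius=(1.0, 2.0),
)


@pytest.fixture(scope="session")
def small_study():
    """One seeded small simulated study shared across tests (read-only)."""
    cfg = SimulationConfig(seed=7, **SMALL_STUDY)
    connectome, truth = simulate_connectome(cfg)
    cohort, truth = simulate_lesion_cohort(cfg, truth)
    values = network_value_matrix(connectome, [rec.mask for rec in cohort])
    return {
        "config": cfg,
        "connectome": connectome,
        "cohort": cohort,
        "truth": truth,
        "network_values": values,
    }
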