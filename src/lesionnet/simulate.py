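"""Synthetic connectomes, lesion cohorts and DBS cohorts with known truth.

The generative model is factor-structured: every voxel ``v`` carries
``x_v(t) = lam(v) f(t) + eta sin(theta_v) g(t) + eta cos(theta_v) h(t) +
sigma eps(t)`` with ``f``, ``g``, ``h`` and ``eps`` iid standard normal. The
primary loading field ``lam`` is +1 inside a planted "node" sphere and
follows a linear gradient spanning [-1, +1] along the x axis elsewhere, so
lesions at the negative end of the gradient are anticorrelated with the node
— the epilepsy-prone configuration. The quadrature pair ``(g, h)`` is an
epilepsy-irrelevant nuisance network of constant power ``eta^2`` everywhere
outside the node (phase ``theta`` varies smoothly along y, loadings vanish
inside the node): it adds outcome-independent connectivity variance at every
non-node voxel, which is what makes the planted node — the only
nuisance-free region — the unique peak of the group contrast rather than one
of many equivalent gradient voxels. With the nuisance off, two voxels with
primary loadings ``la``, ``lb`` correlate at ``la*lb / sqrt((la^2 +
s^2)(lb^2 + s^2))`` — e.g. 0.5 for two node voxels at ``sigma = 1``.

Epilepsy labels follow a logistic model on the standardized, sign-flipped
true lesion-to-node loading; defaults plant an odds ratio of 2.8 per SD on a
baseline prevalence of 0.35, and a DBS outcome slope/noise pair whose
population correlation is 25 / sqrt(25^2 + 31^2) = 0.628 — desk-scale analogs
of the effect sizes the method is meant to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import Cohort, LesionRecord
from .connectome import Connectome, SubjectTimeSeries
from .dbs import DBSCohort, DBSRecord
from .grids import BinaryMask, RegionAtlas, VolumeGrid

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_connectome",
    "simulate_lesion_cohort",
    "simulate_dbs_cohort",
    "make_synthetic_atlas",
    "sphere_mask",
]

_DATASET_NAMES = ("stroke", "hematoma", "trauma", "tumor", "tuber")


@dataclass(frozen=True)
class SimulationConfig:
    """All generator knobs, with the study-condition defaults."""

    shape: tuple[int, int, int] = (18, 18, 18)
    voxel_mm: float = 2.0
    brain_center: tuple[float, float, float] = (9.0, 9.0, 9.0)
    brain_radius: float = 8.0
    t_points: int = 150
    n_subjects: int = 20
    node_center: tuple[float, float, float] = (15.0, 9.0, 9.0)
    node_radius: float = 2.0
    noise_sigma: float = 1.0
    nuisance_loading: float = 1.0  # amplitude eta of the quadrature nuisance pair
    n_datasets: int = 5
    cohort_size: int = 24  # lesions per dataset
    beta0: float = -0.619  # baseline prevalence logistic(-0.619) ~ 0.35
    beta1: float = math.log(2.8)  # planted odds ratio per SD of risk
    lesion_radius: tuple[float, float] = (1.0, 3.0)
    dataset_size_multipliers: tuple[float, ...] = (0.6, 0.8, 1.0, 1.3, 1.6)
    dbs_n: int = 30
    dbs_slope: float = 25.0
    dbs_noise: float = 31.0
    dbs_intercept: float = 30.0
    dbs_locus: tuple[float, float, float] = (13.0, 9.0, 9.0)
    dbs_jitter: float = 3.0
    dbs_radius: tuple[float, float] = (1.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.t_points, self.n_subjects, self.cohort_size, self.n_datasets,
               self.dbs_n) < 1:
            raise ValueError("all sizes must be positive")
        if not math.isfinite(self.beta1):
            raise ValueError("beta1 must be finite")
        d = np.linalg.norm(np.subtract(self.node_center, self.brain_center))
        if d + self.node_radius > self.brain_radius + 1e-9:
            raise ValueError("node sphere must lie inside the brain")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    @property
    def dbs_population_r(self) -> float:
        """Planted outcome correlation s / sqrt(s^2 + sigma_o^2)."""
        return self.dbs_slope / math.hypot(self.dbs_slope, self.dbs_noise)


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    config: SimulationConfig
    node: BinaryMask
    loading: np.ndarray = field(repr=False)
    nuisance_loading: np.ndarray = field(repr=False)
    lesion_connectivity: np.ndarray | None = None  # mean loading per lesion
    lesion_risk: np.ndarray | None = None  # standardized, sign-flipped
    lesion_prob: np.ndarray | None = None
    dbs_true_z: np.ndarray | None = None
    dbs_coefficients: dict | None = None


def sphere_mask(grid: VolumeGrid, center, radius: float) -> BinaryMask:
    """Voxels whose index distance to ``center`` is <= ``radius``."""
    coords = np.indices(grid.shape, dtype=float)
    d2 = sum((coords[k] - center[k]) ** 2 for k in range(3))
    return BinaryMask(grid, d2 <= radius**2)


def _loading_fields(config: SimulationConfig, grid: VolumeGrid, node: BinaryMask):
    """Primary loading (x gradient, +1 in node) and the (2, ...) nuisance pair."""
    coords = np.indices(grid.shape, dtype=float)
    cx, cy, _ = config.brain_center
    lam = np.clip((coords[0] - cx) / config.brain_radius, -1.0, 1.0)
    lam[node.voxels] = 1.0
    # phase winds 4 full periods across the brain (period ~ 4 voxels, the
    # typical lesion diameter): nuisance loadings average out over extended
    # ROIs but stay coherent within single lesions
    theta = 4.0 * np.pi * np.clip((coords[1] - cy) / config.brain_radius, -1.0, 1.0)
    nuis = config.nuisance_loading * np.stack([np.sin(theta), np.cos(theta)])
    nuis[:, node.voxels] = 0.0
    return lam, nuis


def _grid_brain_node(config: SimulationConfig):
    grid = VolumeGrid.isotropic(config.shape, config.voxel_mm)
    brain = sphere_mask(grid, config.brain_center, config.brain_radius)
    node = sphere_mask(grid, config.node_center, config.node_radius)
    return grid, brain, node


def simulate_connectome(config: SimulationConfig) -> tuple[Connectome, GroundTruth]:
    """Draw the multi-subject voxel time series of the normative connectome."""
    grid, brain, node = _grid_brain_node(config)
    lam, nuis = _loading_fields(config, grid, node)
    idx = brain.flat_indices()
    lam_b = lam.ravel()[idx]
    nuis_b = nuis.reshape(2, -1)[:, idx]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    subjects = []
    for _ in range(config.n_subjects):
        f = rng.standard_normal(config.t_points)
        gh = rng.standard_normal((config.t_points, 2))
        eps = rng.standard_normal((config.t_points, idx.size))
        data = np.outer(f, lam_b) + gh @ nuis_b + config.noise_sigma * eps
        subjects.append(SubjectTimeSeries(grid, brain, data))
    truth = GroundTruth(config=config, node=node, loading=lam, nuisance_loading=nuis)
    return Connectome(tuple(subjects)), truth


def _dataset_names(n: int) -> list[str]:
    if n <= len(_DATASET_NAMES):
        return list(_DATASET_NAMES[:n])
    return [f"dataset{i + 1}" for i in range(n)]


def simulate_lesion_cohort(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[Cohort, GroundTruth]:
    """Random spherical lesions with logistic epilepsy labels.

    Dataset labels rotate round-robin; each dataset scales its lesion radii
    by a fixed multiplier, planting the lesion-size-by-dataset confound that
    covariate adjustment must absorb.
    """
    config = truth.config if config is None else config
    grid, brain, _ = _grid_brain_node(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    names = _dataset_names(config.n_datasets)
    mult = list(config.dataset_size_multipliers)
    while len(mult) < config.n_datasets:
        mult.append(1.0)
    n = config.n_datasets * config.cohort_size
    brain_idx = brain.flat_indices()
    lam_flat = truth.loading.ravel()
    records = []
    conn = np.empty(n)
    r0, r1 = config.lesion_radius
    for i in range(n):
        ds = i % config.n_datasets
        center_flat = rng.choice(brain_idx)
        center = np.unravel_index(center_flat, grid.shape)
        radius = rng.uniform(r0, r1) * mult[ds]
        lesion = sphere_mask(grid, center, radius).intersect(brain)
        conn[i] = lam_flat[lesion.flat_indices()].mean()
        records.append((f"{names[ds]}-{i:04d}", names[ds], lesion))
    sd = conn.std()
    risk = -(conn - conn.mean()) / sd if sd > 0 else np.zeros(n)
    prob = 1.0 / (1.0 + np.exp(-(config.beta0 + config.beta1 * risk)))
    labels = (rng.random(n) < prob).astype(int)
    cohort = Cohort(
        tuple(
            LesionRecord(rid, ds, mask, int(lab))
            for (rid, ds, mask), lab in zip(records, labels)
        )
    )
    truth = replace(
        truth, lesion_connectivity=conn, lesion_risk=risk, lesion_prob=prob
    )
    return cohort, truth


def simulate_dbs_cohort(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[DBSCohort, GroundTruth]:
    """Stimulation-site spheres near a fixed locus, outcome linear in loading.

    Outcome = intercept + slope * z + noise, truncated to [-100, 100]%, where
    ``z`` is the standardized true site loading; truncation mildly attenuates
    the planted correlation.
    """
    config = truth.config if config is None else config
    grid, brain, _ = _grid_brain_node(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    lam_flat = truth.loading.ravel()
    brain_vox = brain.voxels
    locus = np.asarray(config.dbs_locus, float)
    masks = []
    conn = np.empty(config.dbs_n)
    for i in range(config.dbs_n):
        while True:
            center = locus + rng.uniform(-config.dbs_jitter, config.dbs_jitter, 3)
            ijk = tuple(np.clip(np.round(center).astype(int), 0, np.array(grid.shape) - 1))
            if brain_vox[ijk]:
                break
        radius = rng.uniform(*config.dbs_radius)
        vta = sphere_mask(grid, ijk, radius).intersect(brain)
        masks.append(vta)
        conn[i] = lam_flat[vta.flat_indices()].mean()
    sd = conn.std()
    z = (conn - conn.mean()) / sd if sd > 0 else np.zeros(config.dbs_n)
    outcome = np.clip(
        config.dbs_intercept + config.dbs_slope * z
        + config.dbs_noise * rng.standard_normal(config.dbs_n),
        -100.0,
        100.0,
    )
    amplitude = rng.uniform(1.0, 5.0, config.dbs_n)  # independent of outcome
    cohort = DBSCohort(
        tuple(
            DBSRecord(f"dbs-{i:03d}", vta, float(out), float(amp))
            for i, (vta, out, amp) in enumerate(zip(masks, outcome, amplitude))
        )
    )
    truth = replace(
        truth,
        dbs_true_z=z,
        dbs_coefficients={
            "slope": config.dbs_slope,
            "noise_sd": config.dbs_noise,
            "intercept": config.dbs_intercept,
            "population_r": config.dbs_population_r,
        },
    )
    return cohort, truth


def make_synthetic_atlas(
    grid: VolumeGrid,
    brain: BinaryMask,
    inner_radius: float = 5.0,
    center: tuple[float, float, float] | None = None,
) -> RegionAtlas:
    """Two-region toy parcellation: an inner 'subcortex' core and a 'cortex'
    shell partitioning the brain mask."""
    if center is None:
        center = tuple((s - 1) / 2 + 0.5 for s in grid.shape)
    core = sphere_mask(grid, center, inner_radius)
    labels = np.zeros(grid.shape, np.int32)
    labels[brain.voxels] = 1
    labels[brain.voxels & core.voxels] = 2
    return RegionAtlas(grid, labels, {1: "cortex", 2: "subcortex"})
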