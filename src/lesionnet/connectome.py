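"""Seed-based functional connectivity against a multi-subject normative connectome.

A "lesion network map" seeds one lesion mask in every connectome subject's
resting-state time series, correlates the mean seed signal with every brain
voxel, Fisher r-to-z transforms the correlations, and aggregates across
subjects (voxelwise mean by default, one-sample t optionally). ROI-to-ROI
connectivity applies the same recipe between two masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import BinaryMask, GridMismatchError, ScalarMap, VolumeGrid, save_mask

__all__ = [
    "SubjectTimeSeries",
    "Connectome",
    "NetworkMap",
    "fisher_z",
    "extract_seed_signal",
    "seed_connectivity_map",
    "lesion_network_map",
    "network_value_matrix",
    "roi_connectivity",
    "load_connectome",
    "save_connectome",
]

#: correlations are clamped to +/- (1 - Z_CLAMP) before atanh so that a seed
#: correlated with itself gets a finite z (atanh(1 - 1e-7) ~ 8.4)
Z_CLAMP = 1e-7


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing Fisher transform z = atanh(r), clamped near +/-1."""
    r = np.clip(r, -1.0 + Z_CLAMP, 1.0 - Z_CLAMP)
    return np.arctanh(r)


@dataclass(frozen=True)
class SubjectTimeSeries:
    """One subject's resting-state series, packed as (T, n_brain_voxels).

    Column ``j`` holds the series of the ``j``-th brain voxel in C-order
    flattening of the grid (``brain.flat_indices()``). Columns with zero
    temporal variance are flagged and excluded from correlation validity.
    """

    grid: VolumeGrid
    brain: BinaryMask
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.grid.require_match(self.brain.grid, "brain mask")
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2 or data.shape[1] != self.brain.n_true:
            raise ValueError(
                f"data must be (T, {self.brain.n_true}), got {data.shape}"
            )
        if data.shape[0] < 3:
            raise ValueError("need at least 3 time points")
        object.__setattr__(self, "data", data)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def constant_columns(self) -> np.ndarray:
        """Boolean flag per brain voxel: zero temporal variance."""
        return self.data.std(axis=0) == 0.0

    @classmethod
    def from_4d(cls, volume_4d: np.ndarray, grid: VolumeGrid, brain: BinaryMask) -> "SubjectTimeSeries":
        """Pack an (nx, ny, nz, T) array into brain-voxel columns."""
        vol = np.asarray(volume_4d, dtype=np.float64)
        if vol.shape[:3] != grid.shape:
            raise GridMismatchError("4D volume does not match grid shape")
        flat = vol.reshape(-1, vol.shape[3])  # C order
        return cls(grid, brain, flat[brain.flat_indices()].T)


@dataclass(frozen=True)
class Connectome:
    """Subjects sharing one grid and brain mask."""

    subjects: tuple[SubjectTimeSeries, ...]

    def __post_init__(self) -> None:
        subjects = tuple(self.subjects)
        if not subjects:
            raise ValueError("connectome needs at least one subject")
        ref = subjects[0]
        for sub in subjects[1:]:
            ref.grid.require_match(sub.grid, "subject")
            if not np.array_equal(ref.brain.voxels, sub.brain.voxels):
                raise ValueError("subjects differ in brain mask")
        object.__setattr__(self, "subjects", subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def grid(self) -> VolumeGrid:
        return self.subjects[0].grid

    @property
    def brain(self) -> BinaryMask:
        return self.subjects[0].brain


# ---------------------------------------------------------------------------
# Seed connectivity

def _seed_columns(subject: SubjectTimeSeries, seed: BinaryMask) -> np.ndarray:
    subject.grid.require_match(seed.grid, "seed")
    brain_idx = subject.brain.flat_indices()
    pos = np.searchsorted(brain_idx, seed.intersect(subject.brain).flat_indices())
    if pos.size == 0:
        raise ValueError("seed mask does not intersect the brain mask")
    return pos


def extract_seed_signal(subject: SubjectTimeSeries, seed: BinaryMask) -> np.ndarray:
    """Unweighted mean time series over seed ∩ brain voxels (length T)."""
    cols = _seed_columns(subject, seed)
    return subject.data[:, cols].mean(axis=1)


def _corr_with_columns(signal: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Pearson r of one series against every column; zero-variance columns -> 0."""
    s = signal - signal.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0.0:
        raise ValueError("seed signal is constant; correlation undefined")
    x = data - data.mean(axis=0)
    norms = np.linalg.norm(x, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (s @ x) / (s_norm * norms)
    r[norms == 0.0] = 0.0
    return np.clip(r, -1.0, 1.0)


def seed_connectivity_map(subject: SubjectTimeSeries, seed: BinaryMask) -> ScalarMap:
    """Per-voxel Pearson r between the seed signal and every brain voxel."""
    r = _corr_with_columns(extract_seed_signal(subject, seed), subject.data)
    vol = np.zeros(subject.grid.shape)
    vol.ravel()[subject.brain.flat_indices()] = r
    return ScalarMap(subject.grid, vol, subject.brain.voxels.copy())


@dataclass(frozen=True)
class NetworkMap:
    """Aggregated Fisher-z connectivity of one seed across subjects."""

    map: ScalarMap
    n_subjects: int
    aggregate: str  # "mean" | "tstat"


def network_value_matrix(
    connectome: Connectome,
    seeds: list[BinaryMask],
    aggregate: str = "mean",
) -> np.ndarray:
    """(n_seeds, n_brain_voxels) aggregated z-connectivity, one row per seed.

    The batch workhorse behind :func:`lesion_network_map`: per subject, all
    seed signals are correlated with all brain voxels in one pass.
    """
    if aggregate not in ("mean", "tstat"):
        raise ValueError("aggregate must be 'mean' or 'tstat'")
    if aggregate == "tstat" and len(connectome) < 2:
        raise ValueError("t-statistic aggregation needs >= 2 subjects")
    n_vox = connectome.brain.n_true
    acc = np.zeros((len(seeds), n_vox))
    acc2 = np.zeros_like(acc) if aggregate == "tstat" else None
    for subject in connectome.subjects:
        sig = np.column_stack([extract_seed_signal(subject, s) for s in seeds])
        sc = sig - sig.mean(axis=0)
        s_norm = np.linalg.norm(sc, axis=0)
        if np.any(s_norm == 0.0):
            raise ValueError("a seed signal is constant for some subject")
        x = subject.data - subject.data.mean(axis=0)
        norms = np.linalg.norm(x, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (sc.T @ x) / np.outer(s_norm, norms)
        r[:, norms == 0.0] = 0.0
        z = fisher_z(np.clip(r, -1.0, 1.0))
        acc += z
        if acc2 is not None:
            acc2 += z * z
    n = len(connectome)
    mean = acc / n
    if aggregate == "mean":
        return mean
    sd = np.sqrt(np.maximum(acc2 / n - mean**2, 0.0) * n / (n - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0.0] = 0.0
    return t


def lesion_network_map(
    connectome: Connectome, seed: BinaryMask, aggregate: str = "mean"
) -> NetworkMap:
    """Aggregate Fisher-z connectivity of one seed across all subjects."""
    row = network_value_matrix(connectome, [seed], aggregate)[0]
    vol = np.zeros(connectome.grid.shape)
    vol.ravel()[connectome.brain.flat_indices()] = row
    smap = ScalarMap(connectome.grid, vol, connectome.brain.voxels.copy())
    return NetworkMap(smap, len(connectome), aggregate)


def roi_connectivity(
    connectome: Connectome, seed: BinaryMask, roi: BinaryMask
) -> float:
    """Mean (across subjects) Fisher-z correlation between two mask signals."""
    zs = []
    for subject in connectome.subjects:
        a = extract_seed_signal(subject, seed)
        b = extract_seed_signal(subject, roi)
        ac = a - a.mean()
        bc = b - b.mean()
        na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
        if na == 0.0 or nb == 0.0:
            raise ValueError("constant mask signal; correlation undefined")
        zs.append(fisher_z(float(np.clip(ac @ bc / (na * nb), -1.0, 1.0))))
    return float(np.mean(zs))


# ---------------------------------------------------------------------------
# On-disk format: manifest TSV + per-subject 4D NIfTI (or packed .npy)

def save_connectome(connectome: Connectome, out_dir: str | Path) -> Path:
    """Write brain mask, per-subject 4D NIfTI volumes, and a manifest TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_mask(connectome.brain, out_dir / "brain_mask.nii.gz")
    rows = []
    idx = connectome.brain.flat_indices()
    for i, sub in enumerate(connectome.subjects):
        vol = np.zeros((connectome.grid.n_voxels, sub.n_timepoints), dtype=np.float32)
        vol[idx] = sub.data.T
        img = nib.Nifti1Image(
            vol.reshape(*connectome.grid.shape, sub.n_timepoints),
            connectome.grid.affine,
        )
        name = f"subject-{i:03d}.nii.gz"
        nib.save(img, out_dir / name)
        rows.append({"subject": f"sub{i:03d}", "path": name})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def load_connectome(manifest_path: str | Path) -> Connectome:
    """Read a connectome written by :func:`save_connectome`.

    The manifest directory must contain ``brain_mask.nii.gz``; subject files
    may be 4D NIfTI or packed ``.npy`` arrays of shape (T, n_brain_voxels).
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    brain_img = nib.load(str(root / "brain_mask.nii.gz"))
    grid = VolumeGrid(tuple(brain_img.shape[:3]), brain_img.affine)
    brain = BinaryMask(grid, np.asarray(brain_img.dataobj) > 0)
    table = pd.read_csv(manifest_path, sep="\t")
    subjects = []
    for _, row in table.iterrows():
        p = root / str(row["path"])
        if p.suffix == ".npy":
            subjects.append(SubjectTimeSeries(grid, brain, np.load(p)))
        else:
            img = nib.load(str(p))
            grid.require_match(VolumeGrid(tuple(img.shape[:3]), img.affine), str(p))
            subjects.append(
                SubjectTimeSeries.from_4d(np.asarray(img.dataobj), grid, brain)
            )
    return Connectome(tuple(subjects))
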