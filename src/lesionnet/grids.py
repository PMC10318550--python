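"""Volumetric data model: grids, binary masks, scalar maps, region atlases.

All volumes in one analysis share a single :class:`VolumeGrid` (shape plus
voxel->world affine). No resampling is performed anywhere in the package:
inputs that do not share the reference grid are rejected outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GridMismatchError",
    "EmptyMaskError",
    "VolumeGrid",
    "BinaryMask",
    "ScalarMap",
    "RegionAtlas",
    "load_mask",
    "save_mask",
    "save_scalar_map",
    "lesion_volume",
    "overlap_map",
    "region_damage",
]

#: tolerance for affine / shape agreement between volumes
AFFINE_TOL = 1e-4


class GridMismatchError(ValueError):
    """Two volumes do not share a voxel grid (shape or affine differ)."""


class EmptyMaskError(ValueError):
    """A mask that must contain at least one voxel is empty."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel grid with a voxel-to-world affine (mm).

    Parameters
    ----------
    shape : tuple of int
        Voxel counts ``(nx, ny, nz)``, each >= 1.
    affine : (4, 4) ndarray
        Voxel-index to world-coordinate transform; must be invertible.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        if len(shape) != 3 or any(n < 1 for n in shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape!r}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        affine = affine.copy()
        affine.flags.writeable = False
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_mm: float = 2.0) -> "VolumeGrid":
        """Axis-aligned grid with cubic voxels of side ``voxel_mm``."""
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls(shape, aff)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length per axis in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def matches(self, other: "VolumeGrid", tol: float = AFFINE_TOL) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, atol=tol)
        )

    def require_match(self, other: "VolumeGrid", what: str = "volume") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"{what} grid {other.shape} does not match reference grid "
                f"{self.shape} (affines differ beyond {AFFINE_TOL})"
            )


@dataclass(frozen=True)
class BinaryMask:
    """A boolean volume (lesion, stimulation site, brain or node mask)."""

    grid: VolumeGrid
    voxels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {vox.shape} does not match grid {self.grid.shape}"
            )
        vox = vox.astype(bool).copy()
        vox.flags.writeable = False
        object.__setattr__(self, "voxels", vox)

    @property
    def n_true(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_true == 0

    @property
    def volume_mm3(self) -> float:
        return self.n_true * self.grid.voxel_volume

    def intersect(self, other: "BinaryMask") -> "BinaryMask":
        self.grid.require_match(other.grid, "mask")
        return BinaryMask(self.grid, self.voxels & other.voxels)

    def flat_indices(self) -> np.ndarray:
        """Indices of true voxels in the C-order flattening of the grid."""
        return np.flatnonzero(self.voxels.ravel(order="C"))


@dataclass(frozen=True)
class ScalarMap:
    """A real-valued volume with an explicit validity (analysis) mask."""

    grid: VolumeGrid
    values: np.ndarray = field(repr=False)
    valid: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        if vals.shape != self.grid.shape or valid.shape != self.grid.shape:
            raise GridMismatchError("scalar map shape does not match grid")
        if not np.all(np.isfinite(vals[valid])):
            raise ValueError("scalar map has non-finite values inside its valid mask")
        vals = vals.copy()
        vals.flags.writeable = False
        valid = valid.copy()
        valid.flags.writeable = False
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "valid", valid)


@dataclass(frozen=True)
class RegionAtlas:
    """Integer-labelled parcellation (0 = background) with region names."""

    grid: VolumeGrid
    labels: np.ndarray = field(repr=False)
    names: dict[int, str]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.shape:
            raise GridMismatchError("atlas shape does not match grid")
        if labels.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        present = set(np.unique(labels).tolist())
        names = {int(k): str(v) for k, v in self.names.items()}
        missing = [name for lab, name in names.items() if lab not in present]
        if missing:
            raise ValueError(f"named regions absent from atlas volume: {missing}")
        if 0 in names:
            raise ValueError("label 0 is reserved for background")
        labels = labels.astype(np.int32).copy()
        labels.flags.writeable = False
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "names", names)

    def label_of(self, region: str) -> int:
        for lab, name in self.names.items():
            if name == region:
                return lab
        raise KeyError(f"unknown region {region!r}; known: {sorted(self.names.values())}")

    @classmethod
    def from_files(cls, labels_path: str | Path, names_tsv: str | Path) -> "RegionAtlas":
        """Load a labelled NIfTI plus a two-column TSV (label, name)."""
        img = nib.load(str(labels_path))
        grid = VolumeGrid(tuple(img.shape[:3]), img.affine)
        table = pd.read_csv(names_tsv, sep="\t")
        names = dict(zip(table["label"].astype(int), table["name"].astype(str)))
        return cls(grid, np.asarray(img.dataobj), names)


# ---------------------------------------------------------------------------
# NIfTI I/O

def load_mask(path: str | Path, reference: VolumeGrid | None = None) -> BinaryMask:
    """Load a binary mask from a NIfTI file (values > 0 are foreground).

    Raises :class:`GridMismatchError` when ``reference`` is given and the file
    is on a different grid, and :class:`EmptyMaskError` for an all-zero volume.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise OSError(f"cannot read NIfTI file {path}: {exc}") from exc
    grid = VolumeGrid(tuple(img.shape[:3]), img.affine)
    if reference is not None:
        reference.require_match(grid, str(path))
        grid = reference
    data = np.asarray(img.dataobj)
    if data.ndim == 4:  # tolerate a trailing singleton volume dimension
        data = data[..., 0]
    mask = BinaryMask(grid, data > 0)
    if mask.is_empty:
        raise EmptyMaskError(f"empty mask: {path} has no voxels > 0")
    return mask


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def save_scalar_map(smap: ScalarMap, path: str | Path, fill: float = 0.0) -> None:
    data = np.where(smap.valid, smap.values, fill).astype(np.float32)
    nib.save(nib.Nifti1Image(data, smap.grid.affine), str(path))


# ---------------------------------------------------------------------------
# Lesion quantification

def lesion_volume(mask: BinaryMask) -> float:
    """Lesion volume in mm^3 (voxel count times voxel volume)."""
    if mask.is_empty:
        raise EmptyMaskError("cannot compute volume of an empty mask")
    return mask.volume_mm3


def overlap_map(masks: list[BinaryMask]) -> tuple[ScalarMap, int, int]:
    """Voxelwise lesion coverage count across a set of masks.

    Returns the count map, the peak count, and the peak coverage as a
    percentage of the number of masks rounded to the nearest integer (the
    convention used when reporting maximum lesion overlap).
    """
    if not masks:
        raise ValueError("overlap_map requires at least one mask")
    grid = masks[0].grid
    counts = np.zeros(grid.shape, dtype=np.int32)
    for m in masks:
        grid.require_match(m.grid, "mask")
        counts += m.voxels
    peak = int(counts.max())
    peak_percent = int(round(100.0 * peak / len(masks)))
    smap = ScalarMap(grid, counts.astype(float), np.ones(grid.shape, bool))
    return smap, peak, peak_percent


def region_damage(
    mask: BinaryMask,
    atlas: RegionAtlas,
    region: str,
    metric: str = "lesion",
) -> float:
    """Overlap between a lesion and a named atlas region.

    With ``metric="lesion"`` (default) this is the fraction of the *lesion*
    inside the region — a per-lesion covariate ("damaged more of the cortex").
    ``metric="region"`` gives the fraction of the region that is lesioned.
    """
    if mask.is_empty:
        raise EmptyMaskError("cannot compute region damage for an empty mask")
    mask.grid.require_match(atlas.grid, "atlas")
    lab = atlas.label_of(region)
    in_region = atlas.labels == lab
    inter = int((mask.voxels & in_region).sum())
    if metric == "lesion":
        return inter / mask.n_true
    if metric == "region":
        n_region = int(in_region.sum())
        return inter / n_region if n_region else 0.0
    raise ValueError(f"metric must be 'lesion' or 'region', got {metric!r}")
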