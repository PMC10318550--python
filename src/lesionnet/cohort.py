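"""Lesion cohorts: per-patient lesion masks with dataset labels and outcomes."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import BinaryMask, VolumeGrid, load_mask, save_mask

__all__ = ["LesionRecord", "Cohort", "load_cohort", "save_cohort"]


@dataclass(frozen=True)
class LesionRecord:
    """One patient's lesion: mask, originating dataset, epilepsy status."""

    id: str
    dataset: str
    mask: BinaryMask
    epilepsy: int
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.epilepsy not in (0, 1):
            raise ValueError(f"epilepsy must be 0 or 1, got {self.epilepsy!r}")
        if self.mask.is_empty:
            raise ValueError(f"lesion {self.id!r} has zero volume")

    @property
    def volume(self) -> float:
        """Lesion volume in mm^3 (derived from the mask)."""
        return self.mask.volume_mm3


@dataclass(frozen=True)
class Cohort:
    """Lesion records sharing one voxel grid, with unique ids."""

    records: tuple[LesionRecord, ...]

    def __post_init__(self) -> None:
        records = tuple(self.records)
        if not records:
            raise ValueError("cohort must contain at least one record")
        grid = records[0].mask.grid
        for rec in records[1:]:
            grid.require_match(rec.mask.grid, f"lesion {rec.id!r}")
        ids = [rec.id for rec in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate lesion ids in cohort")
        object.__setattr__(self, "records", records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def grid(self) -> VolumeGrid:
        return self.records[0].mask.grid

    @property
    def datasets(self) -> list[str]:
        """Distinct dataset labels in first-appearance order."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.dataset, None)
        return list(seen)

    @property
    def epilepsy(self) -> np.ndarray:
        return np.array([rec.epilepsy for rec in self.records], dtype=int)

    @property
    def volumes(self) -> np.ndarray:
        return np.array([rec.volume for rec in self.records], dtype=float)

    def subset(self, keep: np.ndarray) -> "Cohort":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return Cohort(tuple(self.records[i] for i in keep))

    def covariate(self, name: str) -> np.ndarray:
        """One covariate column; 'volume' resolves to the derived volume."""
        if name == "volume":
            return self.volumes
        try:
            return np.array([rec.covariates[name] for rec in self.records], float)
        except KeyError:
            raise KeyError(f"covariate {name!r} missing from some records") from None

    def dataset_indicators(self, drop_first: bool = True) -> tuple[np.ndarray, list[str]]:
        """0/1 dummy columns for the dataset labels (reference level dropped)."""
        levels = self.datasets
        use = levels[1:] if drop_first else levels
        cols = np.column_stack(
            [[1.0 if rec.dataset == lev else 0.0 for rec in self.records] for lev in use]
        ) if use else np.empty((len(self), 0))
        return cols, use

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {
                "id": rec.id,
                "dataset": rec.dataset,
                "epilepsy": rec.epilepsy,
                "volume_mm3": rec.volume,
            }
            row.update(rec.covariates)
            rows.append(row)
        return pd.DataFrame(rows)


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write lesion masks plus a cohort table; returns the table path."""
    out_dir = Path(out_dir)
    mask_dir = out_dir / "lesions"
    mask_dir.mkdir(parents=True, exist_ok=True)
    table = cohort.to_frame()
    paths = []
    for rec in cohort:
        p = mask_dir / f"{rec.id}.nii.gz"
        save_mask(rec.mask, p)
        paths.append(str(p.relative_to(out_dir)))
    table["mask_path"] = paths
    table_path = out_dir / "cohort.tsv"
    table.to_csv(table_path, sep="\t", index=False)
    return table_path


def load_cohort(table_path: str | Path, reference: VolumeGrid | None = None) -> Cohort:
    """Read a cohort table (id, dataset, epilepsy, mask_path, covariates...)."""
    table_path = Path(table_path)
    table = pd.read_csv(table_path, sep="\t")
    required = {"id", "dataset", "epilepsy", "mask_path"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table {table_path} lacks columns {sorted(missing)}")
    reserved = required | {"volume_mm3"}
    cov_cols = [c for c in table.columns if c not in reserved]
    records = []
    for _, row in table.iterrows():
        mask = load_mask(table_path.parent / row["mask_path"], reference)
        covs = {c: float(row[c]) for c in cov_cols}
        records.append(
            LesionRecord(str(row["id"]), str(row["dataset"]), mask, int(row["epilepsy"]), covs)
        )
    return Cohort(tuple(records))
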