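"""Deep brain stimulation site connectivity versus seizure outcome.

Stimulation sites (volumes of tissue activated, VTAs) are consumed as binary
masks. Their connectivity to the lesion network nodes is *positively*
oriented — opposite to the lesion risk score — because sites whose
connectivity profile matches the epilepsy-protective direction are expected
to improve seizures. Outcomes code improvement as positive percent change in
seizure frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome, roi_connectivity
from .grids import BinaryMask, VolumeGrid, load_mask, save_mask
from .inference import _iter_perms, _orient, _with_intercept
from .risk import NetworkNodeMap

__all__ = [
    "DBSRecord",
    "DBSCohort",
    "CorrelationResult",
    "dbs_benefit_score",
    "outcome_correlation",
    "load_dbs_cohort",
    "save_dbs_cohort",
]


@dataclass(frozen=True)
class DBSRecord:
    """One patient's stimulation site and clinical outcome."""

    id: str
    vta: BinaryMask
    outcome: float  # % change in seizure frequency, improvement positive
    amplitude: float = np.nan

    def __post_init__(self) -> None:
        if self.vta.is_empty:
            raise ValueError(f"VTA of {self.id!r} is empty")
        if not np.isfinite(self.outcome):
            raise ValueError(f"outcome of {self.id!r} is not finite")

    @property
    def vta_volume(self) -> float:
        return self.vta.volume_mm3


@dataclass(frozen=True)
class DBSCohort:
    records: tuple[DBSRecord, ...]

    def __post_init__(self) -> None:
        records = tuple(self.records)
        if not records:
            raise ValueError("empty DBS cohort")
        grid = records[0].vta.grid
        for rec in records[1:]:
            grid.require_match(rec.vta.grid, f"VTA {rec.id!r}")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate DBS record ids")
        object.__setattr__(self, "records", records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def grid(self) -> VolumeGrid:
        return self.records[0].vta.grid

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([r.outcome for r in self.records], float)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([r.amplitude for r in self.records], float)

    @property
    def vta_volumes(self) -> np.ndarray:
        return np.array([r.vta_volume for r in self.records], float)


def dbs_benefit_score(
    connectome: Connectome, vta: BinaryMask, nodes: NetworkNodeMap
) -> float:
    """Site-to-node Fisher-z connectivity, positively oriented (no sign flip)."""
    return roi_connectivity(connectome, vta, nodes.nodes)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    sidedness: str
    n_perm: int
    controls: tuple[str, ...] = ()
    loo: tuple[tuple[int, float], ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "p": self.p,
            "n": self.n,
            "sidedness": self.sidedness,
            "n_perm": self.n_perm,
            "controls": list(self.controls),
            "loo_r": {str(i): r for i, r in self.loo},
        }


def _partial_corr(a: np.ndarray, b: np.ndarray, Z: np.ndarray) -> float:
    pinvZ = np.linalg.pinv(Z)
    ra = a - Z @ (pinvZ @ a)
    rb = b - Z @ (pinvZ @ b)
    na, nb = np.linalg.norm(ra), np.linalg.norm(rb)
    if na == 0.0 or nb == 0.0:
        raise ValueError("a variable is constant after adjustment")
    return float(np.clip(ra @ rb / (na * nb), -1.0, 1.0))


def outcome_correlation(
    scores: np.ndarray,
    outcomes: np.ndarray,
    controls: dict[str, np.ndarray] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    sidedness: str = "greater",
    loo_sensitivity: bool = False,
) -> CorrelationResult:
    """(Partial) Pearson correlation of benefit scores with outcomes.

    Permutation p-value (default one-sided, positive association) by
    permuting outcome residuals. With ``loo_sensitivity`` the correlation is
    recomputed excluding each patient in turn (outlier check).
    """
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes, float)
    n = scores.size
    if n < 4:
        raise ValueError("need at least 4 patients")
    if outcomes.shape != scores.shape:
        raise ValueError("scores and outcomes differ in length")
    if np.ptp(scores) == 0.0 or np.ptp(outcomes) == 0.0:
        raise ValueError("constant input")
    names: list[str] = []
    cols: list[np.ndarray] = []
    for name, vals in (controls or {}).items():
        v = np.asarray(vals, float)
        if np.ptp(v) > 0.0:  # constant controls carry no information
            cols.append(v)
            names.append(name)
    Z = _with_intercept(np.column_stack(cols) if cols else None, n)
    pinvZ = np.linalg.pinv(Z)
    rs = scores - Z @ (pinvZ @ scores)
    ry = outcomes - Z @ (pinvZ @ outcomes)
    ns_, ny = np.linalg.norm(rs), np.linalg.norm(ry)
    if ns_ == 0.0 or ny == 0.0:
        raise ValueError("a variable is constant after adjusting for controls")
    r_obs = float(np.clip(rs @ ry / (ns_ * ny), -1.0, 1.0))
    t_obs = float(_orient(np.array([r_obs]), sidedness)[0])
    perms, n_draws, exhaustive = _iter_perms(n, n_perm, seed)
    exceed = 0
    for perm in perms:
        yp = ry[perm]
        y_adj = yp - Z @ (pinvZ @ yp)
        r_perm = float(rs @ y_adj / (ns_ * np.linalg.norm(y_adj)))
        if float(_orient(np.array([r_perm]), sidedness)[0]) >= t_obs:
            exceed += 1
    p = exceed / n_draws if exhaustive else (1 + exceed) / (1 + n_draws)
    loo: list[tuple[int, float]] = []
    if loo_sensitivity:
        for i in range(n):
            keep = np.arange(n) != i
            loo.append((i, _partial_corr(scores[keep], outcomes[keep], Z[keep])))
    return CorrelationResult(
        r_obs, float(p), n, sidedness, n_draws, tuple(names), tuple(loo)
    )


# ---------------------------------------------------------------------------
# I/O: cohort table (id, mask path, outcome, amplitude) + VTA NIfTIs

def save_dbs_cohort(cohort: DBSCohort, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    vta_dir = out_dir / "vta"
    vta_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        p = vta_dir / f"{rec.id}.nii.gz"
        save_mask(rec.vta, p)
        rows.append(
            {
                "id": rec.id,
                "vta_path": str(p.relative_to(out_dir)),
                "outcome": rec.outcome,
                "amplitude": rec.amplitude,
                "vta_volume_mm3": rec.vta_volume,
            }
        )
    table_path = out_dir / "dbs_cohort.tsv"
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)
    return table_path


def load_dbs_cohort(table_path: str | Path, reference: VolumeGrid | None = None) -> DBSCohort:
    table_path = Path(table_path)
    table = pd.read_csv(table_path, sep="\t")
    records = []
    for _, row in table.iterrows():
        vta = load_mask(table_path.parent / row["vta_path"], reference)
        records.append(
            DBSRecord(
                str(row["id"]),
                vta,
                float(row["outcome"]),
                float(row.get("amplitude", np.nan)),
            )
        )
    return DBSCohort(tuple(records))
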