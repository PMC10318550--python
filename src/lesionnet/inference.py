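"""Permutation-based voxelwise inference.

The voxelwise statistic is the Aspin–Welch ``V`` (unequal-variance two-sample
location statistic). Nuisance covariates (lesion volume, dataset indicators)
are handled with Freedman–Lane permutation: data are residualized on the
nuisance model, residual rows are permuted, the nuisance fit is re-added, and
the statistic is recomputed on re-adjusted values. Familywise error is
controlled with the max-statistic permutation distribution; false discovery
rate with Benjamini–Hochberg within the analysis mask (or a supplied ROI).

With nuisance covariates the permutation statistic depends on the full row
permutation (not only on the induced group partition), so the number of
distinct permutations is ``n!``; when ``n! <= n_perm`` the test enumerates all
of them exactly instead of sampling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import Cohort
from .grids import BinaryMask, ScalarMap, save_scalar_map

__all__ = [
    "DesignMatrix",
    "StatResult",
    "welch_v",
    "residualize",
    "bh_fdr",
    "permutation_group_test",
    "vlsm_univariate",
    "voxelwise_outcome_correlation",
]


# ---------------------------------------------------------------------------
# Building blocks

def welch_v(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Aspin–Welch statistic ``(mean(a) - mean(b)) / sqrt(va/na + vb/nb)``.

    Returns ``(v, df)`` with Welch–Satterthwaite degrees of freedom. When both
    sample variances are zero the statistic degenerates: equal means give
    ``v = 0``, unequal means ``v = +/-inf``; ``df`` is NaN in either case.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_v needs at least 2 observations per group")
    v, df = _welch_from_moments(
        float(a.size), a.sum(), (a * a).sum(), float(b.size), b.sum(), (b * b).sum()
    )
    return float(v), float(df)


def _welch_from_moments(n1, s1, q1, n2, s2, q2):
    """Vectorized Welch v and df from per-group sums and sums of squares."""
    m1 = s1 / n1
    m2 = s2 / n2
    var1 = np.maximum(q1 - n1 * m1 * m1, 0.0) / (n1 - 1)
    var2 = np.maximum(q2 - n2 * m2 * m2, 0.0) / (n2 - 1)
    t1 = var1 / n1
    t2 = var2 / n2
    se2 = t1 + t2
    diff = m1 - m2
    with np.errstate(invalid="ignore", divide="ignore"):
        v = diff / np.sqrt(se2)
        df = se2 * se2 / (t1 * t1 / (n1 - 1) + t2 * t2 / (n2 - 1))
    degenerate = se2 == 0.0
    if np.ndim(v):
        v = np.where(degenerate, np.where(diff == 0.0, 0.0, np.inf * np.sign(diff)), v)
        df = np.where(degenerate, np.nan, df)
    elif degenerate:
        v = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        df = np.nan
    return v, df


def residualize(y: np.ndarray, nuisance: np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of ``y`` on nuisance columns plus an intercept."""
    y = np.asarray(y, float)
    Z = _with_intercept(nuisance, y.shape[0])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("nuisance design is rank deficient")
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ beta


def _with_intercept(nuisance: np.ndarray | None, n: int) -> np.ndarray:
    ones = np.ones((n, 1))
    if nuisance is None:
        return ones
    Z = np.asarray(nuisance, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != n:
        raise ValueError("nuisance rows do not match observations")
    return np.column_stack([ones, Z])


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass(frozen=True)
class DesignMatrix:
    """Group indicator plus optional nuisance covariate columns."""

    group: np.ndarray
    nuisance: np.ndarray | None = None
    nuisance_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        g = np.asarray(self.group)
        if not np.isin(g, (0, 1)).all():
            raise ValueError("group must be a 0/1 indicator")
        g = g.astype(bool)
        if g.all() or not g.any():
            raise ValueError("group column is constant")
        object.__setattr__(self, "group", g)
        if self.nuisance is not None:
            Z = np.asarray(self.nuisance, float)
            if Z.ndim == 1:
                Z = Z[:, None]
            full = _with_intercept(Z, g.size)
            if np.linalg.matrix_rank(full) < full.shape[1]:
                raise ValueError("design matrix is rank deficient")
            object.__setattr__(self, "nuisance", Z)

    @property
    def n(self) -> int:
        return self.group.size


@dataclass(frozen=True)
class StatResult:
    """Voxelwise permutation-test result over an analysis mask.

    All per-voxel arrays are 1-D and aligned with
    ``analysis_mask.flat_indices()``.
    """

    stat: np.ndarray = field(repr=False)
    df: np.ndarray = field(repr=False)
    p_unc: np.ndarray = field(repr=False)
    p_fwe: np.ndarray = field(repr=False)
    q_fdr: np.ndarray = field(repr=False)
    n_perm: int
    seed: int
    sidedness: str
    analysis_mask: BinaryMask
    stat_name: str = "v"
    exhaustive: bool = False

    def __post_init__(self) -> None:
        n = self.analysis_mask.n_true
        for name in ("stat", "df", "p_unc", "p_fwe", "q_fdr"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            object.__setattr__(self, name, arr)
        for name in ("p_unc", "p_fwe", "q_fdr"):
            arr = getattr(self, name)
            if np.any((arr <= 0) | (arr > 1)):
                raise ValueError(f"{name} outside (0, 1]")
        if np.any(self.p_fwe < self.p_unc - 1e-12):
            raise ValueError("p_fwe must dominate p_unc voxelwise")

    def to_scalar_map(self, which: str = "stat", fill: float = 0.0) -> ScalarMap:
        arr = getattr(self, which)
        vol = np.full(self.analysis_mask.grid.shape, fill, float).ravel()
        vol[self.analysis_mask.flat_indices()] = np.nan_to_num(arr, nan=fill)
        return ScalarMap(
            self.analysis_mask.grid,
            vol.reshape(self.analysis_mask.grid.shape),
            self.analysis_mask.voxels.copy(),
        )

    def peak(self) -> dict:
        """Location and value of the largest-|statistic| voxel."""
        finite = np.nan_to_num(self.stat, nan=0.0, posinf=np.inf, neginf=-np.inf)
        j = int(np.argmax(np.abs(finite)))
        ijk = np.unravel_index(self.analysis_mask.flat_indices()[j], self.analysis_mask.grid.shape)
        return {
            "stat": float(finite[j]),
            "p_unc": float(self.p_unc[j]),
            "p_fwe": float(self.p_fwe[j]),
            "q_fdr": float(self.q_fdr[j]),
            "ijk": [int(c) for c in ijk],
        }

    def summary(self) -> dict:
        return {
            "stat_name": self.stat_name,
            "n_voxels": int(self.analysis_mask.n_true),
            "n_perm": self.n_perm,
            "exhaustive": self.exhaustive,
            "seed": self.seed,
            "sidedness": self.sidedness,
            "peak": self.peak(),
            "n_fwe_sig_05": int(np.sum(self.p_fwe < 0.05)),
            "n_fdr_sig_05": int(np.sum(self.q_fdr < 0.05)),
        }

    def save(self, out_dir: str | Path, prefix: str = "stat") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for which, tag in (("stat", self.stat_name), ("p_unc", "p_unc"),
                           ("p_fwe", "p_fwe"), ("q_fdr", "q_fdr")):
            fill = 1.0 if tag.startswith(("p", "q")) else 0.0
            save_scalar_map(self.to_scalar_map(which, fill), out_dir / f"{prefix}_{tag}.nii.gz", fill)


# ---------------------------------------------------------------------------
# Permutation engine

def _n_distinct_perms(n: int, cap: int) -> int:
    """min(n!, cap + 1) without overflowing."""
    total = 1
    for k in range(2, n + 1):
        total *= k
        if total > cap:
            return cap + 1
    return total


def _iter_perms(n: int, n_perm: int, seed: int):
    """Yield permutations: exhaustive when n! <= n_perm, else Monte Carlo.

    Returns (iterator, n_draws, exhaustive).
    """
    n_fact = _n_distinct_perms(n, n_perm)
    if n_fact <= n_perm:
        return (np.array(p) for p in itertools.permutations(range(n))), n_fact, True
    rng = np.random.default_rng(seed)
    return (rng.permutation(n) for _ in range(n_perm)), n_perm, False


#: permutations whose statistic equals the observed one up to floating-point
#: noise (e.g. within-group row reorderings) are counted as ties, so p-values
#: are invariant to subject ordering
TIE_REL_TOL = 1e-9


def _tie_threshold(t_obs: np.ndarray) -> np.ndarray:
    return t_obs - TIE_REL_TOL * (1.0 + np.abs(np.nan_to_num(t_obs)))


def _orient(stat: np.ndarray, sidedness: str) -> np.ndarray:
    """Map a statistic to 'large = extreme' under the requested sidedness."""
    if sidedness == "two":
        return np.abs(stat)
    if sidedness == "greater":
        return np.asarray(stat, float)
    if sidedness == "less":
        return -np.asarray(stat, float)
    raise ValueError("sidedness must be 'two', 'greater' or 'less'")


def _finalize(
    stat_obs, df_obs, exceed, fwe_exceed, n_draws, exhaustive, n_perm, seed,
    sidedness, mask, stat_name,
) -> StatResult:
    if exhaustive:
        p_unc = exceed / n_draws
        p_fwe = fwe_exceed / n_draws
    else:
        p_unc = (1.0 + exceed) / (1.0 + n_draws)
        p_fwe = (1.0 + fwe_exceed) / (1.0 + n_draws)
    return StatResult(
        stat=stat_obs,
        df=df_obs,
        p_unc=p_unc,
        p_fwe=np.maximum(p_fwe, p_unc),
        q_fdr=bh_fdr(p_unc),
        n_perm=n_draws,
        seed=seed,
        sidedness=sidedness,
        analysis_mask=mask,
        stat_name=stat_name,
        exhaustive=exhaustive,
    )


def _restrict_mask(mask: BinaryMask, roi: BinaryMask | None) -> BinaryMask:
    if roi is None:
        return mask
    out = mask.intersect(roi)
    if out.is_empty:
        raise ValueError("analysis mask and ROI do not intersect")
    return out


def permutation_group_test(
    values: np.ndarray,
    design: DesignMatrix,
    mask: BinaryMask,
    n_perm: int = 5000,
    seed: int = 0,
    sidedness: str = "two",
    roi: BinaryMask | None = None,
) -> StatResult:
    """Voxelwise Welch-V group contrast with Freedman–Lane permutation.

    Parameters
    ----------
    values : (n_subjects, n_voxels) ndarray
        One row per subject; columns aligned with ``mask.flat_indices()``.
    design : DesignMatrix
        Group indicator (contrast is ``mean(group=1) - mean(group=0)``) and
        nuisance covariates.
    mask : BinaryMask
        Analysis mask matching the columns of ``values``.
    roi : BinaryMask, optional
        Restrict the whole analysis (statistic, FWE max, FDR) to
        ``mask ∩ roi``, as in a-priori region-of-interest tests.
    """
    values = np.asarray(values, float)
    if values.shape != (design.n, mask.n_true):
        raise ValueError(
            f"values must be ({design.n}, {mask.n_true}), got {values.shape}"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    g = design.group
    if g.sum() < 2 or (~g).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    use = mask if roi is None else _restrict_mask(mask, roi)
    if roi is not None:
        cols = np.isin(mask.flat_indices(), use.flat_indices())
        values = values[:, cols]
    Z = _with_intercept(design.nuisance, design.n)
    pinvZ = np.linalg.pinv(Z)
    R = values - Z @ (pinvZ @ values)

    n1 = float(g.sum())
    n0 = float((~g).sum())
    gf = g.astype(float)
    cf = (~g).astype(float)

    def stat_of(adjusted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sq = adjusted * adjusted
        return _welch_from_moments(
            n1, gf @ adjusted, gf @ sq, n0, cf @ adjusted, cf @ sq
        )

    v_obs, df_obs = stat_of(R)
    t_obs = _orient(v_obs, sidedness)
    thresh = _tie_threshold(t_obs)
    exceed = np.zeros(t_obs.size)
    fwe_exceed = np.zeros(t_obs.size)
    perms, n_draws, exhaustive = _iter_perms(design.n, n_perm, seed)
    for perm in perms:
        Rp = R[perm]
        A = Rp - Z @ (pinvZ @ Rp)
        t_perm = _orient(stat_of(A)[0], sidedness)
        t_perm = np.nan_to_num(t_perm, nan=-np.inf)
        exceed += t_perm >= thresh
        fwe_exceed += t_perm.max() >= thresh
    return _finalize(
        v_obs, df_obs, exceed, fwe_exceed, n_draws, exhaustive, n_perm, seed,
        sidedness, use, "v",
    )


def vlsm_univariate(
    cohort: Cohort,
    covariate_names: tuple[str, ...] = ("volume",),
    min_lesioned: int = 5,
    n_perm: int = 5000,
    seed: int = 0,
    sidedness: str = "two",
    analysis_mask: BinaryMask | None = None,
) -> StatResult:
    """Univariate voxel-based lesion symptom mapping.

    At each voxel lesioned in at least ``min_lesioned`` patients (and spared
    in at least 2), the nuisance-adjusted epilepsy status is contrasted
    between lesioned and spared patients with the Welch V statistic;
    inference is by Freedman–Lane permutation of the adjusted status.
    """
    grid = cohort.grid
    base = analysis_mask or BinaryMask(grid, np.ones(grid.shape, bool))
    idx = base.flat_indices()
    L = np.stack([rec.mask.voxels.ravel()[idx] for rec in cohort]).astype(float)
    n = len(cohort)
    counts = L.sum(axis=0)
    ok = (counts >= max(min_lesioned, 2)) & (n - counts >= 2)
    if not ok.any():
        raise ValueError(f"no voxel is lesioned in >= {min_lesioned} patients")
    keep_flat = idx[ok]
    vol = np.zeros(grid.shape, bool).ravel()
    vol[keep_flat] = True
    use = BinaryMask(grid, vol.reshape(grid.shape))
    L = L[:, ok]
    n1 = L.sum(axis=0)
    n0 = n - n1

    Z = _with_intercept(
        np.column_stack([cohort.covariate(c) for c in covariate_names])
        if covariate_names else None,
        n,
    )
    pinvZ = np.linalg.pinv(Z)
    y = cohort.epilepsy.astype(float)
    r = y - Z @ (pinvZ @ y)

    def stat_of(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sq = a * a
        s1 = a @ L
        q1 = sq @ L
        return _welch_from_moments(n1, s1, q1, n0, a.sum() - s1, sq.sum() - q1)

    v_obs, df_obs = stat_of(r)
    t_obs = _orient(v_obs, sidedness)
    thresh = _tie_threshold(t_obs)
    exceed = np.zeros(t_obs.size)
    fwe_exceed = np.zeros(t_obs.size)
    perms, n_draws, exhaustive = _iter_perms(n, n_perm, seed)
    for perm in perms:
        rp = r[perm]
        a = rp - Z @ (pinvZ @ rp)
        t_perm = np.nan_to_num(_orient(stat_of(a)[0], sidedness), nan=-np.inf)
        exceed += t_perm >= thresh
        fwe_exceed += t_perm.max() >= thresh
    return _finalize(
        v_obs, df_obs, exceed, fwe_exceed, n_draws, exhaustive, n_perm, seed,
        sidedness, use, "v",
    )


def voxelwise_outcome_correlation(
    values: np.ndarray,
    outcome: np.ndarray,
    mask: BinaryMask,
    nuisance: np.ndarray | None = None,
    n_perm: int = 5000,
    seed: int = 0,
    sidedness: str = "two",
    roi: BinaryMask | None = None,
) -> StatResult:
    """Voxelwise (partial) Pearson correlation with a continuous outcome.

    Outcome and voxel values are residualized on the nuisance model; the
    permutation null permutes outcome residuals (Freedman–Lane).
    """
    values = np.asarray(values, float)
    outcome = np.asarray(outcome, float)
    n = outcome.size
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if values.shape != (n, mask.n_true):
        raise ValueError(f"values must be ({n}, {mask.n_true})")
    if np.ptp(outcome) == 0.0:
        raise ValueError("outcome is constant")
    use = mask if roi is None else _restrict_mask(mask, roi)
    if roi is not None:
        values = values[:, np.isin(mask.flat_indices(), use.flat_indices())]
    Z = _with_intercept(nuisance, n)
    pinvZ = np.linalg.pinv(Z)
    X = values - Z @ (pinvZ @ values)
    ry = outcome - Z @ (pinvZ @ outcome)
    if np.linalg.norm(ry) == 0.0:
        raise ValueError("outcome is fully explained by the nuisance model")
    x_norm = np.linalg.norm(X, axis=0)

    def corr_of(y_res: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (y_res @ X) / (np.linalg.norm(y_res) * x_norm)
        r[x_norm == 0.0] = 0.0
        return np.clip(r, -1.0, 1.0)

    r_obs = corr_of(ry)
    k = Z.shape[1] - 1
    df_obs = np.full(r_obs.size, float(n - 2 - k))
    t_obs = _orient(r_obs, sidedness)
    thresh = _tie_threshold(t_obs)
    exceed = np.zeros(t_obs.size)
    fwe_exceed = np.zeros(t_obs.size)
    perms, n_draws, exhaustive = _iter_perms(n, n_perm, seed)
    for perm in perms:
        yp = ry[perm]
        y_adj = yp - Z @ (pinvZ @ yp)
        t_perm = np.nan_to_num(_orient(corr_of(y_adj), sidedness), nan=-np.inf)
        exceed += t_perm >= thresh
        fwe_exceed += t_perm.max() >= thresh
    return _finalize(
        r_obs, df_obs, exceed, fwe_exceed, n_draws, exhaustive, n_perm, seed,
        sidedness, use, "r",
    )
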