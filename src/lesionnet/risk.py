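"""Lesion network nodes and out-of-sample epilepsy risk quantification.

The defining group contrast is *negative* (lesions associated with epilepsy
are anticorrelated with the node regions), so the risk score flips the sign
of lesion-to-node connectivity: a lesion more anticorrelated with the nodes
gets a *higher* score. Node maps record the sign of their defining contrast
so this orientation is explicit everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .cohort import Cohort
from .connectome import Connectome, network_value_matrix, roi_connectivity
from .grids import BinaryMask
from .inference import DesignMatrix, StatResult, permutation_group_test

__all__ = [
    "EmptyNodeMapError",
    "NetworkNodeMap",
    "LogisticFit",
    "StratifiedTable",
    "derive_nodes",
    "risk_score",
    "loo_risk_scores",
    "fit_logistic",
    "stratify",
    "chi_square",
    "roc_auc",
]


class EmptyNodeMapError(ValueError):
    """Thresholding produced no node voxels."""


@dataclass(frozen=True)
class NetworkNodeMap:
    """Thresholded, signed map of lesion network nodes."""

    nodes: BinaryMask
    sign: int  # -1: anticorrelated defining contrast, +1: positive
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")
        if self.nodes.is_empty:
            raise EmptyNodeMapError("node map is empty")


def derive_nodes(
    stat: StatResult,
    alpha: float = 0.05,
    sign: str = "negative",
    correction: str = "fwe",
    source: dict | None = None,
) -> NetworkNodeMap:
    """Voxels with corrected p below ``alpha`` and the requested sign."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if correction == "fwe":
        p = stat.p_fwe
    elif correction == "fdr":
        p = stat.q_fdr
    else:
        raise ValueError("correction must be 'fwe' or 'fdr'")
    if sign == "negative":
        directional = stat.stat < 0
        sgn = -1
    elif sign == "positive":
        directional = stat.stat > 0
        sgn = 1
    else:
        raise ValueError("sign must be 'negative' or 'positive'")
    sel = (p < alpha) & directional
    if not sel.any():
        raise EmptyNodeMapError(
            f"no voxel survives {correction} p < {alpha} with {sign} statistic"
        )
    grid = stat.analysis_mask.grid
    vol = np.zeros(grid.shape, bool).ravel()
    vol[stat.analysis_mask.flat_indices()[sel]] = True
    meta = {"alpha": alpha, "correction": correction, "sidedness": stat.sidedness}
    meta.update(source or {})
    return NetworkNodeMap(BinaryMask(grid, vol.reshape(grid.shape)), sgn, meta)


def risk_score(connectome: Connectome, lesion: BinaryMask, nodes: NetworkNodeMap) -> float:
    """Oriented lesion-to-node connectivity: larger = higher epilepsy risk.

    With anticorrelated nodes (``sign = -1``) the score is the negated
    Fisher-z connectivity, so a lesion more anticorrelated with the nodes —
    the epilepsy-associated direction — scores higher.
    """
    return nodes.sign * roi_connectivity(connectome, lesion, nodes.nodes)


def loo_risk_scores(
    cohort: Cohort,
    connectome: Connectome,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    correction: str = "fwe",
    sidedness: str = "two",
    sign: str = "negative",
    covariate_names: tuple[str, ...] = ("volume",),
    include_dataset_covariate: bool = True,
    aggregate: str = "mean",
    network_values: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Leave-one-dataset-out lesion risk scores.

    For each dataset ``D``: the voxelwise permutation contrast (epilepsy vs
    control, adjusted for lesion volume and dataset) is run on the network
    maps of ``cohort \\ D``, nodes are thresholded from it, and every lesion
    of ``D`` is scored against those nodes. A lesion's own dataset therefore
    never contributes to the nodes that score it.

    Returns a per-lesion table (id, dataset, epilepsy, score, fold) and a
    per-fold provenance dict (source datasets, node count, failures).
    """
    datasets = cohort.datasets
    if len(datasets) < 2:
        raise ValueError("leave-one-dataset-out requires >= 2 datasets")
    if network_values is None:
        network_values = network_value_matrix(
            connectome, [rec.mask for rec in cohort], aggregate
        )
    ds_labels = np.array([rec.dataset for rec in cohort])
    scores = np.full(len(cohort), np.nan)
    folds: dict[str, dict] = {}
    for i, held_out in enumerate(datasets):
        train = np.flatnonzero(ds_labels != held_out)
        test = np.flatnonzero(ds_labels == held_out)
        sub = cohort.subset(train)
        nuis_cols = [sub.covariate(c) for c in covariate_names]
        if include_dataset_covariate:
            dummies, _ = sub.dataset_indicators(drop_first=True)
            if dummies.size:
                nuis_cols.append(dummies)
        nuisance = np.column_stack(nuis_cols) if nuis_cols else None
        design = DesignMatrix(sub.epilepsy, nuisance)
        fold_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        stat = permutation_group_test(
            network_values[train],
            design,
            connectome.brain,
            n_perm=n_perm,
            seed=fold_seed,
            sidedness=sidedness,
        )
        fold = {
            "held_out": held_out,
            "source_datasets": [d for d in datasets if d != held_out],
            "seed": fold_seed,
        }
        try:
            nodes = derive_nodes(
                stat, alpha, sign, correction,
                source={"datasets": fold["source_datasets"]},
            )
        except EmptyNodeMapError as exc:
            fold.update(ok=False, error=str(exc), n_node_voxels=0)
            folds[held_out] = fold
            warnings.warn(f"fold {held_out!r}: {exc}", stacklevel=2)
            continue
        fold.update(ok=True, n_node_voxels=nodes.nodes.n_true)
        folds[held_out] = fold
        for j in test:
            scores[j] = risk_score(connectome, cohort.records[j].mask, nodes)
    table = pd.DataFrame(
        {
            "id": [rec.id for rec in cohort],
            "dataset": ds_labels,
            "epilepsy": cohort.epilepsy,
            "score": scores,
        }
    )
    return table, folds


# ---------------------------------------------------------------------------
# Risk quantification

@dataclass(frozen=True)
class LogisticFit:
    """Logistic regression of epilepsy on a standardized risk score."""

    coefficients: dict[str, float]
    or_per_sd: float | None
    ci: tuple[float, float] | None
    p_value: float | None
    covariates: tuple[str, ...]
    converged: bool
    separation: bool
    n: int

    def __post_init__(self) -> None:
        if self.or_per_sd is not None:
            if self.or_per_sd <= 0:
                raise ValueError("odds ratio must be positive")
            lo, hi = self.ci
            if not lo <= self.or_per_sd <= hi:
                raise ValueError("CI must bracket the odds ratio")


def fit_logistic(
    outcome: np.ndarray,
    score: np.ndarray,
    covariates: dict[str, np.ndarray] | None = None,
    standardize: bool = True,
) -> LogisticFit:
    """Epilepsy odds per 1 SD of the risk score (Wald 95% CI).

    The score is standardized internally (``standardize=False`` keeps its raw
    scale, e.g. for a binary exposure); continuous covariates are likewise
    standardized (indicator columns are left alone), which changes nothing
    about the score's adjusted odds ratio.
    """
    y = np.asarray(outcome, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    s = np.asarray(score, float)
    if np.std(s) == 0.0:
        raise ValueError("risk score is constant")
    if standardize:
        s = (s - s.mean()) / s.std(ddof=1)
    cols = [s]
    names = ["score"]
    for name, vals in (covariates or {}).items():
        v = np.asarray(vals, float)
        if np.unique(v).size > 2 and v.std(ddof=1) > 0:
            v = (v - v.mean()) / v.std(ddof=1)
        cols.append(v)
        names.append(name)
    X = sm.add_constant(np.column_stack(cols))
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals["converged"])
    except Exception:
        converged = False
        res = None
    if res is not None and np.max(np.abs(res.params)) > 15:
        separation = True
    if res is None or not converged or separation:
        coefs = {} if res is None else dict(zip(["const"] + names, res.params))
        return LogisticFit(coefs, None, None, None, tuple(names[1:]), converged, True, y.size)
    params = dict(zip(["const"] + names, res.params))
    ci_all = res.conf_int()
    lo, hi = float(np.exp(ci_all[1, 0])), float(np.exp(ci_all[1, 1]))
    return LogisticFit(
        coefficients=params,
        or_per_sd=float(np.exp(res.params[1])),
        ci=(lo, hi),
        p_value=float(res.pvalues[1]),
        covariates=tuple(names[1:]),
        converged=True,
        separation=False,
        n=y.size,
    )


@dataclass(frozen=True)
class StratifiedTable:
    """Counts of epilepsy vs not across low / moderate / high score strata."""

    counts: np.ndarray  # (2 outcomes x 3 strata), rows: no-epilepsy, epilepsy
    cutoffs: tuple[float, float]  # (mean, sd) used for stratification
    strata: tuple[str, ...] = ("low", "moderate", "high")

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, int)
        if counts.shape != (2, 3):
            raise ValueError("counts must be 2x3")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def proportions(self) -> dict[str, float]:
        """Epilepsy proportion per stratum (NaN for an empty stratum)."""
        with np.errstate(invalid="ignore"):
            prop = self.counts[1] / self.counts.sum(axis=0)
        return dict(zip(self.strata, prop))


def _assign_strata(scores: np.ndarray) -> tuple[np.ndarray, float, float]:
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1)) if scores.size > 1 else 0.0
    if sd == 0.0:
        warnings.warn("zero score SD: all lesions fall in the moderate stratum",
                      stacklevel=3)
        return np.ones(scores.size, int), mean, sd
    strata = np.ones(scores.size, int)  # boundaries (exactly +/- 1 SD) stay moderate
    strata[scores < mean - sd] = 0
    strata[scores > mean + sd] = 2
    return strata, mean, sd


def stratify(
    scores: np.ndarray,
    outcome: np.ndarray,
    datasets: np.ndarray | None = None,
    mode: str = "pooled",
) -> StratifiedTable:
    """Stratify lesions at 1 SD above/below the mean score.

    ``mode="pooled"`` (default) uses one mean/SD across all lesions;
    ``mode="within"`` standardizes within each dataset before assignment.
    """
    scores = np.asarray(scores, float)
    outcome = np.asarray(outcome, int)
    if scores.size < 2:
        raise ValueError("need at least 2 lesions to stratify")
    if mode == "pooled":
        strata, mean, sd = _assign_strata(scores)
    elif mode == "within":
        if datasets is None:
            raise ValueError("mode='within' requires dataset labels")
        datasets = np.asarray(datasets)
        strata = np.empty(scores.size, int)
        for d in np.unique(datasets):
            sel = datasets == d
            strata[sel] = _assign_strata(scores[sel])[0]
        mean, sd = float(scores.mean()), float(scores.std(ddof=1))
    else:
        raise ValueError("mode must be 'pooled' or 'within'")
    counts = np.zeros((2, 3), int)
    for s, y in zip(strata, outcome):
        counts[y, s] += 1
    return StratifiedTable(counts, (mean, sd))


def chi_square(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) for a 2x2 or 2x3 table."""
    table = np.asarray(table, float)
    if table.shape not in ((2, 2), (2, 3)):
        raise ValueError("table must be 2x2 or 2x3")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero margin")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def roc_auc(outcome: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (Mann–Whitney form; ties credited 0.5)."""
    outcome = np.asarray(outcome, int)
    if np.unique(outcome).size < 2:
        raise ValueError("both outcome classes must be present")
    return float(roc_auc_score(outcome, np.asarray(scores, float)))
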