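"""Independent reference implementations used to validate the inference engine."""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as sps


def brute_force_group_permutation(values, group, nuisance, sidedness="two"):
    """Exhaustive Freedman-Lane enumeration with scipy's Welch statistic.

    Enumerates all n! row permutations of the nuisance residuals and counts
    statistics at least as extreme as the observed one (ties up to
    floating-point noise included). Returns (p_uncorrected, p_fwe).
    """
    group = np.asarray(group, bool)
    n = group.size
    Z = np.column_stack([np.ones(n)] + ([nuisance] if nuisance is not None else []))
    beta, *_ = np.linalg.lstsq(Z, values, rcond=None)
    fit = Z @ beta
    resid = values - fit

    def stat(y):
        beta_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
        adj = y - Z @ beta_y
        return sps.ttest_ind(adj[group], adj[~group], axis=0, equal_var=False).statistic

    obs = stat(values)
    t_obs = np.abs(obs) if sidedness == "two" else obs
    thresh = t_obs - 1e-9 * (1.0 + np.abs(t_obs))
    count = np.zeros_like(t_obs)
    fwe = np.zeros_like(t_obs)
    total = 0
    for perm in itertools.permutations(range(n)):
        t = stat(fit + resid[list(perm)])
        t = np.abs(t) if sidedness == "two" else t
        count += t >= thresh
        fwe += t.max() >= thresh
        total += 1
    return count / total, fwe / total
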