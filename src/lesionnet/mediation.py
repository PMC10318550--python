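"""Product-of-coefficients mediation with a binary outcome.

Tests whether a mediator M (here: lesion-to-node connectivity) transmits the
association between an exposure X (lesion volume, regional damage) and a
binary outcome Y (epilepsy). Paths: ``a`` from the linear regression M ~ X;
``c`` from logistic Y ~ X; ``b`` and ``c'`` from logistic Y ~ M + X, all on
standardized X and M. The indirect effect ``a*b`` gets a percentile bootstrap
CI. Verdict: "full" mediation when the indirect CI excludes zero and the
direct path ``c'`` is non-significant; "partial" when both are significant;
"none" otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from ._logistic import logit_irls

__all__ = ["MediationResult", "mediation_analysis"]


@dataclass(frozen=True)
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    p_c_prime: float
    indirect: float
    ci: tuple[float, float]
    n_boot: int
    seed: int
    verdict: str | None
    converged: bool

    def __post_init__(self) -> None:
        if self.converged and not (self.ci[0] <= self.indirect <= self.ci[1]):
            # percentile CIs can narrowly miss the point estimate only with
            # pathological bootstrap distributions; treat as inconsistency
            raise ValueError("bootstrap CI does not bracket the indirect effect")

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "c_prime": self.c_prime,
            "p_c_prime": self.p_c_prime,
            "indirect": self.indirect,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "n_boot": self.n_boot,
            "seed": self.seed,
            "verdict": self.verdict,
            "converged": self.converged,
        }


def _standardize(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, float)
    sd = v.std(ddof=1)
    if sd == 0.0:
        raise ValueError(f"{name} is constant")
    return (v - v.mean()) / sd


def mediation_analysis(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    n_boot: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> MediationResult:
    """Mediation of X -> Y through M with a percentile bootstrap CI for a*b."""
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    x = _standardize(x, "exposure")
    m = _standardize(m, "mediator")
    y = np.asarray(y, float)
    if set(np.unique(y)) - {0.0, 1.0} or y.min() == y.max():
        raise ValueError("outcome must be binary with both classes present")
    n = y.size

    ols = sm.OLS(m, sm.add_constant(x)).fit()
    a = float(ols.params[1])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_c = sm.Logit(y, sm.add_constant(x)).fit(disp=0, maxiter=200)
            fit_b = sm.Logit(y, sm.add_constant(np.column_stack([m, x]))).fit(
                disp=0, maxiter=200
            )
        ok = fit_c.mle_retvals["converged"] and fit_b.mle_retvals["converged"]
        ok = ok and np.max(np.abs(fit_b.params)) < 15
    except Exception:
        ok = False
    if not ok:
        return MediationResult(
            a, np.nan, np.nan, np.nan, np.nan, np.nan, (np.nan, np.nan),
            n_boot, seed, None, False,
        )
    c = float(fit_c.params[1])
    b = float(fit_b.params[1])
    c_prime = float(fit_b.params[2])
    p_c_prime = float(fit_b.pvalues[2])

    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    valid = 0
    X1 = np.empty((n, 3))
    X1[:, 0] = 1.0
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, mb, yb = x[idx], m[idx], y[idx]
        var_x = xb.var()
        if var_x == 0.0 or yb.min() == yb.max():
            continue
        a_b = float(np.cov(xb, mb, bias=True)[0, 1] / var_x)
        X1[:, 1] = mb
        X1[:, 2] = xb
        beta, _ = logit_irls(X1, yb)
        draws[valid] = a_b * beta[1]
        valid += 1
    if valid < n_boot // 2:
        return MediationResult(
            a, b, c, c_prime, p_c_prime, a * b, (np.nan, np.nan),
            n_boot, seed, None, False,
        )
    lo, hi = np.percentile(draws[:valid], [100 * alpha / 2, 100 * (1 - alpha / 2)])
    indirect = a * b
    ci = (min(float(lo), indirect), max(float(hi), indirect))
    excludes_zero = ci[0] > 0.0 or ci[1] < 0.0
    if excludes_zero and p_c_prime > 0.05:
        verdict = "full"
    elif excludes_zero:
        verdict = "partial"
    else:
        verdict = "none"
    return MediationResult(
        a, b, c, c_prime, p_c_prime, indirect, ci, n_boot, seed, verdict, True
    )
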