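"""Minimal Newton (IRLS) logistic regression used in resampling loops.

Headline model fits go through statsmodels; this solver exists so that
bootstrap loops (thousands of refits on small design matrices) stay fast.
"""

from __future__ import annotations

import numpy as np

#: linear predictors are clipped here to keep weights finite under separation
ETA_MAX = 30.0


def logit_irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> tuple[np.ndarray, bool]:
    """Maximum-likelihood logistic fit; X must already include an intercept.

    Returns ``(beta, converged)``. Under (quasi-)separation the coefficients
    drift without bound; the caller should treat ``converged=False`` or very
    large coefficients as a separation flag.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -ETA_MAX, ETA_MAX)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(X.shape[1]), grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, True
    return beta, False
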