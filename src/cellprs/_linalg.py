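"""Small dense least-squares helpers shared by the statistical modules.

These are deliberately plain normal-equations implementations: every design
matrix in this package is short and well-conditioned (a handful of covariates,
hundreds to thousands of rows), and the bootstrap loops need a path that can
be batched over resamples without per-fit Python overhead.
"""

from __future__ import annotations

import numpy as np


def ols_fit(X: np.ndarray, y: np.ndarray):
    """OLS via normal equations.

    Returns ``(beta, se, resid, r2)`` where ``se`` are the classical
    homoskedastic standard errors. ``X`` must already contain an intercept
    column if one is wanted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    xtx = X.T @ X
    xty = X.T @ y
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular design matrix (collinear or constant columns)"
        ) from exc
    beta = xtx_inv @ xty
    resid = y - X @ beta
    dof = n - k
    if dof <= 0:
        raise ValueError(f"not enough rows (n={n}) for {k} parameters")
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan
    return beta, se, resid, r2


def weighted_xtx_xty(X: np.ndarray, y: np.ndarray, W: np.ndarray):
    """Batched weighted cross-products for bootstrap resampling.

    ``W`` is (B, n) of nonnegative case weights (multinomial counts for a
    case-resampling bootstrap). Returns ``(XtWX, XtWy)`` with shapes
    (B, k, k) and (B, k).
    """
    Xw = X[None, :, :] * W[:, :, None]          # (B, n, k)
    XtWX = np.einsum("bnk,nm->bkm", Xw, X)
    XtWy = np.einsum("bnk,n->bk", Xw, y)
    return XtWX, XtWy


def batched_ols(X: np.ndarray, y: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Solve the B weighted OLS problems defined by weight rows of ``W``.

    Equivalent to refitting OLS on each case-resampled dataset. Returns the
    (B, k) coefficient array.
    """
    XtWX, XtWy = weighted_xtx_xty(X, y, W)
    return np.linalg.solve(XtWX, XtWy[..., None])[..., 0]


def multinomial_weights(rng: np.random.Generator, n: int, B: int) -> np.ndarray:
    """Case-resampling weights: counts of each row in B bootstrap resamples."""
    return rng.multinomial(n, np.full(n, 1.0 / n), size=B).astype(float)
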