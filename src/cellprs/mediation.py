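"""Linear causal mediation with a nonparametric bootstrap.

For a continuous treatment T (a standardised score), mediator M and outcome
Y with covariates C, the two linear models

    M = a·T + C·γ + e_M
    Y = c'·T + b·M + C·δ + e_Y

define the average causal mediated effect ACME = a·b, the average direct
effect ADE = c', and the total effect, which for linear no-interaction
models decomposes exactly as total = ACME + ADE (the coefficient of T in
Y ~ T + C). The product-of-coefficients estimand coincides with the
simulation-based mediation estimator in this setting, so each bootstrap
draw refits both regressions and recomputes a·b and c' analytically.
Percentile 95% CIs and two-sided empirical p-values use the (1+k)/(B+1)
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._linalg import batched_ols, multinomial_weights, ols_fit

logger = logging.getLogger(__name__)

#: |total| below this is treated as unstable for proportion mediated.
TOTAL_TOL = 1e-8


@dataclass
class EffectEstimate:
    point: float
    ci: tuple[float, float] | None
    p: float | None


@dataclass
class MediationResult:
    acme: EffectEstimate
    ade: EffectEstimate
    total: EffectEstimate
    prop_mediated: EffectEstimate
    prop_mediated_unstable: bool
    n: int
    B: int
    seed: int | None


def _empirical_p(draws: np.ndarray) -> float:
    """Two-sided bootstrap p: 2·min(P(θ* ≤ 0), P(θ* ≥ 0)), (1+k)/(B+1)."""
    B = len(draws)
    p_lo = (1 + np.sum(draws <= 0)) / (B + 1)
    p_hi = (1 + np.sum(draws >= 0)) / (B + 1)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def _summarize(point: float, draws: np.ndarray | None) -> EffectEstimate:
    if draws is None:
        return EffectEstimate(point=float(point), ci=None, p=None)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return EffectEstimate(point=float(point), ci=(float(lo), float(hi)),
                          p=_empirical_p(draws))


def _mediation_draws(XM, M, XY, Y, W):
    """a·b, c' and total for each weighted bootstrap resample.

    Column layout: XM = [1, T, C...] (a at index 1); XY = [1, T, M, C...]
    (c' at 1, b at 2).
    """
    beta_m = batched_ols(XM, M, W)
    beta_y = batched_ols(XY, Y, W)
    a = beta_m[:, 1]
    cprime = beta_y[:, 1]
    b = beta_y[:, 2]
    return a * b, cprime, a * b + cprime


def fit_mediation(
    treatment,
    mediator,
    outcome,
    covariates=None,
    B: int = 10_000,
    seed: int = 0,
) -> MediationResult:
    """Estimate ACME, ADE, total effect and proportion mediated.

    All three variables are continuous; ``covariates`` (array or DataFrame)
    enter both regressions. Rows must be complete. ``B`` bootstrap resamples
    of individuals give percentile CIs and empirical p-values; ``B`` below
    100 is refused.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    T = np.asarray(treatment, float)
    M = np.asarray(mediator, float)
    Y = np.asarray(outcome, float)
    n = len(T)
    if len(M) != n or len(Y) != n:
        raise ValueError("treatment, mediator and outcome must align")
    if np.allclose(M, Y):
        raise ValueError("mediator is identical to outcome")
    for name, v in (("treatment", T), ("mediator", M), ("outcome", Y)):
        if not np.isfinite(v).all():
            raise ValueError(f"{name} contains non-finite values (complete rows required)")
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
    XM = np.column_stack([np.ones(n), T, C])
    XY = np.column_stack([np.ones(n), T, M, C])
    if np.linalg.matrix_rank(XY) < XY.shape[1]:
        raise ValueError("collinear design (mediator or covariate degenerate)")

    beta_m, _, _, _ = ols_fit(XM, M)
    beta_y, _, _, _ = ols_fit(XY, Y)
    a, cprime, b = beta_m[1], beta_y[1], beta_y[2]
    acme = a * b
    ade = cprime
    # total effect from Y ~ T + C; algebraically equal to acme + ade
    beta_t, _, _, _ = ols_fit(XM, Y)  # same columns as XM: [1, T, C]
    total = beta_t[1]
    assert abs((acme + ade) - total) < 1e-9 * max(1.0, abs(total))

    rng = np.random.default_rng(seed)
    W = multinomial_weights(rng, n, B)
    acme_d, ade_d, total_d = _mediation_draws(XM, M, XY, Y, W)

    unstable = abs(total) < TOTAL_TOL
    if unstable:
        logger.warning("total effect below tolerance; proportion mediated unstable")
        prop = _summarize(np.nan, None)
    else:
        prop_d = acme_d / np.where(np.abs(total_d) < TOTAL_TOL, np.nan, total_d)
        prop_d = prop_d[np.isfinite(prop_d)]
        prop = _summarize(acme / total, prop_d if len(prop_d) >= 100 else None)

    return MediationResult(
        acme=_summarize(acme, acme_d),
        ade=_summarize(ade, ade_d),
        total=_summarize(total, total_d),
        prop_mediated=prop,
        prop_mediated_unstable=bool(unstable),
        n=n,
        B=B,
        seed=seed,
    )


def fit_mediation_with_upstream(
    treatment,
    mediator,
    outcome,
    upstream_covariate,
    covariates=None,
    B: int = 10_000,
    seed: int = 0,
) -> MediationResult:
    """Mediation with an upstream endophenotype appended to the covariate
    set of both regressions (e.g. conditioning the NFT -> cognitive-decline
    mediation on neuritic-plaque burden)."""
    U = np.asarray(upstream_covariate, float)
    M = np.asarray(mediator, float)
    if np.allclose(U, M):
        raise ValueError("upstream covariate is identical to the mediator")
    if covariates is None:
        C = U[:, None]
    else:
        C0 = np.asarray(covariates, float)
        if C0.ndim == 1:
            C0 = C0[:, None]
        C = np.column_stack([C0, U])
    return fit_mediation(treatment, mediator, outcome, C, B=B, seed=seed)
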