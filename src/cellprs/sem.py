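"""Recursive path-model SEM on residualised variables.

The model is a directed acyclic set of linear regressions among observed
variables (scores and endophenotypes), with free covariances among the
exogenous variables. For such a recursive model with all variables observed,
maximum-likelihood point estimates equal equation-by-equation OLS, so the
estimator here fits each equation by OLS, assembles the model-implied
covariance Σ(θ) = (I − B)⁻¹ Ψ (I − B)⁻ᵀ, and evaluates the normal-theory
discrepancy

    F_ML = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p,    χ² = n·F_ML,

with S the n-denominator (ML) sample covariance. Fit indices: CFI and TLI
against the independence baseline, RMSEA from the noncentrality estimate,
and SRMR as the RMS of standardised residual covariances. The completely
standardised solution rescales each coefficient by the model-implied SDs of
its variables. Bootstrap SEs and percentile CIs come from case resampling.

Variables are residualised against the covariate set (ε4/ε2 dosages, age,
sex, batch, PCs; education for the cognition variable only) before entering
the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._linalg import ols_fit

DEFAULT_MODEL_TEXT = """
DP ~ AstScore
NP ~ DP + AstScore + MicScore
NFT ~ NP + MicScore
CogDec ~ NFT + NP + MicScore
AstScore ~~ MicScore
"""


@dataclass
class PathModel:
    """Directed edges (regressions) plus free exogenous covariances."""

    regressions: Mapping[str, list[str]]       # child -> parents
    covariances: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regressions = {c: list(ps) for c, ps in self.regressions.items()}
        for child, parents in self.regressions.items():
            if child in parents:
                raise ValueError(f"self-loop on {child}")
        if self._has_cycle():
            raise ValueError("path model must be acyclic")
        endo = set(self.regressions)
        for a, b in self.covariances:
            if a in endo or b in endo:
                raise ValueError(
                    f"covariance {a}~~{b} involves an endogenous variable"
                )

    @classmethod
    def from_text(cls, text: str) -> "PathModel":
        """Parse a lavaan-style edge list: ``child ~ p1 + p2`` regressions
        and ``a ~~ b`` free covariances, one per line."""
        regs: dict[str, list[str]] = {}
        covs: list[tuple[str, str]] = []
        for line in text.strip().splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "~~" in line:
                a, b = (s.strip() for s in line.split("~~"))
                covs.append((a, b))
            elif "~" in line:
                child, rhs = (s.strip() for s in line.split("~", 1))
                regs.setdefault(child, []).extend(
                    p.strip() for p in rhs.split("+")
                )
            else:
                raise ValueError(f"cannot parse model line: {line!r}")
        return cls(regressions=regs, covariances=covs)

    @classmethod
    def default(cls) -> "PathModel":
        return cls.from_text(DEFAULT_MODEL_TEXT)

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for child, parents in self.regressions.items():
            for v in parents + [child]:
                if v not in seen:
                    seen.append(v)
        for a, b in self.covariances:
            for v in (a, b):
                if v not in seen:
                    seen.append(v)
        return seen

    @property
    def endogenous(self) -> list[str]:
        return list(self.regressions)

    @property
    def exogenous(self) -> list[str]:
        endo = set(self.regressions)
        return [v for v in self.variables if v not in endo]

    def n_free_parameters(self) -> int:
        n_edges = sum(len(ps) for ps in self.regressions.values())
        return (
            n_edges
            + len(self.endogenous)          # residual variances
            + len(self.exogenous)           # exogenous variances
            + len(self.covariances)         # free exogenous covariances
        )

    def _has_cycle(self) -> bool:
        state: dict[str, int] = {}

        def visit(v: str) -> bool:
            if state.get(v) == 1:
                return True
            if state.get(v) == 2:
                return False
            state[v] = 1
            for p in self.regressions.get(v, []):
                if visit(p):
                    return True
            state[v] = 2
            return False

        return any(visit(v) for v in list(self.regressions))


@dataclass
class SEMFit:
    edges: pd.DataFrame      # child, parent, est, std, se_boot, ci_lo, ci_hi
    chi2: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    chi2_baseline: float
    df_baseline: int
    n: int
    B: int
    seed: int | None
    sigma: pd.DataFrame
    sample_cov: pd.DataFrame

    def standardized(self, child: str, parent: str) -> float:
        row = self.edges[(self.edges.child == child) & (self.edges.parent == parent)]
        if row.empty:
            raise KeyError(f"no edge {parent} -> {child}")
        return float(row["std"].iloc[0])


def residualize(
    variables: pd.DataFrame,
    covariates: pd.DataFrame,
    per_variable: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Replace each variable by its OLS residual on the covariates.

    ``per_variable`` maps a variable name to the covariate columns used for
    it (e.g. education only for the cognition variable); others use the full
    set. Rows must be complete.
    """
    out = {}
    n = len(variables)
    for col in variables.columns:
        cols = list(per_variable.get(col, covariates.columns)) if per_variable else list(covariates.columns)
        X = np.column_stack([np.ones(n), covariates[cols].to_numpy(float)])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError(f"singular covariate matrix for {col!r}")
        _, _, resid, _ = ols_fit(X, variables[col].to_numpy(float))
        out[col] = resid
    return pd.DataFrame(out, index=variables.index)


def _point_estimates(model: PathModel, X: np.ndarray, order: list[str]):
    """Per-equation OLS coefficients B and disturbance covariance Psi."""
    p = len(order)
    idx = {v: i for i, v in enumerate(order)}
    n = X.shape[0]
    Bmat = np.zeros((p, p))
    Psi = np.zeros((p, p))
    S = np.cov(X.T, bias=True)
    S = np.atleast_2d(S)
    exo = model.exogenous
    for v in exo:
        Psi[idx[v], idx[v]] = S[idx[v], idx[v]]
    for a, b in model.covariances:
        Psi[idx[a], idx[b]] = Psi[idx[b], idx[a]] = S[idx[a], idx[b]]
    for child, parents in model.regressions.items():
        ci = idx[child]
        cols = [idx[pv] for pv in parents]
        Xd = np.column_stack([np.ones(n), X[:, cols]])
        beta, _, resid, _ = ols_fit(Xd, X[:, ci])
        for coef, pv in zip(beta[1:], parents):
            Bmat[ci, idx[pv]] = coef
        Psi[ci, ci] = float(resid @ resid) / n  # ML residual variance
    return Bmat, Psi, S


def implied_covariance(Bmat: np.ndarray, Psi: np.ndarray) -> np.ndarray:
    p = Bmat.shape[0]
    inv = np.linalg.inv(np.eye(p) - Bmat)
    return inv @ Psi @ inv.T


def fml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    p = S.shape[0]
    sign, logdet_sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("model-implied covariance not positive definite")
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sigma + np.trace(S @ np.linalg.inv(Sigma)) - logdet_s - p)


def fit_indices(chi2_m: float, df_m: int, chi2_b: float, df_b: int, n: int,
                S: np.ndarray, Sigma: np.ndarray) -> dict:
    nc_m = max(chi2_m - df_m, 0.0)
    nc_b = max(chi2_b - df_b, 0.0)
    if df_m == 0:
        cfi, tli, rmsea = 1.0, 1.0, 0.0
    else:
        cfi = 1.0 - nc_m / max(nc_b, nc_m, np.finfo(float).tiny)
        ratio_b = chi2_b / df_b
        ratio_m = chi2_m / df_m
        tli = (ratio_b - ratio_m) / (ratio_b - 1.0)
        rmsea = float(np.sqrt(nc_m / (df_m * n)))
    d = np.sqrt(np.diag(S))
    resid = (S - Sigma) / np.outer(d, d)
    tri = np.tril_indices_from(resid)
    srmr = float(np.sqrt(np.mean(resid[tri] ** 2)))
    return {"cfi": float(cfi), "tli": float(tli), "rmsea": float(rmsea), "srmr": srmr}


def _standardized_edges(model: PathModel, Bmat, Sigma, order):
    idx = {v: i for i, v in enumerate(order)}
    sds = np.sqrt(np.diag(Sigma))
    rows = []
    for child, parents in model.regressions.items():
        for pv in parents:
            est = Bmat[idx[child], idx[pv]]
            rows.append({
                "child": child,
                "parent": pv,
                "est": est,
                "std": est * sds[idx[pv]] / sds[idx[child]],
            })
    for a, b in model.covariances:
        cov = Sigma[idx[a], idx[b]]
        rows.append({
            "child": a, "parent": b, "est": cov,
            "std": cov / (sds[idx[a]] * sds[idx[b]]),
        })
    return pd.DataFrame(rows)


def fit_path_model(
    model: PathModel,
    data: pd.DataFrame,
    B: int = 10_000,
    seed: int = 0,
) -> SEMFit:
    """Fit the recursive path model on a residualised data table.

    Returns coefficients (unstandardised and completely standardised, with
    case-resampling bootstrap SE and percentile 95% CI), the χ² test of
    exact fit, and CFI/TLI/RMSEA/SRMR.
    """
    order = model.variables
    missing = [v for v in order if v not in data.columns]
    if missing:
        raise KeyError(f"model variables missing from data: {missing}")
    X = data[order].to_numpy(float)
    n, p = X.shape
    t = model.n_free_parameters()
    df = p * (p + 1) // 2 - t
    if df < 0:
        raise ValueError(f"model has negative df ({df}): too many free parameters")
    if n <= t:
        raise ValueError(f"n={n} too small for {t} free parameters")

    Bmat, Psi, S = _point_estimates(model, X, order)
    Sigma = implied_covariance(Bmat, Psi)
    chi2 = n * fml_discrepancy(S, Sigma)
    # baseline: independence model (variances only)
    sign, logdet_s = np.linalg.slogdet(S)
    chi2_b = n * float(np.sum(np.log(np.diag(S))) - logdet_s)
    df_b = p * (p - 1) // 2
    indices = fit_indices(chi2, df, chi2_b, df_b, n, S, Sigma)

    edges = _standardized_edges(model, Bmat, Sigma, order)

    if B > 0:
        rng = np.random.default_rng(seed)
        draws_est = np.empty((B, len(edges)))
        draws_std = np.empty((B, len(edges)))
        for b in range(B):
            idx_b = rng.integers(0, n, size=n)
            Bb, Psib, _ = _point_estimates(model, X[idx_b], order)
            Sigb = implied_covariance(Bb, Psib)
            eb = _standardized_edges(model, Bb, Sigb, order)
            draws_est[b] = eb["est"].to_numpy()
            draws_std[b] = eb["std"].to_numpy()
        edges["se_boot"] = draws_est.std(axis=0, ddof=1)
        edges["se_boot_std"] = draws_std.std(axis=0, ddof=1)
        lo, hi = np.percentile(draws_std, [2.5, 97.5], axis=0)
        edges["ci_lo_std"] = lo
        edges["ci_hi_std"] = hi
    else:
        edges["se_boot"] = np.nan
        edges["se_boot_std"] = np.nan
        edges["ci_lo_std"] = np.nan
        edges["ci_hi_std"] = np.nan

    return SEMFit(
        edges=edges,
        chi2=float(max(chi2, 0.0)),
        df=df,
        chi2_baseline=float(chi2_b),
        df_baseline=df_b,
        n=n,
        B=B,
        seed=seed,
        sigma=pd.DataFrame(Sigma, index=order, columns=order),
        sample_cov=pd.DataFrame(S, index=order, columns=order),
        **indices,
    )
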