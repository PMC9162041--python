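"""Covariate-adjusted per-taxon score tests.

The association model is a GLM linking the outcome to covariates and one
abundance column at a time, with a logit link for binary outcomes and the
identity link for continuous ones.  Only the null model (outcome ~
intercept + covariates, no taxa) is ever fitted; each taxon k is then
scored with

    U_k = sum_i (Y_i - mu_i) * Mres_ik,

where ``Mres`` is the abundance matrix residualized column-wise on the
covariates by OLS.  The variance of U_k under the null is

    V_kk = sum_i v_i * Mres_ik**2,

with v_i = mu_i (1 - mu_i) for binary outcomes and v_i = sigma2 (the ML
residual variance of the null fit) for continuous ones.  Standardizing,
Utilde_k = U_k / sqrt(V_kk) is asymptotically N(0, 1) under the null, and
the per-taxon one-sided p-values are Phi(Utilde_k) (lower tail) and
1 - Phi(Utilde_k) (upper tail).  Taxa with V_kk = 0 carry no information
and are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.stats import norm
import statsmodels.api as sm

__all__ = [
    "NullModelFit",
    "ResidualizedAbundance",
    "ScoreTestResult",
    "fit_null_model",
    "residualize",
    "score_statistics",
    "one_sided_pvalues",
    "P_FLOOR",
    "P_CEIL",
]

# clamp p-values away from exactly 0/1 so -log p stays finite
P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16

# observed-variance cutoff below which a column is machine-noise (constant
# column after residualization on [0,1]-scaled abundances)
V_TOL = 1e-12


@dataclass
class NullModelFit:
    """Null GLM fit of the outcome on intercept + covariates only."""

    outcome_type: str
    coef: np.ndarray
    mu: np.ndarray
    resid: np.ndarray          # Y - mu
    var_weights: np.ndarray    # v_i: mu(1-mu) binary, sigma2 continuous
    sigma2: Optional[float] = None


@dataclass
class ResidualizedAbundance:
    """Abundance columns regressed on intercept + covariates by OLS."""

    fitted: np.ndarray
    resid: np.ndarray


@dataclass
class ScoreTestResult:
    U: np.ndarray
    V: np.ndarray
    U_std: np.ndarray
    p_lower: np.ndarray
    p_upper: np.ndarray
    kept: np.ndarray  # boolean mask over the input columns


def _design(n: int, Z: Optional[np.ndarray]) -> np.ndarray:
    if Z is None:
        return np.ones((n, 1))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[1] == 0:
        return np.ones((n, 1))
    D = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("covariate design is rank-deficient")
    return D


def fit_null_model(Y, Z=None, outcome_type: str = "binary") -> NullModelFit:
    """Fit the H0 model (no taxa): outcome on intercept + covariates.

    Binary outcomes use logistic regression, continuous outcomes OLS; the
    continuous residual variance is the ML estimate (divide by n).
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.size
    D = _design(n, Z)
    if n < D.shape[1] + 1:
        raise ValueError("too few samples for the null model")
    if outcome_type == "binary":
        uniq = np.unique(Y)
        if not np.all(np.isin(uniq, [0.0, 1.0])) or uniq.size < 2:
            raise ValueError("binary outcome must contain both 0 and 1")
        try:
            fit = sm.GLM(Y, D, family=sm.families.Binomial()).fit()
        except Exception as e:
            raise ValueError(f"null logistic fit failed: {e}") from None
        mu = np.asarray(fit.fittedvalues)
        if np.any(mu <= 1e-10) or np.any(mu >= 1 - 1e-10):
            raise ValueError("perfect separation in the null logistic fit")
        v = mu * (1.0 - mu)
        return NullModelFit("binary", np.asarray(fit.params), mu, Y - mu, v)
    elif outcome_type == "continuous":
        coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
        mu = D @ coef
        resid = Y - mu
        sigma2 = float(resid @ resid) / n
        if sigma2 <= 0:
            raise ValueError("degenerate continuous outcome (zero residual variance)")
        v = np.full(n, sigma2)
        return NullModelFit("continuous", coef, mu, resid, v, sigma2=sigma2)
    raise ValueError(f"unknown outcome_type: {outcome_type!r}")


def residualize(M: np.ndarray, Z=None) -> ResidualizedAbundance:
    """OLS-residualize each abundance column on intercept + covariates."""
    M = np.asarray(M, dtype=float)
    D = _design(M.shape[0], Z)
    Q, _ = np.linalg.qr(D)
    fitted = Q @ (Q.T @ M)
    return ResidualizedAbundance(fitted=fitted, resid=M - fitted)


def score_statistics(null_fit: NullModelFit, res: ResidualizedAbundance) -> ScoreTestResult:
    """Per-taxon score statistics and one-sided p-values.

    Columns whose null variance V_kk vanishes (constant columns) are
    removed; ``kept`` records the surviving mask.
    """
    Mt = res.resid
    if Mt.shape[0] != null_fit.mu.size:
        raise ValueError("sample-size mismatch between null fit and residuals")
    U = Mt.T @ null_fit.resid
    V = (Mt * Mt).T @ null_fit.var_weights
    kept = V > V_TOL
    U, V = U[kept], V[kept]
    U_std = U / np.sqrt(V)
    p_l, p_u = one_sided_pvalues(U_std)
    return ScoreTestResult(U=U, V=V, U_std=U_std, p_lower=p_l, p_upper=p_u, kept=kept)


def one_sided_pvalues(U_std: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Lower/upper-tail normal p-values, clamped away from 0 and 1."""
    p_l = norm.cdf(U_std)
    p_u = norm.sf(U_std)
    return (
        np.clip(p_l, P_FLOOR, P_CEIL),
        np.clip(p_u, P_FLOOR, P_CEIL),
    )
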