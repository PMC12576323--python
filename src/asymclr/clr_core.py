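"""Conditional logistic regression (CLR) for 1:1 matched strata.

For a matched pair with covariates ``X_case`` and ``X_control`` the
conditional likelihood that the case pattern is the observed one depends
only on the difference ``Z = X_case - X_control``:

    l(beta) = sum_i w_i [ Z_i beta - log(1 + exp(Z_i beta)) ]

with optional nonnegative per-stratum weights ``w_i`` (all 1 when
unweighted).  The gradient and Hessian are

    g(beta) = Z' diag(w) (1 - mu),       mu_i = sigmoid(Z_i beta)
    H(beta) = -Z' diag(w * mu * (1 - mu)) Z

which this module evaluates with overflow-safe log1p/softplus forms and
maximizes by Newton-Raphson with step-halving.  The Wald test uses the
large-sample normal reference, matching the convention of survival::clogit.

:func:`relevance_pvalue` is the homogeneity likelihood-ratio test between a
local and an external dataset; its upper-tail chi-squared probability is the
per-dataset relevance p-value q that drives the adaptive integration
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

from .matched_data import DifferenceData

__all__ = [
    "ClrWorkspace",
    "ClrFit",
    "DegenerateDataError",
    "clr_loglik",
    "clr_score_hessian",
    "fit_clr",
    "wald_p",
    "relevance_pvalue",
]


class DegenerateDataError(ValueError):
    """The difference data carry no information (all z rows are zero)."""


@dataclass
class ClrWorkspace:
    """Per-stratum fitted quantities at a given beta."""

    mu: np.ndarray       # P(case pattern) per stratum, in (0,1)
    w: np.ndarray        # mu*(1-mu), the diagonal of W, in (0, 0.25]
    score: np.ndarray    # gradient g(beta), shape (p,)
    hessian: np.ndarray  # H(beta), shape (p,p), symmetric negative semi-definite


@dataclass
class ClrFit:
    """A fitted conditional logistic model."""

    beta: np.ndarray      # shape (p,)
    se: np.ndarray        # shape (p,), from observed information
    loglik: float
    iterations: int
    converged: bool
    p_wald: np.ndarray    # two-sided normal-reference p per coefficient

    @property
    def beta1(self) -> float:
        """The single coefficient, for the genotype-only model."""
        return float(self.beta[0])

    @property
    def se1(self) -> float:
        return float(self.se[0])

    @property
    def p1(self) -> float:
        return float(self.p_wald[0])


def _as_z(arr) -> np.ndarray:
    z = np.asarray(arr, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    return z


def _z_weights(
    diff: DifferenceData | np.ndarray, beta, weights
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    z = diff.z if isinstance(diff, DifferenceData) else _as_z(diff)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if beta.shape[0] != z.shape[1]:
        raise ValueError(f"beta has {beta.shape[0]} entries but z has {z.shape[1]} columns")
    if weights is None:
        w = np.ones(z.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (z.shape[0],):
            raise ValueError("weights length must equal the number of strata")
        if (w < 0).any():
            raise ValueError("stratum weights must be nonnegative")
    return z, beta, w


def clr_loglik(diff, beta, weights=None) -> float:
    """Weighted conditional log-likelihood sum_i w_i [eta_i - log(1+exp(eta_i))]."""
    z, beta, w = _z_weights(diff, beta, weights)
    eta = z @ beta
    # eta - log(1+e^eta) = -log(1+e^-eta) = -softplus(-eta)
    return float(np.dot(w, -np.logaddexp(0.0, -eta)))


def clr_score_hessian(diff, beta, weights=None) -> ClrWorkspace:
    """Gradient and Hessian of the weighted conditional log-likelihood."""
    z, beta, w = _z_weights(diff, beta, weights)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    eta = z @ beta
    mu = expit(eta)
    wdiag = mu * (1.0 - mu)
    score = z.T @ (w * (1.0 - mu))
    hessian = -(z * (w * wdiag)[:, None]).T @ z
    return ClrWorkspace(mu=mu, w=wdiag, score=score, hessian=hessian)


def fit_clr(
    diff,
    weights=None,
    tol: float = 1e-10,
    max_iter: int = 50,
    max_halvings: int = 20,
    separation_bound: float = 15.0,
) -> ClrFit:
    """Maximize the (weighted) conditional log-likelihood by Newton-Raphson.

    Convergence is declared when the log-likelihood change falls below
    ``tol``.  If any coefficient wanders beyond ``separation_bound`` while
    the likelihood is still improving the fit is flagged non-converged
    (quasi-complete separation); standard errors and Wald p-values are then
    NaN rather than silently huge.

    Raises :class:`DegenerateDataError` when every (weighted) z row is zero.
    """
    z = diff.z if isinstance(diff, DifferenceData) else _as_z(diff)
    z, _, w = _z_weights(z, np.zeros(z.shape[1]), weights)
    p = z.shape[1]
    if not np.any((z != 0.0).any(axis=1) & (w > 0)):
        raise DegenerateDataError("all difference rows are zero (or zero-weighted)")

    beta = np.zeros(p)
    ll = clr_loglik(z, beta, w)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        ws = clr_score_hessian(z, beta, w)
        neg_h = -ws.hessian
        try:
            delta = np.linalg.solve(neg_h, ws.score)
        except np.linalg.LinAlgError:
            # information singular: ridge the Newton system minimally
            delta = np.linalg.solve(neg_h + 1e-10 * np.eye(p), ws.score)
        step = 1.0
        ll_new = clr_loglik(z, beta + delta, w)
        halvings = 0
        while ll_new < ll and halvings < max_halvings:
            step *= 0.5
            halvings += 1
            ll_new = clr_loglik(z, beta + step * delta, w)
        if ll_new < ll:
            # no improving step: treat the current point as the optimum
            converged = True
            break
        beta = beta + step * delta
        change = ll_new - ll
        ll = ll_new
        if change < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > separation_bound:
            separated = True
            break

    if separated:
        converged = False
    ws = clr_score_hessian(z, beta, w)
    if converged:
        cov = np.linalg.inv(-ws.hessian)
        se = np.sqrt(np.diag(cov))
        p_wald = 2.0 * stats.norm.sf(np.abs(beta / se))
    else:
        se = np.full(p, np.nan)
        p_wald = np.full(p, np.nan)
    return ClrFit(
        beta=beta, se=se, loglik=ll, iterations=it, converged=converged, p_wald=p_wald
    )


def wald_p(fit: ClrFit) -> float:
    """Two-sided normal-reference Wald p-value for the first coefficient."""
    if not fit.converged:
        raise ValueError("Wald test requires a converged fit")
    if not np.all(fit.se > 0):
        raise ValueError("Wald test undefined with zero standard error")
    return float(2.0 * stats.norm.sf(abs(fit.beta[0] / fit.se[0])))


def relevance_pvalue(local: DifferenceData, external: DifferenceData) -> float:
    """Homogeneity LRT p-value q between a local and an external dataset.

    Fits the CLR separately on each dataset and jointly on their pooled
    strata; the statistic 2[l_loc(b_loc) + l_ext(b_ext) - l_pooled(b_pool)]
    is referred to chi-squared with df equal to the number of coefficients.
    Large q (no detectable heterogeneity) marks the external dataset as
    relevant.
    """
    fit_l = fit_clr(local)
    fit_e = fit_clr(external)
    if not (fit_l.converged and fit_e.converged):
        raise ValueError("relevance test requires both datasets to fit without separation")
    z_pool = np.vstack([local.z, external.z])
    fit_p = fit_clr(z_pool)
    if not fit_p.converged:
        raise ValueError("pooled fit did not converge")
    stat = 2.0 * (fit_l.loglik + fit_e.loglik - fit_p.loglik)
    stat = max(stat, 0.0)
    df = local.z.shape[1]
    return float(stats.chi2.sf(stat, df))
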