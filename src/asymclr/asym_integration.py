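"""Asymmetric integration of auxiliary cohorts into a local CLR fit.

One cohort (the "local" dataset, e.g. the cancer of interest) is primary;
K auxiliary cohorts enter the weighted conditional log-likelihood

    l_w(beta) = l_0(beta) + sum_k omega_k l_k(beta),    omega_k in [0, 1]

so an irrelevant auxiliary dataset can be excluded entirely (omega=0) while
a concordant one contributes at full weight.  The weights are not free
parameters: each auxiliary cohort first receives a relevance p-value q_k
from a homogeneity likelihood-ratio test against the local data, and a
piecewise-linear map with two knots (qA, qB),

    omega = 0            for q <= qA
    omega = (q-qA)/(qB-qA)  for qA < q <= qB
    omega = 1            for q > qB,

turns the K-dimensional weight choice into a 2-D search.  (qA, qB) are
chosen to minimize the local dataset's leave-one-stratum-out
cross-validated negative log-likelihood,

    sum_j -l_j(beta_loo_j),

where beta_loo_j is a one-step Newton approximation to the weighted
estimate refitted without local stratum j:

    beta_loo_j = beta_hat - A^{-1} z_j' (1 - mu_j) / (1 - v_jj)

with A = Z0'W0Z0 + sum_k omega_k Zk'WkZk the weighted information and
v_jj the j-th diagonal of the hat-type matrix W0^(1/2) Z0 A^{-1} Z0' W0^(1/2).
The LOOCV objective measures out-of-sample fit on the local data only, so
auxiliary data are used exactly insofar as they help the primary cohort —
the asymmetry of the method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .clr_core import (
    ClrFit,
    DegenerateDataError,
    clr_loglik,
    clr_score_hessian,
    fit_clr,
    relevance_pvalue,
    wald_p,
)
from .matched_data import DifferenceData, DosageMatrix, MatchedCohort, cohort_differences

__all__ = [
    "WeightMap",
    "IntegrationResult",
    "LooState",
    "map_weights",
    "weighted_fit",
    "loo_onestep",
    "cv_objective",
    "optimize_map",
    "integrate_variant",
    "integrate_all",
    "RESULT_COLUMNS",
]

_FAILED_OBJECTIVE = 1e10  # returned when a candidate weighted fit separates


@dataclass(frozen=True)
class WeightMap:
    """The two knots of the piecewise-linear relevance-to-weight map."""

    qa: float
    qb: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.qa <= self.qb <= 1.0):
            raise ValueError(f"require 0 <= qa <= qb <= 1, got ({self.qa}, {self.qb})")


@dataclass
class LooState:
    """One-step leave-one-stratum-out state for the local cohort."""

    v_diag: np.ndarray    # leverage v_jj in [0, 1), length n0
    beta_loo: np.ndarray  # shape (n0, p): one-step estimates without stratum j


@dataclass
class IntegrationResult:
    """Outcome of the adaptive-weight integration for one variant."""

    q: np.ndarray          # relevance p-values, length K
    map: WeightMap
    omega: np.ndarray      # weights in [0,1], length K
    fit: ClrFit            # weighted fit at the selected omega
    cv_objective: float    # minimized negative LOOCV log-likelihood
    p_integrated: float


def map_weights(q, wmap: WeightMap) -> np.ndarray:
    """Map relevance p-values to integration weights through (qa, qb).

    When qa == qb the map degenerates to the right-continuous step
    1{q > qa}.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if ((q < 0) | (q > 1)).any():
        raise ValueError("relevance p-values must lie in [0, 1]")
    if wmap.qb == wmap.qa:
        return (q > wmap.qa).astype(float)
    omega = (q - wmap.qa) / (wmap.qb - wmap.qa)
    omega = np.clip(omega, 0.0, 1.0)
    # enforce the half-open middle branch exactly at the knots
    omega[q <= wmap.qa] = 0.0
    omega[q > wmap.qb] = 1.0
    return omega


def _stack(local: DifferenceData, externals: list[DifferenceData], omega: np.ndarray):
    """Stack local strata (weight 1) with nonzero-weight external strata.

    Zero-weight externals are dropped before stacking so that omega == 0
    reproduces the local-only fit bit-for-bit.
    """
    blocks = [local.z]
    wts = [np.ones(local.n0)]
    for om, ext in zip(omega, externals):
        if om > 0.0:
            blocks.append(ext.z)
            wts.append(np.full(ext.n0, om))
    if len(blocks) == 1:
        return local.z, np.ones(local.n0)
    return np.vstack(blocks), np.concatenate(wts)


def weighted_fit(
    local: DifferenceData, externals: list[DifferenceData], omega
) -> ClrFit:
    """Maximize l_0(beta) + sum_k omega_k l_k(beta); local strata carry weight 1."""
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    if omega.shape[0] != len(externals):
        raise ValueError("omega length must equal the number of external datasets")
    if ((omega < 0) | (omega > 1)).any():
        raise ValueError("each omega must lie in [0, 1]")
    z, w = _stack(local, externals, omega)
    return fit_clr(z, weights=w)


def loo_onestep(
    local: DifferenceData,
    externals: list[DifferenceData],
    omega,
    fit: ClrFit,
) -> LooState:
    """One-step leave-one-out estimates for every local stratum.

    Uses the Newton step of the weighted likelihood without stratum j,
    collapsed by Sherman-Morrison into the closed form
    beta_hat - A^{-1} z_j (1-mu_j)/(1-v_jj).
    """
    if not fit.converged:
        raise ValueError("one-step LOO requires a converged weighted fit")
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    beta = fit.beta
    z0 = local.z
    ws0 = clr_score_hessian(z0, beta)
    a = -ws0.hessian
    for om, ext in zip(omega, externals):
        if om > 0.0:
            a = a - om * clr_score_hessian(ext.z, beta).hessian
    a_inv = np.linalg.inv(a)
    u = z0 @ a_inv  # (n0, p): rows z_j A^{-1}
    v_diag = ws0.w * np.einsum("ij,ij->i", u, z0)
    if (v_diag >= 1.0).any():
        raise ValueError("a local stratum has leverage v_jj >= 1 and dominates the fit")
    resid = (1.0 - ws0.mu) / (1.0 - v_diag)
    beta_loo = beta[None, :] - u * resid[:, None]
    return LooState(v_diag=v_diag, beta_loo=beta_loo)


def _objective_at_omega(
    local: DifferenceData, externals: list[DifferenceData], omega: np.ndarray
) -> tuple[float, ClrFit | None]:
    try:
        fit = weighted_fit(local, externals, omega)
    except DegenerateDataError:
        return _FAILED_OBJECTIVE, None
    if not fit.converged:
        return _FAILED_OBJECTIVE, None
    loo = loo_onestep(local, externals, omega, fit)
    eta = np.einsum("ij,ij->i", local.z, loo.beta_loo)
    # stratum log-likelihood at its own left-out estimate: eta - log(1+e^eta)
    return float(np.sum(np.logaddexp(0.0, -eta))), fit


def cv_objective(
    local: DifferenceData,
    externals: list[DifferenceData],
    q,
    wmap: WeightMap,
    exact: bool = False,
) -> float:
    """Negative LOOCV log-likelihood of the local data at the weights map(q).

    ``exact=True`` replaces the one-step approximation with a full refit per
    left-out stratum (slow; intended for validation).
    """
    omega = map_weights(q, wmap)
    if exact:
        return _exact_cv_objective(local, externals, omega)
    value, _ = _objective_at_omega(local, externals, omega)
    return value


def _exact_cv_objective(
    local: DifferenceData, externals: list[DifferenceData], omega: np.ndarray
) -> float:
    total = 0.0
    for j in range(local.n0):
        keep = np.ones(local.n0, dtype=bool)
        keep[j] = False
        sub = DifferenceData(local.z[keep])
        fit_j = weighted_fit(sub, externals, omega)
        if not fit_j.converged:
            return _FAILED_OBJECTIVE
        eta = float(local.z[j] @ fit_j.beta)
        total += np.logaddexp(0.0, -eta)
    return total


_GRID = (0.05, 0.5, 0.95)


def optimize_map(
    local: DifferenceData,
    externals: list[DifferenceData],
    q,
    fd_step: float = 1e-4,
) -> IntegrationResult:
    """Choose (qA, qB) minimizing the LOOCV objective.

    The constraint 0 <= qA <= qB <= 1 is enforced smoothly by the
    reparameterization qa = a, qb = a + (1-a) b with a, b in [0, 1]^2,
    searched by bounded quasi-Newton (L-BFGS-B, forward-difference
    gradients) from a 3x3 grid of starts plus the corner (1, 1) whose
    all-zero weights reproduce the non-integrated fit.  Objective values
    are cached on the induced omega vector because many (qA, qB) pairs are
    equivalent.  Ties break toward the first-found lowest objective.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    cache: dict[tuple, float] = {}

    def ab_to_map(a: float, b: float) -> WeightMap:
        a = min(max(a, 0.0), 1.0)
        b = min(max(b, 0.0), 1.0)
        qa = a
        qb = a + (1.0 - a) * b
        return WeightMap(qa, min(qb, 1.0))

    def f(x) -> float:
        wmap = ab_to_map(x[0], x[1])
        omega = map_weights(q, wmap)
        key = tuple(np.round(omega, 9))
        if key not in cache:
            cache[key], _ = _objective_at_omega(local, externals, omega)
        return cache[key]

    starts = [(a, b) for a in _GRID for b in _GRID]
    best_x: np.ndarray | None = None
    best_f = np.inf
    failures = []
    for x0 in starts:
        try:
            res = optimize.minimize(
                f,
                np.asarray(x0, dtype=float),
                method="L-BFGS-B",
                bounds=[(0.0, 1.0), (0.0, 1.0)],
                options={"eps": fd_step, "maxiter": 60},
            )
        except Exception as exc:  # pragma: no cover - scipy failure paths
            failures.append((x0, repr(exc)))
            continue
        for cand_x, cand_f in ((np.asarray(x0, float), f(x0)), (res.x, res.fun)):
            if cand_f < best_f:
                best_f = float(cand_f)
                best_x = np.asarray(cand_x, dtype=float)
    # the all-zero-omega corner is always a candidate
    corner = np.array([1.0, 1.0])
    f_corner = f(corner)
    if f_corner < best_f:
        best_f, best_x = f_corner, corner
    if best_x is None or not np.isfinite(best_f) or best_f >= _FAILED_OBJECTIVE:
        raise RuntimeError(f"weight-map optimization failed from every start: {failures}")

    wmap = ab_to_map(best_x[0], best_x[1])
    omega = map_weights(q, wmap)
    _, fit = _objective_at_omega(local, externals, omega)
    if fit is None:  # pragma: no cover - guarded by best_f check
        raise RuntimeError("selected weights produced a degenerate fit")
    return IntegrationResult(
        q=q,
        map=wmap,
        omega=omega,
        fit=fit,
        cv_objective=best_f,
        p_integrated=wald_p(fit),
    )


RESULT_COLUMNS = [
    "variant_id", "chrom", "pos", "maf",
    "beta_local", "se_local", "p_local", "skipped",
    "qa", "qb",
    "beta_int", "se_int", "p_int",
]


def integrate_variant(
    variant: int,
    cohorts: list[MatchedCohort],
    local_label: str,
    dosages: DosageMatrix,
    prescreen_alpha: float = 0.05,
    _diffs: dict[str, np.ndarray] | None = None,
) -> dict:
    """Run the per-variant pipeline: local CLR, prescreen, then integration.

    The local cohort is fitted alone first; only variants with local Wald
    p below ``prescreen_alpha`` proceed to relevance testing and weight
    optimization against the remaining cohorts.  Returns a flat record;
    ``skipped`` is True when integration was not attempted, ``failed`` when
    the local fit separated (such variants are excluded from FDR input).
    """
    diffs = _diffs if _diffs is not None else {
        c.label: cohort_differences(c, dosages) for c in cohorts
    }
    by_label = {c.label: c for c in cohorts}
    if local_label not in by_label:
        raise KeyError(f"no cohort labeled {local_label!r}")
    ext_labels = [c.label for c in cohorts if c.label != local_label]

    vrec = dosages.variants[variant]
    from .matched_data import compute_maf

    record: dict = {
        "variant_id": vrec.id,
        "chrom": vrec.chrom,
        "pos": vrec.pos,
        "maf": vrec.maf if vrec.maf is not None else compute_maf(dosages, variant),
        "beta_local": np.nan, "se_local": np.nan, "p_local": np.nan,
        "skipped": True, "failed": False,
        "qa": np.nan, "qb": np.nan,
        "beta_int": np.nan, "se_int": np.nan, "p_int": np.nan,
    }
    for lab in ext_labels:
        record[f"q_{lab}"] = np.nan
        record[f"omega_{lab}"] = np.nan

    local = DifferenceData(diffs[local_label][:, [variant]])
    try:
        fit_local = fit_clr(local)
    except DegenerateDataError:
        record["failed"] = True
        return record
    if not fit_local.converged:
        record["failed"] = True
        return record
    record.update(
        beta_local=fit_local.beta1, se_local=fit_local.se1, p_local=fit_local.p1
    )
    if fit_local.p1 >= prescreen_alpha:
        return record

    externals = [DifferenceData(diffs[lab][:, [variant]]) for lab in ext_labels]
    q = np.empty(len(externals))
    for k, ext in enumerate(externals):
        try:
            q[k] = relevance_pvalue(local, ext)
        except (ValueError, DegenerateDataError):
            # a separated or empty auxiliary fit is treated as irrelevant
            q[k] = 0.0
    try:
        result = optimize_map(local, externals, q)
    except RuntimeError:
        record["failed"] = True
        return record
    record.update(
        skipped=False,
        qa=result.map.qa, qb=result.map.qb,
        beta_int=result.fit.beta1, se_int=result.fit.se1, p_int=result.p_integrated,
    )
    for lab, qk, om in zip(ext_labels, q, result.omega):
        record[f"q_{lab}"] = qk
        record[f"omega_{lab}"] = om
    return record


def integrate_all(
    dosages: DosageMatrix,
    cohorts: list[MatchedCohort],
    local_label: str,
    prescreen_alpha: float = 0.05,
    variants: list[int] | None = None,
):
    """Per-variant integration records for all (or selected) variants, as a DataFrame."""
    import pandas as pd

    diffs = {c.label: cohort_differences(c, dosages) for c in cohorts}
    idx = range(dosages.n_variants) if variants is None else variants
    records = [
        integrate_variant(
            j, cohorts, local_label, dosages,
            prescreen_alpha=prescreen_alpha, _diffs=diffs,
        )
        for j in idx
    ]
    return pd.DataFrame.from_records(records)
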