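"""Permutation-based FDR control for integrated and non-integrated p-values.

Integrated p-values are anti-conservative: they come from a weighted CLR
that treats the data-adaptive weights as fixed, and linkage disequilibrium
correlates tests across the genome, so standard procedures such as
Benjamini-Hochberg do not apply.  Instead, case/control labels are swapped
within each stratum with probability 1/2 (one genome-wide plan per cohort,
preserving LD in the permuted statistics), the entire analysis pipeline is
re-run on the permuted labels, and for each observed p-value threshold p_i
the FDR is estimated by the exceedance-count ratio

    FDR_i = min(m*_i / m_i, 1),
    m_i  = #{p in observed : p <= p_i},
    m*_i = #{p in permuted : p <= p_i},

made monotone by FDR_i <- min{FDR_j : j >= i}.  A multi-iteration variant
averages m* over several independent permutation plans; it is less noisy
(hence less liberal) at proportionally higher compute cost.

FDR is estimated within one local cohort's result set at a time — never
pooled across cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .asym_integration import integrate_all
from .matched_data import DifferenceData, DosageMatrix, MatchedCohort

__all__ = [
    "PermutationPlan",
    "FdrTable",
    "make_permutation",
    "apply_plan",
    "apply_plan_differences",
    "permuted_pvalues",
    "estimate_fdr",
    "estimate_fdr_multi",
    "extract_pvalues",
    "fdr_lookup",
]


@dataclass
class PermutationPlan:
    """A seeded within-stratum label-swap plan for one cohort."""

    seed: int
    swap: np.ndarray  # boolean, length n0; True = case/control exchanged

    def __post_init__(self) -> None:
        self.swap = np.asarray(self.swap, dtype=bool)


@dataclass
class FdrTable:
    """Sorted observed p-values with exceedance counts and monotone FDR."""

    p_sorted: np.ndarray
    m: np.ndarray        # |P_i|, observed exceedance counts
    m_star: np.ndarray   # |P*_i| (averaged over plans when multi-iteration)
    fdr_raw: np.ndarray  # min(m*/m, 1) before the monotone correction
    fdr: np.ndarray      # nondecreasing in i


def make_permutation(cohort: MatchedCohort, seed: int) -> PermutationPlan:
    """Flag each stratum for a label swap independently with probability 1/2."""
    rng = np.random.default_rng(seed)
    return PermutationPlan(seed=seed, swap=rng.random(cohort.n0) < 0.5)


def apply_plan(cohort: MatchedCohort, plan: PermutationPlan) -> MatchedCohort:
    """Exchange case/control labels at the plan's flagged strata."""
    if plan.swap.shape != (cohort.n0,):
        raise ValueError("plan length does not match the cohort's strata")
    return cohort.swapped(plan.swap)


def apply_plan_differences(diff: DifferenceData, plan: PermutationPlan) -> DifferenceData:
    """Label exchange is exactly a sign flip of z at the swapped strata."""
    if plan.swap.shape != (diff.n0,):
        raise ValueError("plan length does not match the difference data")
    sign = np.where(plan.swap, -1.0, 1.0)
    return DifferenceData(diff.z * sign[:, None])


def permuted_pvalues(
    dosages: DosageMatrix,
    cohorts: list[MatchedCohort],
    local_label: str,
    plans: dict[str, PermutationPlan],
    prescreen_alpha: float = 0.05,
    variants: list[int] | None = None,
) -> pd.DataFrame:
    """Re-run the full per-variant pipeline on label-permuted cohorts.

    The plans must be fixed before any variant is analyzed: one plan per
    cohort is shared across the genome so LD structure survives in the
    permuted statistics.  Prescreening and weight optimization are repeated
    from scratch on the permuted data.
    """
    permuted = [apply_plan(c, plans[c.label]) for c in cohorts]
    return integrate_all(
        dosages, permuted, local_label,
        prescreen_alpha=prescreen_alpha, variants=variants,
    )


def extract_pvalues(results: pd.DataFrame, method: str) -> np.ndarray:
    """Pull the p-value set a method feeds into the FDR estimator.

    ``method="integrated"`` takes p_int of variants that went through
    integration; ``method="non-integrated"`` takes p_local of every variant
    whose local fit succeeded.
    """
    ok = ~results["failed"].astype(bool)
    if method == "integrated":
        sel = ok & ~results["skipped"].astype(bool)
        return results.loc[sel, "p_int"].to_numpy(dtype=float)
    if method == "non-integrated":
        return results.loc[ok, "p_local"].to_numpy(dtype=float)
    raise ValueError(f"unknown method {method!r}")


def _counts(p_sorted: np.ndarray, pool: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.sort(pool), p_sorted, side="right").astype(float)


def estimate_fdr(observed, permuted) -> FdrTable:
    """Single-iteration permutation FDR estimates at every observed p-value."""
    return estimate_fdr_multi(observed, [permuted])


def estimate_fdr_multi(observed, permuted_sets: list) -> FdrTable:
    """Permutation FDR with m* averaged over B >= 1 permuted p-value sets."""
    observed = np.asarray(observed, dtype=float)
    if observed.size == 0:
        raise ValueError("observed p-value set is empty")
    if len(permuted_sets) < 1:
        raise ValueError("need at least one permuted p-value set")
    permuted_sets = [np.asarray(s, dtype=float) for s in permuted_sets]
    if any(s.size == 0 for s in permuted_sets):
        raise ValueError("a permuted p-value set is empty")
    p_sorted = np.sort(observed)
    m = _counts(p_sorted, observed)  # handles ties: m_i = #{p <= p_i}
    m_star = np.mean([_counts(p_sorted, s) for s in permuted_sets], axis=0)
    fdr_raw = np.minimum(m_star / m, 1.0)
    fdr = np.minimum.accumulate(fdr_raw[::-1])[::-1]
    return FdrTable(p_sorted=p_sorted, m=m, m_star=m_star, fdr_raw=fdr_raw, fdr=fdr)


def fdr_lookup(table: FdrTable, pvalues) -> np.ndarray:
    """Monotone FDR estimate at arbitrary p-values (matched to the table grid)."""
    pvalues = np.asarray(pvalues, dtype=float)
    idx = np.searchsorted(table.p_sorted, pvalues, side="left")
    idx = np.clip(idx, 0, len(table.p_sorted) - 1)
    return table.fdr[idx]
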