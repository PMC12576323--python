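"""Synthetic multi-cohort matched case-control dosage data.

Real matched-cohort genotype data of this kind sit behind patient-privacy
restrictions, so every pipeline stage is exercised on simulated cohorts
whose scale mirrors a hospital-biobank cancer collection: around 14
cohorts of roughly 70 to 2000 strata each, imputed dosages clustering near
{0, 1, 2}, a minor-allele-frequency spectrum spanning the 5% common-variant
cutoff, and per-cohort genotype effects that are shared, heterogeneous, or
null across cohorts.

Genotypes are Binomial(2, f) allele counts with truncated Gaussian
"imputation" noise, clipped to [0, 2].  Case status within a stratum with
member genotype vectors (g1, g2) and cohort effect vector beta is assigned
to member 1 with probability

    exp(g1 beta) / (exp(g1 beta) + exp(g2 beta))

— exactly the kernel of the 1:1 conditional logistic likelihood, so the
fitted coefficient is consistent for the simulated truth.  Matching
covariates are not simulated: the model never sees them (the conditional
likelihood conditions them out by design).

Optional exchangeable-correlation LD blocks (for clumping tests) are
generated by copying each allele from a block-level template with
probability sqrt(rho), giving pairwise dosage correlation approximately
rho within the block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .matched_data import DosageMatrix, MatchedCohort, VariantRecord

__all__ = [
    "SimConfig",
    "simulate_cohorts",
    "simulate_null_panel",
    "table1_template",
    "power_template",
]

GENERATOR_ALGORITHM = "numpy.random.Generator(PCG64)"

#: Cohort sizes shaped after a 14-cancer hospital-biobank collection
#: (strata = matched case-control pairs).
_TEMPLATE_COHORTS = {
    "bladder": 554, "brain": 334, "breast": 1964, "esophageal": 168,
    "head_neck": 670, "kidney": 680, "leukemia": 71, "liver": 260,
    "lung": 394, "ovarian": 158, "pancreatic": 233, "prostate": 1079,
    "sarcoma": 654, "stomach": 76,
}


@dataclass
class SimConfig:
    """Configuration of one simulated multi-cohort panel.

    ``beta`` holds the true per-cohort log-odds for every variant, shape
    (n_variants, n_cohorts): a constant row is a shared effect, a varying
    row a heterogeneous one, a zero row a null variant.  ``seed`` is
    mandatory; the generator algorithm is pinned in metadata so equal seeds
    give byte-identical panels.
    """

    labels: list[str]
    strata_per_cohort: list[int]
    n_variants: int
    seed: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    dosage_noise_sd: float = 0.05
    beta: np.ndarray | None = None
    ld_blocks: list[dict] | None = None  # each: {"start": j, "size": s, "rho": r}
    position_spacing: int = 1_000_000
    generator: str = field(default=GENERATOR_ALGORITHM)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.strata_per_cohort):
            raise ValueError("labels and strata_per_cohort lengths differ")
        if any(n < 1 for n in self.strata_per_cohort):
            raise ValueError("every cohort needs at least one stratum")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be a subset of (0, 0.5]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.beta is None:
            self.beta = np.zeros((self.n_variants, len(self.labels)))
        else:
            self.beta = np.asarray(self.beta, dtype=float)
            if self.beta.shape != (self.n_variants, len(self.labels)):
                raise ValueError(
                    f"beta shape {self.beta.shape} != "
                    f"({self.n_variants}, {len(self.labels)})"
                )

    @property
    def n_cohorts(self) -> int:
        return len(self.labels)


def table1_template(n_variants: int, seed: int, **kw) -> SimConfig:
    """The 14-cohort template at biobank scale (71 to 1964 strata)."""
    return SimConfig(
        labels=list(_TEMPLATE_COHORTS),
        strata_per_cohort=list(_TEMPLATE_COHORTS.values()),
        n_variants=n_variants,
        seed=seed,
        **kw,
    )


def power_template(n_variants: int, seed: int, **kw) -> SimConfig:
    """A small local cohort (ovarian-like, 158 strata) with one large
    auxiliary cohort (breast-like, 1964 strata), for power experiments."""
    return SimConfig(
        labels=["ovarian_like", "breast_like"],
        strata_per_cohort=[158, 1964],
        n_variants=n_variants,
        seed=seed,
        **kw,
    )


def _simulate_genotypes(config: SimConfig, rng: np.random.Generator, n_samples: int):
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], config.n_variants)
    alleles = rng.random((n_samples, config.n_variants, 2)) < freqs[None, :, None]
    if config.ld_blocks:
        for block in config.ld_blocks:
            start, size, rho = block["start"], block["size"], block["rho"]
            if not (0.0 <= rho <= 1.0):
                raise ValueError("ld block rho must lie in [0, 1]")
            theta = np.sqrt(rho)
            template = rng.random((n_samples, 1, 2)) < freqs[start]
            cols = slice(start, start + size)
            copy = rng.random((n_samples, size, 2)) < theta
            alleles[:, cols, :] = np.where(copy, template, alleles[:, cols, :])
    geno = alleles.sum(axis=2).astype(float)
    if config.dosage_noise_sd > 0:
        geno = geno + rng.normal(0.0, config.dosage_noise_sd, geno.shape)
        np.clip(geno, 0.0, 2.0, out=geno)
    return geno, freqs


def simulate_cohorts(
    config: SimConfig,
) -> tuple[DosageMatrix, list[MatchedCohort], pd.DataFrame]:
    """Generate dosages, matched cohorts, and the truth table of effects.

    Returns (dosage matrix over all samples, one cohort per label, a
    DataFrame ``variant cohort beta_true``).
    """
    rng = np.random.default_rng(config.seed)
    n_strata_total = int(np.sum(config.strata_per_cohort))
    n_samples = 2 * n_strata_total
    geno, _ = _simulate_genotypes(config, rng, n_samples)

    samples = [f"S{i:06d}" for i in range(n_samples)]
    # coordinate-style ids survive the TSV round trip (chrom:pos parsing)
    variants = [
        VariantRecord(
            chrom="1",
            pos=(j + 1) * config.position_spacing,
            id=f"1:{(j + 1) * config.position_spacing}",
        )
        for j in range(config.n_variants)
    ]

    cohorts: list[MatchedCohort] = []
    truth_rows = []
    offset = 0
    for c, (label, n0) in enumerate(zip(config.labels, config.strata_per_cohort)):
        beta_c = config.beta[:, c]
        strata = []
        for i in range(n0):
            s1, s2 = samples[offset], samples[offset + 1]
            eta1 = float(geno[offset] @ beta_c)
            eta2 = float(geno[offset + 1] @ beta_c)
            p_first_is_case = expit(eta1 - eta2)
            if rng.random() < p_first_is_case:
                case, control = s1, s2
            else:
                case, control = s2, s1
            strata.append((f"{label}:{i + 1:05d}", case, control))
            offset += 2
        cohorts.append(MatchedCohort(label=label, strata=strata))
        for j in range(config.n_variants):
            truth_rows.append(
                {"variant": variants[j].id, "cohort": label, "beta_true": beta_c[j]}
            )

    dosages = DosageMatrix(samples=samples, variants=variants, values=geno)
    truth = pd.DataFrame(truth_rows)
    return dosages, cohorts, truth


def simulate_null_panel(
    config: SimConfig,
) -> tuple[DosageMatrix, list[MatchedCohort], pd.DataFrame]:
    """Same panel shape with every effect zeroed (global null)."""
    null_cfg = SimConfig(
        labels=list(config.labels),
        strata_per_cohort=list(config.strata_per_cohort),
        n_variants=config.n_variants,
        seed=config.seed,
        maf_range=config.maf_range,
        dosage_noise_sd=config.dosage_noise_sd,
        beta=np.zeros((config.n_variants, config.n_cohorts)),
        ld_blocks=config.ld_blocks,
        position_spacing=config.position_spacing,
    )
    return simulate_cohorts(null_cfg)
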