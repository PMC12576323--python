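# asymclr

Asymmetric integration of matched case–control genotype cohorts with
adaptively weighted conditional logistic regression.

## The problem

Case–control genotype collections for individual diseases — for example,
per-cancer cohorts drawn from a hospital biobank, with each patient matched
1:1 to a control on sex, race, age and ZIP code — are often too small to
detect common risk variants on their own. Related diseases may share
genetic architecture, so auxiliary cohorts could lend power, but naively
pooling them dilutes the signal whenever a cohort is irrelevant or
discordant. `asymclr` treats one cohort as primary (the *local* dataset)
and folds K auxiliary cohorts into its analysis with data-adaptive weights,
so each auxiliary cohort contributes exactly as much as it helps the
primary one.

## The model

For a 1:1 matched stratum with dosage covariates $X_{i1}$ (case) and
$X_{i2}$ (control), the conditional logistic log-likelihood depends only on
$Z_i = X_{i1} - X_{i2}$:

$$\ell(\beta) = \sum_i Z_i\beta - \log(1 + e^{Z_i\beta}).$$

The integrated estimate maximizes
$\ell_0(\beta) + \sum_{k=1}^{K} \omega_k\,\ell_k(\beta)$ with weights
$\omega_k \in [0,1]$. Rather than searching over K free weights, each
auxiliary cohort receives a relevance p-value $q_k$ from a homogeneity
likelihood-ratio test against the local data, and a piecewise-linear map
with knots $0 \le q_A \le q_B \le 1$ sends $q_k \mapsto \omega_k$ (0 below
$q_A$, 1 above $q_B$, linear between). The two knots are chosen to minimize
the local cohort's leave-one-stratum-out cross-validated negative
log-likelihood, with each left-out estimate obtained by a one-step Newton
approximation

$$\hat\beta_0^{-j\star} \approx \hat\beta_0^\star -
A^{-1} Z_j^\top (1-\mu_j)\,/\,(1 - v_{jj}),$$

where $A$ is the weighted information matrix and $v_{jj}$ the stratum's
leverage. Because the weights adapt to the data, raw integrated Wald
p-values are anti-conservative; FDR is therefore estimated by re-running
the entire pipeline after swapping case/control labels within each stratum
with probability 1/2 and comparing exceedance counts
($\widehat{\mathrm{FDR}}_i = \min(m_i^\star/m_i, 1)$, made monotone).
LD clumping and TSS-proximity enrichment summarize the significant
variants.

## Worked example

Simulate a three-cohort panel of 40 common variants in which the first
variant carries a log-odds of 0.5 shared by all cohorts, then integrate the
two auxiliary cohorts into the primary cohort `loc`:

```python
import numpy as np
from asymclr import SimConfig, simulate_cohorts, integrate_all

beta = np.zeros((40, 3)); beta[0, :] = 0.5   # variant 1 shared across cohorts
cfg = SimConfig(labels=["loc", "e1", "e2"], strata_per_cohort=[150, 300, 300],
                n_variants=40, seed=42, beta=beta)
dosages, cohorts, truth = simulate_cohorts(cfg)
results = integrate_all(dosages, cohorts, "loc", prescreen_alpha=0.05)
hit = results.iloc[0]
print(f"signal variant {hit.variant_id}: p_local = {hit.p_local:.2e}, "
      f"p_integrated = {hit.p_int:.2e}, omega = ({hit.omega_e1:.2f}, {hit.omega_e2:.2f})")
print(f"{int((~results.skipped).sum())} of 40 variants passed the prescreen and were integrated")
```

```
signal variant 1:1000000: p_local = 2.44e-04, p_integrated = 7.94e-09, omega = (1.00, 0.00)
4 of 40 variants passed the prescreen and were integrated
```

The shared-effect variant's p-value improves by four orders of magnitude
once the auxiliary strata are folded in; the weights are adaptive per
variant (here one auxiliary cohort is accepted at full weight and the
other excluded by the cross-validated knot choice — with a finite local
sample the LOOCV objective keeps only the borrowing that actually helps).
Raw integrated p-values like the 7.9e-09 above are anti-conservative by
construction and must go through the permutation FDR step before any
significance claim.

The same workflow runs from the shell: `asymclr simulate` writes
`dosages.tsv`/`strata.tsv`/`truth.tsv`, and `asymclr pipeline --config
run.yaml` (paths, local cohort label, thresholds, seed) chains fitting,
integration, one or more label permutations, per-cohort FDR tables at the
0.05 and 0.1 reporting levels, LD clumping and the optional TSS enrichment
summary, echoing per-stage variant counts:

```
variants: 40 read, 40 common (MAF > 0.05); cohorts: e1(300), e2(300), loc(150)
local fits: 40; integrated: 4
variants at FDR <= 0.05: {'integrated': 2, 'non-integrated': 3}
variants at FDR <= 0.1: {'integrated': 2, 'non-integrated': 3}
clumping kept 2 of 2 significant variants
```

Individual stages are also exposed (`asymclr fit`, `integrate`,
`permute-fdr`, `clump`, `tss-enrich`), as is the library surface
(`asymclr.fit_clr`, `asymclr.optimize_map`, `asymclr.estimate_fdr`, ...).

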