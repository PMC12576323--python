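# Methods

## Conditional likelihood for 1:1 matched strata

Each stratum pairs one case with one control, matched on confounders
(sex, race, age, residence in the motivating design). Conditioning on the
stratum containing exactly one case removes the stratum-specific intercept,
and for 1:1 pairs the conditional likelihood reduces to a no-intercept
logistic likelihood in the within-pair covariate difference
`Z_i = X_case − X_control` with all responses equal to 1:

    l(beta) = sum_i w_i [ Z_i beta − log(1 + exp(Z_i beta)) ].

The genotype covariate is the imputed alternative-allele dosage in [0, 2];
matching covariates are never entered (near-exact matching makes them
uninformative and numerically destabilizing). The per-stratum weights `w_i`
are 1 for local strata and `omega_k` for strata of auxiliary cohort k, which
makes the weighted fit an importance-weighted conditional-logistic fit.

Fitting is Newton–Raphson on the gradient `Z'diag(w)(1−mu)` and Hessian
`−Z'diag(w·mu(1−mu))Z`, with log-sum-exp-safe likelihood evaluation.
Numerical choices:

* convergence when the log-likelihood change drops below 1e-10, at most 50
  iterations, with up to 20 step-halvings per iteration — ordinary GLM
  practice;
* a separation guard: |beta| > 15 on the dosage scale (odds ratios beyond
  e^15 are not interpretable here) flags the fit as non-converged instead
  of returning silently huge estimates; standard errors and Wald p-values
  are NaN for such fits and the variant is excluded from FDR input;
* all-zero difference rows raise a degenerate-data error;
* standard errors come from the observed information at the optimum, and
  the Wald test uses the large-sample normal reference (the convention of
  `survival::clogit`, against which this formulation is equivalent).

## Adaptive integration

One cohort is primary; K auxiliary cohorts enter with weights in [0, 1].
Each auxiliary cohort's relevance p-value `q_k` is the upper-tail
chi-squared probability of the homogeneity likelihood-ratio statistic
`2[l_loc(b_loc) + l_ext(b_ext) − l_pooled(b_pooled)]` (df = number of
coefficients, here 1). An auxiliary cohort whose own fit separates is given
q = 0 — i.e. it is excluded — rather than aborting the variant; a single
degenerate cohort should not stop a genome scan.

The knots (qA, qB) of the piecewise-linear q→omega map are chosen to
minimize the negative LOOCV log-likelihood of the local data,
`sum_j −l_j(beta_loo_j)`, where `beta_loo_j` is the one-step Newton
approximation to the weighted estimate refitted without local stratum j.
The one-step form uses the full-data weighted information `A` through
Sherman–Morrison: `beta_loo_j = beta_hat − A^{-1} z_j (1−mu_j)/(1−v_jj)`
with leverage `v_jj = w_j z_j A^{-1} z_j'`. Leverages at or above 1 raise
an error (a single stratum dominating the fit).

Accuracy of the one-step estimate: the error relative to an exact refit
scales with the left-out stratum's influence. At the configuration where
the approximation is actually deployed — a local cohort anchored by
auxiliary strata carrying nonzero weight — the worst-stratum relative error
is of order 0.1% even at 20 local strata. Without any auxiliary anchoring
the error is O(1/n0^2) and can reach several percent below ~50 strata;
an exact-refit mode (`cv_objective(..., exact=True)`) exists for
validation, and the tests bound both regimes.

Optimization over the knots: the constraint 0 ≤ qA ≤ qB ≤ 1 is enforced
smoothly by qa = a, qb = a + (1−a)b with (a, b) in the unit square,
searched by L-BFGS-B with forward-difference gradients (step 1e-4; the
objective is piecewise smooth in the knots) from a 3×3 grid of starts
{0.05, 0.5, 0.95}² plus the corner (1, 1), whose induced weights are all
zero — so the non-integrated model is always among the evaluated
candidates and the selected objective can never be worse than it.
Objective values are cached on the induced weight vector because many knot
pairs are equivalent when K is small; ties break toward the first-found
lowest value.

Pipeline order per variant: MAF > 5% filter (strict inequality), local CLR
fit, Wald prescreen at p < 0.05 (only promising variants pay the
integration cost), relevance tests, knot optimization, weighted fit, and
the integrated Wald p-value.

## Permutation FDR

Because the weights adapt to the data while the Wald p-value treats them
as fixed, integrated p-values are anti-conservative under the null —
among prescreened null variants in simulation, far more than 5% fall below
0.05. Linkage disequilibrium additionally correlates tests. Both issues
preclude Benjamini–Hochberg; FDR is instead estimated by permutation:

* one genome-wide plan per cohort swaps case/control labels within each
  stratum with probability 1/2 (a label swap is exactly a sign flip of
  that stratum's z); a single shared plan preserves LD structure in the
  permuted statistics;
* the full pipeline — prescreen, relevance tests, weight optimization —
  is re-run from scratch on the permuted labels;
* at each observed p-value threshold, FDR = min(m*/m, 1) from the permuted
  and observed exceedance counts (ties counted with ≤ on both sets),
  corrected to be monotone by taking running minima from the largest
  threshold downward.

The single-iteration estimator is noisy and therefore liberal; a
multi-iteration variant averages m* over B independent plans. The FDR
input sets are: integrated method — p_int of all variants that went
through integration; non-integrated method — p_local of all variants whose
local fit converged. FDR is always estimated within one local cohort's
results, never pooled across cohorts.

## Post-processing

LD clumping visits significant variants in ascending p and removes any
variant that is both within 250 kb of and in LD (r² > 0.5) with an already
kept variant — both conditions required, strict inequalities. r² is the
squared Pearson correlation of dosage columns, in-sample by default or
from a supplied reference panel. TSS distances are signed so that upstream
of the gene is negative on either strand; ties in absolute distance break
toward the gene listed first in the annotation. Enrichment of identified
SNPs within ±250 kb of a TSS against randomly sampled reference SNPs uses
the Yates-corrected chi-squared test on the 2×2 within/beyond table; the
continuity correction is the default because it is the variant of the test
that reproduces the reference analysis this workflow follows.

## Synthetic cohorts

The generator emulates the restricted biobank data every stage needs:
around 14 cohorts of 71–1964 matched strata (templates `table1_template`
and `power_template` carry these magnitudes), Binomial(2, f) genotypes
with truncated Gaussian imputation noise (default sd 0.05, clipped to
[0, 2], keeping >99% of dosages within 0.25 of an integer), allele
frequencies uniform on a configurable range spanning the 5% cutoff
(default 0.05–0.5), and a per-variant, per-cohort effect matrix allowing
shared, heterogeneous or null structure. Case labels are assigned within
each stratum from the conditional-likelihood kernel
`P(member 1 is the case) = exp(g1·beta)/(exp(g1·beta)+exp(g2·beta))`, so
the fitted coefficient is consistent for the simulated truth; matching
covariates are not simulated because the conditional likelihood never sees
them. Optional exchangeable-correlation LD blocks (allele copied from a
block template with probability sqrt(rho)) support clumping tests.

What the generator does not emulate: realistic LD block structure along a
chromosome, population stratification and admixture (handled by matching
in the motivating design), imputation-quality variation across variants,
and X/Y chromosomes. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated model, not robustness to those
real-data features.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at desk scale, chosen to keep the full suite
within a few minutes while leaving clear margins: power comparison — local
150 strata, five 400-strata auxiliaries, log-odds 0.3, 50–100 replicates;
null calibration — 2000 variants × 500 strata; anti-conservativeness —
1000 null variants with prescreening (≈40–50 integrated); single- vs
10-iteration FDR — 400 variants (5% carrying shared log-odds 0.6), local
120 strata, three 250-strata auxiliaries, 2–3 replicates. The FDR
comparison is a direction check: with few replicates the two averages have
wide sampling error, but the single-iteration estimator's extra noise
makes it systematically more liberal.

## Known limitations

* The conditional likelihood is specialized to 1:1 pairs; m:n matched sets
  are out of scope, as are Firth or exact-conditional corrections for
  sparse strata.
* Missing dosages are rejected, not imputed.
* The homogeneity LRT is one specific choice of relevance test; it is
  isolated behind `relevance_pvalue` so an alternative can be swapped in.
* The single-iteration FDR estimator is deliberately liberal-but-cheap;
  use `--iterations 10` when compute allows.
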