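# Methods

`stratpca` implements a complete workflow for detecting and controlling
population stratification (PS) in case-control GWAS through genotype
principal components analysis, together with a synthetic-cohort generator
that realises the statistical conditions the workflow is designed for.
This note records the models, the defaults and why they were chosen, and
what the package's tests do and do not demonstrate.

## The stratification problem

Systematic allele-frequency differences between sub-populations become
confounders when sub-population membership is also correlated with
case/control status — every SNP then shows a small spurious association.
The workflow quantifies this with the genomic inflation factor λ, corrects
it by including genotype-PCA scores as regression covariates, and probes
two failure modes of PCA-based correction: components that capture
case-control variation rather than ancestry (checked by fitting loadings on
controls only and projecting everyone), and components that capture one
high-LD genomic region rather than genome-wide ancestry (checked by
detecting loading peaks, thinning each region to a single SNP and
refitting).

## Genotype PCA

Dosages (count of the second allele; missing mean-imputed) are standardized
EIGENSTRAT-style: column `j` is centered at `2p̂_j` and scaled by
`sqrt(2p̂_j(1−p̂_j))`, with `p̂_j` the observed allele frequency; monomorphic
columns are dropped. A center-only mode exists for sensitivity checks.

The decomposition is of the N×N sample kernel `XXᵀ`: scores `S` are its
top-k orthonormal eigenvectors (k = 10 by default, configurable to 100 for
scree-style exploration), eigenvalues `λ₁ ≥ … ≥ λ_k`, and SNP loadings are
defined as

    B = Xᵀ S Λ⁻¹,

the unique choice for which `X·B = S` holds exactly — required so that
projecting the training samples onto their own model reproduces their
stored scores, and so that a control-only model can map cases onto the
control axes coherently. Projection always standardizes new samples with
the *model's* frequencies; a SNP absent or missing in the new data then
contributes exactly zero. Component signs are fixed by making each
component's largest-magnitude loading positive, so output is reproducible
across linear-algebra backends. A dense symmetric solver is used up to
N = 4000 and a matrix-free Lanczos solver beyond; both must satisfy the
brute-force SVD oracle in the test suite. Score/loading normalization is
not observable by any downstream statistic used here (correlations, R²,
regressions are all scale-invariant), which is why only the
projection-consistency property is pinned.

## Outlier removal

A sample is an outlier if any of its first k score coordinates lies more
than 6 SD from that component's mean (mean/SD over all samples in the
model). The default is a single combined pass in which flags from the
full-data model and the control-only model are unioned before removal —
multi-center cohorts routinely flag a handful of individuals this way — and
an iterate-to-convergence mode re-fits the PCA after each round, which
catches secondary outliers masked by a stronger one (the test suite
constructs exactly this situation with a fully ancestry-divergent sample
hiding a half-divergent one).

## Loading-peak (LD region) detection and thinning

Visual bracketing of loading peaks is operationalized as: on each
component, flag SNPs with |loading| > c·(robust SD), where the robust SD is
1.4826·MAD of that component's loadings; take maximal runs of flagged SNPs
per chromosome, merge runs separated by fewer than `gap` map positions, and
keep merged runs containing at least `min_run` flagged SNPs. Defaults
c = 6, min_run = 10, gap = 50 were set so that i.i.d. Gaussian loadings at
P = 10⁴ produce no detections in ≥ 9/10 seeds while injected blocks down to
~10 SNPs are found. Each region records its bracketing SNPs, a 1-based
inclusive bp interval at their positions, every SNP inside the interval,
and the max-|loading| SNP, which is the single SNP retained when the region
is thinned. Region density is reported as (end − start)/1000/n_snps
Kb/SNP. Detect → thin → detect is idempotent at fixed parameters.

## Association scans and λ

Each SNP is tested with a logistic regression of status on allele dosage
(log-additive coding) plus covariates, fitted by Newton–Raphson across all
SNPs simultaneously (the shared intercept+covariate block and the per-SNP
dosage column make the Hessian assembly a batched einsum; a statsmodels fit
of single SNPs is the agreement oracle in the tests, to 1e−6). The 1-df
statistic is a Wald chi-square on the dosage coefficient by default, with a
likelihood-ratio mode against the shared covariate-only null. Constant,
separated and non-converged SNPs are flagged and excluded from λ.

λ is the ratio of the trimmed mean of the observed statistics to the
identically-trimmed mean of the chi-square(1) reference, the latter by
quadrature (cross-checked against a closed form and 10⁷-draw Monte Carlo).
The trim is upper-tail-only at fraction 0.1 by default: trimming exists to
shield λ from genuine associations, which inflate only the upper tail; a
two-sided mode is provided. With 5000 statistics the sampling SD of λ is
roughly 0.02 — bands tighter than that cannot be expected of a single
realization at desk scale.

PC ~ site + disease tables use OLS with treatment contrasts (reference site
configurable; first lexicographically by default). Site association of a
PC, controlling for status, is used throughout as the working proxy for
"this component is ancestry" — localized-LD components and noise components
fail it.

## Ancestry MLE

Given a panel of reference allele frequencies `f_jk` for K populations,
each sample's mixing proportions π maximize the binomial likelihood with
per-SNP success probability `q_j = Σ_k π_k f_jk` (alleles independent, AIMs
in linkage equilibrium). Estimation is EM on allele-level mixture
responsibilities — monotone ascent on a concave likelihood — with
multi-start (uniform plus each near-vertex corner) and the best optimum
kept. Reference frequencies are clipped to [1e−6, 1−1e−6] so fixed 0/1
panel entries cannot produce −∞. The iterate is renormalized onto the
simplex every M-step: the exact update preserves Σπ = 1 only in exact
arithmetic, and the 1/(1−q) factors amplify float rounding into genuine
drift otherwise. Stopping is a log-likelihood gain below 1e−8 or 1000
iterations; near-flat likelihoods (weakly informative panels) may stop at
π values that differ at the 1e−2 level between numerically different paths
while agreeing in likelihood — the proportions are only as identified as
the panel is informative.

## The synthetic cohort

No genotype data are distributed; every test input is generated. The
generator realises, with ground truth:

* **One ancestry cline, two ancestral populations.** Each sample carries a
  proportion a ∈ [0,1] of the "southeastern" population, drawn from a
  site-specific Beta(mean·c, (1−mean)·c). The single-cline choice is the
  minimal model reproducing PC-site associations; secondary structure
  arises from the sites' different mixtures, not from a second geographic
  axis.
* **Balding–Nichols differentiation.** Per SNP, ancestral frequency
  p ~ U(0.05, 0.95) and two population frequencies from
  Beta(p(1−F)/F, (1−p)(1−F)/F); an individual's dosage is Binomial(2, q)
  at the ancestry-weighted mixture q. F = 0 degenerates to no structure.
* **Three localized LD blocks**, each regenerated from one latent variable
  copied by every block SNP with per-allele fidelity φ (block r ≈ φ²):
  a cline-linked block whose latent frequency runs from 0.80 at the
  northern end to 0.05 at the southeastern end (the lactase-persistence
  differential), a local-only block whose latent is independent of
  ancestry, and an inversion-like block whose latent is a Hardy–Weinberg
  genotype of a common "inversion allele" (frequency 0.45). Half of each
  block's SNPs are reported allele-flipped (dosage 2−d) so blocks are not
  detectable from allele frequencies alone. The local-only and
  inversion-like kinds share the copying mechanism and differ in latent
  frequency; haplotype-depth realism (many distinct haplotypes within a
  block, as in real MHC data) is not modeled.
* **Confounded disease.** Status is Bernoulli(logistic(c_site + β_a·a + Σ
  β_j g_j)), with each site's intercept solved numerically to hit that
  site's target case fraction. Two confounding channels exist: within-site
  (β_a = 2 by default) and between-site — per-site case fractions
  (0.35, 0.50, 0.65, 0.50) rise with the sites' ancestry means, emulating
  unequal case/control recruitment across centers, which is the dominant
  source of the headline inflation.
* **An AIMs subset**: the k SNPs with the largest between-population
  frequency differential outside declared blocks (ties to the smaller map
  index), emulating a pre-designed panel; the matching frequency panel for
  the ancestry MLE is built from the generator's true population
  frequencies.
* **Plumbing**: 10 synthetic chromosomes, 1-based positions at fixed 5 kb
  spacing (making region-density arithmetic exactly checkable), 0.1%
  uniform missingness, and full determinism from a single seed via
  per-stage seed sequences.

### Headline configuration and scaling

The default study conditions (`headline_config`) are 4 sites × 500 samples,
P = 5000 SNPs, F_ST = 0.01, site ancestry means (0.10, 0.35, 0.70, 0.40)
with concentration 8. Block widths (20, 20, 15 SNPs at ~0.3–0.4% of the
map) were chosen so that the block eigenvalues fall between the
random-matrix bulk edge (≈13·10³ here) and the cline eigenvalue
(≈35–46·10³): the cline leads the spectrum, the ancestry-independent
blocks own the middle components, and the cline-linked block rides the
leading component as a loading peak — the qualitative ranking the method
is designed to diagnose. This balance is scale-dependent: block strength
grows like (block width)·r̄, ancestry strength like P·F_ST·var(a), so a
faithful miniature must shrink blocks roughly in proportion to P. Under
these conditions the uncorrected λ is ≈1.3–1.5 and ancestry-PC correction
returns it to ≈1 ± 0.03 (the residual spread is trimmed-mean sampling
noise at 5000 SNPs). Tests use further-scaled cohorts (600 × 2000 and
240 × 600) where the same ordering still resolves.

### What passing tests do not show

The generator draws unlinked SNPs (no background LD beyond the injected
blocks), uses a single cline (no two-dimensional geography, no family
structure or cryptic relatedness), equal-size sites, and an AIMs panel with
exactly known reference frequencies. Consequences: background λ behaves
ideally outside the confounding channel; peak detection faces no LD
clutter; and the ancestry MLE sees none of the panel-misspecification error
that dominates real AIMs work. Results on real data will be noisier in all
three respects.

## Numerical choices

* Logistic Newton iterations capped at 30 with gradient tolerance 1e−8,
  step-norm damping at 10, |log-OR| > 15 treated as separation.
* PCA eigenvalues below max(1e−9, 1e−12·λ₁) are discarded as rank
  deficiency; k is truncated with a warning.
* Trimmed means drop exactly ⌊t·n⌋ of the largest order statistics
  (⌊t·n/2⌋ per side in two-sided mode), matching the conditional-mean
  reference computed by quadrature.
* Site-association screening uses α = 1e−4 on the smallest site-term
  p-value per PC.
* Ancestry-MLE ties in the argmax label go to the first label, flagged.

## Problem sizes in the distributed checks

`scripts/acceptance.py` runs, per invocation: the worked region and
outlier arithmetic; 50 small-matrix PCA oracles; λ calibration on 10⁵
(and 10⁷ for the quadrature check) chi-square draws; 10 headline-cohort
rescue replicates; one projection/top-hit cohort; one thinning cohort; and
20 ancestry-recovery replicates at 1000 AIMs — about five minutes on one
CPU. The pipeline defaults mirror the same headline configuration.
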