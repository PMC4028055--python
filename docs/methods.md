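# Methods

This note documents the models behind `expherit`, the numerical and design
choices made where several defensible options existed, what the synthetic
data generator does and does not emulate, and the package's known limits.

## Variance-component model and REML

Expression of one gene is modelled per array as

    y_ij = mu + S_i beta + sum_k alpha_k x_ik + u_i + e_ij

with population indicators `S_i` (first level omitted to keep the design
full rank), optional SNP dosage covariates, polygenic effects
`u ~ N(0, sigma_g^2 K)` and iid residuals `e ~ N(0, sigma_e^2 I)`.  The
observation covariance is `V = sigma_g^2 Z K Z' + sigma_e^2 I`, where `Z`
maps arrays to individuals; replicate arrays of one individual share `u_i`
and are conditionally independent given it.  Narrow-sense heritability is
`sigma_g^2 / (sigma_g^2 + sigma_e^2)`.

**Algorithm.**  The restricted likelihood is profiled over the single
variance ratio `lambda = sigma_g^2 / sigma_e^2`.  With the
eigendecomposition `Z K Z' = U diag(d) U'` — computed once per kinship
matrix and replicate layout, shared across all genes — the rotated model
has diagonal covariance `sigma_e^2 (lambda d + 1)`, so for fixed `lambda`
the GLS fixed effects and `sigma_e^2` are closed-form and one likelihood
evaluation is O(n·p).  The profile is maximised over
`lambda ∈ [0, 1e5]` by an 81-point log grid (plus `lambda = 0`) followed
by bounded scalar refinement (absolute tolerance 1e-10 on log10 lambda,
comfortably below the 1e-8 relative log-likelihood tolerance the package
commits to).  Both components are non-negative by construction, so every
`h2` estimate lies in [0, 1] — no post-hoc truncation of negative variance
estimates is ever needed.  A search-boundary hit and a flat restricted
likelihood (relative variation < 1e-8, e.g. identity kinship with a
single array per individual, where the components are not separable) are
flagged on the result rather than raised.

**ML alongside REML.**  Each fit also reports a *separately maximised* ML
log-likelihood.  AIC comparisons between the additive and interaction SNP
models use ML, not REML: the two models differ in their fixed effects, and
restricted likelihoods computed after projecting out different fixed
designs are not on a common scale.  AIC counts k = (number of fixed
effects) + 2 variance components.

**Kinship must be PSD.**  Method-of-moments pi-hat matrices can have
slightly negative eigenvalues after truncation; `KinshipMatrix.psd_clipped`
clips them at zero before REML (V must stay positive semi-definite).  The
eigen-rotation itself refuses matrices whose most negative eigenvalue
exceeds a 1e-6 relative tolerance, to distinguish estimator jitter from a
genuinely invalid input.

**Model diagnostic.**  After a fit, the correlation (with regression
P-value) between the fixed-effect predictions `X beta_hat` and the
random-plus-residual part `y - X beta_hat` is reported.  When `lambda = 0`
the GLS residual is exactly OLS-orthogonal to the predictions and the
check is vacuous; it has power when `lambda > 0` (the orthogonality then
holds in the V-inverse metric, not the Pearson one) and flags fixed
effects that leak structure into the residual — for instance population
expression shifts omitted from the design while a population-structured
SNP covariate is fitted.

## eQTL heritability (variance-component differencing)

The phenotypic variance explained by the fitted SNP(s) is

    h2_qtl = [ (sg2 + se2)_free - (sg2 + se2)_snp ] / (sg2 + se2)_free

i.e. the drop in the variance-component sum from the SNP-free to the
SNP-inclusive model, relative to the SNP-free total.  Two conventions were
open:

* **Denominator**: the SNP-free total is used (the quantity is "fraction
  of the trait's phenotypic variance"), not the SNP-inclusive total.
* **Flooring/capping**: optimiser noise can make the difference slightly
  negative, and the ratio `pi = h2_qtl / h2` can numerically exceed 1;
  both are clamped to [0, 1] with flags recording when clamping occurred.

The component-wise changes `delta sigma_g^2` and `delta sigma_e^2` are
reported so users can verify the decrease is genetic rather than residual
— on simulated single-QTL genes the mean residual change is two orders of
magnitude below the genetic change.  Adding an *irrelevant* SNP still
produces a small non-negative `h2_qtl` (the difference is floored and one
extra fixed effect always absorbs a little variance); on the validation
fixtures this bias is below 0.02 and it is the reason `h2_qtl` for
null SNPs should not be read as evidence of effect.

Aggregated (multi-eQTL) heritability fits all lead SNPs jointly as fixed
effects and applies the same difference.

## Kinship estimation

Pairwise IBD within one population uses the method of moments on
identity-by-state counts at LD-pruned SNPs.  The expected probabilities
P(IBS | IBD) are computed per SNP from sample allele frequencies with the
small-sample bias correction obtained by treating the pair's 4 (IBD 0) or
3 (IBD 1) alleles as draws *without replacement* from the observed allele
pool (falling-factorial ratios) — the standard correction for
moment-based relatedness estimators.  The three IBD-state proportions are
solved sequentially, truncated to [0, 1], renormalised, and
`pihat = P(IBD=2) + P(IBD=1)/2`.  Pairs sharing fewer than 100 informative
SNPs are flagged unreliable.

**Precision scales as 1/sqrt(m).**  With ~36,000 pruned markers the
pi-hat standard deviation among truly unrelated pairs is ≈0.007–0.015,
so an exclusion threshold of 0.05 isolates genuine relatives.  With only a
few thousand markers the noise grows to 0.02–0.04 and chance exceedances
of 0.05 become common; small simulated panels therefore either need a
large marker count or a raised threshold, and the pipeline leaves the
threshold configurable for exactly this reason.  (The default, 0.05, is
the analysis convention this package implements.)

Per-population tables are merged block-diagonally with cross-population
coefficients fixed at exactly zero — separated populations are assumed
unrelated — and unit diagonal.  Relative exclusion iterates greedily from
the highest pi-hat pair, dropping the member with more missing genotypes
(ties: the id later in sort order) until no pair exceeds the threshold.

MDS for structure inspection is classical (Torgerson) principal
coordinates on the allele-sharing distance `1 - (mean IBS)/2`; coordinate
signs are fixed by making each coordinate's largest-magnitude loading
positive so runs are reproducible.

## Genotype QC

Four filters, applied independently within each population; a SNP
survives only if it passes everywhere (consensus set): autosomes only,
call rate ≥ 0.90, MAF ≥ 0.05 (computed on non-missing alleles), and
Hardy-Weinberg equilibrium P ≥ 0.001 by a 1-df chi-square goodness-of-fit
test (adequate at per-population sample sizes of ~45–90; an exact test is
a documented extension point).  Monomorphic SNPs return HWE P = 1.

LD pruning is greedy within sliding windows of 50 SNPs advancing by 5
(window and step are conventions; only the r² < 0.05 threshold is a study
parameter): while any retained pair in the window has dosage correlation
r² ≥ threshold, the member with the lower call rate is dropped (ties: the
higher-position member).  Passes repeat until no window changes, which
makes pruning idempotent — windows re-pack after removals, so a single
sweep would not be.  r² uses pairwise-complete observations.  Note that
the r² < 0.05 criterion is aggressive at small sample sizes: the null
expectation of r² is 1/n, so with n = 50 individuals chance correlations
prune heavily even among truly independent SNPs.

## Expression preparation

* **Probe filter**: a probe is dropped when its raw intensity is below
  the array background on *all* replicates for strictly more than half of
  the individuals.  Backgrounds are supplied per array; if absent, the 5th
  percentile of that array's intensities is used.  Upstream
  probe-to-transcript mapping screens are consumed as a whitelist file,
  not recomputed.
* **Quantile normalisation across an individual's replicates**: each
  replicate's sorted values are replaced by the mean of sorted values
  across replicates; tied entries receive the mean of the reference
  values at their tied positions (the tie rule had to be fixed by choice).
* **Median normalisation across individuals**: an additive shift
  equalising every individual's median with the global median —
  additive because values are on a log-like scale.
* **Collapsing**: genes with several probes take the unweighted probe
  mean; replicate averaging is the unweighted mean of the (normalised)
  four arrays.

The chain is deterministic and invariant under reordering individuals.

## Association scan and peaks

The scan is ordinary least squares of replicate-averaged expression on
intercept + population indicators + SNP dosage, with a two-sided t-test on
the dosage coefficient (df = n − p); the kinship matrix deliberately does
not enter the scan — population indicators are the structure correction
here, and calibration on structured null data confirms a 5% empirical
type-I rate at alpha 0.05 (versus ~10x inflation without the covariates).
Missing dosages are handled pairwise-complete per SNP; monomorphic SNPs
are skipped; P-values that underflow are floored at the smallest positive
double so they remain in (0, 1].

Bonferroni correction divides alpha by the number of SNPs only — the
number of genes is deliberately not counted, mirroring the analysis
convention; the expected number of chance gene discoveries (alpha per
gene) as a share of actual discoveries quantifies the conservatism.

Significant SNPs of a gene merge into peaks by single-linkage clustering
on position with a 5 Mb *gap* (the alternative total-span reading of "a
region of 5 Mb" was rejected as it makes the result order-dependent);
the lead SNP is the smallest P, ties broken by smaller position.  A peak
is cis when its lead SNP (member SNPs are not consulted — a documented
choice) lies on the gene's chromosome within the gene span ± 500 kb,
inclusive; the strand-resolved "500 kb upstream of transcript start to
500 kb downstream of 3' end" window is symmetric in genomic coordinates,
so both strands use the same interval.  Unannotated genes are labelled
`unknown` and excluded from cis/trans summaries.

## Trio analysis

Heritability in trio families is the least-squares slope of **offspring on
midparent** (mean of the two parents).  The reverse direction
(midparent on offspring) is available as a switch for comparison, but the
offspring-on-midparent direction is the estimator whose expectation is h²
under the additive model and is the default.  Slopes may be negative in
small samples and are reported as-is; at least 3 complete families are
required, and zero midparent variance flags an undefined slope.
Fisher's exact test (two-sided) checks enrichment of non-negative
estimates (slope ≥ 0) among eQTL genes.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions the analysis assumes.

* **Structure**: per SNP an ancestral frequency is uniform on `maf_range`
  (default 0.05–0.5); each population's frequency is Balding-Nichols,
  Beta(p(1−F)/F, (1−p)(1−F)/F), around it; genotypes are Binomial(2, p).
  Divergence F (default 0.1) reproduces clearly separated populations in
  MDS, and the Weir-Cockerham FST of simulated panels matches F.
* **Expression** is simulated directly on the normalised log-like scale
  (intensity units; baseline `mu = 8`, typical of log2 microarray data).
  Per gene: population fixed effects drawn N(0, pop_effect_sd²) with
  default 0.5 (the magnitude is not pinned down by any study quantity; a
  shift of half the phenotypic SD is a realistic cross-population
  expression difference); QTL and epistatic coefficients scaled so their
  empirical variance fractions match the configured ones (the epistatic
  covariate is the dosage product residualised on both dosages, making
  the interaction variance orthogonal to the additive terms); polygenic
  values drawn MVN(0, h² K_true) with K_true the realized
  standardised-genotype GRM within population and zero across — mirroring
  the analysis assumption; iid per-array residuals absorb the remaining
  fraction.  Four replicates per individual by default.
* **Relatives** can be planted (duplicate, parent-offspring) with truth
  recorded; the second member's missingness pattern is preserved.
* **Trios**: parents are unrelated; offspring genotypes follow Mendelian
  transmission.  Offspring *expression* genetic values are set to the
  parental mean without a segregation term, so the expected
  offspring-on-midparent slope equals the configured h² exactly (and the
  h² = 1, noise-free case is an identity).  Replicate noise (default sd
  0.2) is budgeted inside the environmental variance so replicate-averaged
  values keep the configured h²; it is capped at half the environmental
  budget and vanishes as h² → 1.
* **Raw layer**: a separate generator produces raw-scale probe
  intensities with per-array backgrounds, used only to exercise the probe
  filter.

All randomness derives from the single config seed through fixed named
substreams, so outputs are reproducible bit-for-bit.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: linkage disequilibrium beyond planted
duplicate columns (QTL and kinship SNPs are exchangeable, unlike real
genomes where LD both helps tagging and complicates pruning); batch and
hybridisation effects beyond iid array noise; intensity-dependent
(heteroscedastic) microarray noise; genotyping error; admixed or related
founders; non-normal expression distributions.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use simulated studies of
400 individuals (4 populations × 100) with 2,000 SNPs and 4 replicate
arrays — chosen to be comfortably estimable while matching the real
study's scale of ~50–100 individuals per population: 200 genes for
heritability recovery (50 per level at h² ∈ {0, 0.3, 0.6, 0.9}; per-level
mean bias < 0.05), 100 genes for single-SNP variance recovery (planted
20%; MAE ≈ 0.03), ~10⁵ structured-null tests for scan calibration, 100
genes per arm for epistasis AIC selection, 50 random small instances
(n ≤ 60) against a 10,000-point λ-grid for optimiser verification, and
200 trio families at h² = 0.5.  Kinship-estimator fixtures use
20,000–40,000 independent markers, the scale at which pi-hat noise
(≈1/sqrt(m)) makes the 0.05 exclusion threshold meaningful.

## Limitations

* The polygenic model has a single genetic component; cis/trans
  partitioned multi-component models are out of scope.
* The scan is OLS with population indicators, not a mixed-model
  association scan; strong cryptic relatedness within populations would
  require the latter.
* h2_qtl from variance-component differencing is approximate: it is
  floored at zero, slightly positively biased for null SNPs, and its
  accuracy degrades when the SNP is strongly correlated with the kinship
  structure.
* The HWE test is asymptotic chi-square; at very small minor-allele
  counts an exact test would be preferable.
* Trio heritability by midparent regression is vulnerable to shared
  environment, which the generator does not simulate.
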