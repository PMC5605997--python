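# Methods

This note documents the statistical model behind each stage of
`neurogwas`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that
matter for reproducing results.

## Study design being modelled

The pipeline targets a small imaging-genetics cohort: roughly a hundred
subjects with a quantitative, z-scored brain-activity phenotype (caudate
activity during reward is the motivating measure), a binary group
covariate (sated-smoker status, prevalence ≈ 0.4), imputed allelic
dosages genome-wide, and resting-state connectivity values over 12
regions of interest (66 unordered pairs). All defaults below transcribe
that design; every one is overridable.

## Marker QC

A marker is retained when folded MAF ≥ 0.05, call rate ≥ 0.90, exact-HWE
p ≥ 10⁻⁴, and info score > 0.9. The boundary semantics are deliberate:
the exclusion criteria are "less than 5%", "less than 90%", "below the
10⁻⁴ level" and "not greater than 0.9", so values exactly at the first
three thresholds survive while an info score exactly 0.9 does not.

The HWE test is the exact conditional test: given the observed allele
counts, heterozygote counts are enumerated, each table's conditional
probability computed, and the p-value is the total probability of
tables no more probable than the observed one. The exact test rather
than the χ² approximation is the marker-QC community default and is
directly checkable against enumeration (the test suite verifies every
table with up to 30 alleles in exact rational arithmetic). MAF is
computed on unrounded dosages (mean dosage / 2, folded); the HWE count
table uses nearest-integer hard calls, because HWE is defined on
genotype counts — rounding of genuinely fractional dosages is recorded
as a warning in the QC report.

## Association model

Per marker: ordinary least squares of phenotype on dosage, intercept,
group indicator, and the top 3 genotype principal components. Two-sided
p-values come from the t distribution with n − p degrees of freedom.
Estimation is vectorized by Frisch-Waugh-Lovell residualization, which
is algebraically identical to the per-marker full fit (verified against
statsmodels to 10⁻⁹ relative). Missing dosages are mean-imputed per
marker and the reported n is the full aligned sample count, matching
the convention of dosage-based association testing. Zero-variance
(monomorphic) markers are flagged and reported with p = 1 and no
estimate. A frequentist Wald/OLS test is used rather than a score test;
at these sample sizes the difference is negligible.

PCs are computed on mean-imputed, centred dosages scaled by
√(2f(1−f)) — the marker's binomial standard deviation under HWE — via
SVD, with the sign of each component fixed by making its
largest-magnitude loading positive. In the full pipeline PCs are
computed on the QC-passing markers. No LD thinning is applied by
default.

Genomic inflation λ is the median of the χ²₁ statistics implied by the
p-values divided by the null median (the 0.4549 quantile convention).

## Conditional selection

Forward stepwise selection over the candidate pool of markers with
marginal p < 0.05: at each step the candidate with the smallest p-value
conditional on the current joint model (covariates + selected dosages)
enters if that p < 10⁻³; after each entry a backward check drops any
selected marker whose joint-model p has risen above the entry
threshold. The procedure operates on individual-level data (they are
available throughout this pipeline) rather than on summary statistics
with an external LD reference; the intent — avoid reporting many
mutually linked markers as separate signals — is identical. Two
parameters the selection literature leaves open are exposed explicitly:
the collinearity guard (a candidate is skipped when its dosage R²
against the current model exceeds 0.95) and the backward-elimination
toggle (on by default). Ties in conditional p are broken toward the
smaller genomic coordinate, making selection fully deterministic.

## Variant-to-gene mapping

Two routes feed the main analysis and are combined by union before
scoring:

* **intragenic** — conditionally selected variants (marginal p < 0.05
  and conditional p < 0.001) link to every gene whose body contains
  them. Coordinates are 1-based inclusive on both boundaries, matching
  the VCF position convention; BED input is converted on read. A
  variant inside two overlapping genes links to both.
* **eQTL** — any nominally significant variant (marginal p < 0.05)
  links to genes it regulates in the requested tissues. The eQTL route
  deliberately does not require conditional selection; a strict mode
  restricting it to selected variants is available as a flag.

A **proximity** route (windows 5 kb, 20 kb, 50 kb, 100 kb, 500 kb,
1 Mb) supports sensitivity analysis. Distance is base pairs to the
nearest gene-body edge, zero inside the gene, so window 0 reduces
exactly to the intragenic route and link sets grow monotonically with
the window.

Gene score = max over linked variants of −log₁₀ p(marginal), with the
supporting variant recorded. p-values are floored at 10⁻³⁰⁰ upstream;
an exact zero is rejected rather than silently transformed.

## Enrichment (GSEA)

Genes are ranked by descending score (ties broken lexicographically by
id). Walking the list, a hit adds wᵢ/Σw and a miss subtracts
1/(N − n_hit); ES is the signed running-sum value of largest magnitude.
The default weight exponent is 0 (the classic Kolmogorov-Smirnov form,
|ES| ≤ 1, rank-only), since the original description of the running-sum
statistic names no weighting; exponent 1 is available by flag.

The null permutes gene labels over the fixed rank positions — "pathway
label permutation" and "rank-order permutation" are the same
exchangeable null and are implemented once. Defaults: 10,000
permutations, all sets sharing each permutation's relabeling.

* **p** — upper-tail with add-one correction:
  p = (1 + #{ES_null ≥ ES_obs}) / (1 + n_perm), for every set. Only
  top-of-list enrichment is of interest, so a negative observed ES
  lands deep in the upper tail and gets p near 1 rather than a
  lower-tail p; this keeps the rejection rate of null sets at the
  nominal level instead of doubling it.
* **NES** — for positive observed ES only: ES divided by the mean of
  that set's positive null ESs. The same mean scales the set's positive
  null ESs into null NESs.
* **FDR** — the fraction of the null NESs pooled across all tested sets
  that reach or exceed a set's observed NES. Pooling after per-set NES
  normalization is what corrects for set size and for the number of
  sets tested; a per-set (non-pooled) FDR is available by flag.
* Sets are restricted to the ranked universe before scoring (dropped
  genes logged); overlaps outside [10, 2000] or equal to the whole list
  are skipped.

The implementation's extreme-value algebra (the running sum can only
attain its extrema adjacent to a hit) is cross-checked in the tests
against a literal trace walk, against exhaustive enumeration of all
hit placements for small N, and against an independent library
implementation of the unweighted statistic.

## Connectivity group statistics

Connectivity values are Fisher z = arctanh(r) of ROI-pair Pearson
correlations. Group contrasts: Welch's t by default (the equal-variance
assumption is not asserted anywhere in the design; a pooled-variance
flag exists), paired t for within-subject state contrasts, Pearson χ²
without continuity correction (Yates by flag) for categorical traits.
An all-zero paired difference is reported as t = 0, p = 1 ("no change")
rather than an error; a constant non-zero difference has no variance to
test against and is rejected.

Multiple testing across the 66 ROI-pair family uses the BY procedure.
The single-number cutoff is α / c(m) with c(m) = Σᵢ₌₁..m 1/i — the only
reading that yields one threshold independent of the observed p-values;
α = 0.05, m = 66 gives 0.010472, matching the printed 0.0104 to the
rounding. The full data-dependent step-up (statsmodels `fdr_by`) is
offered as a companion mode.

## Synthetic data generator

What it emulates: per-marker allele frequencies uniform on a
configurable MAF range; diploid genotypes in exact HWE (two independent
haplotypes per subject); block LD by copy-with-mutation (within a
block, each haplotype allele copies the previous marker's allele with
probability r, else is redrawn from its own frequency), giving
adjacent-marker genotype correlation ≈ r; additive phenotype effects
plus a group shift and Gaussian noise (default group means 0.186 /
−0.317 reproduce the caudate-reward contrast of the motivating design;
group prevalence 0.4); uniform missingness (default 0); info scores
1 − U(0, 0.2) so roughly half fail the 0.9 filter; hard-call dosages by
default with a continuous-dosage option; non-overlapping gene
intervals; eQTL links confined within 1 Mb of the gene body and tagged
with tissues; random gene sets with an optional planted set; and
three-group Normal measures for the connectivity module (defaults from
the caudate-amygdala contrast: means 0.148 / −0.539 / 0.361). Whether a
published table's parenthesized spread is a standard deviation or a
standard error is ambiguous in the motivating design, so the generator
takes explicit scale parameters and imposes no interpretation.

What it does not emulate: realistic allele-frequency spectra or
population structure (PCs are tested on explicitly constructed
two-population data instead), long-range LD decay, imputation
uncertainty beyond the scalar info score, fMRI time series or any
spatial structure, and non-Gaussian phenotype tails. Passing tests
therefore demonstrate correctness of the statistical machinery under
its stated assumptions, not robustness to the artefacts of real imaging
or genotyping data.

Fixed seeds give bit-identical outputs. The pipeline derives per-stage
seeds by hashing the stage name with the master seed, so stages are
individually reproducible.

## Problem sizes and numerics

Test and acceptance runs use desk-scale sizes chosen to make every
statistical check decisive at small cost: cohorts of 300–2000 subjects,
panels of 20–4000 markers, 1000-gene universes, 200–500 gene sets,
2000 permutations for rate-based checks, and 20 replicate seeds for
selection-recovery rates. Tolerances: exact
oracles (hand OLS, HWE enumeration, ES hand walks) at 10⁻¹⁰–10⁻¹²;
sampled-vs-exhaustive permutation agreement within 3 binomial standard
errors; rate checks at their stated bands. Degenerate inputs are
handled explicitly rather than propagating NaN: monomorphic markers,
all-missing markers, empty candidate pools, sets with degenerate
overlap, zero-variance test inputs.

## Known limitations

No mixed-model association or kinship adjustment; no summary-statistic
conditional analysis with external LD panels; no leading-edge subset
reporting or identifier remapping in GSEA; no sample-level QC beyond an
optional filter (the motivating design applies subject-level screens
upstream); Table-style group p-values of the motivating design are not
exactly recomputable because per-comparison sample sizes are only
published as ranges.
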