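# Methods

This note records the statistical models implemented in haploscan, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Data model and conventions

Genotypes are stored as minor-allele dosages in {0, 1, 2} with an
explicit missingness mask (missing is never a dosage value). Major/minor
designation is by frequency in the loaded cohort, ties broken
alphabetically (the lexically smaller allele becomes major); alleles are
stored as given, with no strand flipping, which is safe for single-study
data. SNP positions are 1-based GRCh37 coordinates as in VCF (an
alternate-build position can be carried but is never computed on);
window arithmetic in the differentiation scan uses 0-based half-open
intervals. A phenotype-missing individual is retained in all genotype
analyses and dropped only from phenotype summaries, which is why a
haplotype table carries both an all-chromosome count (the frequency
denominator) and a phenotype-measured chromosome count.

## Exact Hardy–Weinberg test

The test conditions on the observed allele counts and enumerates every
compatible heterozygote count; a configuration's probability is
proportional to n!/(n_AA! n_AB! n_BB!)·2^n_AB, and the two-sided p-value
sums the probabilities of configurations no more probable than the
observed one (the standard exact test, not mid-p, matching the common
PLINK-style default). The enumeration normalises in log space and
asserts that the configuration probabilities sum to one. Expected
heterozygosity is plain 2pq without the 2n/(2n−1) correction; at the
sample sizes involved both forms round identically at two decimals and
the plain form is simpler to state.

## Two-locus LD and EM

From phased chromosomes the four gamete frequencies are counted
directly. From genotypes, the only phase-ambiguous class is the double
heterozygote (coupling AB/ab vs repulsion Ab/aB); EM splits its gametes
by the current estimate and iterates, initialised at linkage
equilibrium (product of marginals), tolerance 1e-8 on the maximum
frequency change, cap 1000 iterations, asserting the log-likelihood
never decreases. EM preserves the single-locus allele frequencies
exactly, which the tests check. Individuals missing either genotype are
dropped pairwise (Haploview behaviour). The reported LD significance
p-value is a chi-square on r²·n_chrom with 1 df and is flagged
approximate. Defaults follow Haploview: LD from genotypes uses the EM
path.

## Multi-locus EM phasing

Haplotype frequencies are maximum-likelihood under random union of
gametes. Each individual's genotype admits 2^(h−1) unordered compatible
haplotype pairs (h heterozygous sites); the E-step weights pair (i, j)
by 2 f_i f_j (f_i² when homozygous), the M-step re-estimates from
expected gamete counts. Initialisation is uniform over all
observed-compatible haplotypes plus 10 seeded Dirichlet restarts, with
the best converged log-likelihood kept — cheap insurance against local
maxima on small panels. Convergence is a log-likelihood gain below 1e-8,
cap 2000 iterations. Frequencies below 1/(4·chromosomes) — less than
half a chromosome — are pruned after convergence as EM noise and the
rest renormalised. Samples with missing panel genotypes are refused
rather than integrated over; the study design this models has complete
panel genotypes, and silent imputation would blur the frequency
denominator. Per-sample posteriors and the maximum-posterior pair are
returned; the best-pair panel feeds the haplotype table, haplotype F_ST
and bifurcation stages. This EM is a reference-free stand-in for
reference-panel phasing tools; for individuals with genuinely ambiguous
phase the best pair can differ from a reference-informed call, which is
why accuracy claims in the tests are about the frequency spectrum
(recovered to < 0.03 absolute error at n = 500), not per-individual
phase.

Haplotype-table SD uses the sample convention (n−1), with singleton
haplotypes reported as SD 0.00 (the convention of the study tables this
format mirrors).

## Association models

Encodings: additive 0/1/2 (equals the minor-allele dosage) and dominant
0/1 with homozygous-major as reference. The covariate-adjusted model is
a Gaussian GLM with identity link — numerically identical to OLS, fitted
through statsmodels, with t-based Wald p-values on the OLS residual df.
Sex is coded 0 = female, 1 = male, and with exactly two cohorts altitude
becomes a higher-cohort indicator; only two levels exist in the design
this emulates, so an indicator loses nothing. Two-sided p-values
throughout.

The count model is NB2 (variance μ + μ²/θ) with log link, regressing
haplotype chromosome counts on per-haplotype mean phenotype — one row
per haplotype, matching a frequency-vs-phenotype regression across the
spectrum. θ is estimated by alternating a statsmodels GLM for the
coefficients at fixed θ with bounded 1-D maximum likelihood for log θ,
iterated until the joint log-likelihood is stable (the MASS `glm.nb`
scheme); the tests cross-check coefficients and θ against `glm.nb`
itself through Rscript. With 12 aggregated rows the exact p-value is
sensitive to the (unstated in the source material) design-matrix choice,
so downstream checks treat the fit qualitatively: positive slope,
clearly significant.

## Differentiation statistics

Per-site F_ST is Hudson's estimator,
numerator (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1),
denominator p1(1−p2) + p2(1−p1), with windows combined as a ratio of
averages (sum of numerators over sum of denominators), never an average
of per-site ratios — low-frequency sites then carry the little weight
they deserve. This frequency-based estimator is the package's desk-scale
choice where SFS-based machinery would need genotype likelihoods; it is
the standard recommendation of the weighted-F_ST literature. Branch
lengths are T = −ln(1 − F_ST) with F_ST capped at 1 − 1e-12 to stay
finite; PBS_a = (T_ab + T_ac − T_bc)/2 and cyclically, negative
estimates passing through untouched. PBS′ divides each branch by one
plus the sum of the three (the PBSn1 normalisation), damping windows
where every branch is long. Windows are anchored at the region start,
0-based half-open, default 5 kb window and step; the final partial
window is kept, and windows with no usable site are emitted flagged
rather than dropped, so tracks tile the region.

Haplotype-level F_ST treats each distinct haplotype as an allele of one
multi-allelic locus and computes Weir–Cockerham θ for haploid samples,
summing variance components over alleles before taking the ratio. The
estimator is unbiased, so identical sample frequencies give a slightly
negative point estimate (−1/(n_c − 1) scale) — tests allow for this.
The permutation null shuffles individuals (both chromosomes together)
between populations; p = (# permuted θ ≥ observed + 1)/(n_perm + 1),
with a default of 100,000 permutations for 1e-5 resolution (tests and
the pipeline default use 2,000).

## Bifurcation trees

Starting from chromosomes carrying the core allele, the tree splits at
successive polymorphic markers moving away from the core; monomorphic
sites are skipped (they cannot bifurcate) and no MAF filter is applied
beyond that. A missing allele terminates a chromosome's path at that
depth. The homozygosity summary at depth d is Σ c(c−1)/(r(r−1)) over
nodes, the fraction of core-chromosome pairs still unbroken; it starts
at 1 and is non-increasing. Output is a serialisable node table;
rendering is intentionally left out.

## Synthetic generator: what it does and does not emulate

The cohort generator draws two gametes per individual i.i.d. from the
declared spectrum, so Hardy–Weinberg and linkage structure follow from
the spectrum itself; defaults are the published 12-haplotype spectrum,
48 + 24/24 and 51 + 25/26 cohort/sex compositions, age 25.1 ± 3.2 years,
and sex-specific Hb baselines 15.4 ± 0.8 / 13.3 ± 1.0 g/dL. Per-
haplotype Hb effects default to zero (a null generator); an
"EGLN1-like" preset adds +0.35 g/dL per TGCG copy to mimic the observed
ordering qualitatively — a synthetic choice, not an estimate. The
drift generator draws per-site ancestral frequencies uniform on
[0.05, 0.95] and population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F),
binomially sampled at the declared haploid sizes.

Deliberately not emulated: genotyping error and missingness patterns,
recombination (the four-SNP haplotypes are drawn as units),
admixture/linkage between the drift table's sites (sites are
independent), and measurement error structure in the phenotype beyond
Gaussian noise. Passing tests therefore demonstrate estimator
correctness under the declared generative model, not robustness to
real-data artefacts.

## Problem sizes used in tests

The suite keeps simulations at the scale the estimators need: spectrum
recovery at n = 500 individuals, F recovery at 500 sites × 50
replicates, null-uniformity checks at tens of replicates with hundreds
of permutations, and the acceptance script's phasing-recovery average at
25 replicates of the n = 99 study size. The full suite runs in well
under a minute on one CPU.

## Known limitations

- EM phasing posterior calibration is not validated against a
  reference-based phaser; only frequency recovery is.
- The chi-square LD p-value and the NB p-value on aggregated rows are
  approximations, flagged as such where reported.
- Haplotype θ is the allele-frequency AMOVA form (no within-haplotype
  distance matrix); numeric agreement with distance-aware AMOVA
  implementations is not promised.
- The pipeline treats the differentiation scan's frequency table as an
  input; estimating frequencies from sequence reads or genotype
  likelihoods is out of scope.
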