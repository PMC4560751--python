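# Methods

This note documents the models and numerical choices behind each stage of
`panelforge`, what the synthetic-data generator does and does not emulate,
and the limitations a user should know before applying the package to real
cohort data.

## Genotype QC cascade

The cascade assumes a cohort genotype matrix (diploid dosages 0/1/2 with
per-cell read depth) plus three side inputs: SNP-array truth genotypes for
the same samples, per-site repeat-class annotations, and the site set of a
second, more sensitive caller.

**Depth calibration (step 2).**  For each sample, variant calls overlapping
array truth are grouped by integer read depth (capped at 150; higher depths
pooled).  Precision in a bin is the fraction of het/hom-alt calls whose
genotype equals the array genotype.  Bins with fewer than `min_bin_sites`
calls are merged with the nearest lower bin before precision is computed;
the retained depth interval is the longest contiguous run of bins with
precision strictly above 0.998 (ties broken toward the run with more
calls), and calls outside it become missing.  A contiguous interval is used
because depth pathologies are one-sided: too shallow (undercalled
heterozygotes) or too deep (collapsed repeats).

`min_bin_sites` defaults to 500.  The choice is driven by counting
statistics: a bin's precision estimate has binomial standard error
sqrt(p(1−p)/n_calls), and with the 0.998 floor the margin available to a
well-behaved bin is roughly 1−2 per mille.  Bins of a few hundred calls
therefore fail stochastically, fragmenting the retained interval; 500
calls make a single genotyping error survivable (499/500 = 0.998 exactly
at the boundary; the rule is strict, so one error in >500 calls passes).
Samples in which no bin passes are dropped from the cohort with a logged
reason — with a sparse truth set this is the honest outcome, not an error.

**Missingness (step 3).**  Sites not genotyped in strictly more than 10% of
samples are dropped, guaranteeing every surviving site has at least
ceil(0.9·n) called samples — which is what makes the 90% projection size
(below) attainable for every site.

**Repeat classes (step 4).**  Precision is pooled over all samples per
repeat class; classes at or below 0.997 are dropped wholesale.  Classes
with no truth overlap are retained with a warning (nothing can be said
about them).

**Caller intersection (step 5).**  Sites absent from the sensitive caller's
superset are dropped — a guard against aligner/caller-specific artifacts.

**Hardy–Weinberg (step 6).**  The exact (Levene–Haldane) test conditions on
the observed allele counts and sums the probabilities of all heterozygote
counts no more probable than the observed one (two-sided by probability
ordering, with a 1e-10 log-space tolerance for ties).  Sites with p < 1e-5
are dropped.  The exact test is used because the chi-square approximation
is unusable in the rare-variant regime that dominates deep panels.
All-missing sites have an undefined p and are retained with a warning.

Boundary semantics throughout are exactly as stated: retain on
precision > 0.998, remove on precision <= 0.997, remove on
missingness > 10%, remove on p < 1e-5.

## SFS projection and FVRV

Because the depth filter masks different cells in different samples, the
callable sample size varies by site.  Each site with minor count *i* among
2n called chromosomes is downsampled to a uniform 2m chromosomes with the
hypergeometric projection; expected (fractional) class masses are summed
over sites into a folded spectrum.  The projection target is
m = floor(0.90 × cohort), which coincides with the minimum callable count
guaranteed by the missingness filter.  Sites with fewer than m called
individuals cannot be downsampled and are excluded (counted on the
result).  Mass projected to j = 0 (monomorphic leakage) is discarded from
the segregating total.

FVRV is the projected mass at MAF ≤ 0.1% over the total projected mass.
The point estimate uses the raw fractional masses; the 95% CI is
Clopper–Pearson on masses rounded half-to-even (exact binomial intervals
need integers; the rounding choice is documented because expected counts
are fractional by construction).  Category contrasts use Fisher's exact
test on the same rounded masses.  MAF bins use inclusive upper bounds:
very-rare ≤ 0.1% < rare ≤ 0.5% < low ≤ 5% < common.

A note on scale: a very-rare class exists only when 2m ≥ 1000
(1/2m ≤ 0.001), so FVRV is meaningful for cohorts of roughly 560 samples
and up; below that every singleton is already "rare".

## Expected SFS under demographic models

The expected unfolded SFS for a sample of 2n chromosomes under a
piecewise-constant history is computed as E[ξ_b] = Σ_j W_{b,j} c_j, where
c_j = ∫ exp(−C(j,2)Λ(t)) dt with Λ the cumulative pair-coalescence
intensity (closed form per constant piece) and the W weights follow the
Polanski–Kingman three-term recursion, which is numerically stable to at
least 2n = 20,000 in double precision.  A recent exponential-growth epoch
is discretized into 50 piecewise-constant steps at the epoch midpoints.
Constant-size histories reduce to ξ_b ∝ 1/b exactly (verified to 1e-8 at
2n = 2,000 in the tests, and against an independent death-process ODE
oracle and coalescent simulation for a 10x expansion).

**Discovery rate.**  φ(f) is the folded expected SFS of a 20,000-chromosome
reference sample under the model; the discovery rate for a minimum MAF is
the φ-weighted mean of 1 − (1−f)^2n − f^2n over classes with f ≥ the floor.
"Discovered" means the minor allele is seen at least once; a ≥ k-copies
variant is available via `min_copies`.  The rate is invariant to φ's
normalization and monotone in both sample size and MAF floor.

**Fitting.**  The default family is an ancestral constant size plus a
single recent exponential expansion.  Spectrum proportions are scale
invariant, so only two shape parameters are identifiable: the expansion
fold g and the growth duration τ on the 2N-ancestral-generation scale.
The fit maximizes the multinomial composite log-likelihood of folded class
proportions by Nelder-Mead from a 12-point multi-start grid in
(log g, log τ).  The two parameters trade off along a likelihood ridge, so
joint estimates of τ are weakly determined; fold recovery with a known
onset is accurate (sub-percent error at 1e5 sites) and is what the
acceptance checks assert.  The family is a generic stand-in: the package
fits whatever spectrum it is given and makes no claim about any particular
population's history.

## Tandem-gene copy number

Per-region mean per-base depths are normalized by half the depth of a
diploid, mappability-selected reference region (Region Z), so normalized
values equal diploid copy numbers (2.0 in any diploid region).  Mean
per-base depth (rather than raw read counts) removes region-length
confounds and is what makes the "equals two in diploid regions"
calibration hold for regions of different lengths.  The AMY1 copy number
is the sum over AMY1A, AMY1B and AMY1C; the diplotype model y = 2n + 2
links it to the Region X copy count because one amylase copy unit carries
AMY1A, Region X and AMY1B, on top of the constant AMY1C pair.  The shipped
region set uses the printed hg19 coordinates; the AMY1A interval as
printed is much wider than the other gene bodies and looks inconsistent
with the locus schematic — the table is followed as printed, and any BED
can be substituted.

Integer copy calls round half-up; with the even-parity constraint (the
copy unit carries two gene copies) the nearest even integer is returned
with exact ties resolved downward (7.0 → 6).  OLS on (n, y) pairs reports
whether (slope, intercept) = (2, 2) lies inside both 95% t-intervals.

SV calls merge when reciprocal overlap ≥ 80% (computed on 1-based
inclusive intervals), transitively, with merged coordinates the half-up
rounded means of member coordinates; the merge is order invariant.
Insertions are "known" when a catalogued insertion breakpoint lies within
10 bp; deletions when a catalogued deletion covers ≥ 50% of the call.

## Validation FDR

Each candidate site carries outcomes from two platforms (mass-spectrometry
genotyping, amplicon sequencing) and optionally Sanger.  Resolution rules:
a no-call on any contributing platform makes the site no-call; agreement
decides; disagreement is arbitrated by Sanger (taken as truth); unresolved
disagreement is a no-call.  The indel protocol's variant — Sanger rescue
of platform no-calls — is available behind a flag.  FDR is
false/(true+false) with no-calls excluded, plus a Clopper–Pearson 95% CI.
The combined known/novel FDR is the mixture
FDR_known·f_known + FDR_novel·(1−f_known), with the convention that
catalogued variants have FDR 0.

Exact binomial CIs here are conservative (coverage above nominal), which
the tests verify empirically (≥ 93% at n = 200).

## The synthetic cohort generator

Defaults are the study conditions: 1,070 samples, mean depth 32.4x
(log-normal 8% between-sample spread, negative-binomial dispersion 8
within), site frequencies drawn from the folded expected SFS of a 10x
recent expansion (ancestral N = 10,000, growth over the last 1,000
generations).  The default site count is 20,000 — a desk-scale slice
chosen so a full cascade run takes seconds; all rates and proportions are
per-site, so results scale.

Genotypes are generated by placing exactly the drawn number of minor
alleles on chromosomes uniformly at random and pairing them — i.e. the
Levene–Haldane conditional law, which is Hardy–Weinberg conditioned on the
allele count.  This makes the sample spectrum reproduce the drawn class
exactly (the generator's spectrum is testable against the analytic
expectation by chi-square) while keeping genotype counts HWE-consistent.

The error model is layered on top: a base per-cell genotype error of
5e-5, multiplied by 20 below depth 8, by 5 above depth 80, and by a
repeat-class factor (4 for Alu/ERVK/TcMar-Mariner; 60 for Low_complexity,
Satellite and Simple_repeat — the classes the repeat filter exists to
catch).  Each error replaces the genotype with a uniformly chosen
different code.  A configurable fraction of sites (0.5%) carries an
excess-heterozygote calling artifact: each cell is forced het with
probability 0.5, the signature of paralog collapse that the HWE filter
targets.  Depth-zero cells are uncallable and come out missing.

Array truth is error-free genotypes at common (MAF ≥ 5%), non-artifact
sites — emulating a genotyping array's ascertainment toward well-behaved
known SNPs.  The per-category selection surrogate is a geometric tilt of
the class weights toward singletons (weight × exp(−σ·f/0.001)), a single
interpretable knob that produces the FVRV ordering across functional
categories without simulating selection dynamics.

What the generator does **not** emulate: linkage disequilibrium (sites are
independent), read-level artifacts, ancestral-allele polarization, indel
calling, X/Y chromosomes, and between-class correlation of annotation
labels.  Passing tests therefore demonstrate the correctness of the
statistics and filters under the declared noise model, not their behavior
on every real-data pathology.

**Desk-scale truth density.**  The real study compared each sample against
~2.4 million array genotypes; a 20,000-site synthetic cohort yields only
~2,000 comparable common sites, so per-sample precision estimates are
quantized in units of 1/n_calls.  Consequences at default scale: the depth
step typically resolves a single merged bin per sample, and roughly 2-4%
of samples fail calibration (a single unlucky extra error) and are
dropped.  At 10,000 sites the effect is stronger (~10% drops).  This is a
faithful consequence of applying the exact printed thresholds to sparse
truth, and is reported rather than patched.

## Known limitations

- Exact-test CIs on fractional projected masses require integer rounding;
  results are reported both ways but the CI inherits the rounding.
- Validation CIs are Clopper–Pearson throughout; other published interval
  choices for the same counts will differ.
- The demographic family is deliberately minimal (3 parameters, one
  identifiable up to scale); bottlenecks and multi-epoch histories can be
  expressed via `DemographicModel` directly but are not fitted.
- `fisher_2x2` and the hypergeometric pmf are delegated to scipy; the
  package's own exact machinery is the HWE test and the projection logic,
  which are verified against enumeration oracles in the test suite.
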