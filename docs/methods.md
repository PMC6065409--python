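# Methods

This note records the models, conventions and numerical choices behind
`hetrobust`, and what the synthetic data does and does not emulate.

## Post-call filtering

Raw caller output is reduced to analyzable somatic SNVs by four rules,
applied in one pass: FILTER = PASS (for the mutect and varscan dialects
only — the somaticsniper dialect does not populate FILTER meaningfully
and is exempt), normal allele frequency exactly 0 with tumor allele
frequency > 0, read depth ≥ 50 in both tumor and normal, and tumor AF ≥
0.1.  The AF floor is applied to the tumor side only: a normal-side
floor would be vacuous given the exact-zero normal requirement.  "Exactly
0" means exact after parsing, not |x| < ε; the readers produce exact
zeros for zero-count and "0.00%" fields.  The filter is a pure function
and idempotent.

Allele-fraction extraction is dialect-specific: a float allele-fraction
FORMAT field (mutect-like, per-alt values summed at multiallelic sites),
a percent string parsed to a fraction (varscan-like, trailing `%`
required), or alt/(ref+alt) read counts (somaticsniper-like).  In all
dialects a multiallelic site contributes the ratio of all alternative
reads to total reads.

## Copy-number conventions

SEG coordinates are treated as 1-based inclusive (the TCGA convention),
so segment length is end − start + 1; these lengths are the weights of
the whole-genome CNV standard deviation

  WG CNV std = sqrt(Σ pᵢ (cᵢ − c̄)²),  pᵢ = lᵢ/Σlⱼ,  c̄ = Σ pᵢ cᵢ,

which equals the population std of the segment-mean value at a uniformly
drawn covered base (verified against per-base expansion in tests).  All
standard deviations in the package are population-style (ddof 0) for
consistency with this weighted form.  Overlapping segments within a
chromosome are rejected at construction — they should not occur in
segmentation output, and no resolution rule would be defensible.  SNV
loci falling in segmentation gaps are dropped from CNV-at-SNV statistics
(no imputation without probe-level data) but retained, under a
copy-neutral assumption, by the |CNV| > 0.2 locus filter.

## MATH and the extra statistics

MATH = 100 · (1.4826 · MAD)/median.  The 1.4826 scaling (exposed as
`MAD_SCALE`) is the normal-consistency constant; it is what folds with
the percentage factor into the 148.26 prefactor of the closed form
below.  The scorer accepts any non-negative vector, so externally
inferred CCFs can be scored identically; CCF inference itself is out of
scope.  The median-zero case is an error, not a zero.

The panel of additional AF-distribution summaries (mean, median,
population std, skewness, excess kurtosis, IQR, 10th/90th percentiles,
Shannon entropy of the 0.025-binned histogram in nats, the sample
bimodality coefficient, the fraction of AFs above 0.4, and the SNV
count) is this package's own choice of a reasonable panel covering
location, scale, shape and modality; no canonical list exists.

## Distribution distances

Histograms use bin width 0.025 over [0, 1], half-open bins with the last
bin closed.  The EMD is computed in the cumulative-difference chain
form, Σᵢ |Σ_{j≤i}(f₁ⱼ − f₂ⱼ)|, with the absolute value *outside* the
inner sum: this is the reading that equals the optimal 1-D transport
cost (the alternative, abs-inside reading fails on crossing-CDF cases —
[0.5, 0, 0.5] vs [0, 1, 0] costs 1.0, not 2.0 — and is rejected by the
LP transport oracle in the tests).  Units are bins.

KDE-based distances evaluate a Gaussian kernel mean with a fixed
*absolute* bandwidth (σ = 0.02 for the absolute-difference integral,
0.05 for the squared-difference statistic) on a 1001-point uniform grid
over [0, 1], trapezoidal integration, no boundary correction.  The
kernel mean is computed directly rather than through a data-scaled
bandwidth interface so that the stated σ is honored exactly and
zero-variance inputs are well defined.  The permutation p-value is the
literal ratio of permuted statistics ≥ the observed one over 100 label
permutations, ties counted as extreme (so p is never 0), deterministic
under the seed.  KS tests use the asymptotic two-sample distribution.
The per-cohort Bonferroni threshold divides α = 0.05 by the number of
per-sample tests in the caller pair.

## Survival analysis

Follow-up is capped at 4 years = 1460 days: any event or censoring
beyond the horizon becomes a censoring at the horizon (boundary
inclusive).  Cohorts are split at the median of the score with ties
assigned to the low group — deterministic, and invariant to monotone
transforms of the score.  Kaplan-Meier estimation and the chi-square
log-rank test are delegated to lifelines.  The survival difference

  (1/T) ∫₀ᵀ [S_high(t) − S_low(t)] dt

is computed exactly by interval decomposition over the union of the two
step functions' drop points (no quadrature).  The *signed* integrand is
used: the quantity lives in [−1, 1] and is negative when the high-score
group fares worse, which is the interpretation the sign carries;
implementing an absolute-value integrand would destroy both the range
and the direction reading.  Benjamini-Hochberg correction runs jointly
over all (cohort, caller) cells of one score type at a time.

## Expression categories

The operator 𝒜 averages the strictly positive elements of each gene
column; a zero denominator discards the gene (NaN) for that category.
The step function u satisfies u(0) = 0, following the piecewise
definition (the accompanying prose about "including the zero coordinate"
is ambiguous; the formula wins and the discrepancy is simply noted).
Categories: amplified-with-SNV 𝒜(r·u(c−c₂)·s), not-amplified-without-SNV
𝒜(r·u(c₁−c)·(1−s)), amplified-without-SNV 𝒜(r·u(c−c₂)·(1−s)), with
c₁ = 0.1 and c₂ = 1.0; the two masks are mutually exclusive per cell.
Paired comparisons report the fraction of genes with a > b excluding
exact ties, and a Wilcoxon signed-rank p-value (exact for < 25 pairs,
normal approximation otherwise).

## The linear evolution model

Parameters: neutral fraction w ∈ [0, 1], detection floor f_min ∈ (0,
0.5) (default 0.1 — the same floor the post-call AF filter imposes), SNV
count n (default 300), read depth N (default 100).  The AF CDF is 0
below f_min, (ν/2)(1/f_min − 1/f) on [f_min, 0.5) with
ν = 2wf_min/(1 − 2f_min), and 1 at 0.5; the clonal atom at one half
carries mass 1 − w.  Sampling inverts the CDF: a uniform u < w maps to
f = 1/(1/f_min − 2u/ν), otherwise the draw is 0.5.

The closed-form MATH is 148.26 × {0 for w ≤ 1/2; 1/(2φ) − 1 on the
transition band (1/2, 1/2 + Δw]; (√(ν²+φ²) − ν)/φ above}, with
φ = νf_min/(ν − f_min) (the distribution median for w > 1/2) and
Δw = (√(1+32f_min²) − 1)/(16f_min).  It is continuous at both branch
boundaries and **not monotone** in w: it rises steeply through the
transition band (peaking near w ≈ 0.59 for f_min = 0.1, at ≈ 92) and
then decreases toward ≈ 45 at w = 1.  Two consequences shape the tests:
MATH cannot distinguish a moderately swept tumor from a fully neutral
one, and monotone-recovery checks of w from MATH are only meaningful on
the rising regime.  The w = 0 edge (ν = 0) is guarded to fall into the
zero branch.

Sequencing noise replaces each f by a Gaussian draw N(f, f(1−f)/N) — the
normal approximation to binomial read sampling — clipped to
[10⁻³, 1 − 10⁻³]; clipping (rather than resampling) keeps the draw
count, and hence determinism under a seed, fixed.  The f_min measurement
cutoff is *not* re-applied after noising by default; a flag-equivalent
(re-filtering the returned vector) is trivially available to the caller,
and both behaviors are exercised in tests.  With exponential growth,
w = 2^t₂/(t₁ + 2^t₂); all histories on a level set of this map produce
bitwise-identical closed-form MATH.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: per-sample
AFs from the evolution model (w ~ U(0.2, 1.0), 100–300 SNVs per sample);
segmented CNV profiles of 80 contiguous segments with Normal(0, σ_c)
log2-ratio means, σ_c ~ U(0.05, 0.6) per sample; optional CNV→AF
coupling (an SNV on a segment with mean c has its AF scaled by 2^(−c),
the single-mutant-copy dilution) which makes AF dispersion rise with CNV
dispersion; three caller views of one master call set differing by
sensitivity (0.95/0.85/0.80 for the mutect-, somaticsniper- and
varscan-like models), extra dropout just below the detection floor,
small AF jitter (sd 0.01–0.015, reproducing the near-unit AF agreement
at shared loci), and Poisson-rate false calls (2–8%); survival
exponential with hazard h₀·exp(β·z) on the standardized true WG CNV std
(h₀ = 5·10⁻⁴/day, β = 1 by default) and uniform censoring over twice
the 4-year horizon; expression RPKM = base·2^CNV·lognormal noise with
sparse amplification spikes, giving the category comparison a planted
direction.  Regeneration under one seed is byte-identical.

What it does **not** emulate: read-level data (no BAMs), germline
variation, mutational signatures, subclonal copy-number mixtures,
purity contamination of AFs, or realistic chromosome lengths.  Passing
tests therefore demonstrate correctness of the statistics and the
pipeline plumbing under the stated generative assumptions — not that
any particular biological effect exists in real cohorts.

## Problem sizes and tolerances

Monte-Carlo checks of the closed form use 10⁵ draws (tolerance 1 MATH
unit, dominated by sampling error of the median/MAD ratio); the
degeneracy check uses a 20×20 integer grid where equal w is exact in
floating point; the EMD oracle covers 200 random histogram pairs at
N ≤ 12 bins (LP solved exactly, agreement to 10⁻⁹); per-base CNV-std
checks keep profiles under ~10 kb; survival power/type-I studies use
n = 200 cohorts over 100 (β = 1) and 500 (β = 0) seeds with a binomial
99% acceptance band around the nominal 5% level.  Pipeline fixtures use
6–12 samples — large enough to exercise every stage, small enough to
keep the whole suite under a minute.

## Known limitations

The somaticsniper read-count representation quantizes AFs to 1/depth,
so round-tripping through that dialect is lossy by design.  The
Bonferroni denominator for the per-cohort comparison fraction is the
number of per-sample tests in the caller pair; other conventions
(pooling pairs) would shift the threshold.  Log-rank uses the
chi-square approximation throughout; exact small-sample survival tests
are out of scope.  The pipeline treats each cohort independently — no
pan-cohort borrowing beyond the joint BH grid.
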