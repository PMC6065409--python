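# hetrobust

How robust are allele-frequency-based measures of intratumor
heterogeneity to the choice of somatic mutation caller — and do they
actually predict survival?  `hetrobust` is a Python library for asking
that question end to end.  It is aimed at cancer-genomics analysts who
work with tumor/normal SNV calls (MuTect-, SomaticSniper- and
VarScan-style VCFs), SNP-array copy-number segmentations (SEG files) and
clinical follow-up tables, and at modelers who want the analytic side of
the story.

## What it computes

**Heterogeneity scoring.**  The central statistic is the MATH score
(Mutant-Allele Tumor Heterogeneity), a width measure of the tumor
allele-frequency (AF) distribution:

    MATH = 100 · (1.4826 · MAD) / median,

where MAD is the median absolute deviation of the post-filter tumor AFs
and 1.4826 is the normal-consistency constant.  Being a ratio, MATH is
invariant to a multiplicative purity rescaling, and the same scorer
accepts cancer-cell-fraction (CCF) vectors.  Alongside it: the AF
standard deviation, the standard deviation of copy-number values at SNV
loci, and the genome-length-weighted whole-genome CNV standard deviation

    WG CNV std = sqrt( Σᵢ pᵢ (cᵢ − c̄)² ),   pᵢ = lᵢ / Σⱼ lⱼ,

over segments with log2(copy/2) means cᵢ and lengths lᵢ.

**Caller robustness.**  Per-sample AF distributions from different
callers are compared with the two-sample KS test, the earth mover's
distance between 0.025-binned histograms (the 1-D chain form,
EMD = Σᵢ |Σ_{j≤i} (f₁ⱼ − f₂ⱼ)|, equal to the optimal transport cost in
bin units), the integrated absolute difference of Gaussian-KDE densities
(σ = 0.02), and a permutation test on the integrated squared KDE
difference (bandwidth 0.05), with Bonferroni-corrected per-cohort
significance fractions.

**Survival.**  Cohorts are median-split on any per-sample score;
Kaplan-Meier curves and the log-rank test (follow-up capped at 4 years)
give a p-value per (cohort, caller) grid cell; Benjamini-Hochberg
correction runs jointly over the grid.  The direction of effect is the
signed, horizon-normalized integral (1/T)∫[S_high − S_low]dt ∈ [−1, 1].

**Expression.**  Per-gene mean RPKM over patient categories defined by
CNV amplification thresholds and SNV status, via the positive-element
column-mean operator, with paired Wilcoxon comparisons.

**Evolution model.**  A linear tumor-evolution model: mutations before
the last selective sweep are clonal at AF 0.5, later ones follow a 1/f
neutral tail; the mixture is set by the neutral fraction w.  The library
provides the AF CDF, inverse-CDF sampling, a Gaussian read-noise model
N(f, f(1−f)/N), and the closed-form MATH score — zero for w ≤ 1/2,
piecewise-analytic above — plus the (t₁, t₂) → w degeneracy surface
showing that MATH cannot identify the evolutionary history.

**Synthetic cohorts.**  A seed-deterministic generator emits per-caller
VCFs, SEG, clinical and expression files with this exact statistical
structure (caller disagreement about calls but not frequencies,
AF spread coupled to CNV dispersion, survival hazard coupled to CNV
dispersion), so every pipeline stage runs at desk scale.

## Worked example

```python
from hetrobust import (EvoModelParams, add_read_noise, math_closed_form,
                       math_score, sample_afs)

for w in (0.3, 0.7, 1.0):
    afs = sample_afs(EvoModelParams(w=w, n_snvs=300, seed=17))
    print(w, round(math_closed_form(w, 0.1), 2), round(math_score(afs), 2))
```

prints

```
0.3 0.0 0.0
0.7 74.13 66.03
1.0 44.89 39.81
```

— in the clonal regime (w = 0.3) MATH is exactly zero; in the neutral
regime the 300-SNV simulation scatters around the closed form (the
spread is sampling error at n = 300, and note the closed form is *not*
monotone in w).  Adding sequencing noise at read depth 100 lifts the
clonal-regime score off zero:

```python
noised = add_read_noise(sample_afs(EvoModelParams(w=0.3, n_snvs=300, seed=17)),
                        read_depth=100, seed=17)
print(round(math_score(noised), 2))   # 16.99
```

The `examples/` directory holds one short script per capability
(caller comparison, scoring, survival, expression, the model, and the
full pipeline); each prints the numbers it computes and what they mean.
A thin CLI mirrors the pipeline: `hetrobust simulate | compare | score |
survive | evo | evo-surface | run` (see `hetrobust --help`).

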