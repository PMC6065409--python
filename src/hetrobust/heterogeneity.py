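"""Per-sample heterogeneity and copy-number-dispersion scores.

MATH (Mutant-Allele Tumor Heterogeneity) is the width of the tumor
allele-frequency distribution: 100 x scaled MAD / median, where the scaled
MAD multiplies the raw median absolute deviation by the normal-consistency
constant 1.4826.  Being a ratio, MATH is invariant to a multiplicative
rescaling of all AFs, hence (to first order) to tumor purity; the same
scorer applies unchanged to cancer-cell-fraction (CCF) vectors.

Copy-number dispersion comes in two flavours: the standard deviation of
segment means looked up at SNV loci ("CNV std"), and the genome-wide,
segment-length-weighted standard deviation of segment means ("WG CNV std")
which is independent of where the SNVs fall.

All standard deviations here are population-style (ddof=0), consistent
with the weighted whole-genome form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_core import AFSample, CNVProfile, cnv_at_locus

__all__ = [
    "HeterogeneityResult",
    "MAD_SCALE",
    "math_score",
    "af_std",
    "cnv_std_at_snvs",
    "wg_cnv_std",
    "filter_snvs_by_cnv",
    "extra_statistics",
    "score_sample",
]

#: Normal-consistency constant converting raw MAD to scaled MAD.
MAD_SCALE = 1.4826


@dataclass
class HeterogeneityResult:
    """Scores for one sample under one caller."""

    sample_id: str
    caller: str
    math: float
    af_std: float | None
    cnv_std: float | None
    wg_cnv_std: float | None
    n_snvs: int
    extras: dict = field(default_factory=dict)


def math_score(afs, mad_scale: float = MAD_SCALE) -> float:
    """MATH = 100 * (mad_scale * median|x - median(x)|) / median(x).

    Accepts any non-negative score vector (AFs or CCFs).  Raises when the
    median is zero (the ratio is undefined).
    """
    afs = np.asarray(afs, dtype=float)
    if afs.size == 0:
        raise ValueError("cannot score an empty vector")
    med = float(np.median(afs))
    if med == 0:
        raise ValueError("median of scores is zero; MATH undefined")
    mad = float(np.median(np.abs(afs - med)))
    return 100.0 * mad_scale * mad / med


def af_std(afs) -> float | None:
    """Population standard deviation of the AF vector; None for n < 2."""
    afs = np.asarray(afs, dtype=float)
    if afs.size < 2:
        return None
    return float(np.std(afs))


def cnv_std_at_snvs(profile: CNVProfile, loci) -> float | None:
    """Population std of segment means looked up at SNV loci.

    Loci not covered by any segment are dropped; None if fewer than two
    loci remain covered.
    """
    vals = [cnv_at_locus(profile, chrom, pos) for chrom, pos in loci]
    vals = [v for v in vals if v is not None]
    if len(vals) < 2:
        return None
    return float(np.std(vals))


def wg_cnv_std(profile: CNVProfile) -> float:
    """Genome-length-weighted population std of segment means.

    sqrt(sum_i p_i (c_i - cbar)^2) with p_i = l_i / sum_j l_j and
    cbar = sum_i p_i c_i: the std of the segment-mean value at a genomic
    base drawn uniformly from the covered genome.
    """
    if not profile.segments:
        raise ValueError("profile has no segments")
    lengths = np.array([s.length for s in profile.segments], dtype=float)
    means = np.array([s.segment_mean for s in profile.segments], dtype=float)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("zero total segment length")
    p = lengths / total
    cbar = float(np.dot(p, means))
    return float(np.sqrt(np.dot(p, (means - cbar) ** 2)))


def filter_snvs_by_cnv(
    sample: AFSample, profile: CNVProfile, threshold: float = 0.2
) -> AFSample:
    """Drop SNVs whose covering segment has |segment mean| > threshold.

    Removes loci where copy-number change, rather than subclonal
    structure, can distort the allele frequency.  Uncovered loci are
    retained under a copy-neutral assumption; their count is recorded in
    the returned sample's ``n_uncovered`` attribute.
    """
    keep_afs, keep_loci = [], []
    n_uncovered = 0
    for af, (chrom, pos) in zip(sample.afs, sample.loci):
        mean = cnv_at_locus(profile, chrom, pos)
        if mean is None:
            n_uncovered += 1
            keep_afs.append(af)
            keep_loci.append((chrom, pos))
        elif abs(mean) <= threshold:
            keep_afs.append(af)
            keep_loci.append((chrom, pos))
    out = AFSample(
        sample_id=sample.sample_id,
        cohort=sample.cohort,
        caller=sample.caller,
        afs=np.asarray(keep_afs, dtype=float),
        loci=keep_loci,
        purity=sample.purity,
    )
    out.n_uncovered = n_uncovered
    return out


def extra_statistics(afs, bin_width: float = 0.025) -> dict:
    """A configurable panel of summary statistics of the AF distribution.

    Beyond MATH, many single-number reductions of the AF distribution are
    conceivable; this default panel covers location, scale, shape and
    modality.  Moment-based entries are None when n < 3 (bimodality needs
    n >= 4).  Entropy is the Shannon entropy (nats) of the histogram with
    the given bin width.
    """
    afs = np.asarray(afs, dtype=float)
    n = afs.size
    out: dict[str, float | None] = {"n_snvs": int(n)}
    if n == 0:
        return out
    out["mean"] = float(np.mean(afs))
    out["median"] = float(np.median(afs))
    out["iqr"] = float(np.percentile(afs, 75) - np.percentile(afs, 25))
    out["q10"] = float(np.percentile(afs, 10))
    out["q90"] = float(np.percentile(afs, 90))
    out["frac_gt_0.4"] = float(np.mean(afs > 0.4))
    nbins = int(np.ceil(1.0 / bin_width))
    counts, _ = np.histogram(afs, bins=np.linspace(0.0, 1.0, nbins + 1))
    out["entropy"] = float(stats.entropy(counts)) if counts.sum() else None
    if n < 3:
        out["std"] = out["skewness"] = out["kurtosis"] = None
        out["bimodality"] = None
        return out
    out["std"] = float(np.std(afs))
    g1 = float(stats.skew(afs))
    g2 = float(stats.kurtosis(afs))  # excess
    out["skewness"] = g1
    out["kurtosis"] = g2
    if n >= 4:
        # sample bimodality coefficient: (g1^2 + 1) / (g2 + 3(n-1)^2/((n-2)(n-3)))
        denom = g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
        out["bimodality"] = (g1**2 + 1.0) / denom if denom != 0 else None
    else:
        out["bimodality"] = None
    return out


def score_sample(
    sample: AFSample,
    profile: CNVProfile | None = None,
    with_extras: bool = False,
) -> HeterogeneityResult:
    """Convenience: compute the full HeterogeneityResult for one sample."""
    return HeterogeneityResult(
        sample_id=sample.sample_id,
        caller=sample.caller,
        math=math_score(sample.afs),
        af_std=af_std(sample.afs),
        cnv_std=(
            cnv_std_at_snvs(profile, sample.loci) if profile is not None else None
        ),
        wg_cnv_std=wg_cnv_std(profile) if profile is not None else None,
        n_snvs=len(sample.afs),
        extras=extra_statistics(sample.afs) if with_extras else {},
    )
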