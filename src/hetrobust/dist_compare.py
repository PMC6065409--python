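"""Pairwise statistical comparison of allele-frequency distributions.

Different somatic callers produce different call sets for the same tumor;
these statistics quantify how different the resulting AF distributions
are.  Four complementary measures are used:

* the two-sample Kolmogorov-Smirnov test;
* the earth mover's distance between 0.025-binned histograms, which on a
  1-D chain of bins reduces to the summed absolute difference of
  cumulative histograms (in units of bins);
* the integrated absolute difference of Gaussian-KDE-smoothed densities
  (sigma = 0.02);
* a permutation test on the integrated squared difference of KDE
  densities (bandwidth = 0.05).

Per-cohort summaries report the fraction of samples whose KS p-value
clears a Bonferroni-corrected threshold, and cohort medians of the
distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_core import VariantCall

__all__ = [
    "AFHistogram",
    "ComparisonConfig",
    "PairwiseResult",
    "histogram_af",
    "emd",
    "ks_compare",
    "kde_abs_diff",
    "l2_permutation_test",
    "compare_af_samples",
    "cohort_pairwise_summary",
    "shared_af_correlation",
]


@dataclass(frozen=True)
class AFHistogram:
    """Normalized AF histogram over [0, 1] with fixed bin width."""

    bin_width: float
    abundances: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "abundances", np.asarray(self.abundances, dtype=float))
        n_expected = int(np.ceil(1.0 / self.bin_width))
        if len(self.abundances) != n_expected:
            raise ValueError(
                f"expected {n_expected} bins for width {self.bin_width}, "
                f"got {len(self.abundances)}"
            )
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")
        if abs(self.abundances.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")

    @property
    def n_bins(self) -> int:
        return len(self.abundances)


@dataclass(frozen=True)
class ComparisonConfig:
    """Knobs of the four distribution comparisons (defaults as used throughout)."""

    bin_width: float = 0.025
    kde_sigma: float = 0.02
    l2_bandwidth: float = 0.05
    n_permutations: int = 100
    alpha: float = 0.05
    seed: int = 0
    grid_points: int = 1001

    def __post_init__(self) -> None:
        if min(self.bin_width, self.kde_sigma, self.l2_bandwidth, self.alpha) <= 0:
            raise ValueError("bin_width, kde_sigma, l2_bandwidth, alpha must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class PairwiseResult:
    """All comparison statistics for one sample under one caller pair."""

    sample_id: str
    caller_pair: tuple
    ks_D: float
    ks_p: float
    emd: float
    kde_abs_diff: float
    l2_stat: float
    l2_p: float
    shared_af_correlation: float | None = None


def histogram_af(afs, bin_width: float = 0.025) -> AFHistogram:
    """Histogram of AFs in [0, 1]; bins half-open [a, b), last closed at 1."""
    afs = np.asarray(afs, dtype=float)
    if afs.size == 0:
        raise ValueError("cannot histogram an empty AF vector")
    if np.any((afs < 0) | (afs > 1)):
        raise ValueError("AFs must lie in [0, 1]")
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    counts, _ = np.histogram(afs, bins=edges)
    return AFHistogram(bin_width=bin_width, abundances=counts / counts.sum())


def emd(h1: AFHistogram, h2: AFHistogram) -> float:
    """Earth mover's distance in bin units: sum_i |sum_{j<=i} (f1j - f2j)|.

    The cumulative-difference (chain) form equals the optimal 1-D
    transport cost between the histograms; symmetric, zero iff equal.
    """
    if h1.bin_width != h2.bin_width or h1.n_bins != h2.n_bins:
        raise ValueError("histograms must share bin width and bin count")
    cum = np.cumsum(h1.abundances - h2.abundances)
    return float(np.abs(cum[:-1]).sum())


def ks_compare(afs1, afs2) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value."""
    afs1, afs2 = np.asarray(afs1, float), np.asarray(afs2, float)
    if len(afs1) < 2 or len(afs2) < 2:
        raise ValueError("KS test needs at least 2 observations per sample")
    res = stats.ks_2samp(afs1, afs2, method="asymp")
    return float(res.statistic), float(res.pvalue)


def _kde_on_grid(afs: np.ndarray, sigma: float, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE with absolute kernel sd ``sigma``, evaluated on ``grid``."""
    # mean of Gaussian kernels; fixed absolute bandwidth by construction
    z = (grid[:, None] - afs[None, :]) / sigma
    return np.exp(-0.5 * z**2).sum(axis=1) / (afs.size * sigma * np.sqrt(2 * np.pi))


def kde_abs_diff(afs1, afs2, sigma: float = 0.02, grid_points: int = 1001) -> float:
    """Integrated absolute difference of the two KDE-smoothed densities.

    Trapezoidal integral of |f1 - f2| over [0, 1]; approaches 2 for fully
    separated distributions well inside the unit interval.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    afs1, afs2 = np.asarray(afs1, float), np.asarray(afs2, float)
    if afs1.size == 0 or afs2.size == 0:
        raise ValueError("inputs must be non-empty")
    grid = np.linspace(0.0, 1.0, grid_points)
    f1 = _kde_on_grid(afs1, sigma, grid)
    f2 = _kde_on_grid(afs2, sigma, grid)
    return float(np.trapezoid(np.abs(f1 - f2), grid))


def _l2_stat(afs1, afs2, bandwidth, grid) -> float:
    f1 = _kde_on_grid(afs1, bandwidth, grid)
    f2 = _kde_on_grid(afs2, bandwidth, grid)
    return float(np.trapezoid((f1 - f2) ** 2, grid))


def l2_permutation_test(
    afs1,
    afs2,
    bandwidth: float = 0.05,
    n_perm: int = 100,
    seed: int | None = None,
    grid_points: int = 1001,
) -> tuple[float, float]:
    """Integrated squared KDE difference with a label-permutation p-value.

    p = (# permuted statistics >= observed) / n_perm; ties count as
    extreme, so p is never 0.  Deterministic for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    afs1, afs2 = np.asarray(afs1, float), np.asarray(afs2, float)
    if afs1.size == 0 or afs2.size == 0:
        raise ValueError("inputs must be non-empty")
    grid = np.linspace(0.0, 1.0, grid_points)
    observed = _l2_stat(afs1, afs2, bandwidth, grid)
    pooled = np.concatenate([afs1, afs2])
    n1 = afs1.size
    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if _l2_stat(perm[:n1], perm[n1:], bandwidth, grid) >= observed:
            n_extreme += 1
    return observed, n_extreme / n_perm


def compare_af_samples(
    afs1, afs2, sample_id: str = "", caller_pair=("a", "b"),
    config: ComparisonConfig = ComparisonConfig(),
) -> PairwiseResult:
    """Run all four comparisons on one pair of AF vectors."""
    D, p = ks_compare(afs1, afs2)
    h1 = histogram_af(afs1, config.bin_width)
    h2 = histogram_af(afs2, config.bin_width)
    l2s, l2p = l2_permutation_test(
        afs1, afs2, config.l2_bandwidth, config.n_permutations, config.seed,
        config.grid_points,
    )
    return PairwiseResult(
        sample_id=sample_id,
        caller_pair=tuple(caller_pair),
        ks_D=D,
        ks_p=p,
        emd=emd(h1, h2),
        kde_abs_diff=kde_abs_diff(afs1, afs2, config.kde_sigma, config.grid_points),
        l2_stat=l2s,
        l2_p=l2p,
    )


def cohort_pairwise_summary(samples_by_caller: dict, config: ComparisonConfig = ComparisonConfig()) -> dict:
    """Cohort-level summary for every caller pair.

    ``samples_by_caller`` maps caller -> {sample_id -> AF vector}.  For
    each pair of callers, samples present in both are compared; the
    Bonferroni threshold is alpha divided by the number of per-sample
    tests in that pair, and the reported fraction is the share of samples
    whose KS p-value falls below it.  Cohort medians of EMD and the KDE
    absolute difference are reported alongside.
    """
    callers = sorted(samples_by_caller)
    out = {}
    for i, ca in enumerate(callers):
        for cb in callers[i + 1:]:
            shared = sorted(set(samples_by_caller[ca]) & set(samples_by_caller[cb]))
            if not shared:
                raise ValueError(f"no shared samples between {ca} and {cb}")
            results = [
                compare_af_samples(
                    samples_by_caller[ca][sid], samples_by_caller[cb][sid],
                    sample_id=sid, caller_pair=(ca, cb), config=config,
                )
                for sid in shared
            ]
            threshold = config.alpha / len(results)
            out[(ca, cb)] = {
                "n_samples": len(results),
                "bonferroni_threshold": threshold,
                "fraction_significant": float(
                    np.mean([r.ks_p < threshold for r in results])
                ),
                "median_emd": float(np.median([r.emd for r in results])),
                "median_kde_abs_diff": float(
                    np.median([r.kde_abs_diff for r in results])
                ),
                "results": results,
            }
    return out


def shared_af_correlation(calls1, calls2) -> float | None:
    """Pearson r of tumor AFs at loci called by both callers.

    Keys are (chrom, pos, alt); None when fewer than 3 loci are shared or
    either AF vector is constant (correlation undefined).
    """
    def _key(c: VariantCall):
        return (c.chrom, c.pos, c.alt)

    m1 = {_key(c): c.tumor_af for c in calls1}
    m2 = {_key(c): c.tumor_af for c in calls2}
    shared = sorted(set(m1) & set(m2))
    if len(shared) < 3:
        return None
    x = np.array([m1[k] for k in shared])
    y = np.array([m2[k] for k in shared])
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)
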