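"""Expression averages by amplification / SNV category.

To ask whether copy-number amplification (rather than point mutation)
drives expression, per-gene mean RPKM values are computed over patient
subsets defined by CNV and SNV status.  The core operator is the
positive-element column mean

    A(x)[g] = sum_p x[p,g] / sum_p u(x[p,g]),   u(x) = 1 if x > 0 else 0,

applied to masked products of the RPKM matrix r, the log2-ratio CNV
matrix c, and the binary SNV matrix s:

* amplified with SNV:        A(r * u(c - c2) * s)
* not amplified, no SNV:     A(r * u(c1 - c) * (1 - s))
* amplified, no SNV:         A(r * u(c - c2) * (1 - s))

with c1 = 0.1 (no-amplification ceiling) and c2 = 1.0 (amplification
floor).  A gene with no qualifying patient in a category (zero
denominator) is discarded (NaN) for that category.  Known tumor
suppressors and oncogenes can be excluded so the comparison reflects
passenger genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "step_u",
    "positive_mean_by_gene",
    "category_means",
    "compare_categories",
    "exclude_gene_lists",
    "read_gene_list",
]


@dataclass
class ExpressionDataset:
    """Patients x genes matrices: RPKM, CNV (log2 ratio), SNV status (0/1)."""

    rpkm: pd.DataFrame
    cnv: pd.DataFrame
    snv: pd.DataFrame
    c1_th: float = 0.1
    c2_th: float = 1.0

    def __post_init__(self) -> None:
        if not (self.rpkm.shape == self.cnv.shape == self.snv.shape):
            raise ValueError("rpkm, cnv and snv matrices must share shape")
        if not self.rpkm.columns.equals(self.cnv.columns) or not self.rpkm.columns.equals(self.snv.columns):
            raise ValueError("matrices must share gene columns")
        if np.any(self.rpkm.to_numpy() < 0):
            raise ValueError("RPKM values must be non-negative")
        snv_vals = self.snv.to_numpy()
        if not np.isin(snv_vals, (0, 1)).all():
            raise ValueError("SNV matrix must be binary")
        if self.c2_th <= self.c1_th:
            raise ValueError("c2_th must exceed c1_th")

    @property
    def genes(self) -> list[str]:
        return list(self.rpkm.columns)


def step_u(x):
    """Unit step: 0 for x <= 0, 1 for x > 0 (elementwise on arrays)."""
    return np.where(np.asarray(x) > 0, 1.0, 0.0)


def positive_mean_by_gene(x: pd.DataFrame | np.ndarray) -> pd.Series | np.ndarray:
    """Column-wise mean of strictly positive elements.

    A column with no positive element has a zero denominator and is
    discarded: its entry is NaN.
    """
    arr = np.asarray(x, dtype=float)
    pos = step_u(arr)
    denom = pos.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(denom > 0, arr.sum(axis=0) / denom, np.nan)
    if isinstance(x, pd.DataFrame):
        return pd.Series(means, index=x.columns)
    return means


def category_means(ds: ExpressionDataset) -> pd.DataFrame:
    """Per-gene mean RPKM in the three (amplification, SNV) categories.

    Columns: ``amp_with_snv``, ``noamp_no_snv``, ``amp_no_snv``; NaN where
    the category has no qualifying patient for that gene.
    """
    r = ds.rpkm.to_numpy(dtype=float)
    c = ds.cnv.to_numpy(dtype=float)
    s = ds.snv.to_numpy(dtype=float)
    amp = step_u(c - ds.c2_th)
    noamp = step_u(ds.c1_th - c)
    out = pd.DataFrame(
        {
            "amp_with_snv": positive_mean_by_gene(r * amp * s),
            "noamp_no_snv": positive_mean_by_gene(r * noamp * (1.0 - s)),
            "amp_no_snv": positive_mean_by_gene(r * amp * (1.0 - s)),
        },
        index=ds.rpkm.columns,
    )
    return out


def compare_categories(means_a: pd.Series, means_b: pd.Series, min_genes: int = 10):
    """Paired comparison of two per-gene mean vectors.

    Returns (fraction of genes with a > b among non-tied pairs, Wilcoxon
    signed-rank p-value) over genes present (non-NaN) in both categories.
    The fraction is NaN when every pair ties; the p-value is 1 when all
    differences are zero.
    """
    joined = pd.concat({"a": means_a, "b": means_b}, axis=1).dropna()
    if len(joined) < min_genes:
        raise ValueError(
            f"need >= {min_genes} genes present in both categories, got {len(joined)}"
        )
    diffs = joined["a"] - joined["b"]
    nonzero = diffs[diffs != 0]
    fraction = float((nonzero > 0).mean()) if len(nonzero) else float("nan")
    if len(nonzero) == 0:
        return fraction, 1.0
    mode = "approx" if len(nonzero) >= 25 else "exact"
    res = stats.wilcoxon(nonzero.to_numpy(), method=mode)
    return fraction, float(res.pvalue)


def read_gene_list(path) -> list[str]:
    """Read a one-symbol-per-line gene list (blank lines ignored)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def exclude_gene_lists(ds: ExpressionDataset, symbols_to_drop) -> ExpressionDataset:
    """Drop gene columns named in ``symbols_to_drop``; unknown symbols ignored."""
    drop = set(symbols_to_drop)
    present = [g for g in ds.genes if g in drop]
    unknown = len(drop) - len(set(present))
    if unknown:
        logger.warning("%d drop-list symbols not in the dataset", unknown)
    keep = [g for g in ds.genes if g not in drop]
    return ExpressionDataset(
        rpkm=ds.rpkm[keep],
        cnv=ds.cnv[keep],
        snv=ds.snv[keep],
        c1_th=ds.c1_th,
        c2_th=ds.c2_th,
    )
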