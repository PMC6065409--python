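"""Study orchestration: compare -> score -> survive -> express -> model.

``run_study`` drives the whole analysis from one RunConfig: it reads (or
is handed) per-sample VCFs in each caller dialect, applies the post-call
filters, compares AF distributions across callers, computes heterogeneity
and copy-number-dispersion scores, runs the median-split survival grid
with Benjamini-Hochberg correction, the expression category comparison
when expression matrices are present, and tabulates the evolution-model
degeneracy surface.  Every stage writes a TSV; a JSON manifest records
the seed, the config and content hashes so a run can be reproduced
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dist_compare import ComparisonConfig, cohort_pairwise_summary
from .evo_model import degeneracy_surface
from .expression import (
    ExpressionDataset,
    category_means,
    compare_categories,
    exclude_gene_lists,
    read_gene_list,
)
from .heterogeneity import score_sample
from .io_core import (
    DIALECTS,
    apply_postprocessing_filters,
    calls_to_af_sample,
    read_clinical,
    read_seg_multi,
    read_vcf_calls,
)
from .survival import bh_correct, logrank_median_split

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_study", "grid_summary", "child_seed"]


@dataclass
class RunConfig:
    """Inputs, thresholds and seed for one full study run."""

    vcf_dir: str
    seg: str
    clinical: str
    out_dir: str
    cohort: str = "COHORT"
    rpkm: str | None = None
    cnv_matrix: str | None = None
    snv_matrix: str | None = None
    drop_gene_lists: list = field(default_factory=list)
    callers: tuple = DIALECTS
    bin_width: float = 0.025
    kde_sigma: float = 0.02
    l2_bandwidth: float = 0.05
    n_permutations: int = 100
    cnv_threshold: float = 0.2
    min_depth: int = 50
    min_af: float = 0.1
    min_purity: float = 0.8
    horizon_days: float = 1460.0
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def child_seed(seed: int, index: int) -> int:
    """Deterministic per-stage child seed (counter scheme, < 2^31)."""
    return (seed * 1000 + index) % (2**31)


def _discover_vcfs(vcf_dir: Path, callers) -> dict:
    """Map caller -> {sample_id -> path} from <sample>.<caller>.vcf files."""
    out: dict[str, dict[str, Path]] = {c: {} for c in callers}
    for path in sorted(vcf_dir.glob("*.vcf")) + sorted(vcf_dir.glob("*.vcf.gz")):
        stem = path.name.removesuffix(".gz").removesuffix(".vcf")
        sid, _, caller = stem.rpartition(".")
        if caller in out and sid:
            out[caller][sid] = path
    return out


def run_study(config: RunConfig) -> dict:
    """Run all stages; returns a dict of the per-stage DataFrames.

    Any stage failure aborts with the stage name attached to the error.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "load"
    try:
        vcfs = _discover_vcfs(Path(config.vcf_dir), config.callers)
        profiles = read_seg_multi(config.seg)
        clinical = read_clinical(config.clinical)
        samples: dict[str, dict[str, object]] = {c: {} for c in config.callers}
        for caller in config.callers:
            for sid, path in sorted(vcfs[caller].items()):
                calls = apply_postprocessing_filters(
                    read_vcf_calls(path, caller), config.min_depth, config.min_af
                )
                if calls:
                    samples[caller][sid] = calls_to_af_sample(
                        calls, sid, cohort=config.cohort
                    )
            logger.info(
                "loaded %d samples with surviving calls for %s",
                len(samples[caller]), caller,
            )

        stage = "compare"
        cc = ComparisonConfig(
            bin_width=config.bin_width,
            kde_sigma=config.kde_sigma,
            l2_bandwidth=config.l2_bandwidth,
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            seed=child_seed(config.seed, 1),
        )
        pair_summary = cohort_pairwise_summary(
            {c: {sid: s.afs for sid, s in by.items()} for c, by in samples.items()},
            cc,
        )
        rows = []
        for (ca, cb), summ in pair_summary.items():
            for r in summ["results"]:
                rows.append(
                    {
                        "sample_id": r.sample_id, "caller_a": ca, "caller_b": cb,
                        "ks_D": r.ks_D, "ks_p": r.ks_p, "emd": r.emd,
                        "kde_abs_diff": r.kde_abs_diff,
                        "l2_stat": r.l2_stat, "l2_p": r.l2_p,
                    }
                )
        results["comparisons"] = pd.DataFrame(rows).sort_values(
            ["caller_a", "caller_b", "sample_id"]
        )
        results["comparison_summary"] = pd.DataFrame(
            [
                {
                    "caller_a": ca, "caller_b": cb,
                    "n_samples": s["n_samples"],
                    "fraction_significant": s["fraction_significant"],
                    "median_emd": s["median_emd"],
                    "median_kde_abs_diff": s["median_kde_abs_diff"],
                }
                for (ca, cb), s in pair_summary.items()
            ]
        )

        stage = "score"
        score_rows = []
        for caller, by_sid in samples.items():
            for sid, sample in sorted(by_sid.items()):
                res = score_sample(sample, profiles.get(sid))
                score_rows.append(
                    {
                        "sample_id": sid, "caller": caller, "math": res.math,
                        "af_std": res.af_std, "cnv_std": res.cnv_std,
                        "wg_cnv_std": res.wg_cnv_std, "n_snvs": res.n_snvs,
                    }
                )
        scores = pd.DataFrame(score_rows).sort_values(["caller", "sample_id"])
        results["scores"] = scores

        stage = "survive"
        split_results = []
        for score_name in ("math", "cnv_std"):
            for caller in config.callers:
                sub = scores[(scores["caller"] == caller) & scores[score_name].notna()]
                score_map = dict(zip(sub["sample_id"], sub[score_name]))
                if len(score_map) < 4:
                    continue
                split_results.append(
                    logrank_median_split(
                        score_map, clinical, config.horizon_days,
                        cohort=config.cohort, caller=caller, score_name=score_name,
                    )
                )
        results["survival_grid"] = grid_summary(split_results, config.alpha)

        stage = "correlate"
        corr_rows = []
        for caller in config.callers:
            sub = scores[scores["caller"] == caller].dropna(subset=["cnv_std"])
            if len(sub) >= 3:
                corr_rows.append(
                    {
                        "caller": caller,
                        "r_cnvstd_math": float(np.corrcoef(sub["cnv_std"], sub["math"])[0, 1]),
                        "r_cnvstd_afstd": float(np.corrcoef(sub["cnv_std"], sub["af_std"])[0, 1]),
                        "n": len(sub),
                    }
                )
        results["correlations"] = pd.DataFrame(corr_rows)

        stage = "express"
        if config.rpkm and config.cnv_matrix and config.snv_matrix:
            ds = ExpressionDataset(
                rpkm=pd.read_csv(config.rpkm, sep="\t", index_col=0),
                cnv=pd.read_csv(config.cnv_matrix, sep="\t", index_col=0),
                snv=pd.read_csv(config.snv_matrix, sep="\t", index_col=0),
            )
            for lst in config.drop_gene_lists:
                ds = exclude_gene_lists(ds, read_gene_list(lst))
            means = category_means(ds)
            frac, p = compare_categories(means["amp_no_snv"], means["noamp_no_snv"])
            results["expression_means"] = means
            results["expression_comparison"] = pd.DataFrame(
                [{"comparison": "amp_no_snv_vs_noamp_no_snv",
                  "fraction_higher": frac, "wilcoxon_p": p}]
            )

        stage = "model"
        t_grid = np.linspace(0.0, 10.0, 21)
        w_grid, math_grid = degeneracy_surface(t_grid, np.linspace(0.0, 6.0, 13))
        surf = pd.DataFrame(
            {
                "t1": np.repeat(t_grid, 13),
                "t2": np.tile(np.linspace(0.0, 6.0, 13), 21),
                "w": w_grid.ravel(),
                "math": math_grid.ravel(),
            }
        )
        results["evo_surface"] = surf

        stage = "write"
        for name, df in results.items():
            df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=name == "expression_means")
        manifest = {
            "package": "hetrobust",
            "version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "outputs": {
                f"{name}.tsv": hashlib.sha256(
                    (out_dir / f"{name}.tsv").read_bytes()
                ).hexdigest()
                for name in results
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        _write_summary(out_dir, results)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"study stage {stage!r} failed: {exc}") from exc
    return results


def grid_summary(split_results, alpha: float = 0.05) -> pd.DataFrame:
    """Cohort x caller significance grid with raw and BH flags.

    BH is applied jointly over all supplied tests of one score type,
    mirroring correction across all cancer types and callers at once.
    """
    if not split_results:
        return pd.DataFrame(
            columns=["cohort", "caller", "score_name", "logrank_p",
                     "survival_difference", "n_high", "n_low",
                     "significant_raw", "significant_bh"]
        )
    df = pd.DataFrame(
        [
            {
                "cohort": r.cohort, "caller": r.caller, "score_name": r.score_name,
                "logrank_p": r.logrank_p,
                "survival_difference": r.survival_difference,
                "n_high": r.n_high, "n_low": r.n_low,
            }
            for r in split_results
        ]
    )
    df["significant_raw"] = df["logrank_p"] < alpha
    df["significant_bh"] = False
    for score_name, idx in df.groupby("score_name").groups.items():
        flags = bh_correct(df.loc[idx, "logrank_p"].to_numpy(), alpha)
        df.loc[idx, "significant_bh"] = flags
    return df


def _write_summary(out_dir: Path, results: dict) -> None:
    lines = ["# Study summary", ""]
    if "comparison_summary" in results:
        lines += ["## Caller-pair AF distribution comparisons", "```",
                  results["comparison_summary"].to_string(index=False), "```", ""]
    if "survival_grid" in results and len(results["survival_grid"]):
        lines += ["## Median-split survival grid", "```",
                  results["survival_grid"].to_string(index=False), "```", ""]
    if "correlations" in results and len(results["correlations"]):
        lines += ["## CNV dispersion vs AF dispersion", "```",
                  results["correlations"].to_string(index=False), "```", ""]
    (out_dir / "summary.md").write_text("\n".join(lines))
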