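"""Synthetic TCGA-like cohort generator.

Produces, entirely from a seed, the fixture set the analysis pipeline
consumes: per-sample VCFs in three caller dialects, a cohort SEG file of
copy-number segments, a clinical survival TSV, expression matrices, and a
truth table of every latent parameter.

The statistical structure mirrors what the analysis assumes of real
tumors:

* per-sample allele frequencies follow the linear-evolution model (a
  clonal peak at 0.5 plus a 1/f neutral tail, neutral fraction ``w``
  drawn per sample), optionally distorted by the local copy number
  (an SNV on a segment with log2 ratio c is scaled by 2^-c), so samples
  with larger CNV dispersion also have wider AF distributions;
* copy-number profiles are contiguous non-overlapping segments whose
  log2-ratio means are Normal(0, sigma_c), with per-sample dispersion
  sigma_c drawn from a range;
* the three callers see the same underlying mutations but disagree about
  calls, not frequencies: each caller retains a call with its sensitivity
  (reduced near the detection floor), jitters the AF slightly, and adds
  spurious calls at its false-call rate;
* survival is exponential with hazard h0 * exp(beta * z), where z is the
  standardized true whole-genome CNV dispersion, and censoring is uniform
  over twice the follow-up horizon.

Regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import evo_model
from .expression import ExpressionDataset
from .heterogeneity import wg_cnv_std
from .io_core import ClinicalRecord, CNVProfile, CNVSegment
from .survival import HORIZON_DAYS

__all__ = [
    "CallerModel",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cnv_profile",
    "generate_cohort",
    "generate_survival_cohort",
]

_CHROMS = [str(i) for i in range(1, 23)]
_CHROM_LEN = 130_000_000
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CallerModel:
    """Caller error model: sensitivity, false-call rate, AF jitter sd."""

    sensitivity: float
    false_rate: float
    jitter_sd: float

    def __post_init__(self) -> None:
        if not 0.0 < self.sensitivity <= 1.0:
            raise ValueError("sensitivity must be in (0, 1]")
        if self.false_rate < 0 or self.jitter_sd < 0:
            raise ValueError("false_rate and jitter_sd must be non-negative")


def _default_callers() -> dict:
    # Ordering mirrors the observed caller concordance structure: the
    # mutect-like caller is most sensitive/specific, the varscan-like
    # caller most divergent.
    return {
        "mutect": CallerModel(sensitivity=0.95, false_rate=0.02, jitter_sd=0.01),
        "somaticsniper": CallerModel(sensitivity=0.85, false_rate=0.05, jitter_sd=0.01),
        "varscan": CallerModel(sensitivity=0.80, false_rate=0.08, jitter_sd=0.015),
    }


@dataclass(frozen=True)
class CohortConfig:
    """All latent knobs of a synthetic cohort; the seed is mandatory."""

    seed: int
    n_samples: int = 40
    cohort: str = "SYNTH"
    snvs_per_sample: tuple = (100, 300)
    w_range: tuple = (0.2, 1.0)
    f_min: float = 0.1
    read_depth: int = 100
    n_cnv_segments: int = 80
    segment_length_range: tuple = (500_000, 5_000_000)
    sigma_c_range: tuple = (0.05, 0.6)
    callers: dict = field(default_factory=_default_callers)
    baseline_hazard: float = 5e-4
    beta_cnv: float = 1.0
    horizon_days: float = HORIZON_DAYS
    n_genes: int = 60
    snv_gene_rate: float = 0.1
    amp_rate: float = 0.05
    rpkm_noise_sd: float = 0.5
    cnv_coupling: bool = True

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 < self.f_min < 0.5:
            raise ValueError("f_min must be in (0, 0.5)")


@dataclass
class SyntheticCohort:
    """In-memory cohort: call sets, profiles, clinical data, expression, truth."""

    config: CohortConfig
    calls: dict  # sample_id -> caller -> list of call dicts
    profiles: dict  # sample_id -> CNVProfile
    clinical: list  # ClinicalRecord
    expression: ExpressionDataset
    truth: pd.DataFrame

    @property
    def sample_ids(self) -> list:
        return list(self.profiles)


def generate_cnv_profile(
    n_segments: int,
    sigma_c: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    segment_length_range: tuple = (500_000, 5_000_000),
    sample_id: str = "S",
) -> CNVProfile:
    """Contiguous non-overlapping segments with Normal(0, sigma_c) means.

    Segments tile chromosomes 1..22 in order; the length-weighted std of
    the means is ~sigma_c (up to sampling error).
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = segment_length_range
    lengths = rng.integers(lo, hi + 1, size=n_segments)
    means = rng.normal(0.0, sigma_c, size=n_segments)
    segments = []
    chrom_idx, pos = 0, 1
    for length, mean in zip(lengths, means):
        if pos + length - 1 > _CHROM_LEN and chrom_idx + 1 < len(_CHROMS):
            chrom_idx += 1
            pos = 1
        segments.append(
            CNVSegment(
                chrom=_CHROMS[chrom_idx],
                start=pos,
                end=pos + int(length) - 1,
                segment_mean=float(mean),
            )
        )
        pos += int(length)
    return CNVProfile(sample_id=sample_id, segments=segments)


def _random_locus(segment: CNVSegment, rng: np.random.Generator) -> tuple:
    pos = int(rng.integers(segment.start, segment.end + 1))
    return segment.chrom, pos


def _sample_master(config: CohortConfig, w: float, n_snvs: int, profile: CNVProfile,
                   rng: np.random.Generator) -> list:
    """True somatic mutations of one tumor: locus, ref/alt, true AF."""
    params = evo_model.EvoModelParams(
        w=w, f_min=config.f_min, n_snvs=n_snvs, read_depth=config.read_depth
    )
    base_afs = evo_model.sample_afs(params, rng=rng)
    segments = profile.segments
    seg_choice = rng.integers(0, len(segments), size=n_snvs)
    records = []
    used = set()
    for af, si in zip(base_afs, seg_choice):
        seg = segments[int(si)]
        locus = _random_locus(seg, rng)
        while locus in used:
            locus = _random_locus(seg, rng)
        used.add(locus)
        if config.cnv_coupling:
            # mutation on one of two reference copies; total copies 2*2^c
            af = af * 2.0 ** (-seg.segment_mean)
        af = float(np.clip(af, 0.01, 0.99))
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        records.append(
            {"chrom": locus[0], "pos": locus[1], "ref": str(ref), "alt": str(alt),
             "af": af, "cnv": seg.segment_mean}
        )
    return records


def _caller_view(master: list, model: CallerModel, config: CohortConfig,
                 profile: CNVProfile, rng: np.random.Generator) -> list:
    """One caller's call set: dropouts, AF jitter, depths, spurious calls."""
    calls = []
    for rec in master:
        # sensitivity shrinks near/below the detection floor
        edge = 1.0 / (1.0 + np.exp(-(rec["af"] - (config.f_min - 0.01)) / 0.008))
        if rng.uniform() > model.sensitivity * edge:
            continue
        af = float(np.clip(rec["af"] + rng.normal(0.0, model.jitter_sd), 0.01, 0.99))
        calls.append(
            {
                **rec,
                "af": af,
                "tumor_dp": int(rng.poisson(config.read_depth)),
                "normal_dp": int(rng.poisson(config.read_depth)),
            }
        )
    n_false = rng.poisson(model.false_rate * len(master))
    existing = {(c["chrom"], c["pos"]) for c in calls}
    segments = profile.segments
    for _ in range(int(n_false)):
        seg = segments[int(rng.integers(0, len(segments)))]
        locus = _random_locus(seg, rng)
        while locus in existing:
            locus = _random_locus(seg, rng)
        existing.add(locus)
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        calls.append(
            {
                "chrom": locus[0], "pos": locus[1], "ref": str(ref), "alt": str(alt),
                "af": float(rng.uniform(config.f_min, 0.35)),
                "cnv": seg.segment_mean,
                "tumor_dp": int(rng.poisson(config.read_depth)),
                "normal_dp": int(rng.poisson(config.read_depth)),
            }
        )
    calls.sort(key=lambda c: (_CHROMS.index(c["chrom"]), c["pos"]))
    return calls


def generate_survival_cohort(
    n_samples: int,
    beta: float,
    seed: int,
    baseline_hazard: float = 5e-4,
    horizon_days: float = HORIZON_DAYS,
    sigma_c_range: tuple = (0.05, 0.6),
) -> tuple[dict, list]:
    """Lightweight score/survival pairs for power and type-I studies.

    Returns ({sample_id -> CNV-dispersion score}, [ClinicalRecord]).  The
    hazard of sample i is h0 * exp(beta * z_i) with z the standardized
    score; censoring is uniform over [0, 2 * horizon].
    """
    rng = np.random.default_rng(seed)
    scores = rng.uniform(*sigma_c_range, size=n_samples)
    z = (scores - scores.mean()) / scores.std()
    hazards = baseline_hazard * np.exp(beta * z)
    t_event = rng.exponential(1.0 / hazards)
    t_censor = rng.uniform(0.0, 2.0 * horizon_days, size=n_samples)
    ids = [f"S{i:04d}" for i in range(n_samples)]
    records = [
        ClinicalRecord(
            sample_id=sid,
            time_days=float(min(te, tc)),
            event=bool(te <= tc),
        )
        for sid, te, tc in zip(ids, t_event, t_censor)
    ]
    return dict(zip(ids, scores.tolist())), records


def generate_cohort(config: CohortConfig, outdir=None) -> SyntheticCohort:
    """Generate a full cohort; optionally write all fixture files to outdir.

    Files written: ``<sample>.<caller>.vcf`` per sample and caller,
    ``cohort.seg``, ``clinical.tsv``, ``rpkm.tsv``/``cnv.tsv``/``snv.tsv``,
    and ``truth.tsv`` recording every latent parameter.
    """
    rng = np.random.default_rng(config.seed)
    ids = [f"{config.cohort}-{i:04d}" for i in range(config.n_samples)]

    profiles, calls, truth_rows = {}, {}, []
    for sid in ids:
        sigma_c = float(rng.uniform(*config.sigma_c_range))
        w = float(rng.uniform(*config.w_range))
        n_snvs = int(rng.integers(*config.snvs_per_sample))
        profile = generate_cnv_profile(
            config.n_cnv_segments, sigma_c, rng=rng,
            segment_length_range=config.segment_length_range, sample_id=sid,
        )
        master = _sample_master(config, w, n_snvs, profile, rng)
        calls[sid] = {
            caller: _caller_view(master, model, config, profile, rng)
            for caller, model in sorted(config.callers.items())
        }
        profiles[sid] = profile
        truth_rows.append(
            {
                "sample_id": sid,
                "w": w,
                "sigma_c": sigma_c,
                "wg_cnv_std": wg_cnv_std(profile),
                "n_snvs_master": n_snvs,
            }
        )
    truth = pd.DataFrame(truth_rows)

    # survival coupled to the true whole-genome CNV dispersion
    z = (truth["wg_cnv_std"] - truth["wg_cnv_std"].mean()) / truth["wg_cnv_std"].std()
    hazards = config.baseline_hazard * np.exp(config.beta_cnv * z.to_numpy())
    t_event = rng.exponential(1.0 / hazards)
    t_censor = rng.uniform(0.0, 2.0 * config.horizon_days, size=config.n_samples)
    times = np.minimum(t_event, t_censor)
    events = t_event <= t_censor
    clinical = [
        ClinicalRecord(sample_id=sid, time_days=float(t), event=bool(e))
        for sid, t, e in zip(ids, times, events)
    ]
    truth["hazard"] = hazards
    truth["time_days"] = times
    truth["event"] = events
    truth["group"] = np.where(
        truth["wg_cnv_std"] > truth["wg_cnv_std"].median(), "high", "low"
    )

    expression = _generate_expression(config, ids, truth["sigma_c"].to_numpy(), rng)

    cohort = SyntheticCohort(
        config=config, calls=calls, profiles=profiles, clinical=clinical,
        expression=expression, truth=truth,
    )
    if outdir is not None:
        _write_cohort(cohort, Path(outdir))
    return cohort


def _generate_expression(config, ids, sigma_c, rng) -> ExpressionDataset:
    genes = [f"GENE{g:03d}" for g in range(config.n_genes)]
    base = rng.lognormal(mean=2.0, sigma=1.0, size=config.n_genes)
    c = rng.normal(0.0, sigma_c[:, None], size=(len(ids), config.n_genes))
    amp = rng.uniform(size=c.shape) < config.amp_rate
    c = c + amp * rng.uniform(1.0, 1.6, size=c.shape)
    s = (rng.uniform(size=c.shape) < config.snv_gene_rate).astype(int)
    noise = rng.lognormal(0.0, config.rpkm_noise_sd, size=c.shape)
    r = base[None, :] * (2.0**c) * noise
    return ExpressionDataset(
        rpkm=pd.DataFrame(r, index=ids, columns=genes),
        cnv=pd.DataFrame(c, index=ids, columns=genes),
        snv=pd.DataFrame(s, index=ids, columns=genes),
    )


# ---------------------------------------------------------------------------
# File emission

_VCF_HEADERS = {
    "mutect": (
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        '##FORMAT=<ID=FA,Number=A,Type=Float,Description="Allele fraction">\n'
    ),
    "varscan": (
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        '##FORMAT=<ID=FREQ,Number=1,Type=String,Description="Variant allele frequency">\n'
    ),
    "somaticsniper": (
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
        '##FORMAT=<ID=DP4,Number=4,Type=Integer,Description="Ref-fwd, ref-rev, alt-fwd, alt-rev read counts">\n'
    ),
}


def _format_sample(caller: str, af: float, depth: int, somatic: bool) -> str:
    gt = "0/1" if (somatic and af > 0) else "0/0"
    if caller == "mutect":
        return f"{gt}:{depth}:{af:.6f}"
    if caller == "varscan":
        return f"{gt}:{depth}:{af * 100.0:.2f}%"
    alt_reads = int(round(af * depth))
    ref_reads = depth - alt_reads
    return f"{gt}:{depth}:{ref_reads - ref_reads // 2},{ref_reads // 2},{alt_reads - alt_reads // 2},{alt_reads // 2}"


def _write_vcf(path: Path, caller: str, calls: list) -> None:
    fields = {"mutect": "GT:DP:FA", "varscan": "GT:DP:FREQ", "somaticsniper": "GT:DP:DP4"}
    filt = "." if caller == "somaticsniper" else "PASS"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=hetrobust-synth-{caller}\n")
        for chrom in _CHROMS:
            fh.write(f"##contig=<ID={chrom},length={_CHROM_LEN}>\n")
        fh.write(_VCF_HEADERS[caller])
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR\n")
        for c in calls:
            tumor = _format_sample(caller, c["af"], c["tumor_dp"], somatic=True)
            normal = _format_sample(caller, 0.0, c["normal_dp"], somatic=False)
            fh.write(
                f"{c['chrom']}\t{c['pos']}\t.\t{c['ref']}\t{c['alt']}\t.\t{filt}\t.\t"
                f"{fields[caller]}\t{normal}\t{tumor}\n"
            )


def _write_cohort(cohort: SyntheticCohort, outdir: Path) -> None:
    from .io_core import write_seg  # local import to avoid cycle at module load

    outdir.mkdir(parents=True, exist_ok=True)
    for sid, by_caller in cohort.calls.items():
        for caller, calls in by_caller.items():
            _write_vcf(outdir / f"{sid}.{caller}.vcf", caller, calls)
    write_seg(list(cohort.profiles.values()), outdir / "cohort.seg")
    clin = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in cohort.clinical],
            "days_to_death": [
                f"{r.time_days:.2f}" if r.event else "" for r in cohort.clinical
            ],
            "days_to_last_follow_up": [
                "" if r.event else f"{r.time_days:.2f}" for r in cohort.clinical
            ],
            "vital_status": ["Dead" if r.event else "Alive" for r in cohort.clinical],
        }
    )
    clin.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    cohort.expression.rpkm.to_csv(outdir / "rpkm.tsv", sep="\t", float_format="%.6f")
    cohort.expression.cnv.to_csv(outdir / "cnv.tsv", sep="\t", float_format="%.6f")
    cohort.expression.snv.to_csv(outdir / "snv.tsv", sep="\t")
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.10g")
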