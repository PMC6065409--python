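"""Domain types, format readers and post-call filtering.

Somatic SNV calls arrive as VCFs in three caller dialects that encode the
tumor allele fraction differently:

* ``mutect`` — a float allele-fraction FORMAT field (``FA``), one value
  per alternative allele;
* ``varscan`` — a percentage string FORMAT field (``FREQ``, e.g.
  ``"25.00%"``);
* ``somaticsniper`` — no fraction field; the fraction is reconstructed
  from reference/alternative read counts (``DP4``).

Multiallelic sites are treated like biallelic ones: the allele fraction is
the ratio of all alternative-allele reads to the total.

Post-call filtering keeps SNVs that (for MuTect and VarScan) have
FILTER = PASS, have zero normal allele frequency and non-zero tumor allele
frequency, have at least ``min_depth`` reads in both tumor and normal, and
have tumor allele frequency at least ``min_af`` (the detection floor
``f_min`` of the downstream model).

Copy-number segments come as TCGA SEG-style TSV with a ``Segment_Mean``
column holding log2(copy number / 2); coordinates are 1-based inclusive,
so a segment's genomic length is end - start + 1.
"""

from __future__ import annotations

import bisect
import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "VariantCall",
    "AFSample",
    "CNVSegment",
    "CNVProfile",
    "ClinicalRecord",
    "DIALECTS",
    "read_vcf_calls",
    "apply_postprocessing_filters",
    "calls_to_af_sample",
    "read_seg",
    "read_seg_multi",
    "write_seg",
    "cnv_at_locus",
    "read_clinical",
    "filter_by_purity",
]

DIALECTS = ("mutect", "somaticsniper", "varscan")


@dataclass(frozen=True)
class VariantCall:
    """One somatic SNV with tumor/normal allele frequencies and depths."""

    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_af: float
    normal_af: float
    tumor_depth: int
    normal_depth: int
    filter_status: str
    caller: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_af <= 1.0:
            raise ValueError(f"tumor_af out of [0,1]: {self.tumor_af}")
        if not 0.0 <= self.normal_af <= 1.0:
            raise ValueError(f"normal_af out of [0,1]: {self.normal_af}")
        if self.tumor_depth < 0 or self.normal_depth < 0:
            raise ValueError("depths must be non-negative")
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based)")


@dataclass
class AFSample:
    """Per-sample post-filter tumor allele-frequency vector with loci."""

    sample_id: str
    cohort: str
    caller: str
    afs: np.ndarray
    loci: list
    purity: float | None = None

    def __post_init__(self) -> None:
        self.afs = np.asarray(self.afs, dtype=float)
        if len(self.afs) != len(self.loci):
            raise ValueError("afs and loci must have the same length")


@dataclass(frozen=True)
class CNVSegment:
    """A genomic segment with a log2(copy/2) segment mean; 1-based inclusive."""

    chrom: str
    start: int
    end: int
    segment_mean: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"segment end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CNVProfile:
    """Per-sample segmented copy-number profile (non-overlapping per chrom)."""

    sample_id: str
    segments: list

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[CNVSegment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping segments on {chrom}: "
                        f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                    )
        # sorted per-chrom index for locus lookup
        self._index = {
            chrom: sorted(segs, key=lambda s: s.start)
            for chrom, segs in by_chrom.items()
        }
        self._starts = {
            chrom: [s.start for s in segs] for chrom, segs in self._index.items()
        }


@dataclass
class ClinicalRecord:
    """Survival time (days) and death-event flag for one sample."""

    sample_id: str
    time_days: float
    event: bool
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_days < 0:
            raise ValueError("time_days must be non-negative")


# ---------------------------------------------------------------------------
# VCF reading


def _pick_samples(vcf: pysam.VariantFile, caller: str) -> tuple[str, str]:
    """Return (tumor, normal) sample names.

    Prefers names containing TUMOR/NORMAL (the VarScan/SomaticSniper
    convention, also used by our synthetic VCFs); otherwise falls back to
    column order: MuTect writes tumor first, the others normal first.
    """
    names = list(vcf.header.samples)
    if len(names) < 2:
        raise ValueError("VCF must contain tumor and normal sample columns")
    upper = [n.upper() for n in names]
    tumor = normal = None
    for n, u in zip(names, upper):
        if "TUMOR" in u or "PRIMARY" in u:
            tumor = n
        elif "NORMAL" in u or "BLOOD" in u:
            normal = n
    if tumor is not None and normal is not None:
        return tumor, normal
    if caller == "mutect":
        return names[0], names[1]
    return names[1], names[0]


def _sum_alts(value) -> float:
    """Sum a per-alt FORMAT tuple (Number=A) or pass through a scalar."""
    if isinstance(value, (tuple, list)):
        return float(sum(v for v in value if v is not None))
    return float(value)


def _af_from_format(sample_rec, caller: str):
    """Extract (af, depth) from one sample's FORMAT data per dialect."""
    if caller == "mutect":
        fa = sample_rec.get("FA")
        if fa is None:
            raise KeyError("FA")
        return _sum_alts(fa), int(sample_rec["DP"])
    if caller == "varscan":
        freq = sample_rec.get("FREQ")
        if freq is None:
            raise KeyError("FREQ")
        if isinstance(freq, (tuple, list)):
            freq = freq[0]
        if isinstance(freq, bytes):
            freq = freq.decode()
        freq = str(freq).strip()
        if not freq.endswith("%"):
            raise ValueError(f"VarScan FREQ must end with '%': {freq!r}")
        return float(freq[:-1]) / 100.0, int(sample_rec["DP"])
    if caller == "somaticsniper":
        dp4 = sample_rec.get("DP4")
        if dp4 is None:
            raise KeyError("DP4")
        ref_reads = dp4[0] + dp4[1]
        alt_reads = dp4[2] + dp4[3]
        total = ref_reads + alt_reads
        af = alt_reads / total if total > 0 else 0.0
        return af, int(sample_rec["DP"])
    raise ValueError(f"unknown caller dialect: {caller!r}")


def read_vcf_calls(path, caller: str) -> list[VariantCall]:
    """Parse a tumor/normal VCF into VariantCall records for one dialect.

    Raises ValueError for an unknown dialect, and a per-record ValueError
    (with the record index) when the FORMAT field the dialect requires is
    missing or malformed.
    """
    if caller not in DIALECTS:
        raise ValueError(f"unknown caller dialect: {caller!r}")
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        tumor, normal = _pick_samples(vcf, caller)
        for idx, rec in enumerate(vcf):
            try:
                t_af, t_dp = _af_from_format(rec.samples[tumor], caller)
                n_af, n_dp = _af_from_format(rec.samples[normal], caller)
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(
                    f"record {idx} at {rec.chrom}:{rec.pos}: "
                    f"cannot extract {caller} FORMAT fields ({exc})"
                ) from exc
            filt = ";".join(rec.filter.keys()) if len(rec.filter) else "."
            calls.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=",".join(rec.alts) if rec.alts else ".",
                    tumor_af=min(max(t_af, 0.0), 1.0),
                    normal_af=min(max(n_af, 0.0), 1.0),
                    tumor_depth=t_dp,
                    normal_depth=n_dp,
                    filter_status=filt,
                    caller=caller,
                )
            )
    return calls


def apply_postprocessing_filters(
    calls: list[VariantCall], min_depth: int = 50, min_af: float = 0.1
) -> list[VariantCall]:
    """Post-call somatic filter.

    Keeps records with (a) FILTER = PASS for the mutect and varscan
    dialects (SomaticSniper does not populate FILTER meaningfully), (b)
    normal AF exactly 0 and tumor AF > 0, (c) both depths >= min_depth,
    (d) tumor AF >= min_af.  Pure function; idempotent.
    """
    out = []
    for c in calls:
        if c.caller in ("mutect", "varscan") and c.filter_status != "PASS":
            continue
        if c.normal_af != 0.0 or c.tumor_af <= 0.0:
            continue
        if c.tumor_depth < min_depth or c.normal_depth < min_depth:
            continue
        if c.tumor_af < min_af:
            continue
        out.append(c)
    return out


def calls_to_af_sample(
    calls: list[VariantCall],
    sample_id: str,
    cohort: str = "",
    purity: float | None = None,
) -> AFSample:
    """Assemble filtered calls into the per-sample AF vector."""
    caller = calls[0].caller if calls else ""
    return AFSample(
        sample_id=sample_id,
        cohort=cohort,
        caller=caller,
        afs=np.array([c.tumor_af for c in calls], dtype=float),
        loci=[(c.chrom, c.pos) for c in calls],
        purity=purity,
    )


# ---------------------------------------------------------------------------
# SEG reading / writing

_SEG_COLS = {
    "sample": ("sample", "id", "sample_id"),
    "chrom": ("chromosome", "chrom", "chr"),
    "start": ("start", "loc.start"),
    "end": ("end", "loc.end"),
    "segment_mean": ("segment_mean", "segment mean", "seg.mean"),
}


def _seg_columns(df: pd.DataFrame) -> dict[str, str]:
    lower = {c.lower(): c for c in df.columns}
    found = {}
    for key, aliases in _SEG_COLS.items():
        for alias in aliases:
            if alias in lower:
                found[key] = lower[alias]
                break
        else:
            raise ValueError(f"SEG file is missing a column for {key!r}")
    return found


def read_seg_multi(path) -> dict[str, CNVProfile]:
    """Read a (possibly multi-sample) SEG TSV into per-sample profiles."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _seg_columns(df)
    profiles: dict[str, list[CNVSegment]] = {}
    for i, row in df.iterrows():
        lineno = i + 2  # 1-based, after the header line
        try:
            seg = CNVSegment(
                chrom=str(row[cols["chrom"]]),
                start=int(row[cols["start"]]),
                end=int(row[cols["end"]]),
                segment_mean=float(row[cols["segment_mean"]]),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed SEG row at line {lineno}: {exc}") from exc
        profiles.setdefault(str(row[cols["sample"]]), []).append(seg)
    return {sid: CNVProfile(sample_id=sid, segments=segs) for sid, segs in profiles.items()}


def read_seg(path, sample_id: str | None = None) -> CNVProfile:
    """Read one sample's profile from a SEG file.

    With sample_id=None the file must contain exactly one sample.  A
    header-only file yields an empty profile.
    """
    profiles = read_seg_multi(path)
    if sample_id is not None:
        if sample_id not in profiles:
            raise KeyError(f"sample {sample_id!r} not in SEG file")
        return profiles[sample_id]
    if len(profiles) > 1:
        raise ValueError(
            f"SEG file has {len(profiles)} samples; pass sample_id to pick one"
        )
    if not profiles:
        return CNVProfile(sample_id="", segments=[])
    return next(iter(profiles.values()))


def write_seg(profiles, path) -> None:
    """Write profiles to SEG TSV; segment means round-trip bit-exactly."""
    if isinstance(profiles, CNVProfile):
        profiles = [profiles]
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        fh.write("Sample\tChromosome\tStart\tEnd\tSegment_Mean\n")
        for prof in profiles:
            for seg in prof.segments:
                fh.write(
                    f"{prof.sample_id}\t{seg.chrom}\t{seg.start}\t{seg.end}\t"
                    f"{seg.segment_mean!r}\n"
                )


def cnv_at_locus(profile: CNVProfile, chrom: str, pos: int) -> float | None:
    """Segment mean of the unique segment covering (chrom, pos); None if gap.

    Segment bounds are inclusive on both sides.
    """
    segs = profile._index.get(chrom)
    if not segs:
        return None
    i = bisect.bisect_right(profile._starts[chrom], pos) - 1
    if i >= 0 and segs[i].start <= pos <= segs[i].end:
        return segs[i].segment_mean
    return None


# ---------------------------------------------------------------------------
# Clinical


_DEAD_VALUES = {"dead", "deceased"}


def read_clinical(path) -> list[ClinicalRecord]:
    """Read a clinical TSV into ClinicalRecords.

    Expects columns sample_id (or sample), days_to_death,
    days_to_last_follow_up, vital_status.  Survival time is days_to_death
    when present, otherwise days_to_last_follow_up; the event flag is set
    only when vital status indicates death AND days_to_death is present.
    Rows with neither time field are skipped (count logged).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    lower = {c.lower(): c for c in df.columns}
    sid_col = lower.get("sample_id") or lower.get("sample")
    if sid_col is None:
        raise ValueError("clinical TSV needs a sample_id column")
    records: list[ClinicalRecord] = []
    n_skipped = 0
    for _, row in df.iterrows():
        death = pd.to_numeric(row.get(lower.get("days_to_death", ""), None), errors="coerce")
        follow = pd.to_numeric(
            row.get(lower.get("days_to_last_follow_up", ""), None), errors="coerce"
        )
        vital = str(row.get(lower.get("vital_status", ""), "")).strip().lower()
        if pd.notna(death):
            time, event = float(death), vital in _DEAD_VALUES
        elif pd.notna(follow):
            time, event = float(follow), False
        else:
            n_skipped += 1
            continue
        extra = {
            c: row[c]
            for c in df.columns
            if c not in {sid_col, lower.get("days_to_death"), lower.get("days_to_last_follow_up"), lower.get("vital_status")}
        }
        records.append(
            ClinicalRecord(sample_id=str(row[sid_col]), time_days=time, event=event, covariates=extra)
        )
    if n_skipped:
        logger.warning("skipped %d clinical rows with no survival time", n_skipped)
    return records


def filter_by_purity(samples: list[AFSample], min_purity: float = 0.8) -> list[AFSample]:
    """Keep samples with purity >= min_purity; missing purity passes with a warning."""
    out = []
    n_missing = 0
    for s in samples:
        if s.purity is None:
            n_missing += 1
            out.append(s)
        elif s.purity >= min_purity:
            out.append(s)
    if n_missing:
        logger.warning("%d samples had no purity estimate; retained", n_missing)
    return out
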