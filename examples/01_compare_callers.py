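"""Compare the allele-frequency distributions two callers report for one tumor.

Generates a small synthetic cohort, reads the mutect-like and
varscan-like call sets for one sample back through the VCF readers,
applies the post-call filters, and runs the four distribution
comparisons.
"""

import tempfile
from pathlib import Path

from hetrobust import (
    CohortConfig,
    apply_postprocessing_filters,
    calls_to_af_sample,
    compare_af_samples,
    generate_cohort,
    read_vcf_calls,
    shared_af_correlation,
)

with tempfile.TemporaryDirectory() as tmp:
    generate_cohort(CohortConfig(seed=42, n_samples=3), tmp)
    sid = "SYNTH-0000"
    calls = {}
    for caller in ("mutect", "varscan"):
        raw = read_vcf_calls(Path(tmp) / f"{sid}.{caller}.vcf", caller)
        calls[caller] = apply_postprocessing_filters(raw)
        print(f"{caller}: {len(raw)} raw calls, {len(calls[caller])} after filters")

    a = calls_to_af_sample(calls["mutect"], sid)
    b = calls_to_af_sample(calls["varscan"], sid)
    res = compare_af_samples(a.afs, b.afs, sid, ("mutect", "varscan"))
    r = shared_af_correlation(calls["mutect"], calls["varscan"])

print(f"KS D = {res.ks_D:.3f} (p = {res.ks_p:.3f})")
print(f"EMD = {res.emd:.3f} bins")
print(f"KDE |diff| integral = {res.kde_abs_diff:.3f}")
print(f"L2 permutation p = {res.l2_p:.2f}")
print(f"AF correlation at shared loci: r = {r:.3f}")
print()
print("The two call sets disagree about WHICH mutations exist (nonzero")
print("distances) but agree almost perfectly about the allele frequency")
print("of mutations both callers report (r near 1).")
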