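"""Score one tumor: MATH, AF dispersion, and CNV dispersion.

MATH = 100 x scaled MAD / median of the tumor allele frequencies; a wide
AF distribution (subclonal structure, or copy-number distortion) scores
high.  The two CNV dispersions measure the same profile at SNV loci and
genome-wide.
"""

from hetrobust import (
    AFSample,
    filter_snvs_by_cnv,
    generate_cnv_profile,
    math_score,
    score_sample,
)
from hetrobust.evo_model import EvoModelParams, sample_afs

profile = generate_cnv_profile(n_segments=60, sigma_c=0.35, seed=9)
afs = sample_afs(EvoModelParams(w=0.8, n_snvs=200, seed=9))
loci = [(seg.chrom, seg.start) for seg in profile.segments[:60]] * 4
sample = AFSample("demo", "SYNTH", "mutect", afs[: len(loci[:200])], loci[:200])

res = score_sample(sample, profile, with_extras=True)
print(f"MATH = {res.math:.2f}")
print(f"AF std = {res.af_std:.4f}")
print(f"CNV std at SNV loci = {res.cnv_std:.4f}")
print(f"Whole-genome CNV std = {res.wg_cnv_std:.4f}  (length-weighted)")
print(f"n SNVs = {res.n_snvs}, entropy = {res.extras['entropy']:.3f}")

neutral = filter_snvs_by_cnv(sample, profile, threshold=0.2)
print(f"after |CNV| > 0.2 filter: {len(neutral.afs)} of {len(sample.afs)} SNVs remain")
print(f"MATH on copy-neutral loci = {math_score(neutral.afs):.2f}")
print()
print("Removing copy-number-altered loci isolates the subclonal component")
print("of AF spread from the copy-number component.")
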