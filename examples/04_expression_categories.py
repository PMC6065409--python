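"""Does amplification raise expression where no point mutation exists?

Builds a synthetic expression dataset in which RPKM scales with 2^CNV by
construction, computes per-gene mean RPKM in the amplified-without-SNV
and not-amplified-without-SNV categories, and compares them pairwise.
"""

from hetrobust import CohortConfig, category_means, compare_categories, generate_cohort

cohort = generate_cohort(CohortConfig(seed=8, n_samples=120, n_genes=200))
means = category_means(cohort.expression)

present = means.dropna(subset=["amp_no_snv", "noamp_no_snv"])
print(f"genes with both categories populated: {len(present)} of {len(means)}")

frac, p = compare_categories(means["amp_no_snv"], means["noamp_no_snv"])
print(f"fraction of genes with amplified > non-amplified mean RPKM: {frac:.2f}")
print(f"Wilcoxon signed-rank p = {p:.2e}")
print()
print("The generator couples RPKM to 2^CNV, so amplified copies are")
print("over-expressed for nearly every gene; the paired test confirms the")
print("planted direction.")
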