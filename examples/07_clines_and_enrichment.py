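"""Genomic clines, introgression calls, and ancestry fold enrichment.

Estimates each tree's hybrid index, fits per-SNP genomic clines anchored
to the neutral ancestry mixture, calls SNPs with exceptional
donor-species (P2) introgression, and asks whether each gradient's
association outliers are enriched for those introgressed SNPs (Eq.-style
fold enrichment FE = (Bpf/B)/(Spf/S) with a 10,000-draw permutation
null).
"""

from hzadapt.workflows import run_preset

run = run_preset(seed=1, n_perm_fe=10000)
print(f"universe: {len(run.universe)} SNPs biallelic in the hybrid zone "
      f"and across both parental groups")
print(f"significantly introgressed from P2 (Spf): {run.calls.Spf}")
print(f"planted introgressed loci recalled by the cline test: "
      f"{run.cline_recall():.2f}")

print("\nfold enrichment by gradient:")
cols = ["gradient", "class", "B", "Bpf", "fe", "p", "exceed_95", "exceed_99"]
print(run.enrichment[cols].to_string(index=False))
print("\nby gradient class:")
print(run.enrichment_summary.to_string(index=False))
# freeze-class gradients show FE >> 1 (their outliers are dominated by
# recently introgressed variants); water-class gradients show FE ~ 0-1
# (their outliers are background variants), the central sign pattern
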