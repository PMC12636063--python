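"""Inverse-variance meta-analysis of two studies and the multiple-testing
thresholds used when screening many trait lookups.
"""

from adipocomp import (
    VariantAssociation,
    bh_adjust,
    ivw_meta,
    significance_thresholds,
)

study1 = VariantAssociation("rs603424", 10, 102_075_479, "G", "A",
                            beta=-0.12, se=0.04, p=2.7e-3, eaf=0.83, n=28_402)
study2 = VariantAssociation("rs603424", 10, 102_075_479, "G", "A",
                            beta=-0.08, se=0.05, p=0.11, eaf=0.84, n=21_000)
meta = ivw_meta([study1, study2])
print(
    f"meta-analysis: beta = {meta.beta:+.4f}, SE = {meta.se:.4f}, p = {meta.p:.3g} "
    f"(precision-weighted combination; SE below both inputs)"
)

exact, rounded = significance_thresholds(17, alpha=0.05)
print(f"screening 17 trait lookups: per-test threshold {exact:.5f} "
      f"(quoted as p < {rounded})")

pvals = [0.001, 0.02, 0.03, 0.8]
print("Benjamini-Hochberg adjusted p-values for", pvals, "->",
      [round(float(q), 4) for q in bh_adjust(pvals)])
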