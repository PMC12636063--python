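"""Simulate a cohort with one depot-specific variant, run the association
chain for SAT and VAT fSFA, and test depot heterogeneity with Cochran's Q.

The planted variant raises latent NDB in SAT only (0.4 noise-SDs per
allele), so its SAT-fSFA effect should be strongly negative while the VAT
effect stays near zero — the HetPval < 0.05 & I^2 > 75% rule should flag it.
"""

import numpy as np

from adipocomp import (
    CohortSpec,
    VariantSpec,
    cochran_q,
    inverse_normal_transform,
    linear_assoc,
    simulate_genotypes,
    simulate_traits,
)

variants = (
    VariantSpec("rs_specific", 3, 156_000_000, "T", "C", maf=0.35, beta_sat=0.4),
    VariantSpec("rs_shared", 10, 102_000_000, "G", "A", maf=0.3, beta_sat=0.4, beta_vat=0.4),
    VariantSpec("rs_null", 5, 44_000_000, "A", "G", maf=0.2),
)
spec = CohortSpec(n=8000, variants=variants, seed=11)
genotypes = simulate_genotypes(spec)
pheno = simulate_traits(genotypes, spec)
covars = np.column_stack(
    [pheno["age"], pheno["age"] ** 2, pheno["sex"]]
    + [pheno[f"pc{k}"] for k in range(1, 11)]
)

for j, v in enumerate(variants):
    assocs = {}
    for depot in ("sat", "vat"):
        y = inverse_normal_transform(pheno[f"{depot}_fsfa"].to_numpy())
        assocs[depot] = linear_assoc(
            genotypes.dosage[:, j], y, covars,
            rsid=v.rsid, chrom=v.chrom, bp=v.bp, ea=v.ea, oa=v.oa,
        )
    het = cochran_q(assocs["sat"], assocs["vat"])
    print(
        f"{v.rsid}: beta_SAT = {assocs['sat'].beta:+.3f} (p = {assocs['sat'].p:.2g}), "
        f"beta_VAT = {assocs['vat'].beta:+.3f} (p = {assocs['vat'].p:.2g}); "
        f"Q = {het.q:.2f}, HetPval = {het.het_pval:.2g}, I^2 = {het.i_squared:.1f}% "
        f"-> depot-specific: {het.depot_specific}"
    )
print("Only the SAT-only variant should be flagged; the shared and null "
      "variants have homogeneous depot effects.")
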