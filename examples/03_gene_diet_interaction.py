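"""Fit the gene x diet interaction logistic model on a cohort with a planted
interaction between a variant and standardized saturated-fat intake.

The generating model uses gamma = 0.15 log-odds per allele per SD of intake;
the stratified diet effects should increase with allele count.
"""

import numpy as np

from adipocomp import (
    CohortSpec,
    DiseaseModel,
    VariantSpec,
    interaction_logistic,
    simulate_diet_disease,
    simulate_genotypes,
    simulate_traits,
)

spec = CohortSpec(
    n=20_000,
    variants=(VariantSpec("rs_diet", 10, 102_075_479, "G", "A", maf=0.17),),
    diseases=(
        DiseaseModel(
            name="cvd", intercept=-2.0, variant="rs_diet", diet="sfa",
            beta_g=0.05, beta_diet=0.1, gamma=0.15, beta_age=0.03, beta_sex=-0.4,
        ),
    ),
    seed=21,
)
genotypes = simulate_genotypes(spec)
pheno = simulate_diet_disease(genotypes, simulate_traits(genotypes, spec), spec)
diet = pheno["diet_sfa"].to_numpy()
result = interaction_logistic(
    pheno["cvd"].to_numpy(),
    genotypes.dosage[:, 0],
    (diet - diet.mean()) / diet.std(ddof=0),
    pheno["age"].to_numpy(),
    pheno["sex"].to_numpy(),
)

print(f"cases: {int(pheno['cvd'].sum())} / {len(pheno)}")
print(
    f"interaction gamma = {result.gamma_hat:.4f} (SE = {result.se:.4f}, "
    f"p = {result.p:.3g}); generating value 0.15"
)
print("diet (SFA) effect on disease, stratified by genotype:")
for s in result.stratified:
    print(
        f"  {s.genotype} effect alleles (n = {s.n}): "
        f"log-OR per SD intake = {s.effect:+.3f} "
        f"[95% CI {s.ci_low:+.3f}, {s.ci_high:+.3f}]"
    )
print("A positive interaction means carriers of more effect alleles see a "
      "steeper disease risk gradient with saturated-fat intake.")
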