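"""Synthetic cohort: genotypes, planted trait effects, diet and disease."""

import numpy as np
import pytest
from scipy import stats

from adipocomp.cohort import (
    CohortSpec,
    DiseaseModel,
    VariantSpec,
    simulate_diet_disease,
    simulate_genotypes,
    simulate_ld_block,
    simulate_traits,
)
from adipocomp.gwas import inverse_normal_transform, linear_assoc_many


def _variants(n, maf=0.25, beta_sat=0.0, beta_vat=0.0):
    return tuple(
        VariantSpec(
            rsid=f"rs{i}",
            chrom=1 + i % 22,
            bp=10_000 + 1000 * i,
            ea="A",
            oa="G",
            maf=maf,
            beta_sat=beta_sat,
            beta_vat=beta_vat,
        )
        for i in range(n)
    )


class TestGenotypes:
    def test_hwe_frequencies_within_three_se(self):
        spec = CohortSpec(n=10_000, variants=_variants(1, maf=0.25), seed=5)
        g = simulate_genotypes(spec)
        counts = np.bincount(g.hard_calls[:, 0], minlength=3) / spec.n
        for k, expected in enumerate((0.5625, 0.375, 0.0625)):
            se = np.sqrt(expected * (1 - expected) / spec.n)
            assert abs(counts[k] - expected) < 3 * se

    def test_perfect_imputation_info_one(self):
        spec = CohortSpec(
            n=10_000, variants=_variants(5), dosage_noise_sd=0.0, seed=1
        )
        g = simulate_genotypes(spec)
        np.testing.assert_allclose(g.info, 1.0, atol=0.05)
        np.testing.assert_array_equal(g.dosage, g.hard_calls)

    def test_noisy_imputation_drops_info_below_cutoff(self):
        spec = CohortSpec(
            n=10_000, variants=_variants(5), dosage_noise_sd=1.0, seed=1
        )
        g = simulate_genotypes(spec)
        assert np.all(g.info < 0.9)
        assert np.all((g.dosage >= 0) & (g.dosage <= 2))

    def test_eaf_within_three_binomial_se(self):
        spec = CohortSpec(n=20_000, variants=_variants(10, maf=0.3), seed=7)
        g = simulate_genotypes(spec)
        se = np.sqrt(0.3 * 0.7 / (2 * spec.n))
        assert np.all(np.abs(g.eaf - 0.3) < 3 * se)

    def test_invalid_variants_rejected(self):
        with pytest.raises(ValueError, match="maf"):
            VariantSpec("rs1", 1, 100, "A", "G", maf=0.6)
        with pytest.raises(ValueError, match="ambiguous"):
            VariantSpec("rs1", 1, 100, "A", "T", maf=0.2)
        with pytest.raises(ValueError, match="cohort size"):
            CohortSpec(n=10, variants=_variants(1))


class TestTraits:
    def test_fraction_triplets_sum_to_one(self):
        spec = CohortSpec(n=500, variants=_variants(3), seed=2)
        df = simulate_traits(simulate_genotypes(spec), spec)
        for depot in ("sat", "vat"):
            total = (
                df[f"{depot}_fsfa"] + df[f"{depot}_fmufa"] + df[f"{depot}_fpufa"]
            )
            np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_deterministic_given_seed(self):
        spec = CohortSpec(n=200, variants=_variants(4), seed=9)
        a = simulate_traits(simulate_genotypes(spec), spec)
        b = simulate_traits(simulate_genotypes(spec), spec)
        assert a.equals(b)

    def test_planted_effect_recovered_on_transformed_scale(self):
        """An allele planted to raise latent NDB by 0.386 noise-SDs is
        recovered as a ~-0.386 effect on inverse-normal fSFA (fSFA falls
        monotonically with NDB, and the transform absorbs the
        nonlinearity)."""
        betas = []
        for seed in range(20):
            spec = CohortSpec(
                n=2000,
                variants=_variants(1, maf=0.17, beta_sat=0.386),
                seed=100 + seed,
            )
            g = simulate_genotypes(spec)
            df = simulate_traits(g, spec)
            y = inverse_normal_transform(df["sat_fsfa"].to_numpy())
            covars = np.column_stack(
                [df["age"], df["age"] ** 2, df["sex"]]
                + [df[f"pc{k}"] for k in range(1, 11)]
            )
            betas.append(
                linear_assoc_many(g.dosage[:, :1], y, covars)["BETA"].iloc[0]
            )
        assert np.mean(betas) == pytest.approx(-0.386, abs=0.05)

    def test_power_for_small_effect_matches_analytic(self):
        """|beta| = 0.1 SD at MAF 0.2, n = 5000 gives |z| ~ 4; at the
        two-sided 5e-4 level the analytic power is ~0.70."""
        hits = 0
        reps = 200
        for seed in range(reps):
            spec = CohortSpec(
                n=5000,
                variants=_variants(1, maf=0.2, beta_sat=-0.1),
                seed=3000 + seed,
            )
            g = simulate_genotypes(spec)
            df = simulate_traits(g, spec)
            y = inverse_normal_transform(df["sat_fsfa"].to_numpy())
            p = linear_assoc_many(g.dosage[:, :1], y)["P"].iloc[0]
            hits += p < 5e-4
        assert hits / reps == pytest.approx(0.70, abs=0.10)


class TestDietDisease:
    def _spec(self, gamma, n=5000, seed=0):
        return CohortSpec(
            n=n,
            variants=_variants(1, maf=0.3),
            diseases=(
                DiseaseModel(
                    name="cvd",
                    intercept=-1.2,
                    variant="rs0",
                    diet="sfa",
                    beta_g=0.1,
                    beta_diet=0.1,
                    gamma=gamma,
                    beta_age=0.02,
                    beta_sex=-0.3,
                ),
            ),
            seed=seed,
        )

    def test_diet_distributions(self):
        spec = self._spec(0.0, n=20_000)
        g = simulate_genotypes(spec)
        df = simulate_diet_disease(g, simulate_traits(g, spec), spec)
        assert df["diet_sfa"].mean() == pytest.approx(27.54, abs=0.5)
        assert df["diet_sfa"].std() == pytest.approx(11.78, abs=0.5)
        assert df["diet_pufa"].mean() == pytest.approx(19.90, abs=0.5)

    def test_prevalence_matches_analytic_expectation(self):
        """Realized prevalence agrees with the model's expected risk
        integrated over an independent draw of covariates (within 2%)."""
        spec = self._spec(0.15, n=20_000, seed=4)
        g = simulate_genotypes(spec)
        df = simulate_diet_disease(g, simulate_traits(g, spec), spec)
        other = self._spec(0.15, n=20_000, seed=99)
        g2 = simulate_genotypes(other)
        df2 = simulate_diet_disease(g2, simulate_traits(g2, other), other)
        assert df["cvd"].mean() == pytest.approx(df2["cvd_risk"].mean(), abs=0.02)

    def test_null_interaction_centred_at_zero(self):
        from adipocomp.gwas import interaction_logistic

        gammas = []
        for seed in range(30):
            spec = self._spec(0.0, n=3000, seed=500 + seed)
            g = simulate_genotypes(spec)
            df = simulate_diet_disease(g, simulate_traits(g, spec), spec)
            d = df["diet_sfa"].to_numpy()
            res = interaction_logistic(
                df["cvd"].to_numpy(),
                g.dosage[:, 0],
                (d - d.mean()) / d.std(),
                df["age"].to_numpy(),
                df["sex"].to_numpy(),
            )
            gammas.append(res.gamma_hat)
        se_mean = np.std(gammas, ddof=1) / np.sqrt(len(gammas))
        assert abs(np.mean(gammas)) < 3 * se_mean + 0.01

    def test_planted_interaction_recovered(self):
        from adipocomp.gwas import interaction_logistic

        gammas = []
        for seed in range(30):
            spec = self._spec(0.15, n=5000, seed=800 + seed)
            g = simulate_genotypes(spec)
            df = simulate_diet_disease(g, simulate_traits(g, spec), spec)
            d = df["diet_sfa"].to_numpy()
            res = interaction_logistic(
                df["cvd"].to_numpy(),
                g.dosage[:, 0],
                (d - d.mean()) / d.std(),
                df["age"].to_numpy(),
                df["sex"].to_numpy(),
            )
            gammas.append(res.gamma_hat)
        assert np.mean(gammas) == pytest.approx(0.15, abs=0.03)

    def test_unknown_variant_rejected(self):
        spec = CohortSpec(
            n=100,
            variants=_variants(1),
            diseases=(DiseaseModel(name="x", intercept=-1, variant="nope"),),
            seed=0,
        )
        g = simulate_genotypes(spec)
        with pytest.raises(KeyError):
            simulate_diet_disease(g, simulate_traits(g, spec), spec)


def test_ld_block_properties():
    g = simulate_ld_block(4000, 10, maf=0.3, rho=0.5, rng=3)
    assert g.shape == (4000, 10)
    assert set(np.unique(g)) <= {0.0, 1.0, 2.0}
    eaf = g.mean(axis=0) / 2
    np.testing.assert_allclose(eaf, 0.3, atol=0.03)
    r2 = np.corrcoef(g, rowvar=False) ** 2
    off = r2[np.triu_indices(10, 1)]
    assert off.mean() > 0.05  # real LD present
    assert off.max() < 0.9
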