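"""Association statistics: INT, OLS engine, heterogeneity, meta, interaction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from adipocomp.gwas import (
    GENOME_WIDE_P,
    VariantAssociation,
    bh_adjust,
    cochran_q,
    filter_variants,
    interaction_logistic,
    inverse_normal_transform,
    ivw_meta,
    lead_variant,
    linear_assoc,
    linear_assoc_many,
    significance_thresholds,
)


def _assoc(rsid="rs1", beta=0.1, se=0.05, p=1e-4, ea="A", oa="G", bp=100, eaf=0.3):
    return VariantAssociation(rsid, 1, bp, ea, oa, beta, se, p, eaf, 1000)


class TestInverseNormalTransform:
    def test_blom_offsets_at_n3(self):
        z = inverse_normal_transform([1.0, 2.0, 3.0])
        # Phi^-1((3 - 3/8) / (3 + 1/4)) = Phi^-1(0.80769...)
        np.testing.assert_allclose(z, [-0.8694237732888861, 0.0, 0.8694237732888861])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.permutations(list(range(8))))
    def test_rank_equivariance(self, perm):
        base = np.array([0.3, 1.7, -2.0, 5.0, 0.1, 9.9, -4.2, 2.2])
        z = inverse_normal_transform(base)
        zp = inverse_normal_transform(base[perm])
        np.testing.assert_allclose(zp, z[perm])

    def test_zero_mean_and_normality_for_skewed_input(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(2.0, 1000)
        z = inverse_normal_transform(x)
        assert abs(z.mean()) < 1e-6
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_ties_get_average_ranks(self):
        z = inverse_normal_transform([1.0, 1.0, 2.0])
        assert z[0] == z[1] < z[2]

    def test_degenerate_trait_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            inverse_normal_transform([3.0, 3.0, 3.0])


class TestFilterVariants:
    def test_boundary_maf_excluded(self):
        df = pd.DataFrame(
            {"EAF": [0.01, 0.0099, 0.011, 0.2], "INFO": [0.95, 0.95, 0.95, 0.95]}
        )
        kept = filter_variants(df)
        assert list(kept.index) == [2, 3]

    def test_inclusion_exclusion_on_constructed_table(self):
        # 100 variants; 20 fail MAF, 20 fail INFO, 5 fail both -> 65 kept
        eaf = np.full(100, 0.25)
        info = np.full(100, 0.95)
        eaf[:20] = 0.005
        info[15:35] = 0.5
        df = pd.DataFrame({"EAF": eaf, "INFO": info})
        assert len(filter_variants(df)) == 65

    def test_missing_column_errors(self):
        with pytest.raises(KeyError, match="INFO"):
            filter_variants(pd.DataFrame({"EAF": [0.2]}))


class TestLinearAssoc:
    def test_closed_form_without_covariates(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, 500).astype(float)
        y = 0.2 * g + rng.standard_normal(500)
        a = linear_assoc(g, y)
        beta_cf = np.cov(g, y, ddof=1)[0, 1] / np.var(g, ddof=1)
        assert a.beta == pytest.approx(beta_cf, rel=1e-10)

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 400
        g = rng.binomial(2, 0.4, n).astype(float)
        cov = rng.standard_normal((n, 3))
        y = 0.1 * g + cov @ [0.2, -0.1, 0.3] + rng.standard_normal(n)
        a = linear_assoc(g, y, cov)
        X = sm.add_constant(np.column_stack([g, cov]))
        fit = sm.OLS(y, X).fit()
        assert a.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert a.se == pytest.approx(fit.bse[1], abs=1e-10)

    def test_vectorized_engine_equals_per_variant(self):
        rng = np.random.default_rng(3)
        n, m = 300, 7
        G = rng.binomial(2, 0.3, (n, m)).astype(float)
        cov = rng.standard_normal((n, 2))
        y = rng.standard_normal(n)
        many = linear_assoc_many(G, y, cov)
        for j in range(m):
            a = linear_assoc(G[:, j], y, cov)
            assert many["BETA"].iloc[j] == pytest.approx(a.beta, abs=1e-10)
            assert many["SE"].iloc[j] == pytest.approx(a.se, abs=1e-10)

    def test_collinear_design_names_column(self):
        g = np.ones(100)
        y = np.random.default_rng(0).standard_normal(100)
        with pytest.raises(ValueError, match="collinear"):
            linear_assoc(g, y)

    def test_null_calibration_small(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(200):
            g = rng.binomial(2, 0.3, 500).astype(float)
            y = rng.standard_normal(500)
            a = linear_assoc(g, y)
            hits += abs(a.beta) > 3 * a.se
        assert hits / 200 < 0.02  # ~0.27% expected under the null


class TestCochranQ:
    def test_homogeneous_effects(self):
        h = cochran_q(_assoc(beta=0.1), _assoc(beta=0.1))
        assert h.q == pytest.approx(0.0, abs=1e-12)
        assert h.i_squared == 0.0
        assert not h.depot_specific

    def test_worked_two_depot_example(self):
        h = cochran_q(_assoc(beta=0.1, se=0.05), _assoc(beta=-0.1, se=0.05))
        assert h.q == pytest.approx(8.0, abs=1e-12)
        assert h.df == 1
        assert h.het_pval == pytest.approx(0.004677734981047276, rel=1e-10)
        assert h.i_squared == pytest.approx(87.5, abs=1e-10)
        assert h.depot_specific

    def test_invariant_under_simultaneous_allele_flip(self):
        a, b = _assoc(beta=0.2, se=0.04), _assoc(beta=0.05, se=0.04)
        h1 = cochran_q(a, b)
        h2 = cochran_q(a.flipped(), b.flipped())
        assert h1.q == pytest.approx(h2.q, rel=1e-12)

    def test_harmonizes_swapped_alleles(self):
        a = _assoc(beta=0.1, se=0.05, ea="A", oa="G")
        b_swapped = _assoc(beta=0.1, se=0.05, ea="G", oa="A")
        # same underlying effect expressed on the other allele -> heterogeneous
        h = cochran_q(a, b_swapped)
        assert h.q == pytest.approx(8.0)

    def test_allele_mismatch_rejected(self):
        with pytest.raises(ValueError, match="harmonized"):
            cochran_q(_assoc(ea="A", oa="G"), _assoc(ea="T", oa="C"))

    def test_depot_specific_rule_needs_both_conditions(self):
        # significant Q but I^2 below 75 must not flag
        h = cochran_q(_assoc(beta=0.1, se=0.04), _assoc(beta=0.0, se=0.1))
        assert (h.het_pval < 0.05 and h.i_squared > 75) == h.depot_specific


class TestIvwMeta:
    def test_identical_pair(self):
        m = ivw_meta([_assoc(beta=0.2, se=0.1), _assoc(beta=0.2, se=0.1)])
        assert m.beta == pytest.approx(0.2)
        assert m.se == pytest.approx(0.1 / np.sqrt(2))

    def test_worked_example(self):
        m = ivw_meta([_assoc(beta=0.2, se=0.1), _assoc(beta=0.0, se=0.1)])
        assert m.beta == pytest.approx(0.1)
        assert m.se == pytest.approx(0.07071067811865475)

    def test_meta_se_below_every_input(self):
        assocs = [_assoc(beta=b, se=s) for b, s in [(0.1, 0.05), (0.2, 0.08), (0.0, 0.2)]]
        m = ivw_meta(assocs)
        assert m.se < min(a.se for a in assocs)

    def test_single_study_passthrough_warns(self):
        with pytest.warns(UserWarning, match="single study"):
            m = ivw_meta([_assoc(beta=0.3, se=0.1)])
        assert m.beta == 0.3


class TestInteractionLogistic:
    @staticmethod
    def _data(n=4000, gamma=0.15, seed=0):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, 0.3, n).astype(float)
        d = rng.standard_normal(n)
        age = rng.normal(60, 8, n)
        sex = rng.binomial(1, 0.5, n).astype(float)
        eta = -1 + 0.1 * g + 0.1 * d + gamma * g * d + 0.01 * (age - 60) - 0.2 * sex
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        return y, g, d, age, sex

    def test_matches_independent_likelihood_maximizer(self):
        """IRLS agrees with statsmodels' Newton maximum likelihood to 1e-6."""
        import statsmodels.api as sm

        y, g, d, age, sex = self._data()
        res = interaction_logistic(y, g, d, age, sex)
        X = np.column_stack([np.ones_like(g), g, d, g * d, age - age.mean(), sex])
        fit = sm.Logit(y, X).fit(disp=0)
        assert res.gamma_hat == pytest.approx(fit.params[3], abs=1e-6)
        assert res.se == pytest.approx(fit.bse[3], abs=1e-6)

    def test_stratified_effects_reported(self):
        y, g, d, age, sex = self._data(n=6000)
        res = interaction_logistic(y, g, d, age, sex)
        genos = [s.genotype for s in res.stratified]
        assert genos == [0, 1, 2]
        # positive interaction: diet effect grows with allele count
        effects = [s.effect for s in res.stratified]
        assert effects[2] > effects[0]
        for s in res.stratified:
            assert s.ci_low < s.effect < s.ci_high

    def test_separation_detected(self):
        n = 200
        g = np.repeat([0.0, 2.0], n // 2)
        d = np.linspace(-3, 3, n)
        y = (d > 0).astype(float)  # perfectly separated by diet
        age = np.full(n, 60.0)
        sex = np.zeros(n)
        with pytest.raises(ValueError, match="separation|converge|singular"):
            interaction_logistic(y, g, d, age + np.arange(n) * 0.01, sex)

    def test_single_class_outcome_rejected(self):
        y = np.zeros(100)
        with pytest.raises(ValueError):
            interaction_logistic(y, y, y, y + 60, y)


class TestThresholdsAndLead:
    def test_seventeen_tests_rounds_to_0003(self):
        exact, rounded = significance_thresholds(17, 0.05)
        assert exact == pytest.approx(0.05 / 17)
        assert rounded == 0.003

    def test_single_test(self):
        assert significance_thresholds(1, 0.05) == (0.05, 0.05)

    def test_bh_stepup_hand_example(self):
        adj = bh_adjust([0.001, 0.02, 0.03, 0.8])
        np.testing.assert_allclose(adj, [0.004, 0.04, 0.04, 0.8])

    def test_genome_wide_constant(self):
        assert GENOME_WIDE_P == 5e-8
        assert _assoc(p=5e-8).genome_wide
        assert not _assoc(p=6e-8).genome_wide

    def test_lead_variant_rules(self):
        single = _assoc(p=0.5)
        assert lead_variant([single]) is single
        planted = _assoc(rsid="hit", p=1e-12)
        others = [_assoc(rsid=f"null{i}", p=0.1) for i in range(5)]
        assert lead_variant(others + [planted]).rsid == "hit"
        # tie in p: larger |beta| wins, then lower bp
        tie = [
            _assoc(rsid="a", p=1e-5, beta=0.1, bp=200),
            _assoc(rsid="b", p=1e-5, beta=-0.3, bp=300),
            _assoc(rsid="c", p=1e-5, beta=0.3, bp=250),
        ]
        assert lead_variant(tie).rsid == "c"
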