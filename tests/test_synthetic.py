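"""Generator behaviour: haplotype constraint, model recovery, artifact
injection, and reproducibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mrewas as m
from mrewas.preprocess import preprocess_panel
from mrewas.synthetic import array27k_panel_fractions


class TestGenotypes:
    def test_no_variant_alleles(self):
        g = m.gen_genotypes(1000, 0.0, 0.0, seed=3)
        assert np.all(g == 0)

    def test_allele_frequencies_match_binomial_sampling(self):
        n = 10_000
        g = m.gen_genotypes(n, 0.33, 0.23, seed=1)
        for col, maf in ((0, 0.33), (1, 0.23)):
            freq = g[:, col].sum() / (2 * n)
            sd = np.sqrt(maf * (1 - maf) / (2 * n))
            assert abs(freq - maf) < 3 * sd

    @given(maf1=st.floats(0.0, 0.5), maf2=st.floats(0.0, 0.5),
           seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_trans_constraint_always_holds(self, maf1, maf2, seed):
        g = m.gen_genotypes(200, maf1, maf2, seed=seed)
        assert g.sum(axis=1).max() <= 2

    def test_overfull_frequencies_renormalized_with_warning(self):
        with pytest.warns(UserWarning, match="renormaliz"):
            g = m.gen_genotypes(500, 0.6, 0.6, seed=0)
        assert g.sum(axis=1).max() <= 2

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            m.gen_genotypes(0, 0.3, 0.2)
        with pytest.raises(ValueError):
            m.gen_genotypes(10, -0.1, 0.2)
        with pytest.raises(ValueError):
            m.gen_genotypes(10, 0.3, 1.2)


class TestCohort:
    def test_degenerate_model_reduces_to_intercept(self):
        spec = m.CohortSpec(n=100, alpha1=0, alpha2=0, alpha_c=0,
                            sigma_x=1e-9, alpha0=6.6, seed=2)
        cohort, _ = m.gen_cohort(spec)
        assert np.allclose(cohort.log_rbc_folate, 6.6, atol=1e-6)

    def test_first_stage_slope_recovered_by_ols(self):
        spec = m.CohortSpec(n=50_000, alpha0=6.0, alpha1=0.1, seed=4)
        cohort, _ = m.gen_cohort(spec)
        X = np.column_stack([np.ones(len(cohort)),
                             cohort.variant_count.to_numpy(float)])
        fit = m.ols_fit(cohort.log_rbc_folate.to_numpy(), X)
        assert abs(fit.coef[1] - 0.1) < 3 * fit.se[1]

    def test_default_folate_values_span_observed_range(self):
        # typical cord-blood log RBC folate values span ~6.13-7.54
        cohort, _ = m.gen_cohort(m.CohortSpec(seed=0))
        inside = cohort.log_rbc_folate.between(6.13, 7.54).mean()
        assert inside >= 0.75
        assert cohort.log_rbc_folate.between(5.6, 8.1).all()

    def test_confounder_independent_when_loading_zero(self):
        spec = m.CohortSpec(n=50_000, alpha_c=0.0, seed=9)
        cohort, u = m.gen_cohort(spec)
        r = np.corrcoef(u, cohort.log_rbc_folate)[0, 1]
        assert abs(r) < 3 / np.sqrt(spec.n)

    def test_seed_determinism(self):
        a, ua = m.gen_cohort(m.CohortSpec(seed=5))
        b, ub = m.gen_cohort(m.CohortSpec(seed=5))
        c, _ = m.gen_cohort(m.CohortSpec(seed=6))
        pd.testing.assert_frame_equal(a, b)
        assert np.array_equal(ua, ub)
        assert not np.allclose(a.log_rbc_folate, c.log_rbc_folate)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            m.gen_cohort(m.CohortSpec(n=1))
        with pytest.raises(ValueError):
            m.gen_cohort(m.CohortSpec(sigma_x=0.0))
        with pytest.raises(ValueError):
            m.gen_cohort(m.CohortSpec(maf677=0.7))


class TestMethylation:
    def test_degenerate_profile_gives_constant_beta(self):
        cohort, u = m.gen_cohort(m.CohortSpec(seed=1))
        prof = m.EffectProfile(beta0=[np.pi / 8], beta1=[0.0], beta2=[0.0],
                               beta_c=[0.0], sigma_y=[1e-9])
        ann, _ = m.gen_probe_panel(1, 0, 0, 0, seed=1)
        panel = m.gen_methylation(cohort, u, prof, ann, seed=1)
        assert np.allclose(panel.betas.to_numpy(),
                           np.sin(np.pi / 8) ** 2, atol=1e-6)

    def test_outcome_slope_recovered_by_ols(self):
        spec = m.CohortSpec(n=50_000, seed=3)
        cohort, u = m.gen_cohort(spec)
        prof = m.EffectProfile(beta0=[-0.5], beta1=[0.2], beta2=[0.05],
                               beta_c=[0.0], sigma_y=[0.05])
        ann, _ = m.gen_probe_panel(1, 0, 0, 0, seed=3)
        panel = m.gen_methylation(cohort, u, prof, ann, seed=3)
        y = m.transform_beta(panel.betas.to_numpy()[0])
        X = np.column_stack([np.ones(spec.n),
                             cohort.log_rbc_folate.to_numpy(),
                             cohort.conception_planned.to_numpy(float)])
        fit = m.ols_fit(y, X)
        assert abs(fit.coef[1] - 0.2) < 3 * fit.se[1]

    def test_shared_confounder_induces_positive_dependence(self):
        spec = m.CohortSpec(n=20_000, alpha_c=0.2, seed=8)
        cohort, u = m.gen_cohort(spec)
        prof = m.EffectProfile(beta0=[-0.6], beta1=[0.2], beta2=[0.0],
                               beta_c=[0.2], sigma_y=[0.05])
        ann, _ = m.gen_probe_panel(1, 0, 0, 0, seed=8)
        panel = m.gen_methylation(cohort, u, prof, ann, seed=8)
        y = m.transform_beta(panel.betas.to_numpy()[0])
        # residualize both on the instrument and covariate; remaining
        # covariance must reflect the shared confounder
        X = np.column_stack([np.ones(spec.n),
                             cohort.variant_count.to_numpy(float),
                             cohort.conception_planned.to_numpy(float)])
        ra = m.ols_fit(cohort.log_rbc_folate.to_numpy(), X).residuals
        ry = m.ols_fit(y, X).residuals
        assert np.cov(ra, ry)[0, 1] > 0

    def test_beta_values_bounded_and_missing_injected(self):
        cohort, u = m.gen_cohort(m.CohortSpec(seed=2))
        prof = m.EffectProfile.null(50)
        ann, miss = m.gen_probe_panel(50, 0, 0, 0.1, seed=2)
        panel = m.gen_methylation(cohort, u, prof, ann, seed=2,
                                  missing_probes=miss)
        vals = panel.betas.to_numpy()
        finite = vals[np.isfinite(vals)]
        assert finite.min() >= 0 and finite.max() <= 1
        has_missing = np.isnan(vals).any(axis=1)
        assert has_missing.sum() == 5  # round(50 * 0.1)
        assert np.array_equal(np.flatnonzero(has_missing),
                              np.flatnonzero(miss))

    def test_intensities_reproduce_betas(self):
        cohort, u = m.gen_cohort(m.CohortSpec(seed=4))
        prof = m.EffectProfile.null(20)
        ann, _ = m.gen_probe_panel(20, 0, 0, 0, seed=4)
        panel = m.gen_methylation(cohort, u, prof, ann, seed=4,
                                  with_intensities=True)
        back = m.beta_from_intensities(panel.intensities_m.to_numpy(),
                                       panel.intensities_u.to_numpy())
        cap = 4000.0 / 4100.0
        expected = np.minimum(panel.betas.to_numpy(), cap)
        assert np.allclose(back, expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        cohort, u = m.gen_cohort(m.CohortSpec(seed=1))
        prof = m.EffectProfile.null(5)
        ann, _ = m.gen_probe_panel(6, 0, 0, 0, seed=1)
        with pytest.raises(ValueError):
            m.gen_methylation(cohort, u, prof, ann, seed=1)
        with pytest.raises(ValueError):
            m.gen_methylation(cohort, u[:-1], prof, ann.iloc[:5], seed=1)


class TestProbePanel:
    def test_exact_category_counts(self):
        ann, miss = m.gen_probe_panel(100, 0.1, 0.05, 0.0, seed=0)
        assert ann["chromosome"].isin(["X", "Y"]).sum() == 10
        assert ann["cross_reactive"].sum() == 5
        assert miss.sum() == 0
        assert ann["probe_id"].is_unique

    def test_empty_panel(self):
        ann, miss = m.gen_probe_panel(0, 0.1, 0.1, 0.1, seed=0)
        assert len(ann) == 0 and miss.size == 0

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            m.gen_probe_panel(10, 1.5, 0, 0)

    def test_array27k_cascade_retention_ratios(self):
        """The filter cascade on the 27K-style fixture loses ~14% of
        probes to the sex/cross-reactive restriction and ~27% of the
        complete-case probes to the normality filter."""
        fr = array27k_panel_fractions()
        cohort, u = m.gen_cohort(m.CohortSpec(seed=6))
        ann, miss = m.gen_probe_panel(2000, seed=6, **fr)
        prof = m.EffectProfile.null(2000, beta0=0.8, sigma_y=0.05)
        panel = m.gen_methylation(cohort, u, prof, ann, seed=6,
                                  missing_probes=miss)
        _, report = preprocess_panel(panel)
        c = report.counts
        after_restrict = c["after_cross_reactive_removal"] / c["input"]
        final_ratio = (c["after_normality_filter"]
                       / c["after_complete_case"])
        assert after_restrict == pytest.approx(0.859, abs=0.02)
        assert final_ratio == pytest.approx(0.73, abs=0.04)
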