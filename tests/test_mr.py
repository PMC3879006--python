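"""2SLS/OLS estimation, the genome-wide scan, the pairs bootstrap, and
scan comparison — each checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import mrewas as m
from conftest import transformed_matrix


def iv_closed_form(y, X, Z):
    """Independent just-identified IV oracle: (Z'X)^-1 Z'y."""
    return np.linalg.solve(Z.T @ X, Z.T @ y)


def random_iv_instance(rng, n):
    z = rng.integers(0, 3, n).astype(float)
    while np.ptp(z) == 0:
        z = rng.integers(0, 3, n).astype(float)
    u = rng.normal(size=n)
    a = 1.0 + 0.8 * z + 0.5 * u + rng.normal(size=n)
    c = rng.integers(0, 2, n).astype(float)
    while np.ptp(c) == 0:
        c = rng.integers(0, 2, n).astype(float)
    y = 0.3 + 0.6 * a + 0.4 * c + 0.5 * u + rng.normal(size=n)
    return y, a, z, c


class TestOls:
    def test_exact_linear_relation(self):
        x = np.arange(1.0, 9.0)
        fit = m.ols_fit(2 * x, np.column_stack([np.ones(8), x]))
        assert fit.coef[1] == pytest.approx(2.0, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        y = rng.normal(size=20)
        fit = m.ols_fit(y, X)
        ref = sm.OLS(y, X).fit()
        assert np.allclose(fit.coef, ref.params, atol=1e-10)
        assert np.allclose(fit.se, ref.bse, atol=1e-10)
        assert np.allclose(fit.p, ref.pvalues, atol=1e-10)

    def test_orthogonal_regressor_gets_zero_slope(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to x and 1
        fit = m.ols_fit(y, np.column_stack([np.ones(4), x]))
        assert fit.coef[1] == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank"):
            m.ols_fit(np.arange(10.0), X)


class TestTsls:
    def test_wald_ratio_worked_example(self):
        fit = m.tsls_fit([2, 3, 7, 10], [1, 2, 3, 6], [0, 0, 1, 1])
        assert fit.beta1 == pytest.approx(2.0, abs=1e-10)

    def test_equals_wald_ratio_for_binary_instrument(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = 12
            z = rng.integers(0, 2, n).astype(float)
            while np.ptp(z) == 0:
                z = rng.integers(0, 2, n).astype(float)
            a = rng.normal(size=n) + z
            y = rng.normal(size=n) + 0.5 * a
            wald = ((y[z == 1].mean() - y[z == 0].mean())
                    / (a[z == 1].mean() - a[z == 0].mean()))
            assert m.tsls_fit(y, a, z).beta1 == pytest.approx(wald, abs=1e-10)

    def test_equals_closed_form_iv_with_covariates(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(8, 31))
            y, a, z, c = random_iv_instance(rng, n)
            fit = m.tsls_fit(y, a, z, c)
            X = np.column_stack([np.ones(n), a, c])
            Z = np.column_stack([np.ones(n), z, c])
            ref = iv_closed_form(y, X, Z)
            assert np.allclose(fit.coef, ref, atol=1e-10)

    def test_perfect_first_stage_reduces_to_ols(self):
        rng = np.random.default_rng(5)
        z = rng.integers(0, 3, 30).astype(float)
        y = rng.normal(size=30) + z
        tsls = m.tsls_fit(y, z, z)
        ols = m.ols_fit(y, np.column_stack([np.ones(30), z]))
        assert np.allclose(tsls.coef, ols.coef, atol=1e-10)
        assert np.allclose(tsls.se, ols.se, atol=1e-10)

    def test_consistent_under_confounding_where_ols_is_not(self):
        rng = np.random.default_rng(1)
        n = 50_000
        z = rng.binomial(2, 0.4, n).astype(float)
        u = rng.standard_normal(n)
        a = 6.5 + 0.3 * z + 0.3 * u + 0.3 * rng.standard_normal(n)
        y = 0.5 + 0.2 * a + 0.3 * u + 0.1 * rng.standard_normal(n)
        tsls = m.tsls_fit(y, a, z)
        ols = m.ols_fit(y, np.column_stack([np.ones(n), a]))
        assert abs(tsls.beta1 - 0.2) < 3 * tsls.beta1_se
        assert abs(ols.coef[1] - 0.2) > 10 * ols.se[1]

    def test_constant_instrument_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            m.tsls_fit([1.0, 2, 3, 4], [1.0, 2, 3, 4], [1, 1, 1, 1])


class TestScan:
    def _scan_panel(self, cohort, u, n_probes, seed, signal_idx=(),
                    beta1=0.0):
        prof = m.EffectProfile.null(n_probes, beta0=0.8, sigma_y=0.05)
        if len(signal_idx):
            prof = prof.with_signal(list(signal_idx), beta1,
                                    recenter_at=6.66)
        ann, _ = m.gen_probe_panel(n_probes, 0, 0, 0, seed=seed)
        panel = m.gen_methylation(cohort, u, prof, ann, seed=seed)
        return transformed_matrix(panel)

    def test_matches_per_probe_fits(self, strong_cohort):
        cohort, u = strong_cohort
        matrix = self._scan_panel(cohort, u, 25, seed=3, signal_idx=[0],
                                  beta1=0.3)
        results, _ = m.genomewide_scan(matrix, cohort)
        a = cohort.log_rbc_folate.to_numpy()
        z = cohort.variant_count.to_numpy(float)
        c = cohort.conception_planned.to_numpy(float)
        for _, row in results.iloc[:5].iterrows():
            y = matrix.loc[row.probe_id].to_numpy()
            fit = m.tsls_fit(y, a, z, c)
            ols = m.ols_fit(y, np.column_stack([np.ones(len(y)), a, c]))
            assert row.tsls_estimate == pytest.approx(fit.beta1, abs=1e-10)
            assert row.tsls_se == pytest.approx(fit.beta1_se, abs=1e-10)
            assert row.tsls_p == pytest.approx(fit.beta1_p, abs=1e-10)
            assert row.ols_estimate == pytest.approx(ols.coef[1], abs=1e-10)
            assert row.ols_p == pytest.approx(ols.p[1], abs=1e-10)

    def test_probe_and_subject_order_invariance(self, strong_cohort):
        cohort, u = strong_cohort
        matrix = self._scan_panel(cohort, u, 30, seed=8)
        base, _ = m.genomewide_scan(matrix, cohort)

        shuffled = matrix.sample(frac=1, random_state=0)
        res_p, _ = m.genomewide_scan(shuffled, cohort)
        pd.testing.assert_frame_equal(base, res_p)

        perm = np.random.default_rng(0).permutation(len(cohort))
        cohort_s = cohort.iloc[perm].reset_index(drop=True)
        matrix_s = matrix.iloc[:, perm]
        res_s, _ = m.genomewide_scan(matrix_s, cohort_s)
        assert np.allclose(res_s.tsls_estimate, base.tsls_estimate,
                           atol=1e-10)

    def test_planted_signal_ranks_first(self, strong_cohort):
        """A strong planted effect among nulls should top the ranking
        in nearly every replicate."""
        cohort, u = strong_cohort
        top = 0
        reps = 20
        for r in range(reps):
            matrix = self._scan_panel(cohort, u, 200, seed=100 + r,
                                      signal_idx=[0], beta1=0.4)
            signal_id = matrix.index[0]
            results, _ = m.genomewide_scan(matrix, cohort)
            top += signal_id in set(results.probe_id.head(10))
        assert top >= reps * 0.8

    def test_constant_instrument_named_in_error(self, strong_cohort):
        cohort, u = strong_cohort
        matrix = self._scan_panel(cohort, u, 5, seed=2)
        bad = cohort.copy()
        bad["variant_count"] = 1
        with pytest.raises(ValueError, match="variant_count"):
            m.genomewide_scan(matrix, bad)

    def test_subject_mismatch_rejected(self, strong_cohort):
        cohort, u = strong_cohort
        matrix = self._scan_panel(cohort, u, 5, seed=2)
        matrix.columns = [f"X{i}" for i in range(len(cohort))]
        with pytest.raises(ValueError, match="subject"):
            m.genomewide_scan(matrix, cohort)

    def test_multiplicity_columns_optional(self, strong_cohort):
        cohort, u = strong_cohort
        matrix = self._scan_panel(cohort, u, 10, seed=4)
        plain, _ = m.genomewide_scan(matrix, cohort)
        assert "tsls_p_bonferroni" not in plain.columns
        extended, _ = m.genomewide_scan(matrix, cohort, multiplicity=True)
        assert (extended.tsls_p_bonferroni >= extended.tsls_p - 1e-15).all()
        assert extended.tsls_p_bh.between(0, 1).all()


class TestBootstrap:
    def test_zero_noise_ci_collapses(self):
        z = np.tile([0.0, 1, 2], 20)
        a = 6.0 + 0.5 * z
        b = 0.1 + 0.1 * a
        pt, lo, hi = m.bootstrap_delta_beta(b, a, z, n_reps=500, seed=0)
        assert pt == pytest.approx(0.1, abs=1e-10)
        assert hi - lo < 1e-9

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        z = rng.binomial(2, 0.4, 80).astype(float)
        a = 6.5 + 0.3 * z + 0.2 * rng.standard_normal(80)
        b = np.clip(0.1 * a - 0.3 + 0.05 * rng.standard_normal(80), 0, 1)
        r1 = m.bootstrap_delta_beta(b, a, z, n_reps=400, seed=9)
        r2 = m.bootstrap_delta_beta(b, a, z, n_reps=400, seed=9)
        r3 = m.bootstrap_delta_beta(b, a, z, n_reps=400, seed=10)
        assert r1 == r2
        assert r1 != r3

    def test_point_estimate_within_ci_for_wellbehaved_data(self):
        rng = np.random.default_rng(6)
        z = rng.binomial(2, 0.4, 150).astype(float)
        u = rng.standard_normal(150)
        a = 6.5 + 0.3 * z + 0.15 * u + 0.15 * rng.standard_normal(150)
        b = np.clip(0.3 * a - 1.6 + 0.05 * u
                    + 0.04 * rng.standard_normal(150), 0, 1)
        pt, lo, hi = m.bootstrap_delta_beta(b, a, z, n_reps=1000, seed=2)
        assert lo <= pt <= hi

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError, match="200"):
            m.bootstrap_delta_beta([0.1] * 20, [1.0] * 20,
                                   [0, 1] * 10, n_reps=50)

    def test_small_sample_warns(self):
        z = np.array([0.0, 1, 2, 0, 1, 2])
        a = 6.0 + 0.3 * z
        b = 0.05 * a
        with pytest.warns(UserWarning, match="subjects"):
            m.bootstrap_delta_beta(b, a, z, n_reps=300, seed=1)


class TestCompareScans:
    def test_identical_vectors(self):
        v = np.array([0.1, -0.2, 0.5, 0.3])
        comp = m.compare_scans(v, v)
        assert comp.pearson_r == pytest.approx(1.0)

    def test_negated_vectors(self):
        v = np.array([0.1, -0.2, 0.5, 0.3])
        comp = m.compare_scans(v, -v)
        assert comp.pearson_r == pytest.approx(-1.0)

    def test_recovers_population_correlation(self):
        rng = np.random.default_rng(12)
        n = 16_989
        rho = 0.44
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        comp = m.compare_scans(x, y)
        assert comp.pearson_r == pytest.approx(rho, abs=0.02)
        assert comp.r_squared == pytest.approx(rho**2, abs=0.02)
        assert comp.pearson_p < 1e-10

    def test_ranges_and_overlap(self):
        ids = np.array([f"cg{i}" for i in range(6)])
        t = np.array([0.5, -0.4, 0.3, 0.1, -0.05, 0.02])
        o = np.array([0.05, -0.04, 0.3, 0.01, -0.5, 0.002])
        comp = m.compare_scans(t, o, probe_ids=ids, top_k=2)
        assert comp.tsls_range == (-0.4, 0.5)
        assert comp.ols_range == (-0.5, 0.3)
        assert comp.top_tsls == ["cg0", "cg1"]
        assert set(comp.top_ols) == {"cg4", "cg2"}
        assert comp.overlap == len(set(comp.top_tsls) & set(comp.top_ols))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            m.compare_scans([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            m.compare_scans([1.0, 2.0], [0.1, 0.2])
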