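import numpy as np
import pandas as pd
import pytest

from pgstox import (
    SimulationConfig,
    apply_imputation_noise,
    compute_scores,
    fit_survival,
    load_grade_distributions,
    simulate_cohort,
    simulate_covariates_and_survival,
    simulate_genotypes,
    simulate_toxicity,
)
from pgstox.qc import GenotypeCounts, hwe_exact_test
from pgstox.qc import _genotype_counts

from conftest import make_catalog


class TestSimulateGenotypes:
    def test_deterministic_given_seed(self, catalog):
        a = simulate_genotypes(catalog, 50, seed=123)
        b = simulate_genotypes(catalog, 50, seed=123)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.sample_ids == b.sample_ids

    def test_zero_frequency_variant_all_zero(self):
        cat = make_catalog([("rs1", 1.1, 0.0, 1.0)])
        m = simulate_genotypes(cat, 200, seed=0)
        assert np.all(m.dosages == 0.0)

    def test_binomial_moments_at_half(self):
        cat = make_catalog([("rs1", 1.1, 0.5, 1.0)])
        n = 50_000
        m = simulate_genotypes(cat, n, seed=7)
        col = m.dosages[:, 0]
        assert col.mean() == pytest.approx(1.0, abs=3 * np.sqrt(0.5 / n))
        assert col.var(ddof=1) == pytest.approx(
            0.5, abs=3 * 0.5 * np.sqrt(2.0 / (n - 1))
        )

    def test_hwe_holds_across_catalog(self, catalog):
        """Simulated genotypes are in HWE: essentially no exact-test
        rejections at 1e-5 across the 94 variants."""
        m = simulate_genotypes(catalog, 2000, seed=42)
        rejections = 0
        for j in range(m.n_variants):
            p = hwe_exact_test(_genotype_counts(m.dosages[:, j]))
            rejections += p < 1e-5
        assert rejections == 0


class TestImputationNoise:
    def test_perfect_r2_passthrough(self):
        cat = make_catalog([("rs1", 1.1, 0.4, 1.0)])
        m = simulate_genotypes(cat, 500, seed=1)
        noised = apply_imputation_noise(m, cat, seed=2)
        assert np.array_equal(noised.dosages, m.dosages)
        assert not noised.is_imputed[0]

    def test_squared_correlation_matches_r2(self):
        # same r2 as a mid-quality imputed catalog variant
        cat = make_catalog([("rs1", 1.1, 0.43, 0.81)])
        m = simulate_genotypes(cat, 100_000, seed=3)
        noised = apply_imputation_noise(m, cat, seed=4)
        r = np.corrcoef(m.dosages[:, 0], noised.dosages[:, 0])[0, 1]
        assert r**2 == pytest.approx(0.81, abs=0.02)
        assert noised.is_imputed[0]

    def test_variance_deflation_matches_r2(self):
        # pre-clip construction: Var(D) = r2 * 2p(1-p)
        from pgstox.simulate import _noised_dosages

        cat = make_catalog([("rs1", 1.07, 0.34, 0.52)])
        m = simulate_genotypes(cat, 100_000, seed=5)
        rng = np.random.default_rng(6)
        D = _noised_dosages(
            m.dosages, np.array([0.34]), np.array([0.52]), rng
        )
        p = 0.34
        ratio = D[:, 0].var() / (2 * p * (1 - p))
        assert ratio == pytest.approx(0.52, abs=0.03)

    def test_dosages_stay_in_range(self, catalog):
        m = simulate_genotypes(catalog, 2000, seed=8)
        noised = apply_imputation_noise(m, catalog, seed=9)
        assert noised.dosages.min() >= 0.0
        assert noised.dosages.max() <= 2.0


class TestSimulateToxicity:
    def _scores(self, catalog, n, seed=0):
        return compute_scores(simulate_genotypes(catalog, n, seed), catalog)

    def test_null_effect_hits_target_prevalence(self, catalog):
        n = 50_000
        cfg = SimulationConfig(n_samples=n, theta_tox=0.0, target_prevalence=0.30)
        tox = simulate_toxicity(self._scores(catalog, n), cfg, seed=11)
        rate = tox["neutropenia_case"].mean()
        assert rate == pytest.approx(0.30, abs=3 * np.sqrt(0.3 * 0.7 / n))

    def test_grade_strata_respect_case_control_split(self, catalog):
        n = 20_000
        cfg = SimulationConfig(n_samples=n)
        for phenotype, thr in [("neutropenia", 3), ("neuropathy", 2)]:
            tox = simulate_toxicity(
                self._scores(catalog, n), cfg, phenotype=phenotype, seed=12
            )
            cases = tox[tox[f"{phenotype}_case"] == 1]
            controls = tox[tox[f"{phenotype}_case"] == 0]
            assert (cases[f"{phenotype}_grade"] >= thr).all()
            assert (controls[f"{phenotype}_grade"] < thr).all()

    def test_control_grades_proportional_to_observed_counts(self, catalog):
        # neutropenia control grades drawn 733:199:245 for grades 0:1:2
        n = 60_000
        cfg = SimulationConfig(n_samples=n, theta_tox=0.0)
        tox = simulate_toxicity(self._scores(catalog, n), cfg, seed=13)
        controls = tox.loc[tox["neutropenia_case"] == 0, "neutropenia_grade"]
        weights = np.array([733.0, 199.0, 245.0])
        expected = weights / weights.sum()
        observed = controls.value_counts(normalize=True).sort_index().to_numpy()
        n_ctrl = len(controls)
        for g in range(3):
            se = np.sqrt(expected[g] * (1 - expected[g]) / n_ctrl)
            assert observed[g] == pytest.approx(expected[g], abs=3 * se)

    def test_case_grades_proportional_for_neuropathy(self, catalog):
        # neuropathy case grades drawn 304:56 for grades 2:3
        n = 60_000
        cfg = SimulationConfig(n_samples=n, theta_tox=0.0)
        tox = simulate_toxicity(
            self._scores(catalog, n), cfg, phenotype="neuropathy", seed=14
        )
        cases = tox.loc[tox["neuropathy_case"] == 1, "neuropathy_grade"]
        frac3 = (cases == 3).mean()
        expected = 56.0 / 360.0
        se = np.sqrt(expected * (1 - expected) / len(cases))
        assert frac3 == pytest.approx(expected, abs=3 * se)

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(target_prevalence=0.0)

    def test_effect_direction(self, catalog):
        """A protective per-allele effect lowers case rates in the top
        score quartile relative to the bottom quartile."""
        n = 30_000
        cfg = SimulationConfig(n_samples=n, theta_tox=np.log(0.90))
        scores = self._scores(catalog, n)
        tox = simulate_toxicity(scores, cfg, seed=15)
        u = scores.unweighted
        lo, hi = np.quantile(u, [0.25, 0.75])
        rate_low = tox["neutropenia_case"][u <= lo].mean()
        rate_high = tox["neutropenia_case"][u >= hi].mean()
        assert rate_high < rate_low


class TestCovariatesAndSurvival:
    def test_covariate_ranges(self, catalog):
        n = 5000
        cfg = SimulationConfig(n_samples=n)
        scores = compute_scores(simulate_genotypes(catalog, n, 0), catalog)
        cov = simulate_covariates_and_survival(n, cfg, scores, seed=16)
        assert cov["age"].between(25, 75).all()
        assert cov["bmi"].between(16, 45).all()
        assert set(cov["trial"]) <= {"NEAT", "tAnGo", "Neo-tAnGo", "nontrial"}
        assert (cov["rfs_time"] > 0).all()

    def test_null_hazard_gives_flat_association(self, catalog):
        n = 20_000
        cfg = SimulationConfig(n_samples=n, hr_per_allele=1.0)
        scores = compute_scores(simulate_genotypes(catalog, n, 1), catalog)
        cov = simulate_covariates_and_survival(n, cfg, scores, seed=17)
        result = fit_survival(cov.assign(sample_id=scores.sample_ids), scores)
        assert result.ci_low <= 1.0 <= result.ci_high

    def test_hazard_ratio_recovery(self, catalog):
        n = 50_000
        cfg = SimulationConfig(n_samples=n, hr_per_allele=1.02)
        scores = compute_scores(simulate_genotypes(catalog, n, 2), catalog)
        cov = simulate_covariates_and_survival(n, cfg, scores, seed=18)
        result = fit_survival(cov, scores)
        assert result.ci_low <= 1.02 <= result.ci_high

    def test_censor_rate_approximately_attained(self, catalog):
        n = 20_000
        cfg = SimulationConfig(n_samples=n, censor_rate=0.7)
        scores = compute_scores(simulate_genotypes(catalog, n, 3), catalog)
        cov = simulate_covariates_and_survival(n, cfg, scores, seed=19)
        assert (1 - cov["rfs_event"]).mean() == pytest.approx(0.7, abs=0.02)


class TestSimulateCohort:
    def test_bit_identical_replays(self, catalog):
        cfg = SimulationConfig(n_samples=120, seed=99)
        m1, c1 = simulate_cohort(catalog, cfg)
        m2, c2 = simulate_cohort(catalog, cfg)
        assert np.array_equal(m1.dosages, m2.dosages)
        pd.testing.assert_frame_equal(c1, c2)

    def test_grade_fixture_counts_match_printed_table(self):
        grades = load_grade_distributions()
        assert sum(grades.counts["neutropenia"].values()) == 1676
        assert sum(grades.counts["neuropathy"].values()) == 1279
        cases, controls = grades.case_control_counts("neutropenia")
        assert sum(cases.values()) == 499
        cases_np, _ = grades.case_control_counts("neuropathy")
        assert sum(cases_np.values()) == 360
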