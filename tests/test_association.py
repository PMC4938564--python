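import numpy as np
import pandas as pd
import pytest

from pgstox import (
    FitFailure,
    SimulationConfig,
    compute_scores,
    dichotomize,
    fit_score_model,
    fit_survival,
    per_variant_scan,
    simulate_cohort,
    simulate_genotypes,
    simulate_toxicity,
    standardize,
)

from conftest import make_catalog, make_matrix


def _expand_grades(counts: dict[int, int]) -> list[int]:
    out: list[int] = []
    for g, c in counts.items():
        out.extend([g] * c)
    return out


class TestDichotomize:
    def test_neutropenia_printed_distribution_gives_499_cases(self):
        grades = _expand_grades({0: 733, 1: 199, 2: 245, 3: 293, 4: 206})
        case = dichotomize(grades, "neutropenia")
        assert int(case.sum()) == 499
        assert int((case == 0).sum()) == 1177
        assert int(case.sum()) / len(grades) == pytest.approx(0.298, abs=5e-4)

    def test_neuropathy_printed_distribution_gives_360_cases(self):
        grades = _expand_grades({0: 271, 1: 648, 2: 304, 3: 56})
        case = dichotomize(grades, "neuropathy")
        assert int(case.sum()) == 360
        assert int((case == 0).sum()) == 919
        assert int(case.sum()) / len(grades) == pytest.approx(0.281, abs=5e-4)

    def test_grade_two_is_control_for_neutropenia_case_for_neuropathy(self):
        assert dichotomize([2], "neutropenia").iloc[0] == 0
        assert dichotomize([2], "neuropathy").iloc[0] == 1

    def test_missing_grades_propagate_and_counts_conserve(self):
        grades = [0, 1, None, 3, None, 4]
        case = dichotomize(grades, "neutropenia")
        assert case.isna().sum() == 2
        assert int(case.sum()) + int((case == 0).sum()) + case.isna().sum() == 6

    def test_idempotent_on_indicator_scale(self):
        case = dichotomize([0, 1, 2, 3, 4], "neutropenia")
        again = (case >= 1).astype("Int64")  # already 0/1
        assert (case == again).all()

    def test_out_of_range_grade_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            dichotomize([5], "neutropenia")
        with pytest.raises(ValueError, match="outside"):
            dichotomize([4], "neuropathy")


class TestFitScoreModel:
    def _cohort(self, catalog, n, theta, seed, prevalence=0.30):
        cfg = SimulationConfig(
            n_samples=n, theta_tox=theta, target_prevalence=prevalence, seed=seed
        )
        m = simulate_genotypes(catalog, n, seed)
        scores = standardize(compute_scores(m, catalog))
        tox = simulate_toxicity(scores, cfg, seed=seed + 1)
        return scores, tox

    def test_strong_effect_recovered(self, catalog):
        theta = np.log(0.90)
        scores, tox = self._cohort(catalog, 8000, theta, seed=21)
        result = fit_score_model(tox, scores, "neutropenia", "unweighted")
        assert result.scale == "per-allele"
        assert result.ci_low <= np.exp(theta) <= result.ci_high
        assert result.p_value < 1e-6

    def test_wald_ci_brackets_or(self, catalog):
        scores, tox = self._cohort(catalog, 2000, np.log(0.98), seed=22)
        r = fit_score_model(tox, scores, "neutropenia", "unweighted")
        assert r.ci_low <= r.odds_ratio <= r.ci_high
        assert r.n_used == 2000

    def test_per_sd_scale_for_weighted_score(self, catalog):
        scores, tox = self._cohort(catalog, 2000, np.log(0.95), seed=23)
        r = fit_score_model(tox, scores, "neutropenia", "weighted")
        assert r.scale == "per-SD"

    def test_adjusted_fit_close_to_unadjusted_when_covariates_independent(
        self, catalog
    ):
        cfg = SimulationConfig(n_samples=4000, theta_tox=np.log(0.95), seed=24)
        matrix, cohort = simulate_cohort(catalog, cfg)
        scores = standardize(compute_scores(matrix, catalog))
        r_un = fit_score_model(cohort, scores, "neutropenia", "unweighted", False)
        r_ad = fit_score_model(cohort, scores, "neutropenia", "unweighted", True)
        se = (np.log(r_un.ci_high) - np.log(r_un.ci_low)) / (2 * 1.96)
        assert abs(np.log(r_ad.odds_ratio) - np.log(r_un.odds_ratio)) < 3 * se

    def test_rescaling_equivalence_per_10_alleles(self, catalog):
        """exp(10 beta) from the per-allele fit equals the OR from refitting
        on score/10."""
        scores, tox = self._cohort(catalog, 3000, np.log(0.97), seed=25)
        r1 = fit_score_model(tox, scores, "neutropenia", "unweighted")
        scaled = scores.table.copy()
        scaled["unweighted_score"] = scaled["unweighted_score"] / 10.0
        from pgstox.scores import ScoreTable

        r10 = fit_score_model(
            tox, ScoreTable(table=scaled, n_variants=94), "neutropenia",
            "unweighted",
        )
        assert r1.odds_ratio**10 == pytest.approx(r10.odds_ratio, rel=1e-8)

    def test_constant_score_rejected(self):
        cohort = pd.DataFrame(
            {"neutropenia_case": [0, 1] * 20, "sample_id": range(40)}
        )
        from pgstox.scores import ScoreTable

        table = pd.DataFrame(
            {"sample_id": range(40), "unweighted_score": 5.0,
             "weighted_score": 1.0}
        )
        with pytest.raises(FitFailure, match="degenerate"):
            fit_score_model(
                cohort, ScoreTable(table=table, n_variants=1), "neutropenia"
            )

    def test_too_few_cases_rejected(self, catalog):
        scores, tox = self._cohort(catalog, 60, 0.0, seed=26, prevalence=0.05)
        tox["neutropenia_case"] = 0
        tox.loc[:3, "neutropenia_case"] = 1
        with pytest.raises(FitFailure, match="cases"):
            fit_score_model(tox, scores, "neutropenia", "unweighted")


class TestPerVariantScan:
    def test_injected_strong_variant_flagged(self):
        rng = np.random.default_rng(31)
        n = 1676
        cat = make_catalog(
            [("rs_eff", 2.0, 0.3, 1.0)]
            + [(f"rs_null{i}", 1.05, 0.4, 1.0) for i in range(9)]
        )
        G = rng.binomial(2, [0.3] + [0.4] * 9, size=(n, 10)).astype(float)
        logit = -1.2 + np.log(2.0) * (G[:, 0] - 0.6)
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        cohort = pd.DataFrame(
            {"sample_id": range(n), "neutropenia_case": y.astype(int)}
        )
        matrix = make_matrix(G, variant_ids=[r.rsid for r in cat])
        results, failures = per_variant_scan(matrix, cohort, "neutropenia")
        assert not failures
        assert results.iloc[0]["rsid"] == "rs_eff"
        assert bool(results.iloc[0]["significant"])
        assert results["p_value"].is_monotonic_increasing

    def test_monomorphic_variant_recorded_as_failure(self):
        rng = np.random.default_rng(32)
        n = 400
        G = np.column_stack(
            [np.zeros(n), rng.binomial(2, 0.4, n)]
        ).astype(float)
        cohort = pd.DataFrame(
            {"sample_id": range(n),
             "neutropenia_case": rng.integers(0, 2, n)}
        )
        results, failures = per_variant_scan(
            make_matrix(G), cohort, "neutropenia"
        )
        assert "rs1" in failures
        assert len(results) == 1

    def test_null_scan_rarely_flags(self, catalog):
        """Under the null the expected flag count at alpha=5e-4 over 94
        variants is ~0.05 per cohort."""
        cfg = SimulationConfig(n_samples=1676, theta_tox=0.0, seed=33)
        total_flags = 0
        for rep in range(5):
            cfg_r = SimulationConfig(n_samples=1676, theta_tox=0.0, seed=33 + rep)
            matrix, cohort = simulate_cohort(catalog, cfg_r)
            results, _ = per_variant_scan(matrix, cohort, "neutropenia")
            total_flags += int(results["significant"].sum())
        assert total_flags <= 2


class TestFitSurvival:
    def test_per_10_allele_rescaling(self, catalog):
        cfg = SimulationConfig(n_samples=3000, seed=41)
        matrix, cohort = simulate_cohort(catalog, cfg)
        scores = compute_scores(matrix, catalog)
        r = fit_survival(cohort, scores)
        r10 = r.rescaled(10)
        assert r10.hazard_ratio == pytest.approx(r.hazard_ratio**10, rel=1e-12)
        assert r10.per_k_alleles == 10
        # the printed-style rescaling example: 1.02^10 = 1.2190
        assert 1.02**10 == pytest.approx(1.2190, abs=5e-5)

    def test_adjustment_for_neutropenia_runs(self, catalog):
        cfg = SimulationConfig(n_samples=3000, seed=42)
        matrix, cohort = simulate_cohort(catalog, cfg)
        scores = compute_scores(matrix, catalog)
        r = fit_survival(cohort, scores, adjust_for_neutropenia=True)
        assert r.n_events >= 10

    def test_no_events_rejected(self, catalog):
        cfg = SimulationConfig(n_samples=300, seed=43)
        matrix, cohort = simulate_cohort(catalog, cfg)
        cohort["rfs_event"] = 0
        scores = compute_scores(matrix, catalog)
        with pytest.raises(FitFailure, match="events"):
            fit_survival(cohort, scores)
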