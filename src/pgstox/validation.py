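"""Simulation-based calibration checks for the score-association model.

Replicated synthetic cohorts quantify (a) how well the logistic model
recovers a known per-allele effect on the non-weighted score and (b) its
type-I error under the null.  Used by the test suite and the reproduction
script; also handy for planning cohort sizes.
"""

from __future__ import annotations

import numpy as np

from .association import FitFailure, fit_score_model
from .catalog import VariantCatalog
from .scores import compute_scores
from .simulate import SimulationConfig, simulate_genotypes, simulate_toxicity

__all__ = ["replicate_score_fits", "recovery_mean_or", "null_rejection_rate"]


def replicate_score_fits(
    catalog: VariantCatalog,
    theta_tox: float,
    n_samples: int,
    prevalence: float,
    replicates: int,
    seed: int | np.random.SeedSequence,
    phenotype: str = "neutropenia",
) -> np.ndarray:
    """Fit the unadjusted per-allele logistic model on ``replicates``
    independent cohorts; returns an array of (log-OR, p-value) rows.

    Each replicate simulates HWE genotypes at the catalog frequencies,
    builds non-weighted scores, draws case status at the requested
    prevalence with per-allele log-odds ``theta_tox``, and fits case status
    on the score.  Rare non-converged replicates are skipped.
    """
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rows = []
    for child in root.spawn(replicates):
        geno_seed, tox_seed = child.spawn(2)
        matrix = simulate_genotypes(catalog, n_samples, geno_seed)
        scores = compute_scores(matrix, catalog)
        cfg = SimulationConfig(
            n_samples=n_samples,
            theta_tox=theta_tox,
            target_prevalence=prevalence,
        )
        tox = simulate_toxicity(scores, cfg, phenotype=phenotype, seed=tox_seed)
        try:
            result = fit_score_model(tox, scores, phenotype, "unweighted")
        except FitFailure:
            continue
        rows.append((np.log(result.odds_ratio), result.p_value))
    return np.array(rows)


def recovery_mean_or(
    catalog: VariantCatalog,
    theta_tox: float,
    n_samples: int = 1676,
    prevalence: float = 0.30,
    replicates: int = 500,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, int]:
    """Mean recovered per-allele OR (exp of the mean log-OR) over
    replicated cohorts; returns (mean_or, n_replicates_used)."""
    fits = replicate_score_fits(
        catalog, theta_tox, n_samples, prevalence, replicates, seed
    )
    return float(np.exp(fits[:, 0].mean())), int(len(fits))


def null_rejection_rate(
    catalog: VariantCatalog,
    n_samples: int = 1676,
    prevalence: float = 0.30,
    replicates: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, int]:
    """Fraction of null cohorts (no score effect) whose Wald p falls below
    ``alpha``; returns (rate, n_replicates_used)."""
    fits = replicate_score_fits(
        catalog, 0.0, n_samples, prevalence, replicates, seed
    )
    return float(np.mean(fits[:, 1] < alpha)), int(len(fits))
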