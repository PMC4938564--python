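"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the genotyped chemotherapy cohort: per-variant
risk-allele dosages under Hardy-Weinberg equilibrium at the catalog
frequencies, imputation uncertainty matching each variant's r-squared,
toxicity grades with a controllable score effect and the observed marginal
grade distributions, covariates (age, BMI, trial, ancestry PCs) and
exponential relapse-free survival with a per-allele hazard ratio.

Everything is driven by a single seed through ``numpy.random.SeedSequence``
so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .catalog import VariantCatalog
from .dosage import DosageMatrix
from .scores import ScoreTable

__all__ = [
    "SimulationConfig",
    "GradeDistributions",
    "load_grade_distributions",
    "simulate_genotypes",
    "apply_imputation_noise",
    "simulate_toxicity",
    "simulate_covariates_and_survival",
    "simulate_cohort",
]

# grade >= threshold defines a case
CASE_THRESHOLDS = {"neutropenia": 3, "neuropathy": 2}
GRADE_RANGES = {"neutropenia": (0, 4), "neuropathy": (0, 3)}

_TRIALS = ("NEAT", "tAnGo", "Neo-tAnGo", "nontrial")
_TRIAL_PROBS = (0.40, 0.30, 0.27, 0.03)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort generator.

    Defaults mirror the study conditions: ~30% prevalence of
    moderate-severe toxicity, a per-allele toxicity odds ratio of 0.98 on
    the non-weighted score, and a per-allele relapse hazard ratio of 1.02.
    ``theta_tox`` is the per-allele log-odds of toxicity (ln 0.98 by
    default); effects on the weighted score are whatever this induces.
    """

    n_samples: int = 1676
    seed: int = 0
    theta_tox: float = float(np.log(0.98))
    target_prevalence: float = 0.30
    hr_per_allele: float = 1.02
    censor_rate: float = 0.7
    use_imputation_noise: bool = True
    baseline_hazard: float = 0.05  # events per year at the mean score

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0, 1)")
        if self.hr_per_allele <= 0:
            raise ValueError("hr_per_allele must be positive")
        if not 0.0 < self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in (0, 1)")


@dataclass
class GradeDistributions:
    """Observed toxicity grade counts, per phenotype, used as sampling weights."""

    counts: dict[str, dict[int, int]]

    def case_control_counts(self, phenotype: str) -> tuple[dict, dict]:
        thr = CASE_THRESHOLDS[phenotype]
        dist = self.counts[phenotype]
        cases = {g: c for g, c in dist.items() if g >= thr}
        controls = {g: c for g, c in dist.items() if g < thr}
        return cases, controls


def load_grade_distributions(path: str | Path | None = None) -> GradeDistributions:
    """Load grade counts from TSV (phenotype, grade, count); defaults to the
    packaged table of observed neutropenia/neuropathy grades."""
    if path is None:
        path = Path(__file__).parent / "data" / "table2_grades.tsv"
    df = pd.read_csv(path, sep="\t", comment="#")
    counts: dict[str, dict[int, int]] = {}
    for row in df.itertuples(index=False):
        counts.setdefault(row.phenotype, {})[int(row.grade)] = int(row.count)
    return GradeDistributions(counts=counts)


def simulate_genotypes(
    catalog: VariantCatalog, n: int, seed: int | np.random.SeedSequence
) -> DosageMatrix:
    """Hard-call dosages under HWE: ``G_j ~ Binomial(2, p_j)``, independent
    across variants and samples."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = catalog.freqs
    G = rng.binomial(2, p, size=(n, len(p))).astype(float)
    return DosageMatrix(
        sample_ids=[f"S{i + 1:06d}" for i in range(n)],
        variant_ids=catalog.rsids,
        dosages=G,
        is_imputed=np.zeros(len(p), dtype=bool),
    )


def _noised_dosages(
    G: np.ndarray, p: np.ndarray, r2: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """The raw (unclipped) imputation-noise construction; see
    :func:`apply_imputation_noise` for the model."""
    noise_sd = np.sqrt(r2 * (1.0 - r2) * 2.0 * p * (1.0 - p))
    e = rng.normal(0.0, 1.0, size=G.shape) * noise_sd
    return 2.0 * p + r2 * (G - 2.0 * p) + e


def apply_imputation_noise(
    matrix: DosageMatrix,
    catalog: VariantCatalog,
    seed: int | np.random.SeedSequence,
) -> DosageMatrix:
    """Degrade hard calls to imputed dosages matching each variant's r².

    For a variant with frequency ``p`` and imputation quality ``r2 < 1`` the
    observed dosage is ``D = 2p + r2 (G - 2p) + e`` with
    ``e ~ Normal(0, r2 (1 - r2) 2p(1-p))``, clipped to [0, 2].  Before
    clipping this gives ``Var(D) = r2 * 2p(1-p)`` (the familiar deflation of
    imputed-dosage variance) and ``corr(D, G) = r``.  Variants with
    ``r2 = 1`` pass through unchanged.  Clipping pulls a little extra
    variance out of low-frequency, low-quality variants; the stated moments
    hold for the pre-clip construction.
    """
    rng = np.random.default_rng(seed)
    sub = catalog.subset(matrix.variant_ids)
    idx = {r: i for i, r in enumerate(sub.rsids)}
    order = [idx[v] for v in matrix.variant_ids]
    p = sub.freqs[order]
    r2 = sub.imputation_r2[order]
    if np.any((r2 <= 0) | (r2 > 1)):
        raise ValueError("imputation r2 must lie in (0, 1]")
    G = matrix.dosages
    D = np.clip(_noised_dosages(G, p, r2, rng), 0.0, 2.0)
    imputed = r2 < 1.0
    D[:, ~imputed] = G[:, ~imputed]
    return DosageMatrix(
        sample_ids=list(matrix.sample_ids),
        variant_ids=list(matrix.variant_ids),
        dosages=D,
        is_imputed=imputed,
    )


def calibrate_intercept(
    centred_scores: np.ndarray, theta: float, prevalence: float
) -> float:
    """Solve ``mean(expit(alpha + theta * s)) = prevalence`` for alpha.

    1-D root finding (Brent) to 1e-6 in the attained prevalence; the
    centred scores define the population over which the marginal rate is
    taken.
    """

    def gap(alpha: float) -> float:
        return float(expit(alpha + theta * centred_scores).mean() - prevalence)

    lo, hi = -40.0, 40.0
    return brentq(gap, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)


def simulate_toxicity(
    scores: ScoreTable,
    cfg: SimulationConfig,
    grades: GradeDistributions | None = None,
    phenotype: str = "neutropenia",
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Draw case status from a logistic model on the score, then a grade.

    Case indicators follow ``logit P(case) = alpha + theta_tox (s - mean s)``
    with ``alpha`` calibrated so the marginal case rate equals
    ``cfg.target_prevalence``; grades are then drawn within the case and
    control strata in proportion to the observed grade counts, so a case
    can never receive a control-stratum grade.  Returns columns
    ``sample_id``, ``<phenotype>_case`` and ``<phenotype>_grade``.
    """
    if grades is None:
        grades = load_grade_distributions()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    s = scores.unweighted.astype(float)
    centred = s - s.mean()
    if cfg.theta_tox != 0.0 and np.all(centred == 0.0):
        raise ValueError("scores are degenerate but theta_tox is nonzero")
    alpha = calibrate_intercept(centred, cfg.theta_tox, cfg.target_prevalence)
    prob = expit(alpha + cfg.theta_tox * centred)
    case = rng.random(prob.shape) < prob
    case_counts, control_counts = grades.case_control_counts(phenotype)

    def draw(stratum_counts: dict[int, int], size: int) -> np.ndarray:
        gs = np.array(sorted(stratum_counts))
        wts = np.array([stratum_counts[g] for g in gs], dtype=float)
        if wts.sum() == 0:
            raise ValueError(f"no grade mass in stratum for {phenotype}")
        return rng.choice(gs, size=size, p=wts / wts.sum())

    grade = np.empty(len(s), dtype=int)
    grade[case] = draw(case_counts, int(case.sum()))
    grade[~case] = draw(control_counts, int((~case).sum()))
    return pd.DataFrame(
        {
            "sample_id": scores.sample_ids,
            f"{phenotype}_case": case.astype(int),
            f"{phenotype}_grade": grade,
        }
    )


def simulate_covariates_and_survival(
    n: int,
    cfg: SimulationConfig,
    scores: ScoreTable,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Covariates plus exponential relapse-free survival.

    Age ~ Normal(50, 8) truncated to [25, 75]; BMI ~ Normal(26, 4.5)
    truncated to [16, 45]; trial multinomial over NEAT / tAnGo / Neo-tAnGo /
    nontrial; pc1, pc2 ~ Normal(0, 1).  Event times are exponential with
    hazard ``h0 * hr_per_allele**(s - mean s)``; independent exponential
    censoring is tuned to censor approximately ``censor_rate`` of samples.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    age = truncnorm.rvs(
        (25 - 50) / 8, (75 - 50) / 8, loc=50, scale=8, size=n, random_state=rng
    )
    bmi = truncnorm.rvs(
        (16 - 26) / 4.5, (45 - 26) / 4.5, loc=26, scale=4.5, size=n,
        random_state=rng,
    )
    trial = rng.choice(_TRIALS, size=n, p=_TRIAL_PROBS)
    pc1 = rng.normal(0.0, 1.0, n)
    pc2 = rng.normal(0.0, 1.0, n)
    s = scores.unweighted.astype(float)
    if len(s) != n:
        raise ValueError("scores length must match n")
    hazard = cfg.baseline_hazard * cfg.hr_per_allele ** (s - s.mean())
    event_time = rng.exponential(1.0 / hazard)
    # competing exponential censoring: P(censor) = c / (c + h) marginally
    c_rate = cfg.baseline_hazard * cfg.censor_rate / (1.0 - cfg.censor_rate)
    censor_time = rng.exponential(1.0 / c_rate, size=n)
    rfs_time = np.minimum(event_time, censor_time)
    rfs_event = (event_time <= censor_time).astype(int)
    return pd.DataFrame(
        {
            "sample_id": scores.sample_ids,
            "age": age,
            "bmi": bmi,
            "trial": trial,
            "pc1": pc1,
            "pc2": pc2,
            "rfs_time": rfs_time,
            "rfs_event": rfs_event,
        }
    )


def simulate_cohort(
    catalog: VariantCatalog,
    cfg: SimulationConfig,
    grades: GradeDistributions | None = None,
) -> tuple[DosageMatrix, pd.DataFrame]:
    """Full cohort: genotypes (optionally noised), both toxicity phenotypes,
    covariates and survival.  Stage generators draw from independent streams
    spawned off ``cfg.seed`` so stages are individually reproducible."""
    from .scores import compute_scores  # local import to avoid cycle at import time

    root = np.random.SeedSequence(cfg.seed)
    s_geno, s_noise, s_neut, s_neur, s_cov = root.spawn(5)
    genotypes = simulate_genotypes(catalog, cfg.n_samples, s_geno)
    observed = (
        apply_imputation_noise(genotypes, catalog, s_noise)
        if cfg.use_imputation_noise
        else genotypes
    )
    # toxicity and survival act on the true genotypes' score
    true_scores = compute_scores(genotypes, catalog)
    neut = simulate_toxicity(true_scores, cfg, grades, "neutropenia", s_neut)
    neur = simulate_toxicity(true_scores, cfg, grades, "neuropathy", s_neur)
    cov = simulate_covariates_and_survival(cfg.n_samples, cfg, true_scores, s_cov)
    cohort = cov.merge(neut, on="sample_id").merge(neur, on="sample_id")
    return observed, cohort
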