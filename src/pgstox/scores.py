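"""Polygenic risk scores: non-weighted and weighted sums of risk-allele dosages.

For patient *i* over catalog variants *j*:

* non-weighted: ``riskscore_i = sum_j G_ij`` (a risk-allele count, one unit
  per allele, range [0, 2J]);
* weighted: ``weightedriskscore_i = sum_j beta_j G_ij`` with
  ``beta_j = ln(OR_j)`` the per-allele log-odds of breast cancer.

The weighted score is additionally standardised to zero mean and unit
sample SD so that associations can be reported per SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import VariantCatalog
from .dosage import DosageMatrix

__all__ = ["ScoreTable", "compute_scores", "standardize", "allele_count_strata"]

_MISSING_POLICIES = ("mean_impute", "skip", "fail")


@dataclass
class ScoreTable:
    """Per-sample polygenic scores.

    ``weighted_score_std`` is absent (None) until :func:`standardize` runs.
    """

    table: pd.DataFrame  # columns: sample_id, unweighted_score, weighted_score
    n_variants: int

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def unweighted(self) -> np.ndarray:
        return self.table["unweighted_score"].to_numpy()

    @property
    def weighted(self) -> np.ndarray:
        return self.table["weighted_score"].to_numpy()

    @property
    def weighted_std(self) -> np.ndarray:
        if "weighted_score_std" not in self.table.columns:
            raise ValueError("scores not standardised yet; call standardize()")
        return self.table["weighted_score_std"].to_numpy()


def compute_scores(
    matrix: DosageMatrix,
    catalog: VariantCatalog,
    missing_policy: str = "mean_impute",
) -> ScoreTable:
    """Sum risk-allele dosages (plain and beta-weighted) per sample.

    Missing dosages are handled per ``missing_policy``:

    * ``"mean_impute"`` (default): substitute the Hardy-Weinberg expectation
      ``2 p_j``, keeping cohort-level score moments unbiased;
    * ``"skip"``: sum over non-missing variants only;
    * ``"fail"``: raise on any missing entry.

    Every matrix variant must be present in the catalog and dosages must be
    oriented to the catalog risk allele.
    """
    if missing_policy not in _MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {_MISSING_POLICIES}")
    unknown = [v for v in matrix.variant_ids if v not in catalog]
    if unknown:
        raise KeyError(f"variants absent from catalog: {unknown[:5]}")
    sub = catalog.subset(matrix.variant_ids)
    idx = {r: i for i, r in enumerate(sub.rsids)}
    order = [idx[v] for v in matrix.variant_ids]
    p = sub.freqs[order]
    w = sub.weights[order]
    G = matrix.dosages
    miss = ~np.isfinite(G)
    if miss.any():
        if missing_policy == "fail":
            raise ValueError(
                f"{int(miss.sum())} missing dosages with missing_policy='fail'"
            )
        G = G.copy()
        if missing_policy == "mean_impute":
            G[miss] = np.broadcast_to(2.0 * p, G.shape)[miss]
        else:  # skip
            G[miss] = 0.0
    table = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "unweighted_score": G.sum(axis=1),
            "weighted_score": G @ w,
        }
    )
    return ScoreTable(table=table, n_variants=matrix.n_variants)


def standardize(scores: ScoreTable) -> ScoreTable:
    """Add ``weighted_score_std``: (weighted - mean) / sample SD (ddof=1)."""
    x = scores.weighted
    if x.size < 2:
        raise ValueError("standardisation requires at least 2 samples")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("weighted score is constant; cannot standardise")
    out = scores.table.copy()
    out["weighted_score_std"] = (x - x.mean()) / sd
    return ScoreTable(table=out, n_variants=scores.n_variants)


def allele_count_strata(
    scores: ScoreTable, low_cut: float, high_cut: float
) -> pd.Series:
    """Label samples by risk-allele count: "low" (< low_cut), "high"
    (> high_cut), "mid" otherwise (boundaries are mid; strict inequalities).
    """
    if not low_cut < high_cut:
        raise ValueError("low_cut must be below high_cut")
    u = scores.unweighted
    labels = np.where(u < low_cut, "low", np.where(u > high_cut, "high", "mid"))
    return pd.Series(labels, index=scores.sample_ids, name="stratum")
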