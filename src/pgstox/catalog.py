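"""Catalog of breast-cancer susceptibility variants and its score algebra.

The catalog holds, per variant, the published per-allele odds ratio for
breast-cancer risk, the cohort risk-allele frequency and the imputation
quality (r-squared).  The per-allele log-odds weight ``beta = ln(OR)`` is
derived at load time and never stored, so a fixture edit cannot drift from
the weights the analysis uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "VariantCatalog",
    "CatalogValidationError",
    "load_catalog",
    "write_catalog",
    "score_moments",
    "bundled_catalog_path",
    "load_bundled_catalog",
]

_REQUIRED_COLUMNS = (
    "rsid",
    "gene",
    "chr",
    "position",
    "risk_allele",
    "odds_ratio",
    "risk_allele_freq",
    "imputation_r2",
)

_VALID_CHROMOSOMES = {str(i) for i in range(1, 23)}


class CatalogValidationError(ValueError):
    """A catalog file or record violates the catalog contract."""


@dataclass(frozen=True)
class VariantRecord:
    """One risk variant: identity, risk allele, effect size and frequency.

    ``weight`` is the natural log of ``published_or`` and is computed in
    ``__post_init__``; positions are 1-based on genome build 37.
    """

    rsid: str
    gene_label: str
    chromosome: str
    position: int
    risk_allele: str
    published_or: float
    risk_allele_freq: float
    imputation_r2: float
    weight: float = field(init=False)

    def __post_init__(self) -> None:
        if self.published_or <= 0:
            raise CatalogValidationError(
                f"{self.rsid}: odds ratio must be positive, got {self.published_or}"
            )
        if not 0.0 <= self.risk_allele_freq <= 1.0:
            raise CatalogValidationError(
                f"{self.rsid}: risk allele frequency {self.risk_allele_freq} "
                "outside [0, 1]"
            )
        if not 0.0 < self.imputation_r2 <= 1.0:
            raise CatalogValidationError(
                f"{self.rsid}: imputation r2 {self.imputation_r2} outside (0, 1]"
            )
        if self.chromosome not in _VALID_CHROMOSOMES:
            raise CatalogValidationError(
                f"{self.rsid}: chromosome {self.chromosome!r} not an autosome label"
            )
        if self.position <= 0:
            raise CatalogValidationError(
                f"{self.rsid}: position must be a positive 1-based coordinate"
            )
        object.__setattr__(self, "weight", math.log(self.published_or))


@dataclass
class VariantCatalog:
    """Ordered collection of :class:`VariantRecord` with unique rsids."""

    records: list[VariantRecord]
    source_note: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.rsid in seen:
                raise CatalogValidationError(f"duplicate rsid {rec.rsid}")
            seen.add(rec.rsid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def __getitem__(self, rsid: str) -> VariantRecord:
        try:
            return self._index[rsid]
        except AttributeError:
            self._index = {r.rsid: r for r in self.records}
            return self._index[rsid]

    def __contains__(self, rsid: str) -> bool:
        return rsid in {r.rsid for r in self.records}

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    @property
    def freqs(self) -> np.ndarray:
        """Risk-allele frequencies, catalog order."""
        return np.array([r.risk_allele_freq for r in self.records])

    @property
    def weights(self) -> np.ndarray:
        """Per-allele log-odds weights beta_j = ln(OR_j), catalog order."""
        return np.array([r.weight for r in self.records])

    @property
    def imputation_r2(self) -> np.ndarray:
        return np.array([r.imputation_r2 for r in self.records])

    def subset(self, rsids: Iterable[str]) -> "VariantCatalog":
        """Catalog restricted to ``rsids``, preserving catalog order."""
        keep = set(rsids)
        return VariantCatalog(
            records=[r for r in self.records if r.rsid in keep],
            source_note=self.source_note,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "gene": [r.gene_label for r in self.records],
                "chr": [r.chromosome for r in self.records],
                "position": [r.position for r in self.records],
                "risk_allele": [r.risk_allele for r in self.records],
                "odds_ratio": [r.published_or for r in self.records],
                "weight": self.weights,
                "risk_allele_freq": self.freqs,
                "imputation_r2": self.imputation_r2,
            }
        )


def _parse_float(value: str, rsid: str, column: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise CatalogValidationError(
            f"{rsid}: column {column!r} is not numeric: {value!r}"
        ) from None


def load_catalog(path: str | Path, source_note: str = "") -> VariantCatalog:
    """Read a tab-separated variant catalog.

    The file must carry a header with the columns ``rsid, gene, chr, position,
    risk_allele, odds_ratio, risk_allele_freq, imputation_r2``; lines starting
    with ``#`` are ignored.  Row order is preserved.  Malformed rows raise
    :class:`CatalogValidationError` naming the offending variant.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogValidationError(
            f"{path.name}: missing required column(s) {missing}"
        )
    records = []
    for row in df.itertuples(index=False):
        rsid = str(row.rsid)
        records.append(
            VariantRecord(
                rsid=rsid,
                gene_label=str(row.gene),
                chromosome=str(row.chr),
                position=int(_parse_float(row.position, rsid, "position")),
                risk_allele=str(row.risk_allele),
                published_or=_parse_float(row.odds_ratio, rsid, "odds_ratio"),
                risk_allele_freq=_parse_float(
                    row.risk_allele_freq, rsid, "risk_allele_freq"
                ),
                imputation_r2=_parse_float(
                    row.imputation_r2, rsid, "imputation_r2"
                ),
            )
        )
    note = source_note or f"loaded from {path.name}"
    return VariantCatalog(records=records, source_note=note)


def write_catalog(catalog: VariantCatalog, path: str | Path) -> None:
    """Write a catalog back to TSV; round-trips with :func:`load_catalog`."""
    df = catalog.to_frame().drop(columns=["weight"])
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def score_moments(catalog: VariantCatalog, weighted: bool) -> tuple[float, float]:
    """Analytic mean and variance of a polygenic score under Hardy-Weinberg.

    With independent dosages ``G_j ~ Binomial(2, p_j)``:

    * non-weighted score: mean ``sum 2 p_j``, variance ``sum 2 p_j (1 - p_j)``
    * weighted score: mean ``sum beta_j 2 p_j``, variance
      ``sum beta_j^2 2 p_j (1 - p_j)``

    Used by the power calculation (score SD) and as an oracle for the
    genotype simulator.
    """
    if len(catalog) == 0:
        raise ValueError("score_moments requires a non-empty catalog")
    p = catalog.freqs
    w = catalog.weights if weighted else np.ones_like(p)
    mean = float(np.sum(w * 2.0 * p))
    variance = float(np.sum(w**2 * 2.0 * p * (1.0 - p)))
    return mean, variance


def bundled_catalog_path() -> Path:
    """Path of the packaged 94-variant catalog fixture."""
    return Path(__file__).parent / "data" / "table1_catalog.tsv"


def load_bundled_catalog() -> VariantCatalog:
    return load_catalog(
        bundled_catalog_path(),
        source_note="94 published breast-cancer risk variants "
        "(per-allele ORs; risk-allele frequencies and imputation r2 "
        "observed in the genotyped chemotherapy cohort)",
    )
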