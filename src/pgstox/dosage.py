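"""Risk-allele dosage matrices and their file formats.

A dosage is the expected risk-allele count in [0, 2] produced by genotype
imputation (a hard genotype call is the special case 0/1/2).  Matrices are
stored dense, samples x variants, with NaN for missing calls.

Two on-disk formats are supported: a TSV matrix (samples in rows, header of
rsids, ``NA`` for missing) and VCF with a per-genotype dosage FORMAT field
(``DS`` by default).  On read, dosages are oriented so that the counted
allele is the catalog risk allele: when the file counts the other allele the
dosage is flipped to ``2 - D``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import VariantCatalog

__all__ = ["DosageMatrix", "DosageError", "read_dosages", "write_dosages"]

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class DosageError(ValueError):
    """Malformed dosage input (bad value range, unresolvable alleles...)."""


@dataclass
class DosageMatrix:
    """Samples x variants matrix of risk-allele dosages.

    ``dosages[i, j]`` is the dosage of sample ``sample_ids[i]`` at variant
    ``variant_ids[j]``; missing entries are NaN.  ``is_imputed[j]`` marks
    variants whose values came from imputation rather than direct genotyping.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    is_imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise DosageError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise DosageError("duplicate variant ids")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 2.0):
            bad = float(finite[(finite < 0) | (finite > 2)][0])
            raise DosageError(f"dosage {bad} outside [0, 2]")
        if self.is_imputed is None:
            self.is_imputed = np.zeros(len(self.variant_ids), dtype=bool)
        else:
            self.is_imputed = np.asarray(self.is_imputed, dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def variant_index(self, rsid: str) -> int:
        try:
            return self._vidx[rsid]
        except AttributeError:
            self._vidx = {v: j for j, v in enumerate(self.variant_ids)}
            return self._vidx[rsid]

    def subset(
        self,
        sample_ids: Sequence[str] | None = None,
        variant_ids: Sequence[str] | None = None,
    ) -> "DosageMatrix":
        rows = (
            np.arange(self.n_samples)
            if sample_ids is None
            else np.array([self.sample_ids.index(s) for s in sample_ids], dtype=int)
        )
        cols = (
            np.arange(self.n_variants)
            if variant_ids is None
            else np.array([self.variant_index(v) for v in variant_ids], dtype=int)
        )
        return DosageMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            variant_ids=[self.variant_ids[j] for j in cols],
            dosages=self.dosages[np.ix_(rows, cols)].copy(),
            is_imputed=self.is_imputed[cols].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.sample_ids, columns=self.variant_ids
        )


def write_dosages(matrix: DosageMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def _read_tsv(path: Path) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], comment="#")
    return DosageMatrix(
        sample_ids=[str(s) for s in df.index],
        variant_ids=[str(v) for v in df.columns],
        dosages=df.to_numpy(dtype=float),
    )


def _read_vcf(path: Path, dosage_field: str) -> tuple[DosageMatrix, dict]:
    """Read dosages from VCF; returns the matrix plus per-variant allele info."""
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        variant_ids: list[str] = []
        alleles: dict[str, tuple[str, str]] = {}
        columns: list[np.ndarray] = []
        for rec in vcf:
            if rec.id is None or rec.alts is None or len(rec.alts) != 1:
                warnings.warn(
                    f"skipping VCF record without id or biallelic alts at "
                    f"{rec.chrom}:{rec.pos}"
                )
                continue
            col = np.full(len(samples), np.nan)
            for i, sample in enumerate(samples):
                value = rec.samples[sample].get(dosage_field)
                if value is not None:
                    col[i] = float(value[0] if isinstance(value, tuple) else value)
            variant_ids.append(rec.id)
            alleles[rec.id] = (rec.ref, rec.alts[0])
            columns.append(col)
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    matrix = DosageMatrix(
        sample_ids=samples, variant_ids=variant_ids, dosages=dosages
    )
    return matrix, alleles


def _orient_to_risk_allele(
    matrix: DosageMatrix,
    catalog: VariantCatalog,
    counted_alleles: dict[str, tuple[str, str]] | None,
) -> DosageMatrix:
    """Flip dosages (D -> 2 - D) where the counted allele is not the risk allele.

    For a TSV matrix no allele metadata exists, so the counted allele is
    trusted to be the risk allele.  For VCF, the ALT allele is the counted
    one; an ALT matching the catalog risk allele passes through, a REF match
    flips, anything else (including strand flips of ambiguous A/T or C/G
    variants, which cannot be resolved from dosage data) drops the variant
    with a warning.
    """
    if counted_alleles is None:
        return matrix
    keep: list[str] = []
    for rsid in matrix.variant_ids:
        if rsid not in catalog:
            warnings.warn(f"{rsid} not in catalog; excluded")
            continue
        risk = catalog[rsid].risk_allele
        ref, alt = counted_alleles[rsid]
        if (ref, alt) in _AMBIGUOUS_PAIRS:
            warnings.warn(
                f"{rsid}: strand-ambiguous alleles {ref}/{alt}; orientation "
                "trusted as-is"
            )
        if alt == risk:
            keep.append(rsid)
        elif ref == risk:
            j = matrix.variant_index(rsid)
            matrix.dosages[:, j] = 2.0 - matrix.dosages[:, j]
            keep.append(rsid)
        elif alt.translate(_COMPLEMENT) == risk:
            warnings.warn(f"{rsid}: counted allele matches risk allele on the "
                          "opposite strand; kept as counted")
            keep.append(rsid)
        else:
            warnings.warn(
                f"{rsid}: neither allele {ref}/{alt} matches risk allele "
                f"{risk}; excluded"
            )
    return matrix.subset(variant_ids=keep)


def read_dosages(
    path: str | Path,
    format: str = "tsv",
    catalog: VariantCatalog | None = None,
    counted_allele: dict[str, str] | None = None,
    dosage_field: str = "DS",
) -> DosageMatrix:
    """Read a dosage matrix from TSV or VCF, oriented to catalog risk alleles.

    Parameters
    ----------
    path:
        Input file.  TSV: samples in rows, rsid header, ``NA`` missing.
        VCF: one biallelic record per variant with a per-sample dosage
        FORMAT field (default ``DS``).
    format:
        ``"tsv"`` or ``"vcf"``.
    catalog:
        When given, dosages are oriented so the counted allele is the
        catalog risk allele (VCF, or TSV plus ``counted_allele``).
    counted_allele:
        Optional rsid -> allele map stating which allele a TSV file counts;
        entries whose allele differs from the catalog risk allele are
        flipped ``D -> 2 - D``.
    """
    path = Path(path)
    if format == "tsv":
        matrix = _read_tsv(path)
        if catalog is not None and counted_allele is not None:
            pairs = {}
            for rsid in matrix.variant_ids:
                if rsid in counted_allele and rsid in catalog:
                    counted = counted_allele[rsid]
                    risk = catalog[rsid].risk_allele
                    # express as (ref, alt)=(other, counted) for the flipper
                    other = risk if counted != risk else "."
                    pairs[rsid] = (other, counted)
                elif rsid in catalog:
                    pairs[rsid] = (".", catalog[rsid].risk_allele)
            matrix = _orient_to_risk_allele(matrix, catalog, pairs)
        return matrix
    if format == "vcf":
        matrix, alleles = _read_vcf(path, dosage_field)
        if catalog is not None:
            matrix = _orient_to_risk_allele(matrix, catalog, alleles)
        return matrix
    raise ValueError(f"unknown dosage format {format!r}")
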