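"""Ranked-gene overrepresentation analysis.

Variants are mapped to genes (one gene per variant), each gene keeps its
most significant variant-level toxicity p-value, genes are ranked by that
p-value, and the top half of the ranking is tested for overrepresentation
of user-supplied gene sets (GMT format) with a one-sided Fisher exact
(hypergeometric upper-tail) test, Bonferroni-corrected over the sets
tested.  The background universe is the full mapped gene list, not the
genome: the ranked list is its own universe.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GeneRanking",
    "EnrichmentResult",
    "load_gene_map",
    "load_gmt",
    "map_and_rank",
    "top_fraction",
    "hypergeom_upper_tail",
    "fisher_overrepresentation",
    "bundled_gene_map_path",
]


@dataclass
class GeneRanking:
    """Genes ordered by their best variant-level association p-value."""

    table: pd.DataFrame  # columns: gene, best_variant, p_value (ascending)
    background_genes: list[str]

    def __post_init__(self) -> None:
        genes = list(self.table["gene"]) if not self.table.empty else []
        if len(set(genes)) != len(genes):
            raise ValueError("ranked genes must be unique")
        if not self.table.empty:
            p = self.table["p_value"].to_numpy()
            if (p[1:] < p[:-1]).any():
                raise ValueError("ranking must be in non-decreasing p order")
        if not set(genes) <= set(self.background_genes):
            raise ValueError("background must contain every ranked gene")

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"]) if not self.table.empty else []


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap_count: int
    list_size: int
    set_size_in_background: int
    background_size: int
    fisher_p: float
    bonferroni_p: float
    overlap_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.overlap_count > min(self.list_size, self.set_size_in_background):
            raise ValueError("overlap exceeds list or set size")
        if self.bonferroni_p < self.fisher_p - 1e-15:
            raise ValueError("bonferroni_p must be >= fisher_p")


def bundled_gene_map_path() -> Path:
    return Path(__file__).parent / "data" / "variant_gene_map.tsv"


def load_gene_map(path: str | Path | None = None) -> dict[str, str]:
    """rsid -> gene mapping from a two-column TSV (header ``rsid, gene``)."""
    if path is None:
        path = bundled_gene_map_path()
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["rsid"].astype(str), df["gene"].astype(str)))


def load_gmt(path: str | Path) -> dict[str, list[str]]:
    """Gene sets from GMT: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def map_and_rank(
    scan: pd.DataFrame, mapping: dict[str, str]
) -> GeneRanking:
    """Collapse a per-variant scan to a ranked gene list.

    Each variant maps to exactly one gene; when several variants share a
    gene the most significant one represents it.  Ties in p are broken by
    rsid lexicographic order (within a gene and between genes), recorded in
    ``best_variant``.  Variants absent from the mapping are excluded with a
    warning.  ``scan`` needs columns ``rsid`` and ``p_value``.
    """
    if scan.empty:
        return GeneRanking(
            table=pd.DataFrame(columns=["gene", "best_variant", "p_value"]),
            background_genes=[],
        )
    rows = []
    for row in scan.itertuples(index=False):
        gene = mapping.get(str(row.rsid))
        if gene is None:
            warnings.warn(f"variant {row.rsid} not in gene mapping; excluded")
            continue
        rows.append({"gene": gene, "rsid": str(row.rsid), "p_value": float(row.p_value)})
    df = pd.DataFrame(rows)
    if df.empty:
        return GeneRanking(
            table=pd.DataFrame(columns=["gene", "best_variant", "p_value"]),
            background_genes=[],
        )
    df = df.sort_values(["p_value", "rsid"], kind="mergesort")
    best = df.groupby("gene", sort=False).first().reset_index()
    best = best.sort_values(["p_value", "rsid"], kind="mergesort").reset_index(
        drop=True
    )
    best = best.rename(columns={"rsid": "best_variant"})[
        ["gene", "best_variant", "p_value"]
    ]
    return GeneRanking(table=best, background_genes=list(best["gene"]))


def top_fraction(ranking: GeneRanking, fraction: float = 0.5) -> list[str]:
    """First ``floor(fraction * length)`` genes of the ranking."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    k = math.floor(fraction * len(ranking.genes))
    return ranking.genes[:k]


def hypergeom_upper_tail(
    overlap: int, list_size: int, set_size: int, background_size: int
) -> float:
    """P(X >= overlap) for X ~ Hypergeom(background, set_size, list_size).

    This is the one-sided Fisher exact p-value of the 2x2 table
    (in-list x in-set) under the overrepresentation alternative.
    """
    if overlap < 0 or list_size < 0 or set_size < 0:
        raise ValueError("counts must be non-negative")
    if max(list_size, set_size) > background_size:
        raise ValueError("margins exceed background size")
    return float(hypergeom.sf(overlap - 1, background_size, set_size, list_size))


def fisher_overrepresentation(
    top_genes: list[str],
    background: list[str],
    gene_sets: dict[str, list[str]],
) -> list[EnrichmentResult]:
    """One-sided Fisher overrepresentation of each gene set in ``top_genes``.

    Sets are intersected with the background before testing; sets with no
    background overlap are skipped with a warning.  Bonferroni correction
    multiplies by the number of sets actually tested.  Results are sorted
    by ``fisher_p``.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background universe is empty")
    top = set(top_genes)
    if not top <= bg:
        raise ValueError("top genes must be a subset of the background")
    tested: list[tuple[str, set[str]]] = []
    for name, members in gene_sets.items():
        in_bg = set(members) & bg
        if not in_bg:
            warnings.warn(f"gene set {name!r} has no background overlap; skipped")
            continue
        tested.append((name, in_bg))
    results = []
    for name, in_bg in tested:
        overlap = sorted(top & in_bg)
        p = hypergeom_upper_tail(len(overlap), len(top), len(in_bg), len(bg))
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap_count=len(overlap),
                list_size=len(top),
                set_size_in_background=len(in_bg),
                background_size=len(bg),
                fisher_p=p,
                bonferroni_p=min(1.0, p * len(tested)),
                overlap_genes=tuple(overlap),
            )
        )
    return sorted(results, key=lambda r: (r.fisher_p, r.set_name))
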