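from __future__ import annotations

import numpy as np
import pytest

from pgstox import (
    DosageMatrix,
    VariantCatalog,
    VariantRecord,
    load_bundled_catalog,
)


@pytest.fixture(scope="session")
def catalog():
    """The packaged 94-variant catalog."""
    return load_bundled_catalog()


def make_catalog(specs) -> VariantCatalog:
    """Small ad-hoc catalog; specs = [(rsid, odds_ratio, freq, r2), ...]."""
    records = [
        VariantRecord(
            rsid=rsid,
            gene_label=f"GENE{i}",
            chromosome="1",
            position=1000 + i,
            risk_allele="A",
            published_or=odds_ratio,
            risk_allele_freq=freq,
            imputation_r2=r2,
        )
        for i, (rsid, odds_ratio, freq, r2) in enumerate(specs)
    ]
    return VariantCatalog(records=records, source_note="test")


def make_matrix(dosages, variant_ids=None, sample_ids=None) -> DosageMatrix:
    dosages = np.asarray(dosages, dtype=float)
    if variant_ids is None:
        variant_ids = [f"rs{j + 1}" for j in range(dosages.shape[1])]
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(dosages.shape[0])]
    return DosageMatrix(
        sample_ids=sample_ids, variant_ids=variant_ids, dosages=dosages
    )


@pytest.fixture
def two_variant_catalog():
    return make_catalog([("rs1", 1.06, 0.3, 1.0), ("rs2", 1.08, 0.6, 1.0)])
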