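"""Variant/sample quality control and the Hardy-Weinberg exact test.

Simulates genotypes with imputation noise, then applies the standard
array-QC rules (missingness >5%, MAF <1%, MAF <5% & missing >1%,
HWE p < 1e-5; samples missing >10%) to a fixed point.
"""

import numpy as np

import pgstox as pg

catalog = pg.load_bundled_catalog()
matrix = pg.simulate_genotypes(catalog, n=2000, seed=7)

# knock out some calls so the missingness rules have something to do
rng = np.random.default_rng(7)
mask = rng.random(matrix.dosages.shape) < 0.01
matrix.dosages[mask] = np.nan

cleaned, report = pg.apply_qc(matrix)
removed = report.variants.loc[~report.variants["pass"]]
print(f"retained {cleaned.n_variants}/{matrix.n_variants} variants, "
      f"{cleaned.n_samples}/{matrix.n_samples} samples")
for row in removed.itertuples(index=False):
    print(f"  removed {row.rsid}: {row.reasons} "
          f"(MAF {row.maf:.4f}, missing {row.missing_fraction:.3f})")

# the exact test itself: a gross heterozygote deficit is rejected hard
p = pg.hwe_exact_test(pg.GenotypeCounts(n_hom_major=57, n_het=14, n_hom_minor=50))
print(f"HWE exact p for (57 hom / 14 het / 50 hom): {p:.3g} "
      "(a deficit like this flags genotyping error)")

pcs = pg.compute_pcs(cleaned, k=2)
print(f"PC1 SD {pcs['pc1'].std():.2f} — in a single homogeneous population "
      "the PCs carry no structure, they are just covariates for the models")
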