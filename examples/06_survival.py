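"""Risk-allele count versus relapse-free survival.

Simulates a cohort with a per-allele hazard ratio of 1.02, fits a Cox
model of relapse-free survival on the allele count, and rescales to the
per-10-allele hazard ratio.  Also shows the <80 / >90 allele strata used
for Kaplan-Meier comparison.
"""

import pgstox as pg

catalog = pg.load_bundled_catalog()
cfg = pg.SimulationConfig(n_samples=20_000, hr_per_allele=1.02, seed=9)
matrix, cohort = pg.simulate_cohort(catalog, cfg)
scores = pg.compute_scores(matrix, catalog)

r = pg.fit_survival(cohort, scores)
r10 = r.rescaled(10)
print(f"per-allele HR {r.hazard_ratio:.4f} ({r.ci_low:.4f}, {r.ci_high:.4f}) "
      f"p={r.p_value:.3g}  [{r.n_events} events / {r.n_used} patients]")
print(f"per-10-allele HR {r10.hazard_ratio:.3f} "
      f"({r10.ci_low:.3f}, {r10.ci_high:.3f})")

strata = pg.allele_count_strata(scores, low_cut=80.0, high_cut=90.0)
print("allele-count strata:", strata.value_counts().to_dict())
print("each extra risk allele multiplies the relapse hazard by ~1.02, so "
      "ten extra alleles raise it by ~22%; the low/high strata feed a "
      "Kaplan-Meier comparison of the extremes")
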