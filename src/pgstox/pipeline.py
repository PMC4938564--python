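"""End-to-end pipeline: simulate/load -> QC -> score -> associate -> enrich
-> power -> survival, with a JSON run manifest.

A run is fully determined by its config and seed: a single
``numpy.random.SeedSequence`` spawns independent per-stage streams, so
rerunning an identical config reproduces every numeric output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    FitFailure,
    fit_score_model,
    fit_survival,
    per_variant_scan,
)
from .catalog import load_bundled_catalog, load_catalog
from .dosage import read_dosages
from .enrichment import (
    fisher_overrepresentation,
    load_gene_map,
    load_gmt,
    map_and_rank,
    top_fraction,
)
from .power import PowerSpec, analytic_power, catalog_score_sd
from .qc import QCThresholds, apply_qc
from .scores import compute_scores, standardize
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of an end-to-end run.

    Either ``dosage_path``/``phenotype_path`` point at input files, or
    ``simulate`` is true and a synthetic cohort is generated from the
    catalog.  Omitted paths fall back to the packaged fixtures (catalog,
    variant-gene mapping, demo gene sets).
    """

    out_dir: str = "pgstox_run"
    seed: int = 42
    simulate: bool = True
    catalog_path: str | None = None
    dosage_path: str | None = None
    dosage_format: str = "tsv"
    phenotype_path: str | None = None
    gene_map_path: str | None = None
    gmt_path: str | None = None
    enrichment: bool = True
    scan_alpha: float = 5e-4
    power_delta: float = 0.1
    power_alpha: float = 0.05
    qc: QCThresholds = field(default_factory=QCThresholds)
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("dosage_path", "phenotype_path"):
                path = getattr(self, name)
                if path is None:
                    raise PipelineError(
                        f"config: {name} required when simulate is false"
                    )
                if not Path(path).exists():
                    raise PipelineError(f"config: {name} does not exist: {path}")
        if self.enrichment and self.gmt_path is not None:
            if not Path(self.gmt_path).exists():
                raise PipelineError(
                    f"config: gmt_path does not exist: {self.gmt_path}"
                )
        if self.enrichment and self.gmt_path is None:
            raise PipelineError(
                "config: gmt_path required when enrichment is enabled "
                "(set enrichment: false to skip)"
            )


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run config; the ``qc`` and ``sim`` blocks map onto
    :class:`QCThresholds` and :class:`SimulationConfig` fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    qc = QCThresholds(**raw.pop("qc", {}))
    sim = SimulationConfig(**raw.pop("sim", {}))
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"config: unknown field(s) {sorted(unknown)}")
    return RunConfig(qc=qc, sim=sim, **raw)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``cfg.out_dir``.

    Artifacts (all TSV except the JSON manifest): variant and sample QC
    reports, score table, score-association grid ({non-weighted, weighted}
    x {unadjusted, adjusted} per phenotype), per-variant scan, gene
    ranking, enrichment results, power summary, survival fits, manifest.
    Returns the manifest dict.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load_catalog"
    try:
        catalog = (
            load_catalog(cfg.catalog_path)
            if cfg.catalog_path
            else load_bundled_catalog()
        )

        stage = "inputs"
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
        if cfg.simulate:
            matrix, cohort = simulate_cohort(catalog, sim_cfg)
        else:
            matrix = read_dosages(
                cfg.dosage_path, format=cfg.dosage_format, catalog=catalog
            )
            cohort = pd.read_csv(cfg.phenotype_path, sep="\t", comment="#")
            cohort = (
                cohort.set_index("sample_id").loc[matrix.sample_ids].reset_index()
            )

        stage = "qc"
        matrix_qc, report = apply_qc(matrix, thresholds=cfg.qc)
        cohort = (
            cohort.set_index("sample_id").loc[matrix_qc.sample_ids].reset_index()
        )
        _write(report.variants, out / "qc_variants.tsv")
        _write(report.samples, out / "qc_samples.tsv")

        stage = "score"
        scores = standardize(compute_scores(matrix_qc, catalog))
        _write(scores.table, out / "scores.tsv")

        stage = "associate"
        assoc_rows = []
        for phenotype in ("neutropenia", "neuropathy"):
            if f"{phenotype}_grade" not in cohort.columns and (
                f"{phenotype}_case" not in cohort.columns
            ):
                continue
            for score_kind in ("unweighted", "weighted"):
                for adjusted in (False, True):
                    try:
                        r = fit_score_model(
                            cohort, scores, phenotype, score_kind, adjusted
                        )
                        assoc_rows.append(
                            {
                                "phenotype": phenotype,
                                "score": score_kind,
                                "adjusted": adjusted,
                                "scale": r.scale,
                                "odds_ratio": r.odds_ratio,
                                "ci_low": r.ci_low,
                                "ci_high": r.ci_high,
                                "p_value": r.p_value,
                                "n_used": r.n_used,
                            }
                        )
                    except FitFailure as exc:
                        assoc_rows.append(
                            {
                                "phenotype": phenotype,
                                "score": score_kind,
                                "adjusted": adjusted,
                                "scale": "",
                                "odds_ratio": np.nan,
                                "ci_low": np.nan,
                                "ci_high": np.nan,
                                "p_value": np.nan,
                                "n_used": 0,
                                "note": str(exc),
                            }
                        )
        _write(pd.DataFrame(assoc_rows), out / "score_associations.tsv")

        stage = "scan"
        scan, scan_failures = per_variant_scan(
            matrix_qc, cohort, "neutropenia", adjusted=False, alpha=cfg.scan_alpha
        )
        _write(scan, out / "variant_scan.tsv")

        stage = "enrich"
        enrich_df = pd.DataFrame()
        ranking_df = pd.DataFrame()
        if cfg.enrichment:
            mapping = load_gene_map(cfg.gene_map_path)
            ranking = map_and_rank(scan, mapping)
            ranking_df = ranking.table
            top = top_fraction(ranking, 0.5)
            sets = load_gmt(cfg.gmt_path)
            results = fisher_overrepresentation(
                top, ranking.background_genes, sets
            )
            enrich_df = pd.DataFrame(
                [
                    {
                        "set_name": r.set_name,
                        "overlap_count": r.overlap_count,
                        "list_size": r.list_size,
                        "set_size_in_background": r.set_size_in_background,
                        "background_size": r.background_size,
                        "fisher_p": r.fisher_p,
                        "bonferroni_p": r.bonferroni_p,
                        "overlap_genes": ",".join(r.overlap_genes),
                    }
                    for r in results
                ]
            )
        _write(ranking_df, out / "gene_ranking.tsv")
        _write(enrich_df, out / "enrichment.tsv")

        stage = "power"
        sd = catalog_score_sd(catalog, weighted=True)
        power_rows = []
        for phenotype, n_total in (("neutropenia", 1676), ("neuropathy", 1279)):
            spec = PowerSpec(
                n_total=n_total,
                case_fraction=sim_cfg.target_prevalence,
                mean_difference=cfg.power_delta,
                score_sd=sd,
                alpha=cfg.power_alpha,
            )
            power_rows.append(
                {
                    "phenotype": phenotype,
                    "n_total": n_total,
                    "case_fraction": sim_cfg.target_prevalence,
                    "mean_difference": cfg.power_delta,
                    "score_sd": sd,
                    "alpha": cfg.power_alpha,
                    "power": analytic_power(spec),
                }
            )
        _write(pd.DataFrame(power_rows), out / "power.tsv")

        stage = "survive"
        surv_rows = []
        if {"rfs_time", "rfs_event"} <= set(cohort.columns):
            for adjust in (False, True):
                try:
                    r = fit_survival(cohort, scores, adjust_for_neutropenia=adjust)
                    r10 = r.rescaled(10)
                    surv_rows.append(
                        {
                            "adjusted_for_neutropenia": adjust,
                            "hr_per_allele": r.hazard_ratio,
                            "ci_low": r.ci_low,
                            "ci_high": r.ci_high,
                            "p_value": r.p_value,
                            "hr_per_10_alleles": r10.hazard_ratio,
                            "ci10_low": r10.ci_low,
                            "ci10_high": r10.ci_high,
                            "n_used": r.n_used,
                            "n_events": r.n_events,
                        }
                    )
                except FitFailure as exc:
                    surv_rows.append(
                        {"adjusted_for_neutropenia": adjust, "note": str(exc)}
                    )
        _write(pd.DataFrame(surv_rows), out / "survival.tsv")

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": _config_hash(cfg),
            "n_samples": matrix_qc.n_samples,
            "n_variants": matrix_qc.n_variants,
            "scan_failures": scan_failures,
            "artifacts": sorted(p.name for p in out.glob("*.tsv")),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
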