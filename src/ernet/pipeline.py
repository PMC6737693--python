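"""End-to-end driver: configuration, logging, stage orchestration, manifest.

A single validated configuration (YAML on disk, pydantic in memory) drives
the enabled stages in dependency order — synthetic expression generation →
stratified differential expression → scenario panel + qualitative constraint
check → parameter fit — writing versioned outputs plus a manifest of inputs,
derived seeds and per-file checksums.  One global seed deterministically
derives every stage seed, so a rerun with the same config reproduces every
output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

import ernet
from ernet import de, io
from ernet.estimation import DEFAULT_FREE_PARAMETERS, FitConfig, fit_parameters
from ernet.network import (
    build_reference_model,
    check_qualitative_constraints,
    load_default_parameters,
    run_scenario_panel,
    run_treated_panel,
)
from ernet.synthetic import (
    ExperimentDesign,
    ExprSimConfig,
    NoiseModel,
    TimeCourseDataset,
    generate_expression_matrix,
    generate_timecourses,
)
from ernet.network import Scenario

__all__ = ["PipelineConfig", "run_pipeline", "derive_seed"]

logger = logging.getLogger("ernet.pipeline")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 from one global seed."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


class ExprStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_genes: int = 2000
    n_samples: int = 1019
    marker_gene: str = "ESR1"
    n_up_planted: int = 50
    n_down_planted: int = 50
    effect_log2fc: float = 2.0
    baseline_mean: float = 8.0
    noise_sd: float = 0.5
    low_expr_fraction: float = 0.15


class DEStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_mean: float = 2.0
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    moderated: bool = True
    n_up: int = 50
    n_down: int = 50


class ScenarioStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t_end_h: float = 48.0
    gefitinib_dose_um: float = 20.0
    fulvestrant_dose_um: float = 1.0


class FitStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    free_parameters: list[str] = Field(default_factory=lambda: list(DEFAULT_FREE_PARAMETERS))
    n_starts: int = 4
    noise_cv: float = 0.1
    n_replicates: int = 3
    sample_times_h: list[float] = Field(
        default_factory=lambda: [0.5, 1, 2, 4, 8, 16, 24, 48])
    observed_species: list[str] = Field(
        default_factory=lambda: ["ER", "Notch1", "Hes1", "bCatenin"])


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")
    expression: bool = True
    de: bool = True
    scenarios: bool = True
    fit: bool = True


class PipelineConfig(BaseModel):
    """Validated top-level configuration; unknown fields are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "ernet_out"
    stages: StageToggles = Field(default_factory=StageToggles)
    expression: ExprStageConfig = Field(default_factory=ExprStageConfig)
    de: DEStageConfig = Field(default_factory=DEStageConfig)
    scenarios: ScenarioStageConfig = Field(default_factory=ScenarioStageConfig)
    fit: FitStageConfig = Field(default_factory=FitStageConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(raw)
        except ValidationError:
            raise


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; return the manifest.

    The DE stage requires the expression stage (it consumes its matrix); the
    constraint check is part of the scenario stage.  Outputs and the manifest
    land in ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "thresholds in effect: min_mean=%g, FC>%g, p<%g, Gefitinib %g uM, "
        "Fulvestrant %g uM, T=%g h",
        config.de.min_mean, config.de.fc_threshold, config.de.p_threshold,
        config.scenarios.gefitinib_dose_um, config.scenarios.fulvestrant_dose_um,
        config.scenarios.t_end_h)
    manifest = {
        "package_version": ernet.__version__,
        "config": config.model_dump(),
        "seeds": {},
        "outputs": {},
        "results": {},
    }
    files = {}
    matrix = None

    if config.stages.expression:
        seed = derive_seed(config.seed, "expression")
        manifest["seeds"]["expression"] = seed
        e = config.expression
        sim = ExprSimConfig(
            n_genes=e.n_genes, n_samples=e.n_samples, marker_gene=e.marker_gene,
            n_up_planted=e.n_up_planted, n_down_planted=e.n_down_planted,
            effect_log2fc=e.effect_log2fc, baseline_mean=e.baseline_mean,
            noise_sd=e.noise_sd, low_expr_fraction=e.low_expr_fraction, seed=seed)
        matrix, truth = generate_expression_matrix(sim)
        io.write_matrix(matrix, out / "expression_matrix.tsv")
        truth.to_csv(out / "planted_truth.tsv", sep="\t")
        files["expression_matrix"] = out / "expression_matrix.tsv"
        files["planted_truth"] = out / "planted_truth.tsv"
        logger.info("expression stage: %d genes x %d samples", *matrix.shape)

    if config.stages.de:
        if matrix is None:
            raise ValueError("DE stage requires the expression stage")
        filtered = de.filter_low_expression(matrix, config.de.min_mean)
        labels = de.stratify_by_gene(filtered, config.expression.marker_gene)
        table = de.differential_expression(
            filtered, labels, fc_threshold=config.de.fc_threshold,
            p_threshold=config.de.p_threshold, moderated=config.de.moderated)
        top = de.select_top_degs(table, config.de.n_up, config.de.n_down)
        table.to_csv(out / "deg_table.tsv", sep="\t")
        (out / "top_degs.txt").write_text("\n".join(top) + "\n")
        files["deg_table"] = out / "deg_table.tsv"
        files["top_degs"] = out / "top_degs.txt"
        manifest["results"]["de"] = {
            "n_genes_after_filter": int(filtered.shape[0]),
            "group_sizes": {"high": int(len(labels.high)), "low": int(len(labels.low))},
            "n_deg": int(table["is_deg"].sum()),
            "n_top_selected": len(top),
        }
        logger.info("DE stage: %d DEGs (groups %d/%d)", table["is_deg"].sum(),
                    len(labels.high), len(labels.low))

    if config.stages.scenarios:
        model = build_reference_model()
        params = load_default_parameters()
        panel = run_scenario_panel(model, params, t_end=config.scenarios.t_end_h,
                                   t_readout=config.scenarios.t_end_h)
        treated = run_treated_panel(model, params,
                                    gefitinib_dose=config.scenarios.gefitinib_dose_um)
        report = check_qualitative_constraints(panel, treated)
        panel.to_csv(out / "scenario_panel.tsv", sep="\t")
        treated.to_csv(out / "treated_panel.tsv", sep="\t")
        (out / "constraint_report.json").write_text(
            json.dumps({"results": report.results,
                        "details": json.loads(json.dumps(report.details, default=float))},
                       indent=2, sort_keys=True))
        files["scenario_panel"] = out / "scenario_panel.tsv"
        files["treated_panel"] = out / "treated_panel.tsv"
        files["constraint_report"] = out / "constraint_report.json"
        manifest["results"]["constraints"] = report.results
        logger.info("scenario stage: constraints %s",
                    "all pass" if report.all_pass else "FAILURES")

    if config.stages.fit:
        seed = derive_seed(config.seed, "fit")
        manifest["seeds"]["fit"] = seed
        model = build_reference_model()
        params = load_default_parameters()
        f = config.fit
        design = ExperimentDesign(
            observed_species=tuple(f.observed_species),
            sample_times=tuple(f.sample_times_h),
            n_replicates=f.n_replicates,
            scenarios=(Scenario("Stim-E2-Dll1", egf_level=0.01, e2_level=1.0,
                                dll1_level=1.0),))
        dataset = generate_timecourses(
            model, params, design,
            NoiseModel(kind="lognormal_multiplicative", scale=f.noise_cv, seed=seed),
            rtol=1e-6, atol=1e-9)
        fit_cfg = FitConfig(free_parameters=tuple(f.free_parameters),
                            n_starts=f.n_starts, seed=seed)
        result = fit_parameters(model, dataset, fit_cfg)
        io.write_timecourses(dataset.data, out / "timecourses.tsv")
        (out / "fit_result.json").write_text(json.dumps({
            "best_free": result.best_free,
            "objective": result.objective,
            "true_values": {k: dataset.generating_params[k] for k in f.free_parameters},
        }, indent=2, sort_keys=True))
        result.residual_table.to_csv(out / "fit_residuals.tsv", sep="\t", index=False)
        files["timecourses"] = out / "timecourses.tsv"
        files["fit_result"] = out / "fit_result.json"
        files["fit_residuals"] = out / "fit_residuals.tsv"
        manifest["results"]["fit_objective"] = result.objective
        logger.info("fit stage: objective %.4g", result.objective)

    manifest["outputs"] = {k: {"path": str(p), "sha256": _sha256(p)} for k, p in files.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
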