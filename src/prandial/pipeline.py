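"""End-to-end pipeline: read -> validate -> fit -> PoIs -> curate ->
(impute) -> compare -> plots, driven by a single config.

Every intermediate table is written to the run directory as CSV, along
with the curation and imputation reports and a run log recording the seed,
package version and per-stage record counts. Reruns with the same config
and input are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compare import ModelSpec, compare_pois, summarize_pois
from .dataio import StudyTable, read_study, validate_study, write_study
from .errors import ConfigurationError, PipelineError
from .imputation import impute_pois, spread_features
from .pois import CurationRules, curate, extract_pois
from .viz import pca_scores, plot_forest, plot_poi_dotplot, plot_timecourses
from .woodcurve import FitSettings, fit_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative description of one analysis run."""

    input_path: str | None = None
    input_format: str = "wide"
    output_dir: str = "prandial_run"
    reference: str = "REF"
    seed: int = 0
    n_starts: int = 500
    n_refine: int = 10
    t_f: float | None = None            # AUC endpoint; None = last sample time
    curation: dict = field(default_factory=dict)   # {quantity: [lo, hi]}
    impute: bool = False
    impute_targets: tuple[str, ...] = ("auc", "height")
    min_responders: int = 3
    nonresponse_spread_fraction: float = 0.5
    include_period: bool = True
    contrast_types: dict = field(default_factory=dict)
    level: float = 0.95
    adjust: str = "holm"
    plots: bool = True
    aggregation_groups: dict = field(default_factory=dict)
    drop_points: list = field(default_factory=list)  # [participant, intervention, analyte, time]

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def curation_rules(self) -> CurationRules:
        rules = CurationRules()
        for name, (lo, hi) in self.curation.items():
            if name.startswith("param_"):
                rules.param_limits[name.removeprefix("param_")] = (lo, hi)
            else:
                rules.poi_limits[name] = (lo, hi)
        return rules

    def model_spec(self) -> ModelSpec:
        spec = ModelSpec(include_period=self.include_period,
                         level=self.level, adjust=self.adjust)
        spec.contrast_types.update(self.contrast_types)
        return spec


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, table: StudyTable | None = None) -> Path:
    """Execute the full analysis and return the run directory.

    Either ``config.input_path`` (a CSV) or an in-memory StudyTable must be
    given. Any stage's fatal error propagates with the stage named.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "seed": config.seed,
                 "config_hash": _config_hash(config), "stages": {}}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    current = stage("read")
    try:
        if table is None:
            if config.input_path is None:
                raise ConfigurationError("no input_path and no in-memory table")
            table = read_study(config.input_path, format=config.input_format,
                               reference=config.reference)
        if config.drop_points:
            mask = pd.Series(False, index=table.data.index)
            for participant, intervention, analyte, time in config.drop_points:
                mask |= ((table.data["participant"].astype(str) == str(participant))
                         & (table.data["intervention"] == intervention)
                         & (table.data["analyte"] == analyte)
                         & (table.data["time"] == float(time)))
            table = StudyTable(table.data[~mask].reset_index(drop=True),
                               table.reference_intervention, [])
            log["stages"]["dropped_points"] = int(mask.sum())
        write_study(table, outdir / "study_long.csv", format="long")
        log["stages"]["records"] = len(table)

        current = stage("validate")
        report = validate_study(table)
        report.to_csv(outdir / "validation_report.csv", index=False)
        log["stages"]["unfittable_series"] = int((~report["fittable"]).sum())

        current = stage("fit")
        settings = FitSettings(n_starts=config.n_starts, n_refine=config.n_refine,
                               seed=config.seed)
        fits = fit_all(table, settings)
        fits.to_csv(outdir / "fits.csv", index=False)
        log["stages"]["fits"] = len(fits)
        log["stages"]["fit_failures"] = int((~fits["converged"]).sum())

        current = stage("pois")
        pois = extract_pois(fits, t_f=config.t_f)
        pois.to_csv(outdir / "pois_raw.csv", index=False)

        current = stage("curate")
        curated, cur_report = curate(pois, fits, config.curation_rules())
        curated.to_csv(outdir / "pois_curated.csv", index=False)
        cur_report.to_csv(outdir / "curation_report.csv", index=False)
        log["stages"]["curated_values"] = len(cur_report)

        analysis_pois = curated
        log["analysis"] = "responders only"
        if config.impute:
            current = stage("impute")
            features = spread_features(table)
            features.to_csv(outdir / "spread_features.csv", index=False)
            analysis_pois, imp_report = impute_pois(
                curated, features, targets=config.impute_targets,
                min_responders=config.min_responders,
                nonresponse_spread_fraction=config.nonresponse_spread_fraction)
            analysis_pois.to_csv(outdir / "pois_imputed.csv", index=False)
            imp_report.to_csv(outdir / "imputation_report.csv", index=False)
            log["stages"]["imputed_values"] = len(imp_report)
            log["analysis"] = "responders + imputed non-responders"

        current = stage("summarize")
        summarize_pois(analysis_pois).to_csv(outdir / "poi_summary.csv", index=False)

        current = stage("compare")
        spec = config.model_spec()
        results = compare_pois(analysis_pois, table.reference_intervention, spec)
        results.to_csv(outdir / "comparisons.csv", index=False)
        log["stages"]["contrasts"] = len(results)

        if config.plots:
            current = stage("plots")
            import matplotlib.pyplot as plt
            sel = table.participants[:3]
            plot_timecourses(table, sel, table.analyte_roster, fits,
                             path=outdir / "timecourses.png")
            try:
                scores, _ = pca_scores(table, path=outdir / "pca_scores.png")
                scores.to_csv(outdir / "pca_scores.csv", index=False)
            except ConfigurationError:
                pass
            plot_poi_dotplot(pois, curated, path=outdir / "poi_dotplot.png")
            if len(results):
                plot_forest(results, path=outdir / "forest.png")
            plt.close("all")
    except Exception as exc:
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return outdir
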