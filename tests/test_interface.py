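import hashlib
import json
from pathlib import Path

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from prandial.cli import main as cli_main
from prandial.errors import ConfigurationError, PipelineError
from prandial.pipeline import PipelineConfig, run_pipeline
from prandial.viz import (pca_scores, plot_forest, plot_poi_dotplot,
                          plot_timecourses)


@pytest.fixture(autouse=True)
def _close_figures():
    yield
    plt.close("all")


class TestPlots:
    def test_timecourse_panel_grid(self, sim_study, sim_fits, tmp_path):
        table, _ = sim_study
        path = tmp_path / "tc.png"
        fig = plot_timecourses(table, table.participants[:3],
                               table.analyte_roster, sim_fits, path=path)
        assert path.exists()
        assert len(fig.axes) >= 27  # 9 analytes x 3 participants

    def test_unknown_selection_rejected(self, sim_study):
        table, _ = sim_study
        with pytest.raises(ConfigurationError):
            plot_timecourses(table, ["NOBODY"], table.analyte_roster)

    def test_input_table_not_mutated(self, sim_study):
        table, _ = sim_study
        before = table.data.copy()
        plot_timecourses(table, table.participants[:1], table.analyte_roster[:1])
        pd.testing.assert_frame_equal(table.data, before)

    def test_dotplot_drops_curated_values(self, sim_study, sim_fits, tmp_path):
        from prandial.pois import extract_pois
        pois = extract_pois(sim_fits)
        curated = pois.copy()
        curated.loc[0, "time2max"] = np.nan
        fig = plot_poi_dotplot(pois, curated, path=tmp_path / "dp.png")
        assert (tmp_path / "dp.png").exists()

    def test_forest_highlights_and_null_lines(self, tmp_path):
        results = pd.DataFrame({
            "analyte": ["Leu", "Lys"], "poi": ["auc", "auc"],
            "contrast": ["A vs REF"] * 2, "type": ["ratio", "ratio"],
            "estimate": [1.3, 1.05], "ci_low": [1.1, 0.9],
            "ci_high": [1.5, 1.2], "p_raw": [0.01, 0.4],
            "p_adjusted": [0.02, 0.4], "n_used": [36, 36],
            "df": [20.0, 20.0], "df_method": ["satterthwaite"] * 2,
        })
        fig = plot_forest(results, path=tmp_path / "forest.png")
        ax = fig.axes[0]
        # dashed null line at 1 for ratio results
        assert any(line.get_linestyle() == "--" and
                   np.allclose(line.get_xdata(), 1.0) for line in ax.lines)
        # the CI excluding 1 is highlighted
        colors = {line.get_color() for line in ax.lines}
        assert "red" in colors and "black" in colors


class TestPCA:
    def test_row_counts_per_arrangement(self, sim_study):
        table, _ = sim_study
        scores36, _ = pca_scores(table, "per-participant-intervention")
        assert len(scores36) == 36
        scores12, _ = pca_scores(table, "per-participant")
        assert len(scores12) == 12
        scores324, _ = pca_scores(table, "per-series")
        assert len(scores324) == 324

    def test_scores_match_direct_svd_oracle(self, sim_study):
        from sklearn.decomposition import PCA

        table, _ = sim_study
        scores, _ = pca_scores(table, "per-participant-intervention",
                               centering="per-row")
        mat = table.data.pivot_table(
            index=["participant", "intervention"], columns=["analyte", "time"],
            values="value", aggfunc="first", observed=True)
        X = mat.to_numpy(float)
        X = X - X.mean(axis=1, keepdims=True)
        ref = PCA(n_components=2).fit_transform(X)
        got = scores[["PC1", "PC2"]].to_numpy()
        for k in range(2):  # signs are arbitrary per component
            assert (np.allclose(got[:, k], ref[:, k], atol=1e-8)
                    or np.allclose(got[:, k], -ref[:, k], atol=1e-8))

    def test_interventions_separate_on_first_component(self, sim_study):
        table, _ = sim_study
        scores, _ = pca_scores(table, "per-participant-intervention")
        spread_between = scores.groupby("intervention")["PC1"].mean().std()
        spread_within = scores.groupby("intervention")["PC1"].std().mean()
        assert spread_between > spread_within

    def test_too_few_rows_rejected(self, tiny_table):
        with pytest.raises(ConfigurationError):
            pca_scores(tiny_table, "per-participant")


def _hash_tables(rundir: Path) -> dict:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(rundir.glob("*.csv"))}


class TestPipeline:
    def test_run_produces_expected_tables(self, sim_study, tmp_path):
        table, _ = sim_study
        cfg = PipelineConfig(output_dir=str(tmp_path / "run"), n_starts=25,
                             n_refine=2, seed=1, plots=False)
        rundir = run_pipeline(cfg, table=table)
        fits = pd.read_csv(rundir / "fits.csv")
        pois = pd.read_csv(rundir / "pois_curated.csv")
        results = pd.read_csv(rundir / "comparisons.csv")
        assert len(fits) == 324 and len(pois) == 324 and len(results) == 54
        log = json.loads((rundir / "run_log.json").read_text())
        assert log["seed"] == 1
        assert log["analysis"] == "responders only"

    def test_rerun_is_bit_identical(self, sim_study, tmp_path):
        table, _ = sim_study
        h = []
        for name in ("r1", "r2"):
            cfg = PipelineConfig(output_dir=str(tmp_path / name), n_starts=25,
                                 n_refine=2, seed=9, plots=False)
            h.append(_hash_tables(run_pipeline(cfg, table=table)))
        assert h[0] == h[1]

    def test_impute_toggle_controls_report(self, sim_study, tmp_path):
        table, _ = sim_study
        cfg = PipelineConfig(output_dir=str(tmp_path / "imp"), n_starts=25,
                             n_refine=2, seed=1, impute=True, plots=False)
        rundir = run_pipeline(cfg, table=table)
        assert (rundir / "imputation_report.csv").exists()
        log = json.loads((rundir / "run_log.json").read_text())
        assert "imputed" in log["analysis"]

    def test_stage_failure_names_stage(self, tmp_path):
        cfg = PipelineConfig(input_path=str(tmp_path / "nope.csv"),
                             output_dir=str(tmp_path / "x"))
        with pytest.raises(PipelineError, match="read"):
            run_pipeline(cfg)

    def test_config_round_trip_from_yaml(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("reference: REF\nseed: 3\nn_starts: 10\n"
                        "curation:\n  height: [0, 2000]\n")
        cfg = PipelineConfig.from_file(path)
        assert cfg.seed == 3
        assert cfg.curation_rules().poi_limits["height"] == (0, 2000)
        bad = tmp_path / "bad.yaml"
        bad.write_text("not_a_key: 1\n")
        with pytest.raises(ConfigurationError):
            PipelineConfig.from_file(bad)


class TestCLI:
    def test_simulate_validate_fit_chain(self, tmp_path):
        runner = CliRunner()
        study = tmp_path / "study.csv"
        r = runner.invoke(cli_main, ["simulate", "--seed", "4", "--out",
                                     str(study)])
        assert r.exit_code == 0, r.output
        assert "3240" in r.output
        r = runner.invoke(cli_main, ["validate", str(study), "--reference", "REF"])
        assert r.exit_code == 0, r.output
        fits = tmp_path / "fits.csv"
        r = runner.invoke(cli_main, ["fit", str(study), "--reference", "REF",
                                     "--n-starts", "20", "--seed", "4",
                                     "--out", str(fits)])
        assert r.exit_code == 0, r.output
        assert pd.read_csv(fits).shape[0] == 324

    def test_run_subcommand(self, tmp_path):
        runner = CliRunner()
        study = tmp_path / "study.csv"
        runner.invoke(cli_main, ["simulate", "--seed", "4", "--out", str(study)])
        cfg = tmp_path / "cfg.json"
        cfg.write_text(json.dumps({
            "input_path": str(study), "input_format": "wide",
            "output_dir": str(tmp_path / "run"), "reference": "REF",
            "seed": 4, "n_starts": 20, "n_refine": 2, "plots": False}))
        r = runner.invoke(cli_main, ["run", "--config", str(cfg)])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "run" / "comparisons.csv").exists()
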