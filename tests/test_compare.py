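import numpy as np
import pandas as pd
import pytest

from prandial.compare import (ModelSpec, compare_pois, contrasts_vs_reference,
                              fit_poi_model, summarize_pois)
from prandial.errors import ConfigurationError

KEYS = ["participant", "intervention", "analyte", "period"]


def crossover_pois(effects: dict, n=12, sigma_p=0.0, sigma_e=0.0, seed=0,
                   analyte="Leu", poi="height", period_effect=0.0):
    """Balanced 3x3 crossover PoI frame with additive intervention effects."""
    rng = np.random.default_rng(seed)
    levels = list(effects)
    rows = []
    for i in range(n):
        u = rng.normal(0, sigma_p)
        for p in range(3):
            lev = levels[(i + p) % 3]
            val = effects[lev] + u + period_effect * p + rng.normal(0, sigma_e)
            rows.append((f"P{i:02d}", lev, analyte, p + 1, val))
    df = pd.DataFrame(rows, columns=KEYS + [poi])
    for other in {"auc", "height", "time2max"} - {poi}:
        df[other] = np.nan
    df["t_f"] = 180.0
    return df


class TestFitPoiModel:
    def test_balanced_zero_noise_effects_are_group_mean_differences(self):
        pois = crossover_pois({"REF": 100.0, "A": 110.0, "B": 90.0})
        fit = fit_poi_model(pois, "height", "Leu", "REF")
        assert fit.coef["intervention[A]"] == pytest.approx(10.0, abs=1e-8)
        assert fit.coef["intervention[B]"] == pytest.approx(-10.0, abs=1e-8)

    def test_variance_components_recovered(self):
        # moderate simulation: 50 participants, known sd_p / sd_e
        sigma_p, sigma_e = 8.0, 4.0
        est_p, est_e = [], []
        for rep in range(60):
            pois = crossover_pois({"REF": 100.0, "A": 100.0, "B": 100.0},
                                  n=50, sigma_p=sigma_p, sigma_e=sigma_e,
                                  seed=rep)
            fit = fit_poi_model(pois, "height", "Leu", "REF")
            est_p.append(fit.sigma2_participant)
            est_e.append(fit.sigma2_residual)
        assert np.mean(est_p) == pytest.approx(sigma_p**2, rel=0.25)
        assert np.mean(est_e) == pytest.approx(sigma_e**2, rel=0.25)

    def test_period_term_optional_and_harmless_without_period_effect(self):
        pois = crossover_pois({"REF": 100.0, "A": 105.0, "B": 95.0},
                              sigma_p=5.0, sigma_e=2.0, seed=3)
        with_p = fit_poi_model(pois, "height", "Leu", "REF", ModelSpec())
        without = fit_poi_model(pois, "height", "Leu", "REF",
                                ModelSpec(include_period=False))
        # balanced rotation: Period orthogonal to Intervention
        assert with_p.coef["intervention[A]"] == pytest.approx(
            without.coef["intervention[A]"], abs=1e-6)

    def test_insufficient_data_returns_none(self):
        pois = crossover_pois({"REF": 100.0, "A": 110.0, "B": 90.0}, n=2)
        assert fit_poi_model(pois, "height", "Leu", "REF") is None

    def test_nonpositive_values_dropped_under_log(self):
        pois = crossover_pois({"REF": 100.0, "A": 110.0, "B": 90.0}, poi="auc")
        pois.loc[0, "auc"] = -1.0
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_poi_model(pois, "auc", "Leu", "REF")
        assert fit.n_used == len(pois) - 1


class TestContrasts:
    def test_noiseless_doubled_auc_gives_exact_ratio(self):
        pois = crossover_pois({"REF": 1000.0, "A": 2000.0, "B": 1000.0},
                              poi="auc")
        fit = fit_poi_model(pois, "auc", "Leu", "REF")
        res = contrasts_vs_reference([fit])
        row = res[res["contrast"] == "A vs REF"].iloc[0]
        assert row["type"] == "ratio"
        assert row["estimate"] == pytest.approx(2.0, abs=1e-8)
        assert row["ci_high"] - row["ci_low"] == pytest.approx(0.0, abs=1e-6)

    def test_ratio_equals_exponentiated_log_difference(self):
        pois = crossover_pois({"REF": 1000.0, "A": 1400.0, "B": 800.0},
                              sigma_p=100.0, sigma_e=50.0, seed=5, poi="auc")
        ratio_res = compare_pois(pois, "REF", poi_names=("auc",))
        # independent route: difference contrast on manually logged values
        logged = pois.copy()
        logged["auc"] = np.log(logged["auc"])
        spec = ModelSpec(contrast_types={"auc": "difference"})
        diff_res = compare_pois(logged, "REF", spec, poi_names=("auc",))
        merged = ratio_res.merge(diff_res, on=["analyte", "poi", "contrast"],
                                 suffixes=("_r", "_d"))
        assert np.allclose(merged["estimate_r"],
                           np.exp(merged["estimate_d"]), rtol=1e-10)
        assert np.allclose(merged["ci_low_r"],
                           np.exp(merged["ci_low_d"]), rtol=1e-10)

    def test_satterthwaite_matches_classical_df_when_balanced(self):
        pois = crossover_pois({"REF": 100.0, "A": 105.0, "B": 95.0},
                              sigma_p=5.0, sigma_e=2.0, seed=7)
        res = compare_pois(pois, "REF", poi_names=("height",))
        # N - 1 - (n-1) - 2 - 2 = 36 - 16 = 20 for the 12x3 crossover
        assert np.allclose(res["df"], 20.0, atol=0.5)
        assert (res["df_method"] == "satterthwaite").all()

    def test_shift_equivariance_of_difference_contrast(self):
        pois = crossover_pois({"REF": 100.0, "A": 110.0, "B": 90.0},
                              sigma_p=5.0, sigma_e=2.0, seed=9)
        shifted = pois.copy()
        shifted["height"] = shifted["height"] + 500.0
        r1 = compare_pois(pois, "REF", poi_names=("height",))
        r2 = compare_pois(shifted, "REF", poi_names=("height",))
        assert np.allclose(r1["estimate"], r2["estimate"], atol=1e-6)

    def test_scale_equivariance_of_ratio_contrast(self):
        pois = crossover_pois({"REF": 1000.0, "A": 1300.0, "B": 900.0},
                              sigma_p=50.0, sigma_e=30.0, seed=11, poi="auc")
        scaled = pois.copy()
        scaled["auc"] = scaled["auc"] * 7.5
        r1 = compare_pois(pois, "REF", poi_names=("auc",))
        r2 = compare_pois(scaled, "REF", poi_names=("auc",))
        assert np.allclose(r1["estimate"], r2["estimate"], rtol=1e-8)

    def test_unbalanced_data_still_fit(self):
        pois = crossover_pois({"REF": 100.0, "A": 110.0, "B": 90.0},
                              sigma_p=5.0, sigma_e=2.0, seed=13)
        pois = pois.drop(index=[4]).reset_index(drop=True)
        res = compare_pois(pois, "REF", poi_names=("height",))
        assert len(res) == 2
        assert (res["n_used"] == len(pois)).all()
        assert res["estimate"].notna().all()

    def test_holm_adjustment_within_poi_family(self):
        pois = pd.concat([
            crossover_pois({"REF": 100.0, "A": 130.0, "B": 100.0},
                           sigma_p=5.0, sigma_e=3.0, seed=i, analyte=an)
            for i, an in enumerate(["Leu", "Lys", "Val"])],
            ignore_index=True)
        res = compare_pois(pois, "REF", poi_names=("height",))
        assert (res["p_adjusted"] >= res["p_raw"] - 1e-15).all()
        none = compare_pois(pois, "REF", ModelSpec(adjust="none"),
                            poi_names=("height",))
        assert np.allclose(none["p_adjusted"], none["p_raw"])

    def test_ci_bounds_bracket_estimate(self):
        pois = crossover_pois({"REF": 100.0, "A": 110.0, "B": 90.0},
                              sigma_p=5.0, sigma_e=2.0, seed=17)
        res = compare_pois(pois, "REF")
        ok = res["estimate"].notna()
        assert (res.loc[ok, "ci_low"] <= res.loc[ok, "estimate"] + 1e-12).all()
        assert (res.loc[ok, "estimate"] <= res.loc[ok, "ci_high"] + 1e-12).all()

    def test_absent_reference_rejected(self):
        pois = crossover_pois({"REF": 100.0, "A": 110.0, "B": 90.0})
        with pytest.raises(ConfigurationError):
            compare_pois(pois, "MISSING", poi_names=("height",))


class TestSummarize:
    def test_counts_means_sds(self):
        pois = pd.DataFrame({
            "participant": ["P1", "P2", "P3", "P4"],
            "intervention": ["REF", "REF", "REF", "A"],
            "analyte": ["Leu"] * 4, "period": [1, 1, 1, 1],
            "auc": [1.0, 2.0, 3.0, np.nan],
            "height": [np.nan] * 4, "time2max": [np.nan] * 4,
        })
        out = summarize_pois(pois)
        ref_auc = out[(out["intervention"] == "REF") & (out["poi"] == "auc")].iloc[0]
        assert ref_auc["n"] == 3
        assert ref_auc["mean"] == pytest.approx(2.0)
        assert ref_auc["sd"] == pytest.approx(1.0)
        a_auc = out[(out["intervention"] == "A") & (out["poi"] == "auc")].iloc[0]
        assert a_auc["n"] == 0 and np.isnan(a_auc["mean"])
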