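import numpy as np
import pandas as pd
import pytest

from dosagecomp.expression_pipeline import (
    PipelineConfig,
    fit_dosage_models,
    run_pipeline,
    strata_analysis,
    zaa_ratios,
)


def _gene_frame(rng, n=300, tissues=("liver",), age=False):
    rows = []
    for tissue in tissues:
        conc = rng.normal(0, 1, n)
        mbias = rng.normal(0, 1, n)
        ratio = 0.5 - 0.3 * conc + 0.25 * mbias - 0.2 * conc * mbias
        ratio = ratio + rng.normal(0, 0.2, n)
        df = pd.DataFrame(
            {
                "ratio": ratio,
                "concordant": conc,
                "male_bias": mbias,
                "tissue": tissue,
            }
        )
        if age:
            df["stratum_age"] = rng.choice([90.5, 58.0, 52.0], size=n)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


class TestFitDosageModels:
    def test_recovers_planted_signs(self, rng):
        fits = fit_dosage_models(_gene_frame(rng))
        t = fits["liver"].terms
        assert t.loc["concordant", "estimate"] < 0
        assert t.loc["male_bias", "estimate"] > 0
        assert t.loc["concordant:male_bias", "estimate"] < 0
        assert (t.loc[["concordant", "male_bias", "concordant:male_bias"], "p"]
                < 1e-6).all()

    def test_pooled_model_with_tissues(self, rng):
        fits = fit_dosage_models(_gene_frame(rng, tissues=("liver", "heart")))
        assert "pooled" in fits
        assert any("tissue" in term for term in fits["pooled"].terms.index)

    def test_duplicated_predictor_rank_deficiency(self, rng):
        data = _gene_frame(rng, n=50)
        data["male_bias"] = data["concordant"]  # perfectly collinear
        with pytest.raises(ValueError, match="rank"):
            fit_dosage_models(data)

    def test_missing_column(self):
        with pytest.raises(ValueError, match="missing"):
            fit_dosage_models(pd.DataFrame({"ratio": [1.0]}))

    def test_null_type_i_error(self, rng):
        # under a null truth, term p-values reject at the nominal rate
        hits = 0
        n_sims = 200
        for _ in range(n_sims):
            n = 120
            df = pd.DataFrame(
                {
                    "ratio": rng.normal(0, 1, n),
                    "concordant": rng.normal(0, 1, n),
                    "male_bias": rng.normal(0, 1, n),
                    "tissue": "liver",
                }
            )
            p = fit_dosage_models(df)["liver"].terms.loc["concordant", "p"]
            hits += p < 0.05
        # 95% binomial band around 0.05 at 200 sims
        assert 2 <= hits <= 19


class TestStrataAnalysis:
    def test_planted_age_gradient_recovered(self, rng):
        data = _gene_frame(rng, n=400, age=True)
        data["ratio"] += 0.03 * (data["stratum_age"] - data["stratum_age"].mean())
        res = strata_analysis(data)
        t = res["fit"].terms
        assert t.loc["stratum_age", "estimate"] > 0
        assert t.loc["stratum_age", "p"] < 0.01

    def test_null_age_effect_not_significant(self, rng):
        hits = 0
        for _ in range(60):
            res = strata_analysis(_gene_frame(rng, n=150, age=True))
            hits += res["fit"].terms.loc["stratum_age", "p"] < 0.05
        assert hits <= 9  # ~3 expected at the nominal rate

    def test_low_power_stratum_flagged(self, rng):
        data = _gene_frame(rng, n=40, age=True)
        data.loc[data["stratum_age"] == 52.0, "stratum_age"] = 58.0
        data.loc[data.index[:2], "stratum_age"] = 52.0
        res = strata_analysis(data)
        counts = res["strata_counts"]
        assert counts.loc[counts["stratum_age"] == 52.0, "low_power"].item()


class TestZAARatios:
    def test_fully_compensated_and_matched(self):
        # Z genes expression-matched to autosomes in both sexes -> ratios 1
        genes = [f"gA{i}" for i in range(30)] + [f"gZ{i}" for i in range(30)]
        annot = pd.DataFrame(
            {
                "chrom": ["A"] * 30 + ["Z"] * 30,
                "stratum": [0] * 30 + [1, 2, 3] * 10,
            },
            index=genes,
        )
        mean_rpkm = pd.DataFrame({"M": 10.0, "F": 10.0}, index=genes)
        res = zaa_ratios(mean_rpkm, annot)
        assert np.allclose(res["z_aa_male"], 1.0)
        assert np.allclose(res["z_aa_female"], 1.0)
        assert not res["low_power"].any()

    def test_uncompensated_female_deficit(self):
        genes = [f"gA{i}" for i in range(10)] + [f"gZ{i}" for i in range(10)]
        annot = pd.DataFrame(
            {"chrom": ["A"] * 10 + ["Z"] * 10, "stratum": [0] * 10 + [1] * 10},
            index=genes,
        )
        mean_rpkm = pd.DataFrame(
            {"M": [10.0] * 20, "F": [10.0] * 10 + [5.0] * 10}, index=genes
        )
        res = zaa_ratios(mean_rpkm, annot)
        assert res["z_aa_female"].item() == pytest.approx(0.5)
        assert res["z_aa_male"].item() == pytest.approx(1.0)


class TestPipelineEndToEnd:
    def test_determinism(self, small_dataset):
        r1 = run_pipeline(small_dataset.cm)
        r2 = run_pipeline(small_dataset.cm)
        pd.testing.assert_frame_equal(r1.bcv, r2.bcv)
        pd.testing.assert_frame_equal(r1.z_table, r2.z_table)
        assert r1.report == r2.report

    def test_report_and_outputs(self, small_dataset, tmp_path):
        res = run_pipeline(small_dataset.cm)
        assert res.report["n_retained_liver"] > 0
        assert "wilcoxon" in res.report
        res.write(tmp_path / "out")
        assert (tmp_path / "out" / "report.json").exists()
        assert (tmp_path / "out" / "bcv.tsv").exists()

    def test_female_bcv_inflation_detected(self, small_dataset):
        res = run_pipeline(small_dataset.cm)
        w = res.wilcoxon["liver"]["all"]
        assert w["p"] < 0.01
        assert w["V"] < w["n"] * (w["n"] + 1) / 4  # male below female

    def test_liver_regime_sign_recovery(self, recovery_dataset):
        res = run_pipeline(recovery_dataset.cm)
        t = res.fits["liver"].terms
        assert res.fits["liver"].n_obs >= 350
        assert t.loc["concordant", "estimate"] < 0
        assert t.loc["concordant", "p"] < 0.05
        assert t.loc["male_bias", "estimate"] > 0
        assert t.loc["male_bias", "p"] < 0.05
        assert t.loc["concordant:male_bias", "estimate"] < 0
        assert t.loc["concordant:male_bias", "p"] < 0.05
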