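"""End-to-end pipeline: counts -> normalization -> filters -> BCV ->
axes -> regressions -> strata summaries, with a JSON-able run report."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ..synthetic_transcriptome import CountMatrix
from .axes import project_axes
from .bcv import compare_bcv_by_sex, estimate_bcv_by_sex
from .filters import filter_expressed, mf_ratio, sexbias_filter
from .models import fit_dosage_models, strata_analysis, zaa_ratios
from .normalization import rpkm, tmm_factors

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    expression_threshold_log2: float = 1.0
    bcv_prior_weight: float = 10.0
    sexbias_preset: str = "methods"
    tmm_trim_m: float = 0.3
    tmm_trim_a: float = 0.05
    min_stratum_genes: int = 3


@dataclass
class PipelineResult:
    factors: pd.Series
    rpkm: pd.DataFrame
    retained: dict[str, pd.Index]
    ratios: pd.DataFrame  # long: gene_id, tissue, ratio
    bcv: pd.DataFrame  # long: gene_id, tissue, sex, dispersion, bcv, log2_bcv
    wilcoxon: dict
    axes: pd.DataFrame  # long: gene_id, tissue, concordant, male_bias
    z_table: pd.DataFrame  # Z genes entering the dosage models
    fits: dict
    strata: dict
    report: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.factors.to_csv(out / "tmm_factors.tsv", sep="\t", header=True)
        self.ratios.to_csv(out / "mf_ratios.tsv", sep="\t", index=False)
        self.bcv.to_csv(out / "bcv.tsv", sep="\t", index=False)
        self.axes.to_csv(out / "selection_axes.tsv", sep="\t", index=False)
        self.z_table.to_csv(out / "z_genes.tsv", sep="\t", index=False)
        for tissue, genes in self.retained.items():
            pd.Series(genes).to_csv(
                out / f"retained_{tissue}.txt", index=False, header=False
            )
        for name, fit in self.fits.items():
            fit.terms.to_csv(out / f"model_{name}.tsv", sep="\t")
        if "fit" in self.strata:
            self.strata["fit"].terms.to_csv(out / "model_strata.tsv", sep="\t")
        if "zaa" in self.strata and isinstance(self.strata["zaa"], pd.DataFrame):
            self.strata["zaa"].to_csv(out / "zaa_ratios.tsv", sep="\t", index=False)
        (out / "report.json").write_text(json.dumps(self.report, indent=2))


def run_pipeline(cm: CountMatrix, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run every analysis stage on a count matrix.

    Deterministic: identical inputs and config give identical outputs.
    """
    counts, samples, annot = cm.counts, cm.samples, cm.annotation
    report: dict = {"config": asdict(config), "n_genes_input": int(len(counts))}

    # drop genes with no reads anywhere, normalize on autosomal genes only
    counts = counts.loc[counts.sum(axis=1) > 0]
    report["n_genes_detected"] = int(len(counts))
    lib_sizes = cm.counts.sum(axis=0)
    autosomal = counts.index[annot.loc[counts.index, "chrom"] != "Z"]
    factors = tmm_factors(
        counts,
        lib_sizes=lib_sizes,
        use_genes=autosomal,
        trim_m=config.tmm_trim_m,
        trim_a=config.tmm_trim_a,
    )
    eff_lib = lib_sizes * factors
    rpkm_all = rpkm(counts, annot["length"], eff_lib)

    tissues = list(dict.fromkeys(samples["tissue"]))
    retained: dict[str, pd.Index] = {}
    ratio_rows, bcv_rows, axes_rows = [], [], []
    wilcoxon_res: dict[str, dict] = {}
    z_rows = []
    mean_rpkm_by_tissue: dict[str, pd.DataFrame] = {}

    for tissue in tissues:
        t_samples = samples[samples["tissue"] == tissue]
        t_rpkm = rpkm_all[t_samples.index]
        genes = filter_expressed(t_rpkm, t_samples, config.expression_threshold_log2)
        retained[tissue] = genes

        ratios = mf_ratio(t_rpkm.loc[genes], t_samples)
        ratio_rows.append(
            pd.DataFrame(
                {"gene_id": genes, "tissue": tissue, "ratio": ratios.to_numpy()}
            )
        )

        bcv_by_sex = estimate_bcv_by_sex(
            counts.loc[genes, t_samples.index],
            t_samples,
            eff_lib,
            config.bcv_prior_weight,
        )
        for sex in ("M", "F"):
            est = bcv_by_sex[sex]
            tab = est.table.copy()
            tab.insert(0, "gene_id", tab.index)
            tab.insert(1, "tissue", tissue)
            tab.insert(2, "sex", sex)
            bcv_rows.append(tab.reset_index(drop=True))

        wilcoxon_res[tissue] = {
            "all": compare_bcv_by_sex(
                bcv_by_sex["M"].log2_bcv, bcv_by_sex["F"].log2_bcv
            ),
            "autosomal": compare_bcv_by_sex(
                bcv_by_sex["M"].log2_bcv.loc[
                    lambda s: annot.loc[s.index, "chrom"] != "Z"
                ],
                bcv_by_sex["F"].log2_bcv.loc[
                    lambda s: annot.loc[s.index, "chrom"] != "Z"
                ],
            ),
        }

        both = bcv_by_sex["M"].table.index.intersection(bcv_by_sex["F"].table.index)
        axes = project_axes(
            bcv_by_sex["M"].log2_bcv.loc[both], bcv_by_sex["F"].log2_bcv.loc[both]
        )
        ax = axes.table.copy()
        ax.insert(0, "gene_id", ax.index)
        ax.insert(1, "tissue", tissue)
        axes_rows.append(ax.reset_index(drop=True))

        # Z-chromosome genes entering the dosage-compensation models
        z_genes = genes[annot.loc[genes, "chrom"] == "Z"]
        z_unbiased = sexbias_filter(ratios.loc[z_genes], preset=config.sexbias_preset)
        z_model_genes = z_unbiased.intersection(both)
        z_rows.append(
            pd.DataFrame(
                {
                    "gene_id": z_model_genes,
                    "tissue": tissue,
                    "ratio": ratios.loc[z_model_genes].to_numpy(),
                    "concordant": axes.concordant.loc[z_model_genes].to_numpy(),
                    "male_bias": axes.male_bias.loc[z_model_genes].to_numpy(),
                    "stratum": annot.loc[z_model_genes, "stratum"].to_numpy(),
                    "stratum_age": annot.loc[z_model_genes, "stratum_age"].to_numpy(),
                }
            )
        )
        report[f"n_retained_{tissue}"] = int(len(genes))
        report[f"n_z_retained_{tissue}"] = int(len(z_genes))
        report[f"n_z_unbiased_{tissue}"] = int(len(z_unbiased))

        sexes = t_samples["sex"]
        mean_rpkm_by_tissue[tissue] = pd.DataFrame(
            {
                "M": t_rpkm.loc[genes, sexes.index[sexes == "M"]].mean(axis=1),
                "F": t_rpkm.loc[genes, sexes.index[sexes == "F"]].mean(axis=1),
            }
        )

    ratios_long = pd.concat(ratio_rows, ignore_index=True)
    bcv_long = pd.concat(bcv_rows, ignore_index=True)
    axes_long = pd.concat(axes_rows, ignore_index=True)
    z_table = pd.concat(z_rows, ignore_index=True)

    fits = {}
    if len(z_table) >= 10:
        fits = fit_dosage_models(
            z_table.rename(columns={"ratio": "ratio"})[
                ["ratio", "concordant", "male_bias", "tissue"]
            ]
        )
    strata: dict = {}
    z_strat = z_table[z_table["stratum"] > 0]
    if len(z_strat) >= 10 and z_strat["stratum_age"].nunique() > 1:
        # Z:AA uses the first tissue's per-sex means (reported per tissue below)
        strata = strata_analysis(
            z_strat, min_genes=config.min_stratum_genes
        )
        strata["zaa_by_tissue"] = {
            tissue: zaa_ratios(
                mean_rpkm_by_tissue[tissue], annot, config.min_stratum_genes
            )
            for tissue in tissues
        }

    report["wilcoxon"] = {
        t: {k: {kk: (None if (isinstance(vv, float) and np.isnan(vv)) else vv)
                for kk, vv in v.items() if kk != "method"}
            for k, v in res.items()}
        for t, res in wilcoxon_res.items()
    }
    report["n_z_model_obs"] = int(len(z_table))
    for name, fit in fits.items():
        report[f"model_{name}"] = {
            "n_obs": fit.n_obs,
            "r_squared": fit.r_squared,
            "terms": {
                term: {"estimate": float(row["estimate"]), "p": float(row["p"])}
                for term, row in fit.terms.iterrows()
            },
        }

    return PipelineResult(
        factors=factors,
        rpkm=rpkm_all,
        retained=retained,
        ratios=ratios_long,
        bcv=bcv_long,
        wilcoxon=wilcoxon_res,
        axes=axes_long,
        z_table=z_table,
        fits=fits,
        strata=strata,
        report=report,
    )
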