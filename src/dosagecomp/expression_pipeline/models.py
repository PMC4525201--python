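"""Linear models of dosage compensation and strata summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = ["ModelFit", "fit_dosage_models", "strata_analysis", "zaa_ratios"]


@dataclass
class ModelFit:
    """Ordinary-least-squares coefficient table for one fitted formula."""

    formula: str
    terms: pd.DataFrame  # index: term; columns: estimate, se, t, p
    n_obs: int
    r_squared: float

    @classmethod
    def from_results(cls, formula: str, res) -> "ModelFit":
        terms = pd.DataFrame(
            {
                "estimate": res.params,
                "se": res.bse,
                "t": res.tvalues,
                "p": res.pvalues,
            }
        )
        terms.index.name = "term"
        return cls(
            formula=formula,
            terms=terms,
            n_obs=int(res.nobs),
            r_squared=float(res.rsquared),
        )


def _center(data: pd.DataFrame, columns: tuple[str, ...]) -> pd.DataFrame:
    """Mean-center continuous predictors.

    With interaction terms in the model, centering makes each main effect
    the effect at an average gene (rather than at coordinate zero, outside
    the data range) and removes the main-effect/interaction collinearity
    that otherwise inflates standard errors.
    """
    out = data.copy()
    for col in columns:
        out[col] = out[col] - out[col].mean()
    return out


def _fit_ols(formula: str, data: pd.DataFrame) -> ModelFit:
    model = smf.ols(formula, data=data)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {exog.shape[1]}) for {formula!r}; "
            "check for duplicated or collinear predictors"
        )
    return ModelFit.from_results(formula, model.fit())


def fit_dosage_models(data: pd.DataFrame) -> dict[str, ModelFit]:
    """OLS models of the log2 M:F ratio on the selection axes.

    ``data`` needs columns ``ratio``, ``concordant``, ``male_bias`` and
    ``tissue``.  Returns a pooled model with tissue interactions (when
    more than one tissue is present) plus one
    ``ratio ~ concordant * male_bias`` model per tissue.  Genes are
    treated as independent observations.
    """
    required = {"ratio", "concordant", "male_bias", "tissue"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    data = data.dropna(subset=sorted(required))
    data = _center(data, ("concordant", "male_bias"))

    fits: dict[str, ModelFit] = {}
    tissues = data["tissue"].unique()
    if len(tissues) > 1:
        fits["pooled"] = _fit_ols(
            "ratio ~ concordant * male_bias * C(tissue)", data
        )
    for tissue in tissues:
        fits[str(tissue)] = _fit_ols(
            "ratio ~ concordant * male_bias", data[data["tissue"] == tissue]
        )
    return fits


def zaa_ratios(
    mean_rpkm_by_sex: pd.DataFrame,
    annotation: pd.DataFrame,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Median Z:AA expression ratio per stratum and sex.

    ``mean_rpkm_by_sex`` holds per-gene mean RPKM with columns 'M' and
    'F' (one tissue).  For each stratum the median Z-gene expression is
    divided by the median autosomal expression within the same sex;
    strata with fewer than ``min_genes`` genes are flagged low-power.
    """
    is_z = annotation.loc[mean_rpkm_by_sex.index, "chrom"] == "Z"
    auto_med = mean_rpkm_by_sex.loc[~is_z].median()
    rows = []
    strata = annotation.loc[mean_rpkm_by_sex.index[is_z], "stratum"]
    for stratum in sorted(strata.unique()):
        genes = strata.index[strata == stratum]
        z_med = mean_rpkm_by_sex.loc[genes].median()
        rows.append(
            {
                "stratum": int(stratum),
                "n_genes": int(len(genes)),
                "low_power": bool(len(genes) < min_genes),
                "z_aa_male": float(z_med["M"] / auto_med["M"]),
                "z_aa_female": float(z_med["F"] / auto_med["F"]),
            }
        )
    return pd.DataFrame(rows)


def strata_analysis(
    data: pd.DataFrame,
    mean_rpkm_by_sex: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    min_genes: int = 3,
) -> dict:
    """Stratum-age model of dosage compensation plus per-stratum summaries.

    ``data`` needs columns ``ratio``, ``concordant``, ``male_bias``,
    ``tissue`` and ``stratum_age`` (genes without an unambiguous stratum
    must be excluded upstream).  Fits the full-interaction OLS model of the
    ratio on the two selection measures, tissue and stratum age.  When
    per-gene mean RPKM and annotation are supplied, per-stratum Z:AA
    ratios are appended.
    """
    required = {"ratio", "concordant", "male_bias", "tissue", "stratum_age"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    data = data.dropna(subset=sorted(required))
    counts = data.groupby("stratum_age").size()
    data = _center(data, ("concordant", "male_bias", "stratum_age"))
    multi_tissue = data["tissue"].nunique() > 1
    formula = (
        "ratio ~ concordant * male_bias * C(tissue) * stratum_age"
        if multi_tissue
        else "ratio ~ concordant * male_bias * stratum_age"
    )
    fit = _fit_ols(formula, data)

    summary = pd.DataFrame(
        {
            "stratum_age": counts.index,
            "n_obs": counts.to_numpy(),
            "low_power": counts.to_numpy() < min_genes,
        }
    ).reset_index(drop=True)

    out = {"fit": fit, "strata_counts": summary}
    if mean_rpkm_by_sex is not None and annotation is not None:
        out["zaa"] = zaa_ratios(mean_rpkm_by_sex, annotation, min_genes)
    return out
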