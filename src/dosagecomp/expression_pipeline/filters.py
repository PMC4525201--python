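"""Expression-level filters and the male:female expression ratio."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["filter_expressed", "mf_ratio", "sexbias_filter", "SEXBIAS_PRESETS"]

#: retained band of log2(M:F) ratios; 'methods' is the asymmetric printed
#: band, 'figure' the symmetric compensated-gene band used for display
SEXBIAS_PRESETS = {
    "methods": (np.log2(1.0 / 1.25), np.log2(1.25 / 0.5)),
    "figure": (np.log2(0.8), np.log2(1.2)),
}


def filter_expressed(
    rpkm: pd.DataFrame,
    samples: pd.DataFrame,
    threshold_log2: float = 1.0,
) -> pd.Index:
    """Genes expressed in all individuals of at least one sex.

    A gene is retained iff there exists a sex in which every replicate has
    ``log2(RPKM) >= threshold_log2``.  ``rpkm`` columns must belong to a
    single tissue; ``samples`` provides the sex labels.
    """
    sexes = samples.loc[rpkm.columns, "sex"]
    thr = 2.0**threshold_log2
    keep = np.zeros(len(rpkm), dtype=bool)
    for sex in sexes.unique():
        cols = rpkm.columns[sexes == sex]
        keep |= (rpkm[cols] >= thr).all(axis=1).to_numpy()
    return rpkm.index[keep]


def mf_ratio(rpkm: pd.DataFrame, samples: pd.DataFrame) -> pd.Series:
    """Per-gene log2(mean male RPKM / mean female RPKM).

    Averages are taken on the linear scale before logging.  Genes with a
    zero mean in either sex come back as NaN rather than +-inf.
    """
    sexes = samples.loc[rpkm.columns, "sex"]
    m_cols = rpkm.columns[sexes == "M"]
    f_cols = rpkm.columns[sexes == "F"]
    if len(m_cols) == 0 or len(f_cols) == 0:
        raise ValueError("need samples of both sexes")
    mean_m = rpkm[m_cols].mean(axis=1)
    mean_f = rpkm[f_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(mean_m) - np.log2(mean_f)
    ratio[(mean_m <= 0) | (mean_f <= 0)] = np.nan
    return pd.Series(ratio, index=rpkm.index, name="log2_mf_ratio")


def sexbias_filter(
    ratios: pd.Series,
    preset: str = "methods",
    bounds: tuple[float, float] | None = None,
) -> pd.Index:
    """Remove strongly sex-biased genes.

    Retains genes whose log2(M:F) ratio lies inside the closed band;
    ``bounds`` overrides the preset.  NaN ratios are dropped.
    """
    if bounds is None:
        try:
            bounds = SEXBIAS_PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; use one of {sorted(SEXBIAS_PRESETS)}"
            ) from None
    lo, hi = bounds
    ok = (ratios >= lo) & (ratios <= hi)
    return ratios.index[ok.fillna(False)]
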