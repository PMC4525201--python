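"""Projection of sex-specific expression variability onto selection axes.

The pair (log2 BCV_m, log2 BCV_f) is rotated by 45 degrees into a
sexually concordant selection-strength coordinate (growing as both BCVs
shrink) and a male-bias-in-selection coordinate (growing as the male BCV
shrinks and/or the female BCV grows).  The rotation is orthogonal, so
pairwise distances between genes are preserved; the overall 1/sqrt(2)
scale is conventional and does not affect downstream inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SelectionAxes", "project_axes"]

SQRT2 = np.sqrt(2.0)


@dataclass
class SelectionAxes:
    """Per-gene coordinates on the two selection axes."""

    table: pd.DataFrame  # columns: concordant, male_bias

    @property
    def concordant(self) -> pd.Series:
        return self.table["concordant"]

    @property
    def male_bias(self) -> pd.Series:
        return self.table["male_bias"]


def project_axes(log2_bcv_m: pd.Series, log2_bcv_f: pd.Series) -> SelectionAxes:
    """Rotate (log2 BCV_m, log2 BCV_f) into (concordant, male_bias).

    Both series must cover the same genes with finite values; genes
    missing either sex are an error (align and drop beforehand).
    """
    if not log2_bcv_m.index.equals(log2_bcv_f.index):
        common = log2_bcv_m.index.intersection(log2_bcv_f.index)
        if len(common) < len(log2_bcv_m) or len(common) < len(log2_bcv_f):
            raise ValueError("both sexes' log2 BCV must cover the same genes")
        log2_bcv_f = log2_bcv_f.reindex(log2_bcv_m.index)
    m = log2_bcv_m.to_numpy(dtype=float)
    f = log2_bcv_f.to_numpy(dtype=float)
    if np.isnan(m).any() or np.isnan(f).any():
        raise ValueError("missing log2 BCV values; drop incomplete genes first")
    table = pd.DataFrame(
        {
            "concordant": -(m + f) / SQRT2,
            "male_bias": (f - m) / SQRT2,
        },
        index=log2_bcv_m.index,
    )
    return SelectionAxes(table=table)
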