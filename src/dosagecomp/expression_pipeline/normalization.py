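"""Between-library normalization: trimmed mean of M-values and RPKM."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["tmm_factors", "rpkm"]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one library against the reference (log2 scale)."""
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok].astype(float), ref[ok].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic binomial variance of M
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep):
        return 0.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_factors(
    counts: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    use_genes: pd.Index | np.ndarray | None = None,
    ref_sample: str | None = None,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> pd.Series:
    """Weighted trimmed-mean-of-M-values scaling factors, one per sample.

    ``use_genes`` restricts the factor computation to a gene subset (e.g.
    autosomal genes) while ``lib_sizes`` stay those of the full libraries.
    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean, unless given explicitly.  Factors are normalized
    to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = lib_sizes.reindex(counts.columns)
    if (lib_sizes <= 0).any():
        bad = lib_sizes.index[lib_sizes <= 0].tolist()
        raise ValueError(f"all-zero / empty libraries: {bad}")

    sub = counts.loc[use_genes] if use_genes is not None else counts
    mat = sub.to_numpy(dtype=float)
    libs = lib_sizes.to_numpy(dtype=float)

    if ref_sample is None:
        f75 = np.array(
            [np.quantile(mat[:, j] / libs[j], 0.75) for j in range(mat.shape[1])]
        )
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_sample)

    log_f = np.array(
        [
            _tmm_pair(mat[:, j], mat[:, ref_idx], libs[j], libs[ref_idx], trim_m, trim_a)
            for j in range(mat.shape[1])
        ]
    )
    factors = 2.0**log_f
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    lib_sizes: pd.Series,
) -> pd.DataFrame:
    """Reads per kilobase of exon per million mapped reads.

    ``lib_sizes`` should be the *effective* library sizes (raw totals times
    TMM factors).
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    lib_sizes = lib_sizes.reindex(counts.columns)
    if lib_sizes.isna().any() or (lib_sizes <= 0).any():
        raise ValueError("invalid library sizes")
    kb = lengths.to_numpy(dtype=float) / 1000.0
    millions = lib_sizes.to_numpy(dtype=float) / 1e6
    return pd.DataFrame(
        counts.to_numpy(dtype=float) / np.outer(kb, millions),
        index=counts.index,
        columns=counts.columns,
    )
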