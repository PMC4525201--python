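"""Negative-binomial dispersion (BCV) estimation and sex comparison.

Per-gene dispersions are estimated by maximizing the Cox-Reid adjusted
profile likelihood (APL) on a dispersion grid, with weighted-likelihood
shrinkage toward the common (all-gene) dispersion: the per-gene objective
is ``APL_g + (prior_weight / residual_df) * mean-APL-across-genes``, so a
large prior weight collapses every estimate onto the common value.  The
BCV is the square root of the dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy
from scipy.stats import rankdata, wilcoxon

__all__ = [
    "BCVEstimates",
    "estimate_bcv",
    "estimate_bcv_by_sex",
    "compare_bcv_by_sex",
    "wilcoxon_v",
]


@dataclass
class BCVEstimates:
    """Per-gene dispersion/BCV table plus the common dispersion used for
    shrinkage."""

    table: pd.DataFrame  # columns: dispersion, bcv, log2_bcv
    common_dispersion: float
    prior_weight: float

    @property
    def log2_bcv(self) -> pd.Series:
        return self.table["log2_bcv"]


def _nb_apl_curve(
    y: np.ndarray, offsets: np.ndarray, disp_grid: np.ndarray, n_iter: int = 12
) -> np.ndarray:
    """Cox-Reid APL of every gene at every grid dispersion.

    ``y``: (genes, samples) counts; ``offsets``: log effective library
    sizes.  The gene-wise mean model is intercept + offset; the intercept
    MLE is found by Newton iterations (vectorized over genes).
    Returns (genes, len(grid)).
    """
    G, n = y.shape
    s = np.exp(offsets)[None, :]  # (1, n)
    tot_y = y.sum(axis=1)
    out = np.empty((G, disp_grid.size))
    beta0 = np.log(np.maximum(tot_y, 0.5) / s.sum())
    for k, phi in enumerate(disp_grid):
        beta = beta0.copy()
        for _ in range(n_iter):
            mu = s * np.exp(beta)[:, None]
            w = mu / (1.0 + phi * mu)
            score = ((y - mu) / (1.0 + phi * mu)).sum(axis=1)
            info = w.sum(axis=1)
            step = score / np.maximum(info, 1e-12)
            beta = beta + np.clip(step, -5.0, 5.0)
        mu = s * np.exp(beta)[:, None]
        r = 1.0 / phi
        ll = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + xlogy(y, mu / (r + mu))
            + r * np.log(r / (r + mu))
        ).sum(axis=1)
        cr = 0.5 * np.log((mu / (1.0 + phi * mu)).sum(axis=1))
        out[:, k] = ll - cr
    return out


def _interp_argmax(x: np.ndarray, y: np.ndarray) -> float:
    """Quadratic-interpolated argmax of y over x (scalar, one curve)."""
    i = int(np.argmax(y))
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (y0 - 2.0 * y1 + y2)
    if denom >= 0 or abs(denom) < 1e-300:
        return float(x1)
    return float(x1 - 0.5 * ((x2 - x0) / 2.0) * (y2 - y0) / denom)


def estimate_bcv(
    counts: pd.DataFrame,
    eff_lib_sizes: pd.Series,
    prior_weight: float = 10.0,
    grid_bcv: tuple[float, float, int] = (0.005, 3.0, 91),
) -> BCVEstimates:
    """Shrunken per-gene NB dispersion for one tissue x sex group.

    ``counts`` columns are the biological replicates of the group (>= 2);
    genes with zero counts in every replicate are excluded.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 replicates to estimate dispersion")
    keep = counts.sum(axis=1) > 0
    y = counts.loc[keep].to_numpy(dtype=float)
    offsets = np.log(eff_lib_sizes.reindex(counts.columns).to_numpy(dtype=float))
    lo, hi, n_pts = grid_bcv
    disp_grid = np.exp(np.linspace(np.log(lo**2), np.log(hi**2), int(n_pts)))
    apl = _nb_apl_curve(y, offsets, disp_grid)

    shared = apl.mean(axis=0)
    log_grid = np.log(disp_grid)
    common = float(np.exp(_interp_argmax(log_grid, shared)))

    df_resid = counts.shape[1] - 1
    weight = prior_weight / df_resid
    objective = apl + weight * shared[None, :]
    disp = np.exp(
        [_interp_argmax(log_grid, objective[g]) for g in range(y.shape[0])]
    )
    table = pd.DataFrame(
        {
            "dispersion": disp,
            "bcv": np.sqrt(disp),
            "log2_bcv": 0.5 * np.log2(disp),
        },
        index=counts.index[keep],
    )
    return BCVEstimates(table=table, common_dispersion=common, prior_weight=prior_weight)


def estimate_bcv_by_sex(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    eff_lib_sizes: pd.Series,
    prior_weight: float = 10.0,
    grid_bcv: tuple[float, float, int] = (0.005, 3.0, 91),
) -> dict[str, BCVEstimates]:
    """Per-sex shrunken dispersions with a *pooled* shrinkage target.

    Both sexes' per-gene estimates are shrunk toward one common dispersion
    estimated from all samples of the tissue.  The shrinkage target is a
    nuisance parameter: giving each sex its own target lets its sampling
    error shift every gene of that sex coherently, which badly inflates
    the type-I error of the paired male-female BCV comparison.  A shared
    target cancels out of the differences and leaves the comparison
    calibrated.
    """
    lo, hi, n_pts = grid_bcv
    disp_grid = np.exp(np.linspace(np.log(lo**2), np.log(hi**2), int(n_pts)))
    log_grid = np.log(disp_grid)

    curves: dict[str, np.ndarray] = {}
    kept: dict[str, pd.Index] = {}
    df_resid: dict[str, int] = {}
    for sex in ("M", "F"):
        cols = samples.index[samples["sex"] == sex].intersection(counts.columns)
        if len(cols) < 2:
            raise ValueError(f"need >= 2 replicates for sex {sex!r}")
        sub = counts[cols]
        keep = sub.sum(axis=1) > 0
        y = sub.loc[keep].to_numpy(dtype=float)
        offsets = np.log(eff_lib_sizes.reindex(cols).to_numpy(dtype=float))
        curves[sex] = _nb_apl_curve(y, offsets, disp_grid)
        kept[sex] = counts.index[keep]
        df_resid[sex] = len(cols) - 1

    shared = np.vstack([curves["M"], curves["F"]]).mean(axis=0)
    common = float(np.exp(_interp_argmax(log_grid, shared)))

    out: dict[str, BCVEstimates] = {}
    for sex in ("M", "F"):
        weight = prior_weight / df_resid[sex]
        objective = curves[sex] + weight * shared[None, :]
        disp = np.exp(
            [_interp_argmax(log_grid, objective[g]) for g in range(objective.shape[0])]
        )
        table = pd.DataFrame(
            {
                "dispersion": disp,
                "bcv": np.sqrt(disp),
                "log2_bcv": 0.5 * np.log2(disp),
            },
            index=kept[sex],
        )
        out[sex] = BCVEstimates(
            table=table, common_dispersion=common, prior_weight=prior_weight
        )
    return out


# -- paired rank test -------------------------------------------------------


def wilcoxon_v(diff: np.ndarray) -> float:
    """Signed-rank statistic V: sum of ranks of positive differences,
    zeros dropped, ties given average ranks (the convention R prints)."""
    d = np.asarray(diff, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    ranks = rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def compare_bcv_by_sex(
    log2_bcv_m: pd.Series,
    log2_bcv_f: pd.Series,
    exact_max_n: int = 25,
) -> dict:
    """Paired Wilcoxon signed-rank test of male minus female log2 BCV.

    Uses the exact null for small samples and the normal approximation
    with continuity correction otherwise.  An all-zero difference vector
    is reported as degenerate instead of raising.
    """
    genes = log2_bcv_m.index.intersection(log2_bcv_f.index)
    d = (log2_bcv_m.loc[genes] - log2_bcv_f.loc[genes]).dropna().to_numpy()
    n = d.size
    if n == 0 or np.all(d == 0):
        return {"V": np.nan, "p": np.nan, "n": int(n), "degenerate": True}
    n_nonzero = int(np.sum(d != 0))
    method = "exact" if n_nonzero <= exact_max_n else "approx"
    res = wilcoxon(
        d, alternative="two-sided", correction=(method == "approx"), method=method
    )
    return {
        "V": wilcoxon_v(d),
        "p": float(res.pvalue),
        "n": int(n),
        "degenerate": False,
        "method": method,
    }
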