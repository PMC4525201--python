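"""Stochastic trajectories of expression evolution and sex-chromosome
effective sizes under harem polygyny.

The origin-fixation process converges to a linear diffusion: drift equals
the deterministic expected change and the noise is white with
per-generation variance ``mu sigma2`` in the heterogametic sex and
``4 mu sigma2`` in the homogametic sex (a fixation shifts the latter by
twice the per-copy effect).  The two Brownian motions are taken
independent.  Paths are integrated by Euler-Maruyama.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .popgen_core import ExpressionState, ModelParams, drift_matrix
from .trajectories import default_initial_state, degradation_profile, rescale_time

__all__ = [
    "MatingSystem",
    "PathEnsemble",
    "effective_size",
    "simulate_paths",
    "ensemble_summary",
]


@dataclass(frozen=True)
class MatingSystem:
    """Harem polygyny: ``N_f`` breeding females, ``eta`` = breeding females
    per breeding male."""

    N_f: float
    eta: float

    def __post_init__(self) -> None:
        if self.N_f < 1:
            raise ValueError("N_f must be >= 1")
        if not self.eta > 0:
            raise ValueError("eta must be > 0")


def effective_size(ms: MatingSystem, chromosome: str) -> float:
    """Effective population size of the X or Z under harem polygyny.

    ``N_eX = 9 N_f / (6 + 2 eta)`` and ``N_eZ = 9 N_f / (6 + 4 eta)``:
    male reproductive skew (eta > 1) hits the Z harder because males
    transmit two-thirds of Z copies but only one-third of X copies.
    """
    if chromosome == "X":
        return 9.0 * ms.N_f / (6.0 + 2.0 * ms.eta)
    if chromosome == "Z":
        return 9.0 * ms.N_f / (6.0 + 4.0 * ms.eta)
    raise ValueError(f"chromosome must be 'X' or 'Z', got {chromosome!r}")


@dataclass
class PathEnsemble:
    """Replicate stochastic trajectories on a shared time grid.

    ``paths`` has shape (n_replicates, n_times, 2) with the last axis
    ordered (z_m, z_f).  Regenerating with the same seed is bit-identical:
    replicate i consumes the i-th child stream of
    ``np.random.SeedSequence(seed).spawn(n_replicates)``.
    """

    t: np.ndarray
    tau: np.ndarray
    paths: np.ndarray
    seed: int
    params: ModelParams

    @property
    def n_replicates(self) -> int:
        return self.paths.shape[0]

    @property
    def z_het(self) -> np.ndarray:
        """Heterogametic-sex paths, shape (n_replicates, n_times)."""
        i = 0 if self.params.system == "XY" else 1
        return self.paths[:, :, i]

    def to_tsv(self, path) -> None:
        n_rep, n_t, _ = self.paths.shape
        rep = np.repeat(np.arange(n_rep), n_t)
        t = np.tile(self.t, n_rep)
        zm = self.paths[:, :, 0].ravel()
        zf = self.paths[:, :, 1].ravel()
        np.savetxt(
            path,
            np.column_stack([rep, t, zm, zf]),
            delimiter="\t",
            header="replicate\tt\tz_m\tz_f",
            comments="",
            fmt=["%d", "%.8g", "%.8g", "%.8g"],
        )


def _diffusion_coeffs(params: ModelParams) -> np.ndarray:
    """Per-generation diffusion coefficients (b_m, b_f)."""
    b_het = np.sqrt(params.mu * params.sigma2)
    b_hom = 2.0 * np.sqrt(params.mu * params.sigma2)
    if params.system == "XY":
        return np.array([b_het, b_hom])
    return np.array([b_hom, b_het])


def default_dt(params: ModelParams) -> float:
    """Step (in generations) keeping ``max drift eigenvalue * dt <= 0.01``."""
    A_gen = drift_matrix(params) * (2.0 * params.mu / 30.0)
    lam = np.max(np.abs(np.linalg.eigvals(A_gen)))
    if lam <= 0:
        return 1.0
    return min(1.0, 0.01 / lam)


def simulate_paths(
    params: ModelParams,
    init: ExpressionState | None = None,
    T: float = 1e4,
    dt: float | None = None,
    n_replicates: int = 100,
    seed: int = 0,
    n_record: int = 201,
    diffusion: bool = True,
) -> PathEnsemble:
    """Euler-Maruyama ensemble of the expression diffusion.

    ``T`` and ``dt`` are in generations.  ``diffusion=False`` switches the
    noise off (each path then follows the deterministic flow).  Warns when
    ``dt`` fails the stability heuristic (drift eigenvalue * dt > 0.1).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if init is None:
        init = default_initial_state(params)
    if dt is None:
        dt = default_dt(params)
    A_gen = drift_matrix(params) * (2.0 * params.mu / 30.0)
    lam = np.max(np.abs(np.linalg.eigvals(A_gen)))
    if lam * dt > 0.1:
        warnings.warn(
            f"dt={dt:g} is coarse for drift rate {lam:g}/generation "
            "(eigenvalue * dt > 0.1); results may be biased",
            stacklevel=2,
        )

    n_steps = max(1, int(np.ceil(T / dt)))
    rec_idx = np.unique(np.linspace(0, n_steps, min(n_record, n_steps + 1)).astype(int))
    t_rec = rec_idx * dt

    b = _diffusion_coeffs(params) if diffusion else np.zeros(2)
    sqdt = np.sqrt(dt)
    het = 0 if params.system == "XY" else 1
    gradual = params.degradation == "gradual"

    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    gens = [np.random.Generator(np.random.PCG64(s)) for s in streams]

    z = np.tile(np.array([init.z_m, init.z_f]), (n_replicates, 1))
    out = np.empty((n_replicates, len(rec_idx), 2))
    rec_pos = {int(k): i for i, k in enumerate(rec_idx)}
    if 0 in rec_pos:
        out[:, 0, :] = z

    chunk = 4096
    step = 0
    while step < n_steps:
        m = min(chunk, n_steps - step)
        if diffusion:
            inc = np.empty((n_replicates, m, 2))
            for r, g in enumerate(gens):
                inc[r] = g.standard_normal((m, 2))
        for k in range(m):
            p = z
            if gradual:
                t_now = (step + k) * dt
                p = z.copy()
                p[:, het] += degradation_profile(t_now, params.alpha, params.z0)
            drift = -(p @ A_gen.T)
            if diffusion:
                z = z + dt * drift + sqdt * b * inc[:, k, :]
            else:
                z = z + dt * drift
            pos = rec_pos.get(step + k + 1)
            if pos is not None:
                out[:, pos, :] = z
        step += m

    return PathEnsemble(
        t=t_rec,
        tau=rescale_time(t_rec, params.mu),
        paths=out,
        seed=seed,
        params=params,
    )


def ensemble_summary(ens: PathEnsemble, at_time: float) -> dict:
    """Cross-replicate moments of (z_m, z_f) at ``at_time`` (generations).

    Also returns the heterogametic-sex values at that time (the terminal
    histogram when ``at_time`` is the end of the grid).
    """
    idx = int(np.argmin(np.abs(ens.t - at_time)))
    if not np.isclose(ens.t[idx], at_time, rtol=1e-6, atol=1e-9 * max(1.0, ens.t[-1])):
        raise ValueError(f"time {at_time} not on the recorded grid")
    snap = ens.paths[:, idx, :]
    ddof = 1 if ens.n_replicates > 1 else 0
    return {
        "t": float(ens.t[idx]),
        "mean_z_m": float(snap[:, 0].mean()),
        "mean_z_f": float(snap[:, 1].mean()),
        "var_z_m": float(snap[:, 0].var(ddof=ddof)),
        "var_z_f": float(snap[:, 1].var(ddof=ddof)),
        "het_values": ens.z_het[:, idx].copy(),
    }
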