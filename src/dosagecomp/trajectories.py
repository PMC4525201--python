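"""Deterministic expected dynamics of sex-linked expression evolution.

The expected trajectory obeys a linear 2x2 ODE system ``dz/dtau = -A z``
(:func:`dosagecomp.popgen_core.drift_matrix`).  The baseline model
(additive effects, instantaneous Y/W loss) admits an exact eigen-solution;
variant models (dominant mutations, gradual Y/W decay) are integrated
numerically.  Time is carried both in generations ``t`` and on the rescaled
axis ``tau = 2 mu t / 30``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .popgen_core import TIME_RESCALE, ExpressionState, ModelParams, drift_matrix

__all__ = [
    "Trajectory",
    "DegradationProfile",
    "rescale_time",
    "unrescale_time",
    "degradation_profile",
    "default_initial_state",
    "solve_expected",
    "stationary_variance",
    "stationary_covariance",
    "time_to_recover",
]


def rescale_time(t, mu: float):
    """Generations -> rescaled time, ``tau = 2 mu t / 30``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if not mu > 0:
        raise ValueError("mu must be > 0")
    return 2.0 * mu * t / TIME_RESCALE


def unrescale_time(tau, mu: float):
    """Rescaled time -> generations (inverse of :func:`rescale_time`)."""
    if not mu > 0:
        raise ValueError("mu must be > 0")
    return np.asarray(tau, dtype=float) * TIME_RESCALE / (2.0 * mu)


def degradation_profile(t, alpha: float, z0: float):
    """Expression of the decaying Y/W gene copy at time ``t`` (generations).

    Starts at half the ancestral two-copy level, ``z0/2``, and decays
    exponentially at rate ``alpha`` toward total shut-down.
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    return 0.5 * z0 * np.exp(-alpha * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class DegradationProfile:
    """Decaying Y/W-copy expression, ``y(t) = (z0/2) exp(-alpha t)``."""

    alpha: float
    z0: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")

    def y(self, t):
        return degradation_profile(t, self.alpha, self.z0)


@dataclass
class Trajectory:
    """Male and female expected expression through time.

    ``z_m``/``z_f`` hold the evolving X- or Z-copy state.  Under gradual
    degradation the heterogametic sex's *realized* phenotype additionally
    includes the decaying Y/W contribution ``y``; use ``z_het_realized``.
    """

    t: np.ndarray
    tau: np.ndarray
    z_m: np.ndarray
    z_f: np.ndarray
    params: ModelParams
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.z_m = np.asarray(self.z_m, dtype=float)
        self.z_f = np.asarray(self.z_f, dtype=float)
        n = len(self.t)
        if not (len(self.tau) == len(self.z_m) == len(self.z_f) == n):
            raise ValueError("all trajectory arrays must share one length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def z_het(self) -> np.ndarray:
        """Evolving-copy state of the heterogametic sex."""
        return self.z_m if self.params.system == "XY" else self.z_f

    @property
    def z_hom(self) -> np.ndarray:
        return self.z_f if self.params.system == "XY" else self.z_m

    @property
    def z_het_realized(self) -> np.ndarray:
        """Heterogametic-sex phenotype including any Y/W contribution."""
        if self.y is None:
            return self.z_het
        return self.z_het + self.y

    def to_tsv(self, path) -> None:
        cols = [self.t, self.tau, self.z_m, self.z_f]
        header = "t\ttau\tz_m\tz_f"
        if self.y is not None:
            cols.append(self.y)
            header += "\ty"
        np.savetxt(path, np.column_stack(cols), delimiter="\t", header=header, comments="")


def default_initial_state(params: ModelParams) -> ExpressionState:
    """Post-degradation starting point.

    Instantaneous loss: the heterogametic sex sits at ``-z0``, the
    homogametic sex at the optimum.  Gradual decay: the evolving copy starts
    at ``-z0/2`` (the realized phenotype starts at the optimum because the
    Y/W copy still contributes ``z0/2``).
    """
    deficit = -params.z0 if params.degradation == "instantaneous" else -0.5 * params.z0
    if params.system == "XY":
        return ExpressionState(z_m=deficit, z_f=0.0)
    return ExpressionState(z_m=0.0, z_f=deficit)


# -- closed-form solution ---------------------------------------------------


def _eigen_solution(A: np.ndarray, z0: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Exact solution of dz/dtau = -A z via explicit 2x2 eigendecomposition.

    The discriminant ``(a-d)^2 + 4bc`` is nonnegative for every valid
    parameter set (b and c share the sign of rho), so eigenvalues are real.
    Returns an array of shape (len(tau), 2).
    """
    (a, b), (c, d) = A
    tr = a + d
    disc = (a - d) ** 2 + 4.0 * b * c
    if disc < 0:  # pragma: no cover - unreachable for valid params
        raise ValueError("complex eigenvalues; drift matrix outside model class")
    root = np.sqrt(disc)
    lam1 = 0.5 * (tr + root)
    lam2 = 0.5 * (tr - root)
    if root < 1e-12 * max(1.0, abs(tr)):
        # defective (or scalar) matrix: exp(-A tau) = e^{-lam tau} (I - tau (A - lam I))
        lam = 0.5 * tr
        ea = np.exp(-lam * tau)[:, None, None]
        eye = np.eye(2)
        mats = ea * (eye - tau[:, None, None] * (A - lam * eye))
        return np.einsum("tij,j->ti", mats, z0)
    # eigenvectors of A
    if abs(b) > 1e-300:
        v1 = np.array([b, lam1 - a])
        v2 = np.array([b, lam2 - a])
    elif abs(c) > 1e-300:
        v1 = np.array([lam1 - d, c])
        v2 = np.array([lam2 - d, c])
    elif abs(lam1 - a) <= abs(lam1 - d):  # diagonal, lam1 belongs to axis 1
        v1 = np.array([1.0, 0.0])
        v2 = np.array([0.0, 1.0])
    else:  # diagonal, lam1 belongs to axis 2
        v1 = np.array([0.0, 1.0])
        v2 = np.array([1.0, 0.0])
    V = np.column_stack([v1, v2])
    coef = np.linalg.solve(V, z0)
    e1 = np.exp(-lam1 * tau)
    e2 = np.exp(-lam2 * tau)
    return np.outer(e1, coef[0] * v1) + np.outer(e2, coef[1] * v2)


def solve_expected(
    params: ModelParams,
    init: ExpressionState | None = None,
    t_grid: np.ndarray | None = None,
    method: str = "closed_form",
) -> Trajectory:
    """Expected trajectory of (z_m, z_f) over a grid of generations.

    ``closed_form`` is only valid for the baseline model (additive,
    instantaneous); ``numeric`` integrates the (possibly variant)
    right-hand side with a tight-tolerance adaptive integrator.
    """
    if method not in ("closed_form", "numeric"):
        raise ValueError(f"unknown method {method!r}")
    if init is None:
        init = default_initial_state(params)
    if t_grid is None:
        t_grid = np.linspace(0.0, 1.5e5, 301)
    t_grid = np.asarray(t_grid, dtype=float)
    tau_grid = rescale_time(t_grid, params.mu)
    z0 = np.array([init.z_m, init.z_f])
    A = drift_matrix(params)

    variant = params.dominance != "additive" or params.degradation != "instantaneous"
    if method == "closed_form":
        if variant:
            raise ValueError(
                "closed_form covers only the baseline model "
                "(additive, instantaneous); use method='numeric'"
            )
        z = _eigen_solution(A, z0, tau_grid)
        return Trajectory(t_grid, tau_grid, z[:, 0], z[:, 1], params)

    het = 0 if params.system == "XY" else 1
    gradual = params.degradation == "gradual"

    def rhs(tau, z):
        p = z.copy()
        if gradual:
            t = unrescale_time(tau, params.mu)
            p[het] += degradation_profile(t, params.alpha, params.z0)
        return -A @ p

    sol = solve_ivp(
        rhs,
        (tau_grid[0], tau_grid[-1]),
        z0,
        t_eval=tau_grid,
        method="DOP853",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = degradation_profile(t_grid, params.alpha, params.z0) if gradual else None
    return Trajectory(t_grid, tau_grid, sol.y[0], sol.y[1], params, y=y)


# -- stationary law ---------------------------------------------------------


def stationary_covariance(params: ModelParams) -> np.ndarray:
    """Exact stationary covariance of the (z_m, z_f) diffusion.

    Solves the 2x2 Lyapunov equation ``A S + S A^T = Q`` where A is the
    drift matrix (per tau) and Q the diffusion covariance rate: per
    generation the heterogametic sex accumulates variance ``mu sigma2`` and
    the homogametic sex ``4 mu sigma2`` (fixations shift it by twice the
    per-copy effect), i.e. 15 sigma2 and 60 sigma2 per unit tau.
    """
    A = drift_matrix(params)
    q_het = 15.0 * params.sigma2
    q_hom = 60.0 * params.sigma2
    if params.system == "XY":
        q = np.array([q_het, q_hom])
    else:
        q = np.array([q_hom, q_het])
    (a, b), (c, d) = A
    # unknowns (S11, S12, S22)
    M = np.array(
        [
            [2.0 * a, 2.0 * b, 0.0],
            [c, a + d, b],
            [0.0, 2.0 * c, 2.0 * d],
        ]
    )
    rhs = np.array([q[0], 0.0, q[1]])
    s11, s12, s22 = np.linalg.solve(M, rhs)
    return np.array([[s11, s12], [s12, s22]])


def stationary_variance(params: ModelParams) -> float:
    """Stationary variance of heterogametic-sex expression."""
    cov = stationary_covariance(params)
    i = 0 if params.system == "XY" else 1
    return float(cov[i, i])


# -- summary statistics -----------------------------------------------------


def time_to_recover(
    params: ModelParams,
    frac: float = 0.9,
    method: str = "closed_form",
    t_max: float = 1e8,
) -> float:
    """Generations until the heterogametic sex recovers ``frac`` of its
    initial deficit, i.e. first crossing of ``-(1 - frac) * |z_het(0)|``.

    Uses root finding on the continuous solution (closed form when
    available, otherwise a dense numeric solution).
    """
    init = default_initial_state(params)
    target = (1.0 - frac) * (init.z_m if params.system == "XY" else init.z_f)

    if method == "closed_form":
        A = drift_matrix(params)
        z0 = np.array([init.z_m, init.z_f])
        het = 0 if params.system == "XY" else 1

        def f(t):
            tau = rescale_time(np.array([t]), params.mu)
            return _eigen_solution(A, z0, tau)[0, het] - target

    else:
        grid = np.linspace(0.0, t_max, 4097)
        traj = solve_expected(params, init, grid, method="numeric")
        zh = traj.z_het_realized
        idx = np.nonzero(zh >= target)[0]
        if len(idx) == 0:
            raise ValueError("no recovery within t_max")
        i = idx[0]
        if i == 0:
            return 0.0
        lo, hi = grid[i - 1], grid[i]

        def f(t):
            tr = solve_expected(params, init, np.array([0.0, t]), method="numeric")
            return tr.z_het_realized[-1] - target

        return float(brentq(f, lo, hi, xtol=1e-6 * hi))

    if f(t_max) < 0:
        raise ValueError("no recovery within t_max")
    return float(brentq(f, 0.0, t_max, xtol=1e-4))
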