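"""Origin-fixation model of sex-linked expression evolution.

A dose-sensitive gene on the X (or Z) evolves by the sequential fixation of
cis-regulatory mutations of small effect.  Mutational effects on male and
female expression are drawn from a mean-zero bivariate normal with common
variance ``sigma2`` and inter-sexual correlation ``rho``.  Expression is
under sex-specific Gaussian stabilizing selection around an optimum at zero,
``w_s(z) = exp(-S_s z^2 / 2)``.

The fixation probability of a rare sex-linked mutant is the linearized
diffusion approximation: the neutral term ``1/(3N)`` times a selection
bracket in which the homogametic sex carries double weight (it holds two of
the three chromosome copies).  Integrating the per-substitution change over
the mutation kernel gives closed-form expected dynamics; see
:mod:`dosagecomp.trajectories` for their solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ModelParams",
    "MutationEffect",
    "ExpressionState",
    "LinearizationWarning",
    "sample_mutation",
    "sample_mutations",
    "fixation_prob",
    "expected_change",
    "drift_matrix",
    "clamp_counter",
]

#: number of generations of scaled time per unit of 2*mu*t (tau = 2*mu*t/30)
TIME_RESCALE = 30.0


class LinearizationWarning(UserWarning):
    """Raised when the linearized fixation probability leaves [0, 1]."""


class _ClampCounter:
    """Diagnostic counter for out-of-range linearized probabilities."""

    def __init__(self) -> None:
        self.count = 0

    def reset(self) -> None:
        self.count = 0


clamp_counter = _ClampCounter()


@dataclass(frozen=True)
class MutationEffect:
    """Effect of a single cis-regulatory mutation on expression."""

    delta_m: float
    delta_f: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.delta_m) and np.isfinite(self.delta_f)):
            raise ValueError("mutation effects must be finite")


@dataclass(frozen=True)
class ExpressionState:
    """Mean male and female expression, as deviation from the optimum."""

    z_m: float
    z_f: float
    time: float = 0.0
    #: when True, ``time`` is on the rescaled tau axis instead of generations
    rescaled: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.z_m) and np.isfinite(self.z_f)):
            raise ValueError("expression state must be finite")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the evolutionary model.

    ``Ne`` is the effective size of the focal sex chromosome and is carried
    independently of the census size ``N``: ``N`` only sets the initial
    frequency of a new mutant, ``Ne`` sets the strength of drift.
    """

    system: str = "XY"
    S_m: float = 1.0
    S_f: float = 1.0
    rho: float = 0.0
    sigma2: float = 0.1
    mu: float = 3e-4
    N: int = 1000
    Ne: float = 1125.0
    z0: float = 1.0
    dominance: str = "additive"
    degradation: str = "instantaneous"
    alpha: float = 1e-3

    def __post_init__(self) -> None:
        if self.system not in ("XY", "ZW"):
            raise ValueError(f"system must be 'XY' or 'ZW', got {self.system!r}")
        if self.dominance not in ("additive", "dominant"):
            raise ValueError(f"unknown dominance mode {self.dominance!r}")
        if self.degradation not in ("instantaneous", "gradual"):
            raise ValueError(f"unknown degradation mode {self.degradation!r}")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be > 0")
        if not self.mu > 0:
            raise ValueError("mu must be > 0")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not self.Ne > 0:
            raise ValueError("Ne must be > 0")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")
        if self.S_m < 0 or self.S_f < 0:
            raise ValueError("selection intensities must be >= 0")
        if self.degradation == "gradual" and not self.alpha > 0:
            raise ValueError("alpha must be > 0 for gradual degradation")

    # -- sex-role helpers ---------------------------------------------------

    @property
    def heterogametic_sex(self) -> str:
        """'m' for XY systems, 'f' for ZW systems."""
        return "m" if self.system == "XY" else "f"

    @property
    def S_het(self) -> float:
        return self.S_m if self.system == "XY" else self.S_f

    @property
    def S_hom(self) -> float:
        return self.S_f if self.system == "XY" else self.S_m

    @property
    def hom_weight(self) -> float:
        """Weight of the homogametic-sex selection term in the fixation
        probability: 2 under additivity, 8/3 when mutants are dominant."""
        return 2.0 if self.dominance == "additive" else 8.0 / 3.0

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    # -- flat config round trip --------------------------------------------

    def to_config(self, path: str | Path) -> None:
        """Write the parameters to a flat ``key = value`` text file."""
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "ModelParams":
        kwargs: dict = {}
        casts = {f.name: f.type for f in fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in casts:
                raise KeyError(f"unknown parameter {key!r}")
            if key in ("system", "dominance", "degradation"):
                kwargs[key] = value
            elif key == "N":
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


# -- mutation kernel --------------------------------------------------------


def sample_mutation(params: ModelParams, rng: np.random.Generator) -> MutationEffect:
    """Draw a single mutational effect pair from the bivariate normal kernel."""
    dm, df = sample_mutations(params, 1, rng)
    return MutationEffect(float(dm[0]), float(df[0]))


def sample_mutations(
    params: ModelParams, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized draw of ``n`` effect pairs.

    Marginals are N(0, sigma2) in each sex with correlation rho; implemented
    by a Cholesky-style transform of two independent standard normals.
    """
    sigma = np.sqrt(params.sigma2)
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    delta_m = sigma * x
    delta_f = sigma * (params.rho * x + np.sqrt(1.0 - params.rho**2) * y)
    return delta_m, delta_f


# -- fixation probability ---------------------------------------------------


def _selection_bracket(
    delta: MutationEffect, state: ExpressionState, params: ModelParams
) -> float:
    """Sex-weighted selection term of the linearized fixation probability.

    Returns ``(2 Ne / 3) * (S_het z_het d_het + w_hom S_hom z_hom d_hom)``
    where ``w_hom`` is 2 (additive) or 8/3 (dominant).  Negative values of
    ``z_s * delta_s`` (mutation toward the optimum) increase fixation.
    """
    if params.system == "XY":
        z_het, d_het = state.z_m, delta.delta_m
        z_hom, d_hom = state.z_f, delta.delta_f
    else:
        z_het, d_het = state.z_f, delta.delta_f
        z_hom, d_hom = state.z_m, delta.delta_m
    return (2.0 * params.Ne / 3.0) * (
        params.S_het * z_het * d_het
        + params.hom_weight * params.S_hom * z_hom * d_hom
    )


def fixation_prob(
    delta: MutationEffect, state: ExpressionState, params: ModelParams
) -> float:
    """Linearized fixation probability of a single-copy sex-linked mutant.

    The neutral fixation probability of a sex-linked mutant present as one
    of the 3N gene copies is 1/(3N); weak selection perturbs it linearly in
    the mutational effects.  The linearization can leave [0, 1] for strong
    selection or large states; the value is then clamped and a
    :class:`LinearizationWarning` is emitted (``clamp_counter`` counts the
    events).
    """
    p0 = 1.0 / (3.0 * params.N)
    raw = p0 * (1.0 - _selection_bracket(delta, state, params))
    if raw < 0.0 or raw > 1.0:
        clamp_counter.count += 1
        warnings.warn(
            f"linearized fixation probability {raw:.3g} outside [0, 1]; "
            "clamped (outside the small-effect regime of validity)",
            LinearizationWarning,
            stacklevel=2,
        )
        raw = min(max(raw, 0.0), 1.0)
    return raw


# -- expected per-substitution dynamics -------------------------------------


def drift_matrix(params: ModelParams) -> np.ndarray:
    """Linear drift matrix A (per unit of rescaled time tau).

    The expected dynamics are ``d(z_m, z_f)/dtau = -A @ (z_m, z_f)``.  Rows
    and columns are ordered (male, female) for both systems.  Derived by
    integrating delta times the linearized fixation probability over the
    mutation kernel: per generation the heterogametic sex moves by delta_het
    per fixation and the homogametic sex by 2*delta_hom, and tau advances by
    2*mu/30 per generation.
    """
    k = 10.0 * params.sigma2 * params.Ne
    w = params.hom_weight
    S_het, S_hom, rho = params.S_het, params.S_hom, params.rho
    # (het, hom) block, then reorder to (m, f)
    a = np.array(
        [
            [k * S_het, k * w * rho * S_hom],
            [2.0 * k * rho * S_het, 2.0 * k * w * S_hom],
        ]
    )
    if params.system == "XY":
        return a
    # ZW: male is homogametic -> swap both axes
    return a[::-1, ::-1]


def expected_change(
    state: ExpressionState, params: ModelParams
) -> tuple[float, float]:
    """Expected change in (z_m, z_f) per unit of rescaled time tau.

    This is the drift of the diffusion limit of the origin-fixation
    process, linear in the state.  Under gradual Y/W degradation the caller
    is responsible for passing the heterogametic sex's *realized* phenotype
    (evolving copy plus the decaying ancestral contribution).
    """
    z = np.array([state.z_m, state.z_f])
    dz = -drift_matrix(params) @ z
    return float(dz[0]), float(dz[1])
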