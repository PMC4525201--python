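"""Individual-based Wright-Fisher simulator of a single sex-linked locus.

Serves as the brute-force oracle for the linearized fixation probability
and as an end-to-end origin-fixation simulator.  The population holds N
males and N females; generations are non-overlapping.  Parents of each
offspring are sampled with replacement, with probability proportional to
their Gaussian fitness within each sex (equivalent to zygote-stage
viability selection in the weak-selection diffusion limit).

Sex-linked transmission: offspring of the homogametic sex receive one
focal-chromosome gamete from each parent; offspring of the heterogametic
sex receive theirs from the homogametic parent only (in XY a son's X comes
from his mother, in ZW a daughter's Z comes from her father).

With Poisson-equivalent multinomial reproduction and equal sex numbers the
implied effective size of the focal chromosome is ``1.5 N``; oracle
comparisons must therefore set ``Ne = 1.5 N`` in the analytic formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popgen_core import (
    ExpressionState,
    ModelParams,
    MutationEffect,
    sample_mutations,
)

__all__ = [
    "Genotype",
    "InvasionResult",
    "fitness",
    "expression_of",
    "run_invasion",
    "invasion_probability",
    "run_origin_fixation",
    "origin_fixation_ensemble",
    "implied_ne",
]


def implied_ne(n_census: int) -> float:
    """Effective size of the focal sex chromosome implied by the simulated
    demography (N males, N females, multinomial offspring numbers)."""
    return 1.5 * n_census


def fitness(z, S: float):
    """Gaussian stabilizing selection: ``w(z) = exp(-S z^2 / 2)``, maximal
    at the optimum z = 0."""
    if S < 0:
        raise ValueError("S must be >= 0")
    return np.exp(-0.5 * S * np.asarray(z, dtype=float) ** 2)


@dataclass(frozen=True)
class Genotype:
    """Alleles at the focal locus: 'R' (resident) / 'M' (mutant).

    One allele in the heterogametic sex (hemizygous), two in the
    homogametic sex.
    """

    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) not in (1, 2) or any(
            a not in ("R", "M") for a in self.alleles
        ):
            raise ValueError(f"invalid genotype {self.alleles!r}")

    @property
    def n_mutant(self) -> int:
        return sum(a == "M" for a in self.alleles)


@dataclass(frozen=True)
class InvasionResult:
    """Fate of a single mutant invasion."""

    outcome: str  # 'fixed' | 'lost' | 'undecided'
    generations: int
    seed: int


def expression_of(
    g: Genotype,
    sex: str,
    state: ExpressionState,
    delta: MutationEffect,
    dominance: str = "additive",
    system: str = "XY",
) -> float:
    """Expression of an individual given its genotype.

    Additive map: each mutant copy shifts expression by the per-copy
    effect (hemizygote M -> z + delta, heterozygote -> z + delta,
    homozygote MM -> z + 2 delta).  Dominant map: heterozygotes express
    like mutant homozygotes.
    """
    if sex not in ("m", "f"):
        raise ValueError("sex must be 'm' or 'f'")
    het_sex = "m" if system == "XY" else "f"
    expected_ploidy = 1 if sex == het_sex else 2
    if len(g.alleles) != expected_ploidy:
        raise ValueError(
            f"ploidy mismatch: sex {sex!r} in {system} carries "
            f"{expected_ploidy} allele(s), genotype has {len(g.alleles)}"
        )
    z = state.z_m if sex == "m" else state.z_f
    d = delta.delta_m if sex == "m" else delta.delta_f
    n = g.n_mutant
    if expected_ploidy == 2 and dominance == "dominant" and n >= 1:
        n = 2
    return z + n * d


# -- vectorized invasion engine ---------------------------------------------


def _genotype_weights(
    z_het, d_het, S_het, z_hom, d_hom, S_hom, dominance: str
):
    """Fitness of each genotype class.

    Returns (w_R, w_M) for the hemizygous heterogametic sex and
    (w_RR, w_RM, w_MM) for the diploid homogametic sex; all broadcastable
    arrays.
    """
    w_R = fitness(z_het, S_het)
    w_M = fitness(z_het + d_het, S_het)
    w_RR = fitness(z_hom, S_hom)
    het_shift = 2.0 * d_hom if dominance == "dominant" else d_hom
    w_RM = fitness(z_hom + het_shift, S_hom)
    w_MM = fitness(z_hom + 2.0 * d_hom, S_hom)
    return w_R, w_M, w_RR, w_RM, w_MM


def _simulate_invasions(
    n_census: int,
    z_het,
    d_het,
    S_het: float,
    z_hom,
    d_hom,
    S_hom: float,
    dominance: str,
    n_replicates: int,
    rng: np.random.Generator,
    max_generations: int = 10**6,
    start_in_hom: np.ndarray | None = None,
):
    """Run ``n_replicates`` independent invasions in parallel.

    Returns (outcome codes, generations): outcome 1 = fixed, 0 = lost,
    -1 = undecided at the generation cap.  ``z``/``d`` may be scalars or
    per-replicate arrays.  ``start_in_hom`` optionally fixes, per
    replicate, whether the initial copy lands in the homogametic sex;
    by default it is random among the 3N gene copies (2N of which are in
    the homogametic sex).
    """
    N = n_census
    R = n_replicates
    z_het = np.broadcast_to(np.asarray(z_het, dtype=float), (R,))
    d_het = np.broadcast_to(np.asarray(d_het, dtype=float), (R,))
    z_hom = np.broadcast_to(np.asarray(z_hom, dtype=float), (R,))
    d_hom = np.broadcast_to(np.asarray(d_hom, dtype=float), (R,))
    w_R, w_M, w_RR, w_RM, w_MM = _genotype_weights(
        z_het, d_het, S_het, z_hom, d_hom, S_hom, dominance
    )

    if start_in_hom is None:
        start_in_hom = rng.random(R) < (2.0 * N) / (3.0 * N)
    # homogametic genotype counts
    RM = np.where(start_in_hom, 1, 0).astype(np.int64)
    MM = np.zeros(R, dtype=np.int64)
    # heterogametic mutant count
    M = np.where(start_in_hom, 0, 1).astype(np.int64)

    outcome = np.full(R, -1, dtype=np.int64)
    gens = np.zeros(R, dtype=np.int64)
    active = np.arange(R)

    for gen in range(1, max_generations + 1):
        RR = N - RM - MM
        R_het = N - M
        # gamete M-frequencies under fitness-biased parent sampling
        tot_hom = RR * w_RR + RM * w_RM + MM * w_MM
        q_hom = (0.5 * RM * w_RM + MM * w_MM) / tot_hom
        tot_het = R_het * w_R + M * w_M
        q_het = M * w_M / tot_het

        # next-generation homogametic sex: gametes from both parents
        p_MM = q_hom * q_het
        p_RM = q_hom * (1.0 - q_het) + q_het * (1.0 - q_hom)
        MM = rng.binomial(N, p_MM)
        rem = 1.0 - p_MM
        with np.errstate(divide="ignore", invalid="ignore"):
            p_RM_cond = np.where(rem > 0, p_RM / np.where(rem > 0, rem, 1.0), 0.0)
        RM = rng.binomial(N - MM, np.clip(p_RM_cond, 0.0, 1.0))
        # next-generation heterogametic sex: gamete from homogametic parent
        M = rng.binomial(N, q_hom)

        total_m = 2 * MM + RM + M
        lost = total_m == 0
        fixed = total_m == 3 * N
        done = lost | fixed
        if np.any(done):
            idx = active[done]
            outcome[idx] = np.where(fixed[done], 1, 0)
            gens[idx] = gen
            keep = ~done
            active = active[keep]
            RM, MM, M = RM[keep], MM[keep], M[keep]
            z_het, d_het = z_het[keep], d_het[keep]
            z_hom, d_hom = z_hom[keep], d_hom[keep]
            w_R, w_M = w_R[keep], w_M[keep]
            w_RR, w_RM, w_MM_w = w_RR[keep], w_RM[keep], w_MM[keep]
            w_MM = w_MM_w
            if active.size == 0:
                break
    if active.size:
        gens[active] = max_generations
    return outcome, gens


def _sex_roles(params: ModelParams, state: ExpressionState, delta: MutationEffect):
    if params.system == "XY":
        return (state.z_m, delta.delta_m, params.S_m, state.z_f, delta.delta_f, params.S_f)
    return (state.z_f, delta.delta_f, params.S_f, state.z_m, delta.delta_m, params.S_m)


def run_invasion(
    params: ModelParams,
    state: ExpressionState,
    delta: MutationEffect,
    n_census: int,
    seed: int,
    max_generations: int = 10**6,
) -> InvasionResult:
    """Fate of one mutant copy introduced into a monomorphic population."""
    rng = np.random.Generator(np.random.PCG64(seed))
    z_het, d_het, S_het, z_hom, d_hom, S_hom = _sex_roles(params, state, delta)
    outcome, gens = _simulate_invasions(
        n_census, z_het, d_het, S_het, z_hom, d_hom, S_hom,
        params.dominance, 1, rng, max_generations,
    )
    label = {1: "fixed", 0: "lost", -1: "undecided"}[int(outcome[0])]
    return InvasionResult(outcome=label, generations=int(gens[0]), seed=seed)


def invasion_probability(
    params: ModelParams,
    state: ExpressionState,
    delta: MutationEffect,
    n_census: int,
    n_replicates: int,
    seed: int,
    max_generations: int = 10**6,
    batch: int = 200_000,
) -> dict:
    """Monte-Carlo fixation probability over replicate invasions."""
    rng = np.random.Generator(np.random.PCG64(seed))
    z_het, d_het, S_het, z_hom, d_hom, S_hom = _sex_roles(params, state, delta)
    fixed = lost = undecided = 0
    remaining = n_replicates
    while remaining > 0:
        n = min(batch, remaining)
        outcome, _ = _simulate_invasions(
            n_census, z_het, d_het, S_het, z_hom, d_hom, S_hom,
            params.dominance, n, rng, max_generations,
        )
        fixed += int(np.sum(outcome == 1))
        lost += int(np.sum(outcome == 0))
        undecided += int(np.sum(outcome == -1))
        remaining -= n
    est = fixed / n_replicates
    se = np.sqrt(max(est * (1.0 - est), 1e-300) / n_replicates)
    return {
        "fixed": fixed,
        "lost": lost,
        "undecided": undecided,
        "estimate": est,
        "se": float(se),
        "n_replicates": n_replicates,
    }


# -- origin-fixation simulation ---------------------------------------------


def origin_fixation_ensemble(
    params: ModelParams,
    n_census: int,
    n_substitutions: int,
    n_chains: int,
    seed: int,
    init: ExpressionState | None = None,
    max_generations: int = 10**6,
):
    """Run ``n_chains`` independent origin-fixation chains in parallel.

    Each chain repeatedly draws a mutation, lets it invade, and on fixation
    updates (z_m, z_f) by (delta_m, 2 delta_f) in XY (per-copy effect in the
    hemizygous sex, two copies' worth in the diploid sex); for ZW the roles
    swap.  Segregation time is ignored; waiting time between mutations is
    1/(3 N mu) generations per attempt.

    Returns (z, t): ``z`` of shape (n_chains, n_substitutions + 1, 2)
    holding (z_m, z_f) after each substitution, ``t`` of matching shape
    (n_chains, n_substitutions + 1) with cumulative waiting generations.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    if init is None:
        from .trajectories import default_initial_state

        init = default_initial_state(params)
    N = n_census
    R = n_chains
    z = np.tile(np.array([init.z_m, init.z_f]), (R, 1))
    out = np.empty((R, n_substitutions + 1, 2))
    out[:, 0, :] = z
    attempts = np.zeros(R, dtype=np.int64)
    t_out = np.zeros((R, n_substitutions + 1))
    if n_substitutions == 0:
        return out, t_out
    subs = np.zeros(R, dtype=np.int64)
    active = np.ones(R, dtype=bool)
    het = 0 if params.system == "XY" else 1
    hom = 1 - het
    S_het, S_hom = params.S_het, params.S_hom

    # every chain always carries exactly one segregating invasion; all
    # chains advance one generation per loop iteration (flat vectorization)
    d = np.zeros((R, 2))
    RM = np.zeros(R, dtype=np.int64)
    MM = np.zeros(R, dtype=np.int64)
    M = np.zeros(R, dtype=np.int64)

    def new_mutations(idx: np.ndarray) -> None:
        """Draw fresh mutants for chains ``idx`` and reseed one copy."""
        dm, df = sample_mutations(params, idx.size, rng)
        d[idx, 0] = dm
        d[idx, 1] = df
        attempts[idx] += 1
        in_hom = rng.random(idx.size) < 2.0 / 3.0
        RM[idx] = np.where(in_hom, 1, 0)
        MM[idx] = 0
        M[idx] = np.where(in_hom, 0, 1)

    new_mutations(np.arange(R))
    gen_guard = 0
    cap = max_generations * max(1, n_substitutions) * 200
    while np.any(active):
        gen_guard += 1
        if gen_guard > cap:  # pragma: no cover - safety valve
            raise RuntimeError("origin-fixation simulation exceeded generation cap")
        idx = np.nonzero(active)[0]
        z_het, z_hom = z[idx, het], z[idx, hom]
        d_het, d_hom = d[idx, het], d[idx, hom]
        w_R, w_M, w_RR, w_RM, w_MM = _genotype_weights(
            z_het, d_het, S_het, z_hom, d_hom, S_hom, params.dominance
        )
        rm, mm, m = RM[idx], MM[idx], M[idx]
        rr = N - rm - mm
        r_het = N - m
        tot_hom = rr * w_RR + rm * w_RM + mm * w_MM
        q_hom = (0.5 * rm * w_RM + mm * w_MM) / tot_hom
        q_het = m * w_M / (r_het * w_R + m * w_M)
        p_MM = q_hom * q_het
        p_RM = q_hom * (1.0 - q_het) + q_het * (1.0 - q_hom)
        mm2 = rng.binomial(N, p_MM)
        rem = 1.0 - p_MM
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = np.where(rem > 0, p_RM / np.where(rem > 0, rem, 1.0), 0.0)
        rm2 = rng.binomial(N - mm2, np.clip(cond, 0.0, 1.0))
        m2 = rng.binomial(N, q_hom)
        RM[idx], MM[idx], M[idx] = rm2, mm2, m2

        total = 2 * mm2 + rm2 + m2
        fixed = idx[total == 3 * N]
        lost = idx[total == 0]
        if fixed.size:
            z[fixed, het] += d[fixed, het]
            z[fixed, hom] += 2.0 * d[fixed, hom]
            subs[fixed] += 1
            out[fixed, subs[fixed], :] = z[fixed]
            t_out[fixed, subs[fixed]] = attempts[fixed] / (3.0 * N * params.mu)
            done = fixed[subs[fixed] >= n_substitutions]
            active[done] = False
            fixed = fixed[subs[fixed] < n_substitutions]
        resolved = np.concatenate([fixed, lost])
        if resolved.size:
            new_mutations(resolved)
    return out, t_out


def run_origin_fixation(
    params: ModelParams,
    n_census: int,
    n_substitutions: int,
    seed: int,
    init: ExpressionState | None = None,
    max_generations: int = 10**6,
):
    """Single origin-fixation chain; returns a Trajectory over substitutions."""
    from .trajectories import Trajectory, rescale_time

    z, t = origin_fixation_ensemble(
        params, n_census, n_substitutions, 1, seed, init, max_generations
    )
    t1 = t[0]
    # waiting times are strictly increasing except the degenerate 1-point case
    if n_substitutions == 0:
        t1 = np.array([0.0])
        z = z[:, :1, :]
    return Trajectory(
        t=t1,
        tau=rescale_time(t1, params.mu),
        z_m=z[0, :, 0],
        z_f=z[0, :, 1],
        params=params,
    )
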