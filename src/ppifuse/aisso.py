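"""Aquila-influenced shark smell optimization (AISSO).

A small-population metaheuristic over a box-bounded real vector, minimizing
a pluggable objective. Each candidate ("shark") carries a velocity built
from a gradient ("odour") term and a momentum term,

    VV = eta * Rand1 * (-grad OF) + phi * Rand2 * VV_prev,

magnitude-capped per dimension at |beta * VV_prev| (the velocity limiter,
keeping the sign of the capped term), and moves by VV * dt. The gradient is
central finite differences unless the objective supplies an analytic one;
the descent (negative) direction is used because the objective is a
minimization. The Aquila "contour flight with short glide attack" then
proposes

    X2 = X_best * Levy(D) + X_Rand + (Pi - K) * ra,

with a Mantegna-style Levy step and the spiral terms Pi = r cos(theta),
K = r sin(theta), r = r1 + Upsilon * D1, theta = -omega * D1 + 3*pi/2; the
mixing variate ra is |r3| from the ICMIC chaotic map x <- sin(a / x).

Both the shark move and the Aquila proposal are accepted greedily per
candidate, a delta-fraction of non-best candidates plus the incumbent best
receive greedy Gauss mutation each iteration, and the global best is
elitist, so the best-so-far trace never increases. Velocity and momentum
track the raw (pre-limit) velocity sequence so a limiter ratio below 1
damps movement instead of extinguishing it geometrically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import gamma as gamma_fn

THETA1_DEFAULT = 3.0 * math.pi / 2.0


@dataclass
class AissoConfig:
    """Optimizer parameters (names mirror the standard SSO/Aquila constants)."""

    n_pop: int = 10
    n_dim: int = 2
    iter_max: int = 25
    eta: float = 0.5  # gradient (odour) rate
    inertia: float = 0.5  # momentum coefficient
    beta_limit: float = 0.5  # velocity limiter ratio
    dt: float = 0.1
    levy_s: float = 0.01
    levy_beta: float = 1.5
    upsilon: float = 0.00565
    omega: float = 0.005
    theta1: float = THETA1_DEFAULT
    delta: float = 0.1  # mutation fraction and mutation scale (of the range)
    lb: np.ndarray | float = 0.0
    ub: np.ndarray | float = 1.0
    fd_step: float = 1e-3
    seed: int = 0
    icmic_a: float = 0.7
    icmic_x0: float = 0.7
    mantegna_exponent: bool = False  # apply the standard 1/beta outer exponent to sigma
    legacy_r: bool = False  # spiral radius r = r0 + u * iteration instead of r1 + upsilon * D1
    legacy_r0: float = 10.0
    legacy_u: float = 0.0265
    refine_best: bool = True  # greedy Gauss refinement of the incumbent best

    def __post_init__(self) -> None:
        if self.n_pop < 2:
            raise ValueError("population size must be >= 2")
        if self.iter_max < 0:
            raise ValueError("iter_max must be >= 0")
        self.lb = np.broadcast_to(np.asarray(self.lb, dtype=float), (self.n_dim,)).copy()
        self.ub = np.broadcast_to(np.asarray(self.ub, dtype=float), (self.n_dim,)).copy()
        if np.any(self.lb >= self.ub):
            raise ValueError("lower bounds must be strictly below upper bounds")


@dataclass
class Candidate:
    """A population member: position, raw velocity and objective value."""

    position: np.ndarray
    velocity: np.ndarray
    value: float = math.inf


@dataclass
class ObjectiveSpec:
    """Wraps the objective callable, counting evaluations.

    ``gradient`` is optional; when absent the optimizer falls back to
    central finite differences.
    """

    fn: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray] | None = None
    n_evals: int = 0

    def __call__(self, x: np.ndarray) -> float:
        self.n_evals += 1
        return float(self.fn(np.asarray(x, dtype=float)))


@dataclass
class AissoResult:
    best_position: np.ndarray
    best_value: float
    trace: np.ndarray  # best-so-far value per iteration (including iteration 0)
    n_evals: int
    population: list[Candidate] = field(repr=False, default_factory=list)


class IcmicStream:
    """Deterministic chaotic stream x_{k+1} = sin(a / x_k), values in [-1, 1]."""

    def __init__(self, a: float, x0: float):
        if a <= 0:
            raise ValueError("icmic parameter a must be positive")
        if x0 == 0:
            raise ValueError("icmic seed must be nonzero")
        self.a = a
        self.x = x0

    def next(self) -> float:
        self.x = math.sin(self.a / self.x)
        if self.x == 0.0:  # sine can hit exactly zero; nudge to keep the map defined
            self.x = 1e-12
        return self.x


def icmic_stream(a: float, x0: float, n: int) -> np.ndarray:
    """First ``n`` iterates of the ICMIC map."""
    stream = IcmicStream(a, x0)
    return np.array([stream.next() for _ in range(n)])


def levy_sigma(config: AissoConfig) -> float:
    """The sigma constant of the Levy step for beta = config.levy_beta.

    Implemented as printed (no outer 1/beta exponent);
    ``mantegna_exponent=True`` restores the standard Mantegna form.
    """
    b = config.levy_beta
    sigma = (gamma_fn(1.0 + b) * math.sin(math.pi * b / 2.0)) / (
        gamma_fn((1.0 + b) / 2.0) * b * 2.0 ** ((b - 1.0) / 2.0)
    )
    if config.mantegna_exponent:
        sigma = sigma ** (1.0 / b)
    return sigma


def levy_step(dim: int, config: AissoConfig, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed step s * (N1 * sigma) / |N2|^(1/beta), elementwise."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    sigma = levy_sigma(config)
    r1 = rng.standard_normal(dim)
    r2 = rng.standard_normal(dim)
    denom = np.maximum(np.abs(r2), 1e-12) ** (1.0 / config.levy_beta)
    return config.levy_s * (r1 * sigma) / denom


def finite_difference_gradient(
    objective: ObjectiveSpec, x: np.ndarray, step: float
) -> np.ndarray:
    """Central-difference gradient; a non-finite probe is retried once at step/10."""
    grad = np.empty_like(x)
    for j in range(x.size):
        for h in (step, step / 10.0):
            xp = x.copy()
            xm = x.copy()
            xp[j] += h
            xm[j] -= h
            fp, fm = objective(xp), objective(xm)
            if math.isfinite(fp) and math.isfinite(fm):
                grad[j] = (fp - fm) / (2.0 * h)
                break
        else:
            raise FloatingPointError(f"objective non-finite near dimension {j}")
    return grad


def sso_move(
    candidate: Candidate,
    best: Candidate,
    config: AissoConfig,
    rng: np.random.Generator,
    objective: ObjectiveSpec,
) -> Candidate:
    """One shark move: gradient + momentum velocity, limiter, position update.

    Returns a new evaluated candidate; the caller decides whether to accept
    the move. The raw velocity (before the limiter) is stored so momentum
    does not collapse under a limiter ratio below 1.
    """
    if objective.gradient is not None:
        grad = np.asarray(objective.gradient(candidate.position), dtype=float)
    else:
        grad = finite_difference_gradient(objective, candidate.position, config.fd_step)
    rand1 = rng.random(config.n_dim)
    rand2 = rng.random(config.n_dim)
    raw = config.eta * rand1 * (-grad) + config.inertia * rand2 * candidate.velocity
    limit = np.abs(config.beta_limit * candidate.velocity)
    applied = raw.copy()
    over = (limit > 0) & (np.abs(raw) > limit)
    applied[over] = np.copysign(limit[over], candidate.velocity[over])
    position = np.clip(candidate.position + applied * config.dt, config.lb, config.ub)
    return Candidate(position=position, velocity=raw, value=objective(position))


def aquila_update(
    candidate: Candidate,
    best: Candidate,
    population: Sequence[Candidate],
    iteration: int,
    config: AissoConfig,
    rng: np.random.Generator,
    ra: float | None = None,
) -> np.ndarray:
    """Contour-flight proposal X2 = X_best * Levy + X_R + (Pi - K) * ra, clamped."""
    d1 = np.arange(1, config.n_dim + 1, dtype=float)
    r1 = rng.uniform(0.0, 10.0)
    if config.legacy_r:
        r = np.full(config.n_dim, config.legacy_r0 + config.legacy_u * iteration)
    else:
        r = r1 + config.upsilon * d1
    theta = -config.omega * d1 + config.theta1
    pi_term = r * np.cos(theta)
    k_term = r * np.sin(theta)
    x_r = population[rng.integers(len(population))].position
    lev = levy_step(config.n_dim, config, rng)
    if ra is None:
        ra = rng.random()
    proposal = best.position * lev + x_r + (pi_term - k_term) * ra
    return np.clip(proposal, config.lb, config.ub)


def gauss_mutate(
    position: np.ndarray, config: AissoConfig, rng: np.random.Generator
) -> np.ndarray:
    """Add N(0, (delta * range)^2) noise per element, clamped to bounds."""
    sigma = config.delta * (config.ub - config.lb)
    return np.clip(position + rng.normal(0.0, 1.0, position.shape) * sigma, config.lb, config.ub)


def init_population(
    config: AissoConfig,
    rng: np.random.Generator,
    seed_solution: np.ndarray | None = None,
) -> list[Candidate]:
    """Uniform random population; an optional seed solution replaces one member."""
    span = config.ub - config.lb
    population = [
        Candidate(
            position=config.lb + rng.random(config.n_dim) * span,
            velocity=np.zeros(config.n_dim),
        )
        for _ in range(config.n_pop)
    ]
    if seed_solution is not None:
        seed_solution = np.asarray(seed_solution, dtype=float)
        if seed_solution.shape != (config.n_dim,):
            raise ValueError("seed solution dimension mismatch")
        idx = int(rng.integers(config.n_pop))
        population[idx] = Candidate(
            position=np.clip(seed_solution, config.lb, config.ub),
            velocity=np.zeros(config.n_dim),
        )
    return population


def optimize(
    objective: Callable[[np.ndarray], float] | ObjectiveSpec,
    config: AissoConfig,
    seed_solution: np.ndarray | None = None,
) -> AissoResult:
    """Run AISSO; returns the elitist best, its value, and the per-iteration trace."""
    obj = objective if isinstance(objective, ObjectiveSpec) else ObjectiveSpec(objective)
    rng = np.random.default_rng(config.seed)
    icmic = IcmicStream(config.icmic_a, config.icmic_x0)
    population = init_population(config, rng, seed_solution)
    for cand in population:
        cand.value = obj(cand.position)
    if not any(math.isfinite(c.value) for c in population):
        raise FloatingPointError("objective non-finite on the whole initial population")
    best = _clone_best(population)
    trace = [best.value]
    for iteration in range(1, config.iter_max + 1):
        for cand in population:
            moved = sso_move(cand, best, config, rng, obj)
            cand.velocity = moved.velocity
            if moved.value <= cand.value:
                cand.position, cand.value = moved.position, moved.value
            ra = abs(icmic.next())
            proposal = aquila_update(cand, best, population, iteration, config, rng, ra)
            value = obj(proposal)
            if value <= cand.value:
                cand.position, cand.value = proposal, value
        best_idx = min(range(len(population)), key=lambda i: population[i].value)
        non_best = [i for i in range(len(population)) if i != best_idx]
        n_mut = max(1, round(config.delta * len(non_best)))
        for i in rng.choice(non_best, size=min(n_mut, len(non_best)), replace=False):
            cand = population[i]
            trial = gauss_mutate(cand.position, config, rng)
            value = obj(trial)
            if value <= cand.value:
                cand.position, cand.value = trial, value
        if config.refine_best:
            trial = gauss_mutate(best.position, config, rng)
            value = obj(trial)
            if value <= best.value:
                best = Candidate(position=trial, velocity=np.zeros(config.n_dim), value=value)
        iter_best = _clone_best(population)
        if iter_best.value <= best.value:
            best = iter_best
        trace.append(best.value)
    return AissoResult(
        best_position=best.position.copy(),
        best_value=best.value,
        trace=np.asarray(trace),
        n_evals=obj.n_evals,
        population=population,
    )


def _clone_best(population: Sequence[Candidate]) -> Candidate:
    best = min(population, key=lambda c: c.value)
    return Candidate(position=best.position.copy(), velocity=best.velocity.copy(), value=best.value)
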