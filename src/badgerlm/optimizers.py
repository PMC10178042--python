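"""Population metaheuristics minimising a black-box fitness over a box.

Implements the Honey Badger Algorithm (HBA) — alternating smell-guided
"digging" moves and guide-following "honey" moves around the current best
("prey") position, with an exponentially decaying density factor — and its
tHBA extension, which perturbs agents with an adaptive Student-t mutation
whose degrees of freedom equal the iteration number: Cauchy-like heavy-tailed
exploration early, Gaussian-like refinement late. A real-coded genetic
algorithm is provided as a baseline under the same contract.

RNG discipline: each run spawns two independent streams from its seed, one
for the HBA moves and one for the mutation stage, so that tHBA with mutation
probability 0 reproduces the plain HBA trajectory exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

FitnessFn = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box: lower/upper bound per coordinate."""

    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self) -> None:
        lb = np.asarray(self.lb, dtype=float)
        ub = np.asarray(self.ub, dtype=float)
        if lb.shape != ub.shape or lb.ndim != 1:
            raise ValueError("lb and ub must be 1-D vectors of equal length")
        if not np.all(lb < ub):
            raise ValueError("lb must be strictly below ub element-wise")
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)

    @property
    def dim(self) -> int:
        return self.lb.shape[0]

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lb, self.ub)

    @classmethod
    def cube(cls, dim: int, low: float = -1.0, high: float = 1.0) -> "SearchSpace":
        return cls(np.full(dim, low), np.full(dim, high))


@dataclass(frozen=True)
class HBAConfig:
    pop_size: int = 50
    max_iter: int = 300
    C: float = 2.0  # density-factor constant, >= 1
    beta_ability: float = 6.0  # honey badger's food-finding strength
    seed: int = 0

    def validate(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be at least 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.C < 1:
            raise ValueError("C must be >= 1")


@dataclass(frozen=True)
class THBAConfig(HBAConfig):
    mutation_prob: float = 0.8  # per-agent per-iteration Bernoulli gate P
    mutation_accept: str = "greedy"  # or "always"

    def validate(self) -> None:
        super().validate()
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.mutation_accept not in ("greedy", "always"):
            raise ValueError("mutation_accept must be 'greedy' or 'always'")


@dataclass(frozen=True)
class GAConfig:
    pop_size: int = 50
    max_iter: int = 300
    tournament_size: int = 3
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    mutation_sigma_frac: float = 0.1  # sigma = frac * (ub - lb)
    seed: int = 0

    def validate(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be at least 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass
class OptimizerRun:
    """Result of one optimizer run: best point, best value, convergence trace."""

    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best-so-far fitness per iteration, length max_iter
    n_evaluations: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.history) > 0):
            raise ValueError("best-so-far history must be non-increasing")
        if self.history.size and self.best_fitness != self.history[-1]:
            raise ValueError("best_fitness must equal the last history entry")

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(1, self.history.size + 1),
                "best_fitness": self.history,
                "n_evals": np.nan,
            }
        ).assign(n_evals=self.n_evaluations)

    def write_trace(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "iteration": np.arange(1, self.history.size + 1),
                "best_fitness": self.history,
            }
        ).assign(n_evals=self.n_evaluations).to_csv(path, index=False)


def init_population(space: SearchSpace, N: int, rng) -> np.ndarray:
    """x_i = lb + r1 * (ub - lb), r1 uniform per element."""
    r1 = rng.random((N, space.dim))
    return space.lb + r1 * (space.ub - space.lb)


def smell_intensity(position, next_position, prey, rng) -> np.ndarray:
    """Inverse-square smell intensity I = r2 * S / (4 pi d^2).

    S = (x_i - x_{i+1})^2 measures local honey concentration from the gap to
    the neighbouring agent; d = x_prey - x_i is the distance to the prey.
    An epsilon guards the d = 0 singularity.
    """
    x = np.asarray(position, dtype=float)
    xn = np.asarray(next_position, dtype=float)
    p = np.asarray(prey, dtype=float)
    S = (x - xn) ** 2
    d = p - x
    r2 = rng.random(x.shape)
    return r2 * S / (4.0 * np.pi * d**2 + 1e-12)


def density_factor(t: int, tmax: int, C: float = 2.0) -> float:
    """Exploration-decay schedule alpha = C * exp(-t / tmax), 1 <= t <= tmax."""
    if not 1 <= t <= tmax:
        raise ValueError(f"iteration t={t} outside [1, {tmax}]")
    return C * np.exp(-t / tmax)


def t_mutation(position: np.ndarray, iteration: int, rng) -> np.ndarray:
    """Adaptive t-distribution disturbance x' = x + x * t_df, df = iteration.

    Early iterations (df=1, Cauchy) give heavy-tailed jumps out of local
    optima; late iterations approach Gaussian perturbations. Draws are
    independent per dimension.
    """
    if iteration < 1:
        raise ValueError("iteration must be >= 1 (t-distribution df)")
    x = np.asarray(position, dtype=float)
    return x + x * rng.standard_t(df=iteration, size=x.shape)


def hba_step(
    positions: np.ndarray,
    fitnesses: np.ndarray,
    prey: np.ndarray,
    t: int,
    config: HBAConfig,
    space: SearchSpace,
    fitness_fn: FitnessFn,
    rng,
) -> tuple[np.ndarray, np.ndarray, int]:
    """One HBA generation: digging/honey proposals with greedy replacement.

    Digging: x' = prey + F*beta*I*prey + F*r3*alpha*d*|cos(2 pi r4)*(1 - cos(2 pi r5))|
    Honey:   x' = prey + F*r7*alpha*d
    with F = +/-1 equiprobable, d = prey - x, alpha the density factor.
    Returns updated (positions, fitnesses, n_new_evaluations).
    """
    N, dim = positions.shape
    alpha = density_factor(t, config.max_iter, config.C)
    new_pos = positions.copy()
    new_fit = fitnesses.copy()
    n_evals = 0
    for i in range(N):
        x = new_pos[i]
        neighbour = new_pos[(i + 1) % N]
        I = smell_intensity(x, neighbour, prey, rng)
        d = prey - x
        F = 1.0 if rng.random() < 0.5 else -1.0
        if rng.random() < 0.5:  # digging mode
            r3 = rng.random(dim)
            r4 = rng.random(dim)
            r5 = rng.random(dim)
            cand = (
                prey
                + F * config.beta_ability * I * prey
                + F * r3 * alpha * d * np.abs(np.cos(2 * np.pi * r4) * (1 - np.cos(2 * np.pi * r5)))
            )
        else:  # honey mode
            r7 = rng.random(dim)
            cand = prey + F * r7 * alpha * d
        cand = space.clamp(cand)
        f = float(fitness_fn(cand))
        n_evals += 1
        if not np.isfinite(f):
            raise ValueError(f"non-finite fitness at iteration {t}, agent {i}")
        if f < new_fit[i]:  # greedy replacement
            new_pos[i] = cand
            new_fit[i] = f
    return new_pos, new_fit, n_evals


def _run_badger(
    fitness_fn: FitnessFn,
    space: SearchSpace,
    config: HBAConfig,
    mutation_prob: float,
    mutation_accept: str = "greedy",
) -> OptimizerRun:
    config.validate()
    root = np.random.default_rng(config.seed)
    move_rng, mut_rng = root.spawn(2)
    N = config.pop_size
    positions = init_population(space, N, move_rng)
    fitnesses = np.array([float(fitness_fn(x)) for x in positions])
    if not np.all(np.isfinite(fitnesses)):
        raise ValueError("non-finite fitness in initial population")
    n_evals = N
    best = int(np.argmin(fitnesses))
    prey = positions[best].copy()
    prey_fit = float(fitnesses[best])
    history = np.empty(config.max_iter)
    for t in range(1, config.max_iter + 1):
        positions, fitnesses, used = hba_step(
            positions, fitnesses, prey, t, config, space, fitness_fn, move_rng
        )
        n_evals += used
        if mutation_prob > 0.0:
            for i in range(N):
                if mut_rng.random() >= mutation_prob:
                    continue
                mutant = space.clamp(t_mutation(positions[i], t, mut_rng))
                f = float(fitness_fn(mutant))
                n_evals += 1
                if not np.isfinite(f):
                    raise ValueError(f"non-finite fitness at iteration {t}, agent {i} (mutation)")
                if mutation_accept == "always" or f < fitnesses[i]:
                    positions[i] = mutant
                    fitnesses[i] = f
        best = int(np.argmin(fitnesses))
        if fitnesses[best] < prey_fit:
            prey = positions[best].copy()
            prey_fit = float(fitnesses[best])
        history[t - 1] = prey_fit
    return OptimizerRun(
        best_position=prey, best_fitness=prey_fit, history=history, n_evaluations=n_evals
    )


def hba_optimize(fitness_fn: FitnessFn, space: SearchSpace, config: HBAConfig) -> OptimizerRun:
    """Plain Honey Badger Algorithm run."""
    return _run_badger(fitness_fn, space, config, mutation_prob=0.0)


def thba_optimize(fitness_fn: FitnessFn, space: SearchSpace, config: THBAConfig) -> OptimizerRun:
    """HBA with per-agent adaptive t-distribution mutation (probability P)."""
    config.validate()
    return _run_badger(
        fitness_fn, space, config,
        mutation_prob=config.mutation_prob, mutation_accept=config.mutation_accept,
    )


def ga_optimize(fitness_fn: FitnessFn, space: SearchSpace, config: GAConfig) -> OptimizerRun:
    """Real-coded GA baseline: tournament selection, arithmetic crossover,
    Gaussian mutation, single-elite survival."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    N, dim = config.pop_size, space.dim
    sigma = config.mutation_sigma_frac * (space.ub - space.lb)
    pop = init_population(space, N, rng)
    fit = np.array([float(fitness_fn(x)) for x in pop])
    if not np.all(np.isfinite(fit)):
        raise ValueError("non-finite fitness in initial population")
    n_evals = N

    def tournament() -> np.ndarray:
        idx = rng.integers(0, N, size=config.tournament_size)
        return pop[idx[np.argmin(fit[idx])]]

    history = np.empty(config.max_iter)
    for t in range(1, config.max_iter + 1):
        elite_i = int(np.argmin(fit))
        elite, elite_f = pop[elite_i].copy(), float(fit[elite_i])
        children = [elite]
        child_fit = [elite_f]
        while len(children) < N:
            p1, p2 = tournament(), tournament()
            if rng.random() < config.crossover_rate:
                lam = rng.random()
                child = lam * p1 + (1 - lam) * p2
            else:
                child = p1.copy()
            mask = rng.random(dim) < config.mutation_rate
            if mask.any():
                child = child + mask * rng.normal(0.0, sigma)
            child = space.clamp(child)
            f = float(fitness_fn(child))
            if not np.isfinite(f):
                raise ValueError(f"non-finite fitness at generation {t}")
            n_evals += 1
            children.append(child)
            child_fit.append(f)
        pop = np.array(children)
        fit = np.array(child_fit)
        history[t - 1] = float(fit.min())
    best = int(np.argmin(fit))
    return OptimizerRun(
        best_position=pop[best].copy(),
        best_fitness=float(fit[best]),
        history=np.minimum.accumulate(history),
        n_evaluations=n_evals,
    )
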