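"""Binary-coded genetic algorithm providing the identifier's cold start.

The bounded search box is mapped onto a bitstring: each of the five
parameters is linearly quantised to 2^bits levels over its own
[lb_i, ub_i] interval and the five codes are concatenated in the fixed
Theta order.  A small generational GA (tournament selection, single-point
crossover, per-bit mutation, elitism) evolves a population against the
identification cost of the first buffered cycle and returns the decoded
best individual.  It is run once at start-up only; after that, the
per-cycle optimiser is warm-started from the previous cycle's estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .identification import cost as _cycle_cost
from .signals_io import CycleBuffer
from .windkessel import DivergenceError, ParamBounds, WindkesselParams

__all__ = ["GAConfig", "encode", "decode", "ga_initialize"]


@dataclass(frozen=True)
class GAConfig:
    """Operator settings; defaults are a textbook generational GA."""

    population: int = 100
    bits: int = 16  # bits per parameter
    p_crossover: float = 0.8  # single-point crossover probability
    p_mutation: float = 0.01  # per-bit mutation probability
    elite: int = 1
    max_generations: int = 100
    stall_tol: float = 1e-6  # relative best-cost change ...
    stall_window: int = 20  # ... over this many generations
    n_restarts: int = 3  # independent populations; best result wins
    seed: int | None = None

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.bits < 4:
            raise ValueError("need at least 4 bits per parameter")
        for p in (self.p_crossover, self.p_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def encode(theta: WindkesselParams, bounds: ParamBounds, bits: int = 16) -> np.ndarray:
    """Map theta onto a concatenated binary code (boolean array, 5*bits).

    Each parameter is quantised to the nearest of 2^bits levels spread
    linearly over [lb_i, ub_i]; theta must lie inside the bounds.
    """
    t = theta.as_array() if isinstance(theta, WindkesselParams) else np.asarray(theta)
    lb, ub = bounds.lb.as_array(), bounds.ub.as_array()
    if np.any(t < lb) or np.any(t > ub):
        raise ValueError("theta outside bounds cannot be encoded")
    levels = (1 << bits) - 1
    codes = np.rint((t - lb) / (ub - lb) * levels).astype(np.int64)
    out = np.zeros(5 * bits, dtype=bool)
    for i, c in enumerate(codes):
        for b in range(bits):
            out[i * bits + b] = (c >> (bits - 1 - b)) & 1
    return out


def decode(bitstring: np.ndarray, bounds: ParamBounds, bits: int = 16) -> WindkesselParams:
    """Inverse of :func:`encode`: all-zero maps to lb, all-one to ub."""
    bitstring = np.asarray(bitstring).astype(bool)
    if bitstring.shape != (5 * bits,):
        raise ValueError(f"bitstring must have length {5 * bits}, got {bitstring.shape}")
    lb, ub = bounds.lb.as_array(), bounds.ub.as_array()
    levels = (1 << bits) - 1
    weights = 1 << np.arange(bits - 1, -1, -1, dtype=np.int64)
    codes = bitstring.reshape(5, bits) @ weights
    return WindkesselParams.from_array(lb + codes / levels * (ub - lb))


def _fitness(pop: np.ndarray, cycle: CycleBuffer, bounds: ParamBounds, bits: int):
    costs = np.empty(pop.shape[0])
    for i, individual in enumerate(pop):
        try:
            costs[i] = _cycle_cost(decode(individual, bounds, bits), cycle)
        except DivergenceError:
            costs[i] = np.inf
    return costs


def ga_initialize(
    cycle: CycleBuffer,
    bounds: ParamBounds,
    config: GAConfig | None = None,
    initial_population: np.ndarray | None = None,
) -> WindkesselParams:
    """Run ``config.n_restarts`` independent GA populations against the
    cycle cost, refine each restart's champion with the bounded local
    solver, and return the refined parameter vector with the lowest
    cost.  Fully reproducible from ``config.seed``.

    Restarts plus local refinement are the standard memetic guard
    against premature convergence: a single small-population binary GA
    occasionally homogenises inside a deceptive basin (e.g. with the
    inertance stuck near its upper bound) whose raw sample cost can even
    undercut a coarse sample of the true basin; comparing the basins
    *after* local descent makes the selection sharp.

    ``initial_population`` (boolean array, population x 5*bits) overrides
    the random initialisation and disables restarts — mainly for
    studying operator behaviour.
    """
    from .identification import IdentConfig, identify_cycle

    config = config or GAConfig()
    n_runs = 1 if initial_population is not None else max(1, config.n_restarts)
    best_theta = None
    best_cost = np.inf
    for child in np.random.SeedSequence(config.seed).spawn(n_runs):
        theta, cost = _evolve_once(
            cycle, bounds, config, np.random.default_rng(child), initial_population
        )
        try:
            refined = identify_cycle(cycle, theta, IdentConfig(bounds=bounds))
            if refined.cost < cost:
                theta, cost = refined.theta_hat, refined.cost
        except DivergenceError:
            pass  # keep the unrefined champion
        if cost < best_cost or best_theta is None:
            best_theta, best_cost = theta, cost
    return best_theta


def _evolve_once(cycle, bounds, config, rng, initial_population):
    n_bits = 5 * config.bits
    if initial_population is not None:
        pop = np.array(initial_population, dtype=bool)
        if pop.shape != (config.population, n_bits):
            raise ValueError("initial_population has wrong shape")
    else:
        pop = rng.random((config.population, n_bits)) < 0.5
    costs = _fitness(pop, cycle, bounds, config.bits)
    best_hist = [costs.min()]

    for _ in range(config.max_generations):
        order = np.argsort(costs, kind="stable")
        elite = pop[order[: config.elite]].copy()

        # tournament selection, size 2
        n_off = config.population - config.elite
        a = rng.integers(0, config.population, 2 * n_off)
        b = rng.integers(0, config.population, 2 * n_off)
        parents = pop[np.where(costs[a] <= costs[b], a, b)]

        # single-point crossover on consecutive pairs
        children = parents.copy()
        for i in range(0, 2 * n_off - 1, 2):
            if rng.random() < config.p_crossover:
                cut = rng.integers(1, n_bits)
                children[i, cut:], children[i + 1, cut:] = (
                    parents[i + 1, cut:].copy(),
                    parents[i, cut:].copy(),
                )
        children = children[:n_off]

        # per-bit mutation
        flip = rng.random(children.shape) < config.p_mutation
        children ^= flip

        pop = np.concatenate([elite, children])
        costs = _fitness(pop, cycle, bounds, config.bits)
        best_hist.append(costs.min())

        # stall: relative best-cost change over the window
        if len(best_hist) > config.stall_window:
            old = best_hist[-1 - config.stall_window]
            new = best_hist[-1]
            if np.isfinite(old) and old > 0 and (old - new) / old < config.stall_tol:
                break

    i = int(np.argmin(costs))
    return decode(pop[i], bounds, config.bits), float(costs[i])
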