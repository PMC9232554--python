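"""Optimal experimental design of chemostat inflow patterns.

The design variable is the per-cycle, per-construct inflow-fraction matrix
(optionally together with the stock concentrations).  A design is scored by
the information it carries about the model parameters: the D-criterion is
log det of the Fisher information matrix FIM = S^T S built from relative
output sensitivities -- maximizing it minimizes the volume of the parameter
confidence ellipsoid.  Alternatively the (negated) mean lumped collinearity
index can be used, targeting covariance between parameters directly.

Because sensitivities depend on the parameter values, an optimized design is
only optimal near its nominal parameters; a robust mode averages the score
over an ensemble of plausible parameter sets.

The search is a seeded elitist genetic algorithm over the discrete
inflow-fraction grid: the hardware loads material in fixed steps, so fraction
levels are inherently quantized.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chemostat_io import ChemostatConfig, InflowProtocol
from .circuit_model import NetworkSpec, ParameterSet
from .identifiability import mean_lumped_index, pairwise_collinearity
from .simulator import IntegrationError, forward_sensitivities

RIDGE = 1e-12
DEFAULT_IF_LEVELS = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


@dataclass
class DesignProblem:
    """Search space and scoring configuration for one inflow-pattern design."""

    network: NetworkSpec
    params: ParameterSet | Sequence[ParameterSet]  # nominal estimate or ensemble
    labels: Sequence[str]  # parameters the design should inform
    n_cycles: int = 16
    if_levels: tuple[float, ...] = DEFAULT_IF_LEVELS
    stocks: dict[str, float] | None = None  # fixed stocks, or None to co-optimize
    stock_bounds: tuple[float, float] = (1.0, 20.0)
    criterion: str = "D"  # "D" | "collinearity"
    config: ChemostatConfig = field(default_factory=ChemostatConfig)
    rtol: float = 1e-6

    def __post_init__(self) -> None:
        if self.criterion not in ("D", "collinearity"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if not self.if_levels or min(self.if_levels) < 0 or max(self.if_levels) > 1:
            raise ValueError("IF levels must lie in [0, 1]")
        if self.n_cycles < 1:
            raise ValueError("design space needs at least one cycle")

    @property
    def param_list(self) -> list[ParameterSet]:
        if isinstance(self.params, ParameterSet):
            return [self.params]
        return list(self.params)


def score_design(protocol: InflowProtocol, problem: DesignProblem) -> float:
    """Information score of one protocol; higher is better.

    D-criterion: log det(FIM + ridge); collinearity criterion: negated mean
    lumped pairwise collinearity index.  Robust mode (ensemble nominal
    parameters) averages over the ensemble.  Integration failure scores -inf.
    """
    scores = []
    for params in problem.param_list:
        try:
            S = forward_sensitivities(
                problem.network,
                params,
                protocol,
                labels=problem.labels,
                rtol=problem.rtol,
                scaling="absolute" if problem.criterion == "D" else "relative",
            )
        except IntegrationError:
            return -math.inf
        if problem.criterion == "D":
            # absolute (log-parameter) sensitivities against an implicit
            # constant noise scale: signal magnitude carries information
            flat = S.flattened()
            fim = flat.T @ flat + RIDGE * np.eye(flat.shape[1])
            sign, logdet = np.linalg.slogdet(fim)
            scores.append(logdet if sign > 0 else -math.inf)
        else:
            scores.append(-mean_lumped_index(pairwise_collinearity(S)))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Genetic search


@dataclass
class _Individual:
    fractions: np.ndarray  # [cycle, construct] on the IF grid
    stocks: np.ndarray  # per construct

    def feasible(self) -> np.ndarray:
        """Renormalize rows whose fraction sum exceeds the DNA/MQ share."""
        f = self.fractions.copy()
        s = f.sum(axis=1)
        over = s > 1.0
        if over.any():
            f[over] /= s[over, None]
        return f


def _protocol_of(ind: _Individual, problem: DesignProblem) -> InflowProtocol:
    names = tuple(c.name for c in problem.network.constructs)
    return InflowProtocol(
        constructs=names,
        stocks={n: float(s) for n, s in zip(names, ind.stocks)},
        fractions=ind.feasible(),
        config=problem.config,
    )


def optimize_design(
    problem: DesignProblem,
    budget: int = 200,
    seed: int = 0,
    population: int = 20,
    elite: int = 4,
    mutation_rate: float = 0.15,
    log_path=None,
) -> tuple[InflowProtocol, float]:
    """Elitist genetic search over inflow matrices (and stocks, if free).

    Reproducible given ``seed``; the returned score is guaranteed to be at
    least the best of the random initial population (elitism).  ``budget``
    counts design evaluations and must cover the initial population.
    """
    if budget < population:
        raise ValueError("budget must cover at least the initial population")
    rng = np.random.default_rng(seed)
    names = [c.name for c in problem.network.constructs]
    n_c = len(names)
    levels = np.asarray(problem.if_levels)

    def random_individual() -> _Individual:
        frac = rng.choice(levels, size=(problem.n_cycles, n_c))
        if problem.stocks is not None:
            stocks = np.array([problem.stocks[n] for n in names])
        else:
            lo, hi = problem.stock_bounds
            stocks = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_c))
        return _Individual(frac, stocks)

    def mutate(ind: _Individual) -> _Individual:
        frac = ind.fractions.copy()
        mask = rng.random(frac.shape) < mutation_rate
        frac[mask] = rng.choice(levels, size=int(mask.sum()))
        stocks = ind.stocks.copy()
        if problem.stocks is None and rng.random() < 0.5:
            k = rng.integers(n_c)
            lo, hi = problem.stock_bounds
            stocks[k] = float(np.clip(stocks[k] * math.exp(rng.normal(0, 0.3)), lo, hi))
        return _Individual(frac, stocks)

    def crossover(a: _Individual, b: _Individual) -> _Individual:
        rows = rng.random(problem.n_cycles) < 0.5
        frac = np.where(rows[:, None], a.fractions, b.fractions)
        stocks = np.where(rng.random(n_c) < 0.5, a.stocks, b.stocks)
        return _Individual(frac, stocks)

    pop = [random_individual() for _ in range(population)]
    scores = [score_design(_protocol_of(ind, problem), problem) for ind in pop]
    evaluations = population
    log_rows = [(0, max(scores))]

    gen = 0
    while evaluations < budget:
        gen += 1
        order = np.argsort(scores)[::-1]
        pop = [pop[i] for i in order]
        scores = [scores[i] for i in order]
        children: list[_Individual] = []
        while len(children) < population - elite and evaluations + len(children) < budget:
            pa, pb = rng.choice(elite + 2, 2, replace=False)
            child = mutate(crossover(pop[min(pa, len(pop) - 1)], pop[min(pb, len(pop) - 1)]))
            children.append(child)
        if not children:
            break
        child_scores = [score_design(_protocol_of(c, problem), problem) for c in children]
        evaluations += len(children)
        pop = pop[:elite] + children
        scores = scores[:elite] + child_scores
        log_rows.append((gen, max(scores)))

    best = int(np.argmax(scores))
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["generation", "best_score"])
            w.writerows(log_rows)
    return _protocol_of(pop[best], problem), float(scores[best])
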