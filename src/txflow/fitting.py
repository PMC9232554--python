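"""Ensemble fitting of experiment databases with shared parameters.

All experiments -- possibly from different circuits -- are fitted
simultaneously: parameters are globally labelled, so a rate shared by two
networks (say the activator's transcription rate) is a single degree of
freedom constrained by every experiment that uses it.  The optimizer is an
island-model differential-evolution population search in log-parameter space
(Hill coefficients stay linear); rather than a point estimate it returns an
ensemble of good parameter sets, whose spread is summarized by the
distribution width: mean of the five highest over mean of the five lowest
values per parameter.

A soft biophysical constraint keeps the fully-activated steady-state
mRNA/template ratio of every construct inside (2, 500), ruling out parameter
sets that trade transcription against translation in regimes incompatible
with measured cell-free mRNA levels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chemostat_io import InflowProtocol
from .circuit_model import (
    GeneConstruct,
    NetworkSpec,
    ParameterSet,
    build_ode_system,
    steady_state_mrna_ratio,
)
from .simulator import IntegrationError, Trajectory, simulate

logger = logging.getLogger(__name__)

RATIO_LO = 2.0
RATIO_HI = 500.0
BOUNDARY_TOL = 1e-9
FAILURE_PENALTY = 1e12


class FittingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Database containers


@dataclass
class Experiment:
    """One chemostat run: network, executed protocol and observed reporter traces."""

    network: NetworkSpec
    protocol: InflowProtocol
    times: np.ndarray  # min, observation times (subset of simulatable times)
    observed: np.ndarray  # [time, reporters] in nM
    reporters: tuple[str, ...]  # observable species names (mature pools)
    weights: np.ndarray | None = None  # per-point weights; default 1/max(trace)
    name: str = "experiment"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float).reshape(
            self.times.size, len(self.reporters)
        )
        if self.weights is None:
            scale = np.maximum(np.abs(self.observed).max(axis=0), 1.0)
            self.weights = np.tile(1.0 / scale, (self.times.size, 1))
        else:
            self.weights = np.asarray(self.weights, dtype=float).reshape(self.observed.shape)


@dataclass
class ExperimentDatabase:
    experiments: list[Experiment]

    def networks(self) -> list[NetworkSpec]:
        seen: dict[str, NetworkSpec] = {}
        for e in self.experiments:
            seen.setdefault(e.network.name, e.network)
        return list(seen.values())

    def parameter_labels(self, params: ParameterSet) -> list[str]:
        """Global labels actually exercised by the database's networks."""
        labels: list[str] = []
        for lbl in params.labels():
            if any(_network_uses(net, lbl) for net in self.networks()):
                labels.append(lbl)
        return labels


def _network_uses(network: NetworkSpec, label: str) -> bool:
    cons = network.constructs
    if label == "kcat_tx_s70":
        return any(c.promoter == "p70a" for c in cons)
    if label in ("kcat_tx_s19", "kd_s19"):
        return any(c.promoter == "p19a" for c in cons)
    if label.startswith("kcat_tl."):
        _, orf, flag = label.split(".")
        return any(c.orf == orf and c.riboj == (flag == "riboj") for c in cons)
    if label.startswith(("kd_rep.", "n_rep.")):
        rep = label.split(".")[1]
        return any(c.repressed_by == rep for c in cons)
    if label.startswith("kdeg_mrna."):
        orf = label.split(".")[1]
        return any(c.orf == orf for c in cons)
    return False


# ---------------------------------------------------------------------------
# Objective


def soft_constraint_penalty(
    params: ParameterSet,
    networks: Sequence[NetworkSpec],
    lam: float,
    weight: float = 1.0,
) -> float:
    """Quadratic hinge outside the allowed steady-state mRNA/DNA ratio (2, 500).

    Zero inside the interval (boundaries accepted to within 1e-9); grows
    smoothly outside.  Evaluated for every construct of every network in its
    fully activated, unrepressed condition.
    """
    total = 0.0
    for net in networks:
        for c in net.constructs:
            r = steady_state_mrna_ratio(c, params, lam)
            if math.isinf(r):
                total += FAILURE_PENALTY
            elif r < RATIO_LO - BOUNDARY_TOL:
                total += (RATIO_LO - r) ** 2
            elif r > RATIO_HI + BOUNDARY_TOL:
                total += ((r - RATIO_HI) / RATIO_HI) ** 2
    return weight * total


def objective(
    db: ExperimentDatabase,
    params: ParameterSet,
    penalty_weight: float = 1.0,
    rtol: float = 1e-6,
) -> float:
    """Weighted sum of squared residuals over all experiments plus soft penalty.

    Integration failures return a large finite penalty so population searches
    survive pathological parameter sets.
    """
    total = 0.0
    lam = db.experiments[0].protocol.config.dilution_rate if db.experiments else 0.0
    for exp in db.experiments:
        try:
            system = build_ode_system(exp.network, params)
            traj = simulate(system, exp.protocol, exp.times, rtol=rtol)
        except (IntegrationError, ValueError) as exc:
            logger.warning("simulation failed for %s: %s", exp.name, exc)
            return FAILURE_PENALTY
        sim = np.column_stack(
            [traj.observable(r) for r in exp.reporters]
        )
        res = (sim - exp.observed) * exp.weights
        total += float(np.sum(res**2))
    total += soft_constraint_penalty(params, db.networks(), lam, weight=penalty_weight)
    return total


# ---------------------------------------------------------------------------
# Parameter-space transforms and sampling


def _is_log_label(label: str) -> bool:
    """Rates and dissociation constants vary over decades -> log scale;
    Hill coefficients stay linear."""
    return not label.startswith("n_rep.")


def _to_z(value: float, label: str) -> float:
    return math.log(value) if _is_log_label(label) else value


def _from_z(z: float, label: str) -> float:
    return math.exp(z) if _is_log_label(label) else z


def sample_parameter_sets(
    template: ParameterSet,
    bounds: Mapping[str, tuple[float, float]],
    n: int,
    rng: np.random.Generator,
    labels: Sequence[str] | None = None,
) -> list[ParameterSet]:
    """Uniform sampling within bounds: log-uniform for rates, uniform for Hill
    coefficients.  Unlisted labels keep the template value."""
    labels = list(labels) if labels is not None else [l for l in template.labels() if l in bounds]
    out = []
    for _ in range(n):
        p = template.copy()
        for lbl in labels:
            lo, hi = bounds[lbl]
            zlo, zhi = _to_z(lo, lbl), _to_z(hi, lbl)
            p[lbl] = _from_z(rng.uniform(zlo, zhi), lbl)
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# Ensemble containers


@dataclass
class ParameterEnsemble:
    """Scored collection of parameter sets from one fitting run, best first."""

    members: list[tuple[ParameterSet, float]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.members.sort(key=lambda m: m[1])

    def __len__(self) -> int:
        return len(self.members)

    @property
    def best(self) -> ParameterSet:
        return self.members[0][0]

    @property
    def best_score(self) -> float:
        return self.members[0][1]

    def values(self, label: str) -> np.ndarray:
        return np.array([p[label] for p, _ in self.members])

    def top_fraction(self, quantile: float) -> list[ParameterSet]:
        if not (0.0 < quantile <= 1.0):
            raise ValueError("quantile must lie in (0, 1]")
        k = max(1, math.ceil(quantile * len(self.members)))
        return [p for p, _ in self.members[:k]]


def distribution_width(ensemble: ParameterEnsemble | Sequence[float], label: str | None = None) -> float:
    """Spread metric: mean of the five highest over mean of the five lowest values."""
    if isinstance(ensemble, ParameterEnsemble):
        if label is None:
            raise ValueError("label required when passing an ensemble")
        values = ensemble.values(label)
    else:
        values = np.asarray(ensemble, dtype=float)
    if values.size < 10:
        raise ValueError(f"distribution width needs >= 10 members, got {values.size}")
    s = np.sort(values)
    return float(s[-5:].mean() / s[:5].mean())


def category_widths(
    ensemble: ParameterEnsemble,
    labels: Sequence[str] | None = None,
    reference: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Mean distribution width per lumped category, optionally normalized to a
    reference run's category widths."""
    labels = list(labels) if labels is not None else ensemble.best.labels()
    per_cat: dict[str, list[float]] = {}
    for lbl in labels:
        w = distribution_width(ensemble, lbl)
        per_cat.setdefault(ParameterSet.category_of(lbl), []).append(w)
    out = {c: float(np.mean(v)) for c, v in per_cat.items()}
    if reference:
        out = {c: out[c] / reference[c] for c in out if c in reference}
    return out


def riboj_factor(pairs: Sequence[tuple[float, float]]) -> float:
    """Median translation-rate increase upon adding the RiboJ insulator.

    ``pairs`` are (rate with RiboJ, rate without); used to extrapolate rates
    for parts characterized only in one configuration.
    """
    if not pairs:
        raise ValueError("at least one (with, without) pair required")
    ratios = []
    for with_rj, without_rj in pairs:
        if with_rj <= 0 or without_rj <= 0:
            raise ValueError("translation rates must be positive")
        ratios.append(with_rj / without_rj)
    return float(np.median(ratios))


# ---------------------------------------------------------------------------
# Database fitting (island-model differential evolution)


def fit_database(
    db: ExperimentDatabase,
    template: ParameterSet,
    bounds: Mapping[str, tuple[float, float]],
    n_agents: int = 24,
    n_rounds: int = 40,
    seed: int = 0,
    n_islands: int = 2,
    migration_every: int = 10,
    de_f: float = 0.7,
    de_cr: float = 0.9,
    ensemble_factor: float = 2.0,
    penalty_weight: float = 1.0,
    rtol: float = 1e-6,
) -> ParameterEnsemble:
    """Fit all experiments simultaneously; return an ensemble of good agents.

    Differential evolution (rand/1/bin) runs on ``n_islands`` islands with
    periodic best-agent migration; proposals live in log space for rates.  The
    returned ensemble holds every distinct agent from the final population
    (plus the best-ever point) whose objective is within ``ensemble_factor``
    of the best, mirroring a distribution-keeping rather than point-estimate
    philosophy.
    """
    if n_agents < 20:
        raise ValueError("population search needs at least 20 agents")
    labels = [l for l in db.parameter_labels(template) if l in bounds]
    if not labels:
        raise FittingError("no free parameters: bounds do not cover the database's labels")
    rng = np.random.default_rng(seed)
    d = len(labels)
    zlo = np.array([_to_z(bounds[l][0], l) for l in labels])
    zhi = np.array([_to_z(bounds[l][1], l) for l in labels])
    if np.any(zhi < zlo):
        raise FittingError("invalid bounds: lower > upper")

    def decode(z: np.ndarray) -> ParameterSet:
        p = template.copy()
        for k, lbl in enumerate(labels):
            p[lbl] = _from_z(float(z[k]), lbl)
        return p

    def evaluate(z: np.ndarray) -> float:
        return objective(db, decode(z), penalty_weight=penalty_weight, rtol=rtol)

    pop = rng.uniform(zlo, zhi, size=(n_agents, d))
    scores = np.array([evaluate(z) for z in pop])
    if not np.any(np.isfinite(scores) & (scores < FAILURE_PENALTY)):
        raise FittingError("no agent attained a finite objective on the initial population")

    islands = np.array_split(np.arange(n_agents), n_islands)
    best_z = pop[scores.argmin()].copy()
    best_s = float(scores.min())

    for rnd in range(n_rounds):
        for isl in islands:
            for i in isl:
                a, b, c = rng.choice(isl[isl != i] if isl.size > 3 else np.arange(n_agents), 3, replace=False)
                mutant = pop[a] + de_f * (pop[b] - pop[c])
                cross = rng.random(d) < de_cr
                cross[rng.integers(d)] = True
                trial = np.where(cross, mutant, pop[i])
                trial = np.clip(trial, zlo, zhi)
                s = evaluate(trial)
                if s <= scores[i]:
                    pop[i] = trial
                    scores[i] = s
                    if s < best_s:
                        best_s = s
                        best_z = trial.copy()
        if n_islands > 1 and (rnd + 1) % migration_every == 0:
            # replace each island's worst with the global best
            for isl in islands:
                w = isl[scores[isl].argmax()]
                pop[w] = best_z.copy()
                scores[w] = best_s

    # assemble ensemble from the final population + best-ever; every agent
    # within the objective cutoff is kept (the product is a distribution of
    # plausible fits, not a point estimate)
    candidates = [(pop[i].copy(), float(scores[i])) for i in range(n_agents)]
    candidates.append((best_z, best_s))
    cutoff = ensemble_factor * best_s + 1e-12
    members: list[tuple[ParameterSet, float]] = [
        (decode(z), s) for z, s in candidates if s <= cutoff
    ]
    return ParameterEnsemble(
        members=members,
        provenance={
            "seed": seed,
            "labels": labels,
            "n_agents": n_agents,
            "n_rounds": n_rounds,
            "n_islands": n_islands,
            "best_score": best_s,
        },
    )


def prediction_band(
    ensemble: ParameterEnsemble,
    network: NetworkSpec,
    protocol: InflowProtocol,
    quantile: float = 0.25,
    t_grid: Sequence[float] | None = None,
    rtol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    """Pointwise mean and standard deviation of the observables over the best
    ``quantile`` fraction of the ensemble.

    Returns (times, mean [time, reporters], sd, reporter names).
    """
    members = ensemble.top_fraction(quantile)
    if not members:
        raise ValueError("empty quantile slice")
    sims = []
    reporters: tuple[str, ...] = ()
    times = None
    for p in members:
        traj = simulate(build_ode_system(network, p), protocol, t_grid, rtol=rtol)
        sims.append(traj.observables)
        reporters = traj.observable_species
        times = traj.times
    stack = np.stack(sims)
    return times, stack.mean(axis=0), stack.std(axis=0), reporters
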