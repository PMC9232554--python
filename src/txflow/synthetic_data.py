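"""Ground-truth synthetic chemostat studies for benchmarking every analysis stage.

The generator emulates what the microfluidic platform measures: one image per
refresh cycle of the mature reporter pools, corrupted by additive truncated
Gaussian noise with sd = max(sigma_abs, sigma_rel * signal).  The true
parameters are stored separately from the observations, so fitting and
prediction can be validated against a known answer.  Regeneration from the
same (seed, configuration) is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemostat_io import ChemostatConfig
from .circuit_library import (
    ExperimentRegistry,
    characterization_protocol,
    iffl_characterization_registry,
    make_iffl,
)
from .circuit_model import ParameterSet, build_ode_system
from .fitting import Experiment, ExperimentDatabase
from .identifiability import pool_experiments
from .simulator import (
    SensitivityMatrix,
    batch_sensitivities,
    cycle_boundary_times,
    forward_sensitivities,
    simulate,
)


@dataclass(frozen=True)
class NoiseModel:
    """Additive truncated Gaussian on mature-reporter observables only."""

    sigma_abs: float = 5.0  # nM
    sigma_rel: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma_abs < 0 or self.sigma_rel < 0:
            raise ValueError("noise standard deviations must be non-negative")

    def apply(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        sd = np.maximum(self.sigma_abs, self.sigma_rel * signal)
        noisy = signal + rng.normal(0.0, 1.0, size=signal.shape) * sd
        return np.clip(noisy, 0.0, None)


@dataclass
class SyntheticStudy:
    """A generated database plus the ground truth that produced it."""

    truth: ParameterSet
    database: ExperimentDatabase
    noise: NoiseModel
    seed: int
    registry: ExperimentRegistry


def generate_study(
    true_params: ParameterSet,
    registry: ExperimentRegistry | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    n_cycles: int = 24,
    rtol: float = 1e-8,
    config: ChemostatConfig | None = None,
) -> SyntheticStudy:
    """Simulate every registry entry at the truth and add measurement noise.

    Observation times are cycle boundaries (one image per cycle); noiseless
    mode (sigma_abs = sigma_rel = 0) returns the simulations exactly.
    """
    registry = registry or iffl_characterization_registry()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    experiments = []
    for entry in registry.entries:
        protocol = characterization_protocol(entry, n_cycles=n_cycles, config=config)
        system = build_ode_system(entry.network, true_params)
        traj = simulate(system, protocol, rtol=rtol)
        observed = noise.apply(traj.observables, rng)
        experiments.append(
            Experiment(
                network=entry.network,
                protocol=protocol,
                times=traj.times,
                observed=observed,
                reporters=traj.observable_species,
                name=entry.experiment_id,
            )
        )
    return SyntheticStudy(
        truth=true_params,
        database=ExperimentDatabase(experiments=experiments),
        noise=noise,
        seed=seed,
        registry=registry,
    )


# ---------------------------------------------------------------------------
# Identifiability scenario bundles (design-quality comparison)

BATCH_TETR_DNA_SERIES = (0.0, 0.25, 0.5, 0.75, 1.0)  # nM, linear spacing

#: extract-activity decay rate in batch reactions (1/min, ~2 h lifetime):
#: without media refresh, nutrient depletion shuts expression down within a
#: few hours, which bounds the informative window of a batch experiment
BATCH_ACTIVITY_DECAY = 0.008


def make_identifiability_scenarios(
    true_params: ParameterSet,
    seed: int = 0,
    n_cycles: int = 16,
    batch_cycles: int = 6,
    rtol: float = 1e-6,
    repressors: tuple[str, ...] = ("TetR", "CymR", "PhlF"),
) -> dict[str, SensitivityMatrix]:
    """Pooled sensitivity matrices for four experiment-design scenarios.

    * ``batch``: five batch experiments on the TetR-RiboJ IFFL, no dilution,
      initial TetR-construct template spanning 0 to 1 nM; extract activity
      decays (no media refresh) and the observation window covers the first
      few hours during which batch expression lasts (``batch_cycles``);
    * ``step``: the single step-calibration flow experiment;
    * ``optimized``: the single information-optimized flow experiment;
    * ``database``: every step and optimized experiment of all IFFL variants
      pooled into one design matrix (shared parameters share columns).

    All scenarios are deterministic given the parameters; ``seed`` is recorded
    for provenance of any downstream stochastic use.
    """
    del seed  # scenarios are deterministic; kept for interface symmetry
    tetr_net = make_iffl("TetR", riboj=True)
    labels = _network_labels(tetr_net, true_params)
    T = ChemostatConfig().cycle_time

    # batch series: fixed initial templates, no inflow/dilution, aging extract
    batch_mats = []
    species = tetr_net.species
    batch_grid = np.arange(0, batch_cycles + 1) * T
    for dna in BATCH_TETR_DNA_SERIES:
        y0 = np.zeros(len(species))
        y0[species.index("DNA_p70a-s19")] = 1.0
        y0[species.index("DNA_p19a-RiboJ-TetR")] = dna
        y0[species.index("DNA_p19aTetRO1-RiboJ-deGFP")] = 1.0
        batch_mats.append(
            batch_sensitivities(
                tetr_net, true_params, y0, batch_grid,
                labels=labels, rtol=rtol,
                activity=lambda t: np.exp(-BATCH_ACTIVITY_DECAY * t),
            )
        )
    scenarios: dict[str, SensitivityMatrix] = {"batch": pool_experiments(batch_mats)}

    registry = iffl_characterization_registry()
    flow_mats: dict[str, SensitivityMatrix] = {}
    for entry in registry.entries:
        if entry.kind == "sigma19_pulse":
            net_labels = _network_labels(entry.network, true_params)
        elif not entry.model_id.startswith(
            tuple(f"IFFL-{r}" for r in repressors)
        ):
            continue
        else:
            net_labels = _network_labels(entry.network, true_params)
        protocol = characterization_protocol(entry, n_cycles=n_cycles)
        flow_mats[entry.experiment_id] = forward_sensitivities(
            entry.network, true_params, protocol, labels=net_labels, rtol=rtol
        )

    scenarios["step"] = flow_mats["IFFL-TetR-RiboJ-step"]
    scenarios["optimized"] = flow_mats["IFFL-TetR-RiboJ-optimized"]
    scenarios["database"] = pool_experiments(list(flow_mats.values()))
    return scenarios


def _network_labels(network, params: ParameterSet) -> list[str]:
    from .fitting import _network_uses

    return [l for l in params.labels() if _network_uses(network, l)]
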