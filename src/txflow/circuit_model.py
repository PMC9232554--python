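"""Domain types for cell-free gene circuits and assembly of the chemostat ODE right-hand side.

The model is a coarse-grained description of cell-free transcription-translation
(TX-TL) in a continuously diluted microfluidic reactor.  Each transcription unit
(construct) contributes three state variables -- template DNA, mRNA and protein --
with fluorescent reporters split into a dark (immature) and a mature pool.  Rates
fall into four lumped categories:

* ``K_TX`` -- transcription: linear in template for the constitutive sigma-70
  promoter; Michaelis-Menten in the sigma-19 activator for the inducible promoter,
  optionally gated by a Hill repression term when an operator is present.
* ``K_TL`` -- translation: linear in mRNA with an (ORF, RiboJ)-specific rate.
* ``K_reg`` -- repression: Hill function of repressor concentration.
* ``K_deg`` -- first-order mRNA degradation.  Protein degradation is neglected
  (half-life >> dilution); proteins are removed by chemostat outflow only.

Units are nM and minutes throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import yaml

PROMOTERS = ("p70a", "p19a")
OPERATORS = ("TetRO1", "CymRO1", "PhlFO1")
REPRESSORS = ("TetR", "CymR", "PhlF")
REPORTERS = ("deGFP", "mmCherry")
ORFS = ("sigma19", "TetR", "CymR", "PhlF", "deGFP", "mmCherry")

#: operator -> repressor protein that binds it
REPRESSOR_OF_OPERATOR = {"TetRO1": "TetR", "CymRO1": "CymR", "PhlFO1": "PhlF"}

CATEGORIES = ("K_TX", "K_TL", "K_reg", "K_deg")


class ConfigurationError(ValueError):
    """Invalid circuit or parameter configuration."""


class UncharacterizedPartError(ConfigurationError):
    """A network uses an (ORF, RiboJ) combination with no translation rate.

    This is the hook for RiboJ-factor extrapolation: the missing rate can be
    filled in from the characterized variant times the inferred insulation
    factor (see :func:`txflow.fitting.riboj_factor`).
    """


@dataclass(frozen=True)
class GeneConstruct:
    """One transcription unit: promoter, optional operator, RiboJ flag, ORF."""

    name: str
    promoter: str
    orf: str
    operator: str | None = None
    riboj: bool = False

    def __post_init__(self) -> None:
        if self.promoter not in PROMOTERS:
            raise ConfigurationError(f"unknown promoter {self.promoter!r}")
        if self.orf not in ORFS:
            raise ConfigurationError(f"unknown ORF {self.orf!r}")
        if self.operator is not None and self.operator not in OPERATORS:
            raise ConfigurationError(f"unknown operator {self.operator!r}")

    @property
    def repressed_by(self) -> str | None:
        """Name of the repressor protein gating this construct, if any."""
        if self.operator is None:
            return None
        return REPRESSOR_OF_OPERATOR[self.operator]

    @property
    def is_reporter(self) -> bool:
        return self.orf in REPORTERS


@dataclass(frozen=True)
class NetworkSpec:
    """An ordered collection of constructs forming one genetic network."""

    constructs: tuple[GeneConstruct, ...]
    name: str = "network"

    def __post_init__(self) -> None:
        names = [c.name for c in self.constructs]
        if len(set(names)) != len(names):
            raise ConfigurationError("construct names must be unique within a network")

    @property
    def species(self) -> tuple[str, ...]:
        """Deterministic state ordering: per construct DNA, mRNA, protein (dark),
        plus a mature pool appended for reporters."""
        out: list[str] = []
        for c in self.constructs:
            out.append(f"DNA_{c.name}")
            out.append(f"mRNA_{c.name}")
            out.append(f"P_{c.name}")
            if c.is_reporter:
                out.append(f"Pmat_{c.name}")
        return tuple(out)

    def producers_of(self, orf: str) -> tuple[GeneConstruct, ...]:
        return tuple(c for c in self.constructs if c.orf == orf)

    def validate(self) -> None:
        """Every operator's repressor must be produced in-network or be
        externally absent (concentration zero) -- both are legal; we only
        record which repressors are absent."""
        for c in self.constructs:
            _ = c.repressed_by  # raises for unknown operators

    def to_yaml(self) -> str:
        doc = {
            "name": self.name,
            "constructs": [
                {
                    "name": c.name,
                    "promoter": c.promoter,
                    "operator": c.operator,
                    "riboj": c.riboj,
                    "orf": c.orf,
                }
                for c in self.constructs
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkSpec":
        doc = yaml.safe_load(text)
        constructs = tuple(
            GeneConstruct(
                name=d["name"],
                promoter=d["promoter"],
                operator=d.get("operator"),
                riboj=bool(d.get("riboj", False)),
                orf=d["orf"],
            )
            for d in doc["constructs"]
        )
        return cls(constructs=constructs, name=doc.get("name", "network"))


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class ParameterSet:
    """All kinetic symbols of the lumped TX-TL model.

    ``kcat_tl`` is keyed by ``(orf, riboj)``; regulatory constants by repressor
    name; mRNA degradation by ORF.  Maturation rates ``kmat`` are measured
    independently and never varied during fitting.
    """

    kcat_tx_s70: float
    kcat_tx_s19: float
    kd_s19: float
    kcat_tl: dict[tuple[str, bool], float]
    kd_rep: dict[str, float]
    n_rep: dict[str, float]
    kdeg_mrna: dict[str, float]
    kmat: dict[str, float] = field(
        default_factory=lambda: {"deGFP": 0.087, "mmCherry": 0.023}
    )

    # -- label-based flat view (used by fitting, sensitivities, OED) --------

    def labels(self) -> list[str]:
        out = ["kcat_tx_s70", "kcat_tx_s19", "kd_s19"]
        out += [f"kcat_tl.{orf}.{'riboj' if rj else 'noriboj'}"
                for (orf, rj) in sorted(self.kcat_tl, key=lambda k: (k[0], k[1]))]
        out += [f"kd_rep.{r}" for r in sorted(self.kd_rep)]
        out += [f"n_rep.{r}" for r in sorted(self.n_rep)]
        out += [f"kdeg_mrna.{o}" for o in sorted(self.kdeg_mrna)]
        return out

    def __getitem__(self, label: str) -> float:
        head, _, rest = label.partition(".")
        if head == "kcat_tx_s70":
            return self.kcat_tx_s70
        if head == "kcat_tx_s19":
            return self.kcat_tx_s19
        if head == "kd_s19":
            return self.kd_s19
        if head == "kcat_tl":
            orf, _, flag = rest.partition(".")
            return self.kcat_tl[(orf, flag == "riboj")]
        if head == "kd_rep":
            return self.kd_rep[rest]
        if head == "n_rep":
            return self.n_rep[rest]
        if head == "kdeg_mrna":
            return self.kdeg_mrna[rest]
        raise KeyError(label)

    def __setitem__(self, label: str, value: float) -> None:
        head, _, rest = label.partition(".")
        if head == "kcat_tx_s70":
            self.kcat_tx_s70 = value
        elif head == "kcat_tx_s19":
            self.kcat_tx_s19 = value
        elif head == "kd_s19":
            self.kd_s19 = value
        elif head == "kcat_tl":
            orf, _, flag = rest.partition(".")
            self.kcat_tl[(orf, flag == "riboj")] = value
        elif head == "kd_rep":
            self.kd_rep[rest] = value
        elif head == "n_rep":
            self.n_rep[rest] = value
        elif head == "kdeg_mrna":
            self.kdeg_mrna[rest] = value
        else:
            raise KeyError(label)

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            kcat_tx_s70=self.kcat_tx_s70,
            kcat_tx_s19=self.kcat_tx_s19,
            kd_s19=self.kd_s19,
            kcat_tl=dict(self.kcat_tl),
            kd_rep=dict(self.kd_rep),
            n_rep=dict(self.n_rep),
            kdeg_mrna=dict(self.kdeg_mrna),
            kmat=dict(self.kmat),
        )

    def validate(self, bounds: Mapping[str, tuple[float, float]] | None = None) -> None:
        for lbl in self.labels():
            v = self[lbl]
            if not (v > 0) or not math.isfinite(v):
                raise ConfigurationError(f"parameter {lbl} must be a positive finite rate, got {v}")
        for r, n in self.n_rep.items():
            if not (1.0 <= n <= 4.0):
                raise ConfigurationError(f"Hill coefficient n_rep.{r} = {n} outside [1, 4]")
        if bounds:
            for lbl, (lo, hi) in bounds.items():
                v = self[lbl]
                if not (lo <= v <= hi):
                    raise ConfigurationError(f"{lbl} = {v} outside bounds [{lo}, {hi}]")

    def to_json_dict(self) -> dict:
        return {
            "values": {l: self[l] for l in self.labels()},
            "kmat": dict(self.kmat),
        }

    @classmethod
    def from_json_dict(cls, doc: Mapping) -> "ParameterSet":
        values = doc["values"]
        kcat_tl: dict[tuple[str, bool], float] = {}
        kd_rep: dict[str, float] = {}
        n_rep: dict[str, float] = {}
        kdeg: dict[str, float] = {}
        scalars: dict[str, float] = {}
        for lbl, v in values.items():
            head, _, rest = lbl.partition(".")
            if head == "kcat_tl":
                orf, _, flag = rest.partition(".")
                kcat_tl[(orf, flag == "riboj")] = float(v)
            elif head == "kd_rep":
                kd_rep[rest] = float(v)
            elif head == "n_rep":
                n_rep[rest] = float(v)
            elif head == "kdeg_mrna":
                kdeg[rest] = float(v)
            else:
                scalars[head] = float(v)
        return cls(
            kcat_tx_s70=scalars["kcat_tx_s70"],
            kcat_tx_s19=scalars["kcat_tx_s19"],
            kd_s19=scalars["kd_s19"],
            kcat_tl=kcat_tl,
            kd_rep=kd_rep,
            n_rep=n_rep,
            kdeg_mrna=kdeg,
            kmat={k: float(v) for k, v in doc.get("kmat", {}).items()} or None
            or {"deGFP": 0.087, "mmCherry": 0.023},
        )

    @staticmethod
    def category_of(label: str) -> str:
        """Map a parameter label to its lumped category."""
        if label.startswith(("kcat_tx", "kd_s19")):
            return "K_TX"
        if label.startswith("kcat_tl"):
            return "K_TL"
        if label.startswith(("kd_rep", "n_rep")):
            return "K_reg"
        if label.startswith("kdeg_mrna"):
            return "K_deg"
        raise KeyError(label)


# ---------------------------------------------------------------------------
# Rate laws


def hill_repression(repressor_conc: float, kd: float, n: float) -> float:
    """Fractional promoter activity 1/(1 + (R/kd)^n) under Hill repression.

    Equals 1 with no repressor and 0.5 at R = kd; monotonically decreasing.
    """
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd}")
    if n < 1:
        raise ValueError(f"Hill coefficient must be >= 1, got {n}")
    if repressor_conc < 0:
        raise ValueError(f"repressor concentration must be non-negative, got {repressor_conc}")
    if repressor_conc == 0.0:
        return 1.0
    return 1.0 / (1.0 + (repressor_conc / kd) ** n)


def transcription_rate(
    construct: GeneConstruct,
    dna: float,
    sigma19: float,
    repressor: float,
    params: ParameterSet,
) -> float:
    """Transcription rate (nM/min) of one construct.

    p70a: constitutive, linear in template (sigma-70 saturating and constant).
    p19a: Michaelis-Menten in the sigma-19 activator.  An operator multiplies
    the rate by the Hill repression term; hybrid promoters share the bare
    promoter's sigma-19 dissociation constant.
    """
    if dna < 0 or sigma19 < 0 or repressor < 0:
        raise ValueError("concentrations must be non-negative")
    if construct.promoter == "p70a":
        rate = params.kcat_tx_s70 * dna
    elif construct.promoter == "p19a":
        rate = params.kcat_tx_s19 * dna * sigma19 / (params.kd_s19 + sigma19)
    else:  # pragma: no cover - guarded in GeneConstruct
        raise ConfigurationError(f"unknown promoter {construct.promoter!r}")
    rep = construct.repressed_by
    if rep is not None:
        rate *= hill_repression(repressor, params.kd_rep[rep], params.n_rep[rep])
    return rate


def steady_state_mrna_ratio(
    construct: GeneConstruct, params: ParameterSet, lam: float
) -> float:
    """Fully-activated, unrepressed steady-state mRNA/DNA ratio in flow.

    Closed form kcat_TX_eff / (kdeg_mRNA + lambda).  Used by the fitting
    module's soft biophysical constraint (acceptance interval (2, 500)).
    Degenerate kdeg + lambda = 0 returns ``inf`` (divergence flag).
    """
    if lam < 0:
        raise ValueError(f"dilution rate must be non-negative, got {lam}")
    kcat = params.kcat_tx_s70 if construct.promoter == "p70a" else params.kcat_tx_s19
    denom = params.kdeg_mrna[construct.orf] + lam
    if denom == 0.0:
        return math.inf
    return kcat / denom


# ---------------------------------------------------------------------------
# ODE assembly


@dataclass
class ODESystem:
    """Compiled right-hand side for one network at one ParameterSet.

    ``rhs(t, y, kin, lam)`` takes the current inflow rate per construct
    (nM/min, array) and the dilution rate (1/min).  State layout follows
    :attr:`NetworkSpec.species`.
    """

    network: NetworkSpec
    params: ParameterSet
    species: tuple[str, ...]
    rhs: Callable[[float, np.ndarray, np.ndarray, float], np.ndarray]
    observable_species: tuple[str, ...]

    @property
    def n_states(self) -> int:
        return len(self.species)

    @property
    def observable_indices(self) -> list[int]:
        return [self.species.index(s) for s in self.observable_species]


def build_ode_system(
    network: NetworkSpec,
    params: ParameterSet,
    activity: Callable[[float], float] | None = None,
) -> ODESystem:
    """Assemble the chemostat TX-TL ODE right-hand side for ``network``.

    Per construct i:
        dDNA_i/dt  = k_in,i(t) - lam * DNA_i
        dmRNA_i/dt = v_TX,i - (kdeg_i + lam) * mRNA_i
        dP_i/dt    = kcat_TL,i * mRNA_i - lam * P_i            (non-reporter)
    Reporters additionally mature first-order (dark -> mature), both pools
    diluted by lam; only the mature pool is observable.

    ``activity`` optionally scales both transcription and translation rates
    over time.  In the chemostat, lysate and energy solution are refreshed
    every cycle and activity stays 1 (default); in batch reactions the
    expression machinery decays as nutrients deplete, which is emulated by a
    decaying activity factor.
    """
    network.validate()
    cons = network.constructs
    species = network.species
    idx = {s: k for k, s in enumerate(species)}

    n = len(cons)
    dna_ix = np.array([idx[f"DNA_{c.name}"] for c in cons])
    mrna_ix = np.array([idx[f"mRNA_{c.name}"] for c in cons])
    prot_ix = np.array([idx[f"P_{c.name}"] for c in cons])
    is_p70 = np.array([c.promoter == "p70a" for c in cons])

    # translation rates; missing (orf, riboj) -> uncharacterized part
    kcat_tl = np.empty(n)
    for k, c in enumerate(cons):
        key = (c.orf, c.riboj)
        if key not in params.kcat_tl:
            raise UncharacterizedPartError(
                f"no translation rate for ORF {c.orf!r} with riboj={c.riboj}; "
                "characterize the part or extrapolate with the RiboJ factor"
            )
        kcat_tl[k] = params.kcat_tl[key]
    kdeg = np.array([params.kdeg_mrna[c.orf] for c in cons])

    # repression wiring: total protein of every construct producing repressor r
    rep_sources: list[np.ndarray | None] = []
    rep_kd = np.ones(n)
    rep_n = np.ones(n)
    for c in cons:
        r = c.repressed_by
        if r is None:
            rep_sources.append(None)
        else:
            src = [idx[f"P_{p.name}"] for p in network.producers_of(r)]
            # a reporter never doubles as repressor in this library, so the
            # dark pool is the full protein pool for repressors
            rep_sources.append(np.array(src, dtype=int))
            rep_kd[cons.index(c)] = params.kd_rep[r]
            rep_n[cons.index(c)] = params.n_rep[r]

    sigma_sources = np.array(
        [idx[f"P_{p.name}"] for p in network.producers_of("sigma19")], dtype=int
    )
    reporter = [(k, c) for k, c in enumerate(cons) if c.is_reporter]
    rep_dark_ix = np.array([idx[f"P_{c.name}"] for _, c in reporter], dtype=int)
    rep_mat_ix = np.array([idx[f"Pmat_{c.name}"] for _, c in reporter], dtype=int)
    rep_kmat = np.array([params.kmat[c.orf] for _, c in reporter])

    kcat70 = params.kcat_tx_s70
    kcat19 = params.kcat_tx_s19
    kd19 = params.kd_s19

    def rhs(t: float, y: np.ndarray, kin: np.ndarray, lam: float) -> np.ndarray:
        dy = np.zeros_like(y)
        dna = np.maximum(y[dna_ix], 0.0)
        mrna = np.maximum(y[mrna_ix], 0.0)
        sigma19 = max(float(y[sigma_sources].sum()), 0.0) if sigma_sources.size else 0.0

        vtx = np.where(
            is_p70,
            kcat70 * dna,
            kcat19 * dna * (sigma19 / (kd19 + sigma19)),
        )
        for k, src in enumerate(rep_sources):
            if src is not None:
                r = max(float(y[src].sum()), 0.0)
                if r > 0.0:
                    vtx[k] /= 1.0 + (r / rep_kd[k]) ** rep_n[k]

        act = 1.0 if activity is None else activity(t)
        dy[dna_ix] = kin - lam * y[dna_ix]
        dy[mrna_ix] = act * vtx - (kdeg + lam) * y[mrna_ix]
        dy[prot_ix] = act * kcat_tl * mrna - lam * y[prot_ix]
        if rep_dark_ix.size:
            dark = np.maximum(y[rep_dark_ix], 0.0)
            dy[rep_dark_ix] -= rep_kmat * dark
            dy[rep_mat_ix] = rep_kmat * dark - lam * y[rep_mat_ix]
        return dy

    observable = tuple(f"Pmat_{c.name}" for _, c in reporter)
    return ODESystem(
        network=network,
        params=params,
        species=species,
        rhs=rhs,
        observable_species=observable,
    )
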