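"""Discrete refresh-cycle mechanics of the microfluidic chemostat and inflow-file I/O.

The reactor is refreshed once per cycle: a fixed refresh fraction RF of the
reactor volume is replaced (default 40% per 22.5 min).  Most of the replaced
volume carries lysate and energy solution; the remaining DNA/MQ share is split
between DNA stocks and water according to per-cycle inflow fractions (IF) read
from tab-delimited pattern files, one row per cycle and one column per
construct -- the same dialect the chemostat hardware consumes.

Two dynamical views of the same protocol are provided:

* continuous (default): dilution rate lam = RF / cycle_time with piecewise
  constant inflow k_in = IF * RF * stock / cycle_time -- matches the ODE model;
* discrete map: per-cycle replacement ``state <- (1 - RF) * state + RF * input``
  for fidelity studies of the hardware's stepwise loading.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import numpy as np


class ProtocolError(ValueError):
    """Invalid inflow protocol or pattern file."""


@dataclass(frozen=True)
class ChemostatConfig:
    """Fixed operating constants of the chemostat."""

    refresh_fraction: float = 0.40
    cycle_time: float = 22.5  # min
    lysate_fraction: float = 0.70  # share of refreshed volume carrying lysate/ES

    def __post_init__(self) -> None:
        if not (0.0 < self.refresh_fraction < 1.0):
            raise ProtocolError("refresh fraction must lie in (0, 1)")
        if self.cycle_time <= 0:
            raise ProtocolError("cycle time must be positive")
        if not (0.0 <= self.lysate_fraction < 1.0):
            raise ProtocolError("lysate fraction must lie in [0, 1)")

    @property
    def dna_mq_fraction(self) -> float:
        return 1.0 - self.lysate_fraction

    @property
    def dilution_rate(self) -> float:
        """Continuous-equivalent dilution rate lam = RF / cycle_time (1/min)."""
        return self.refresh_fraction / self.cycle_time


@dataclass
class InflowProtocol:
    """Per-cycle inflow fractions per construct plus stock concentrations.

    ``fractions`` is an (n_cycles, n_constructs) matrix of the DNA/MQ share
    allocated to each stock; the per-row remainder is MQ water.
    """

    constructs: tuple[str, ...]
    stocks: dict[str, float]  # nM
    fractions: np.ndarray
    config: ChemostatConfig = field(default_factory=ChemostatConfig)

    def __post_init__(self) -> None:
        self.constructs = tuple(self.constructs)
        self.fractions = np.asarray(self.fractions, dtype=float).reshape(
            -1, len(self.constructs)
        )
        self.validate()

    def validate(self) -> None:
        for name in self.constructs:
            if name not in self.stocks:
                raise ProtocolError(f"missing stock concentration for {name!r}")
            if self.stocks[name] < 0:
                raise ProtocolError(f"negative stock for {name!r}")
        f = self.fractions
        if f.size and ((f < 0).any() or (f > 1).any()):
            raise ProtocolError("inflow fractions must lie in [0, 1]")
        if f.size:
            over = np.nonzero(f.sum(axis=1) > 1.0 + 1e-12)[0]
            if over.size:
                raise ProtocolError(
                    f"cycle {over[0]}: inflow fractions sum over the DNA/MQ share"
                )

    @property
    def n_cycles(self) -> int:
        return self.fractions.shape[0]

    @property
    def horizon(self) -> float:
        """Total protocol duration in minutes."""
        return self.n_cycles * self.config.cycle_time

    def stock_vector(self) -> np.ndarray:
        return np.array([self.stocks[c] for c in self.constructs])

    def cycle_of(self, t: float) -> int:
        if t < 0 or t > self.horizon + 1e-9:
            raise ProtocolError(f"time {t} outside protocol horizon [0, {self.horizon}]")
        return min(int(t // self.config.cycle_time), self.n_cycles - 1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InflowProtocol):
            return NotImplemented
        return (
            self.constructs == other.constructs
            and self.stocks == other.stocks
            and self.fractions.shape == other.fractions.shape
            and bool(np.all(self.fractions == other.fractions))
            and self.config == other.config
        )


# ---------------------------------------------------------------------------
# Pattern-file I/O (tab-delimited, header = construct names)


def parse_inflow_file(
    stream: IO[str] | str,
    stocks: Mapping[str, float],
    config: ChemostatConfig | None = None,
) -> InflowProtocol:
    """Parse a tab-delimited inflow-pattern file into an :class:`InflowProtocol`.

    One header row of construct names, then one row of decimal fractions per
    cycle.  Round-trips bit-identically through :func:`write_inflow_file`.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.rstrip("\n") for ln in stream]
    lines = [ln for ln in lines if ln.strip() != "" and not ln.startswith("#")]
    if not lines:
        raise ProtocolError("empty inflow file: missing header row")
    names = tuple(lines[0].split("\t"))
    rows: list[list[float]] = []
    for ln_no, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(names):
            raise ProtocolError(
                f"line {ln_no}: expected {len(names)} columns, got {len(parts)}"
            )
        try:
            row = [float(p) for p in parts]
        except ValueError as exc:
            raise ProtocolError(f"line {ln_no}: {exc}") from exc
        for v in row:
            if not (0.0 <= v <= 1.0):
                raise ProtocolError(f"line {ln_no}: fraction {v} outside [0, 1]")
        if sum(row) > 1.0 + 1e-12:
            raise ProtocolError(f"line {ln_no}: fractions sum over the DNA/MQ share")
        rows.append(row)
    fractions = np.array(rows, dtype=float).reshape(len(rows), len(names))
    return InflowProtocol(
        constructs=names,
        stocks={n: float(stocks[n]) for n in names},
        fractions=fractions,
        config=config or ChemostatConfig(),
    )


def write_inflow_file(protocol: InflowProtocol, stream: IO[str] | None = None) -> str:
    """Write the pattern file; ``repr``-formatted floats keep round trips exact."""
    out = io.StringIO()
    out.write("\t".join(protocol.constructs) + "\n")
    for row in protocol.fractions:
        out.write("\t".join(repr(float(v)) for v in row) + "\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# Controls


def protocol_to_controls(protocol: InflowProtocol):
    """Continuous-time control functions for the ODE model.

    Returns ``(kin(t) -> array of nM/min per construct, lam(t) -> 1/min)``;
    both piecewise constant per refresh cycle.
    """
    cfg = protocol.config
    stocks = protocol.stock_vector()
    scale = cfg.refresh_fraction / cfg.cycle_time
    fractions = protocol.fractions
    n_cycles = protocol.n_cycles

    def kin(t: float) -> np.ndarray:
        if n_cycles == 0:
            return np.zeros(len(protocol.constructs))
        j = min(int(t // cfg.cycle_time), n_cycles - 1)
        if t < 0 or t > protocol.horizon + 1e-9:
            return np.zeros(len(protocol.constructs))
        return fractions[j] * scale * stocks

    def lam(t: float) -> float:
        return cfg.dilution_rate

    return kin, lam


def realized_dna_trace(
    protocol: InflowProtocol,
    times: Sequence[float],
    mode: str = "continuous",
) -> np.ndarray:
    """DNA concentration (nM) per construct at ``times`` under inflow/dilution alone.

    ``continuous``: closed-form piecewise-exponential solution of
    dD/dt = kin - lam D.  ``discrete``: per-cycle replacement map evaluated at
    cycle resolution (concentration constant within a cycle).
    """
    times = np.asarray(times, dtype=float)
    if times.size and (times.min() < -1e-9 or times.max() > protocol.horizon + 1e-9):
        raise ProtocolError("requested times fall outside the protocol horizon")
    cfg = protocol.config
    stocks = protocol.stock_vector()
    n_c = len(protocol.constructs)
    T = cfg.cycle_time
    RF = cfg.refresh_fraction

    if mode == "discrete":
        # boundary map: D_{j+1} = (1 - RF) D_j + RF * IF_j * stock
        levels = np.zeros((protocol.n_cycles + 1, n_c))
        for j in range(protocol.n_cycles):
            levels[j + 1] = (1 - RF) * levels[j] + RF * protocol.fractions[j] * stocks
        out = np.empty((times.size, n_c))
        for k, t in enumerate(times):
            # load happens at the start of cycle j; the post-load level holds
            # for the remainder of the cycle
            j = min(int(t // T), protocol.n_cycles - 1) if protocol.n_cycles else -1
            out[k] = levels[j + 1]
        return out
    if mode != "continuous":
        raise ValueError(f"unknown mode {mode!r}")

    lam = cfg.dilution_rate
    # integrate cycle by cycle in closed form, then interpolate inside cycles
    boundary = np.zeros((protocol.n_cycles + 1, n_c))
    kin_per_cycle = protocol.fractions * (RF / T) * stocks
    for j in range(protocol.n_cycles):
        k = kin_per_cycle[j]
        d0 = boundary[j]
        boundary[j + 1] = d0 * math.exp(-lam * T) + (k / lam) * (1 - math.exp(-lam * T))
    out = np.empty((times.size, n_c))
    for i, t in enumerate(times):
        j = min(int(t // T), protocol.n_cycles - 1) if protocol.n_cycles else 0
        if protocol.n_cycles == 0:
            out[i] = 0.0
            continue
        tau = t - j * T
        k = kin_per_cycle[j]
        d0 = boundary[j]
        out[i] = d0 * math.exp(-lam * tau) + (k / lam) * (1 - math.exp(-lam * tau))
    return out


def constant_protocol(
    constructs: Sequence[str],
    stocks: Mapping[str, float],
    fractions: Mapping[str, float],
    n_cycles: int,
    config: ChemostatConfig | None = None,
) -> InflowProtocol:
    """Convenience builder: the same inflow fractions every cycle."""
    names = tuple(constructs)
    mat = np.tile(np.array([fractions.get(n, 0.0) for n in names]), (n_cycles, 1))
    return InflowProtocol(
        constructs=names,
        stocks={n: float(stocks[n]) for n in names},
        fractions=mat,
        config=config or ChemostatConfig(),
    )
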