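"""Circuit data model: species nodes, flux elements, conservation pools.

The mapping is the standard analog-circuit picture of mass-action kinetics:
a species concentration is a node voltage, a reaction flux is a current, and
Kirchhoff's current law at each node reproduces the species' rate equation.

* A **dynamic** node carries a capacitor (C = 1 by convention, a
  volume-normalised container), so d(value)/dt = net current / C.
* An **algebraic** node has its capacitor removed — the quasi-steady-state
  approximation — and its net current must balance to zero at all times.
* A **transconductor** is a voltage-controlled current source: its current is
  a gain times the product of its input values (mass action).  Inputs may be
  node values or the free value of a conservation pool.
* A **decay path** is a resistor to ground: current = value / R, with
  R = 1/k for a first-order rate constant k, or R = 1/K_m for the merged
  quasi-steady-state sink of an enzyme complex.
* A **conservation pool** is the adder/subtracter bookkeeping of a conserved
  total: free = total - sum(multiplier * bound node value).  Multipliers may
  be non-integer (polymerase sequestration) or negative (a produced species
  feeding back into an inhibitor pool).

Node values are never clamped: mass-action systems preserve non-negativity
analytically, so a significantly negative value or free-pool value indicates
a solver or parameter problem and is surfaced, not hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import math

__all__ = [
    "SpeciesNode",
    "TransconductorFlux",
    "DecayPath",
    "ConservationPool",
    "Circuit",
    "CircuitError",
]

SOURCE = +1
SINK = -1


class CircuitError(ValueError):
    """Structural error while building or evaluating a circuit."""


@dataclass(frozen=True)
class SpeciesNode:
    """A species concentration, represented as a node voltage.

    ``capacitance`` is the volume-normalisation constant (default 1); it is
    ``None`` for algebraic (quasi-steady-state) nodes, whose capacitor is
    removed from the circuit.
    """

    name: str
    kind: str  # "dynamic" | "algebraic"
    initial_value: float = 0.0
    capacitance: float | None = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("dynamic", "algebraic"):
            raise CircuitError(f"node {self.name!r}: unknown kind {self.kind!r}")
        if self.initial_value < 0:
            raise CircuitError(
                f"node {self.name!r}: negative initial value {self.initial_value}"
            )
        if self.kind == "dynamic":
            if self.capacitance is None or self.capacitance <= 0:
                raise CircuitError(
                    f"dynamic node {self.name!r} needs capacitance > 0"
                )
        elif self.capacitance is not None:
            raise CircuitError(
                f"algebraic node {self.name!r} must not carry a capacitor"
            )


@dataclass(frozen=True)
class TransconductorFlux:
    """Voltage-controlled current source: current = gain * prod(inputs).

    ``inputs`` name nodes or pools (a pool contributes its free value); the
    multiplication is the multiplier block feeding the transconductor.
    ``sign`` is +1 for a source into ``target``, -1 for a sink.
    """

    name: str
    gain: float
    inputs: tuple[str, ...]
    target: str
    sign: int = SOURCE

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise CircuitError(f"flux {self.name!r}: negative gain {self.gain}")
        if self.sign not in (SOURCE, SINK):
            raise CircuitError(f"flux {self.name!r}: sign must be +1 or -1")
        if not self.inputs:
            raise CircuitError(f"flux {self.name!r}: needs at least one input")


@dataclass(frozen=True)
class DecayPath:
    """Resistor to ground on ``node``: sink current = value / resistance.

    resistance = 1/k for first-order decay at rate k, or 1/K_m for a merged
    quasi-steady-state complex sink.  ``math.inf`` disables the path.
    """

    name: str
    node: str
    resistance: float

    def __post_init__(self) -> None:
        if not self.resistance > 0:
            raise CircuitError(
                f"decay path {self.name!r}: resistance must be > 0, got {self.resistance}"
            )


@dataclass(frozen=True)
class ConservationPool:
    """free = total - sum(multiplier * node value); an adder/subtracter block."""

    name: str
    total: float
    deductions: tuple[tuple[str, float], ...] = ()

    def free_value(self, state: Mapping[str, float]) -> float:
        free = self.total
        for node, mult in self.deductions:
            try:
                free -= mult * state[node]
            except KeyError as exc:
                raise CircuitError(
                    f"pool {self.name!r}: node {node!r} missing from state"
                ) from exc
        return free


@dataclass
class Circuit:
    """In-memory netlist: nodes, flux elements, and conservation pools."""

    name: str = "circuit"
    nodes: dict[str, SpeciesNode] = field(default_factory=dict)
    fluxes: dict[str, TransconductorFlux | DecayPath] = field(default_factory=dict)
    pools: dict[str, ConservationPool] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    # -- construction -----------------------------------------------------

    def add_species(
        self,
        name: str,
        kind: str = "dynamic",
        initial_value: float = 0.0,
        capacitance: float | None = None,
    ) -> SpeciesNode:
        """Register a species node; dynamic nodes default to C = 1."""
        self._check_fresh_name(name)
        if kind == "dynamic" and capacitance is None:
            capacitance = 1.0
        node = SpeciesNode(name, kind, initial_value, capacitance)
        self.nodes[name] = node
        return node

    def add_transconductor(
        self,
        name: str,
        gain: float,
        inputs: Iterable[str],
        target: str,
        sign: int = SOURCE,
    ) -> TransconductorFlux:
        if name in self.fluxes:
            raise CircuitError(f"duplicate flux name {name!r}")
        flux = TransconductorFlux(name, gain, tuple(inputs), target, sign)
        self.fluxes[name] = flux
        return flux

    def add_decay(self, name: str, node: str, resistance: float) -> DecayPath:
        if name in self.fluxes:
            raise CircuitError(f"duplicate flux name {name!r}")
        path = DecayPath(name, node, resistance)
        self.fluxes[name] = path
        return path

    def add_pool(
        self,
        name: str,
        total: float,
        deductions: Iterable[tuple[str, float]] = (),
    ) -> ConservationPool:
        self._check_fresh_name(name)
        pool = ConservationPool(name, total, tuple(deductions))
        self.pools[name] = pool
        return pool

    def _check_fresh_name(self, name: str) -> None:
        if name in self.nodes or name in self.pools:
            raise CircuitError(f"duplicate name {name!r} in circuit {self.name!r}")

    # -- evaluation -------------------------------------------------------

    def value_of(self, ref: str, state: Mapping[str, float]) -> float:
        """Resolve a node or pool reference against a state mapping."""
        if ref in self.nodes:
            return state[ref]
        if ref in self.pools:
            return self.pools[ref].free_value(state)
        raise CircuitError(f"unknown reference {ref!r}")

    def flux_current(self, name: str, state: Mapping[str, float]) -> float:
        """Current through one flux element (always reported >= 0)."""
        try:
            elem = self.fluxes[name]
        except KeyError as exc:
            raise CircuitError(f"unknown flux element {name!r}") from exc
        if isinstance(elem, DecayPath):
            if math.isinf(elem.resistance):
                return 0.0
            return state[elem.node] / elem.resistance
        current = elem.gain
        for ref in elem.inputs:
            current *= self.value_of(ref, state)
        return current

    def net_current(self, node: str, state: Mapping[str, float]) -> float:
        """Kirchhoff current balance: sum of source minus sink currents."""
        if node not in self.nodes:
            raise CircuitError(f"unknown node {node!r}")
        net = 0.0
        for name, elem in self.fluxes.items():
            if isinstance(elem, DecayPath):
                if elem.node == node:
                    net -= self.flux_current(name, state)
            elif elem.target == node:
                net += elem.sign * self.flux_current(name, state)
        return net

    def free_value(self, pool: str, state: Mapping[str, float]) -> float:
        try:
            return self.pools[pool].free_value(state)
        except KeyError as exc:
            raise CircuitError(f"unknown pool {pool!r}") from exc

    def initial_state(self) -> dict[str, float]:
        return {name: node.initial_value for name, node in self.nodes.items()}

    # -- validation -------------------------------------------------------

    def validate(self) -> list[str]:
        """Structural diagnostics; an empty list means the circuit is well formed."""
        problems: list[str] = []
        for name, elem in self.fluxes.items():
            if isinstance(elem, DecayPath):
                if elem.node not in self.nodes:
                    problems.append(f"decay path {name!r} references unknown node {elem.node!r}")
            else:
                if elem.target not in self.nodes:
                    problems.append(f"flux {name!r} targets unknown node {elem.target!r}")
                for ref in elem.inputs:
                    if ref not in self.nodes and ref not in self.pools:
                        problems.append(f"flux {name!r} input {ref!r} is neither node nor pool")
        for pname, pool in self.pools.items():
            for node, _ in pool.deductions:
                if node not in self.nodes:
                    problems.append(f"pool {pname!r} deducts unknown node {node!r}")
        for name, node in self.nodes.items():
            if node.kind != "algebraic":
                continue
            has_source = any(
                isinstance(e, TransconductorFlux) and e.target == name and e.sign == SOURCE
                for e in self.fluxes.values()
            )
            has_sink = any(
                (isinstance(e, DecayPath) and e.node == name)
                or (isinstance(e, TransconductorFlux) and e.target == name and e.sign == SINK)
                for e in self.fluxes.values()
            )
            if not (has_source and has_sink):
                problems.append(
                    f"unbalanced algebraic node {name!r}: needs at least one source and one sink"
                )
        return problems
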