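"""Netlist reading/writing: a portable text schema for circuits and motifs.

A netlist is a YAML mapping with exactly one of a ``motif:`` block (motif
name plus unit-tagged parameters) or a raw ``circuit:`` block (nodes, fluxes,
pools), an optional ``simulate:`` block (t_end, points, tolerances) and an
optional ``analysis:`` block (S0 grid and rate window).  All dimensioned
values carry explicit unit tags ("0.167 mM", "2903 per_s"); a bare number
where a concentration or rate is expected is rejected.  Parameters whose
published values live outside the main text are shipped as the placeholder
``UNKNOWN`` and rejected at load time with an actionable message.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from importlib import resources
from pathlib import Path

import yaml

from . import units
from .circuit import Circuit, ConservationPool, DecayPath, SINK, SOURCE, TransconductorFlux
from .compiler import SolverSettings
from . import motifs as motifs_mod

__all__ = [
    "MotifSpec",
    "NetlistError",
    "load_netlist",
    "loads_netlist",
    "serialize_circuit",
    "write_trajectory",
    "example_path",
    "list_examples",
    "MOTIF_REGISTRY",
]


class NetlistError(ValueError):
    """Netlist fails to parse or validate."""


# ---------------------------------------------------------------------------
# motif registry: name -> (builder adapter, parameter kinds, substrate field,
# product node).  Parameter kinds drive unit parsing: conc / rate / plain /
# str / int.

def _build_mm(kind):
    def build(params):
        mm = motifs_mod.MMParameters(**params)
        if kind == "exact":
            return motifs_mod.build_mm_exact(mm)
        return motifs_mod.build_mm_qssa(mm)
    return build


def _build_inhibition(params):
    return motifs_mod.build_inhibition(motifs_mod.InhibitionParameters(**params))


def _build_product_feedback(params):
    params = dict(params)
    gal0 = params.pop("Gal0", None)
    p = motifs_mod.InhibitionParameters(inhibition_type="competitive", **params)
    return motifs_mod.build_product_feedback(p, gal0)


def _build_two_substrate(params):
    return motifs_mod.build_two_substrate(**params)


def _build_bibi(params):
    return motifs_mod.build_reversible_bibi(motifs_mod.BiBiRates(**params))


def _build_txtl(params):
    return motifs_mod.build_txtl(motifs_mod.TxtlParameters(**params))


def _build_production_decay(params):
    return motifs_mod.build_production_decay(**params)


_MM_KINDS = {"K_m": "conc", "k_cat": "rate", "E0": "conc", "S0": "conc",
             "k_f": "rate", "k_r": "rate"}
_INH_KINDS = {"K_m": "conc", "k_cat": "rate", "K_i": "conc", "K_m2": "conc",
              "K_i2": "conc", "E0": "conc", "S0": "conc", "I0": "conc",
              "inhibition_type": "str"}

MOTIF_REGISTRY: dict[str, dict] = {
    "production_decay": {
        "build": _build_production_decay,
        "kinds": {"k_cat": "rate", "r": "plain", "V_in": "conc", "P0": "conc"},
        "substrate_field": "V_in",
        "product_node": "P",
    },
    "mm_exact": {
        "build": _build_mm("exact"),
        "kinds": _MM_KINDS,
        "substrate_field": "S0",
        "product_node": "P",
    },
    "mm_qssa": {
        "build": _build_mm("qssa"),
        "kinds": _MM_KINDS,
        "substrate_field": "S0",
        "product_node": "P",
    },
    "inhibition": {
        "build": _build_inhibition,
        "kinds": _INH_KINDS,
        "substrate_field": "S0",
        "product_node": "P",
    },
    "product_feedback": {
        "build": _build_product_feedback,
        "kinds": {**_INH_KINDS, "Gal0": "conc"},
        "substrate_field": "S0",
        "product_node": "P",
    },
    "two_substrate": {
        "build": _build_two_substrate,
        "kinds": {"KdA": "conc", "KdB": "conc", "k_cat": "rate", "order": "str",
                  "A0": "conc", "B0": "conc", "E0": "conc"},
        "substrate_field": "A0",
        "product_node": "P",
    },
    "reversible_bibi": {
        "build": _build_bibi,
        "kinds": {**{k: "rate" for k in
                     ("k1", "km1", "k2", "km2", "k3", "km3", "k4", "km4", "k5", "km5")},
                  "E0": "conc", "NAD0": "conc", "S0": "conc"},
        "substrate_field": "S0",
        "product_node": "NADH",
    },
    "txtl": {
        "build": _build_txtl,
        "kinds": {"k_TX": "rate", "d": "rate", "k_TL": "rate", "k_mat": "rate",
                  "Lm": "plain", "Lp": "plain", "Cm": "plain", "Cp": "plain",
                  "K_RNAP": "conc", "K_TetR": "conc", "K_ribo": "conc",
                  "DNA0": "conc", "RNAP0": "conc", "Ribo0": "conc", "TetR0": "conc"},
        "substrate_field": "RNAP0",
        "product_node": "GFP",
    },
}


@dataclass(frozen=True)
class MotifSpec:
    """A motif name plus parameters in internal units; buildable and
    re-parameterisable (used by rate sweeps and fixtures)."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in MOTIF_REGISTRY:
            raise NetlistError(
                f"unknown motif {self.name!r}; known: {sorted(MOTIF_REGISTRY)}"
            )

    @property
    def _entry(self) -> dict:
        return MOTIF_REGISTRY[self.name]

    @property
    def product_node(self) -> str:
        return self._entry["product_node"]

    @property
    def substrate_field(self) -> str:
        return self._entry["substrate_field"]

    def build(self) -> Circuit:
        return self._entry["build"](dict(self.params))

    def with_substrate(self, value: float) -> "MotifSpec":
        return self.with_params(**{self.substrate_field: value})

    def with_params(self, **updates) -> "MotifSpec":
        return MotifSpec(self.name, {**self.params, **updates})


# ---------------------------------------------------------------------------
# parsing helpers

def _parse_param(motif: str, key: str, raw, kinds: dict) -> object:
    if isinstance(raw, str) and raw.strip().upper() == "UNKNOWN":
        raise NetlistError(
            f"motif {motif!r}: parameter {key!r} is the placeholder UNKNOWN "
            "(its published value is not in the main text); supply a measured "
            "value before simulating"
        )
    kind = kinds.get(key)
    if kind is None:
        raise NetlistError(f"motif {motif!r}: unknown parameter {key!r}")
    try:
        if kind == "conc":
            return units.molar(raw)
        if kind == "rate":
            return units.rate(raw)
        if kind == "plain":
            return float(units.quantity(raw)) if isinstance(raw, str) else float(raw)
        if kind == "str":
            return str(raw)
    except units.UnitError as exc:
        raise NetlistError(f"motif {motif!r}, parameter {key!r}: {exc}") from exc
    raise NetlistError(f"motif {motif!r}: bad parameter kind {kind!r}")


def _parse_motif_block(block: dict) -> MotifSpec:
    if not isinstance(block, dict) or "name" not in block:
        raise NetlistError("motif block needs a 'name' and a 'parameters' mapping")
    name = block["name"]
    if name not in MOTIF_REGISTRY:
        raise NetlistError(f"unknown motif {name!r}; known: {sorted(MOTIF_REGISTRY)}")
    kinds = MOTIF_REGISTRY[name]["kinds"]
    raw_params = block.get("parameters", {}) or {}
    params = {k: _parse_param(name, k, v, kinds) for k, v in raw_params.items()}
    return MotifSpec(name, params)


def _parse_circuit_block(block: dict) -> Circuit:
    c = Circuit(block.get("name", "circuit"))
    for nd in block.get("nodes", []) or []:
        cap = nd.get("capacitance")
        c.add_species(
            nd["name"], nd.get("kind", "dynamic"),
            units.molar(nd.get("initial", "0 M")),
            float(cap) if cap is not None else None,
        )
    for pl in block.get("pools", []) or []:
        deds = [(d["node"], float(d.get("times", 1.0))) for d in pl.get("deduct", []) or []]
        c.add_pool(pl["name"], units.molar(pl["total"]), deds)
    for fx in block.get("fluxes", []) or []:
        kind = fx.get("kind", "transconductor")
        if kind == "decay":
            res = fx["resistance"]
            if isinstance(res, str):
                value, unit = str(res).split()
                if unit != "ohm":
                    raise NetlistError(f"decay {fx['name']!r}: resistance unit must be 'ohm'")
                res = float(value)
            else:
                raise NetlistError(
                    f"decay {fx['name']!r}: resistance needs the 'ohm' unit tag"
                )
            c.add_decay(fx["name"], fx["node"], res)
        elif kind == "transconductor":
            sign = {"source": SOURCE, "sink": SINK}.get(fx.get("sign", "source"))
            if sign is None:
                raise NetlistError(f"flux {fx['name']!r}: sign must be source or sink")
            c.add_transconductor(
                fx["name"], units.rate(fx["gain"]), list(fx["inputs"]),
                fx["target"], sign,
            )
        else:
            raise NetlistError(f"unknown flux kind {kind!r}")
    return c


def _parse_settings_block(block: dict | None) -> tuple[float | None, SolverSettings]:
    settings = SolverSettings()
    t_end = None
    if not block:
        return t_end, settings
    if "t_end" in block:
        t_end = units.quantity(block["t_end"]) if isinstance(block["t_end"], str) \
            else float(block["t_end"])
    kwargs = {}
    for key in ("points", "rtol", "atol"):
        if key in block:
            kwargs[key] = block[key]
    if kwargs:
        settings = dc_replace(settings, **kwargs)
    return t_end, settings


@dataclass
class Netlist:
    """Parsed netlist: a motif spec or raw circuit, plus run settings."""

    motif: MotifSpec | None
    circuit: Circuit | None
    t_end: float | None
    settings: SolverSettings
    analysis: dict = field(default_factory=dict)

    def build(self) -> Circuit:
        return self.motif.build() if self.motif is not None else self.circuit


def loads_netlist(text: str) -> Netlist:
    """Parse netlist text; see :func:`load_netlist`."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise NetlistError(f"netlist does not parse as YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise NetlistError("netlist must be a YAML mapping")
    has_motif = "motif" in doc
    has_circuit = "circuit" in doc
    if has_motif == has_circuit:
        raise NetlistError("netlist needs exactly one of a 'motif' or 'circuit' block")
    motif = _parse_motif_block(doc["motif"]) if has_motif else None
    circuit = _parse_circuit_block(doc["circuit"]) if has_circuit else None
    if circuit is not None:
        problems = circuit.validate()
        if problems:
            raise NetlistError("invalid circuit block:\n  " + "\n  ".join(problems))
    t_end, settings = _parse_settings_block(doc.get("simulate"))
    analysis = {}
    ablock = doc.get("analysis") or {}
    if "S0_grid" in ablock:
        analysis["S0_grid"] = [units.molar(v) for v in ablock["S0_grid"]]
    if "window" in ablock:
        analysis["window"] = tuple(
            units.quantity(v) if isinstance(v, str) else float(v)
            for v in ablock["window"]
        )
    if "t_end" in ablock:
        analysis["t_end"] = units.quantity(ablock["t_end"]) \
            if isinstance(ablock["t_end"], str) else float(ablock["t_end"])
    return Netlist(motif, circuit, t_end, settings, analysis)


def load_netlist(path) -> Netlist:
    """Load and validate a netlist file."""
    path = Path(path)
    if not path.exists():
        raise NetlistError(f"netlist file {path} does not exist")
    return loads_netlist(path.read_text())


# ---------------------------------------------------------------------------
# serialization

def serialize_circuit(circuit: Circuit, t_end: float | None = None) -> str:
    """Render a circuit as a raw-circuit netlist (internal molar units)."""
    nodes = []
    for n in circuit.nodes.values():
        entry = {"name": n.name, "kind": n.kind, "initial": f"{n.initial_value!r} M"}
        if n.kind == "dynamic" and n.capacitance != 1.0:
            entry["capacitance"] = n.capacitance
        nodes.append(entry)
    pools = [
        {
            "name": p.name,
            "total": f"{p.total!r} M",
            "deduct": [{"node": nd, "times": m} for nd, m in p.deductions],
        }
        for p in circuit.pools.values()
    ]
    fluxes = []
    for f in circuit.fluxes.values():
        if isinstance(f, DecayPath):
            fluxes.append({
                "kind": "decay", "name": f.name, "node": f.node,
                "resistance": f"{f.resistance!r} ohm",
            })
        else:
            unit = "per_s" if len(f.inputs) == 1 else "per_M_s"
            fluxes.append({
                "kind": "transconductor", "name": f.name,
                "gain": f"{f.gain!r} {unit}", "inputs": list(f.inputs),
                "target": f.target,
                "sign": "source" if f.sign == SOURCE else "sink",
            })
    doc: dict = {"circuit": {"name": circuit.name, "nodes": nodes,
                             "pools": pools, "fluxes": fluxes}}
    if t_end is not None:
        doc["simulate"] = {"t_end": f"{t_end!r} s"}
    return yaml.safe_dump(doc, sort_keys=False)


def write_trajectory(trajectory, path) -> Path:
    """Write a trajectory as CSV: time_s, node columns, then flux columns.

    Full double precision (repr round-trip), deterministic column order.
    """
    path = Path(path)
    df = trajectory.to_frame()
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# bundled examples

def list_examples() -> list[str]:
    root = resources.files("circuitkinetics") / "examples"
    return sorted(p.name for p in root.iterdir() if p.name.endswith(".yaml"))


def example_path(name: str) -> Path:
    root = resources.files("circuitkinetics") / "examples"
    p = root / name
    if not p.is_file():
        raise NetlistError(f"no bundled example {name!r}; have {list_examples()}")
    return Path(str(p))
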