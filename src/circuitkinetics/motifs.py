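"""Parameterised circuit factories for the standard reaction motifs.

Every motif returns a plain :class:`~circuitkinetics.circuit.Circuit` built
from the same three primitives (transconductor, resistor, conservation
pool), so motifs compose and validate uniformly:

* production/decay (the elementary RC block),
* Michaelis-Menten enzyme kinetics, both exact mass-action and with the
  quasi-steady-state approximation (QSSA),
* the generalised enzyme-substrate-inhibitor binding block covering
  competitive, noncompetitive, uncompetitive and mixed inhibition,
* product-feedback (competitive) inhibition,
* two-substrate reactions with random or obligatory binding order,
* the five-step reversible ordered Bi-Bi mechanism (alcohol dehydrogenase
  style), and
* cell-free transcription-translation (TXTL) repressed noncompetitively by
  a TetR homodimer, with polymerase/ribosome sequestration multipliers.

In QSSA blocks the forward transconductor gains are fixed at 1: the binding
equilibria are normalised by the forward rate constant, so every reverse
path is a resistor R = 1/K (K the dissociation / Michaelis constant) and no
separate k_f is accepted.  All parameters are in internal units (molar,
seconds); use :mod:`circuitkinetics.units` to convert tagged quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .circuit import Circuit, SINK

__all__ = [
    "MMParameters",
    "InhibitionParameters",
    "BiBiRates",
    "TxtlParameters",
    "build_production_decay",
    "build_mm_exact",
    "build_mm_qssa",
    "build_inhibition",
    "build_product_feedback",
    "build_two_substrate",
    "build_reversible_bibi",
    "build_txtl",
    "rnap_multiplier",
    "ribosome_multiplier",
]

_INHIBITION_TYPES = ("competitive", "noncompetitive", "uncompetitive", "mixed")


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class MMParameters:
    """Michaelis-Menten constants (molar, 1/s).

    ``K_m = (k_r + k_cat) / k_f``.  The exact mass-action builder needs
    ``k_f`` and ``k_r``; the QSSA builder needs only ``K_m``.  If both the
    grouped and the elementary constants are given they must agree.
    """

    k_cat: float
    E0: float
    S0: float
    K_m: float | None = None
    k_f: float | None = None
    k_r: float | None = None

    def __post_init__(self) -> None:
        if self.k_cat <= 0:
            raise ValueError("k_cat must be > 0")
        if self.E0 < 0 or self.S0 < 0:
            raise ValueError("initial concentrations must be >= 0")
        if self.K_m is not None and self.K_m <= 0:
            raise ValueError("K_m must be > 0")
        if (self.k_f is None) != (self.k_r is None):
            raise ValueError("give both k_f and k_r or neither")
        if self.k_f is not None:
            if self.k_f <= 0 or self.k_r < 0:
                raise ValueError("k_f must be > 0 and k_r >= 0")
            grouped = (self.k_r + self.k_cat) / self.k_f
            if self.K_m is not None and not math.isclose(grouped, self.K_m, rel_tol=1e-6):
                raise ValueError(
                    f"inconsistent constants: (k_r + k_cat)/k_f = {grouped:g} "
                    f"but K_m = {self.K_m:g}"
                )
            if self.K_m is None:
                object.__setattr__(self, "K_m", grouped)


@dataclass(frozen=True)
class InhibitionParameters:
    """Generalised binding-block constants for enzyme inhibition.

    K_i is the EI dissociation constant, K_m2 the ESI <- EI + S constant and
    K_i2 the ESI <- ES + I constant.  The four mechanisms constrain them:
    competitive drops the ESI branch entirely, noncompetitive requires
    K_m2 = K_m and K_i2 = K_i (independent sites), uncompetitive drops the
    EI branch (the single ESI sink uses K_i), and mixed leaves all four free.
    """

    K_m: float
    k_cat: float
    K_i: float
    E0: float
    S0: float
    I0: float
    inhibition_type: str = "mixed"
    K_m2: float | None = None
    K_i2: float | None = None

    def __post_init__(self) -> None:
        if self.inhibition_type not in _INHIBITION_TYPES:
            raise ValueError(
                f"inhibition_type must be one of {_INHIBITION_TYPES}, got "
                f"{self.inhibition_type!r}"
            )
        for name in ("K_m", "k_cat", "K_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("E0", "S0", "I0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        t = self.inhibition_type
        if t == "competitive":
            if self.K_m2 is not None or self.K_i2 is not None:
                raise ValueError("competitive inhibition has no ESI branch; drop K_m2/K_i2")
        elif t == "noncompetitive":
            if self.K_m2 is not None and not math.isclose(self.K_m2, self.K_m, rel_tol=1e-9):
                raise ValueError("noncompetitive inhibition requires K_m2 = K_m")
            if self.K_i2 is not None and not math.isclose(self.K_i2, self.K_i, rel_tol=1e-9):
                raise ValueError("noncompetitive inhibition requires K_i2 = K_i")
            object.__setattr__(self, "K_m2", self.K_m)
            object.__setattr__(self, "K_i2", self.K_i)
        elif t == "uncompetitive":
            if self.K_m2 is not None:
                raise ValueError("uncompetitive inhibition has no EI branch; drop K_m2")
            if self.K_i2 is None:
                object.__setattr__(self, "K_i2", self.K_i)
        else:  # mixed
            if self.K_m2 is None or self.K_i2 is None:
                raise ValueError("mixed inhibition needs independent K_m2 and K_i2")


@dataclass(frozen=True)
class BiBiRates:
    """Rate constants and initial concentrations for the five-step reversible
    ordered Bi-Bi mechanism (cofactor binds first, e.g. NAD+ then ethanol).

    Bimolecular constants (k1, km4, km5, k2) are in 1/(M*s); unimolecular
    constants in 1/s.  ``km<n>`` denotes the reverse constant of step n.
    """

    k1: float
    km1: float
    k2: float
    km2: float
    k3: float
    km3: float
    k4: float
    km4: float
    k5: float
    km5: float
    E0: float = 0.0
    NAD0: float = 0.0
    S0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k1", "km1", "k2", "km2", "k3", "km3", "k4", "km4", "k5", "km5"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("E0", "NAD0", "S0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TxtlParameters:
    """Cell-free transcription-translation constants.

    The DNA template acts as the "enzyme": RNA polymerase (substrate) and the
    TetR homodimer (inhibitor) bind it noncompetitively at separate sites.
    During elongation several polymerases occupy one transcribing template,
    so each DNA-RNAP complex sequesters 1 + k_TX*Lm/Cm polymerases from the
    free pool, and each ribosome-mRNA complex sequesters 1 + k_TL*Lp/Cp
    ribosomes.  TetR0 is the homodimer concentration.
    """

    k_TX: float      # transcription initiation rate, 1/s
    d: float         # mRNA degradation, 1/s
    k_TL: float      # translation initiation rate, 1/s
    k_mat: float     # GFP maturation, 1/s
    Lm: float        # mRNA length, nt
    Lp: float        # coding length translated, nt
    Cm: float        # RNAP elongation velocity, nt/s
    Cp: float        # ribosome elongation velocity, nt/s
    K_RNAP: float    # DNA-RNAP dissociation constant, M
    K_TetR: float    # DNA-TetR (tetO) dissociation constant, M
    K_ribo: float    # ribosome-mRNA dissociation constant, M (no default exists)
    DNA0: float
    RNAP0: float
    Ribo0: float
    TetR0: float = 0.0

    def __post_init__(self) -> None:
        positive = ("k_TX", "d", "k_TL", "k_mat", "Lm", "Lp", "Cm", "Cp",
                    "K_RNAP", "K_TetR", "K_ribo")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("DNA0", "RNAP0", "Ribo0", "TetR0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def rnap_multiplier(p: TxtlParameters) -> float:
    """Average polymerases per transcribing template: 1 + k_TX*Lm/Cm."""
    return 1.0 + p.k_TX * p.Lm / p.Cm


def ribosome_multiplier(p: TxtlParameters) -> float:
    """Average ribosomes per translated mRNA: 1 + k_TL*Lp/Cp."""
    return 1.0 + p.k_TL * p.Lp / p.Cp


# ---------------------------------------------------------------------------
# builders


def build_production_decay(k_cat: float, r: float, V_in: float, P0: float = 0.0) -> Circuit:
    """Elementary RC block: constant production V_in*k_cat, decay at 1/r.

    ``r`` is the product lifetime (the resistance, since C = 1); pass
    ``math.inf`` for a non-decaying product.
    """
    if k_cat <= 0 or not r > 0:
        raise ValueError("k_cat and r must be > 0")
    if V_in < 0:
        raise ValueError("V_in must be >= 0")
    c = Circuit("production_decay")
    c.add_species("P", "dynamic", P0)
    c.add_pool("V_in", V_in)
    c.add_transconductor("I_in", k_cat, ["V_in"], "P")
    c.add_decay("I_d", "P", r)
    return c


def build_mm_exact(params: MMParameters) -> Circuit:
    """Exact mass-action Michaelis-Menten circuit (ES keeps its capacitor)."""
    p = params
    if p.k_f is None:
        raise ValueError(
            "build_mm_exact needs elementary constants k_f and k_r; "
            "with only K_m available use build_mm_qssa"
        )
    c = Circuit("mm_exact")
    c.add_species("ES", "dynamic", 0.0)
    c.add_species("P", "dynamic", 0.0)
    c.add_pool("E_free", p.E0, [("ES", 1.0)])
    c.add_pool("S_free", p.S0, [("ES", 1.0), ("P", 1.0)])
    c.add_transconductor("I_f", p.k_f, ["E_free", "S_free"], "ES")
    c.add_decay("I_r", "ES", math.inf if p.k_r == 0 else 1.0 / p.k_r)
    c.add_decay("I_cat", "ES", 1.0 / p.k_cat)
    c.add_transconductor("I_p", p.k_cat, ["ES"], "P")
    return c


def build_mm_qssa(params: MMParameters) -> Circuit:
    """QSSA Michaelis-Menten circuit: the ES capacitor is removed.

    The forward gain is unity and the merged reverse/catalytic sink is the
    resistor R = 1/K_m, so the ES balance is the equilibrium
    E_free * S_free = ES * K_m.  Both enzyme and substrate conservation are
    wired in, so the circuit stays correct when E0 is comparable to S0
    (tight-binding regime) where the free-ligand hyperbola fails.
    """
    p = params
    if p.K_m is None:
        raise ValueError("build_mm_qssa needs K_m")
    c = Circuit("mm_qssa")
    c.add_species("ES", "algebraic", 0.0)
    c.add_species("P", "dynamic", 0.0)
    c.add_pool("E_free", p.E0, [("ES", 1.0)])
    c.add_pool("S_free", p.S0, [("ES", 1.0), ("P", 1.0)])
    c.add_transconductor("I_f", 1.0, ["E_free", "S_free"], "ES")
    c.add_decay("I_km", "ES", 1.0 / p.K_m)
    c.add_transconductor("I_p", p.k_cat, ["ES"], "P")
    c.metadata["R_ohm"] = 1.0 / p.K_m
    return c


def build_inhibition(params: InhibitionParameters) -> Circuit:
    """Generalised QSSA binding block for the four inhibition mechanisms.

    Balances: E_free*S_free = ES*K_m; E_free*I_free = EI*K_i; and for the
    ternary complex EI*S_free + ES*I_free = ESI*(K_m2 + K_i2).  Competitive
    removes the ESI node, uncompetitive removes the EI node (exact removal,
    not a huge resistance, to keep the algebra well conditioned).
    """
    p = params
    t = p.inhibition_type
    has_esi = t != "competitive"
    has_ei = t != "uncompetitive"

    c = Circuit(f"inhibition_{t}")
    c.add_species("ES", "algebraic", 0.0)
    if has_ei:
        c.add_species("EI", "algebraic", 0.0)
    if has_esi:
        c.add_species("ESI", "algebraic", 0.0)
    c.add_species("P", "dynamic", 0.0)

    bound_e = [("ES", 1.0)] + ([("EI", 1.0)] if has_ei else []) \
        + ([("ESI", 1.0)] if has_esi else [])
    bound_s = [("ES", 1.0), ("P", 1.0)] + ([("ESI", 1.0)] if has_esi else [])
    bound_i = ([("EI", 1.0)] if has_ei else []) + ([("ESI", 1.0)] if has_esi else [])
    c.add_pool("E_free", p.E0, bound_e)
    c.add_pool("S_free", p.S0, bound_s)
    c.add_pool("I_free", p.I0, bound_i)

    c.add_transconductor("I_f1", 1.0, ["E_free", "S_free"], "ES")
    c.add_decay("I_km", "ES", 1.0 / p.K_m)
    if has_ei:
        c.add_transconductor("I_f3", 1.0, ["E_free", "I_free"], "EI")
        c.add_decay("I_ki", "EI", 1.0 / p.K_i)
    if has_esi:
        c.add_transconductor("I_f2", 1.0, ["ES", "I_free"], "ESI")
        c.add_decay("I_ki2", "ESI", 1.0 / p.K_i2)
        if has_ei:
            c.add_transconductor("I_f4", 1.0, ["EI", "S_free"], "ESI")
            c.add_decay("I_km2", "ESI", 1.0 / p.K_m2)
    c.add_transconductor("I_p", p.k_cat, ["ES"], "P")
    c.metadata["inhibition_type"] = t
    return c


def build_product_feedback(params: InhibitionParameters, Gal0: float | None = None) -> Circuit:
    """Competitive inhibition by the reaction's own product.

    The inhibitor pool totals the externally added product (``Gal0``, falling
    back to ``params.I0``) plus everything the reaction has produced: its free
    value is Gal0 + [P] - [EI], wiring new product into the inhibitor input.
    """
    if params.inhibition_type != "competitive":
        raise ValueError("product feedback is built on the competitive mechanism")
    if Gal0 is None:
        Gal0 = params.I0
    if Gal0 < 0:
        raise ValueError("Gal0 must be >= 0")
    c = build_inhibition(replace(params, I0=0.0))
    c.name = "product_feedback"
    # rebuild the inhibitor pool: P counts *into* the pool (multiplier -1)
    c.pools["I_free"] = type(c.pools["I_free"])(
        "I_free", Gal0, (("EI", 1.0), ("P", -1.0))
    )
    return c


def build_two_substrate(
    KdA: float,
    KdB: float,
    k_cat: float,
    order: str,
    A0: float,
    B0: float,
    E0: float,
) -> Circuit:
    """Two-substrate QSSA binding block; only the ternary complex EAB is
    catalytically productive.

    ``order`` is ``"random"`` (independent sites, same Kd for first and
    second binding), ``"A_first"`` or ``"B_first"`` (the disallowed
    first-binding branch is removed).  Both substrate pools deduct the
    ternary complex and the product.
    """
    if order not in ("random", "A_first", "B_first"):
        raise ValueError(f"unknown binding order {order!r}")
    if KdA <= 0 or KdB <= 0 or k_cat < 0:
        raise ValueError("KdA, KdB must be > 0 and k_cat >= 0")
    has_ea = order in ("random", "A_first")
    has_eb = order in ("random", "B_first")

    c = Circuit(f"two_substrate_{order}")
    if has_ea:
        c.add_species("EA", "algebraic", 0.0)
    if has_eb:
        c.add_species("EB", "algebraic", 0.0)
    c.add_species("EAB", "algebraic", 0.0)
    c.add_species("P", "dynamic", 0.0)

    bound_e = ([("EA", 1.0)] if has_ea else []) + ([("EB", 1.0)] if has_eb else []) \
        + [("EAB", 1.0)]
    bound_a = ([("EA", 1.0)] if has_ea else []) + [("EAB", 1.0), ("P", 1.0)]
    bound_b = ([("EB", 1.0)] if has_eb else []) + [("EAB", 1.0), ("P", 1.0)]
    c.add_pool("E_free", E0, bound_e)
    c.add_pool("A_free", A0, bound_a)
    c.add_pool("B_free", B0, bound_b)

    if has_ea:
        c.add_transconductor("I_ea", 1.0, ["E_free", "A_free"], "EA")
        c.add_decay("I_kda", "EA", 1.0 / KdA)
        c.add_transconductor("I_eab_from_ea", 1.0, ["EA", "B_free"], "EAB")
        c.add_decay("I_kdb2", "EAB", 1.0 / KdB)
    if has_eb:
        c.add_transconductor("I_eb", 1.0, ["E_free", "B_free"], "EB")
        c.add_decay("I_kdb", "EB", 1.0 / KdB)
        c.add_transconductor("I_eab_from_eb", 1.0, ["EB", "A_free"], "EAB")
        c.add_decay("I_kda2", "EAB", 1.0 / KdA)
    c.add_transconductor("I_p", k_cat, ["EAB"], "P")
    return c


def _maybe_decay(c: Circuit, name: str, node: str, k: float) -> None:
    c.add_decay(name, node, math.inf if k == 0 else 1.0 / k)


def build_reversible_bibi(rates: BiBiRates) -> Circuit:
    """Five-step reversible ordered Bi-Bi circuit, full mass action.

    Steps (forward / reverse): (1) E + NAD+ <-> E-NAD, (2) E-NAD + S <->
    E-NAD-S, (3) E-NAD-S <-> E-NADH-P, (4) E-NADH-P <-> E-NADH + P,
    (5) E-NADH <-> E + NADH.  Every intermediate keeps its capacitor (no
    QSSA), each with two production and two consumption fluxes; the products
    rebind (I_m4 = km4*[P][E-NADH], I_m5 = km5*[NADH][E_free]).  Pools:
    enzyme over the four complexes, the NAD+/NADH moiety over the complexes
    and free NADH, and the substrate moiety over E-NAD-S, E-NADH-P and P.
    """
    r = rates
    c = Circuit("reversible_bibi")
    for name in ("E_NAD", "E_NAD_S", "E_NADH_P", "E_NADH", "P", "NADH"):
        c.add_species(name, "dynamic", 0.0)
    complexes = [("E_NAD", 1.0), ("E_NAD_S", 1.0), ("E_NADH_P", 1.0), ("E_NADH", 1.0)]
    c.add_pool("E_free", r.E0, complexes)
    c.add_pool("NAD_free", r.NAD0, complexes + [("NADH", 1.0)])
    c.add_pool("S_free", r.S0, [("E_NAD_S", 1.0), ("E_NADH_P", 1.0), ("P", 1.0)])

    # step 1: E + NAD <-> E-NAD
    c.add_transconductor("I_1f", r.k1, ["E_free", "NAD_free"], "E_NAD")
    _maybe_decay(c, "I_1r", "E_NAD", r.km1)
    # step 2: E-NAD + S <-> E-NAD-S (regenerated current on both nodes)
    c.add_transconductor("I_2f_out", r.k2, ["E_NAD", "S_free"], "E_NAD", SINK)
    c.add_transconductor("I_2f_in", r.k2, ["E_NAD", "S_free"], "E_NAD_S")
    c.add_transconductor("I_2r_in", r.km2, ["E_NAD_S"], "E_NAD")
    _maybe_decay(c, "I_2r_out", "E_NAD_S", r.km2)
    # step 3: E-NAD-S <-> E-NADH-P (isomerisation / chemistry)
    c.add_transconductor("I_3f_in", r.k3, ["E_NAD_S"], "E_NADH_P")
    _maybe_decay(c, "I_3f_out", "E_NAD_S", r.k3)
    c.add_transconductor("I_3r_in", r.km3, ["E_NADH_P"], "E_NAD_S")
    _maybe_decay(c, "I_3r_out", "E_NADH_P", r.km3)
    # step 4: E-NADH-P <-> E-NADH + P
    c.add_transconductor("I_4f_in", r.k4, ["E_NADH_P"], "E_NADH")
    c.add_transconductor("I_4f_p", r.k4, ["E_NADH_P"], "P")
    _maybe_decay(c, "I_4f_out", "E_NADH_P", r.k4)
    c.add_transconductor("I_4r_in", r.km4, ["P", "E_NADH"], "E_NADH_P")
    c.add_transconductor("I_4r_out", r.km4, ["P", "E_NADH"], "E_NADH", SINK)
    c.add_transconductor("I_4r_p", r.km4, ["P", "E_NADH"], "P", SINK)
    # step 5: E-NADH <-> E + NADH
    c.add_transconductor("I_5f_in", r.k5, ["E_NADH"], "NADH")
    _maybe_decay(c, "I_5f_out", "E_NADH", r.k5)
    c.add_transconductor("I_5r_in", r.km5, ["NADH", "E_free"], "E_NADH")
    c.add_transconductor("I_5r_out", r.km5, ["NADH", "E_free"], "NADH", SINK)
    return c


def bibi_step_net_fluxes(rates: BiBiRates, state: dict[str, float]) -> list[float]:
    """Net flux (forward - reverse, M/s) of each of the five steps at a state.

    Assembled term-by-term from the reaction scheme, independently of the
    circuit's flux elements; at equilibrium all five vanish.
    """
    r = rates
    complexes = state["E_NAD"] + state["E_NAD_S"] + state["E_NADH_P"] + state["E_NADH"]
    e_free = r.E0 - complexes
    nad_free = r.NAD0 - complexes - state["NADH"]
    s_free = r.S0 - state["E_NAD_S"] - state["E_NADH_P"] - state["P"]
    return [
        r.k1 * e_free * nad_free - r.km1 * state["E_NAD"],
        r.k2 * state["E_NAD"] * s_free - r.km2 * state["E_NAD_S"],
        r.k3 * state["E_NAD_S"] - r.km3 * state["E_NADH_P"],
        r.k4 * state["E_NADH_P"] - r.km4 * state["P"] * state["E_NADH"],
        r.k5 * state["E_NADH"] - r.km5 * state["NADH"] * e_free,
    ]


def build_txtl(p: TxtlParameters) -> Circuit:
    """Cell-free TXTL circuit with TetR repression.

    The DNA template binds RNAP (substrate role) and the TetR homodimer
    (inhibitor role) noncompetitively; only free DNA-RNAP transcribes.
    mRNA decays as a whole (one resistor on the total-mRNA node); ribosome
    binding to mRNA is a second QSSA block; Ribo-mRNA drives dark GFP which
    matures at k_mat.  The free-polymerase pool loses 1 + k_TX*Lm/Cm per
    transcribing complex (one promoter-bound plus the elongating ones) and
    one per repressed ternary complex; the ribosome pool loses
    1 + k_TL*Lp/Cp per translated mRNA.  No species is consumed by
    transcription or translation, matching the early (resource-unlimited)
    phase of a cell-free reaction; GFP has no decay.
    """
    m_rnap = rnap_multiplier(p)
    m_ribo = ribosome_multiplier(p)
    c = Circuit("txtl")
    for name in ("DNA_RNAP", "DNA_TetR", "DNA_RNAP_TetR", "Ribo_mRNA"):
        c.add_species(name, "algebraic", 0.0)
    for name in ("mRNA", "GFP_dark", "GFP"):
        c.add_species(name, "dynamic", 0.0)

    c.add_pool("DNA_free", p.DNA0,
               [("DNA_RNAP", 1.0), ("DNA_TetR", 1.0), ("DNA_RNAP_TetR", 1.0)])
    c.add_pool("RNAP_free", p.RNAP0,
               [("DNA_RNAP", m_rnap), ("DNA_RNAP_TetR", 1.0)])
    c.add_pool("TetR_free", p.TetR0,
               [("DNA_TetR", 1.0), ("DNA_RNAP_TetR", 1.0)])
    c.add_pool("mRNA_free", 0.0, [("mRNA", -1.0), ("Ribo_mRNA", 1.0)])
    c.add_pool("Ribo_free", p.Ribo0, [("Ribo_mRNA", m_ribo)])

    # noncompetitive binding block: DNA is the "enzyme"
    c.add_transconductor("I_dr", 1.0, ["DNA_free", "RNAP_free"], "DNA_RNAP")
    c.add_decay("I_krnap", "DNA_RNAP", 1.0 / p.K_RNAP)
    c.add_transconductor("I_dt", 1.0, ["DNA_free", "TetR_free"], "DNA_TetR")
    c.add_decay("I_ktetr", "DNA_TetR", 1.0 / p.K_TetR)
    c.add_transconductor("I_drt_from_dt", 1.0, ["DNA_TetR", "RNAP_free"], "DNA_RNAP_TetR")
    c.add_transconductor("I_drt_from_dr", 1.0, ["DNA_RNAP", "TetR_free"], "DNA_RNAP_TetR")
    c.add_decay("I_krnap2", "DNA_RNAP_TetR", 1.0 / p.K_RNAP)
    c.add_decay("I_ktetr2", "DNA_RNAP_TetR", 1.0 / p.K_TetR)

    # transcription and mRNA turnover
    c.add_transconductor("I_tx", p.k_TX, ["DNA_RNAP"], "mRNA")
    c.add_decay("I_deg", "mRNA", 1.0 / p.d)

    # ribosome binding (QSSA) and translation
    c.add_transconductor("I_rm", 1.0, ["mRNA_free", "Ribo_free"], "Ribo_mRNA")
    c.add_decay("I_kribo", "Ribo_mRNA", 1.0 / p.K_ribo)
    c.add_transconductor("I_tl", p.k_TL, ["Ribo_mRNA"], "GFP_dark")
    c.add_decay("I_mat_out", "GFP_dark", 1.0 / p.k_mat)
    c.add_transconductor("I_mat_in", p.k_mat, ["GFP_dark"], "GFP")
    c.metadata["rnap_multiplier"] = m_rnap
    c.metadata["ribosome_multiplier"] = m_ribo
    return c
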