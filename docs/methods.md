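# Methods

## The circuit formalism

`circuitkinetics` simulates biochemical reaction networks through their exact
correspondence with transconductor–resistor–capacitor circuits:

* a species concentration (M) is a node **voltage**;
* a reaction flux (M/s) is a **current**;
* a mass-action flux `k * [A][B]` is a **transconductor** — a
  voltage-controlled current source whose gain is the rate constant and whose
  input is the product of its input voltages (the multiplier block);
* a first-order consumption `[X] * k` is a **resistor** to ground with
  `R = 1/k` (Ohm's law gives the current `[X]/R`);
* a conserved total is an **adder/subtracter** (a `ConservationPool`):
  `free = total − Σ multiplier·bound`.

Kirchhoff's current law at each node then *is* the species' rate equation:
`C · dV/dt = Σ source currents − Σ sink currents`. All capacitors default to
`C = 1`, the volume-normalised container, so amounts and concentrations
coincide numerically. Capacitances other than 1 are accepted by the data
model (a true reaction volume) but none of the shipped motifs uses them, so
that path is exercised only by the unit invariants, not by any validated
configuration.

Units are molar and seconds internally. Boundary code (netlists, helper
constructors) accepts explicitly tagged quantities (`"0.167 mM"`,
`"2903 per_s"`); a dimensioned value without a tag is an error, because
published constants for these systems mix mM, µM and nM freely.

## Quasi-steady state as capacitor removal

When complex formation is much faster than catalysis, an intermediate's
capacitor is removed: the node becomes *algebraic* and its current balance
must be zero at all times. For the Michaelis–Menten block the balance with
unity forward gain is the equilibrium `E_free·S_free = ES·K_m`, i.e. the
merged reverse/catalytic sink is a resistor `R = 1/K_m` with
`K_m = (k_r + k_cat)/k_f`. Forward gains in QSSA blocks are fixed at 1 and
not user-configurable: the equilibria are normalised by `k_f`, so a second
gain would be redundant and inconsistent.

Because the enzyme *and* substrate pools both deduct the bound complex, the
algebraic balance is the conservation-coupled quadratic
`(S0 − ES − P)(E0 − ES) = ES·K_m`, not the free-ligand hyperbola. The solver
therefore lands on the physical (Morrison/tight-binding) branch
`0 ≤ ES ≤ min(E0, S0)` automatically, and the circuits remain correct when
enzyme and substrate concentrations are comparable — the regime where the
textbook Michaelis–Menten formula fails.

For the generalised inhibition block the three balances are
`E·S = ES·K_m`, `E·I = EI·K_i`, and for the ternary complex the summed
balance `EI·S + ES·I = ESI·(K_m2 + K_i2)` (two source currents, two sink
resistors). Mechanisms are parameter settings on this one circuit:

| mechanism      | setting                                   |
|----------------|-------------------------------------------|
| competitive    | ESI branch removed                         |
| noncompetitive | `K_m2 = K_m`, `K_i2 = K_i`                 |
| uncompetitive  | EI branch removed; single ESI sink `1/K_i` |
| mixed          | all four constants independent             |

Branch removal is exact (the node and its fluxes are not built) rather than
a very large resistance; both are mathematically equivalent but exact
removal avoids ill-conditioned Newton systems.

## Numerical strategy

The compiler partitions nodes into dynamic (ODE states) and algebraic
(residuals) and integrates the resulting semi-explicit DAE with the *nested*
approach: every right-hand-side evaluation solves the algebraic balances by
a damped Newton iteration (finite-difference Jacobian, warm-started from the
previous solution, scipy's hybrid solver as fallback) and hands a plain
stiff ODE to `scipy.integrate.solve_ivp` with BDF. The circuits of interest
have at most four algebraic nodes, so nesting is cheap and keeps the
integrator standard.

Numerical choices, with rationale:

* **Tolerances**: `rtol = 1e-8`, `atol = 1e-12 M`. Concentrations within one
  circuit span nM (enzyme) to mM (substrate), about nine decades.
* **Newton convergence** is judged on *scaled* residuals: each balance is
  compared against the sum of the absolute currents entering its node
  (relative tolerance `1e-10`). Balances whose currents are all zero — an
  absent inhibitor, zero substrate — use a floor of `1e-6` of the largest
  current scale, since an absolute zero is unreachable in floating point.
* **Initial algebraic state** is solved at `t = 0` from an all-zeros guess
  (complexes are assumed to equilibrate effectively instantaneously).
* **Output grid**: 500 evenly spaced points by default, overridable;
  comparable to plate-reader sampling.
* **No clamping**: node values and pool free values are never forced
  non-negative. Mass action preserves non-negativity analytically, so a
  converged free value below `−10·(atol + rtol·scale)` raises a
  model-consistency error instead of being hidden — it signals bad
  parameters or a mis-wired circuit, not physics. Negative excursions
  smaller than that slack (integrator roundoff near exhaustion plateaus)
  are tolerated and reported in the trajectory diagnostics.
* **Determinism**: the solver chain is deterministic; identical inputs give
  bitwise-identical trajectories. The `seed` field in `SolverSettings` is
  reserved and unused.

## Motif-specific modelling choices

**Reversible ordered Bi-Bi** (alcohol-dehydrogenase-style): full mass
action, all six species dynamic, no QSSA — each intermediate keeps its
capacitor and carries two production and two consumption fluxes. Products
rebind (`k₋₄·[P][E-NADH]`, `k₋₅·[NADH][E_free]`), so the circuit relaxes to
true equilibrium with every step's forward flux equal to its reverse flux.
Conservation pools cover the enzyme (four complexes), the NAD⁺/NADH moiety
(four complexes plus free NADH) and the substrate moiety (the two
substrate-containing complexes plus product). No thermodynamic (Haldane)
consistency is enforced on user-supplied rate sets. The shipped ADH netlist
carries `UNKNOWN` placeholders: the ten published rate constants were
adjusted to the original assay conditions in supplementary material not
reproduced here, so no numeric defaults are claimed.

**Product feedback**: the competitive circuit with the inhibitor pool's free
value defined as `Gal0 + [P] − [EI]` — the produced sugar feeds the same
pool as externally added inhibitor. Implemented as a deduction with
multiplier −1 on the product node.

**Two-substrate reactions**: the ternary-complex binding block with
substrates A and B in the substrate/inhibitor roles; only EAB is
catalytically productive, and both substrate pools deduct EAB and P. Random
order assumes independent sites (second binding constant equals the first);
ordered variants remove the disallowed first-binding branch. The simulations
reproduce the ordering rule that binding the smaller-`S/K_d` substrate first
is never slower.

**TXTL**: the DNA template is the "enzyme", RNA polymerase the substrate,
the TetR homodimer the inhibitor, bound noncompetitively (separate sites);
neither is consumed. Only free DNA–RNAP transcribes. Choices made where the
design was genuinely open:

* Each transcribing template sequesters `1 + k_TX·Lm/Cm` polymerases (one at
  the promoter plus the elongating ones — a non-integer pool multiplier);
  each translated mRNA sequesters `1 + k_TL·Lp/Cp` ribosomes. The repressed
  ternary complex DNA–RNAP–TetR additionally sequesters exactly one
  polymerase (promoter-bound but not elongating).
* mRNA decays as a *total* (one resistor on the total-mRNA node), i.e.
  ribosome-bound mRNA is not protected from degradation; whether protection
  occurs is not established, and this is the simpler assumption.
* Ribosome binding is a QSSA block with a single dissociation constant
  `K_ribo`, which has **no default** — it must be supplied.
* TetR dimerisation is collapsed: `TetR0` is the homodimer concentration.
* GFP and dark GFP have no decay: the model targets the early,
  resource-unlimited phase (~first 4000 s) of a cell-free reaction.
* The test-suite TXTL constants (`k_TX = 0.05/s`, `d = 2×10⁻³/s`, etc.) are
  synthetic order-of-magnitude values for an *E. coli* extract with T7
  polymerase, chosen once for structural property checks (multiplier
  arithmetic, repressor reduction, monotone repression); they are not fitted
  to any dataset.

## Rate analysis

Initial rates are ordinary-least-squares slopes of product versus time over
an early window. The default window is the earliest 10% of the simulated
span, shortened so product formation stays below 5% of the substrate total
(published assays use "the first few minutes"; no single rule exists), with
at least five samples. The cap matters: a window consuming x% of substrate
biases the smallest-`S0` rates low by roughly `x·K_m/(K_m+S0)` percent, and
the double-reciprocal fit amplifies exactly those points. Calibration-grade
recoveries therefore tighten the cap to 1% consumption (the acceptance
pipeline does), which brings apparent-constant recovery errors below 0.1%.

The Lineweaver–Burk fit is unweighted least squares on `(1/S0, 1/V0)` with
zero entries excluded; `V_max = 1/Y-intercept`, `K_m = −1/X-intercept`.
Unweighted reciprocal regression is statistically inefficient under noise —
it is used deliberately, as the classical convention the reference analyses
follow; weighted or nonlinear fitting is out of scope.

Inhibition classification compares apparent constants with and without
inhibitor using a 10% relative-change threshold (arbitrary but documented,
exposed as a parameter), plus slope equality to separate uncompetitive from
mixed.

## Synthetic fixtures

`generate_fixture` attaches seeded noisy replicates to a clean trajectory:
`observed = value·(1 + ε)`, `ε ~ N(0, sd)` i.i.d. per point, clamped at
zero, default `sd = 5%` with a 20% bound matching the replicate spread
reported for the reference assays (triplicate plate-reader data). This
emulates proportional assay scatter only — not drift, calibration offsets,
or a constant read-noise floor — so fixture-based results characterise the
analysis pipeline's statistical behaviour, not instrument systematics.
The Monte-Carlo K_m-recovery experiment reuses one clean simulation per
substrate concentration and draws 50 decorrelated per-seed noise streams
from the base seed; with triplicate averaging and a 12-point grid it
recovers K_m within a few percent (median) and within 15% in essentially
all seeds.

## Problem sizes and scope

The shipped analyses use 12–16-point substrate grids, 500-point output
grids, windows of 10–120 s of simulated time, 50 Monte-Carlo seeds, and
equilibration horizons up to 2×10⁵ s for the reversible circuit — sizes
chosen to match the reference assay designs while keeping any single
pipeline run in seconds on one core.

Known limitations: no stochastic (molecular-noise) simulation; no SBML or
schematic-file interoperability; no electrical fidelity beyond the mapping
(no impedance or frequency-domain analysis); netlists cannot yet express
circuits with non-unit capacitance per node except through the raw block;
and the QSSA inhibition block inherits the classical assumption that all
binding steps are fast relative to catalysis — systems violating it should
use the exact mass-action builders.
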