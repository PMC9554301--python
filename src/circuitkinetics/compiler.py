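"""Compile a Circuit to a semi-explicit DAE and integrate it.

Dynamic nodes become ODE states (dV/dt = net current / C); algebraic
(quasi-steady-state) nodes become current-balance residuals (net current
= 0).  The DAE is solved with the nested approach: at every right-hand-side
evaluation the algebraic residuals are solved by a damped Newton iteration
warm-started from the previous solution, and the resulting ODE system is
handed to a stiff implicit integrator (BDF).  The circuits of interest have
at most a handful of algebraic nodes, so the inner solves are cheap.

Tolerances default to rtol 1e-8 / atol 1e-12 M because concentrations in a
single circuit can span nM to mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .circuit import Circuit, DecayPath, TransconductorFlux, CircuitError

__all__ = [
    "SolverSettings",
    "CompiledSystem",
    "Trajectory",
    "compile_circuit",
    "simulate",
    "flux_series",
    "CompileError",
    "AlgebraicSolveError",
    "IntegrationError",
    "ModelConsistencyError",
]


class CompileError(CircuitError):
    """Circuit has fatal structural diagnostics."""


class AlgebraicSolveError(RuntimeError):
    """The quasi-steady-state current balance could not be solved."""


class IntegrationError(RuntimeError):
    """Stiff integrator failed; carries the partial trajectory if any."""

    def __init__(self, message: str, partial: "Trajectory | None" = None) -> None:
        super().__init__(message)
        self.partial = partial


class ModelConsistencyError(RuntimeError):
    """A conserved pool went significantly negative: bad parameters, not physics."""


@dataclass
class SolverSettings:
    """Integration and Newton settings.

    rtol / atol are the integrator tolerances (atol in molar); ``points`` is
    the evenly spaced output grid; ``newton_rtol`` is the relative residual
    tolerance of the inner algebraic solves (scaled by the magnitude of the
    currents entering each algebraic node).  ``seed`` is reserved: the
    deterministic solver does not use it.
    """

    rtol: float = 1e-8
    atol: float = 1e-12
    points: int = 500
    newton_rtol: float = 1e-10
    newton_max_iter: int = 60
    method: str = "BDF"
    check_conservation: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")
        if self.points < 2:
            raise ValueError("need at least two output points")


@dataclass
class Trajectory:
    """Time grid with all node values (M) and element currents (M/s)."""

    times: np.ndarray
    values: dict[str, np.ndarray]
    currents: dict[str, np.ndarray]
    circuit: Circuit
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time_s, then node columns, then flux-element columns."""
        data = {"time_s": self.times}
        for name in self.circuit.nodes:
            data[name] = self.values[name]
        for name in self.circuit.fluxes:
            data[name] = self.currents[name]
        return pd.DataFrame(data)

    def state_at(self, index: int) -> dict[str, float]:
        return {name: series[index] for name, series in self.values.items()}


def _scale_floor(scale: np.ndarray) -> np.ndarray:
    """Per-component scale with a floor tied to the largest current.

    A balance whose currents are all exactly zero (an inhibitor absent, a
    substrate at zero) would otherwise demand an impossible absolute zero
    from finite-precision Newton steps.
    """
    top = float(np.max(scale, initial=0.0))
    return np.maximum(scale, 1e-6 * top) + 1e-300


class CompiledSystem:
    """Index-flattened evaluator for a circuit's ODEs and residuals.

    The state vector is ordered dynamic nodes first, then algebraic nodes.
    ``rhs`` and ``residual`` are pure functions of (dynamic, algebraic, t).
    """

    def __init__(self, circuit: Circuit) -> None:
        problems = circuit.validate()
        if problems:
            raise CompileError(
                "cannot compile circuit %r:\n  %s"
                % (circuit.name, "\n  ".join(problems))
            )
        self.circuit = circuit
        self.dynamic_layout = [n for n, nd in circuit.nodes.items() if nd.kind == "dynamic"]
        self.algebraic_layout = [n for n, nd in circuit.nodes.items() if nd.kind == "algebraic"]
        order = self.dynamic_layout + self.algebraic_layout
        self._index = {name: i for i, name in enumerate(order)}
        self.n_dynamic = len(self.dynamic_layout)
        self.n_algebraic = len(self.algebraic_layout)
        self.capacitance = np.array(
            [circuit.nodes[n].capacitance for n in self.dynamic_layout], dtype=float
        )
        self.y0 = np.array(
            [circuit.nodes[n].initial_value for n in self.dynamic_layout], dtype=float
        )

        # pools flattened: (total, [(node index, multiplier), ...])
        self._pool_names = list(circuit.pools)
        self._pool_index = {name: i for i, name in enumerate(self._pool_names)}
        self._pools = [
            (p.total, [(self._index[n], m) for n, m in p.deductions])
            for p in circuit.pools.values()
        ]

        # fluxes flattened: decay -> (node_idx, conductance); transconductor ->
        # (gain, [(is_pool, idx)], target_idx, sign)
        self._flux_names = list(circuit.fluxes)
        self._decays: list[tuple[int, int, float]] = []  # (flux pos, node idx, 1/R)
        self._trans: list[tuple[int, float, list[tuple[bool, int]], int, int]] = []
        for pos, (name, elem) in enumerate(circuit.fluxes.items()):
            if isinstance(elem, DecayPath):
                g = 0.0 if math.isinf(elem.resistance) else 1.0 / elem.resistance
                self._decays.append((pos, self._index[elem.node], g))
            else:
                refs = [
                    (ref in circuit.pools,
                     self._pool_index[ref] if ref in circuit.pools else self._index[ref])
                    for ref in elem.inputs
                ]
                self._trans.append(
                    (pos, elem.gain, refs, self._index[elem.target], elem.sign)
                )

        # characteristic concentration for Newton scaling / FD steps
        totals = [abs(t) for t, _ in self._pools]
        inits = [abs(v) for v in self.y0]
        self.char_conc = max(totals + inits + [1e-9])

    # -- low-level evaluation (vals = full node vector, dynamic then algebraic)

    def _pool_values(self, vals: np.ndarray) -> np.ndarray:
        out = np.empty(len(self._pools))
        for i, (total, ded) in enumerate(self._pools):
            v = total
            for idx, mult in ded:
                v -= mult * vals[idx]
            out[i] = v
        return out

    def _all_currents(self, vals: np.ndarray) -> np.ndarray:
        pv = self._pool_values(vals)
        cur = np.zeros(len(self._flux_names))
        for pos, idx, g in self._decays:
            cur[pos] = vals[idx] * g
        for pos, gain, refs, _tgt, _sign in self._trans:
            c = gain
            for is_pool, idx in refs:
                c *= pv[idx] if is_pool else vals[idx]
            cur[pos] = c
        return cur

    def _net_and_scale(self, vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-node net current and sum of absolute current magnitudes."""
        cur = self._all_currents(vals)
        net = np.zeros(len(vals))
        scale = np.zeros(len(vals))
        for pos, idx, _g in self._decays:
            net[idx] -= cur[pos]
            scale[idx] += abs(cur[pos])
        for pos, _gain, _refs, tgt, sign in self._trans:
            net[tgt] += sign * cur[pos]
            scale[tgt] += abs(cur[pos])
        return net, scale

    # -- public pure maps --------------------------------------------------

    def rhs(self, y: np.ndarray, z: np.ndarray, t: float = 0.0) -> np.ndarray:
        """dV/dt = net current / C for the dynamic nodes."""
        vals = np.concatenate([y, z])
        net, _ = self._net_and_scale(vals)
        return net[: self.n_dynamic] / self.capacitance

    def residual(self, y: np.ndarray, z: np.ndarray, t: float = 0.0) -> np.ndarray:
        """Current balances (must be zero) for the algebraic nodes."""
        vals = np.concatenate([y, z])
        net, _ = self._net_and_scale(vals)
        return net[self.n_dynamic:]

    # -- algebraic solve ---------------------------------------------------

    def solve_algebraic(
        self,
        dynamic_state: np.ndarray,
        guess: np.ndarray | None = None,
        settings: SolverSettings | None = None,
    ) -> np.ndarray:
        """Solve the quasi-steady-state current balances for given dynamics.

        Damped Newton with finite-difference Jacobian, warm-startable via
        ``guess``; falls back to scipy's hybrid root finder.  Returned values
        are non-negative (tiny negative roundoff is snapped to zero).
        """
        settings = settings or SolverSettings()
        n = self.n_algebraic
        if n == 0:
            return np.empty(0)
        y = np.asarray(dynamic_state, dtype=float)
        z = np.zeros(n) if guess is None else np.array(guess, dtype=float)

        def res_scale(zv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            vals = np.concatenate([y, zv])
            net, scale = self._net_and_scale(vals)
            return net[self.n_dynamic:], scale[self.n_dynamic:]

        tol = settings.newton_rtol
        F, S = res_scale(z)
        for _ in range(settings.newton_max_iter):
            if np.all(np.abs(F) <= tol * _scale_floor(S)):
                return self._snap_nonneg(z, settings)
            J = self._fd_jacobian(res_scale, z, F)
            try:
                step = np.linalg.solve(J, -F)
            except np.linalg.LinAlgError:
                break
            # damped line search on the scaled residual norm
            norm0 = np.max(np.abs(F) / _scale_floor(S))
            lam = 1.0
            for _damp in range(40):
                z_new = z + lam * step
                F_new, S_new = res_scale(z_new)
                norm1 = np.max(np.abs(F_new) / _scale_floor(S_new))
                if norm1 < norm0 or np.all(np.abs(F_new) <= tol * _scale_floor(S_new)):
                    z, F, S = z_new, F_new, S_new
                    break
                lam *= 0.5
            else:
                break
        # fall back to the hybrid solver
        sol = root(lambda zz: res_scale(zz)[0], z, method="hybr", options={"xtol": 1e-13})
        F, S = res_scale(sol.x)
        if np.all(np.abs(F) <= 1e3 * tol * _scale_floor(S)):
            return self._snap_nonneg(sol.x, settings)
        raise AlgebraicSolveError(
            f"Newton failed on circuit {self.circuit.name!r}; last residual {F}"
        )

    def _fd_jacobian(self, res_scale, z: np.ndarray, F0: np.ndarray) -> np.ndarray:
        n = len(z)
        J = np.empty((n, n))
        for j in range(n):
            h = 1e-7 * max(abs(z[j]), 1e-6 * self.char_conc)
            zp = z.copy()
            zp[j] += h
            Fp, _ = res_scale(zp)
            J[:, j] = (Fp - F0) / h
        return J

    def _snap_nonneg(self, z: np.ndarray, settings: SolverSettings) -> np.ndarray:
        slack = 10 * (settings.atol + settings.rtol * self.char_conc)
        z = z.copy()
        small = (z < 0) & (z >= -slack)
        z[small] = 0.0
        if np.any(z < 0):
            raise AlgebraicSolveError(
                f"negative quasi-steady-state solution {z} in circuit {self.circuit.name!r}"
            )
        return z


def compile_circuit(circuit: Circuit) -> CompiledSystem:
    """Validate and flatten a circuit for simulation."""
    return CompiledSystem(circuit)


def simulate(
    system: CompiledSystem | Circuit,
    t_end: float,
    settings: SolverSettings | None = None,
) -> Trajectory:
    """Integrate the compiled system from t = 0 to ``t_end``.

    The algebraic nodes are re-solved inside every right-hand-side call
    (warm-started), then once more on the output grid so the stored series
    satisfy the current balances at every reported time.
    """
    if isinstance(system, Circuit):
        system = compile_circuit(system)
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    settings = settings or SolverSettings()
    sys_ = system

    z_cache = {"z": None}
    stats = {"rhs_evals": 0}

    def ode_rhs(t: float, y: np.ndarray) -> np.ndarray:
        stats["rhs_evals"] += 1
        z = sys_.solve_algebraic(y, z_cache["z"], settings)
        z_cache["z"] = z
        return sys_.rhs(y, z, t)

    t_eval = np.linspace(0.0, t_end, settings.points)
    sol = solve_ivp(
        ode_rhs,
        (0.0, t_end),
        sys_.y0,
        method=settings.method,
        rtol=settings.rtol,
        atol=settings.atol,
        t_eval=t_eval,
        dense_output=False,
    )

    # assemble whatever was integrated, then decide whether it is complete
    times = sol.t
    n_out = len(times)
    values = {name: sol.y[i, :] for i, name in enumerate(sys_.dynamic_layout)}
    z_series = np.empty((sys_.n_algebraic, n_out))
    z_prev = None
    max_res = 0.0
    for k in range(n_out):
        y_k = sol.y[:, k]
        z_k = sys_.solve_algebraic(y_k, z_prev, settings)
        z_series[:, k] = z_k
        z_prev = z_k
        if sys_.n_algebraic:
            vals = np.concatenate([y_k, z_k])
            net, scale = sys_._net_and_scale(vals)
            res = np.abs(net[sys_.n_dynamic:])
            sc = _scale_floor(scale[sys_.n_dynamic:])
            max_res = max(max_res, float(np.max(res / sc)))
    for i, name in enumerate(sys_.algebraic_layout):
        values[name] = z_series[i, :]

    currents = {name: np.empty(n_out) for name in sys_._flux_names}
    min_free = math.inf
    min_node = math.inf
    for k in range(n_out):
        vals = np.concatenate([sol.y[:, k], z_series[:, k]])
        cur = sys_._all_currents(vals)
        for pos, name in enumerate(sys_._flux_names):
            currents[name][k] = cur[pos]
        pv = sys_._pool_values(vals)
        if len(pv):
            min_free = min(min_free, float(np.min(pv)))
        min_node = min(min_node, float(np.min(vals)))

    diagnostics = {
        "rhs_evals": stats["rhs_evals"],
        "integrator_status": sol.status,
        "integrator_message": sol.message,
        "max_scaled_residual": max_res,
        "min_free_pool": min_free,
        "min_node_value": min_node,
    }
    traj = Trajectory(times, values, currents, sys_.circuit, diagnostics)

    if not sol.success:
        raise IntegrationError(
            f"integrator failed on circuit {sys_.circuit.name!r}: {sol.message}", traj
        )
    slack = 10 * (settings.atol + settings.rtol * sys_.char_conc)
    if settings.check_conservation and min_free < -slack:
        raise ModelConsistencyError(
            f"conserved pool went negative ({min_free:.3e} M) in circuit "
            f"{sys_.circuit.name!r}; check parameters and initial conditions"
        )
    return traj


def flux_series(trajectory: Trajectory, element: str) -> np.ndarray:
    """Current of one flux element, recomputed pointwise from node values."""
    circuit = trajectory.circuit
    if element not in circuit.fluxes:
        raise CircuitError(f"unknown flux element {element!r}")
    n = len(trajectory.times)
    out = np.empty(n)
    for k in range(n):
        out[k] = circuit.flux_current(element, trajectory.state_at(k))
    return out
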