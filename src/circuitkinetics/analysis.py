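"""Initial rates, Lineweaver-Burk fits, apparent constants, classification.

This is the plate-reader analysis layer: simulate a motif over a grid of
initial substrate concentrations, take the ordinary-least-squares slope of
product versus time over an early window as the initial rate V0, then fit
the double-reciprocal line 1/V0 ~ 1/S0.  By the classical convention the
Y-intercept is 1/V_max and the X-intercept is -1/K_m, so the apparent
constants follow from an unweighted linear regression.

The default rate window is the earliest 10% of the simulated span, further
capped so that substrate consumption inside the window stays below 5%
(published assays use windows of roughly the first minutes of reaction; the
cap keeps the slope a genuine *initial* rate).  Both limits are
user-overridable per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .compiler import SolverSettings, Trajectory, compile_circuit, simulate

__all__ = [
    "RateAnalysis",
    "initial_rate",
    "default_window",
    "rate_curve",
    "lineweaver_burk",
    "classify_inhibition",
    "apparent_mm_constants",
]


@dataclass
class RateAnalysis:
    """Initial-rate data plus (after the fit) the Lineweaver-Burk results."""

    S0: np.ndarray                      # grid of initial substrate conc (M)
    V0: np.ndarray                      # initial rates (M/s)
    lb_slope: float | None = None       # s (= K_m / V_max)
    y_intercept: float | None = None    # s/M (= 1 / V_max)
    x_intercept: float | None = None    # 1/M (= -1 / K_m)
    K_m_app: float | None = None        # M
    V_max_app: float | None = None      # M/s
    fit_residual: float | None = None   # rms of 1/V0 residuals (s/M)
    meta: dict = field(default_factory=dict)


def default_window(
    trajectory: Trajectory,
    product: str = "P",
    substrate_total: float | None = None,
    max_span_fraction: float = 0.1,
    max_consumed_fraction: float = 0.05,
    min_points: int = 5,
) -> tuple[float, float]:
    """Pick the initial-rate window (t0, t1) for a trajectory.

    Takes the earliest ``max_span_fraction`` of the span, shortened so the
    product formed stays below ``max_consumed_fraction`` of the substrate
    total, but always keeping at least ``min_points`` samples.
    """
    t = trajectory.times
    p = trajectory.values[product]
    t1 = t[0] + max_span_fraction * (t[-1] - t[0])
    if substrate_total and substrate_total > 0:
        consumed = p - p[0]
        over = np.nonzero(consumed > max_consumed_fraction * substrate_total)[0]
        if len(over):
            t1 = min(t1, t[over[0]])
    k = np.searchsorted(t, t1, side="right")
    k = max(k, min_points)
    if k > len(t):
        raise ValueError("trajectory too short for an initial-rate window")
    return float(t[0]), float(t[k - 1])


def initial_rate(
    trajectory: Trajectory,
    product_node: str = "P",
    window: tuple[float, float] | None = None,
) -> float:
    """OLS slope of product concentration versus time over the window (M/s)."""
    t = trajectory.times
    p = trajectory.values[product_node]
    if window is None:
        window = default_window(trajectory, product_node)
    t0, t1 = window
    mask = (t >= t0) & (t <= t1)
    if mask.sum() < 5:
        raise ValueError(
            f"initial-rate window [{t0}, {t1}] contains only {int(mask.sum())} "
            "samples; need at least 5"
        )
    if np.allclose(p[mask], p[mask][0]):
        return 0.0
    fit = stats.linregress(t[mask], p[mask])
    return float(fit.slope)


def rate_curve(
    motif_spec,
    S0_grid,
    window: tuple[float, float] | None = None,
    t_end: float = 60.0,
    settings: SolverSettings | None = None,
    max_consumed_fraction: float = 0.05,
) -> RateAnalysis:
    """Simulate one trajectory per S0 and collect initial rates.

    ``motif_spec`` is a :class:`~circuitkinetics.netlist.MotifSpec` (anything
    with ``with_substrate(S0) -> spec`` and ``build() -> Circuit`` plus a
    ``product_node`` attribute).
    """
    settings = settings or SolverSettings()
    S0_grid = np.asarray(S0_grid, dtype=float)
    rates = np.empty_like(S0_grid)
    product = getattr(motif_spec, "product_node", "P")
    for i, s0 in enumerate(S0_grid):
        if s0 == 0:
            rates[i] = 0.0
            continue
        circuit = motif_spec.with_substrate(s0).build()
        traj = simulate(compile_circuit(circuit), t_end, settings)
        win = window
        if win is None:
            win = default_window(
                traj, product, substrate_total=s0,
                max_consumed_fraction=max_consumed_fraction,
            )
        rates[i] = initial_rate(traj, product, win)
    if np.any(rates < 0):
        raise ValueError("negative initial rate encountered")
    return RateAnalysis(S0=S0_grid, V0=rates, meta={"t_end": t_end})


def lineweaver_burk(rate_analysis: RateAnalysis) -> RateAnalysis:
    """Unweighted least squares on (1/S0, 1/V0); fills the apparent constants.

    Entries with S0 = 0 or V0 = 0 are excluded before the reciprocal
    transform.  K_m_app = -1/x_intercept and V_max_app = 1/y_intercept.
    """
    usable = (rate_analysis.S0 > 0) & (rate_analysis.V0 > 0)
    if usable.sum() < 3:
        raise ValueError(
            f"Lineweaver-Burk fit needs at least 3 usable points, got {int(usable.sum())}"
        )
    inv_s = 1.0 / rate_analysis.S0[usable]
    inv_v = 1.0 / rate_analysis.V0[usable]
    fit = stats.linregress(inv_s, inv_v)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if intercept <= 0 or slope <= 0:
        raise ValueError(
            "degenerate Lineweaver-Burk fit (non-positive slope or intercept)"
        )
    resid = inv_v - (slope * inv_s + intercept)
    out = replace(rate_analysis)
    out.lb_slope = slope
    out.y_intercept = intercept
    out.x_intercept = -intercept / slope
    out.K_m_app = slope / intercept
    out.V_max_app = 1.0 / intercept
    out.fit_residual = float(np.sqrt(np.mean(resid**2)))
    return out


def apparent_mm_constants(
    motif_spec,
    S0_grid,
    t_end: float = 60.0,
    settings: SolverSettings | None = None,
    max_consumed_fraction: float = 0.05,
) -> RateAnalysis:
    """Convenience: rate_curve followed by lineweaver_burk."""
    return lineweaver_burk(
        rate_curve(
            motif_spec, S0_grid, t_end=t_end, settings=settings,
            max_consumed_fraction=max_consumed_fraction,
        )
    )


def classify_inhibition(
    fit_without: RateAnalysis,
    fit_with: RateAnalysis,
    threshold: float = 0.10,
) -> tuple[str, dict]:
    """Classify the inhibition mechanism from two Lineweaver-Burk fits.

    Compares the apparent constants with and without inhibitor using a
    relative-change threshold (default 10%): competitive raises K_m only;
    noncompetitive lowers V_max only; uncompetitive lowers both while the
    slope K_m/V_max is unchanged; anything else that moves is mixed.
    Returns (label, evidence) where evidence holds the relative changes.
    """
    for fit, label in ((fit_without, "without"), (fit_with, "with")):
        if fit.K_m_app is None or fit.V_max_app is None:
            raise ValueError(f"fit {label!r} lacks apparent constants; run lineweaver_burk")
    e0 = fit_without.meta.get("E0")
    e1 = fit_with.meta.get("E0")
    if e0 is not None and e1 is not None and not np.isclose(e0, e1, rtol=1e-9, atol=0.0):
        raise ValueError("fits are incomparable: different total enzyme concentrations")

    d_km = fit_with.K_m_app / fit_without.K_m_app - 1.0
    d_vmax = fit_with.V_max_app / fit_without.V_max_app - 1.0
    d_slope = fit_with.lb_slope / fit_without.lb_slope - 1.0
    evidence = {"d_K_m": d_km, "d_V_max": d_vmax, "d_slope": d_slope}

    km_changed = abs(d_km) > threshold
    vmax_changed = abs(d_vmax) > threshold
    slope_changed = abs(d_slope) > threshold
    if not km_changed and not vmax_changed:
        label = "none"
    elif km_changed and d_km > 0 and not vmax_changed:
        label = "competitive"
    elif vmax_changed and d_vmax < 0 and not km_changed:
        label = "noncompetitive"
    elif d_km < 0 and d_vmax < 0 and not slope_changed:
        label = "uncompetitive"
    else:
        label = "mixed"
    return label, evidence
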