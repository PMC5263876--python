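"""Order-of-accuracy diagnostics for the discretizations.

The spatial operator is a second-order central difference on the periodic
grid; time stepping is classical fourth-order Runge-Kutta for the
regulatory model and first-order forward Euler for the branching model.
The estimators below measure the observed orders by refinement against an
independent reference (the analytic diffusion solution in space, a
high-order adaptive integrator in time).
"""

from __future__ import annotations

from collections.abc import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .grid import SpatialGrid
from .mrf import MRFParameters, MRFProblem, SPECIES
from .pb import PBParameters, pb_reaction


def rk4_step(f: Callable[[np.ndarray], np.ndarray], y: np.ndarray,
             dt: float) -> np.ndarray:
    k1 = f(y)
    k2 = f(y + 0.5 * dt * k1)
    k3 = f(y + 0.5 * dt * k2)
    k4 = f(y + dt * k3)
    return y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def euler_step(f: Callable[[np.ndarray], np.ndarray], y: np.ndarray,
               dt: float) -> np.ndarray:
    return y + dt * f(y)


def integrate(f, y0, t_final, dt, method="rk4"):
    """Fixed-step integration to exactly t_final (last step shortened)."""
    step = rk4_step if method == "rk4" else euler_step
    y = np.array(y0, dtype=float)
    t = 0.0
    while t < t_final - 1e-12:
        h = min(dt, t_final - t)
        y = step(f, y, h)
        t += h
    return y


def observed_orders(errors: Sequence[float], ratio: float = 2.0) -> list[float]:
    """log_ratio of successive error ratios for a refinement sequence."""
    errors = list(errors)
    if len(errors) < 2:
        raise ValueError("need at least two errors")
    return [
        float(np.log(errors[i] / errors[i + 1]) / np.log(ratio))
        for i in range(len(errors) - 1)
    ]


def _check_geometric(values: Sequence[float]) -> float:
    if len(values) < 3:
        raise ValueError("need at least 3 resolutions in geometric progression")
    ratios = [values[i + 1] / values[i] for i in range(len(values) - 1)]
    if not np.allclose(ratios, ratios[0], rtol=1e-9):
        raise ValueError("resolutions must form a geometric progression")
    return float(abs(ratios[0]))


def spatial_order_diffusion(
    resolutions: Sequence[int] = (50, 100, 200),
    diffusivity: float = 1e-3,
    t_final: float = 5.0,
    dt: float | None = None,
) -> float:
    """Observed spatial order on pure diffusion of sin(2 pi x).

    The analytic solution exp(-4 pi^2 D t) sin(2 pi x) is the reference;
    a tiny common RK4 step keeps temporal error negligible, so the error
    is dominated by the O(dx^2) spatial truncation.
    """
    resolutions = sorted(resolutions)
    ratio = _check_geometric([float(n) for n in resolutions])
    if dt is None:
        dx_min = 1.0 / max(resolutions)
        dt = 0.25 * dx_min**2 / (2.0 * diffusivity)
    errors = []
    for n in resolutions:
        grid = SpatialGrid(n)
        u0 = np.sin(2 * np.pi * grid.x)
        u = integrate(
            lambda y: diffusivity * grid.laplacian(y), u0, t_final, dt
        )
        exact = np.exp(-4 * np.pi**2 * diffusivity * t_final) * u0
        errors.append(float(np.max(np.abs(u - exact))))
    return float(np.mean(observed_orders(errors, ratio)))


def _reference_solution(rhs, y0, t_final):
    sol = solve_ivp(
        lambda t, y: rhs(y), (0.0, t_final), np.asarray(y0, float),
        method="DOP853", rtol=1e-12, atol=1e-13, dense_output=False,
        t_eval=[t_final],
    )
    if not sol.success:
        raise RuntimeError("reference integration failed")
    return sol.y[:, -1]


def temporal_order(
    rhs: Callable[[np.ndarray], np.ndarray],
    y0: np.ndarray,
    dts: Sequence[float],
    t_final: float,
    method: str = "rk4",
) -> float:
    """Observed temporal order of a fixed-step method on a smooth ODE
    system, referenced against an adaptive eighth-order integrator."""
    dts = sorted(dts, reverse=True)
    ratio = _check_geometric([dts[0] / d for d in dts])
    y_ref = _reference_solution(rhs, y0, t_final)
    errors = []
    for dt in dts:
        y = integrate(rhs, y0, t_final, dt, method=method)
        errors.append(float(np.max(np.abs(y - y_ref))))
    return float(np.mean(observed_orders(errors, ratio)))


def mrf_temporal_order(
    dts: Sequence[float] = (0.2, 0.1, 0.05),
    t_final: float = 2.0,
) -> float:
    """RK4 order on the reaction-only regulatory system (expected ~ 4).

    The configuration keeps all rates of comparable magnitude so the
    refinement sequence sits in the asymptotic range.
    """
    params = MRFParameters(
        D_RAo=0.0, D_WNT=0.0, D_GDF=0.0, D_GREM=0.0, m_on=1.0,
    )
    grid = SpatialGrid(16)
    problem = MRFProblem(params, grid)
    rng = np.random.default_rng(7)
    y0 = 0.2 + 0.1 * rng.uniform(size=(len(SPECIES), grid.n_points))

    def rhs_flat(y):
        return problem.rhs(y.reshape(len(SPECIES), -1)).ravel()

    return temporal_order(rhs_flat, y0.ravel(), dts, t_final, method="rk4")


def pb_temporal_order(
    dts: Sequence[float] = (0.02, 0.01, 0.005),
    t_final: float = 1.0,
) -> float:
    """Euler order on the reaction-only branching system (expected ~ 1)."""
    params = PBParameters(D_A=0.0, D_B=0.0)

    def rhs(y):
        return np.array(pb_reaction(y[0], y[1], y[2], 0.0, 0.0, params))

    y0 = np.array([0.7, 0.3, 0.5])
    return temporal_order(rhs, y0, dts, t_final, method="euler")


def estimate_convergence_order(
    mode: str,
    resolutions: Sequence[float] | None = None,
    method: str = "rk4",
) -> float:
    """Unified entry point for order-of-accuracy studies.

    ``mode='spatial'`` refines the grid (resolutions = node counts) on a
    smooth diffusion problem at fixed small dt; ``mode='temporal'``
    refines dt (resolutions = step sizes) at fixed grid with the named
    stepper ('rk4' for the regulatory model, 'euler' for the branching
    model).
    """
    if mode == "spatial":
        return spatial_order_diffusion(resolutions or (50, 100, 200))
    if mode == "temporal":
        if method == "rk4":
            return mrf_temporal_order(resolutions or (0.2, 0.1, 0.05))
        return pb_temporal_order(resolutions or (0.02, 0.01, 0.005))
    raise ValueError("mode must be 'spatial' or 'temporal'")
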