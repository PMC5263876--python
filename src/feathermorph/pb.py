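"""Periodic-branching activator-inhibitor model.

A diffusible self-regulating activator ``A`` drives a diffusible inhibitor
``B`` and a non-diffusible inhibitor ``C``; both inhibitors downregulate
``A``.  Periodic activator peaks on the circumference are the barb ridges;
their drift over time yields the helical growth of barbs.

Steady-state GREM1 and GDF10 profiles from the regulatory model couple in
through two Hill-gated terms: GREM1 relieves the B-mediated inhibition of
A (widening the disordered barb generative zone), while GDF10 raises the
basal production of B (suppressing discrete barbs at the rachis).  With
both profiles identically zero the equations reduce exactly to the
uncoupled model.

Per node, with H(u) = u^n_G / (s_G^n_G + u^n_G):

    dA/dt = D_A lap(A) + s A^2 / ((1 + s_A A^2)(1 + s_C C)
            (1 + s_B B (1 - g_grem H(GREM)))) + b_A - r_A A
    dB/dt = D_B lap(B) + c_B A^2/(1 + s_A A^2)
            + b_B (1 + g_gdf H(GDF)) - r_B B
    dC/dt = b_C A^2/(1 + s_A A^2) - r_C C

Integration is forward Euler (first order) on the same periodic grid.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy import optimize

from .grid import SpatialGrid
from .mrf import NumericalBlowupError

PB_FIELDS = ("A", "B", "C")


@dataclass(frozen=True)
class PBParameters:
    """Parameters of the branching model.

    ``s`` scales the maximum autocatalysis of A; ``s_A``, ``s_B``, ``s_C``
    and ``s_G`` are saturation coefficients; ``b_A``/``b_B`` are basal
    productions and ``b_C`` the maximum production scale of C; ``n_G`` is
    the Hill coefficient of the GREM/GDF coupling.  ``g_grem`` and
    ``g_gdf`` are the coupling gains; ``c_B`` scales the A-activated
    production of B.
    """

    D_A: float = 2e-5
    D_B: float = 1e-3
    r_A: float = 1.0
    r_B: float = 1.5
    r_C: float = 0.04
    s: float = 1.0
    s_A: float = 0.05
    s_B: float = 1.0
    s_C: float = 1.0
    s_G: float = 0.5
    b_A: float = 0.02
    b_B: float = 0.02
    b_C: float = 0.04
    c_B: float = 1.0
    n_G: float = 4.0
    g_grem: float = 0.9
    g_gdf: float = 8.0
    s_c_placement: str = "inhibition"  # or "production"

    def __post_init__(self) -> None:
        for name in (
            "D_A", "D_B", "r_A", "r_B", "r_C", "s", "s_A", "s_B", "s_C",
            "s_G", "b_A", "b_B", "b_C", "c_B", "n_G", "g_grem", "g_gdf",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0")
        if self.s_c_placement not in ("inhibition", "production"):
            raise ValueError("s_c_placement must be 'inhibition' or 'production'")
        if self.D_A >= self.D_B:
            warnings.warn(
                "D_A >= D_B: the inhibitor should normally out-diffuse the "
                "activator for lateral inhibition",
                stacklevel=2,
            )

    def with_updates(self, **kwargs) -> "PBParameters":
        return replace(self, **kwargs)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class Kymograph:
    """Activator concentration over (time step, node)."""

    A_xt: np.ndarray          # shape (n_times, n_points)
    times: np.ndarray         # recording times, length n_times
    dt: float                 # integration step
    dx: float
    metadata: dict = field(default_factory=dict)

    @property
    def t_final(self) -> float:
        return float(self.times[-1])

    @property
    def n_points(self) -> int:
        return self.A_xt.shape[1]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.A_xt)):
            raise ValueError("kymograph contains non-finite values")
        if self.A_xt.shape[0] != len(self.times):
            raise ValueError("times length must match the number of rows")


def coupling_gates(
    grem: np.ndarray | float,
    gdf: np.ndarray | float,
    params: PBParameters,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Hill gates H(GREM), H(GDF) used by the two coupling terms."""
    n, sg = params.n_G, params.s_G
    sgn = sg**n

    def _h(u):
        un = np.power(np.maximum(u, 0.0), n)
        return un / (sgn + un)

    return _h(grem), _h(gdf)


def pb_reaction(
    A, B, C, grem, gdf, params: PBParameters
):
    """Pointwise reaction terms (no diffusion); works on arrays or scalars."""
    p = params
    h_grem, h_gdf = coupling_gates(grem, gdf, p)
    A2 = A * A
    sat = A2 / (1.0 + p.s_A * A2)
    if p.s_c_placement == "inhibition":
        c_factor = 1.0 + p.s_C * C
        c_prod = p.b_C * sat
    else:
        c_factor = 1.0 + C
        c_prod = p.b_C * A2 / (1.0 + p.s_C * A2)
    b_factor = 1.0 + p.s_B * B * (1.0 - p.g_grem * h_grem)
    dA = p.s * sat / (c_factor * b_factor) + p.b_A - p.r_A * A
    dB = p.c_B * sat + p.b_B * (1.0 + p.g_gdf * h_gdf) - p.r_B * B
    dC = c_prod - p.r_C * C
    return dA, dB, dC


def pb_rhs(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    grem_profile: np.ndarray | float,
    gdf_profile: np.ndarray | float,
    params: PBParameters,
    grid: SpatialGrid,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full right-hand side: reactions plus periodic diffusion of A and B."""
    for name, f in (("A", A), ("B", B), ("C", C)):
        if not np.all(np.isfinite(f)):
            node = int(np.flatnonzero(~np.isfinite(f))[0])
            raise NumericalBlowupError(
                f"non-finite value in PB field {name} at node {node}"
            )
    dA, dB, dC = pb_reaction(A, B, C, grem_profile, gdf_profile, params)
    dA = dA + params.D_A * grid.laplacian(A)
    dB = dB + params.D_B * grid.laplacian(B)
    return dA, dB, dC


def homogeneous_fixed_point(
    params: PBParameters,
    grem: float = 0.0,
    gdf: float = 0.0,
) -> tuple[float, float, float]:
    """Spatially uniform fixed point of the reaction system.

    The system is typically multistable (a low basal state plus an active
    branch); patterning develops around the active branch, so the root
    with the largest activator level is returned.
    """

    def fun(z):
        return np.array(pb_reaction(z[0], z[1], z[2], grem, gdf, params))

    p = params
    best = None
    for a0 in np.linspace(0.05, 5.0, 20):
        b0 = (p.c_B * a0**2 / (1 + p.s_A * a0**2) + p.b_B) / p.r_B
        c0 = p.b_C * a0**2 / (1 + p.s_A * a0**2) / max(p.r_C, 1e-12)
        sol = optimize.root(fun, (a0, b0, c0), method="hybr")
        if not sol.success or np.any(np.asarray(sol.x) < -1e-10):
            continue
        if float(np.max(np.abs(fun(sol.x)))) > 1e-9:
            continue
        if best is None or sol.x[0] > best[0]:
            best = sol.x
    if best is None:
        raise RuntimeError("no non-negative homogeneous fixed point found")
    return tuple(float(max(v, 0.0)) for v in best)


def reaction_jacobian(
    params: PBParameters,
    point: tuple[float, float, float],
    grem: float = 0.0,
    gdf: float = 0.0,
    eps: float = 1e-7,
) -> np.ndarray:
    """3x3 Jacobian of the pointwise reactions by central differences."""
    z0 = np.asarray(point, dtype=float)
    J = np.empty((3, 3))
    for j in range(3):
        zp, zm = z0.copy(), z0.copy()
        h = eps * max(1.0, abs(z0[j]))
        zp[j] += h
        zm[j] -= h
        fp = np.array(pb_reaction(zp[0], zp[1], zp[2], grem, gdf, params))
        fm = np.array(pb_reaction(zm[0], zm[1], zm[2], grem, gdf, params))
        J[:, j] = (fp - fm) / (2 * h)
    return J


def dispersion_relation(
    params: PBParameters,
    wavenumbers: np.ndarray,
    grem: float = 0.0,
    gdf: float = 0.0,
    dx: float | None = None,
) -> np.ndarray:
    """Max real part of the growth eigenvalues at each angular wavenumber q.

    Linearization about the homogeneous fixed point; diffusion contributes
    -q^2 diag(D_A, D_B, 0).  When ``dx`` is given the discrete symbol
    (2 - 2 cos(q dx)) / dx^2 of the periodic second-order Laplacian
    replaces q^2, matching the simulated operator exactly.
    """
    fp = homogeneous_fixed_point(params, grem, gdf)
    J = reaction_jacobian(params, fp, grem, gdf)
    growth = np.empty(len(wavenumbers))
    for i, q in enumerate(wavenumbers):
        if dx is None:
            q2 = q**2
        else:
            q2 = (2.0 - 2.0 * np.cos(q * dx)) / dx**2
        Jq = J - np.diag([params.D_A * q2, params.D_B * q2, 0.0])
        growth[i] = np.max(np.linalg.eigvals(Jq).real)
    return growth


def most_unstable_mode(
    params: PBParameters,
    grem: float = 0.0,
    gdf: float = 0.0,
    max_mode: int = 64,
    dx: float | None = None,
) -> tuple[int, float]:
    """Integer circumferential mode k (wavelength 1/k) with the largest
    linear growth rate, and that growth rate."""
    modes = np.arange(1, max_mode + 1)
    growth = dispersion_relation(params, 2.0 * np.pi * modes, grem, gdf,
                                 dx=dx)
    i = int(np.argmax(growth))
    return int(modes[i]), float(growth[i])


def pb_stable_dt(params: PBParameters, grid: SpatialGrid,
                 safety: float = 0.2) -> float:
    """Euler stability margin for the diffusive terms."""
    d_max = max(params.D_A, params.D_B)
    if d_max <= 0:
        return 0.01
    return safety * grid.dx**2 / d_max


def initial_pb_fields(
    params: PBParameters,
    grid: SpatialGrid,
    grem: float = 0.0,
    gdf: float = 0.0,
    noise_amplitude: float = 1e-2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Homogeneous fixed point plus seeded uniform noise on A."""
    a0, b0, c0 = homogeneous_fixed_point(params, grem, gdf)
    rng = np.random.default_rng(seed)
    n = grid.n_points
    A = np.full(n, a0) + noise_amplitude * rng.uniform(-1, 1, n)
    B = np.full(n, b0)
    C = np.full(n, c0)
    return np.abs(A), B, C


def run_pb(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    grem_profile: np.ndarray | float,
    gdf_profile: np.ndarray | float,
    params: PBParameters,
    grid: SpatialGrid,
    dt: float | None = None,
    n_steps: int = 20_000,
    record_every: int = 50,
    seed: int | None = None,
) -> Kymograph:
    """Forward-Euler integration, recording A every ``record_every`` steps.

    Deterministic for fixed inputs; any randomness lives in the initial
    condition (see :func:`initial_pb_fields`).
    """
    if dt is None:
        dt = pb_stable_dt(params, grid)
    bound = pb_stable_dt(params, grid, safety=0.5)
    if dt > bound:
        raise ValueError(
            f"dt={dt:g} violates the Euler diffusive bound {bound:g}"
        )
    A = np.array(A, dtype=float)
    B = np.array(B, dtype=float)
    C = np.array(C, dtype=float)
    rows = [A.copy()]
    times = [0.0]
    for step in range(1, n_steps + 1):
        dA, dB, dC = pb_rhs(A, B, C, grem_profile, gdf_profile, params, grid)
        A += dt * dA
        B += dt * dB
        C += dt * dC
        if step % record_every == 0:
            if not np.all(np.isfinite(A)):
                raise NumericalBlowupError(
                    f"PB integration diverged at step {step}"
                )
            rows.append(A.copy())
            times.append(step * dt)
    meta = {"params_digest": params.digest(), "seed": seed,
            "n_steps": n_steps, "record_every": record_every}
    return Kymograph(
        A_xt=np.asarray(rows), times=np.asarray(times), dt=dt,
        dx=grid.dx, metadata=meta,
    )
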