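"""Multi-module regulatory model of the feather epithelial cylinder.

Nine dynamic species on the periodic circumferential grid:

* the retinoic-acid (RA) module — extracellular RA (``RA_o``, diffusible),
  intracellular RA (``RA_i``), free receptor (``R``), the RA-receptor
  signalling complex (``RAR``), free CRABP1 (``BP``) and the RA-CRABP1
  complex (``RABP``) — with a prescribed CYP26B1 profile (``CYP``) that
  degrades channelled RA;
* three diffusible ligands — ``WNT`` (anterior-peaked), ``GDF`` (GDF10,
  rachis-promoting) and ``GREM`` (GREM1, BGZ-promoting) — wired through
  Hill-regulated production.

Extracellular RA enters the cell at rate ``k_p`` (a fraction ``beta_loss``
is lost in the transition).  Intracellular RA binds receptors
(``k_on``/``k_off``) and CRABP1 (``m_on``/``m_off``); bound RA is handed
between the two carriers at rates ``j_alpha`` (RAR -> RABP) and ``j_beta``
(RABP -> RAR).  The RAR complex is the RA signal: it represses GREM1 (and,
more weakly, GDF10), so CRABP1 abundance raises and CYP26B1 lowers the
effective RA signal.  GDF10 is activated by WNT; GREM1 is repressed by
WNT, RAR and GDF10, confining it to the posterior barb generative zone.

The model is run to steady state with classical fourth-order Runge-Kutta
time stepping on a second-order finite-difference spatial discretization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .grid import SpatialGrid
from .gradients import GradientSpec, build_gradient

SPECIES = ("RA_o", "RA_i", "R", "RAR", "BP", "RABP", "WNT", "GDF", "GREM")
DIFFUSIBLE = ("RA_o", "WNT", "GDF", "GREM")

#: Hill-link wiring: regulatory edge -> index into (k1..k5, n1..n5).
DEFAULT_HILL_LINKS: Mapping[str, int] = {
    "wnt_gdf_act": 1,   # WNT activates GDF10
    "wnt_grem_inh": 2,  # WNT represses GREM1
    "rar_grem_inh": 3,  # RA signal represses GREM1
    "rar_gdf_inh": 4,   # RA signal (weakly) represses GDF10
    "gdf_grem_inh": 5,  # GDF10 excludes GREM1 from the rachis
}


class NumericalBlowupError(RuntimeError):
    """A concentration field became non-finite or negative during stepping."""


@dataclass(frozen=True)
class MRFParameters:
    """Full parameter vector of the regulatory model.

    ``V_i`` are maximum production rates, ``B_i`` basal production rates,
    ``D_i`` diffusion coefficients (zero for intracellular species) and
    ``r_i`` decay rates.  Species that decay both free and in complex carry
    paired rates (``r_BP1``/``r_BP2``, ``r_R1``/``r_R2``,
    ``r_RAi1``/``r_RAi2`` for the unbound/bound pools).
    """

    # extracellular RA
    V_RAo: float = 1.0
    B_RAo: float = 0.0
    D_RAo: float = 1e-4
    r_RAo: float = 0.1
    # intracellular RA (non-diffusible)
    B_RAi: float = 0.0
    r_RAi1: float = 0.5
    r_RAi2: float = 0.2
    # receptor
    B_R: float = 1.0
    r_R1: float = 1.0
    r_R2: float = 1.0
    # CRABP1: production amplitude comes from grad_BP
    V_BP: float = 1.0
    B_BP: float = 0.0
    r_BP1: float = 1.0
    r_BP2: float = 0.2
    # WNT
    V_WNT: float = 1.0
    B_WNT: float = 0.01
    D_WNT: float = 2e-4
    r_WNT: float = 1.0
    # GDF10
    V_GDF: float = 1.0
    B_GDF: float = 0.0
    D_GDF: float = 1e-4
    r_GDF: float = 1.0
    # GREM1
    V_GREM: float = 1.0
    B_GREM: float = 0.0
    D_GREM: float = 1e-4
    r_GREM: float = 1.0
    # binding / exchange / transport
    k_on: float = 0.005
    k_off: float = 0.1
    m_on: float = 5.0
    m_off: float = 0.05
    j_alpha: float = 0.1
    j_beta: float = 2.0
    k_p: float = 1.0
    beta_loss: float = 0.2
    # CYP26B1-mediated degradation of channelled RA
    r_cyp: float = 0.2
    cyp_target: str = "bound"  # "bound" (RABP pool) or "free" (RA_i pool)
    # residual GREM production under saturating RA signal (partial repression)
    rar_grem_floor: float = 0.55
    # Hill dissociation constants and coefficients
    k1: float = 0.3
    k2: float = 0.05
    k3: float = 0.01
    k4: float = 1.0
    k5: float = 0.3
    n1: float = 2.0
    n2: float = 2.0
    n3: float = 2.0
    n4: float = 2.0
    n5: float = 2.0
    hill_links: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_HILL_LINKS)
    )
    # graded inputs
    grad_CYP: GradientSpec = GradientSpec(a=0.0)
    grad_BP: GradientSpec = GradientSpec(a=0.0)
    grad_WNT: GradientSpec = GradientSpec(
        a=1.0, v=-12.0, axis="anterior_posterior"
    )
    grad_RAo: GradientSpec = GradientSpec(a=1.0, form="constant")

    def __post_init__(self) -> None:
        for name in (
            "V_RAo", "B_RAo", "D_RAo", "r_RAo", "B_RAi", "r_RAi1", "r_RAi2",
            "B_R", "r_R1", "r_R2", "V_BP", "B_BP", "r_BP1", "r_BP2",
            "V_WNT", "B_WNT", "D_WNT", "r_WNT", "V_GDF", "B_GDF", "D_GDF",
            "r_GDF", "V_GREM", "B_GREM", "D_GREM", "r_GREM", "k_on", "k_off",
            "m_on", "m_off", "j_alpha", "j_beta", "k_p", "r_cyp",
            "k1", "k2", "k3", "k4", "k5",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0")
        for name in ("n1", "n2", "n3", "n4", "n5"):
            if getattr(self, name) < 1:
                raise ValueError(f"Hill coefficient {name} must be >= 1")
        if not 0.0 <= self.beta_loss <= 1.0:
            raise ValueError("beta_loss must lie in [0, 1]")
        if not 0.0 <= self.rar_grem_floor < 1.0:
            raise ValueError("rar_grem_floor must lie in [0, 1)")
        if self.cyp_target not in ("bound", "free"):
            raise ValueError("cyp_target must be 'bound' or 'free'")
        if set(self.hill_links) != set(DEFAULT_HILL_LINKS):
            raise ValueError(
                f"hill_links must wire exactly {sorted(DEFAULT_HILL_LINKS)}"
            )

    def diffusion_of(self, species: str) -> float:
        """Diffusion coefficient of a species; intracellular species are 0."""
        return {
            "RA_o": self.D_RAo,
            "WNT": self.D_WNT,
            "GDF": self.D_GDF,
            "GREM": self.D_GREM,
        }.get(species, 0.0)

    def hill_kn(self, link: str) -> tuple[float, float]:
        i = self.hill_links[link]
        return getattr(self, f"k{i}"), getattr(self, f"n{i}")

    def with_updates(self, **kwargs) -> "MRFParameters":
        return replace(self, **kwargs)


@dataclass
class MRFState:
    """Per-species concentration fields plus the prescribed CYP profile."""

    fields: dict[str, np.ndarray]
    CYP: np.ndarray
    t: float = 0.0

    def __getattr__(self, name: str):
        try:
            return self.__dict__["fields"][name]
        except KeyError:
            raise AttributeError(name) from None

    @classmethod
    def from_array(
        cls, y: np.ndarray, cyp: np.ndarray, t: float = 0.0
    ) -> "MRFState":
        return cls(
            fields={s: y[i].copy() for i, s in enumerate(SPECIES)},
            CYP=cyp.copy(),
            t=t,
        )

    def to_array(self) -> np.ndarray:
        return np.stack([self.fields[s] for s in SPECIES])


@dataclass
class SteadyState:
    """Converged (or terminated) state with convergence diagnostics."""

    state: MRFState
    residual: float
    n_steps: int
    converged: bool
    tol: float

    def profile(self, species: str) -> np.ndarray:
        return self.state.fields[species]


def hill_act(u: np.ndarray, k: float, n: float) -> np.ndarray:
    """Activating Hill function u^n / (k^n + u^n)."""
    un = np.power(np.maximum(u, 0.0), n)
    return un / (k**n + un)


def hill_inh(u: np.ndarray, k: float, n: float) -> np.ndarray:
    """Inhibitory Hill function k^n / (k^n + u^n)."""
    kn = k**n
    return kn / (kn + np.power(np.maximum(u, 0.0), n))


def initial_state(
    params: MRFParameters,
    grid: SpatialGrid,
    noise_amplitude: float = 1e-3,
    seed: int = 0,
) -> MRFState:
    """Basal homogeneous start plus (optionally) seeded uniform noise."""
    rng = np.random.default_rng(seed)
    y = np.zeros((len(SPECIES), grid.n_points))
    if noise_amplitude > 0:
        y += noise_amplitude * rng.uniform(size=y.shape)
    cyp = build_gradient(params.grad_CYP, grid)
    return MRFState.from_array(y, cyp)


class MRFProblem:
    """Right-hand side of the regulatory system with cached graded inputs."""

    def __init__(self, params: MRFParameters, grid: SpatialGrid):
        self.params = params
        self.grid = grid
        self.cyp = build_gradient(params.grad_CYP, grid)
        self.g_RAo = (
            params.V_RAo * build_gradient(params.grad_RAo, grid) + params.B_RAo
        )
        self.g_BP = (
            params.V_BP * build_gradient(params.grad_BP, grid) + params.B_BP
        )
        self.g_WNT = (
            params.V_WNT * build_gradient(params.grad_WNT, grid) + params.B_WNT
        )

    def rhs(self, y: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(y)):
            bad = np.argwhere(~np.isfinite(y))[0]
            raise NumericalBlowupError(
                f"non-finite value in species {SPECIES[bad[0]]} "
                f"at node {bad[1]}"
            )
        p = self.params
        lap = self.grid.laplacian
        RA_o, RA_i, R, RAR, BP, RABP, WNT, GDF, GREM = y

        bind_R = p.k_on * RA_i * R - p.k_off * RAR
        bind_BP = p.m_on * RA_i * BP - p.m_off * RABP
        # carrier hand-off, mass-action in the receiving free pool
        handoff_ab = p.j_alpha * RAR * BP   # RAR + BP -> RABP + R
        handoff_ba = p.j_beta * RABP * R    # RABP + R -> RAR + BP
        if p.cyp_target == "bound":
            cyp_bound = p.r_cyp * self.cyp * RABP
            cyp_free = 0.0
        else:
            cyp_bound = 0.0
            cyp_free = p.r_cyp * self.cyp * RA_i

        d = np.empty_like(y)
        d[0] = (
            p.D_RAo * lap(RA_o) + self.g_RAo
            - (p.r_RAo + p.k_p) * RA_o
        )
        d[1] = (
            p.B_RAi + (1.0 - p.beta_loss) * p.k_p * RA_o
            - bind_R - bind_BP - p.r_RAi1 * RA_i - cyp_free
        )
        d[2] = (
            p.B_R - p.r_R1 * R - bind_R + handoff_ab - handoff_ba
        )
        d[3] = bind_R - handoff_ab + handoff_ba - p.r_R2 * RAR
        # RA decay / CYP degradation of complexed RA return free CRABP1
        d[4] = (
            self.g_BP - p.r_BP1 * BP - bind_BP - handoff_ab + handoff_ba
            + p.r_RAi2 * RABP + cyp_bound
        )
        d[5] = (
            bind_BP + handoff_ab - handoff_ba
            - (p.r_BP2 + p.r_RAi2) * RABP - cyp_bound
        )
        d[6] = p.D_WNT * lap(WNT) + self.g_WNT - p.r_WNT * WNT
        k1, n1 = p.hill_kn("wnt_gdf_act")
        k4, n4 = p.hill_kn("rar_gdf_inh")
        d[7] = (
            p.D_GDF * lap(GDF)
            + p.V_GDF * hill_act(WNT, k1, n1) * hill_inh(RAR, k4, n4)
            + p.B_GDF - p.r_GDF * GDF
        )
        k2, n2 = p.hill_kn("wnt_grem_inh")
        k3, n3 = p.hill_kn("rar_grem_inh")
        k5, n5 = p.hill_kn("gdf_grem_inh")
        fl = p.rar_grem_floor
        rar_factor = fl + (1.0 - fl) * hill_inh(RAR, k3, n3)
        d[8] = (
            p.D_GREM * lap(GREM)
            + p.V_GREM
            * hill_inh(WNT, k2, n2)
            * rar_factor
            * hill_inh(GDF, k5, n5)
            + p.B_GREM - p.r_GREM * GREM
        )
        return d


def mrf_rhs(
    state: MRFState, params: MRFParameters, grid: SpatialGrid
) -> MRFState:
    """Time derivative of every dynamic field (functional form)."""
    problem = MRFProblem(params, grid)
    problem.cyp = state.CYP  # honour the state's prescribed profile
    d = problem.rhs(state.to_array())
    return MRFState.from_array(d, state.CYP, t=state.t)


def stable_dt(params: MRFParameters, grid: SpatialGrid, safety: float = 0.4,
              dt_cap: float = 0.02) -> float:
    """Diffusive stability bound safety * dx^2 / (2 max D), capped for
    stiff reaction terms."""
    d_max = max(params.diffusion_of(s) for s in SPECIES)
    if d_max <= 0:
        return dt_cap
    return min(safety * grid.dx**2 / (2.0 * d_max), dt_cap)


def run_to_steady_state(
    initial: MRFState,
    params: MRFParameters,
    grid: SpatialGrid,
    dt: float | None = None,
    tol: float = 1e-8,
    max_steps: int = 5_000_000,
    sustain: int = 100,
    positivity_floor: float = -1e-9,
) -> SteadyState:
    """Advance with classical RK4 until the max-norm residual stays below
    ``tol`` for ``sustain`` consecutive steps.

    Non-convergence within ``max_steps`` returns ``converged=False`` rather
    than raising; NaN/Inf or a field dipping below ``positivity_floor``
    raises :class:`NumericalBlowupError` (the step size is too large).
    """
    if dt is None:
        dt = stable_dt(params, grid)
    bound = stable_dt(params, grid, safety=1.0, dt_cap=np.inf)
    if dt > bound:
        raise ValueError(
            f"dt={dt:g} violates the diffusive stability bound {bound:g}"
        )
    problem = MRFProblem(params, grid)
    problem.cyp = initial.CYP
    y = initial.to_array()
    residual = np.inf
    below = 0
    step = 0
    for step in range(1, max_steps + 1):
        k1 = problem.rhs(y)
        k2 = problem.rhs(y + 0.5 * dt * k1)
        k3 = problem.rhs(y + 0.5 * dt * k2)
        k4 = problem.rhs(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if y.min() < positivity_floor:
            bad = np.argwhere(y < positivity_floor)[0]
            raise NumericalBlowupError(
                f"negative concentration in species {SPECIES[bad[0]]} at "
                f"node {bad[1]} on step {step}; reduce dt"
            )
        residual = float(np.max(np.abs(k1)))
        below = below + 1 if residual < tol else 0
        if below >= sustain:
            state = MRFState.from_array(y, initial.CYP, t=initial.t + step * dt)
            return SteadyState(state, residual, step, True, tol)
    state = MRFState.from_array(y, initial.CYP, t=initial.t + step * dt)
    return SteadyState(state, residual, step, False, tol)


def solve_preset_state(
    params: MRFParameters,
    grid: SpatialGrid,
    seed: int = 0,
    noise_amplitude: float = 1e-3,
    **kwargs,
) -> SteadyState:
    """Convenience: basal-noise initial condition, then steady state."""
    init = initial_state(params, grid, noise_amplitude=noise_amplitude,
                         seed=seed)
    return run_to_steady_state(init, params, grid, **kwargs)
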