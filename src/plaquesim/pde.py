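"""Method-of-lines solver for the lipid-structured transport system.

The dimensionless live-cell density m(a, t) obeys a non-local transport
equation on a >= 1:

    dm/dt + v(t) dm/da = eta P [ (m * p)(a) - m ]            (efferocytosis)
                         + rho [ 4 m(2a - 1) - m ]           (proliferation)
                         - ( R/M + rho ) m                   (renormalisation)

with advection speed v = lam/M + theta N (lipid on-loading), the convolution
(m * p)(a) = int_1^{a-1} m(a - a') p(a') da' (zero for a < 2), and the
recruitment boundary condition v m(1, t) = R/M.  The apoptotic density
relaxes towards the live one, dp/dt = (M/P)(m - p).  Both densities are
probability distributions (the aggregate scales live in the co-integrated
ODE subsystem).

Scheme: the semi-infinite domain is truncated at a_max, the lipid derivative
uses second-order upwinding (backward-biased; transport is always rightward),
the convolution uses the trapezoidal rule on exactly aligned nodes, and the
proliferation source 4 rho m(2a-1) is omitted where 2a - 1 > a_max.  The
boundary node is an algebraic constraint re-evaluated from the aggregate
state at every right-hand-side call.

Mass stabilisation: the manifold of normalised densities is invariant under
the exact dynamics but *transversally unstable* whenever eta P* > 1+gamma-rho
(quadrature-level mass errors are amplified exponentially through the
efferocytosis gain).  The solver therefore adds a consistent restoring term
-sigma (int m da - 1) m that vanishes identically for normalised densities;
see docs/methods.md.  Set ``mass_relaxation=0`` to recover the literal
scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .grid import LipidGrid
from .ode import ODEState, ode_rhs, recruitment_rate
from .parameters import DimensionlessParameters, initial_state, validate

__all__ = [
    "PDESolution",
    "advection_velocity",
    "boundary_value",
    "upwind_derivative",
    "efferocytosis_convolution",
    "pantograph_terms",
    "pde_rhs",
    "simulate",
    "normalization_error",
]


def advection_velocity(s: ODEState, nd: DimensionlessParameters) -> float:
    """Lipid on-loading speed v = lam/M + theta*N (always positive)."""
    if s.M <= 0:
        raise ValueError(f"advection velocity undefined for M={s.M} <= 0")
    return nd.lam / s.M + nd.theta * s.N


def boundary_value(s: ODEState, nd: DimensionlessParameters) -> float:
    """Recruitment-pinned density at a = 1: m(1,t) = R / (lam + theta*M*N)."""
    if s.M <= 0:
        raise ValueError(f"boundary value undefined for M={s.M} <= 0")
    R = recruitment_rate(s, nd.kappa)
    denom = nd.lam + nd.theta * s.M * s.N
    if denom <= 0:
        raise ValueError("zero advection flux at the boundary")
    return R / denom


def upwind_derivative(f: np.ndarray, grid: LipidGrid) -> np.ndarray:
    """Backward-biased d/da: second order in the interior.

    Node j >= 2 uses (3 f_j - 4 f_{j-1} + f_{j-2}) / 2h; the first interior
    node falls back to first order; node 0 is boundary-assigned and its
    derivative is never used (returned as 0).
    """
    if f.shape != (grid.n_nodes,):
        raise ValueError("grid function shape mismatch")
    h = grid.h
    D = np.empty_like(f)
    D[0] = 0.0
    D[1] = (f[1] - f[0]) / h
    D[2:] = (3.0 * f[2:] - 4.0 * f[1:-1] + f[:-2]) / (2.0 * h)
    return D


def efferocytosis_convolution(
    m: np.ndarray, p: np.ndarray, grid: LipidGrid
) -> np.ndarray:
    """(m * p)(a_j) = int_1^{a_j - 1} m(a_j - a') p(a') da', trapezoidal.

    Zero for a_j < 2 (a cell of lipid a results from eating a cell of lipid
    >= 1 while itself carrying >= 1).  Unit offsets are whole numbers of
    nodes, so the quadrature is an exactly aligned discrete convolution.
    """
    if m.shape != p.shape or m.shape != (grid.n_nodes,):
        raise ValueError("m and p must live on the same grid")
    q, J, h = grid.q, grid.J, grid.h
    n = J - q + 1  # nodes participating: a <= a_max - 1
    full = np.convolve(m[:n], p[:n])[:n]
    out = np.zeros(grid.n_nodes)
    # trapezoid: half-weight the end points a' = 1 and a' = a - 1
    out[q:] = h * (full - 0.5 * (m[:n] * p[0] + m[0] * p[:n]))
    return out


def pantograph_terms(m: np.ndarray, grid: LipidGrid, rho: float) -> np.ndarray:
    """Proliferation source/sink rho [4 m(2a - 1) - m] with exact alignment.

    2 a_j - 1 = a_{2j}, so the source needs no interpolation.  Where the
    argument leaves the truncated domain (2j > J) the source is omitted —
    justified because m must vanish as a grows — while the sink remains.
    """
    if m.shape != (grid.n_nodes,):
        raise ValueError("grid function shape mismatch")
    out = -rho * m
    half = grid.J // 2  # largest j with 2j <= J
    out[: half + 1] += 4.0 * rho * m[: 2 * half + 1 : 2]
    return out


def pde_rhs(
    m: np.ndarray,
    p: np.ndarray,
    s: ODEState,
    grid: LipidGrid,
    nd: DimensionlessParameters,
    mass_relaxation: float = 0.0,
):
    """Assembled right-hand side (dm, dp, ds).

    The boundary node of ``m`` is pinned to the recruitment value before the
    spatial operators are applied; its returned derivative is zero (the pin
    is algebraic, not evolutionary).  ``mass_relaxation`` is the gain sigma of
    the consistent normalisation-restoring term (see module docstring).
    """
    if s.P <= 0:
        raise ValueError("apoptotic relaxation undefined for P <= 0")
    mloc = m.copy()
    mloc[0] = boundary_value(s, nd)
    v = advection_velocity(s, nd)
    R = recruitment_rate(s, nd.kappa)
    D = upwind_derivative(mloc, grid)
    conv = efferocytosis_convolution(mloc, p, grid)
    pan = pantograph_terms(mloc, grid, nd.rho)
    dm = (
        -v * D
        + nd.eta * s.P * (conv - mloc)
        + pan
        - (R / s.M + nd.rho) * mloc
    )
    if mass_relaxation:
        dm -= mass_relaxation * (grid.integrate(mloc) - 1.0) * mloc
    dm[0] = 0.0
    dp = (s.M / s.P) * (mloc - p)
    return dm, dp, ode_rhs(s, nd)


@dataclass
class PDESolution:
    """Snapshots of a method-of-lines run."""

    grid: LipidGrid
    times: np.ndarray                  # (n_t,)
    m: np.ndarray                      # (n_t, J+1)
    p: np.ndarray                      # (n_t, J+1)
    ode: np.ndarray                    # (n_t, 5) rows of (M, P, A_M, A_P, N)
    diagnostics: dict = field(default_factory=dict)

    def state(self, i: int) -> ODEState:
        return ODEState.from_array(self.ode[i])

    @property
    def terminal_state(self) -> ODEState:
        return self.state(len(self.times) - 1)

    @property
    def terminal_m(self) -> np.ndarray:
        return self.m[-1]

    @property
    def terminal_p(self) -> np.ndarray:
        return self.p[-1]

    def norm_error_series(self) -> tuple[np.ndarray, np.ndarray]:
        em = np.array([abs(self.grid.integrate(mk) - 1.0) for mk in self.m])
        ep = np.array([abs(self.grid.integrate(pk) - 1.0) for pk in self.p])
        return em, ep


def simulate(
    nd: DimensionlessParameters,
    grid: LipidGrid,
    t_end: float = 200.0,
    snapshot_times: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "RK45",
    p0_ratio: float = 0.5,
    mass_relaxation: float = 5.0,
    norm_ceiling: float = 0.05,
    steady_stop: float | None = None,
) -> PDESolution:
    """Integrate densities and aggregates from the half-normal start.

    State vector: interior live density m_1..m_J (the boundary node is
    algebraic), full apoptotic density p_0..p_J, and the five aggregates.
    Integration aborts with a diagnostic if the normalisation drift exceeds
    ``norm_ceiling``.  If ``steady_stop`` is given, the run also terminates
    once the sup-norm of the state derivative falls below it.
    """
    report = validate(nd)
    if report.hard_violations:
        names = ", ".join(v.name for v in report.hard_violations)
        raise ValueError(f"hard parameter-regime violations: {names}")
    J = grid.J
    m0, p0, s0 = initial_state(nd, grid, p0_ratio=p0_ratio)
    if snapshot_times is None:
        snapshot_times = np.linspace(0.0, t_end, 81)
    w = grid.trapezoid_weights

    def unpack(y):
        s = ODEState.from_array(y[2 * J + 1:])
        m = np.empty(J + 1)
        m[1:] = y[:J]
        m[0] = boundary_value(s, nd)
        return m, y[J : 2 * J + 1], s

    def f(t, y):
        m, p, s = unpack(y)
        dm, dp, ds = pde_rhs(m, p, s, grid, nd, mass_relaxation=mass_relaxation)
        return np.concatenate([dm[1:], dp, ds.as_array()])

    def norm_guard(t, y):
        m, p, _ = unpack(y)
        drift = max(abs(w @ m - 1.0), abs(w @ p - 1.0))
        return norm_ceiling - drift

    norm_guard.terminal = True
    events = [norm_guard]
    if steady_stop is not None:
        def quiescent(t, y):
            return np.max(np.abs(f(t, y))) - steady_stop
        quiescent.terminal = True
        events.append(quiescent)

    y0 = np.concatenate([m0[1:], p0, s0.as_array()])
    sol = solve_ivp(
        f, (0.0, t_end), y0, method=method, rtol=rtol, atol=atol,
        t_eval=snapshot_times, events=events,
    )
    if sol.status == -1:
        last = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(f"PDE solver failed at t={last}: {sol.message}")
    if sol.status == 1 and len(sol.t_events[0]):
        raise RuntimeError(
            f"normalisation drift exceeded {norm_ceiling} at "
            f"t={sol.t_events[0][0]:.3f}; increase a_max or q"
        )

    n_t = sol.t.size
    m = np.empty((n_t, J + 1))
    p = np.empty((n_t, J + 1))
    ode = np.empty((n_t, 5))
    for k in range(n_t):
        mk, pk, sk = unpack(sol.y[:, k])
        m[k], p[k], ode[k] = mk, pk, sk.as_array()
    diag = {
        "nfev": sol.nfev,
        "status": sol.status,
        "message": sol.message,
        "mass_relaxation": mass_relaxation,
        "min_m": float(m.min()),
        "min_p": float(p.min()),
    }
    return PDESolution(grid=grid, times=sol.t, m=m, p=p, ode=ode, diagnostics=diag)


def normalization_error(sol: PDESolution) -> tuple[float, float]:
    """Maximum |int m da - 1| and |int p da - 1| over the stored snapshots."""
    em, ep = sol.norm_error_series()
    return float(em.max()), float(ep.max())
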