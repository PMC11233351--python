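"""Closed five-variable aggregate subsystem.

Integrating the lipid-structured transport equations over all lipid contents
yields a closed system of ODEs for the live macrophage number M, apoptotic
cell number P, the lipid totals A_M and A_P carried by those populations, and
the necrotic core lipid N (all dimensionless):

    dM/dt   = R + (rho - 1 - gamma) M
    dP/dt   = M - (eta M + nu) P
    dA_M/dt = R + rho M - (1 + gamma) A_M + lam + M (eta A_P + theta N)
    dA_P/dt = A_M - (eta M + nu) A_P
    dN/dt   = nu A_P - theta M N

with the saturating recruitment flux R = (A_M - M)/(kappa + A_M - M).  The
subsystem decouples from the distribution shape, has a unique positive steady
state whenever ``rho < 1 + gamma`` (M* solves a quadratic with one positive
root), and carries all the information needed for the steady-state analysis
of the full model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import (
    DimensionalParameters,
    DimensionlessParameters,
    nondimensionalise,
)

__all__ = [
    "ODEState",
    "SteadyStateODE",
    "Trajectory",
    "recruitment_rate",
    "ode_rhs",
    "solve_ode",
    "ode_steady_state",
    "steady_state_sensitivity",
    "steady_state_stable",
    "equivalent_recruitment",
    "proliferation_fraction",
    "dimensional_steady_state",
]


@dataclass(frozen=True)
class ODEState:
    """Aggregate state: cell numbers (M, P), lipid totals (A_M, A_P, N)."""

    M: float
    P: float
    A_M: float
    A_P: float
    N: float

    def as_array(self) -> np.ndarray:
        return np.array([self.M, self.P, self.A_M, self.A_P, self.N])

    @staticmethod
    def from_array(y: np.ndarray) -> "ODEState":
        return ODEState(*map(float, y))


@dataclass(frozen=True)
class SteadyStateODE:
    """Equilibrium aggregates; ``exists`` is False when rho >= 1 + gamma."""

    exists: bool
    M: float = math.nan
    P: float = math.nan
    A_M: float = math.nan
    A_P: float = math.nan
    N: float = math.nan

    def as_state(self) -> ODEState:
        if not self.exists:
            raise ValueError("no bounded steady state (rho >= 1 + gamma)")
        return ODEState(self.M, self.P, self.A_M, self.A_P, self.N)


@dataclass(frozen=True)
class Trajectory:
    times: np.ndarray           # shape (n,), strictly increasing
    values: np.ndarray          # shape (5, n), rows M, P, A_M, A_P, N
    diagnostics: dict

    @property
    def terminal(self) -> ODEState:
        return ODEState.from_array(self.values[:, -1])

    def state(self, i: int) -> ODEState:
        return ODEState.from_array(self.values[:, i])


def recruitment_rate(s: ODEState, kappa: float) -> float:
    """Saturating monocyte recruitment flux R = (A_M - M)/(kappa + A_M - M).

    The drive is the internalised lipid of the live population, A_M - M
    (each cell carries one endogenous unit); R rises from 0 with no
    internalised lipid to 1 in the heavily laden limit, with half-maximum at
    A_M - M = kappa.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    excess = s.A_M - s.M
    if excess < 0:
        raise ValueError(
            f"corrupted state: A_M={s.A_M} < M={s.M} (negative internalised lipid)"
        )
    return excess / (kappa + excess)


def ode_rhs(s: ODEState, nd: DimensionlessParameters) -> ODEState:
    """Time derivatives of the five aggregates."""
    R = recruitment_rate(s, nd.kappa)
    return ODEState(
        M=R + (nd.rho - 1.0 - nd.gamma) * s.M,
        P=s.M - (nd.eta * s.M + nd.nu) * s.P,
        A_M=R + nd.rho * s.M - (1.0 + nd.gamma) * s.A_M + nd.lam
        + s.M * (nd.eta * s.A_P + nd.theta * s.N),
        A_P=s.A_M - (nd.eta * s.M + nd.nu) * s.A_P,
        N=nd.nu * s.A_P - nd.theta * s.M * s.N,
    )


def solve_ode(
    nd: DimensionlessParameters,
    s0: ODEState,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t_eval: np.ndarray | None = None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the aggregate subsystem to ``t_end``.

    The system is mildly stiff near equilibrium; the default LSODA switches
    automatically.  Raises RuntimeError with the last accepted time on solver
    failure.
    """
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    if t_end == 0:
        y = s0.as_array()[:, None]
        return Trajectory(np.array([0.0]), y, {"nfev": 0, "status": 0})

    def f(t, y):
        return ode_rhs(ODEState.from_array(y), nd).as_array()

    sol = solve_ivp(
        f, (0.0, t_end), s0.as_array(), method=method,
        rtol=rtol, atol=atol, t_eval=t_eval,
    )
    if sol.status != 0:
        last = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(f"ODE solver failed at t={last}: {sol.message}")
    diag = {"nfev": sol.nfev, "status": sol.status, "message": sol.message}
    return Trajectory(sol.t, sol.y, diag)


def _msquared_coeffs(nd: DimensionlessParameters) -> tuple[float, float, float]:
    """Coefficients (a, b, c) of the quadratic a M*^2 + b M* + c = 0."""
    a = 1.0 + nd.gamma - nd.rho
    b = (
        nd.lam - 1.0
        + nd.gamma * (nd.kappa + nd.gamma * nd.kappa + nd.lam)
        - nd.rho * (nd.lam + nd.gamma * nd.kappa)
    )
    c = -nd.lam
    return a, b, c


def ode_steady_state(nd: DimensionlessParameters) -> SteadyStateODE:
    """Closed-form equilibrium of the aggregate subsystem.

    M* is the unique positive root of the quadratic (the product of roots is
    -lam/(1+gamma-rho) < 0, so exactly one root is positive); the remaining
    values follow algebraically.  Evaluated in the cancellation-free branch of
    the quadratic formula.
    """
    if not nd.bounded:
        return SteadyStateODE(exists=False)
    a, b, c = _msquared_coeffs(nd)
    disc = b * b - 4.0 * a * c          # c < 0 so disc > b^2 >= 0
    sq = math.sqrt(disc)
    if b <= 0:
        M = (-b + sq) / (2.0 * a)
    else:
        # -b + sq would cancel; use the product-of-roots form instead
        M = 2.0 * (-c) / (b + sq)
    clearance = nd.eta * M + nd.nu
    P = M / clearance
    # at equilibrium the recruitment flux equals (1 + gamma - rho) M < 1
    R = a * M
    A_M = M + nd.kappa * (1.0 / (1.0 - R) - 1.0)
    A_P = A_M / clearance
    N = nd.nu * A_P / (nd.theta * M)
    return SteadyStateODE(exists=True, M=M, P=P, A_M=A_M, A_P=A_P, N=N)


def steady_state_sensitivity(
    nd: DimensionlessParameters, h: float | None = None
) -> dict[str, float]:
    """Central finite-difference derivatives of the equilibrium w.r.t. rho.

    Default step h = 1e-4*(1 + gamma - rho).  The expected sign pattern is
    M*, P*, A_M* increasing and N* decreasing in rho, with A_P* increasing
    exactly when eta < (1 + gamma) nu / lam.
    """
    if h is None:
        h = 1e-4 * (1.0 + nd.gamma - nd.rho)
    lo, hi = nd.rho - h, nd.rho + h
    if not (0.0 < lo and hi < 1.0 + nd.gamma):
        raise ValueError(
            f"finite-difference step crosses the admissible range "
            f"(0, 1+gamma): rho +- h = ({lo}, {hi})"
        )
    up = ode_steady_state(nd.replace(rho=hi))
    dn = ode_steady_state(nd.replace(rho=lo))
    return {
        name: (getattr(up, name) - getattr(dn, name)) / (2.0 * h)
        for name in ("M", "P", "A_M", "A_P", "N")
    }


def steady_state_stable(nd: DimensionlessParameters, h: float = 1e-7) -> bool:
    """Numerical linear stability of the equilibrium.

    Eigenvalues of a central finite-difference Jacobian of the right-hand
    side; returns True when all real parts are negative.
    """
    ss = ode_steady_state(nd)
    if not ss.exists:
        raise ValueError("no steady state to test (rho >= 1 + gamma)")
    y0 = ss.as_state().as_array()
    jac = np.empty((5, 5))
    for k in range(5):
        step = h * max(1.0, abs(y0[k]))
        yp, ym = y0.copy(), y0.copy()
        yp[k] += step
        ym[k] -= step
        fp = ode_rhs(ODEState.from_array(yp), nd).as_array()
        fm = ode_rhs(ODEState.from_array(ym), nd).as_array()
        jac[:, k] = (fp - fm) / (2.0 * step)
    return bool(np.all(np.linalg.eigvals(jac).real < 0))


def equivalent_recruitment(
    beta: float, gamma: float, rho1: float, alpha1: float, rho2: float
) -> float:
    """Recruitment scale preserving the dimensional equilibrium cell count.

    Two plaques with (rho1, alpha1) and (rho2, alpha2) have identical
    dimensional steady states (except for the lipid distribution shape) when
    the ratio (beta + gamma - rho)/alpha is held fixed:

        alpha2 = alpha1 * (beta + gamma - rho2) / (beta + gamma - rho1)
    """
    if alpha1 <= 0:
        raise ValueError("alpha1 must be positive")
    if rho1 >= beta + gamma or rho2 >= beta + gamma:
        raise ValueError("rho must be below beta + gamma for a bounded equilibrium")
    return alpha1 * (beta + gamma - rho2) / (beta + gamma - rho1)


def equivalent_parameters(
    nd: DimensionlessParameters, rho2: float
) -> DimensionlessParameters:
    """Dimensionless parameter set of the recruitment-compensated plaque.

    Changing the proliferation rate to ``rho2`` while rescaling the maximal
    recruitment rate alpha to keep (beta + gamma - rho)/alpha — and hence the
    whole dimensional equilibrium — fixed multiplies alpha by
    c = (1 + gamma - rho2)/(1 + gamma - rho).  Since alpha enters the
    non-dimensionalisation, eta and theta scale by c while lam and kappa
    scale by 1/c; gamma, nu and a_sigma are untouched.
    """
    if nd.rho >= 1.0 + nd.gamma or rho2 >= 1.0 + nd.gamma:
        raise ValueError("rho must stay below 1 + gamma along the family")
    c = (1.0 + nd.gamma - rho2) / (1.0 + nd.gamma - nd.rho)
    return nd.replace(
        rho=rho2, eta=c * nd.eta, theta=c * nd.theta,
        lam=nd.lam / c, kappa=nd.kappa / c,
    )


def proliferation_fraction(nd: DimensionlessParameters) -> float:
    """Steady-state share of macrophages sourced from division, r = rho/(1+gamma).

    Equals rho*M*/(rho*M* + R*) with R* the equilibrium recruitment flux; the
    ratio collapses to rho/(1 + gamma) independently of the other parameters.
    """
    if not nd.bounded:
        raise ValueError("rho >= 1 + gamma: no steady state")
    return nd.rho / (1.0 + nd.gamma)


def dimensional_steady_state(dim: DimensionalParameters) -> SteadyStateODE:
    """Equilibrium in dimensional units.

    M* is obtained by rescaling the dimensionless root by alpha/beta; the
    remaining values use the dimensional equilibrium relations, in which only
    M* and the fixed ratio (beta + gamma - rho)/alpha involve the
    proliferation/recruitment pair — hence P*, A_M*, A_P*, N* are invariant
    under :func:`equivalent_recruitment` transformations.
    """
    if dim.rho >= dim.beta + dim.gamma:
        return SteadyStateODE(exists=False)
    nd = nondimensionalise(dim)
    M = ode_steady_state(nd).M * dim.alpha / dim.beta
    clearance = dim.eta * M + dim.nu
    P = dim.beta * M / clearance
    ratio = (dim.beta + dim.gamma - dim.rho) / dim.alpha
    A_M = dim.a0 * M + dim.kappa * ratio * M / (1.0 - ratio * M)
    A_P = dim.beta * A_M / clearance
    N = dim.nu * A_P / (dim.theta * M)
    return SteadyStateODE(exists=True, M=M, P=P, A_M=A_M, A_P=A_P, N=N)
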