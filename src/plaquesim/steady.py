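"""Steady-state analysis of the equilibrium lipid distribution m*(a).

At equilibrium the apoptotic distribution equals the live one (p* = m*) and
m* satisfies the boundary-value problem

    dm*/da = k1 (m* * m*)(a) - k2 m*(a) + k3 m*(2a - 1),      m*(1) = m1*,

whose constants are algebraic groupings of the aggregate equilibrium divided
by the steady advection speed v* = lam/M* + theta N*:

    k1 = eta P* / v*,   k2 = (eta P* + 1 + gamma + rho) / v*,
    k3 = 4 rho / v*,    m1* = (R*/M*) / v*.

The mixed delayed/advanced argument structure blocks a general closed form,
but three exact tools are available and implemented here: an infinite-series
solution for the no-efferocytosis case k1 = 0, a full-history recurrence for
the raw moments, and an analytic sign criterion for the boundary slope that
separates the four qualitative profile shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.signal import find_peaks

from .grid import LipidGrid
from .ode import SteadyStateODE, recruitment_rate
from .parameters import DimensionlessParameters
from .pde import advection_velocity

__all__ = [
    "BVPConstants",
    "MomentSequence",
    "ProfileClass",
    "ProfileReport",
    "bvp_constants",
    "series_solution_no_efferocytosis",
    "moments",
    "summary_stats",
    "argmax_location",
    "classify_profile",
]


@dataclass(frozen=True)
class BVPConstants:
    """Rate groupings (inverse lipid) and boundary density of the steady BVP."""

    k1: float
    k2: float
    k3: float
    m1_star: float
    velocity: float  # steady advection speed v*

    def __post_init__(self) -> None:
        if not (self.k2 > self.k1 >= 0 and self.k2 > 0 and self.k3 >= 0):
            raise ValueError("require k2 > k1 >= 0 and k3 >= 0")
        if self.m1_star < 0:
            raise ValueError("boundary density must be non-negative")


def bvp_constants(nd: DimensionlessParameters, ss: SteadyStateODE) -> BVPConstants:
    """Constants of the steady boundary-value problem from the ODE equilibrium."""
    if not ss.exists:
        raise ValueError("no ODE steady state (rho >= 1 + gamma)")
    s = ss.as_state()
    v = advection_velocity(s, nd)
    R = recruitment_rate(s, nd.kappa)
    return BVPConstants(
        k1=nd.eta * ss.P / v,
        k2=(nd.eta * ss.P + 1.0 + nd.gamma + nd.rho) / v,
        k3=4.0 * nd.rho / v,
        m1_star=(R / ss.M) / v,
        velocity=v,
    )


def _log_coefficients(j: int) -> tuple[np.ndarray, np.ndarray]:
    """Signs and log-magnitudes of c_i = 2^i / prod_{l != i, 0<=l<=j} (1 - 2^{i-l}).

    The products alternate in sign and span hundreds of orders of magnitude,
    so they are accumulated as sign + log|.| to keep every coefficient
    accurate in double precision.
    """
    signs = np.empty(j + 1)
    logs = np.empty(j + 1)
    for i in range(j + 1):
        sign = 1.0
        logmag = i * math.log(2.0)
        for l in range(j + 1):
            if l == i:
                continue
            term = 1.0 - 2.0 ** (i - l)
            if term < 0:
                sign = -sign
            logmag -= math.log(abs(term))
        signs[i] = sign
        logs[i] = logmag
    return signs, logs


def series_solution_no_efferocytosis(
    c: BVPConstants,
    a_values: np.ndarray,
    j_max: int = 40,
    tol: float = 1e-12,
) -> np.ndarray:
    """Evaluate the k1 = 0 series solution of the steady BVP.

    m*(a) = m1* sum_j (k3/2k2)^j sum_i c_{j,i} exp(-2^i k2 (a-1)) with the
    alternating-product coefficients of :func:`_log_coefficients`.  Terms are
    added until the j-term bound (k3/2k2)^j max_i |c_{j,i}| drops below
    ``tol`` (hard cap ``j_max``); requires k3 < 2 k2 for geometric decay,
    which holds exactly when rho < 1 + gamma.
    """
    if c.k1 != 0:
        raise ValueError("series solution valid only without efferocytosis (k1 = 0)")
    ratio = c.k3 / (2.0 * c.k2)
    if ratio >= 1.0:
        raise ValueError(f"series does not converge: k3/(2 k2) = {ratio} >= 1")
    a = np.asarray(a_values, dtype=float)
    if np.any(a < 1.0):
        raise ValueError("lipid contents must satisfy a >= 1")
    out = np.zeros_like(a)
    log_ratio = math.log(ratio) if ratio > 0 else -math.inf
    for j in range(j_max + 1):
        signs, logs = _log_coefficients(j)
        log_weight = 0.0 if j == 0 else j * log_ratio
        if ratio > 0 and log_weight + logs.max() < math.log(tol):
            break
        # exp(-2^i k2 (a-1)) assembled in log space per coefficient
        for i in range(j + 1):
            expo = log_weight + logs[i] - (2.0**i) * c.k2 * (a - 1.0)
            out += signs[i] * np.exp(expo)
        if ratio == 0:
            break
    return c.m1_star * out


@dataclass(frozen=True)
class MomentSequence:
    """Raw moments phi_0..phi_n of m*; finite_up_to marks recurrence validity."""

    phi: np.ndarray
    finite_up_to: int

    def __getitem__(self, n: int) -> float:
        if n > self.finite_up_to:
            raise IndexError(f"moment {n} beyond finite range {self.finite_up_to}")
        return float(self.phi[n])


def moments(c: BVPConstants, phi1: float, n_max: int = 6) -> MomentSequence:
    """Raw moments of m* by the full-history recurrence.

    phi_0 = 1 by normalisation and phi_1 = A_M*/M* is supplied from the ODE
    equilibrium (the recurrence is derived for n >= 2 only).  Higher moments:

        phi_n = [ m1* + n phi_{n-1} + k3/2^{n+1}
                  + sum_{j=1}^{n-1} C(n,j) phi_j (k1 phi_{n-j} + k3/2^{n+1}) ]
                / (k2 - 2 k1 - k3/2^{n+1})

    The computation stops at the first non-positive denominator (moments
    beyond that index are infinite: the distribution's tail is too heavy).
    """
    if phi1 < 1.0:
        raise ValueError("phi_1 >= 1 required (each cell carries >= 1 lipid unit)")
    phi = np.full(n_max + 1, np.nan)
    phi[0] = 1.0
    if n_max >= 1:
        phi[1] = phi1
    finite = min(n_max, 1)
    for n in range(2, n_max + 1):
        shift = c.k3 / 2.0 ** (n + 1)
        den = c.k2 - 2.0 * c.k1 - shift
        if den <= 0:
            break
        num = c.m1_star + n * phi[n - 1] + shift + sum(
            math.comb(n, j) * phi[j] * (c.k1 * phi[n - j] + shift)
            for j in range(1, n)
        )
        phi[n] = num / den
        finite = n
    return MomentSequence(phi=phi, finite_up_to=finite)


def summary_stats(ms: MomentSequence) -> tuple[float, float]:
    """Mean and (standardised third-moment) skewness of m*."""
    if ms.finite_up_to < 3:
        raise ValueError("need finite moments up to order 3")
    p1, p2, p3 = ms[1], ms[2], ms[3]
    var = p2 - p1 * p1
    if var <= 0:
        raise ValueError(f"degenerate variance {var} (point-mass distribution)")
    skew = (p3 - 3.0 * p1 * var - p1**3) / var**1.5
    return p1, skew


class ProfileClass(str, Enum):
    """Qualitative shapes of m*(a).

    a: monotone decreasing from the boundary;
    b: boundary maximum plus interior efferocytosis peaks near unit spacing;
    c: single interior maximum (proliferation-dominated);
    d: interior maximum plus a secondary efferocytosis peak near twice its
       location.
    """

    A = "a"
    B = "b"
    C = "c"
    D = "d"


@dataclass(frozen=True)
class ProfileReport:
    profile_class: ProfileClass
    a_argmax: float
    peak_locations: tuple[float, ...]
    boundary_slope_sign: int


def argmax_location(m_star: np.ndarray, grid: LipidGrid) -> float:
    """Location of the global maximum, refined by a local quadratic fit."""
    j = int(np.argmax(m_star))
    if j == 0 or j == grid.J:
        return float(grid.nodes[j])
    y0, y1, y2 = m_star[j - 1], m_star[j], m_star[j + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # flat or degenerate: keep the node
        return float(grid.nodes[j])
    delta = 0.5 * (y0 - y2) / denom
    return float(grid.nodes[j] + delta * grid.h)


def classify_profile(
    m_star: np.ndarray,
    grid: LipidGrid,
    nd: DimensionlessParameters,
    ss: SteadyStateODE,
    p_star: np.ndarray | None = None,
    convergence_tol: float = 1e-3,
    prominence_fraction: float = 0.01,
    min_separation_cells: int = 2,
) -> ProfileReport:
    """Assign one of the four qualitative profile classes to a converged m*.

    The boundary slope sign is analytic: at a = 1 the convolution vanishes
    and the advanced argument coincides with the boundary, so
    dm*/da(1) = (k3 - k2) m1*, positive exactly when 3 rho > eta P* + 1 +
    gamma.  Classes c/d (interior global maximum) occur precisely then.
    Interior peaks are detected with a relative-prominence filter; b and d
    are the multi-peaked variants, with d's secondary peak near twice the
    primary location (cells that ate an equally laden apoptotic cell).
    """
    if p_star is not None:
        gap = float(np.max(np.abs(m_star - p_star)))
        if gap > convergence_tol:
            raise ValueError(
                f"input not converged: max|m - p| = {gap:.3g} > {convergence_tol}"
            )
    c = bvp_constants(nd, ss)
    slope_sign = int(np.sign(c.k3 - c.k2))

    height = prominence_fraction * float(m_star.max())
    idx, _ = find_peaks(m_star, height=height, distance=min_separation_cells)
    peaks = tuple(argmax_location(m_star, grid) if j == np.argmax(m_star)
                  else float(grid.nodes[j]) for j in idx)

    if slope_sign <= 0:
        cls = ProfileClass.A if len(idx) == 0 else ProfileClass.B
    else:
        cls = ProfileClass.C if len(idx) <= 1 else ProfileClass.D
    a_arg = argmax_location(m_star, grid)
    return ProfileReport(
        profile_class=cls,
        a_argmax=a_arg,
        peak_locations=peaks,
        boundary_slope_sign=slope_sign,
    )
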