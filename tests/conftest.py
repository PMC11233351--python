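"""Shared fixtures: the reference parameter set, small grids, cached runs."""

from __future__ import annotations

from math import comb, gamma as gamma_fn, pi, sqrt

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import plaquesim as ps


@pytest.fixture(scope="session")
def baseline_nd() -> ps.DimensionlessParameters:
    """Reference regime: moderate proliferation, efficient efferocytosis."""
    return ps.DimensionlessParameters(
        rho=0.8, gamma=0.25, nu=0.8, eta=1.5, theta=0.4,
        lam=0.1, kappa=5.0, a_sigma=2.0,
    )


@pytest.fixture(scope="session")
def baseline_ss(baseline_nd) -> ps.SteadyStateODE:
    return ps.ode_steady_state(baseline_nd)


@pytest.fixture(scope="session")
def small_grid() -> ps.LipidGrid:
    return ps.LipidGrid.from_extent(10, 30)


@pytest.fixture(scope="session")
def small_run(baseline_nd, small_grid) -> ps.PDESolution:
    """Baseline dynamics on a compact domain, long enough to equilibrate."""
    return ps.simulate(
        baseline_nd, small_grid, t_end=150.0,
        snapshot_times=np.linspace(0.0, 150.0, 61),
    )


@pytest.fixture(scope="session")
def reference_run(baseline_nd) -> ps.PDESolution:
    """Production-scale run: q = 20 nodes per lipid unit, domain to a = 100,
    integrated for 200 macrophage lifespans."""
    grid = ps.LipidGrid.from_extent(20, 100)
    return ps.simulate(
        baseline_nd, grid, t_end=200.0,
        snapshot_times=np.linspace(0.0, 200.0, 81),
    )


@pytest.fixture(scope="session")
def eta_zero_runs(baseline_nd, small_grid):
    """No-efferocytosis steady states (slowly converging: integrate to t=400)."""
    out = {}
    for rho in (0.0, 0.4, 0.8):
        nd = baseline_nd.replace(eta=0.0, rho=rho)
        out[rho] = (nd, ps.simulate(nd, small_grid, t_end=400.0))
    return out


def exact_moment_trajectory(
    nd: ps.DimensionlessParameters, n_max: int, t_end: float,
    p0_ratio: float = 0.5,
) -> dict[int, float]:
    """Independent oracle: raw moments of m at ``t_end`` with no spatial grid.

    Multiplying the transport equation by a^n and integrating over a >= 1
    closes the moment dynamics on the aggregate subsystem:

        dmu_n/dt = v m(1) + v n mu_{n-1}
                   + eta P [ sum_j C(n,j) mu_j^m mu_{n-j}^p - mu_n^m ]
                   + rho [ 2^{1-n} sum_j C(n,j) mu_j^m - mu_n^m ]
                   - (R/M + rho) mu_n^m

    with mu_0 = 1 and mu_1 = A_M/M pinned by the aggregates.  This hierarchy
    is exact (no truncation, no discretisation) and is integrated here with a
    tight-tolerance stiff solver.
    """
    NM = n_max

    def f(t, y):
        M, P, AM, AP, N = y[:5]
        mum = np.empty(NM + 1)
        mup = np.empty(NM + 1)
        mum[0] = mup[0] = 1.0
        mum[1] = AM / M
        mup[1] = AP / P
        mum[2:] = y[5 : 5 + NM - 1]
        mup[2:] = y[5 + NM - 1 :]
        R = (AM - M) / (nd.kappa + AM - M)
        v = nd.lam / M + nd.theta * N
        m1 = R / (nd.lam + nd.theta * M * N)
        dmum = np.zeros(NM + 1)
        dmup = np.zeros(NM + 1)
        for n in range(2, NM + 1):
            convn = sum(comb(n, j) * mum[j] * mup[n - j] for j in range(n + 1))
            pann = 2.0 ** (1 - n) * sum(comb(n, j) * mum[j] for j in range(n + 1))
            dmum[n] = (
                v * m1 + v * n * mum[n - 1]
                + nd.eta * P * (convn - mum[n])
                + nd.rho * (pann - mum[n])
                - (R / M + nd.rho) * mum[n]
            )
            dmup[n] = (M / P) * (mum[n] - mup[n])
        s = ps.ODEState(M=M, P=P, A_M=AM, A_P=AP, N=N)
        ds = ps.ode_rhs(s, nd).as_array()
        return np.concatenate([ds, dmum[2:], dmup[2:]])

    s0 = ps.initial_ode_state(nd, p0_ratio=p0_ratio)
    # raw moments of the half-normal: E[(1+X)^n], X half-normal(a_sigma)
    ex = [
        nd.a_sigma**k * 2 ** (k / 2) * gamma_fn((k + 1) / 2) / sqrt(pi)
        for k in range(NM + 1)
    ]
    mu0 = [sum(comb(n, k) * ex[k] for k in range(n + 1)) for n in range(NM + 1)]
    y0 = np.concatenate([s0.as_array(), mu0[2:], mu0[2:]])
    sol = solve_ivp(f, (0.0, t_end), y0, method="LSODA", rtol=1e-10, atol=1e-12)
    assert sol.status == 0
    M, P, AM, AP, N = sol.y[:5, -1]
    out = {0: 1.0, 1: AM / M}
    for n in range(2, NM + 1):
        out[n] = float(sol.y[5 + n - 2, -1])
    return out
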