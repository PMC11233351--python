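"""Tests of the steady-distribution analysis: constants, series, moments,
summary statistics and profile classification."""

import numpy as np
import pytest

import plaquesim as ps
from plaquesim.steady import _log_coefficients

from conftest import exact_moment_trajectory


class TestBVPConstants:
    def test_internal_consistency_identities(self, baseline_nd, baseline_ss):
        c = ps.bvp_constants(baseline_nd, baseline_ss)
        v = c.velocity
        assert c.k2 - c.k1 == pytest.approx(
            (1 + baseline_nd.gamma + baseline_nd.rho) / v, rel=1e-12)
        assert c.k3 == pytest.approx(4 * baseline_nd.rho / v, rel=1e-12)

    def test_limiting_cases(self, baseline_nd):
        nd0 = baseline_nd.replace(rho=0.0)
        c0 = ps.bvp_constants(nd0, ps.ode_steady_state(nd0))
        assert c0.k3 == 0.0
        nd1 = baseline_nd.replace(eta=0.0)
        c1 = ps.bvp_constants(nd1, ps.ode_steady_state(nd1))
        assert c1.k1 == 0.0

    def test_boundary_density_matches_simulation(self, baseline_nd, baseline_ss,
                                                 small_run):
        c = ps.bvp_constants(baseline_nd, baseline_ss)
        assert small_run.terminal_m[0] == pytest.approx(c.m1_star, rel=1e-3)

    def test_requires_existing_equilibrium(self, baseline_nd):
        with pytest.raises(ValueError):
            ps.bvp_constants(baseline_nd,
                             ps.ode_steady_state(baseline_nd.replace(rho=1.3)))


class TestSeries:
    def test_pure_exponential_without_proliferation(self, baseline_nd):
        nd = baseline_nd.replace(eta=0.0, rho=0.0)
        c = ps.bvp_constants(nd, ps.ode_steady_state(nd))
        a = np.linspace(1.0, 8.0, 50)
        got = ps.series_solution_no_efferocytosis(c, a)
        np.testing.assert_allclose(
            got, c.m1_star * np.exp(-c.k2 * (a - 1.0)), rtol=1e-12)

    def test_boundary_value_recovered(self, baseline_nd):
        # inner alternating sums cancel at a = 1 for every j >= 1
        nd = baseline_nd.replace(eta=0.0)
        c = ps.bvp_constants(nd, ps.ode_steady_state(nd))
        got = ps.series_solution_no_efferocytosis(c, np.array([1.0]))
        assert got[0] == pytest.approx(c.m1_star, rel=1e-9)

    def test_inner_coefficient_sums_cancel(self):
        for j in range(1, 16):
            signs, logs = _log_coefficients(j)
            total = float(np.sum(signs * np.exp(logs)))
            assert abs(total) < 1e-9 * float(np.exp(logs.max()))

    def test_satisfies_the_steady_equation(self, baseline_nd):
        # independent check: plug the series into the pantograph BVP
        nd = baseline_nd.replace(eta=0.0, rho=0.4)
        c = ps.bvp_constants(nd, ps.ode_steady_state(nd))
        a = np.linspace(1.0, 12.0, 2201)
        m = ps.series_solution_no_efferocytosis(c, a)
        da = a[1] - a[0]
        lhs = np.gradient(m, da)
        rhs = -c.k2 * m + c.k3 * np.interp(2 * a - 1.0, a, m, right=0.0)
        mask = (a > 1.05) & (a < 5.5)
        assert np.max(np.abs(lhs - rhs)[mask]) < 1e-4 * m.max()

    def test_matches_time_marched_steady_state(self, eta_zero_runs, small_grid):
        # the rho = 0 profile decays slowly (k2 ~ 0.14), so domain
        # truncation dominates its error budget on this grid
        budget = {0.0: 1e-2, 0.4: 5e-3, 0.8: 5e-3}
        for rho, (nd, sol) in eta_zero_runs.items():
            c = ps.bvp_constants(nd, ps.ode_steady_state(nd))
            series = ps.series_solution_no_efferocytosis(c, small_grid.nodes)
            err = np.max(np.abs(series - sol.terminal_m)) / series.max()
            assert err < budget[rho], f"rho={rho}: {err}"

    def test_rejects_efferocytosis(self, baseline_nd, baseline_ss):
        c = ps.bvp_constants(baseline_nd, baseline_ss)
        with pytest.raises(ValueError, match="efferocytosis"):
            ps.series_solution_no_efferocytosis(c, np.array([1.0]))


class TestMoments:
    def test_normalisation_anchor(self, baseline_nd, baseline_ss):
        c = ps.bvp_constants(baseline_nd, baseline_ss)
        ms = ps.moments(c, baseline_ss.A_M / baseline_ss.M, n_max=4)
        assert ms[0] == 1.0

    def test_shifted_exponential_second_moment(self):
        # normalised distribution k2 exp(-k2 (a-1)): phi_2 = 1 + 2/k2 + 2/k2^2
        k2 = 1.7
        c = ps.BVPConstants(k1=0.0, k2=k2, k3=0.0, m1_star=k2, velocity=1.0)
        ms = ps.moments(c, 1.0 + 1.0 / k2, n_max=3)
        assert ms[2] == pytest.approx(1 + 2 / k2 + 2 / k2**2, rel=1e-12)

    def test_recurrence_agrees_with_exact_moment_dynamics(self, baseline_nd,
                                                          baseline_ss):
        # oracle: integrate the closed moment hierarchy in time (grid-free)
        exact = exact_moment_trajectory(baseline_nd, n_max=6, t_end=400.0)
        c = ps.bvp_constants(baseline_nd, baseline_ss)
        ms = ps.moments(c, baseline_ss.A_M / baseline_ss.M, n_max=6)
        for n in range(2, 7):
            assert ms[n] == pytest.approx(exact[n], rel=1e-6), f"phi_{n}"

    def test_moments_monotone_for_supported_above_one(self, baseline_nd,
                                                      baseline_ss):
        c = ps.bvp_constants(baseline_nd, baseline_ss)
        ms = ps.moments(c, baseline_ss.A_M / baseline_ss.M, n_max=6)
        phis = [ms[n] for n in range(7)]
        assert all(b >= a for a, b in zip(phis, phis[1:]))

    def test_quadrature_cross_check_on_simulated_distribution(
            self, baseline_nd, baseline_ss, reference_run):
        # phi_2 by recurrence vs trapezoid on the simulated m* at a_max=100;
        # the ~1% budget is the tail mass beyond the domain (phi_3 is more
        # tail-dominated and is checked against the exact hierarchy instead)
        c = ps.bvp_constants(baseline_nd, baseline_ss)
        ms = ps.moments(c, baseline_ss.A_M / baseline_ss.M, n_max=3)
        grid = reference_run.grid
        phi2_quad = grid.moment(reference_run.terminal_m, 2)
        assert phi2_quad == pytest.approx(ms[2], rel=0.02)


class TestSummaryStats:
    def test_exponential_family_skewness(self):
        k2 = 0.9
        c = ps.BVPConstants(k1=0.0, k2=k2, k3=0.0, m1_star=k2, velocity=1.0)
        ms = ps.moments(c, 1.0 + 1.0 / k2, n_max=3)
        mean, skew = ps.summary_stats(ms)
        assert mean == pytest.approx(1 + 1 / k2)
        assert skew == pytest.approx(2.0, rel=1e-10)

    def test_point_mass_raises_degenerate_variance(self):
        ms = ps.MomentSequence(phi=np.ones(4), finite_up_to=3)
        with pytest.raises(ValueError, match="variance"):
            ps.summary_stats(ms)

    def test_proliferation_lightens_and_skews_the_lipid_load(self, baseline_nd):
        means, skews = [], []
        rhos = np.linspace(0.05, 1.2, 12)
        for rho in rhos:
            nd = baseline_nd.replace(rho=rho)
            ss = ps.ode_steady_state(nd)
            c = ps.bvp_constants(nd, ss)
            mean, skew = ps.summary_stats(ps.moments(c, ss.A_M / ss.M, n_max=3))
            means.append(mean)
            skews.append(skew)
        assert all(b < a for a, b in zip(means, means[1:]))
        # the skewness trend has a shallow dip below rho ~ 0.2 and rises
        # steadily thereafter
        assert skews[-1] > skews[0]
        rising = [s2 > s1 for s1, s2 in zip(skews, skews[1:])]
        assert all(rising[2:])

    def test_recruitment_equivalent_family_fixes_mean_reduces_skewness(self):
        base = ps.DimensionlessParameters(rho=1.0 / 120, gamma=0.2, nu=0.8,
                                          eta=2.0, theta=1.0, lam=0.1,
                                          kappa=5.0, a_sigma=2.0)
        stats = []
        for k in range(1, 102, 10):
            nd = ps.equivalent_parameters(base, k / 120.0)
            ss = ps.ode_steady_state(nd)
            c = ps.bvp_constants(nd, ss)
            stats.append(ps.summary_stats(ps.moments(c, ss.A_M / ss.M, n_max=3)))
        means = [s[0] for s in stats]
        skews = [s[1] for s in stats]
        assert max(means) - min(means) < 1e-6 * means[0]
        assert all(b < a for a, b in zip(skews, skews[1:]))


class TestProfiles:
    def test_argmax_recovers_symmetric_peak_exactly(self, small_grid):
        a = small_grid.nodes
        m = np.exp(-((a - 4.0) ** 2))
        assert ps.argmax_location(m, small_grid) == pytest.approx(4.0, abs=1e-12)

    def test_monotone_decreasing_without_proliferation(self, baseline_nd):
        nd = baseline_nd.replace(rho=0.0, eta=0.3, theta=0.1)
        g = ps.LipidGrid.from_extent(10, 30)
        sol = ps.simulate(nd, g, t_end=250.0)
        rep = ps.classify_profile(sol.terminal_m, g, nd, ps.ode_steady_state(nd),
                                  p_star=sol.terminal_p)
        assert rep.profile_class is ps.ProfileClass.A
        assert rep.a_argmax == 1.0
        assert rep.boundary_slope_sign < 0

    def test_unimodal_interior_maximum_for_strong_proliferation(
            self, baseline_nd, baseline_ss, small_run):
        rep = ps.classify_profile(small_run.terminal_m, small_run.grid,
                                  baseline_nd, baseline_ss,
                                  p_star=small_run.terminal_p)
        assert rep.profile_class is ps.ProfileClass.C
        assert rep.a_argmax > 1.0
        assert rep.boundary_slope_sign > 0

    def test_secondary_efferocytosis_peak_at_twice_the_maximum(self, baseline_nd):
        # strong efferocytosis on top of strong proliferation; the boundary
        # structure is thin (width ~ 1/k2), so resolve it with q = 40
        nd = baseline_nd.replace(rho=1.0, eta=10.0)
        g = ps.LipidGrid.from_extent(40, 15)
        sol = ps.simulate(nd, g, t_end=300.0)
        rep = ps.classify_profile(sol.terminal_m, g, nd, ps.ode_steady_state(nd),
                                  p_star=sol.terminal_p)
        assert rep.profile_class is ps.ProfileClass.D
        assert rep.boundary_slope_sign > 0
        doubles = [p for p in rep.peak_locations
                   if abs(p - 2.0 * rep.a_argmax) < 0.3]
        assert doubles, (rep.a_argmax, rep.peak_locations)

    def test_boundary_peaked_with_interior_echoes_is_class_b(
            self, baseline_nd, small_grid):
        # classifier logic on a synthesised shape: decaying exponential from
        # the boundary with efferocytosis echoes at unit spacing, under a
        # parameter set whose analytic boundary slope is negative
        nd = baseline_nd.replace(rho=0.02, eta=60.0, theta=2.0)
        a = small_grid.nodes
        m = np.exp(-1.3 * (a - 1.0))
        for centre in (2.0, 3.0):
            m += 0.12 * np.exp(-((a - centre) ** 2) / (2 * 0.15**2))
        m /= small_grid.integrate(m)
        rep = ps.classify_profile(m, small_grid, nd, ps.ode_steady_state(nd))
        assert rep.profile_class is ps.ProfileClass.B
        assert rep.boundary_slope_sign < 0
        assert len(rep.peak_locations) >= 2

    def test_unconverged_input_rejected(self, baseline_nd, baseline_ss,
                                        small_grid):
        m = np.ones(small_grid.n_nodes)
        with pytest.raises(ValueError, match="converged"):
            ps.classify_profile(m, small_grid, baseline_nd, baseline_ss,
                                p_star=2 * m)

    def test_maximum_location_rises_then_returns_toward_boundary(
            self, baseline_nd):
        g40 = ps.LipidGrid.from_extent(40, 15)
        g10 = ps.LipidGrid.from_extent(10, 30)
        loc_low = ps.argmax_location(
            ps.simulate(baseline_nd.replace(rho=0.3), g10, t_end=250.0).terminal_m, g10)
        loc_mid = ps.argmax_location(
            ps.simulate(baseline_nd.replace(rho=0.9), g40, t_end=300.0).terminal_m, g40)
        loc_high = ps.argmax_location(
            ps.simulate(baseline_nd.replace(rho=1.2), g40, t_end=300.0).terminal_m, g40)
        assert loc_low == pytest.approx(1.0)
        assert loc_mid > 1.3
        assert 1.0 < loc_high < loc_mid
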