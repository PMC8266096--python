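"""Oxygen and growth-factor transport: kinetics, kernels, field solves."""

import numpy as np
import pytest

from angiosim import Parameters
from angiosim import transport as tr
from angiosim.geometry import build_hex_domain
from angiosim.hemodynamics import iterate_flow
from angiosim.network import single_vessel_network


class TestHillSaturation:
    def test_midpoint(self, params):
        assert tr.hill_saturation(40.2, params) == pytest.approx(0.5)

    def test_zero(self, params):
        assert tr.hill_saturation(0.0, params) == 0.0

    def test_hand_value(self, params):
        # S(100) with n=2.59, P50=40.2, evaluated independently
        expected = 100 ** 2.59 / (100 ** 2.59 + 40.2 ** 2.59)
        assert tr.hill_saturation(100.0, params) == pytest.approx(
            expected, rel=1e-12)

    def test_strictly_increasing(self, params):
        p = np.linspace(0, 150, 200)
        s = tr.hill_saturation(p, params)
        assert np.all(np.diff(s) > 0)
        assert np.all((s >= 0) & (s <= 1))

    def test_negative_rejected(self, params):
        with pytest.raises(ValueError):
            tr.hill_saturation(-1.0, params)


class TestConsumption:
    def test_half_max(self, params):
        assert tr.consumption_rate(10.5, params) == pytest.approx(
            params.m0 / 2)

    def test_saturation(self, params):
        assert tr.consumption_rate(1e9, params) == pytest.approx(
            params.m0, rel=1e-6)

    def test_hand_value(self, params):
        assert tr.consumption_rate(40.0, params) == pytest.approx(
            7.5 * 40.0 / (10.5 + 40.0), rel=1e-12)


class TestGFRelease:
    def test_half_max_at_p_gf(self, params):
        assert tr.gf_release_rate(40.0, params) == pytest.approx(
            params.k_gf_deg * params.c_gf0 / 2)

    def test_maximal_at_zero(self, params):
        assert tr.gf_release_rate(0.0, params) == pytest.approx(
            params.k_gf_deg * params.c_gf0)

    def test_hand_value(self, params):
        expected = params.k_gf_deg / (1 + (80.0 / 40.0) ** 2.5)
        assert tr.gf_release_rate(80.0, params) == pytest.approx(
            expected, rel=1e-12)

    def test_decreasing(self, params):
        p = np.linspace(0, 120, 100)
        r = tr.gf_release_rate(p, params)
        assert np.all(np.diff(r) < 0)


class TestGFDecayLength:
    def test_reference_value(self, params):
        assert params.gf_decay_length == pytest.approx(50.0)


def krogh_fixture(m0=60.0, length=84.0, diameter=10.0, r_out=36.0, h=6.0):
    """Single vessel in a wide consuming cylinder (free space).

    Demand is high enough that the oxygenated region ends at a critical
    radius well inside the tissue, which reproduces the closed-form
    cylinder solution with zero flux at its outer rim. A small
    half-maximum pressure keeps the kinetics near zero-order where the
    tissue is oxygenated.
    """
    params = Parameters(m0=m0, p_crit=0.8)
    net = single_vessel_network(length=length, diameter=diameter,
                                n_sub=int(length // 12),
                                inflow_pressure=100.0, outflow_pressure=99.0)
    xs = np.arange(-r_out, r_out + 1e-9, h)
    zs = np.arange(h / 2, length, h)
    pts = np.array([[x, y, z] for x in xs for y in xs for z in zs
                    if diameter / 2 + 0.5 <= np.hypot(x, y) <= r_out])
    return params, net, pts, h


class TestOxygenField:
    def test_no_consumption_no_loss(self):
        """With M0 -> 0 the blood leaves at the inflow P_O2 and tissue
        equilibrates near the vessel value."""
        params = Parameters(m0=1e-12)
        net = single_vessel_network(length=96.0, diameter=10.0, n_sub=8,
                                    inflow_pressure=100.0,
                                    outflow_pressure=99.0)
        iterate_flow(net, params)
        pts = np.array([[12.0, 0, z] for z in np.arange(6, 96, 12)]
                       + [[0, 15.0, z] for z in np.arange(6, 96, 12)])
        blood, tissue = tr.solve_oxygen_field(net, pts, 12.0 ** 3, params,
                                              domain=None)
        assert blood.po2.min() > 99.0  # no arteriovenous loss
        assert np.all(np.abs(tissue.po2 - blood.po2.mean()) < 2.0)

    def test_krogh_cylinder_profile(self):
        """Radial tissue profile matches the closed-form cylinder
        solution (quadratic + log) within 5% of the total drop."""
        params, net, pts, h = krogh_fixture()
        iterate_flow(net, params)
        blood, tissue = tr.solve_oxygen_field(net, pts, h ** 3, params,
                                              domain=None, tol=5e-3)
        assert tissue.converged
        k = params.krogh_k * 60e-4  # cm^3O2/(um min mmHg)
        m = params.m0 / 100 * 1e-12  # cm^3O2/(um^3 min), zero-order here
        rv = 5.0
        length = 84.0
        mid = np.abs(pts[:, 2] - length / 2) < h
        r = np.hypot(pts[mid, 0], pts[mid, 1])
        p_sim = tissue.po2[mid]
        # wall P_O2 from the matching condition at the mid subsegment
        i = int(np.argmin(np.abs(blood.midpoints[:, 2] - length / 2)))
        r_iv = 1.0 / (tr.NUSSELT * np.pi * k * blood.lengths[i])
        p_wall = blood.po2[i] - blood.source[i] * r_iv

        def profile(rr, r_crit):
            return (p_wall + m / (4 * k) * (rr ** 2 - rv ** 2)
                    - m * r_crit ** 2 / (2 * k) * np.log(rr / rv))

        # critical radius from the closed form: P(R) = 0
        from scipy.optimize import brentq
        r_crit = brentq(lambda rr: profile(rr, rr), rv + 1.0, 60.0)
        bins = np.arange(7.0, min(r_crit, 30.0), 4.0)
        sim_prof = np.array([p_sim[np.abs(r - b) < 2.0].mean()
                             for b in bins])
        ref_prof = np.maximum(profile(bins, r_crit), 0.0)
        assert np.max(np.abs(sim_prof - ref_prof)) < 0.05 * p_wall

    def test_supply_equals_consumption(self):
        params, net, pts, h = krogh_fixture()
        iterate_flow(net, params)
        blood, tissue = tr.solve_oxygen_field(net, pts, h ** 3, params,
                                              domain=None, tol=5e-3)
        supply = blood.inflow_flux - blood.outflow_flux
        assert supply == pytest.approx(tissue.total_consumption, rel=0.05)

    def test_monotone_in_demand(self):
        """Raising M0 lowers tissue P_O2 everywhere (single vessel)."""
        fields = []
        for m0 in (4.0, 8.0):
            params = Parameters(m0=m0)
            net = single_vessel_network(length=96.0, diameter=10.0, n_sub=8,
                                        inflow_pressure=100.0,
                                        outflow_pressure=99.0)
            iterate_flow(net, params)
            pts = np.array([[14.0, 0, z] for z in np.arange(6, 96, 6)])
            _, tissue = tr.solve_oxygen_field(net, pts, 10.0 ** 3, params,
                                              domain=None)
            fields.append(tissue.po2)
        assert np.all(fields[1] <= fields[0] + 1e-6)


class TestFiniteDifferenceEquivalence:
    """Kernel superposition vs an independent finite-difference solve."""

    def test_oxygen_field_three_segment_fixture(self):
        from angiosim.fdsolve import OracleGrid, finite_difference_reference
        from angiosim.network import y_bifurcation_network

        params = Parameters(m0=20.0)
        net = y_bifurcation_network()
        iterate_flow(net, params)
        h, n = 15.0, 16
        offset = np.array([0.0, 0.0, 140.0])
        grid = OracleGrid(shape=(n, n, n), spacing=h,
                          d_coef=params.krogh_k * 60e-4, k_coef=0.0)
        pts = grid.points() + offset
        blood, tissue = tr.solve_oxygen_field(net, pts, h ** 3, params,
                                              domain=None, tol=2e-3)
        sinks = tissue.consumption * h ** 3 / 1e12 / 100
        kern, _ = tr._oxygen_kernel(params)

        def field_at(x):
            x = np.atleast_2d(x)
            gq = tr._kernel_sum(x, blood.midpoints, kern,
                                np.zeros((1, 3)), blood.diameters / 2)
            gs = tr._kernel_sum(x, pts, kern, np.zeros((1, 3)), 1e-6)
            return tissue.p_inf + gq @ blood.source - gs @ sinks

        # matched sources: sinks at the grid points, vessel sources
        # deposited with cloud-in-cell weights
        s = -(sinks / h ** 3).reshape(n, n, n)
        origin = pts.reshape(n, n, n, 3)[0, 0, 0]
        for q, mp in zip(blood.source, blood.midpoints):
            f = (mp - origin) / h
            i0 = np.floor(f).astype(int)
            w = f - i0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        ii = np.clip(i0 + [dx, dy, dz], 0, n - 1)
                        ww = ((w[0] if dx else 1 - w[0])
                              * (w[1] if dy else 1 - w[1])
                              * (w[2] if dz else 1 - w[2]))
                        s[ii[0], ii[1], ii[2]] += q * ww / h ** 3
        c = finite_difference_reference(
            grid, s, dirichlet_fn=lambda g: field_at(g + offset)).ravel()
        sim = tissue.po2
        dist_v = np.min(np.linalg.norm(
            pts[:, None, :] - blood.midpoints[None, :, :], axis=2), axis=1)
        mask = dist_v > 1.5 * h  # away from the singular line sources
        rng_f = sim[mask].max() - sim[mask].min()
        l2 = np.sqrt(np.mean((sim[mask] - c[mask]) ** 2))
        assert l2 < 0.05 * rng_f

    def test_gf_field_vs_finite_difference(self, params):
        from angiosim.fdsolve import OracleGrid, finite_difference_reference

        h, n = 15.0, 15
        grid = OracleGrid(shape=(n, n, n), spacing=h,
                          d_coef=params.d_gf * 1e8,
                          k_coef=params.k_gf_deg)
        pts = grid.points()
        # a compact hypoxic blob releasing GF near the center
        r = np.linalg.norm(pts, axis=1)
        rates = np.where(r < 40.0, params.k_gf_deg * params.c_gf0, 0.0)
        state = tr.GFState(pts[rates > 0], rates[rates > 0] * h ** 3,
                           params, h ** 3, domain=None)
        c_kernel = state.concentration(pts)
        c_fd = finite_difference_reference(
            grid, rates.reshape(n, n, n),
            dirichlet_fn=lambda g: state.concentration(g)).ravel()
        rng_f = c_kernel.max() - c_kernel.min()
        l2 = np.sqrt(np.mean((c_kernel - c_fd) ** 2))
        assert l2 < 0.05 * rng_f


def uniform_hypoxia_gf(params, domain, pts, volume):
    po2 = np.zeros(len(pts))
    return tr.solve_gf_field(po2, pts, volume, params, domain=domain)


class TestGFField:
    def test_uniform_hypoxia_saturates(self, params):
        """Maximal release in a uniformly hypoxic ball approaches the
        homogeneous balance C_GF0; the finite-ball center value has the
        closed form C_GF0 (1 - (1 + R/L) exp(-R/L))."""
        h = 15.0
        radius = 150.0
        xs = np.arange(-radius, radius + 1, h)
        pts = np.array([[x, y, z] for x in xs for y in xs for z in xs
                        if np.sqrt(x * x + y * y + z * z) <= radius])
        state = uniform_hypoxia_gf(params, None, pts, h ** 3)
        c_center = state.concentration(np.array([[0.0, 0.0, 0.0]]))[0]
        x = radius / params.gf_decay_length
        expected = params.c_gf0 * (1.0 - (1.0 + x) * np.exp(-x))
        assert c_center == pytest.approx(expected, rel=0.02)
        # and it approaches the saturation level from below
        assert 0.7 < c_center < params.c_gf0

    def test_point_source_matches_screened_kernel(self, params):
        """A single release point reproduces exp(-r/L)/(4 pi D r)."""
        src = np.array([[0.0, 0.0, 0.0]])
        strength = np.array([120.0])  # um^3/s (small: keep C well below C_GF0)
        state = tr.GFState(src, strength, params, 10.0 ** 3, domain=None)
        d_um = params.d_gf * 1e8
        lgf = params.gf_decay_length
        for r in (10.0, 25.0, 60.0, 120.0):
            c = state.concentration(np.array([[r, 0.0, 0.0]]))[0]
            expected = strength[0] * np.exp(-r / lgf) / (4 * np.pi * d_um * r)
            assert c == pytest.approx(expected, rel=1e-9)

    def test_gradient_symmetry_zero(self, params):
        """Symmetric source arrangement -> zero gradient at the center."""
        src = np.array([[30.0, 0, 0], [-30.0, 0, 0],
                        [0, 30.0, 0], [0, -30.0, 0]])
        state = tr.GFState(src, np.full(4, 50.0), params, 10.0 ** 3,
                           domain=None)
        g = state.gradient(np.array([[0.0, 0.0, 0.0]]))[0]
        np.testing.assert_allclose(g, 0.0, atol=1e-15)

    def test_gradient_points_to_source(self, params):
        src = np.array([[50.0, 0.0, 0.0]])
        state = tr.GFState(src, np.array([50.0]), params, 10.0 ** 3,
                           domain=None)
        g = state.gradient(np.array([[0.0, 0.0, 0.0]]))[0]
        assert g[0] > 0  # toward +x
        assert abs(g[1]) < 1e-18 and abs(g[2]) < 1e-18

    def test_gradient_matches_central_difference(self, params, rng):
        src = rng.uniform(-80, 80, size=(30, 3))
        state = tr.GFState(src, rng.uniform(0.5, 2.0, 30) * 40.0, params,
                           10.0 ** 3, domain=None)
        for _ in range(20):
            x = rng.uniform(-60, 60, 3)
            if np.min(np.linalg.norm(src - x, axis=1)) < 8.0:
                continue
            g = state.gradient(x[None, :])[0]
            num = np.zeros(3)
            eps = 0.1
            for ax in range(3):
                e = np.zeros(3)
                e[ax] = eps
                cp = state.concentration((x + e)[None, :])[0]
                cm = state.concentration((x - e)[None, :])[0]
                num[ax] = (cp - cm) / (2 * eps)
            np.testing.assert_allclose(g, num, rtol=0.01, atol=1e-12)

    def test_bounded_by_cgf0(self, params, reference_grid, domain):
        po2 = np.zeros(reference_grid.n_points)
        state = tr.solve_gf_field(po2, reference_grid.points,
                                  reference_grid.point_volume, params,
                                  domain=domain)
        assert np.all(state.at_tissue >= 0.0)
        assert np.all(state.at_tissue <= params.c_gf0 + 1e-12)

    def test_hexagonal_periodicity(self, params, domain):
        """Field values agree at a point and its lattice translate."""
        rng = np.random.default_rng(7)
        src = rng.uniform(-60, 60, size=(40, 3))
        src[:, 2] = rng.uniform(100, 400, 40)
        state = tr.GFState(src, np.full(40, 2e3), params, 20.0 ** 3,
                           domain=domain)
        v1 = np.append(domain.lattice_vectors[0], 0.0)
        for p in ([10.0, 20.0, 250.0], [-40.0, 15.0, 300.0]):
            p = np.array(p)
            c0 = state.concentration(p[None, :])[0]
            c1 = state.concentration((p + v1)[None, :])[0]
            assert c1 == pytest.approx(c0, rel=0.01)
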