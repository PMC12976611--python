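"""Double perturbation velocity, stream function and bolus extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import annuflow as af
from conftest import solve_all


class TestOrders:
    def test_wave_frame_no_slip(self, preset):
        _, grid, _, _, vel = solve_all(preset)
        assert abs(vel.u3[0] + 1) <= 1e-8
        assert abs(vel.u3[-1] + 1) <= 1e-8
        assert abs(vel.orders["u300"][0] + 1) <= 1e-12
        for k in ("u301", "u310", "u311"):
            assert abs(vel.orders[k][0]) <= 1e-12
            assert abs(vel.orders[k][-1]) <= 1e-10

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        G1=st.floats(0.0, 4.0),
        G2=st.floats(0.0, 3.0),
        We=st.floats(0.0, 0.3),
        alpha=st.floats(0.0, 0.4),
        n=st.floats(0.1, 1.5),
        zt=st.floats(0.0, 1.0),
    )
    def test_no_slip_for_random_draws(self, preset, G1, G2, We, alpha, n, zt):
        p = preset.replace(G1=G1, G2=G2, We=We, alpha=alpha, n=n)
        _, _, _, _, vel = solve_all(p, zt=zt)
        assert abs(vel.u3[0] + 1) <= 1e-8
        assert abs(vel.u3[-1] + 1) <= 1e-8

    def test_rigid_body_wave_frame_solution(self, preset):
        """No forcing at all: the annulus translates with the wave."""
        p = preset.replace(phi=0.0, G1=0.0, G2=0.0)
        _, _, _, _, vel = solve_all(p, zt=0.3)
        for k, u in vel.orders.items():
            ref = -1.0 if k == "u300" else 0.0
            assert np.max(np.abs(u - ref)) <= 1e-10, k
        assert np.max(np.abs(vel.u3 + 1)) <= 1e-10
        assert np.max(np.abs(vel.w)) <= 1e-10

    def test_newtonian_index_kills_weissenberg_orders(self, preset):
        p = preset.replace(n=1.0)
        _, _, _, _, vel = solve_all(p)
        we2 = p.We**2 * np.abs(
            vel.orders["u310"] + p.alpha * vel.orders["u311"]
        )
        assert np.max(we2) <= 1e-12

    def test_zero_we_and_zero_alpha_collapse(self, preset):
        p = preset.replace(We=0.0, alpha=0.0)
        _, _, _, _, vel = solve_all(p)
        assert np.max(np.abs(vel.u3 - vel.orders["u300"])) <= 1e-12

    def test_alpha_content_vanishes_at_alpha_zero(self, preset):
        p = preset.replace(alpha=0.0)
        _, _, _, _, vel = solve_all(p)
        no_alpha = vel.orders["u300"] + p.We**2 * vel.orders["u310"]
        assert np.max(np.abs(vel.u3 - no_alpha)) <= 1e-12

    def test_grid_refinement_converges(self, preset):
        """Richardson check of the composite-Simpson pipeline: the
        default grid meets the 1e-8 quadrature target and halving the
        spacing shrinks the change ~16x (4th order)."""
        _, _, _, _, v1 = solve_all(preset, n=129)
        _, _, _, _, v2 = solve_all(preset, n=257)
        _, _, _, _, v3 = solve_all(preset, n=513)
        d12 = np.max(np.abs(v1.u3 - v2.u3[::2]))   # nested grids
        d23 = np.max(np.abs(v2.u3 - v3.u3[::2]))
        assert d23 <= 1e-8
        assert 8 <= d12 / d23 <= 32

    def test_coarse_grid_rejected(self, preset, trough):
        grid = af.RadialGrid(np.linspace(preset.eps, trough.h, 8))
        H = af.solve_temperature(preset, trough, grid)
        xi = af.solve_concentration(preset, trough, grid, H)
        with pytest.raises(af.ResolutionError):
            af.solve_orders(preset, trough, grid, H, xi)


class TestAssembly:
    def test_lab_frame_walls_are_zero(self, preset):
        _, _, _, _, vel = solve_all(preset)
        assert abs(vel.w[0]) <= 1e-8
        assert abs(vel.w[-1]) <= 1e-8

    def test_assemble_is_the_linear_combination(self, preset):
        _, _, _, _, vel = solve_all(preset)
        u3, w = af.assemble(vel.orders, preset.We, preset.alpha)
        manual = (
            vel.orders["u300"]
            + preset.alpha * vel.orders["u301"]
            + preset.We**2
            * (vel.orders["u310"] + preset.alpha * vel.orders["u311"])
        )
        np.testing.assert_array_equal(u3, manual)
        np.testing.assert_array_equal(w, u3 + 1)

    def test_single_peak_at_the_reporting_station(self, preset):
        """At the trough the lab-frame profile is one concave bump."""
        _, grid, _, _, vel = solve_all(preset, zt=af.core.DEFAULT_SECTION_ZT)
        i = int(np.argmax(vel.w))
        assert 0 < i < grid.n - 1
        assert np.all(np.diff(vel.w[: i + 1]) >= -1e-12)
        assert np.all(np.diff(vel.w[i:]) <= 1e-12)


class TestStreamFunction:
    def test_gauge_on_catheter(self, preset):
        field = af.stream_function(preset, n_z=32, grid_n=129)
        np.testing.assert_allclose(field.psi[:, 0], 0.0, atol=1e-15)

    def test_rigid_case_exact_parabola(self, preset):
        p = preset.replace(phi=0.0, G1=0.0, G2=0.0)
        field = af.stream_function(p, n_z=32, grid_n=257)
        expected = -(field.r**2 - p.eps**2) / 2
        for i in range(field.z.size):
            np.testing.assert_allclose(field.psi[i], expected, atol=1e-9)

    def test_radial_derivative_recovers_velocity(self, preset):
        """Differencing psi reproduces r*u3 to quadrature order."""
        field = af.stream_function(preset, n_z=32, grid_n=513)
        i = 8  # a column safely inside the domain
        z = field.z[i]
        section = af.make_section(preset, z, 0.0)
        valid = field.r <= section.h
        r = field.r[valid]
        psi = field.psi[i, valid]
        dpsi = np.gradient(psi, r)
        grid = af.make_radial_grid(preset, section, r.size)
        H = af.solve_temperature(preset, section, grid)
        xi = af.solve_concentration(preset, section, grid, H)
        vel = af.solve_orders(preset, section, grid, H, xi)
        ru3 = np.interp(r, grid.r, grid.r * vel.u3)
        # central differences are O(dr^2); compare away from endpoints
        assert np.max(np.abs(dpsi[2:-2] - ru3[2:-2])) <= 5e-2 * np.max(np.abs(ru3))

    def test_too_few_axial_samples_rejected(self, preset):
        with pytest.raises(af.ResolutionError):
            af.stream_function(preset, n_z=8)


class TestBolusExtraction:
    def test_rigid_field_has_no_closed_contours(self, preset):
        p = preset.replace(phi=0.0, G1=0.0, G2=0.0)
        field = af.stream_function(p, n_z=32, grid_n=129)
        summary = af.extract_boluses(field)
        assert summary.count == 0
        assert summary.total_area == 0.0

    def test_synthetic_vortex_area_matches_circle(self, preset):
        """A Gaussian psi bump yields closed contours whose enclosed
        area matches the analytic level-set circle area."""
        z = np.linspace(0.0, 1.0, 201)
        r = np.linspace(preset.eps, 1.0 + preset.phi, 201)
        Z, R = np.meshgrid(z, r, indexing="ij")
        sig = 0.08
        psi = np.exp(-((Z - 0.5) ** 2 + (R - 0.6) ** 2) / (2 * sig**2))
        field = af.StreamFunctionField(z=z, r=r, psi=psi, t=0.0, params=preset)
        summary = af.extract_boluses(field, n_levels=21)
        assert summary.count >= 10
        for (lev, verts), area in zip(summary.contours, summary.areas):
            # level set of the Gaussian: radius^2 = -2 sig^2 ln(lev)
            expected = np.pi * (-2 * sig**2 * np.log(lev))
            assert area == pytest.approx(expected, rel=0.02)

    def test_preset_bolus_area_is_finite_and_reproducible(self, preset):
        field = af.stream_function(preset, n_z=48, grid_n=201)
        s1 = af.extract_boluses(field)
        s2 = af.extract_boluses(field)
        assert s1.total_area == s2.total_area
        assert s1.count == s2.count
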