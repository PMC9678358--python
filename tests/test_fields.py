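"""Layered-indentation solver vs. the Hertz half-space closed forms."""

import numpy as np
import pytest

from nocimech.contact import ElasticMedium, ProbeSpec, contact_force, effective_modulus
from nocimech.fields import (
    FieldMap,
    Layer,
    LayerStack,
    MeshSpec,
    RadialProfile,
    ResolutionError,
    hertz_surface_stress_oracle,
    normalize_profile,
    peak_location,
    radial_to_map,
    solve_indentation,
)

MEDIUM = ElasticMedium(2.6, 0.45)
#: peaks are consumed at the 1 μm field-map resolution
MAP_CELL = 1.0


def hertz_reference(probe, d):
    a = np.sqrt(probe.radius * d)
    f = contact_force(effective_modulus(MEDIUM), probe, d)
    p0 = 3 * f * 1000.0 / (2 * np.pi * a * a)
    return a, f, p0


class TestOracleClosedForm:
    def test_center_pressure_and_edge_tension(self):
        probe, d = ProbeSpec(60), 20.0
        a, _, p0 = hertz_reference(probe, d)
        pp, _ = hertz_surface_stress_oracle(MEDIUM, probe, d, 0.0)
        assert pp[0] == pytest.approx(p0, rel=1e-9)
        _, tl = hertz_surface_stress_oracle(MEDIUM, probe, d, a)
        assert tl[0] == pytest.approx((1 - 2 * 0.45) / 3 * p0, rel=1e-9)

    def test_tension_decays_as_inverse_square(self):
        probe, d = ProbeSpec(60), 20.0
        a, _, _ = hertz_reference(probe, d)
        _, t1 = hertz_surface_stress_oracle(MEDIUM, probe, d, 2 * a)
        _, t2 = hertz_surface_stress_oracle(MEDIUM, probe, d, 4 * a)
        assert t1[0] / t2[0] == pytest.approx(4.0, rel=1e-9)


class TestSolverVsOracle:
    def test_pressure_matches_hertz(self, homog_profile, probe60):
        a, _, p0 = hertz_reference(probe60, 20.0)
        sel = homog_profile.rho <= 0.9 * a
        pp, _ = hertz_surface_stress_oracle(MEDIUM, probe60, 20.0, homog_profile.rho[sel])
        err = np.abs(homog_profile.p_perp[sel] - pp).max() / p0
        assert err < 0.05

    def test_total_force_matches_hertz(self, homog_profile, probe60):
        _, f, _ = hertz_reference(probe60, 20.0)
        assert homog_profile.total_force == pytest.approx(f, rel=0.05)

    def test_tension_peak_at_contact_edge(self, homog_profile, probe60):
        a, _, _ = hertz_reference(probe60, 20.0)
        peak = peak_location(homog_profile.rho, homog_profile.t_lat)
        assert abs(peak - a) <= MAP_CELL

    def test_pressure_integral_consistency(self, homog_profile):
        """Disc-integrated nodal pressure reproduces the reaction total."""
        rho, p = homog_profile.rho, homog_profile.p_perp
        f_un = np.trapezoid(p * 2 * np.pi * rho, rho)
        assert f_un / 1000.0 == pytest.approx(homog_profile.total_force, rel=0.02)


class TestLayeredSolve:
    def test_tension_peak_in_reported_band(self, layered_profile):
        peak = peak_location(layered_profile.rho, layered_profile.t_lat)
        assert 20.0 <= peak <= 25.0

    def test_pressure_monotone_envelope(self, layered_profile):
        """P_P decreases from the centre (no off-axis pressure maximum)."""
        p = layered_profile.p_perp
        assert p[0] == pytest.approx(p.max(), rel=0.01)
        inside = layered_profile.rho <= layered_profile.contact_radius
        assert np.all(np.diff(p[inside]) <= 5e-3 * p.max())

    def test_tension_outreaches_pressure(self, layered_profile):
        """At 40 μm the tension channel retains signal where pressure is gone."""
        rho = layered_profile.rho
        t_frac = np.interp(40.0, rho, layered_profile.t_lat) / layered_profile.t_lat.max()
        p_frac = np.interp(40.0, rho, layered_profile.p_perp) / layered_profile.p_perp.max()
        assert t_frac > p_frac

    def test_mesh_convergence_of_peak(self, layered_profile, probe60):
        refined = solve_indentation(
            LayerStack.default(), probe60, 20.0, mesh=MeshSpec().refined(0.5)
        )
        p1 = peak_location(layered_profile.rho, layered_profile.t_lat)
        p2 = peak_location(refined.rho, refined.t_lat)
        assert abs(p1 - p2) < MAP_CELL

    def test_too_coarse_mesh_rejected(self, probe60):
        mesh = MeshSpec(fine_spacing=5.0, mid_spacing=10.0, top_layer_elems=3)
        with pytest.raises(ResolutionError):
            solve_indentation(LayerStack.default(), probe60, 20.0, mesh=mesh)

    def test_depth_validity(self, probe60):
        with pytest.raises(ValueError):
            solve_indentation(LayerStack.default(), probe60, 0.0)
        with pytest.raises(ValueError):
            solve_indentation(LayerStack.default(), probe60, 20.0, indenter="banana")
        with pytest.raises(ValueError):
            solve_indentation(LayerStack.default(), ProbeSpec(30), 20.0, indenter="parabolic")


class TestLayerStack:
    def test_default_composition(self):
        stack = LayerStack.default()
        assert [l.thickness for l in stack.layers] == [10.0, 1000.0]
        assert stack.layers[1].modulus == 2.6
        assert stack.total_thickness == 1010.0
        assert stack.layer_at_depth(5.0) is stack.layers[0]
        assert stack.layer_at_depth(500.0) is stack.layers[1]

    def test_invalid_layers(self):
        with pytest.raises(ValueError):
            Layer(thickness=-1, modulus=1.0)
        with pytest.raises(ValueError):
            Layer(thickness=1, modulus=1.0, poisson=0.5)
        with pytest.raises(ValueError):
            LayerStack(())


class TestProfileUtilities:
    def make_profile(self, rho, p, t):
        return RadialProfile(rho=np.asarray(rho, float), p_perp=np.asarray(p, float),
                             t_lat=np.asarray(t, float))

    def test_normalize(self):
        prof = self.make_profile([0, 10, 20], [2.0, 1.0, 0.0], [0.0, 3.0, 1.5])
        norm = normalize_profile(prof)
        assert norm.p_perp.max() == 1.0 and norm.t_lat.max() == 1.0
        again = normalize_profile(norm)
        np.testing.assert_allclose(again.p_perp, norm.p_perp)
        assert peak_location(norm.rho, norm.t_lat) == pytest.approx(
            peak_location(prof.rho, prof.t_lat), rel=1e-9
        )

    def test_normalize_zero_channel_rejected(self):
        prof = self.make_profile([0, 10, 20], [1.0, 0.5, 0.0], [0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            normalize_profile(prof)

    def test_peak_location_cases(self):
        assert peak_location([0, 10, 20], [0, 1, 0]) == pytest.approx(10.0)
        # monotone decrease: the peak sits at the centre
        assert peak_location([0, 10, 20, 30], [3, 2, 1, 0]) == 0.0
        # exact on quadratic samples
        rho = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
        vertex = 8.0
        vals = -((rho - vertex) ** 2)
        assert peak_location(rho, vals) == pytest.approx(vertex, abs=1e-9)

    def test_peak_location_plateau_warns(self):
        with pytest.warns(UserWarning):
            loc = peak_location([0, 10, 20, 30], [0, 5, 5, 0])
        assert loc == 10.0

    def test_radial_to_map_roundtrip(self):
        rho = np.linspace(0, 100, 101)
        prof = self.make_profile(rho, np.exp(-rho / 20), np.exp(-((rho - 25) ** 2) / 50))
        fmap = radial_to_map(prof, pixel_size=1.0, extent=60.0)
        n = fmap.p_perp.shape[0]
        c = (n - 1) // 2
        # value at a pixel equals the profile at that pixel's radius
        assert fmap.p_perp[c, c + 30] == pytest.approx(np.interp(30, rho, prof.p_perp), rel=1e-6)
        # radial symmetry: invariant under 90-degree rotation
        np.testing.assert_allclose(fmap.t_lat, np.rot90(fmap.t_lat), atol=1e-12)

    def test_radial_to_map_constant_profile(self):
        prof = self.make_profile(np.linspace(0, 200, 21), np.ones(21), np.ones(21))
        fmap = radial_to_map(prof, pixel_size=10.0, extent=100.0)
        np.testing.assert_allclose(fmap.p_perp, 1.0)

    def test_radial_to_map_extent_beyond_profile(self):
        prof = self.make_profile(np.linspace(0, 50, 6), np.ones(6), np.ones(6))
        with pytest.raises(ValueError):
            radial_to_map(prof, pixel_size=1.0, extent=60.0)

    def test_field_map_sampling(self):
        prof = self.make_profile(np.linspace(0, 100, 101),
                                 np.linspace(1, 0, 101), np.linspace(1, 0, 101))
        fmap = radial_to_map(prof, pixel_size=1.0, extent=70.0)
        vals = fmap.sample(np.array([[0.0, 0.0], [50.0, 0.0], [0.0, -50.0], [500.0, 0.0]]), "P_P")
        assert vals[0] == pytest.approx(1.0, abs=1e-6)
        assert vals[1] == pytest.approx(0.5, abs=0.01)
        assert vals[2] == pytest.approx(0.5, abs=0.01)
        assert vals[3] == 0.0  # outside the map
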