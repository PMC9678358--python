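"""Arbor I/O and morphometrics: SWC round-trips, Sholl, distance maps, sampling."""

import numpy as np
import pytest

from nocimech.morphology import (
    Arbor,
    SwcFormatError,
    distance_map,
    read_swc,
    sample_stimulus_positions,
    sholl,
    total_length,
    write_swc,
)
from nocimech.synthetic import ArborGenParams, generate_arbor


class TestSwcIO:
    def test_round_trip_identity(self, tmp_path, cross_arbor):
        path = tmp_path / "cross.swc"
        write_swc(cross_arbor, path)
        back = read_swc(path)
        np.testing.assert_allclose(back.nodes, cross_arbor.nodes, atol=1e-6)
        np.testing.assert_array_equal(back.parents, cross_arbor.parents)

    def test_round_trip_generated(self, tmp_path):
        arbor = generate_arbor(ArborGenParams(target_total_length=2000.0,
                                              territory_radius=80.0), seed=3)
        path = tmp_path / "gen.swc"
        write_swc(arbor, path)
        back = read_swc(path)
        np.testing.assert_allclose(back.nodes, arbor.nodes, atol=1e-6)
        assert total_length(back) == pytest.approx(total_length(arbor), abs=1e-3)

    def test_malformed_parent_rejected(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 1 -1\n2 3 10 0 0 1 99\n")
        with pytest.raises(SwcFormatError):
            read_swc(p)

    def test_multi_root_rejected(self, tmp_path):
        p = tmp_path / "forest.swc"
        p.write_text("1 1 0 0 0 1 -1\n2 1 50 0 0 1 -1\n")
        with pytest.raises(SwcFormatError):
            read_swc(p)

    def test_cycle_rejected(self, tmp_path):
        p = tmp_path / "cycle.swc"
        p.write_text("1 1 0 0 0 1 -1\n2 3 5 0 0 1 3\n3 3 9 0 0 1 2\n")
        with pytest.raises(SwcFormatError):
            read_swc(p)

    def test_3d_input_flattened_with_warning(self, tmp_path):
        p = tmp_path / "three_d.swc"
        p.write_text("1 1 0 0 5 1 -1\n2 3 10 0 5 1 1\n")
        with pytest.warns(UserWarning):
            arbor = read_swc(p)
        assert arbor.nodes.shape == (2, 2)
        assert total_length(arbor) == pytest.approx(10.0)


class TestTotalLength:
    def test_single_segment(self):
        arbor = Arbor(nodes=[[0, 0], [0, 100]], parents=[-1, 0])
        assert total_length(arbor) == pytest.approx(100.0)

    def test_cross(self, cross_arbor):
        assert total_length(cross_arbor) == pytest.approx(1200.0)

    def test_empty_arbor_warns(self):
        arbor = Arbor(nodes=[[0.0, 0.0]], parents=[-1])
        with pytest.warns(UserWarning):
            assert total_length(arbor) == 0.0

    def test_matches_per_edge_sum(self):
        arbor = generate_arbor(ArborGenParams(target_total_length=3000.0,
                                              territory_radius=100.0), seed=5)
        brute = sum(
            float(np.hypot(*(arbor.nodes[i] - arbor.nodes[arbor.parents[i]])))
            for i in range(1, len(arbor.nodes))
        )
        assert total_length(arbor) == pytest.approx(brute, rel=1e-12)


class TestSholl:
    def test_radial_cross_analytic(self, cross_arbor):
        prof = sholl(cross_arbor, ring_spacing=10.0, max_radius=280.0)
        np.testing.assert_array_equal(prof.intersections, 4)
        np.testing.assert_allclose(prof.density, 4 / (2 * np.pi * prof.radii))

    def test_ring_beyond_extent_is_zero(self, cross_arbor):
        prof = sholl(cross_arbor, ring_spacing=100.0, max_radius=500.0)
        assert prof.intersections[-1] == 0

    def test_density_definition_exact(self, cross_arbor):
        prof = sholl(cross_arbor, ring_spacing=25.0)
        np.testing.assert_allclose(
            prof.density * 2 * np.pi * prof.radii, prof.intersections
        )

    def test_tangent_segment_counts_once(self):
        # horizontal chord tangent to the 50 μm ring at (0, 50)
        arbor = Arbor(
            nodes=[[0, 0], [-30, 50], [30, 50]], parents=[-1, 0, 1]
        )
        prof = sholl(arbor, ring_spacing=50.0, max_radius=51.0)
        # ring 50: soma->(-30,50) crosses once, tangent chord touches once
        assert prof.intersections[0] == 2

    def test_invalid_spacing(self, cross_arbor):
        with pytest.raises(ValueError):
            sholl(cross_arbor, ring_spacing=0.0)


class TestDistanceMap:
    def test_single_segment_exact(self):
        arbor = Arbor(nodes=[[0, -50], [0, 50]], parents=[-1, 0])
        dm = distance_map(arbor, pixel_size=5.0, extent=50.0, method="exact")
        x, y = dm.pixel_coords()
        j20 = np.argmin(np.abs(x - 20.0))
        i0 = np.argmin(np.abs(y - 0.0))
        assert dm.values[i0, j20] == pytest.approx(20.0, abs=1e-9)
        j0 = np.argmin(np.abs(x - 0.0))
        assert dm.values[i0, j0] == pytest.approx(0.0, abs=1e-9)

    def test_kdtree_agrees_with_bruteforce(self):
        arbor = generate_arbor(ArborGenParams(target_total_length=2000.0,
                                              territory_radius=80.0), seed=9)
        fast = distance_map(arbor, pixel_size=4.0, extent=90.0, method="kdtree")
        seg = arbor.segments()
        rng = np.random.default_rng(0)
        n = fast.values.shape[0]
        x, y = fast.pixel_coords()
        for _ in range(100):
            i, j = rng.integers(0, n, 2)
            p = np.array([x[j], y[i]])
            brute = min(
                _point_to_segment(p, s[0], s[1]) for s in seg
            )
            assert fast.values[i, j] == pytest.approx(brute, abs=fast.pixel_size / 2)

    def test_invalid_pixel_size(self, cross_arbor):
        with pytest.raises(ValueError):
            distance_map(cross_arbor, pixel_size=0.0)


def _point_to_segment(p, a, b):
    d = b - a
    t = np.clip(np.dot(p - a, d) / np.dot(d, d), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * d)))


class TestStimulusSampling:
    def test_uniform_inside_territory(self, cross_arbor):
        pts = sample_stimulus_positions(cross_arbor, 200, "uniform", seed=1)
        r = np.linalg.norm(pts - cross_arbor.soma, axis=1)
        assert np.all(r <= 220.0 + 1e-9)

    def test_deterministic_under_seed(self, cross_arbor):
        a = sample_stimulus_positions(cross_arbor, 50, "uniform", seed=42)
        b = sample_stimulus_positions(cross_arbor, 50, "uniform", seed=42)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("mode, ring", [("proximal", 100.0), ("distal", 200.0)])
    def test_ring_modes_lie_on_dendrite_near_ring(self, cross_arbor, mode, ring):
        pts = sample_stimulus_positions(cross_arbor, 30, mode, seed=2)
        r = np.linalg.norm(pts - cross_arbor.soma, axis=1)
        assert np.all(np.abs(r - ring) <= 5.0 + 1e-6)
        # on the cross, dendrite points lie on an axis
        assert np.all(np.minimum(np.abs(pts[:, 0]), np.abs(pts[:, 1])) < 1e-6)

    def test_d_off_mode_hits_requested_distance(self):
        # the cut-knockdown variant leaves dendrite-free distal patches
        arbor = generate_arbor(ArborGenParams(class_label="c4da_cti"), seed=0)
        pts = sample_stimulus_positions(arbor, 20, "d_off", seed=3, distance=20.0)
        seg = arbor.segments()
        for p in pts:
            d = min(_point_to_segment(p, s[0], s[1]) for s in seg)
            assert abs(d - 20.0) <= 2.0 + 1e-9

    def test_d_off_unattainable_on_dense_arbor(self):
        # a space-filling wild-type arbor leaves no point 50 μm from a dendrite
        arbor = generate_arbor(ArborGenParams(), seed=0)
        with pytest.raises(ValueError):
            sample_stimulus_positions(arbor, 5, "d_off", seed=0, distance=50.0)

    def test_unknown_mode(self, cross_arbor):
        with pytest.raises(ValueError):
            sample_stimulus_positions(cross_arbor, 5, "sideways", seed=0)
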