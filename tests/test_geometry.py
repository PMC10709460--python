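"""Rim descriptors: closed forms, oracles, invariances; binding classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cdtraj import synthetic
from cdtraj.geometry import (
    best_fit_plane, cavity_volume, cavity_volume_hull, circularity,
    classify_binding, cog_distance, rim_area, rim_geometry_frame, rim_height,
)
from tests.conftest import random_rotation


def regular_polygon(n, radius=1.0, z=0.0):
    a = 2 * np.pi * np.arange(n) / n
    return np.stack([radius * np.cos(a), radius * np.sin(a), np.full(n, z)], axis=1)


class TestBestFitPlane:
    def test_unit_square(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        centroid, normal = best_fit_plane(pts)
        assert np.allclose(centroid, [0.5, 0.5, 0.0])
        assert abs(abs(normal[2]) - 1.0) < 1e-12

    def test_coplanar_residuals_vanish(self):
        rng = np.random.default_rng(0)
        xy = rng.normal(size=(12, 2))
        pts = np.column_stack([xy, 0.3 * xy[:, 0] - 0.7 * xy[:, 1] + 2.0])
        centroid, normal = best_fit_plane(pts)
        assert np.abs((pts - centroid) @ normal).max() < 1e-10

    def test_matches_svd_oracle_on_jittered_heptagon(self):
        rng = np.random.default_rng(1)
        pts = regular_polygon(7) + rng.normal(0, 0.05, size=(7, 3))
        centroid, normal = best_fit_plane(pts)
        c = pts - pts.mean(axis=0)
        # independent oracle: eigenvector of the smallest eigenvalue of C^T C
        w, v = np.linalg.eigh(c.T @ c)
        oracle = v[:, 0]
        assert min(np.linalg.norm(normal - oracle),
                   np.linalg.norm(normal + oracle)) < 1e-10

    def test_collinear_rejected(self):
        pts = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            best_fit_plane(pts)


class TestRimArea:
    def test_unit_square(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        assert rim_area(pts) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n", range(3, 13))
    def test_regular_ngon_closed_form(self, n):
        r = 0.65
        assert rim_area(regular_polygon(n, r)) == pytest.approx(
            n / 2 * r ** 2 * np.sin(2 * np.pi / n), abs=1e-10)

    def test_rotation_invariance(self):
        pts = regular_polygon(7, 0.65)
        c, s = np.cos(np.pi / 6), np.sin(np.pi / 6)
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        assert rim_area(pts @ rot.T) == pytest.approx(rim_area(pts), abs=1e-10)

    def test_self_intersecting_polygon_warns(self):
        # bow-tie: vertices ordered to cross
        pts = np.array([[0, 0, 0], [1, 1, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        with pytest.warns(UserWarning, match="self-intersecting"):
            rim_area(pts)


class TestCircularity:
    @pytest.mark.parametrize("n", range(3, 13))
    def test_cross_ring_is_one_for_regular_ngons(self, n):
        assert circularity(regular_polygon(n)) == pytest.approx(1.0, abs=1e-10)

    def test_literal_heptagon_closed_form(self):
        expected = np.sin(np.pi / 7) / np.sin(3 * np.pi / 7)
        assert circularity(regular_polygon(7), "literal") == pytest.approx(
            expected, abs=1e-12)

    def test_squeezed_heptagon_against_brute_force(self):
        pts = regular_polygon(7)
        pts[:, 0] *= 0.8
        n = 7
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        idx = np.arange(n)
        chords = np.concatenate([dist[idx, (idx + 3) % n], dist[idx, (idx + 4) % n]])
        assert circularity(pts) == pytest.approx(chords.min() / chords.max(), abs=1e-12)
        assert circularity(pts) < 1.0
        iu = np.triu_indices(n, 1)
        assert circularity(pts, "literal") == pytest.approx(
            dist[iu].min() / dist[iu].max(), abs=1e-12)

    def test_literal_never_exceeds_cross_ring(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pts = regular_polygon(7) + rng.normal(0, 0.1, size=(7, 3))
            assert circularity(pts, "literal") <= circularity(pts) + 1e-12

    def test_coincident_points_rejected(self):
        pts = regular_polygon(5)
        pts[1] = pts[0]
        with pytest.raises(ValueError, match="coincident"):
            circularity(pts)


class TestRimHeight:
    def test_parallel_offset_rings(self):
        a = regular_polygon(7, z=0.0)
        b = regular_polygon(7, 0.8, z=0.33)
        assert rim_height(a, b) == pytest.approx(0.33, abs=1e-12)

    def test_identical_rings(self):
        a = regular_polygon(6)
        assert rim_height(a, a) == 0.0

    def test_mass_weighted_centroid_oracle(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        ma, mb = rng.uniform(1, 16, 5), rng.uniform(1, 16, 5)
        want = np.linalg.norm(np.average(a, axis=0, weights=ma)
                              - np.average(b, axis=0, weights=mb))
        assert rim_height(a, b, ma, mb) == pytest.approx(want, abs=1e-12)


class TestCavityVolume:
    def test_cylinder_limit(self):
        assert cavity_volume(1.2, 1.2, 1.2, 0.3, 0.3) == pytest.approx(2 * 1.2 * 0.3)

    def test_cone_limit(self):
        assert cavity_volume(0.0, 0.9, 0.0, 0.0, 0.3) == pytest.approx(0.9 * 0.3 / 3)

    def test_beta_cd_scale_inputs(self):
        """Frustum value for the canonical rim geometry, frozen from the formula."""
        a_phr, a_mid, a_shr, h12, h16 = 1.10, 0.83, 1.32, 0.22, 0.33
        want = (h16 / 3 * (a_phr + a_mid + np.sqrt(a_phr * a_mid))
                + h12 / 3 * (a_shr + a_mid + np.sqrt(a_shr * a_mid)))
        got = cavity_volume(a_phr, a_mid, a_shr, h12, h16)
        assert got == pytest.approx(want, abs=1e-12)
        # sanity bracket: same order as the convex hull of the three rims
        topo, frame = synthetic.make_cd_ring()
        hull = cavity_volume_hull(frame.coordinates[topo.phr_oxygens],
                                  frame.coordinates[topo.mid_oxygens],
                                  frame.coordinates[topo.shr_oxygens])
        assert 0.5 * hull < got < 2.0 * hull

    @given(st.floats(0.5, 2.0), st.floats(0.5, 2.0), st.floats(0.5, 2.0),
           st.floats(0.1, 0.5), st.floats(0.1, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_every_argument(self, a1, a2, a3, h1, h2):
        base = cavity_volume(a1, a2, a3, h1, h2)
        eps = 1e-3
        assert cavity_volume(a1 + eps, a2, a3, h1, h2) > base
        assert cavity_volume(a1, a2 + eps, a3, h1, h2) > base
        assert cavity_volume(a1, a2, a3 + eps, h1, h2) > base
        assert cavity_volume(a1, a2, a3, h1 + eps, h2) > base
        assert cavity_volume(a1, a2, a3, h1, h2 + eps) > base

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            cavity_volume(-1.0, 1.0, 1.0, 0.2, 0.3)


@given(seed=st.integers(0, 500))
@settings(max_examples=25, deadline=None)
def test_area_and_circularity_rigid_motion_invariant(seed):
    rng = np.random.default_rng(seed)
    pts = regular_polygon(7, 0.65) + rng.normal(0, 0.08, size=(7, 3))
    rot = random_rotation(rng)
    moved = pts @ rot.T + rng.normal(0, 2.0, size=3)
    assert rim_area(moved) == pytest.approx(rim_area(pts), abs=1e-10)
    assert circularity(moved) == pytest.approx(circularity(pts), abs=1e-10)
    assert circularity(moved, "literal") == pytest.approx(
        circularity(pts, "literal"), abs=1e-10)


class TestFrameDescriptors:
    def test_h_decomposition_and_collinearity(self):
        topo, frame = synthetic.make_cd_ring()
        row = rim_geometry_frame(frame, topo)
        # coaxial construction: rim centroids are collinear, h = h12 + h16
        assert row["h"] == pytest.approx(row["h12"] + row["h16"], abs=1e-10)
        assert abs(row["h_collinearity_deviation"]) < 1e-10
        assert row["V_C"] > 0


class TestBindingKinetics:
    def test_cog_distance_initial_condition(self):
        topo, traj, truth = synthetic.make_binding_trajectory(
            script=synthetic.BindingScript(insertion_frame=20, seed=0), n_frames=40)
        host = topo.phr_oxygens + topo.mid_oxygens + topo.shr_oxygens
        d = cog_distance(traj, topo.guest_atoms, host)
        # guest starts ~1.5 nm below the cavity midplane (host COG is close to it)
        assert d[0] == pytest.approx(truth["cog_distance"][0], abs=0.15)

    def test_identical_groups_zero(self):
        topo, traj, _ = synthetic.make_binding_trajectory(
            script=synthetic.BindingScript(insertion_frame=2), n_frames=5)
        assert np.allclose(cog_distance(traj, topo.guest_atoms, topo.guest_atoms), 0.0)

    def test_scripted_approach_trend(self):
        topo, traj, truth = synthetic.make_binding_trajectory(
            script=synthetic.BindingScript(insertion_frame=80, noise=0.0, seed=0),
            n_frames=100)
        host = topo.phr_oxygens + topo.mid_oxygens + topo.shr_oxygens
        d = cog_distance(traj, topo.guest_atoms, host)
        assert np.all(np.diff(d[:80]) <= 1e-9)

    @pytest.mark.parametrize("mechanism", ["direct_insert", "surface_then_insert"])
    @pytest.mark.parametrize("orientation", ["O_toward_PHR", "O_toward_SHR"])
    def test_classifier_recovers_script(self, mechanism, orientation):
        topo, traj, truth = synthetic.make_binding_trajectory(
            script=synthetic.BindingScript(mechanism=mechanism,
                                           orientation=orientation,
                                           insertion_frame=60, seed=13),
            n_frames=100)
        state = classify_binding(traj, topo)
        true_first = int(truth.index[truth["state"] == "inserted"][0])
        assert abs(state.first_insertion_frame - true_first) <= 2
        for s, o in zip(state.states, state.orientations):
            if s == "inserted":
                assert o == orientation

    def test_never_bind_all_unbound(self):
        topo, traj, _ = synthetic.make_binding_trajectory(
            script=synthetic.BindingScript(mechanism="never_bind", seed=3),
            n_frames=50)
        state = classify_binding(traj, topo)
        assert all(s == "unbound" for s in state.states)
        assert all(o == "undefined" for o in state.orientations)

    def test_threshold_ordering_enforced(self):
        topo, traj, _ = synthetic.make_binding_trajectory(
            script=synthetic.BindingScript(insertion_frame=2), n_frames=5)
        with pytest.raises(ValueError):
            classify_binding(traj, topo, d_insert=0.9, d_surface=0.8)
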