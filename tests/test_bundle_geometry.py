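"""Geometry: affine transport, density maps, lengths, volume, along-tract means."""

import numpy as np
import pytest

from trtrel import (DensityMap, StreamlineBundle, bundle_volume, density_map,
                    mean_length, mean_scalar_along_tract, streamline_length,
                    transform_streamlines)

from conftest import assert_density_matches_oracle, random_polyline


def translation(t):
    T = np.eye(4)
    T[:3, 3] = t
    return T


class TestStreamlineBundle:
    def test_rejects_short_and_nonfinite_polylines(self):
        with pytest.raises(ValueError):
            StreamlineBundle([np.array([[0.0, 0, 0]])])
        with pytest.raises(ValueError):
            StreamlineBundle([np.array([[0.0, 0, 0], [np.nan, 0, 0]])])

    def test_empty_bundle_allowed(self):
        assert len(StreamlineBundle([])) == 0


class TestTransform:
    def test_identity_and_translation(self, rng):
        b = StreamlineBundle([random_polyline(rng) for _ in range(3)])
        same = transform_streamlines(b, np.eye(4))
        for s0, s1 in zip(b, same):
            np.testing.assert_allclose(s0, s1)
        moved = transform_streamlines(b, translation([10, 0, 0]))
        for s0, s1 in zip(b, moved):
            np.testing.assert_allclose(s1[:, 0], s0[:, 0] + 10)
            np.testing.assert_allclose(s1[:, 1:], s0[:, 1:])

    def test_composition_matches_pointwise(self, rng):
        """Applying A then B equals applying B @ A in one step."""
        b = StreamlineBundle([random_polyline(rng) for _ in range(4)])
        A, B = np.eye(4), np.eye(4)
        A[:3, :3] = rng.normal(size=(3, 3)) + np.eye(3) * 2
        A[:3, 3] = rng.normal(size=3)
        B[:3, :3] = rng.normal(size=(3, 3)) + np.eye(3) * 2
        B[:3, 3] = rng.normal(size=3)
        two_step = transform_streamlines(transform_streamlines(b, A), B)
        one_step = transform_streamlines(b, B @ A)
        for s1, s2 in zip(two_step, one_step):
            np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_inverse_restores_coordinates(self, rng):
        b = StreamlineBundle([random_polyline(rng) for _ in range(3)])
        T = np.eye(4)
        T[:3, :3] = rng.normal(size=(3, 3)) + np.eye(3) * 3
        T[:3, 3] = rng.normal(size=3) * 5
        back = transform_streamlines(transform_streamlines(b, T),
                                     np.linalg.inv(T))
        for s0, s1 in zip(b, back):
            np.testing.assert_allclose(s0, s1, atol=1e-6)

    def test_singular_transform_rejected(self):
        b = StreamlineBundle([np.array([[0.0, 0, 0], [1, 0, 0]])])
        T = np.zeros((4, 4))
        T[3, 3] = 1
        with pytest.raises(ValueError, match="singular"):
            transform_streamlines(b, T)


class TestDensityMap:
    def test_straight_streamline_crosses_five_unit_voxels(self):
        pts = np.column_stack([np.arange(0.1, 5.0, 0.2),
                               np.full(25, 0.5), np.full(25, 0.5)])
        dm = density_map(StreamlineBundle([pts]), (5, 5, 5), np.eye(4))
        assert dm.support_size == 5
        assert dm.data.max() == 1
        np.testing.assert_array_equal(dm.data[:, 0, 0], np.ones(5))

    def test_duplicate_streamline_doubles_weights(self):
        pts = np.column_stack([np.arange(0.1, 5.0, 0.2),
                               np.full(25, 0.5), np.full(25, 0.5)])
        dm = density_map(StreamlineBundle([pts, pts.copy()]), (5, 5, 5),
                         np.eye(4))
        assert dm.support_size == 5
        assert dm.data.max() == 2

    @pytest.mark.parametrize("affine", [
        np.eye(4),
        np.diag([0.8, 1.2, 2.0, 1.0]) + np.array([[0, 0, 0, 1.0],
                                                  [0, 0, 0, 2.0],
                                                  [0, 0, 0, 3.0],
                                                  [0, 0, 0, 0.0]]),
    ], ids=["isotropic", "anisotropic"])
    def test_counts_match_supersampling_oracle(self, rng, affine):
        polys = [random_polyline(rng) for _ in range(3)]
        dm = density_map(StreamlineBundle(polys), (15, 15, 15), affine)
        assert_density_matches_oracle(dm, polys, (15, 15, 15), affine)

    def test_invariant_to_streamline_order_and_reversal(self, rng):
        polys = [random_polyline(rng) for _ in range(4)]
        a = density_map(StreamlineBundle(polys), (15, 15, 15), np.eye(4))
        b = density_map(StreamlineBundle([p[::-1] for p in polys[::-1]]),
                        (15, 15, 15), np.eye(4))
        np.testing.assert_array_equal(a.data, b.data)

    def test_volume_monotone_under_adding_streamlines(self, rng):
        polys = [random_polyline(rng) for _ in range(6)]
        vols = [bundle_volume(density_map(StreamlineBundle(polys[:i]),
                                          (15, 15, 15), np.eye(4)))
                for i in range(1, 7)]
        assert all(b >= a for a, b in zip(vols, vols[1:]))

    def test_empty_bundle_warns_and_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            dm = density_map(StreamlineBundle([]), (5, 5, 5), np.eye(4))
        assert dm.total_weight == 0

    def test_degenerate_grid_rejected(self):
        b = StreamlineBundle([np.array([[0.0, 0, 0], [1, 1, 1]])])
        bad = np.eye(4)
        bad[0, 0] = 0
        with pytest.raises(ValueError, match="degenerate"):
            density_map(b, (5, 5, 5), bad)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            DensityMap(-np.ones((2, 2, 2)), np.eye(4))

    def test_voxel_volume_from_affine(self):
        dm = DensityMap(np.ones((2, 2, 2)), np.diag([0.5, 2.0, 3.0, 1.0]))
        assert dm.voxel_volume == pytest.approx(3.0)


class TestLengths:
    def test_three_four_five_triangle(self):
        assert streamline_length([[0, 0, 0], [3, 4, 0]]) == pytest.approx(5.0)

    def test_collinear_points(self):
        assert streamline_length([[0, 0, 0], [1, 0, 0], [2, 0, 0]]) == 2.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            streamline_length([[0, 0, 0]])

    def test_random_polyline_matches_segment_accumulation(self, rng):
        p = random_polyline(rng, n_points=50)
        expected = sum(float(np.linalg.norm(p[i + 1] - p[i]))
                       for i in range(len(p) - 1))
        assert streamline_length(p) == pytest.approx(expected, abs=1e-12)

    def test_mean_length_of_known_lengths(self):
        b = StreamlineBundle([[[0, 0, 0], [5, 0, 0]], [[0, 0, 0], [7, 0, 0]]])
        assert mean_length(b) == pytest.approx(6.0)

    def test_mean_length_brute_force_over_random_bundle(self, rng):
        polys = [random_polyline(rng, n_points=rng.integers(5, 20))
                 for _ in range(100)]
        expected = np.mean([streamline_length(p) for p in polys])
        assert mean_length(StreamlineBundle(polys)) == pytest.approx(expected)

    def test_mean_length_rigid_invariance(self, rng):
        b = StreamlineBundle([random_polyline(rng) for _ in range(5)])
        theta = 0.7
        R = np.eye(4)
        R[:3, :3] = np.array([[np.cos(theta), -np.sin(theta), 0],
                              [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        R[:3, 3] = [4, -2, 9]
        assert mean_length(transform_streamlines(b, R)) == pytest.approx(
            mean_length(b), abs=1e-9)

    def test_empty_bundle_rejected(self):
        with pytest.raises(ValueError):
            mean_length(StreamlineBundle([]))


class TestVolume:
    @pytest.mark.parametrize("n_voxels,voxel_mm,expected",
                             [(10, 1.0, 10.0), (3, 2.0, 24.0), (0, 1.0, 0.0)])
    def test_volume_counts_support_voxels(self, n_voxels, voxel_mm, expected):
        data = np.zeros((5, 5, 5))
        data.flat[:n_voxels] = 2.0
        dm = DensityMap(data, np.diag([voxel_mm] * 3 + [1.0]))
        assert bundle_volume(dm) == pytest.approx(expected)


class TestMeanScalarAlongTract:
    def _map(self, weights):
        data = np.zeros((4, 4, 4))
        for (i, j, k), w in weights.items():
            data[i, j, k] = w
        return DensityMap(data, np.eye(4))

    def test_constant_scalar_returns_constant(self):
        dm = self._map({(0, 0, 0): 3, (1, 1, 1): 1})
        scalar = np.full((4, 4, 4), 0.42)
        for weighted in (True, False):
            assert mean_scalar_along_tract(scalar, np.eye(4), dm,
                                           weighted=weighted) == pytest.approx(0.42)

    def test_weighted_vs_unweighted_hand_case(self):
        dm = self._map({(0, 0, 0): 3, (1, 1, 1): 1})
        scalar = np.zeros((4, 4, 4))
        scalar[0, 0, 0] = 0.2
        scalar[1, 1, 1] = 0.6
        assert mean_scalar_along_tract(scalar, np.eye(4), dm) == pytest.approx(0.3)
        assert mean_scalar_along_tract(scalar, np.eye(4), dm,
                                       weighted=False) == pytest.approx(0.4)

    def test_equal_weights_make_modes_agree(self, rng):
        dm = self._map({(0, 0, 0): 2, (1, 1, 1): 2, (2, 2, 2): 2})
        scalar = rng.normal(size=(4, 4, 4))
        assert mean_scalar_along_tract(scalar, np.eye(4), dm) == pytest.approx(
            mean_scalar_along_tract(scalar, np.eye(4), dm, weighted=False))

    def test_grid_mismatch_and_empty_support_rejected(self):
        dm = self._map({(0, 0, 0): 1})
        with pytest.raises(ValueError, match="shape"):
            mean_scalar_along_tract(np.zeros((5, 5, 5)), np.eye(4), dm)
        other = np.eye(4)
        other[0, 3] = 1.0
        with pytest.raises(ValueError, match="affine"):
            mean_scalar_along_tract(np.zeros((4, 4, 4)), other, dm)
        empty = DensityMap(np.zeros((4, 4, 4)), np.eye(4))
        with pytest.raises(ValueError, match="support"):
            mean_scalar_along_tract(np.zeros((4, 4, 4)), np.eye(4), empty)
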