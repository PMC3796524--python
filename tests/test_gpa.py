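"""Superimposition: centroid size, rotational alignment, GPA, tangent projection."""

import numpy as np
import pytest

from murimorph.geometry_io import LandmarkConfiguration
from murimorph.gpa import (
    centroid_size,
    center_and_scale,
    full_procrustes_distance,
    gpa,
    orthogonal_align,
    procrustes_correlation,
)
from conftest import make_noisy_dataset

SQUARE = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestCentroidSize:
    def test_square_analytic(self):
        assert np.isclose(centroid_size(SQUARE), np.sqrt(8.0))

    def test_unit_after_normalization(self, template):
        assert np.isclose(centroid_size(center_and_scale(template * 3.7 + 5)), 1.0)

    def test_homogeneous_and_rigid_invariant(self, template):
        cs = centroid_size(template)
        assert np.isclose(centroid_size(template * 3), 3 * cs)
        assert np.isclose(centroid_size(template @ _rot(0.7).T + [2, -1]), cs)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            centroid_size(np.zeros((4, 2)))


class TestOrthogonalAlign:
    def test_recovers_rotation(self, template):
        moving = center_and_scale(template)
        target = moving @ _rot(np.pi / 6).T
        rot, aligned = orthogonal_align(moving, target)
        assert np.allclose(aligned, target, atol=1e-12)
        assert np.isclose(np.linalg.det(rot), 1.0)
        assert np.isclose(np.arctan2(rot[1, 0], rot[0, 0]), -np.pi / 6) or np.isclose(
            np.arctan2(rot[0, 1], rot[0, 0]), -np.pi / 6
        )

    def test_identity_for_same_target(self, template):
        moving = center_and_scale(template)
        rot, aligned = orthogonal_align(moving, moving)
        assert np.allclose(rot, np.eye(2), atol=1e-10)

    def test_reflection_disallowed(self, template):
        moving = center_and_scale(template)
        mirrored = moving * [-1, 1]
        _, aligned = orthogonal_align(moving, mirrored)
        # an asymmetric shape cannot reach its mirror image by proper rotation
        assert np.sum((aligned - mirrored) ** 2) > 1e-4

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            orthogonal_align(SQUARE, SQUARE[:3])


class TestGPA:
    def test_copies_of_one_shape_collapse(self, template):
        rng = np.random.default_rng(3)
        configs = [
            template @ _rot(rng.uniform(-0.7, 0.7)).T * rng.uniform(0.5, 2) + rng.normal(size=2)
            for _ in range(6)
        ]
        res = gpa(configs)
        assert res.converged
        assert np.all(res.procrustes_distances < 1e-8)

    def test_two_shapes_equidistant_from_consensus(self, template):
        other = template + 0.05 * np.outer(np.linspace(-1, 1, 16), [1, 0])
        res = gpa([template, other])
        assert np.isclose(res.procrustes_distances[0], res.procrustes_distances[1], rtol=1e-6)

    def test_invariance_under_input_pose(self, moderate_dataset):
        res1 = gpa(moderate_dataset)
        perturbed = list(moderate_dataset)
        pts = perturbed[3].points @ _rot(0.9).T * 4.2 + [10.0, -3.0]
        perturbed[3] = perturbed[3].copy_with(points=pts)
        res2 = gpa(perturbed)
        assert np.allclose(res1.tangent_coords, res2.tangent_coords, atol=1e-8)

    def test_unit_sizes_and_centered_tangent(self, moderate_dataset):
        res = gpa(moderate_dataset)
        for cfg in res.aligned:
            assert np.isclose(centroid_size(cfg), 1.0, atol=1e-10)
        assert np.isclose(np.linalg.norm(res.mean_shape), 1.0, atol=1e-10)
        assert np.allclose(res.mean_shape.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(res.tangent_coords.sum(axis=0), 0, atol=1e-8)

    def test_pairwise_distances_match_direct_superimposition(self, small_noise_dataset):
        """Tangent-space distances reproduce brute-force pairwise Procrustes fits."""
        res = gpa(small_noise_dataset)
        t = res.tangent_coords
        n = len(small_noise_dataset)
        for i in range(n):
            for j in range(i + 1, n):
                direct = full_procrustes_distance(
                    small_noise_dataset[i].points, small_noise_dataset[j].points
                )
                assert abs(np.linalg.norm(t[i] - t[j]) - direct) < 1e-6

    def test_axis_orientation_convention(self, moderate_dataset, scheme):
        res = gpa(moderate_dataset, scheme=scheme)
        a, b = scheme.axis0
        chord = res.mean_shape[b] - res.mean_shape[a]
        assert abs(np.arctan2(chord[1], chord[0])) < 1e-10

    def test_tangent_contracts_chordal_distances(self, moderate_dataset):
        res = gpa(moderate_dataset)
        z = res.aligned.reshape(len(moderate_dataset), -1)
        for i in (0, 5):
            for j in (10, 20):
                chord = np.linalg.norm(z[i] - z[j])
                tang = np.linalg.norm(res.tangent_coords[i] - res.tangent_coords[j])
                assert tang <= chord + 1e-12


class TestProcrustesCorrelation:
    def test_rotated_copy_gives_r_one(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(30, 4))
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        r, p = procrustes_correlation(a, a @ q, n_perm=99, seed=1)
        assert r > 1 - 1e-10
        assert p == pytest.approx(1 / 100)

    def test_independent_matrices_low_r(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(200, 5))
        b = rng.normal(size=(200, 5))
        r, p = procrustes_correlation(a, b, n_perm=199, seed=2)
        assert r < 0.35
        assert p > 0.01

    def test_permutation_floor(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=(25, 3))
        r, p = procrustes_correlation(a, a * 2.0, n_perm=9999, seed=3)
        assert p == pytest.approx(1e-4)

    def test_rejects_bad_nperm(self):
        a = np.zeros((4, 2))
        with pytest.raises(ValueError):
            procrustes_correlation(a, a, n_perm=0)
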