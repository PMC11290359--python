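"""Scaled Procrustes fitting against constructed and brute-force oracles."""

import numpy as np
import pytest

from compound_embed import (
    CentroidMatrix,
    DegenerateFitError,
    MissingTypeError,
    apply_transform,
    compute_type_centers,
    fit_procrustes,
)
from compound_embed.procrustes import identity_transform


def planar_rotation(P, theta):
    R = np.eye(P)
    R[0, 0] = R[1, 1] = np.cos(theta)
    R[0, 1], R[1, 0] = -np.sin(theta), np.sin(theta)
    return R


def random_orthogonal(P, rng):
    Q, _ = np.linalg.qr(rng.normal(size=(P, P)))
    return Q


class TestComputeTypeCenters:
    def test_single_cell_types_return_the_cells(self):
        coords = np.array([[1.0, 2.0], [3.0, 4.0]])
        cm = compute_type_centers(coords, np.array([0, 1]), [0, 1])
        np.testing.assert_array_equal(cm.centers, coords)

    def test_symmetric_pair_centers_at_origin(self):
        cm = compute_type_centers(np.array([[1.0, 1.0], [-1.0, -1.0]]),
                                  np.array([0, 0]), [0])
        np.testing.assert_allclose(cm.centers, [[0.0, 0.0]])

    def test_matches_brute_force_group_means(self, rng):
        X = rng.normal(size=(200, 6))
        labels = rng.integers(0, 5, size=200)
        cm = compute_type_centers(X, labels, [0, 1, 2, 3, 4])
        for i in range(5):
            np.testing.assert_allclose(cm.centers[i],
                                       X[labels == i].mean(axis=0))

    def test_empty_type_raises(self):
        with pytest.raises(MissingTypeError):
            compute_type_centers(np.zeros((2, 2)), np.array([0, 0]), [1])

    def test_missing_code_rejected(self):
        with pytest.raises(MissingTypeError):
            compute_type_centers(np.zeros((2, 2)), np.array([-1, -1]), [-1])


class TestFitProcrustes:
    def test_identity_on_self(self, rng):
        cm = CentroidMatrix([0, 1, 2], rng.normal(size=(3, 4)))
        t = fit_procrustes(cm, cm)
        assert t.sse < 1e-20
        np.testing.assert_allclose(t.rotation @ t.rotation.T, np.eye(4),
                                   atol=1e-10)
        np.testing.assert_allclose(t.net_scale, 1.0, atol=1e-12)

    def test_recovers_known_planar_rotation(self, rng):
        ref = CentroidMatrix([0, 1, 2, 3], rng.normal(size=(4, 5)))
        R = planar_rotation(5, np.pi / 2)
        sample = CentroidMatrix([0, 1, 2, 3], ref.centers @ R.T)
        t = fit_procrustes(ref, sample)
        assert t.sse < 1e-10
        back = apply_transform(t, sample.centers)
        np.testing.assert_allclose(back, ref.centers, atol=1e-8)

    def test_p2_matches_dense_angle_grid(self, rng):
        """Closed-form rotation beats/equals a dense grid over angles."""
        ref = CentroidMatrix([0, 1, 2], rng.normal(size=(3, 2)))
        theta = 1.234
        sample = CentroidMatrix([0, 1, 2],
                                ref.centers @ planar_rotation(2, theta).T * 2.0
                                + np.array([3.0, -1.0]))
        t = fit_procrustes(ref, sample, allow_reflection=False)
        best = grid_search_sse(ref.centers, sample.centers)
        assert t.sse <= best + 1e-6


def grid_search_sse(B, A, n_angles=200001):
    """Best SSE over a dense grid of planar rotations (P=2), with the
    per-angle optimal scale in closed form.  Independent oracle."""
    mu_a, mu_b = A.mean(0), B.mean(0)
    Ac, Bc = A - mu_a, B - mu_b
    na2 = np.sum(Ac**2)
    angles = np.linspace(-np.pi, np.pi, n_angles)
    c, s = np.cos(angles), np.sin(angles)
    # rotated Ac for all angles: (n_angles, K, 2)
    x = Ac[:, 0][None, :] * c[:, None] - Ac[:, 1][None, :] * s[:, None]
    y = Ac[:, 0][None, :] * s[:, None] + Ac[:, 1][None, :] * c[:, None]
    dot = x @ Bc[:, 0] + y @ Bc[:, 1]
    scale = dot / na2
    sse = (scale**2) * na2 - 2 * scale * dot + np.sum(Bc**2)
    return float(sse.min())

    def test_double_scale_gives_half_net_scale(self, rng):
        ref = CentroidMatrix([0, 1, 2], rng.normal(size=(3, 4)))
        sample = CentroidMatrix([0, 1, 2], ref.centers * 2.0)
        t = fit_procrustes(ref, sample)
        assert t.sse < 1e-10
        np.testing.assert_allclose(t.net_scale, 0.5, atol=1e-10)

    def test_beats_random_orthogonal_candidates(self, rng):
        """Optimality: fitted SSE is below every random orthogonal try."""
        for _ in range(5):
            K, P = int(rng.integers(3, 9)), int(rng.integers(2, 11))
            ref = CentroidMatrix(list(range(K)), rng.normal(size=(K, P)))
            smp = CentroidMatrix(list(range(K)), rng.normal(size=(K, P)))
            t = fit_procrustes(ref, smp)
            A, B = smp.centers, ref.centers
            Ac, Bc = A - A.mean(0), B - B.mean(0)
            na = np.linalg.norm(Ac)
            for _ in range(200):
                R = random_orthogonal(P, rng)
                s = max(np.sum((Ac @ R) * Bc) / na**2, 1e-12)
                sse = np.sum((Ac @ R * s - Bc) ** 2)
                assert t.sse <= sse + 1e-9

    def test_k1_degenerate(self):
        cm = CentroidMatrix([0], np.array([[1.0, 2.0]]))
        with pytest.raises(DegenerateFitError):
            fit_procrustes(cm, cm)

    def test_mismatched_type_lists_rejected(self, rng):
        a = CentroidMatrix([0, 1], rng.normal(size=(2, 3)))
        b = CentroidMatrix([0, 2], rng.normal(size=(2, 3)))
        with pytest.raises(DegenerateFitError):
            fit_procrustes(a, b)

    def test_no_reflection_flag_forces_det_plus_one(self, rng):
        ref = CentroidMatrix([0, 1, 2, 3], rng.normal(size=(4, 3)))
        F = np.diag([-1.0, 1.0, 1.0])  # reflected copy
        sample = CentroidMatrix([0, 1, 2, 3], ref.centers @ F)
        t_free = fit_procrustes(ref, sample, allow_reflection=True)
        t_rot = fit_procrustes(ref, sample, allow_reflection=False)
        assert t_free.sse < 1e-10
        assert np.linalg.det(t_rot.rotation) > 0
        assert t_rot.sse >= t_free.sse


class TestApplyTransform:
    def test_identity_returns_input(self, rng):
        X = rng.normal(size=(10, 3))
        np.testing.assert_array_equal(apply_transform(identity_transform(3), X), X)

    def test_rigid_case_recovers_original_cloud(self, rng):
        X = rng.normal(size=(50, 4))
        labels = rng.integers(0, 4, size=50)
        R = random_orthogonal(4, rng)
        Xr = X @ R.T * 1.7 + rng.normal(size=4)
        types = [0, 1, 2, 3]
        t = fit_procrustes(compute_type_centers(X, labels, types),
                           compute_type_centers(Xr, labels, types))
        np.testing.assert_allclose(apply_transform(t, Xr), X, atol=1e-8)

    def test_centroid_commutes_with_transform(self, rng):
        X = rng.normal(size=(30, 3))
        labels = rng.integers(0, 3, size=30)
        ref = compute_type_centers(rng.normal(size=(30, 3)),
                                   labels, [0, 1, 2])
        t = fit_procrustes(ref, compute_type_centers(X, labels, [0, 1, 2]))
        lhs = compute_type_centers(apply_transform(t, X), labels,
                                   [0, 1, 2]).centers
        rhs = apply_transform(t, compute_type_centers(X, labels,
                                                      [0, 1, 2]).centers)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_unit_scale_preserves_pairwise_distances(self, rng):
        from scipy.spatial.distance import pdist

        X = rng.normal(size=(20, 3))
        R = random_orthogonal(3, rng)
        t = identity_transform(3)
        t.rotation = R
        Y = apply_transform(t, X)
        np.testing.assert_allclose(pdist(Y), pdist(X), atol=1e-8)

    def test_refit_after_apply_is_identity(self, rng):
        labels = np.repeat(np.arange(4), 10)
        X = rng.normal(size=(40, 3))
        ref = compute_type_centers(rng.normal(size=(40, 3)) + 2.0,
                                   labels, [0, 1, 2, 3])
        t = fit_procrustes(ref, compute_type_centers(X, labels, [0, 1, 2, 3]))
        X2 = apply_transform(t, X)
        t2 = fit_procrustes(ref, compute_type_centers(X2, labels,
                                                      [0, 1, 2, 3]))
        np.testing.assert_allclose(t2.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(t2.net_scale, 1.0, atol=1e-6)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="P="):
            apply_transform(identity_transform(3), rng.normal(size=(5, 4)))
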