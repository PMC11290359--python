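"""Embedding initialization, force mechanics, and reference chaining."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from compound_embed import (
    AlignmentImpossibleError,
    EmbedConfig,
    ReferenceCenters,
    build_complete_reference,
    compute_type_centers,
    embed_plain,
    embed_reference,
    embed_with_forces,
    force_step,
    initialize_embedding,
)

from conftest import blob_sample, make_sample


def centers_of(codes_to_xy):
    rc = ReferenceCenters()
    for code, xy in codes_to_xy.items():
        rc.add(code, np.asarray(xy, float), "ref")
    return rc


class TestInitializeEmbedding:
    def test_matches_closed_form_rescaling(self, rng):
        X = rng.normal(size=(80, 6)) * 3.0
        cfg = EmbedConfig(init_std=1e-4)
        Y = initialize_embedding(X, cfg)
        expected = X[:, :2] * (1e-4 / X[:, 0].std())
        np.testing.assert_allclose(Y, expected, rtol=1e-12)
        assert Y[:, 0].std() == pytest.approx(1e-4, rel=1e-9)

    def test_input_already_at_target_std_unchanged(self, rng):
        X = rng.normal(size=(50, 2))
        X[:, 0] *= 1e-4 / X[:, 0].std()
        Y = initialize_embedding(X, EmbedConfig(init_std=1e-4))
        np.testing.assert_allclose(Y, X, rtol=1e-9)

    def test_scale_invariant(self, rng):
        X = rng.normal(size=(40, 5))
        cfg = EmbedConfig()
        np.testing.assert_allclose(initialize_embedding(X, cfg),
                                   initialize_embedding(2.0 * X, cfg),
                                   rtol=1e-12)

    def test_zero_variance_falls_back_to_gaussian(self):
        X = np.ones((30, 3))
        cfg = EmbedConfig(seed=5)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            Y = initialize_embedding(X, cfg)
        assert Y.shape == (30, 2)
        assert Y.std() > 0


class TestForceStep:
    def test_lambda_one_single_step_lands_on_center(self, rng):
        """With the t-SNE step disabled, lambda=1 moves a type's center
        exactly onto the reference center in one step."""
        Y = rng.normal(size=(40, 2))
        labels = np.zeros(40, dtype=int)
        target = np.array([5.0, -3.0])
        Y2 = force_step(Y, labels, centers_of({0: target}), lam=1.0)
        np.testing.assert_allclose(Y2[labels == 0].mean(axis=0), target,
                                   atol=1e-12)

    def test_pure_translation_within_type(self, rng):
        Y = rng.normal(size=(60, 2))
        labels = rng.integers(0, 3, size=60)
        Y2 = force_step(Y, labels, centers_of({0: [1, 1], 1: [-2, 0],
                                               2: [0, 3]}), lam=0.3)
        for t in range(3):
            m = labels == t
            np.testing.assert_allclose(pdist(Y2[m]), pdist(Y[m]), rtol=1e-12)

    @pytest.mark.parametrize("lam", [0.1, 0.5, 1.0])
    def test_geometric_decay_of_center_distance(self, rng, lam):
        """j frozen force steps shrink sum d_i by exactly (1-lam)^(2j)."""
        Y = rng.normal(size=(50, 2))
        labels = rng.integers(0, 2, size=50)
        centers = centers_of({0: [4.0, 0.0], 1: [0.0, -4.0]})

        def sum_d(Yc):
            return sum(
                float(((centers.centers[t] - Yc[labels == t].mean(0)) ** 2)
                      .sum()) for t in (0, 1))

        d0 = sum_d(Y)
        Yj = Y
        for j in range(1, 6):
            Yj = force_step(Yj, labels, centers, lam)
            assert sum_d(Yj) == pytest.approx((1 - lam) ** (2 * j) * d0,
                                              rel=1e-9, abs=1e-24)

    def test_types_without_reference_center_untouched(self, rng):
        Y = rng.normal(size=(30, 2))
        labels = np.array([0] * 15 + [1] * 15)
        Y2 = force_step(Y, labels, centers_of({0: [1.0, 1.0]}), lam=0.5)
        np.testing.assert_array_equal(Y2[15:], Y[15:])

    def test_missing_code_cells_receive_no_force(self, rng):
        Y = rng.normal(size=(20, 2))
        labels = np.array([0] * 10 + [-1] * 10)
        Y2 = force_step(Y, labels, centers_of({0: [2.0, 2.0]}), lam=1.0)
        np.testing.assert_array_equal(Y2[10:], Y[10:])


MEANS = np.array([[0.0, 0.0, 0.0, 0.0], [8.0, 0.0, 0.0, 0.0],
                  [0.0, 8.0, 0.0, 0.0]])


class TestEmbedReference:
    def test_same_seed_is_bit_reproducible(self, rng, quick_config):
        s = blob_sample("r", MEANS[:2], 40, 0.5, rng)
        a, ca = embed_reference(s, quick_config)
        b, cb = embed_reference(s, quick_config)
        assert (a.coords == b.coords).all()
        for t in ca.centers:
            assert (ca.centers[t] == cb.centers[t]).all()

    def test_separated_blobs_stay_separated(self, rng, quick_config):
        s = blob_sample("r", MEANS[:2], 50, 0.3, rng)
        res, centers = embed_reference(s, quick_config)
        y0, y1 = res.coords[s.labels == 0], res.coords[s.labels == 1]
        gap = np.linalg.norm(y0.mean(0) - y1.mean(0))
        spread = max(y0.std(), y1.std())
        assert gap > 3 * spread
        # each center lies inside its own cluster's bounding box
        for t, y in ((0, y0), (1, y1)):
            c = centers.centers[t]
            assert (y.min(0) <= c).all() and (c <= y.max(0)).all()

    def test_minimal_n_runs(self, rng):
        cfg = EmbedConfig(perplexity=5, n_iter_early=10, n_iter_main=10)
        s = blob_sample("r", MEANS[:1], 6, 0.5, rng)  # n = perplexity + 1
        res, _ = embed_reference(s, cfg)
        assert res.coords.shape == (6, 2)

    def test_perplexity_at_least_n_rejected(self, rng):
        s = blob_sample("r", MEANS[:1], 10, 0.5, rng)
        with pytest.raises(ValueError, match="perplexity"):
            embed_reference(s, EmbedConfig(perplexity=10))

    def test_unlabeled_rejected(self, rng, quick_config):
        s = blob_sample("r", MEANS[:2], 20, 0.5, rng, labels=False)
        with pytest.raises(ValueError, match="labeled"):
            embed_reference(s, quick_config)


class TestEmbedWithForces:
    def test_lambda_zero_equals_plain_run(self, rng, quick_config):
        s = blob_sample("s", MEANS, 30, 0.5, rng)
        centers = centers_of({0: [0, 0], 1: [10, 0], 2: [0, 10]})
        cfg = EmbedConfig(perplexity=15, n_iter_early=50, n_iter_main=100,
                          lam=0.0)
        forced, state = embed_with_forces(s, centers, cfg)
        plain = embed_plain(s, cfg)
        assert (forced.coords == plain.coords).all()

    def test_force_reduces_center_distance(self, rng):
        s = blob_sample("s", MEANS, 40, 0.5, rng)
        centers = centers_of({0: [-20, 0], 1: [20, 0], 2: [0, 20]})
        cfg = EmbedConfig(perplexity=15, n_iter_early=50, n_iter_main=150,
                          lam=0.5)
        _, state = embed_with_forces(s, centers, cfg)
        assert state.sum_d_history[-1] < state.sum_d_history[0]
        assert state.K == 3
        assert (state.d >= 0).all()
        assert state.sum_d == pytest.approx(state.d.sum())

    def test_no_shared_types_impossible(self, rng, quick_config):
        s = blob_sample("s", MEANS[:2], 20, 0.5, rng)
        with pytest.raises(AlignmentImpossibleError):
            embed_with_forces(s, centers_of({7: [0, 0]}), quick_config)

    def test_unmatched_types_warn(self, rng):
        s = blob_sample("s", MEANS, 25, 0.5, rng)
        cfg = EmbedConfig(perplexity=10, n_iter_early=20, n_iter_main=30)
        with pytest.warns(RuntimeWarning, match="no reference center"):
            embed_with_forces(s, centers_of({0: [0, 0], 1: [5, 5]}), cfg)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            EmbedConfig(lam=-0.1)


class TestBuildCompleteReference:
    def test_no_secondaries_returns_primary_centers(self, rng, quick_config):
        s = blob_sample("p", MEANS, 30, 0.5, rng)
        res, _ = embed_reference(s, quick_config)
        centers, embs, states = build_complete_reference(
            res, s.labels, [], quick_config)
        assert centers.codes() == [0, 1, 2]
        assert embs == {} and states == {}
        for t in (0, 1, 2):
            expect = res.coords[s.labels == t].mean(axis=0)
            np.testing.assert_allclose(centers.centers[t], expect)
            assert centers.source[t] == "p"

    def test_secondary_contributes_only_new_types(self, rng):
        cfg = EmbedConfig(perplexity=10, n_iter_early=30, n_iter_main=60)
        primary = blob_sample("p", MEANS[:2], 25, 0.5, rng)
        secondary = blob_sample("s", MEANS[1:], 25, 0.5, rng)
        secondary = secondary.with_labels(secondary.labels + 1)  # types 1,2
        p_res, _ = embed_reference(primary, cfg)
        centers, embs, _ = build_complete_reference(
            p_res, primary.labels, [secondary], cfg)
        assert centers.codes() == [0, 1, 2]
        assert centers.source[0] == "p"
        assert centers.source[1] == "p"  # shared type keeps primary center
        assert centers.source[2] == "s"
        assert "s" in embs and embs["s"].provenance == "force"
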