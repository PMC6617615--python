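"""Forward-pass operators: convolution, pooling, gather, heads, loss."""

import numpy as np
import pytest

from mgcnn.gcnn_core import (
    ClassifierHead,
    ConvStageWeights,
    DimensionError,
    PredictionVector,
    classify,
    convolve,
    cross_entropy_loss,
    forward,
    gather,
    init_model,
    max_pool,
    ModelArchitecture,
)
from mgcnn.molgraph import AtomAlphabet, AtomFeatureMatrix, MolecularGraph, one_hot_encode


def _feat(values, layer=0):
    return AtomFeatureMatrix(np.asarray(values, dtype=float), layer_index=layer)


class TestConvolve:
    def test_isolated_atom_identity_map(self):
        g = MolecularGraph("x", ("C",))
        w = ConvStageWeights(np.eye(2), np.eye(2), np.zeros(2))
        out = convolve(_feat([[1.0, 0.0]]), g, w)
        assert out.values.tolist() == [[1.0, 0.0]]
        assert out.layer_index == 1

    def test_two_bonded_atoms_self_plus_neighbor(self):
        g = MolecularGraph.from_edge_pairs("x", ("C", "C"), [(0, 1)])
        w = ConvStageWeights(np.array([[1.0]]), np.array([[1.0]]), np.zeros(1))
        out = convolve(_feat([[1.0], [2.0]]), g, w)
        assert out.values.tolist() == [[3.0], [3.0]]

    def test_relu_clamps_negative_map(self):
        g = MolecularGraph.from_edge_pairs("x", ("C", "O"), [(0, 1)])
        w = ConvStageWeights(-np.eye(2), -np.eye(2), np.zeros(2))
        out = convolve(_feat([[1.0, 0.5], [0.2, 0.0]]), g, w)
        assert (out.values == 0.0).all()

    def test_matches_double_loop_oracle(self, oracles):
        rng = np.random.default_rng(17)
        for _ in range(20):
            g = oracles["random_graph"](rng, int(rng.integers(2, 9)))
            f = rng.normal(size=(g.n_atoms, 3))
            w = ConvStageWeights(
                rng.normal(size=(4, 3)), rng.normal(size=(4, 3)), rng.normal(size=4)
            )
            fast = convolve(_feat(f), g, w).values
            slow = oracles["convolve"](f, g, w)
            np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_shape_mismatch_raises(self):
        g = MolecularGraph("x", ("C",))
        w = ConvStageWeights(np.eye(2), np.eye(2))
        with pytest.raises(DimensionError):
            convolve(_feat([[1.0, 0.0], [0.0, 1.0]]), g, w)


class TestMaxPool:
    def test_path_takes_neighborhood_maxima(self):
        g = MolecularGraph.from_edge_pairs("x", ("C", "C", "C"), [(0, 1), (1, 2)])
        out = max_pool(_feat([[1.0], [5.0], [2.0]], layer=1), g)
        assert out.values.tolist() == [[5.0], [5.0], [5.0]]

    def test_idempotent_on_constant_features(self, oracles):
        rng = np.random.default_rng(3)
        g = oracles["random_graph"](rng, 8)
        f = _feat(np.full((8, 4), 2.5), layer=1)
        assert (max_pool(f, g).values == 2.5).all()

    def test_isolated_atom_unchanged(self):
        g = MolecularGraph("x", ("C",))
        assert max_pool(_feat([[3.0, -1.0]]), g).values.tolist() == [[3.0, -1.0]]


class TestGather:
    def test_column_sums(self):
        assert gather(_feat([[1.0, 2.0], [3.0, 4.0]])).tolist() == [4.0, 6.0]

    def test_single_row_is_identity(self):
        assert gather(_feat([[7.0, 1.0]])).tolist() == [7.0, 1.0]

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(6, 3))
        np.testing.assert_allclose(gather(_feat(f)), gather(_feat(f[::-1])))


class TestClassify:
    def test_equal_logits_give_half(self):
        head = ClassifierHead(np.zeros((4, 3)))
        pred = classify(np.ones(3), head, ["a", "b"])
        np.testing.assert_allclose(pred.probabilities, 0.5)

    def test_large_negative_margin_saturates(self):
        head = ClassifierHead(np.array([[0.0], [50.0]]))  # N logit dominates
        pred = classify(np.array([1.0]), head, ["a"])
        assert pred.probabilities[0, 1] == pytest.approx(1.0, abs=1e-15)

    def test_pairs_sum_to_one(self):
        rng = np.random.default_rng(8)
        head = ClassifierHead(rng.normal(size=(10, 4)), rng.normal(size=10))
        pred = classify(rng.normal(size=4), head, list("abcde"))
        np.testing.assert_allclose(pred.probabilities.sum(axis=1), 1.0, atol=1e-12)

    def test_calls_use_strict_threshold(self):
        pv = PredictionVector(["a"], np.array([[0.5, 0.5]]))
        assert pv.calls().tolist() == [0]


class TestLoss:
    def test_uniform_prediction_closed_form(self):
        k = 15
        pred = PredictionVector([f"c{i}" for i in range(k)], np.full((k, 2), 0.5))
        label = np.zeros(k, dtype=int)
        assert cross_entropy_loss(pred, label) == pytest.approx(k * np.log(2), abs=1e-9)

    def test_confident_correct_prediction_near_zero(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        pred = PredictionVector(["a", "b"], probs)
        assert cross_entropy_loss(pred, np.array([1, 0])) < 1e-6

    def test_matches_scalar_loop_oracle(self, oracles):
        rng = np.random.default_rng(21)
        for _ in range(20):
            k = int(rng.integers(1, 8))
            p = rng.dirichlet((1.0, 1.0), size=k)
            pred = PredictionVector([f"c{i}" for i in range(k)], p)
            label = rng.integers(0, 2, size=k)
            assert cross_entropy_loss(pred, label) == pytest.approx(
                oracles["loss"](p, label), abs=1e-12
            )

    def test_loss_nonnegative(self, oracles):
        rng = np.random.default_rng(2)
        for _ in range(30):
            k = int(rng.integers(1, 6))
            p = rng.dirichlet((1.0, 1.0), size=k)
            pred = PredictionVector([f"c{i}" for i in range(k)], p)
            assert cross_entropy_loss(pred, rng.integers(0, 2, size=k)) >= 0.0

    def test_category_count_mismatch(self):
        pred = PredictionVector(["a"], np.array([[0.5, 0.5]]))
        with pytest.raises(DimensionError):
            cross_entropy_loss(pred, np.array([1, 0]))


class TestForward:
    def test_permutation_invariance(self, small_model, oracles):
        rng = np.random.default_rng(33)
        for _ in range(10):
            g = oracles["random_graph"](rng, int(rng.integers(2, 12)))
            base = forward(g, small_model).probabilities
            perm = rng.permutation(g.n_atoms)
            gp = oracles["permute_graph"](g, perm)
            np.testing.assert_allclose(
                forward(gp, small_model).probabilities, base, atol=1e-9
            )

    def test_untrained_model_gives_finite_prob_pairs(self, small_model, oracles):
        rng = np.random.default_rng(44)
        g = oracles["random_graph"](rng, 10)
        pred = forward(g, small_model)
        assert np.isfinite(pred.probabilities).all()
        np.testing.assert_allclose(pred.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_post_relu_features_nonnegative(self, small_model, oracles):
        rng = np.random.default_rng(55)
        g = oracles["random_graph"](rng, 9)
        f = one_hot_encode(g, small_model.architecture.alphabet)
        for stage in small_model.stages:
            f = max_pool(convolve(f, g, stage), g)
            assert f.layer_index >= 1
            assert (f.values >= 0.0).all()

    def test_locality_radius_two_per_stage(self):
        """A stage (conv + pool) has receptive radius 2: perturbing an atom
        beyond distance 2s cannot change atom 0's features after s stages."""
        n = 9  # path 0-1-...-8
        atoms_a = tuple("C" * n)
        atoms_b = ("C",) * (n - 1) + ("N",)  # perturb the far end (distance 8)
        edges = [(i, i + 1) for i in range(n - 1)]
        alpha = AtomAlphabet(("C", "N"))
        arch = ModelArchitecture(alpha, ["a"], n_stages=2, stage_dims=[4, 4])
        model = init_model(arch, seed=2)

        def stage_features(atoms, n_stages):
            g = MolecularGraph.from_edge_pairs("x", atoms, edges)
            f = one_hot_encode(g, alpha)
            for stage in model.stages[:n_stages]:
                f = max_pool(convolve(f, g, stage), g)
            return f.values

        for s in (1, 2):  # radius 2s = 2 or 4, both < 8
            fa = stage_features(atoms_a, s)
            fb = stage_features(atoms_b, s)
            np.testing.assert_allclose(fa[0], fb[0], atol=0)
        # and the perturbation does propagate to atoms within range
        assert not np.allclose(stage_features(atoms_a, 1)[7], stage_features(atoms_b, 1)[7])
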