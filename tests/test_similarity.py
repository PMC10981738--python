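import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plmhomology import (
    BilinearModel,
    TrainConfig,
    cos_similarity,
    euclidean_similarity,
    predict_tm,
    predict_tm_matrix,
    ss_predictor_similarity,
    ss_predictor_similarity_matrix,
    train_bilinear,
)
from plmhomology.records import LabeledPair
from plmhomology.similarity import predict_tm_raw


class TestEuclidean:
    def test_identical_vectors_score_one(self):
        p = np.array([1.0, 2.0, 3.0])
        assert euclidean_similarity(p, p) == 1.0

    def test_hand_value_three_four_five(self):
        assert euclidean_similarity(np.zeros(2), np.array([3.0, 4.0])) == pytest.approx(
            1.0 / 6.0
        )

    def test_symmetry_and_dimension_mismatch(self):
        p, q = np.array([1.0, 0.0]), np.array([0.0, 2.0])
        assert euclidean_similarity(p, q) == euclidean_similarity(q, p)
        with pytest.raises(ValueError, match="dimension mismatch"):
            euclidean_similarity(p, np.zeros(3))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 500))
    def test_strictly_decreasing_in_distance_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.standard_normal(4)
        delta = rng.standard_normal(4)
        near = euclidean_similarity(p, p + 0.5 * delta)
        far = euclidean_similarity(p, p + 1.5 * delta)
        assert 0 < far <= near <= 1
        if np.linalg.norm(delta) > 0:
            assert far < near


class TestCosine:
    def test_self_similarity_one(self):
        p = np.array([1.0, 2.0])
        assert cos_similarity(p, p) == pytest.approx(1.0)

    def test_orthogonal_zero(self):
        assert cos_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_zero_vector_epsilon_floor(self):
        # numerator is exactly 0, denominator floors at epsilon
        assert cos_similarity(np.zeros(3), np.array([1.0, 2.0, 3.0])) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 500), st.floats(0.1, 50.0))
    def test_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        p, q = rng.standard_normal(5), rng.standard_normal(5)
        assert cos_similarity(scale * p, q) == pytest.approx(cos_similarity(p, q))


class TestPredictTM:
    def test_zero_model_zero_everywhere(self):
        model = BilinearModel(np.zeros((3, 3)))
        rng = np.random.default_rng(0)
        assert predict_tm(model, rng.standard_normal(3), rng.standard_normal(3)) == 0.0

    def test_hand_bilinear_product(self):
        model = BilinearModel(np.eye(2))
        z1, z2 = np.array([0.5, 0.5]), np.array([0.6, 0.2])
        assert predict_tm(model, z1, z2) == pytest.approx(0.4)

    def test_clamped_to_unit_interval(self):
        model = BilinearModel(np.eye(2) * 10)
        z = np.array([1.0, 1.0])
        assert predict_tm_raw(model, z, z) == pytest.approx(20.0)
        assert predict_tm(model, z, z) == 1.0
        assert predict_tm(model, z, -z) == 0.0

    def test_batch_equals_scalar_loop(self):
        rng = np.random.default_rng(1)
        model = BilinearModel(rng.standard_normal((4, 4)))
        Z1, Z2 = rng.standard_normal((5, 4)), rng.standard_normal((7, 4))
        batch = predict_tm_matrix(model, Z1, Z2)
        for i in range(5):
            for j in range(7):
                assert batch[i, j] == pytest.approx(
                    predict_tm(model, Z1[i], Z2[j]), abs=1e-12
                )

    def test_dimension_mismatch(self):
        model = BilinearModel(np.eye(3))
        with pytest.raises(ValueError, match="dimension mismatch"):
            predict_tm(model, np.zeros(2), np.zeros(3))


class TestCombinationRule:
    """Cosine above the 0.995 threshold wins; otherwise TM x cosine."""

    def test_high_cos_returns_cos_regardless_of_model(self):
        theta = np.arccos(0.999)
        z1 = np.array([1.0, 0.0])
        z2 = np.array([np.cos(theta), np.sin(theta)])
        for w_scale in (0.0, 0.5, 100.0):
            model = BilinearModel(np.eye(2) * w_scale)
            assert ss_predictor_similarity(model, z1, z2) == pytest.approx(
                0.999, abs=1e-12
            )

    def test_product_branch_hand_value(self):
        # cos = 0.5, predicted TM = 0.8 -> 0.4
        z1 = np.array([1.0, 0.0])
        z2 = np.array([0.5, np.sqrt(0.75)])
        w = 0.8 / float(z1 @ z2)
        model = BilinearModel(np.eye(2) * w)
        assert ss_predictor_similarity(model, z1, z2) == pytest.approx(0.4)

    def test_threshold_is_strict(self):
        # pass the measured cosine as the threshold itself: equality must
        # take the product branch
        rng = np.random.default_rng(2)
        z1, z2 = rng.standard_normal(3), rng.standard_normal(3)
        model = BilinearModel(np.eye(3) * 0.01)
        cos = cos_similarity(z1, z2)
        tm = predict_tm(model, z1, z2)
        assert ss_predictor_similarity(
            model, z1, z2, cos_threshold=cos
        ) == pytest.approx(tm * cos)

    def test_matrix_form_matches_scalar(self):
        rng = np.random.default_rng(3)
        model = BilinearModel(0.1 * np.eye(4) + 0.01 * rng.standard_normal((4, 4)))
        Z1, Z2 = rng.standard_normal((6, 4)), rng.standard_normal((5, 4))
        batch = ss_predictor_similarity_matrix(model, Z1, Z2)
        for i in range(6):
            for j in range(5):
                assert batch[i, j] == pytest.approx(
                    ss_predictor_similarity(model, Z1[i], Z2[j]), abs=1e-12
                )


class TestTrainer:
    def _pairs_from(self, Z, labels_fn, n, rng):
        ids = list(Z)
        pairs = []
        for _ in range(n):
            q, t = rng.choice(ids, 2, replace=False)
            pairs.append(LabeledPair(q, t, labels_fn(Z[q], Z[t])))
        return pairs

    def test_all_zero_labels_drive_predictions_to_zero(self):
        rng = np.random.default_rng(0)
        Z = {f"p{i}": rng.uniform(0, 1, 4) for i in range(30)}
        pairs = self._pairs_from(Z, lambda a, b: 0.0, 300, rng)
        cfg = TrainConfig(batch_size=50, learning_rate=1e-2, epochs=60, seed=0)
        result = train_bilinear(pairs, Z, cfg)
        assert result.epoch_losses[-1] < 1e-3
        assert result.epoch_losses[-1] < result.epoch_losses[0]

    def test_same_seed_bit_identical_model(self):
        rng = np.random.default_rng(1)
        Z = {f"p{i}": rng.uniform(0, 1, 4) for i in range(20)}
        pairs = self._pairs_from(Z, lambda a, b: float(np.clip(a @ b / 4, 0, 1)), 200, rng)
        cfg = TrainConfig(batch_size=32, learning_rate=1e-2, epochs=10, seed=5)
        w1 = train_bilinear(pairs, Z, cfg).model.W
        w2 = train_bilinear(pairs, Z, cfg).model.W
        assert np.array_equal(w1, w2)

    def test_different_seed_different_model(self):
        rng = np.random.default_rng(1)
        Z = {f"p{i}": rng.uniform(0, 1, 4) for i in range(20)}
        pairs = self._pairs_from(Z, lambda a, b: float(np.clip(a @ b / 4, 0, 1)), 200, rng)
        w1 = train_bilinear(
            pairs, Z, TrainConfig(batch_size=32, learning_rate=1e-2, epochs=5, seed=5)
        ).model.W
        w2 = train_bilinear(
            pairs, Z, TrainConfig(batch_size=32, learning_rate=1e-2, epochs=5, seed=6)
        ).model.W
        assert not np.array_equal(w1, w2)

    def test_missing_embedding_errors_with_id(self):
        pairs = [LabeledPair("a", "ghost", 0.5)]
        with pytest.raises(KeyError, match="ghost"):
            train_bilinear(pairs, {"a": np.zeros(3)}, TrainConfig())

    def test_model_save_load_roundtrip(self, tmp_path):
        model = BilinearModel(np.random.default_rng(0).standard_normal((5, 5)))
        path = tmp_path / "model.npz"
        model.save(path)
        assert np.array_equal(BilinearModel.load(path).W, model.W)
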