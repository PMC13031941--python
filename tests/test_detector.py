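"""CNN detector: architecture contracts, training behaviour, classification."""

import numpy as np
import pytest

import finpulse as fp
from finpulse import _nn
from finpulse.detector import PulseDetectorCNN, build, head_param_count

SMALL_SHAPE = (12, 10, 3)


def _toy_frames(n, rng, shape=SMALL_SHAPE):
    """Tiny separable task: class 1 carries a bright horizontal stripe."""
    X = rng.random((n, *shape)).astype(np.float32) * 0.3
    y = rng.integers(0, 2, n)
    X[y == 1, 4:6, :, :] += 1.0
    return X, y


class TestArchitecture:
    def test_output_is_probability_pair(self):
        det = build(input_shape=SMALL_SHAPE, seed=0)
        probs = _nn.softmax(det.network_.forward(np.random.default_rng(0).random((3, *SMALL_SHAPE))))
        assert probs.shape == (3, 2)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_head_parameter_count_closed_form(self):
        det = build(seed=0)
        # head: GAP features -> 512 -> 256 -> 2, weights + biases
        expected = 16 * 512 + 512 + 512 * 256 + 256 + 256 * 2 + 2
        assert head_param_count(16) == expected
        dense_layers = [l for l in det.network_.layers if isinstance(l, _nn.Dense)]
        assert sum(l.n_params for l in dense_layers) == expected

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            build(backbone="resnet152")

    def test_dropout_rates_validated(self):
        with pytest.raises(ValueError):
            build(dropout_rates=(1.5, 0.2))


class TestTraining:
    def test_learning_rate_staircase_values(self):
        assert _nn.staircase_lr(0) == 0.001
        assert _nn.staircase_lr(89) == 0.001
        assert _nn.staircase_lr(90) == 0.00075
        assert _nn.staircase_lr(180) == pytest.approx(0.0005625)

    def test_single_class_dataset_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.random((8, *SMALL_SHAPE))
        with pytest.raises(ValueError):
            PulseDetectorCNN(input_shape=SMALL_SHAPE).fit(X, np.ones(8))

    def test_separable_toy_task_learned_within_10_epochs(self):
        rng = np.random.default_rng(1)
        X, y = _toy_frames(200, rng)
        det = PulseDetectorCNN(input_shape=SMALL_SHAPE, epochs=10, seed=0).fit(X, y)
        assert det.history_["accuracy"][-1] >= 0.95

    def test_fixed_seed_reproducible_history(self):
        rng = np.random.default_rng(2)
        X, y = _toy_frames(60, rng)
        h1 = PulseDetectorCNN(input_shape=SMALL_SHAPE, epochs=3, seed=5).fit(X, y).history_
        h2 = PulseDetectorCNN(input_shape=SMALL_SHAPE, epochs=3, seed=5).fit(X, y).history_
        assert h1 == h2


class TestPrediction:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(3)
        X, y = _toy_frames(120, rng)
        det = PulseDetectorCNN(input_shape=SMALL_SHAPE, epochs=5, seed=0).fit(X, y)
        Xq = rng.random((20, *SMALL_SHAPE)).astype(np.float32)
        return det, Xq

    def test_identical_frames_identical_probabilities(self, fitted):
        det, Xq = fitted
        twice = np.stack([Xq[0], Xq[0]])
        p = det.predict_proba(twice)
        assert np.array_equal(p[0], p[1])

    def test_probability_pairs_sum_to_one(self, fitted):
        det, Xq = fitted
        assert np.allclose(det.predict_proba(Xq).sum(axis=1), 1.0)

    def test_permutation_equivariance(self, fitted):
        det, Xq = fitted
        perm = np.random.default_rng(4).permutation(len(Xq))
        assert np.allclose(det.decision_function(Xq)[perm], det.decision_function(Xq[perm]))

    def test_single_vs_batched_identical(self, fitted):
        det, Xq = fitted
        batched = det.decision_function(Xq)
        singly = np.array([det.decision_function(Xq[i : i + 1])[0] for i in range(len(Xq))])
        assert np.allclose(batched, singly)

    def test_shape_mismatch_rejected(self, fitted):
        det, _ = fitted
        with pytest.raises(ValueError):
            det.predict_proba(np.zeros((1, 5, 5, 3)))

    def test_save_load_roundtrip(self, fitted, tmp_path):
        det, Xq = fitted
        path = tmp_path / "det.npz"
        det.save(path)
        clone = PulseDetectorCNN().load(path)
        assert np.allclose(clone.decision_function(Xq), det.decision_function(Xq))


class TestClassify:
    def test_threshold_is_inclusive(self):
        assert fp.classify(np.array([0.51]), 0.5)[0] == 1
        assert fp.classify(np.array([0.5]), 0.5)[0] == 1

    def test_extremes(self):
        assert fp.classify(np.array([0.0]), 0.5)[0] == 0
        assert fp.classify(np.array([1.0]), 0.5)[0] == 1

    def test_zero_threshold_all_positive(self):
        probs = np.linspace(0, 1, 11)
        assert fp.classify(probs, 0.0).all()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        probs = rng.random(200)
        counts = [fp.classify(probs, t).sum() for t in np.linspace(0, 1, 21)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fp.classify(np.array([1.2]), 0.5)
        with pytest.raises(ValueError):
            fp.classify(np.array([0.5]), 1.5)


class TestMaskedConditionRobustness:
    """With airgun shots mixed into half of all frames, in-gap pulses are
    partially suppressed by PCEN's slow gain recovery after each shot, so
    discriminability sits between chance and the clean-scene level.  The
    loss of detectability under shooting is the acoustic-masking phenomenon
    the pipeline's correction stage accounts for."""

    def test_auc_well_above_chance_under_airgun_masking(self):
        frames, y = fp.make_labelled_frames(1000, snr_db=10.0, with_airguns=True, seed=7)
        X = fp.SpectrogramFrontend().fit().transform(frames).astype(np.float32)
        det = PulseDetectorCNN(epochs=10, seed=0).fit(X[:800], y[:800])
        *_, auc = fp.roc(y[800:], det.decision_function(X[800:]))
        assert auc >= 0.80
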