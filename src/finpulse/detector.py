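"""CNN frame detector for fin-whale 20-Hz pulse presence.

A binary image classifier over 97 x 90 x 3 PCEN spectrogram tensors:
a small convolutional feature extractor, global average pooling, then the
classification head used throughout the underwater-acoustics literature —
dense layers of 512 and 256 rectified-linear units with dropout rates 0.5
and 0.2, and a two-unit softmax output (pulse present vs absent).

Training uses categorical cross-entropy with an Adam optimizer whose
learning rate decays exponentially with a staircase: initial 0.001,
multiplied by 0.75 every 90 optimizer steps.  Dense weights are
Glorot-uniform initialised with zero biases.  Each 30-s frame is
classified independently of its chronological context, by construction.

The default ``small_conv`` backbone (two 3x3 conv blocks with max
pooling) trains in minutes on one CPU; the full analysis pipeline — not
any particular pretrained feature extractor — is what this package
reproduces, so heavyweight transfer-learned backbones are deliberately
out of scope.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn

__all__ = ["PulseDetectorCNN", "build", "train", "predict", "classify", "head_param_count"]


def head_param_count(feature_dim: int, widths: tuple[int, ...] = (512, 256), n_classes: int = 2) -> int:
    """Closed-form parameter count of the dense classification head."""
    dims = (feature_dim, *widths, n_classes)
    return sum(d_in * d_out + d_out for d_in, d_out in zip(dims[:-1], dims[1:]))


class PulseDetectorCNN(ClassifierMixin, BaseEstimator):
    """Binary CNN classifier over fixed-shape spectrogram tensors.

    Parameters
    ----------
    backbone : {"small_conv"}
        Convolutional feature extractor.  ``small_conv`` is two 3x3
        convolution blocks (ReLU + 2x2 max pool) with ``conv_filters``
        output channels.
    conv_filters : tuple of int
        Channel widths of the backbone blocks.
    pool_size : int
        Max-pooling factor after each block.
    head_widths : tuple of int
        Dense classification-head widths (512, 256 by default).
    dropout_rates : tuple of float
        Dropout after each head layer (0.5, 0.2 by default).
    lr, lr_decay, lr_decay_steps : float, float, int
        Staircase exponential schedule: ``lr * lr_decay**(step // steps)``.
    batch_size, epochs : int
        Mini-batch size and number of passes over the training data.
    input_shape : tuple
        Expected (time, freq, channels) tensor shape.
    seed : int
        Pins initialisation, shuffling and dropout masks.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels (always two).
    history_ : dict
        Per-epoch training loss and accuracy.
    n_steps_ : int
        Total optimizer steps taken.
    """

    def __init__(
        self,
        backbone: str = "small_conv",
        conv_filters: tuple[int, ...] = (8, 16),
        pool_size: int = 3,
        head_widths: tuple[int, ...] = (512, 256),
        dropout_rates: tuple[float, ...] = (0.5, 0.2),
        lr: float = 1e-3,
        lr_decay: float = 0.75,
        lr_decay_steps: int = 90,
        batch_size: int = 32,
        epochs: int = 20,
        input_shape: tuple[int, int, int] = (97, 90, 3),
        seed: int = 0,
    ):
        self.backbone = backbone
        self.conv_filters = conv_filters
        self.pool_size = pool_size
        self.head_widths = head_widths
        self.dropout_rates = dropout_rates
        self.lr = lr
        self.lr_decay = lr_decay
        self.lr_decay_steps = lr_decay_steps
        self.batch_size = batch_size
        self.epochs = epochs
        self.input_shape = input_shape
        self.seed = seed

    # ------------------------------------------------------------------
    def _build_network(self, rng: np.random.Generator) -> _nn.Sequential:
        if self.backbone == "efficientnet_b0":
            raise NotImplementedError(
                "the efficientnet_b0 backbone needs a deep-learning runtime and "
                "pretrained weights; use the small_conv backbone"
            )
        if self.backbone != "small_conv":
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if any(not 0 <= d < 1 for d in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")
        layers: list[_nn.Layer] = []
        in_ch = self.input_shape[2]
        for out_ch in self.conv_filters:
            layers += [_nn.Conv2D(in_ch, out_ch, rng=rng), _nn.ReLU(), _nn.MaxPool2(self.pool_size)]
            in_ch = out_ch
        layers.append(_nn.GlobalAvgPool())
        dim = in_ch
        for width, rate in zip(self.head_widths, self.dropout_rates):
            layers += [_nn.Dense(dim, width, rng=rng), _nn.ReLU(), _nn.Dropout(rate, rng=rng)]
            dim = width
        layers.append(_nn.Dense(dim, 2, rng=rng))
        return _nn.Sequential(layers)

    def build(self) -> "PulseDetectorCNN":
        """Initialise the (untrained) network; returns self."""
        rng = np.random.default_rng(self.seed)
        self.network_ = self._build_network(rng)
        self._rng = rng
        self.n_steps_ = 0
        self.history_ = {"loss": [], "accuracy": []}
        return self

    @property
    def feature_dim_(self) -> int:
        return self.conv_filters[-1]

    def head_param_count_(self) -> int:
        return head_param_count(self.feature_dim_, tuple(self.head_widths), 2)

    # ------------------------------------------------------------------
    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[None]
        if X.shape[1:] != tuple(self.input_shape):
            raise ValueError(f"expected frames of shape {self.input_shape}, got {X.shape[1:]}")
        return X

    def fit(self, X, y) -> "PulseDetectorCNN":
        X = self._check_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("training data must contain exactly two classes")
        y_idx = np.searchsorted(self.classes_, y)
        self.build()
        onehot_all = np.eye(2)[y_idx]
        optimizer = _nn.Adam(self.network_.params)
        n = X.shape[0]
        for _epoch in range(self.epochs):
            order = self._rng.permutation(n)
            epoch_loss, epoch_correct = 0.0, 0
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                logits = self.network_.forward(X[batch], train=True)
                loss, dlogits = _nn.softmax_cross_entropy(logits, onehot_all[batch])
                self.network_.backward(dlogits)
                lr_now = _nn.staircase_lr(self.n_steps_, self.lr, self.lr_decay, self.lr_decay_steps)
                optimizer.step(self.network_.grads, lr_now)
                self.n_steps_ += 1
                epoch_loss += loss * batch.size
                epoch_correct += int((logits.argmax(axis=1) == y_idx[batch]).sum())
            self.history_["loss"].append(epoch_loss / n)
            self.history_["accuracy"].append(epoch_correct / n)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities, each frame scored independently."""
        check_is_fitted(self, "network_")
        X = self._check_X(X)
        out = np.empty((X.shape[0], 2))
        for start in range(0, X.shape[0], 256):
            logits = self.network_.forward(X[start : start + 256], train=False)
            out[start : start + 256] = _nn.softmax(logits)
        return out

    def decision_function(self, X) -> np.ndarray:
        """Probability of the positive (pulse-present) class."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        probs = self.decision_function(X)
        return self.classes_[classify(probs, threshold).astype(int)]

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        check_is_fitted(self, "network_")
        arrays = {f"param_{i}": p for i, p in enumerate(self.network_.params)}
        np.savez(path, _params=np.array(self.get_params(deep=False), dtype=object), **arrays)

    def load(self, path) -> "PulseDetectorCNN":
        data = np.load(path, allow_pickle=True)
        self.set_params(**data["_params"].item())
        self.build()
        for i, p in enumerate(self.network_.params):
            p[...] = data[f"param_{i}"]
        self.classes_ = np.array([0, 1])
        return self


def classify(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary detections from pulse probabilities.

    Detection iff probability >= threshold (a score exactly at the
    threshold counts as positive).  The operating threshold 0.5 is the
    rounded ROC-optimal value for this detector family.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    if np.any((probabilities < 0) | (probabilities > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must lie in [0, 1]")
    return (probabilities >= threshold).astype(int)


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimator

def build(**config) -> PulseDetectorCNN:
    """Construct and initialise an untrained detector."""
    return PulseDetectorCNN(**config).build()


def train(X, y, **config) -> PulseDetectorCNN:
    """Train a detector on labelled frames; returns the fitted estimator."""
    return PulseDetectorCNN(**config).fit(X, y)


def predict(detector: PulseDetectorCNN, X) -> np.ndarray:
    """Pulse-presence probability per frame."""
    return detector.decision_function(X)
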