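"""Feed-forward regression network and window-to-subject aggregation.

A small fully connected ReLU network maps the selected EEG features plus
the three fixed clinical inputs onto the follow-up FMAUE score.  Every
epoch (window) of a subject is one training row carrying that subject's
FMAUE_T1 as target; at prediction time the median over a subject's
window predictions is taken and clipped to the FMAUE range [0, 66].

Training is plain numpy: He-initialized weights, mean-squared-error
loss, Adam, fixed learning rate 0.01, exactly 20 passes over the data.
Inputs are standardized by training-set mean/sd; the output bias is
initialized to the training-target mean so that the short 20-epoch
budget is spent learning deviations rather than the target offset.
All randomness (init, shuffling) flows from the config seed, so a fixed
seed gives bit-identical predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["HIDDEN_CONFIGS", "BATCH_SIZES", "NetConfig", "FittedNet",
           "SubjectPrediction", "train", "predict_subject"]

HIDDEN_CONFIGS: Tuple[Tuple[int, ...], ...] = (
    (8,), (16,), (32,), (16, 8), (32, 16), (32, 16, 8),
)
BATCH_SIZES: Tuple[object, ...] = (64, 128, "full")

FMAUE_MAX = 66.0


@dataclass(frozen=True)
class NetConfig:
    hidden_layers: Tuple[int, ...] = (8,)
    batch_size: object = "full"     # 64, 128 or "full"
    epochs: int = 20
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers not in HIDDEN_CONFIGS:
            raise ValueError(
                f"hidden_layers {self.hidden_layers} not in the search grid "
                f"{HIDDEN_CONFIGS}"
            )
        if self.batch_size not in BATCH_SIZES:
            raise ValueError(f"batch_size {self.batch_size} not in {BATCH_SIZES}")


@dataclass
class FittedNet:
    config: NetConfig
    feature_names: Tuple[str, ...]
    mu: np.ndarray
    sd: np.ndarray
    weights: List[np.ndarray]
    biases: List[np.ndarray]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        a = (X - self.mu) / self.sd
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        return (a @ self.weights[-1] + self.biases[-1]).ravel()


@dataclass
class SubjectPrediction:
    epoch_predictions: np.ndarray
    aggregate: float          # exact median over epochs, before clipping
    clipped: float            # aggregate clamped to [0, 66]


def _init_params(
    sizes: Sequence[int], rng: np.random.Generator, y_mean: float
) -> Tuple[List[np.ndarray], List[np.ndarray]]:
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    # zero-init the linear output layer: the network starts at the
    # bias-only (target-mean) solution and learns deviations from it
    weights[-1][:] = 0.0
    biases[-1][:] = y_mean
    return weights, biases


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: NetConfig,
    feature_names: Sequence[str] = (),
) -> FittedNet:
    """Fit the network on epoch rows ``X`` (n x d) and targets ``y``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd

    rng = np.random.default_rng(config.seed)
    sizes = [d, *config.hidden_layers, 1]
    weights, biases = _init_params(sizes, rng, float(y.mean()))

    batch = n if config.batch_size == "full" else min(int(config.batch_size), n)
    lr, b1, b2, eps = config.learning_rate, 0.9, 0.999, 1e-8
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    step = 0

    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            xb, yb = Xs[idx], y[idx]
            # forward
            activations = [xb]
            a = xb
            for W, b in zip(weights[:-1], biases[:-1]):
                a = np.maximum(a @ W + b, 0.0)
                activations.append(a)
            out = (a @ weights[-1] + biases[-1]).ravel()
            loss = float(np.mean((out - yb) ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(f"NaN/inf loss during training ({config})")
            # backward (MSE)
            delta = (2.0 / len(yb)) * (out - yb)[:, None]
            grads_w, grads_b = [], []
            for li in range(len(weights) - 1, -1, -1):
                grads_w.insert(0, activations[li].T @ delta)
                grads_b.insert(0, delta.sum(axis=0))
                if li > 0:
                    delta = (delta @ weights[li].T) * (activations[li] > 0)
            # Adam update
            step += 1
            corr1 = 1.0 - b1**step
            corr2 = 1.0 - b2**step
            for li in range(len(weights)):
                m_w[li] = b1 * m_w[li] + (1 - b1) * grads_w[li]
                v_w[li] = b2 * v_w[li] + (1 - b2) * grads_w[li] ** 2
                weights[li] -= lr * (m_w[li] / corr1) / (np.sqrt(v_w[li] / corr2) + eps)
                m_b[li] = b1 * m_b[li] + (1 - b1) * grads_b[li]
                v_b[li] = b2 * v_b[li] + (1 - b2) * grads_b[li] ** 2
                biases[li] -= lr * (m_b[li] / corr1) / (np.sqrt(v_b[li] / corr2) + eps)

    return FittedNet(
        config=config,
        feature_names=tuple(feature_names),
        mu=mu,
        sd=sd,
        weights=weights,
        biases=biases,
    )


def predict_subject(model: FittedNet, subject_epochs: np.ndarray) -> SubjectPrediction:
    """Aggregate per-epoch predictions into one FMAUE_T1 estimate: the
    exact median over epochs, clipped to [0, 66]."""
    preds = model.predict(np.atleast_2d(subject_epochs))
    if preds.size == 0:
        raise ValueError("subject has no epochs to predict")
    agg = float(np.median(preds))
    return SubjectPrediction(
        epoch_predictions=preds,
        aggregate=agg,
        clipped=float(np.clip(agg, 0.0, FMAUE_MAX)),
    )
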