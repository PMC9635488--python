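"""Distributed feedforward reading model (orthography -> hidden -> phonology).

A single-hidden-layer logistic network trained online by backpropagation of
cross-entropy error on binary orthography inputs and binary phonology
targets.  Output units whose target is 1 additionally receive an external
input that ramps up over training as a function of the word's log-compressed
frequency, standing in for a growing frequency-weighted semantic push toward
the correct phonology.

Word representations are read out from the hidden layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AnnConfig", "AnnModel", "TrainingHistory", "ReadingOutput",
    "initialize_model", "external_phoneme_input", "forward", "train",
    "score_word", "jaccard_similarity", "score_nonword",
    "hidden_representations",
]


@dataclass(frozen=True)
class AnnConfig:
    n_input: int = 105
    n_hidden: int = 100
    n_output: int = 61
    epochs: int = 400
    learning_rate: float = 0.3
    weight_init_halfwidth: float = 0.1
    seed: int = 0
    ramp_gain: float = 0.05
    ramp_halflife: float = 100.0  # epochs at which the ramp reaches 1/2
    frequency_compression: str = "log1p"

    def __post_init__(self):
        if min(self.n_input, self.n_hidden, self.n_output) <= 0:
            raise ValueError("layer sizes must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0 or self.weight_init_halfwidth < 0:
            raise ValueError("learning_rate and init halfwidth must be >= 0")
        if self.ramp_gain < 0 or self.ramp_halflife <= 0:
            raise ValueError("ramp_gain >= 0 and ramp_halflife > 0 required")
        if self.frequency_compression not in ("log1p", "log"):
            raise ValueError(
                f"unknown frequency_compression {self.frequency_compression!r}"
            )


@dataclass
class AnnModel:
    """Weights and biases; ``w1`` maps input->hidden, ``w2`` hidden->output."""

    w1: np.ndarray  # (n_hidden, n_input)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_output, n_hidden)
    b2: np.ndarray  # (n_output,)
    config: AnnConfig

    def __post_init__(self):
        c = self.config
        expected = {
            "w1": (c.n_hidden, c.n_input), "b1": (c.n_hidden,),
            "w2": (c.n_output, c.n_hidden), "b2": (c.n_output,),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != {shape}")

    def copy(self) -> "AnnModel":
        return AnnModel(self.w1.copy(), self.b1.copy(),
                        self.w2.copy(), self.b2.copy(), self.config)


@dataclass
class TrainingHistory:
    mean_error: list[float] = field(default_factory=list)
    word_accuracy: list[float] = field(default_factory=list)
    nonword_accuracy: list[float] | None = None


@dataclass(frozen=True)
class ReadingOutput:
    hidden: np.ndarray
    output: np.ndarray
    rounded: np.ndarray


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def initialize_model(config: AnnConfig) -> AnnModel:
    """Draw every weight and bias i.i.d. uniform on [-h, +h] from the seed."""
    rng = np.random.default_rng(config.seed)
    h = config.weight_init_halfwidth
    return AnnModel(
        w1=rng.uniform(-h, h, (config.n_hidden, config.n_input)),
        b1=rng.uniform(-h, h, config.n_hidden),
        w2=rng.uniform(-h, h, (config.n_output, config.n_hidden)),
        b2=rng.uniform(-h, h, config.n_output),
        config=config,
    )


def _compress(frequency: np.ndarray | float, how: str) -> np.ndarray | float:
    if np.any(np.asarray(frequency) <= 0):
        raise ValueError("frequency must be positive")
    if how == "log1p":
        return np.log1p(frequency)
    return np.log(frequency)


def _ramp(epoch: float, halflife: float) -> float:
    return epoch / (epoch + halflife)


def external_phoneme_input(frequency: float, epoch: float,
                           config: AnnConfig) -> float:
    """Magnitude of the frequency-driven external input at a given epoch.

    g * ramp(epoch) * compress(frequency): zero at epoch 0, nondecreasing in
    epoch, saturating at g * compress(frequency).
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    comp = _compress(frequency, config.frequency_compression)
    return float(config.ramp_gain * _ramp(epoch, config.ramp_halflife) * comp)


def forward(model: AnnModel, x: np.ndarray,
            external: np.ndarray | None = None) -> ReadingOutput:
    """One forward pass; ``external`` is added to the output pre-activation."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.config.n_input,):
        raise ValueError(
            f"input shape {x.shape} != ({model.config.n_input},)"
        )
    hidden = _sigmoid(model.w1 @ x + model.b1)
    pre = model.w2 @ hidden + model.b2
    if external is not None:
        external = np.asarray(external, dtype=float)
        if external.shape != pre.shape:
            raise ValueError("external input shape mismatch")
        pre = pre + external
    output = _sigmoid(pre)
    return ReadingOutput(hidden=hidden, output=output,
                         rounded=(output >= 0.5).astype(np.uint8))


def _external_matrix(targets: np.ndarray, freqs: np.ndarray, epoch: float,
                     config: AnnConfig) -> np.ndarray:
    """Per-word external input vectors: nonzero only on target-1 output units."""
    mag = (config.ramp_gain * _ramp(epoch, config.ramp_halflife)
           * np.asarray(_compress(freqs, config.frequency_compression)))
    return targets.astype(float) * mag[:, None]


def _batch_forward(model: AnnModel, X: np.ndarray,
                   external: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    H = _sigmoid(X @ model.w1.T + model.b1)
    pre = H @ model.w2.T + model.b2
    if external is not None:
        pre = pre + external
    return H, _sigmoid(pre)


def train(model: AnnModel, X: np.ndarray, Y: np.ndarray,
          frequencies: Sequence[float] | None = None,
          config: AnnConfig | None = None) -> tuple[AnnModel, TrainingHistory]:
    """Online gradient descent on cross-entropy over `epochs` full passes.

    Presentation order is reshuffled every epoch under an RNG stream derived
    from the config seed, so (seed, config, data) determines the trained
    weights bit for bit.  Per-epoch mean error and whole-word accuracy are
    recorded; accuracy is evaluated with the external input at that epoch's
    ramp value.
    """
    cfg = config or model.config
    model = model.copy()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if frequencies is None:
        freqs = np.ones(n)
    else:
        freqs = np.asarray(frequencies, dtype=float)
        if np.any(freqs <= 0):
            raise ValueError("frequencies must be positive")
    order_rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(1)[0]
    )
    lr = cfg.learning_rate
    history = TrainingHistory()
    for epoch in range(cfg.epochs):
        E = _external_matrix(Y, freqs, epoch, cfg)
        order = order_rng.permutation(n)
        total_err = 0.0
        for i in order:
            x, y, e = X[i], Y[i], E[i]
            h = _sigmoid(model.w1 @ x + model.b1)
            a = _sigmoid(model.w2 @ h + model.b2 + e)
            # cross-entropy with logistic output: delta = a - y
            delta_out = a - y
            if not np.isfinite(delta_out).all():
                raise FloatingPointError(
                    f"non-finite gradient at epoch {epoch}, word index {i}"
                )
            delta_hid = (model.w2.T @ delta_out) * h * (1.0 - h)
            model.w2 -= lr * np.outer(delta_out, h)
            model.b2 -= lr * delta_out
            model.w1 -= lr * np.outer(delta_hid, x)
            model.b1 -= lr * delta_hid
            with np.errstate(divide="ignore"):
                ce = -(y * np.log(a) + (1 - y) * np.log1p(-a))
            total_err += float(np.where(np.isfinite(ce), ce, 36.0).sum())
        history.mean_error.append(total_err / n)
        _, out = _batch_forward(model, X, _external_matrix(Y, freqs, epoch, cfg))
        correct = ((out >= 0.5).astype(np.uint8) == Y.astype(np.uint8)).all(axis=1)
        history.word_accuracy.append(float(correct.mean()))
    return model, history


def score_word(rounded: np.ndarray, target: np.ndarray) -> bool:
    """A word is read correctly iff the rounded output equals the target."""
    rounded = np.asarray(rounded)
    target = np.asarray(target)
    if rounded.shape != target.shape:
        raise ValueError("length mismatch")
    return bool(np.array_equal(rounded.astype(np.uint8), target.astype(np.uint8)))


def jaccard_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b| for binary vectors; two empty vectors give 1."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def score_nonword(rounded: np.ndarray, acceptable: Sequence[np.ndarray],
                  pool: Sequence[np.ndarray], criterion: str = "jaccard") -> bool:
    """Score a nonword pronunciation against its acceptable targets.

    jaccard: correct iff the output's best Jaccard match over the whole pool
    is one of the item's acceptable vectors and strictly beats every
    non-acceptable pool vector (a tie with a foreign vector is incorrect).
    exact: correct iff the rounded output equals some acceptable vector.
    """
    if len(acceptable) == 0:
        raise ValueError("acceptable set must be non-empty")
    rounded = np.asarray(rounded).astype(np.uint8)
    if criterion == "exact":
        return any(np.array_equal(rounded, np.asarray(v).astype(np.uint8))
                   for v in acceptable)
    if criterion != "jaccard":
        raise ValueError(f"unknown criterion {criterion!r}")
    acc_keys = {np.asarray(v).astype(np.uint8).tobytes() for v in acceptable}
    best_acc = -1.0
    best_foreign = -1.0
    for v in pool:
        v = np.asarray(v).astype(np.uint8)
        sim = jaccard_similarity(rounded, v)
        if v.tobytes() in acc_keys:
            best_acc = max(best_acc, sim)
        else:
            best_foreign = max(best_foreign, sim)
    if best_acc < 0:
        raise ValueError("acceptable set must be a subset of the pool")
    return best_acc > best_foreign


def hidden_representations(model: AnnModel, X: np.ndarray) -> np.ndarray:
    """Hidden-layer activation matrix (n_stimuli x n_hidden).

    The external input targets the output layer only, so hidden
    representations do not depend on it.
    """
    X = np.asarray(X, dtype=float)
    return _sigmoid(X @ model.w1.T + model.b1)


def training_accuracy(model: AnnModel, X: np.ndarray, Y: np.ndarray,
                      frequencies: Sequence[float] | None = None) -> float:
    """Whole-word accuracy with the external input at its end-of-training value."""
    cfg = model.config
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    freqs = (np.ones(n) if frequencies is None
             else np.asarray(frequencies, dtype=float))
    E = _external_matrix(Y, freqs, cfg.epochs, cfg)
    _, out = _batch_forward(model, np.asarray(X, dtype=float), E)
    correct = ((out >= 0.5).astype(np.uint8) == Y.astype(np.uint8)).all(axis=1)
    return float(correct.mean())


def read_nonwords(model: AnnModel, X: np.ndarray) -> np.ndarray:
    """Rounded network outputs for nonword inputs (no external input)."""
    _, out = _batch_forward(model, np.asarray(X, dtype=float))
    return (out >= 0.5).astype(np.uint8)


def with_seed(config: AnnConfig, seed: int) -> AnnConfig:
    return replace(config, seed=seed)
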