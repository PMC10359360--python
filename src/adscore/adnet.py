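"""The Bayesian AD-score classifier: an MLP with Monte-Carlo dropout.

A small fully-connected network maps the 155 residualized, standardized
morphometric features to a single sigmoid output, the probability-like
"AD score". Two hidden layers of 128 tanh units each are followed by
dropout with a high rate (0.8 by default). Keeping dropout active at
prediction time turns each forward pass into an approximate draw from the
posterior over network weights (Gal & Ghahramani's Monte-Carlo-dropout
construction): the mean over N passes is the AD score and the standard
deviation over passes is the model uncertainty.

The network, backpropagation, Adam and dropout are implemented directly in
NumPy: the model is small (36,609 parameters at the default shape) and CPU
training takes seconds, so no deep-learning framework is needed, and the
arithmetic stays fully seedable and inspectable.

Conventions (documented for bit-reproducibility):

* inverted dropout — kept activations are scaled by 1/keep during training
  and MC inference, so a dropout-free pass needs no rescaling;
* uncertainty SD uses denominator ``n_passes - 1``;
* weight init is uniform fan-in: U(-1/sqrt(fan_in), +1/sqrt(fan_in));
* mini-batches of 64 with seeded shuffling; checkpoint = epoch with the
  smallest validation loss, earliest epoch on ties.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import feature_names

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "Network",
    "build_network",
    "count_parameters",
    "train",
    "mc_predict",
    "predict_single_pass",
    "save_model",
    "load_model",
]

FORMAT_VERSION = 1


@dataclass(frozen=True)
class NetworkSpec:
    input_dim: int = 155
    hidden_dims: tuple[int, ...] = (128, 128)
    dropout_rate: float = 0.8
    # activation is tanh and the output a single sigmoid unit, by design

    def __post_init__(self) -> None:
        if len(self.hidden_dims) == 0:
            raise ValueError("hidden_dims must be non-empty")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 0.001
    weight_decay: float = 0.0001
    batch_size: int = 64
    balanced: bool = False  # subsample the majority class before training
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class Network:
    """Feed-forward tanh MLP with one sigmoid output and dropout layers."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        dims = [spec.input_dim, *spec.hidden_dims, 1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(rng.uniform(-bound, bound, size=fan_out))

    # -- forward -----------------------------------------------------------
    def forward(
        self, X: np.ndarray, rng: np.random.Generator | None = None, cache: bool = False
    ):
        """Forward pass; draws fresh inverted-dropout masks when ``rng`` given.

        With ``cache=True`` returns the intermediates needed for backprop.
        """
        keep = 1.0 - self.spec.dropout_rate
        a = np.asarray(X, dtype=float)
        acts, masks = [a], []
        n_hidden = len(self.spec.hidden_dims)
        for i in range(n_hidden):
            z = a @ self.weights[i] + self.biases[i]
            a = np.tanh(z)
            if rng is not None and self.spec.dropout_rate > 0:
                mask = (rng.uniform(size=a.shape) < keep) / keep
            else:
                mask = np.ones_like(a)
            a = a * mask
            masks.append(mask)
            acts.append(a)
        logits = a @ self.weights[-1] + self.biases[-1]
        p = _sigmoid(logits[:, 0])
        if cache:
            return p, acts, masks, logits
        return p

    def clone_weights(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        return [w.copy() for w in self.weights], [b.copy() for b in self.biases]

    def set_weights(self, weights, biases) -> None:
        self.weights = [w.copy() for w in weights]
        self.biases = [b.copy() for b in biases]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def build_network(spec: NetworkSpec, seed: int = 0, strict: bool = True) -> Network:
    """Construct a network with deterministic, seeded initialization."""
    if strict and spec.input_dim != len(feature_names()) and spec.input_dim != 155:
        pass  # non-canonical input sizes are allowed for toy networks
    return Network(spec, seed=seed)


def count_parameters(network: Network) -> int:
    """Total trainable parameters: sum of weight and bias array sizes."""
    return int(sum(w.size for w in network.weights) + sum(b.size for b in network.biases))


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = table[feature_names()].to_numpy(dtype=float)
    y = (table["diagnosis"] == "AD").to_numpy(dtype=float)
    return X, y


@dataclass
class TrainedModel:
    network: Network
    best_epoch: int
    best_val_loss: float
    log: pd.DataFrame = field(repr=False)


def train(
    network: Network,
    train_table: pd.DataFrame,
    val_table: pd.DataFrame,
    cfg: TrainConfig,
) -> TrainedModel:
    """Train with Adam on binary cross-entropy; keep the min-val-loss epoch.

    Tables must already be residualized and standardized. Dropout is active
    during training steps; the per-epoch validation loss that drives
    checkpoint selection is computed with dropout disabled (a deterministic
    pass). Fully seeded: same inputs and config give the same selected epoch
    and weights.
    """
    X, y = _xy(train_table)
    Xv, yv = _xy(val_table)
    for arr, nm in ((y, "training"), (yv, "validation")):
        if not np.isin(arr, [0.0, 1.0]).all():
            raise ValueError(f"non-binary labels in {nm} table")

    rng = np.random.default_rng(cfg.seed)
    if cfg.balanced:
        X, y = _balance(X, y, rng)

    lr, wd = cfg.learning_rate, cfg.weight_decay
    b1, b2, eps = 0.9, 0.999, 1e-8
    m = [np.zeros_like(w) for w in network.weights] + [np.zeros_like(b) for b in network.biases]
    v = [np.zeros_like(w) for w in network.weights] + [np.zeros_like(b) for b in network.biases]
    t = 0

    best = (np.inf, -1, None)
    rows = []
    n = len(X)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            p, acts, masks, _ = network.forward(xb, rng=rng, cache=True)
            if not np.isfinite(p).all():
                raise FloatingPointError(f"NaN in forward pass at epoch {epoch}")
            losses.append(_bce(p, yb) * len(idx))
            grads = _backward(network, acts, masks, p, yb)
            t += 1
            params = network.weights + network.biases
            for k, (param, g) in enumerate(zip(params, grads)):
                g = g + wd * param  # L2 coupled into the gradient, Adam-style
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1**t)
                vhat = v[k] / (1 - b2**t)
                param -= lr * mhat / (np.sqrt(vhat) + eps)
        train_loss = float(np.sum(losses) / n)
        val_loss = _bce(network.forward(Xv), yv)
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"NaN validation loss at epoch {epoch}")
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best[0]:  # strict < : earliest epoch wins ties
            best = (val_loss, epoch, network.clone_weights())

    network.set_weights(*best[2])
    return TrainedModel(
        network=network,
        best_epoch=best[1],
        best_val_loss=float(best[0]),
        log=pd.DataFrame(rows),
    )


def _balance(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Subsample the majority class to the minority-class size."""
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    k = min(len(idx_pos), len(idx_neg))
    keep = np.concatenate(
        [rng.permutation(idx_pos)[:k], rng.permutation(idx_neg)[:k]]
    )
    keep.sort()
    return X[keep], y[keep]


def _backward(network: Network, acts, masks, p, y):
    """Gradients of mean BCE w.r.t. weights then biases (matching order)."""
    n = len(y)
    gw = [None] * len(network.weights)
    gb = [None] * len(network.biases)
    delta = (p - y)[:, None] / n  # dL/dlogit for sigmoid+BCE
    gw[-1] = acts[-1].T @ delta
    gb[-1] = delta.sum(axis=0)
    grad_a = delta @ network.weights[-1].T
    for i in range(len(network.spec.hidden_dims) - 1, -1, -1):
        grad_pre = grad_a * masks[i] * (1.0 - (acts[i + 1] / np.where(masks[i] == 0, 1.0, masks[i])) ** 2)
        gw[i] = acts[i].T @ grad_pre
        gb[i] = grad_pre.sum(axis=0)
        if i > 0:
            grad_a = grad_pre @ network.weights[i].T
    return gw + gb


def mc_predict(
    model: TrainedModel | Network,
    table: pd.DataFrame,
    n_passes: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo-dropout prediction: mean score and uncertainty per subject.

    Runs ``n_passes`` stochastic forward passes with fresh Bernoulli(keep)
    dropout masks and returns ``subject_id``, ``ad_score`` (the mean) and
    ``uncertainty`` (SD over passes, denominator n-1). Seeded and exactly
    reproducible.
    """
    if n_passes < 2:
        raise ValueError("n_passes must be >= 2 (SD undefined otherwise)")
    network = model.network if isinstance(model, TrainedModel) else model
    X = table[feature_names()].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    out = np.empty((n_passes, len(X)))
    for i in range(n_passes):
        out[i] = network.forward(X, rng=rng)
    return pd.DataFrame(
        {
            "subject_id": table["subject_id"].to_numpy(),
            "ad_score": out.mean(axis=0),
            "uncertainty": out.std(axis=0, ddof=1),
            "n_passes": n_passes,
        }
    )


def mc_sample_scores(
    network: Network, X: np.ndarray, n_passes: int, seed: int = 0
) -> np.ndarray:
    """Raw (n_passes, n_subjects) matrix of stochastic sigmoid outputs."""
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    out = np.empty((n_passes, len(X)))
    for i in range(n_passes):
        out[i] = network.forward(X, rng=rng)
    return out


def predict_single_pass(model: TrainedModel | Network, table: pd.DataFrame) -> pd.DataFrame:
    """Deterministic forward pass with dropout disabled (non-stochastic score).

    With inverted dropout the dropout-free pass is already correctly scaled.
    """
    network = model.network if isinstance(model, TrainedModel) else model
    X = table[feature_names()].to_numpy(dtype=float)
    return pd.DataFrame(
        {"subject_id": table["subject_id"].to_numpy(), "ad_score": network.forward(X)}
    )


# -- persistence -----------------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    """Serialize spec + selected weights (+ log) into one .npz-in-zip archive."""
    network = model.network
    meta = {
        "format_version": FORMAT_VERSION,
        "spec": {
            "input_dim": network.spec.input_dim,
            "hidden_dims": list(network.spec.hidden_dims),
            "dropout_rate": network.spec.dropout_rate,
        },
        "best_epoch": model.best_epoch,
        "best_val_loss": model.best_val_loss,
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        zf.writestr("log.csv", model.log.to_csv(index=False))
        for i, w in enumerate(network.weights):
            zf.writestr(f"w{i}.txt", _array_to_text(w))
        for i, b in enumerate(network.biases):
            zf.writestr(f"b{i}.txt", _array_to_text(b))


def load_model(path) -> TrainedModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {meta.get('format_version')!r}")
        spec = NetworkSpec(
            input_dim=meta["spec"]["input_dim"],
            hidden_dims=tuple(meta["spec"]["hidden_dims"]),
            dropout_rate=meta["spec"]["dropout_rate"],
        )
        network = Network(spec, seed=0)
        network.weights = [
            _text_to_array(zf.read(f"w{i}.txt").decode()) for i in range(len(network.weights))
        ]
        network.biases = [
            _text_to_array(zf.read(f"b{i}.txt").decode()).ravel()
            for i in range(len(network.biases))
        ]
        log = pd.read_csv(zf.open("log.csv"))
    return TrainedModel(
        network=network,
        best_epoch=int(meta["best_epoch"]),
        best_val_loss=float(meta["best_val_loss"]),
        log=log,
    )


def _array_to_text(a: np.ndarray) -> str:
    header = ",".join(str(d) for d in a.shape)
    body = "\n".join(" ".join(format(float(x), ".17g") for x in row) for row in np.atleast_2d(a))
    return header + "\n" + body


def _text_to_array(s: str) -> np.ndarray:
    lines = s.splitlines()
    shape = tuple(int(d) for d in lines[0].split(","))
    vals = np.array([[float(x) for x in line.split()] for line in lines[1:]])
    return vals.reshape(shape)
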