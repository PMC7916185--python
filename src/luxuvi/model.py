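"""Feedforward UVI regression: training backend, evaluation, grid search,
and the portable weight format.

The network is a fully connected multilayer perceptron with ReLU hidden
activations and a linear scalar output, trained by mini-batch Adam on mean
absolute error (the model-selection metric; squared error is available as a
flag).  Predictions are clamped at zero — the UV index is nonnegative.

Trained weights serialize to a small self-describing JSON container
(``.litemodel.json``) holding layer shapes, activation tags, row-major
float32 weight blocks (base64), and the feature/normalization metadata
needed to rebuild inputs from raw illuminance and a timestamp.  The
container is executed by :mod:`luxuvi.lite`, a forward-pass interpreter
written without numpy, mirroring an on-device deployment runtime.
"""

from __future__ import annotations

import base64
import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import InputConfig, TrainingSet, extract, split

__all__ = [
    "MLPConfig",
    "MLPWeights",
    "GridResult",
    "train",
    "predict",
    "evaluate_mae",
    "grid_search",
    "export_lite",
    "load_lite_weights",
    "LiteFormatError",
    "LITE_FORMAT_VERSION",
]

LITE_FORMAT_VERSION = 1

#: node counts permitted in architecture grid runs
GRID_NODE_CHOICES = (8, 16, 32, 64, 128)


class LiteFormatError(ValueError):
    """A portable weight file is corrupt or internally inconsistent."""


@dataclass(frozen=True)
class MLPConfig:
    """Architecture and optimization settings."""

    n_inputs: int
    hidden: tuple[int, ...] = (64, 64)
    loss: str = "mae"  # "mae" or "mse"
    epochs: int = 200
    batch_size: int = 256
    learning_rate: float = 1e-3
    patience: int = 20  # early-stopping patience on validation MAE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be positive")
        if not 1 <= len(self.hidden) <= 4 or any(h < 1 for h in self.hidden):
            raise ValueError("hidden must list 1-4 positive node counts")
        if self.loss not in ("mae", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, learning_rate must be positive")


@dataclass(frozen=True)
class MLPWeights:
    """Ordered dense layers; ``weights[i]`` maps layer i inputs to outputs."""

    weights: tuple[np.ndarray, ...]  # each (n_in, n_out)
    biases: tuple[np.ndarray, ...]  # each (n_out,)
    activations: tuple[str, ...]  # "relu" per hidden layer, "identity" last

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.biases) == len(self.activations)):
            raise ValueError("layer lists must have equal length")
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.ndim != 2 or b.shape != (w.shape[1],):
                raise ValueError(f"layer {i}: inconsistent shapes {w.shape} / {b.shape}")
            if i and w.shape[0] != self.weights[i - 1].shape[1]:
                raise ValueError(f"layer {i}: dimension chain broken")
            if not (np.isfinite(w).all() and np.isfinite(b).all()):
                raise ValueError(f"layer {i}: non-finite values")

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Raw (un-clamped) network output for a batch of feature rows."""
        h = np.atleast_2d(np.asarray(x, dtype=float))
        if h.shape[1] != self.n_inputs:
            raise ValueError(f"feature dim {h.shape[1]} != model input dim {self.n_inputs}")
        for w, b, act in zip(self.weights, self.biases, self.activations):
            h = h @ w + b
            if act == "relu":
                np.maximum(h, 0.0, out=h)
        return h[:, 0]


def predict(weights: MLPWeights, features: np.ndarray) -> np.ndarray:
    """UVI estimates for feature rows; clamped at zero from below."""
    return np.maximum(weights.forward(features), 0.0)


def _init_weights(config: MLPConfig, rng: np.random.Generator) -> MLPWeights:
    dims = [config.n_inputs, *config.hidden, 1]
    ws, bs, acts = [], [], []
    for i in range(len(dims) - 1):
        fan_in = dims[i]
        ws.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(dims[i], dims[i + 1])))
        bs.append(np.zeros(dims[i + 1]))
        acts.append("relu" if i < len(dims) - 2 else "identity")
    return MLPWeights(tuple(ws), tuple(bs), tuple(acts))


def train(
    ts: TrainingSet, config: MLPConfig
) -> tuple[MLPWeights, list[dict[str, float]]]:
    """Fit the network on the training split with mini-batch Adam.

    Early-stops on validation-split MAE when a validation split exists
    (patience in epochs), restoring the best weights seen.  Fully
    reproducible from ``config.seed``.  Returns the weights and a per-epoch
    history of training loss and validation MAE.
    """
    if ts.features.shape[1] != config.n_inputs:
        raise ValueError(
            f"training set dim {ts.features.shape[1]} != config.n_inputs {config.n_inputs}"
        )
    x_train, y_train = ts.subset("train")
    if x_train.shape[0] == 0:
        raise ValueError("empty training split")
    x_val, y_val = ts.subset("val")

    rng = np.random.default_rng(config.seed)
    model = _init_weights(config, rng)
    ws = [w.copy() for w in model.weights]
    bs = [b.copy() for b in model.biases]
    n_layers = len(ws)
    # Adam state
    m_w = [np.zeros_like(w) for w in ws]
    v_w = [np.zeros_like(w) for w in ws]
    m_b = [np.zeros_like(b) for b in bs]
    v_b = [np.zeros_like(b) for b in bs]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    step = 0

    def current() -> MLPWeights:
        return MLPWeights(tuple(w.copy() for w in ws), tuple(b.copy() for b in bs), model.activations)

    history: list[dict[str, float]] = []
    best_val = np.inf
    best_weights = current()
    stall = 0
    n = x_train.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            # forward, caching pre-activations
            hs = [xb]
            h = xb
            for i in range(n_layers):
                z = h @ ws[i] + bs[i]
                h = np.maximum(z, 0.0) if model.activations[i] == "relu" else z
                hs.append(h)
            pred = h[:, 0]
            err = pred - yb
            if config.loss == "mae":
                epoch_loss += float(np.abs(err).sum())
                grad_out = np.sign(err)[:, None] / len(idx)
            else:
                epoch_loss += float((err**2).sum())
                grad_out = 2.0 * err[:, None] / len(idx)
            if not np.isfinite(epoch_loss):
                raise FloatingPointError("training diverged: non-finite loss")
            # backward
            delta = grad_out
            step += 1
            grads_w = [None] * n_layers
            grads_b = [None] * n_layers
            for i in range(n_layers - 1, -1, -1):
                if model.activations[i] == "relu":
                    delta = delta * (hs[i + 1] > 0)
                grads_w[i] = hs[i].T @ delta
                grads_b[i] = delta.sum(axis=0)
                if i:
                    delta = delta @ ws[i].T
            corr1 = 1.0 - beta1**step
            corr2 = 1.0 - beta2**step
            for i in range(n_layers):
                for g, w, m_, v_ in (
                    (grads_w[i], ws[i], m_w[i], v_w[i]),
                    (grads_b[i], bs[i], m_b[i], v_b[i]),
                ):
                    m_ *= beta1
                    m_ += (1 - beta1) * g
                    v_ *= beta2
                    v_ += (1 - beta2) * g**2
                    w -= lr * (m_ / corr1) / (np.sqrt(v_ / corr2) + eps)
        entry = {"epoch": epoch, "train_loss": epoch_loss / n}
        if x_val.shape[0]:
            snapshot = current()
            val_mae = float(np.abs(predict(snapshot, x_val) - y_val).mean())
            entry["val_mae"] = val_mae
            if val_mae < best_val - 1e-6:
                best_val, best_weights, stall = val_mae, snapshot, 0
            else:
                stall += 1
                if stall >= config.patience:
                    history.append(entry)
                    return best_weights, history
        history.append(entry)
    return (best_weights if x_val.shape[0] else current()), history


def evaluate_mae(weights: MLPWeights, ts: TrainingSet, split_label: str = "test") -> float:
    """Mean absolute error of clamped predictions over one split."""
    x, y = ts.subset(split_label)
    if x.shape[0] == 0:
        raise ValueError(f"empty split {split_label!r}")
    return float(np.abs(predict(weights, x) - y).mean())


@dataclass(frozen=True)
class GridResult:
    """One architecture-search cell: configuration and its held-out MAE."""

    input_config: InputConfig
    hidden_layers: int
    nodes: int
    val_mae: float  # mean over seeds
    seed_maes: tuple[float, ...]
    seeds: tuple[int, ...]

    @property
    def describe(self) -> str:
        inputs = "+".join(
            ["lux"]
            + (["zenith"] if self.input_config.use_zenith else [])
            + (["month"] if self.input_config.use_month else [])
        )
        return f"{inputs}/{self.hidden_layers}x{self.nodes}"


def grid_search(
    records,
    input_configs: Sequence[InputConfig],
    layer_counts: Sequence[int],
    node_counts: Sequence[int],
    seed: int = 0,
    n_seeds: int = 3,
    epochs: int = 200,
    eval_split: str = "val",
) -> list[GridResult]:
    """Train and evaluate one model per (inputs, depth, width) grid cell.

    All cells share the identical month-stratified data partition (derived
    from ``seed``), so MAE differences reflect the architecture, not the
    split.  Each cell's MAE is averaged over ``n_seeds`` training seeds.
    Results come back sorted by ascending MAE.
    """
    if not (input_configs and layer_counts and node_counts):
        raise ValueError("grids must be non-empty")
    for nodes in node_counts:
        if nodes not in GRID_NODE_CHOICES:
            raise ValueError(f"grid node count {nodes} not in {GRID_NODE_CHOICES}")
    results = []
    for cfg in input_configs:
        ts = split(extract(records, cfg), seed=seed)
        for n_layers in layer_counts:
            for nodes in node_counts:
                seeds = tuple(seed + 1000 * k for k in range(n_seeds))
                maes = []
                for s in seeds:
                    mc = MLPConfig(
                        n_inputs=cfg.n_features,
                        hidden=(nodes,) * n_layers,
                        epochs=epochs,
                        seed=s,
                    )
                    try:
                        w, _ = train(ts, mc)
                    except (ValueError, FloatingPointError) as exc:
                        raise RuntimeError(
                            f"grid cell inputs={cfg} layers={n_layers} nodes={nodes}: {exc}"
                        ) from exc
                    maes.append(evaluate_mae(w, ts, eval_split))
                results.append(
                    GridResult(cfg, n_layers, nodes, float(np.mean(maes)), tuple(maes), seeds)
                )
    return sorted(results, key=lambda r: r.val_mae)


def save_weights(
    weights: MLPWeights,
    path: str | Path,
    config: InputConfig | None = None,
    normalization: Sequence[tuple[float, float]] | None = None,
) -> Path:
    """Write full-precision weights as JSON (server-side checkpoint)."""
    doc = {
        "format": "luxuvi-weights",
        "version": 1,
        "inputs": None
        if config is None
        else {"use_zenith": config.use_zenith, "use_month": config.use_month},
        "normalization": None
        if normalization is None
        else [[float(o), float(s)] for o, s in normalization],
        "layers": [
            {"weights": w.tolist(), "bias": b.tolist(), "activation": act}
            for w, b, act in zip(weights.weights, weights.biases, weights.activations)
        ],
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_weights(path: str | Path) -> tuple[MLPWeights, InputConfig | None, list[tuple[float, float]] | None]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "luxuvi-weights":
        raise ValueError(f"{path}: not a luxuvi weight checkpoint")
    weights = MLPWeights(
        tuple(np.asarray(l["weights"], dtype=float) for l in doc["layers"]),
        tuple(np.asarray(l["bias"], dtype=float) for l in doc["layers"]),
        tuple(l["activation"] for l in doc["layers"]),
    )
    cfg = None
    if doc.get("inputs"):
        cfg = InputConfig(use_zenith=doc["inputs"]["use_zenith"], use_month=doc["inputs"]["use_month"])
    norm = None
    if doc.get("normalization"):
        norm = [(float(o), float(s)) for o, s in doc["normalization"]]
    return weights, cfg, norm


# --------------------------------------------------------------------------
# portable weight container


def _encode_f32(arr: np.ndarray) -> str:
    return base64.b64encode(np.ascontiguousarray(arr, dtype="<f4").tobytes()).decode("ascii")


def export_lite(
    weights: MLPWeights,
    path: str | Path,
    config: InputConfig | None = None,
    normalization: Sequence[tuple[float, float]] | None = None,
) -> Path:
    """Write a self-describing portable weight file.

    The container stores layer shapes, activation tags, row-major float32
    weight/bias blocks, the input configuration and the continuous-feature
    normalization constants, plus a CRC of the weight bytes so a corrupted
    file is rejected at load time.
    """
    config = config or InputConfig()
    normalization = list(normalization) if normalization is not None else [
        (0.0, 120000.0)
    ] + ([(0.0, 90.0)] if config.use_zenith else [])
    if weights.n_inputs != config.n_features:
        raise ValueError("weights input dim does not match input config")
    layers = []
    crc = 0
    for w, b, act in zip(weights.weights, weights.biases, weights.activations):
        wb = np.ascontiguousarray(w, dtype="<f4").tobytes()
        bb = np.ascontiguousarray(b, dtype="<f4").tobytes()
        crc = zlib.crc32(bb, zlib.crc32(wb, crc))
        layers.append(
            {
                "shape": [int(w.shape[0]), int(w.shape[1])],
                "activation": act,
                "weights_b64": _encode_f32(w),
                "bias_b64": _encode_f32(b),
            }
        )
    doc = {
        "format": "luxuvi-lite",
        "version": LITE_FORMAT_VERSION,
        "inputs": {
            "use_zenith": config.use_zenith,
            "use_month": config.use_month,
            "n_features": config.n_features,
        },
        "normalization": [[float(o), float(s)] for o, s in normalization],
        "output_clamp_min": 0.0,
        "layers": layers,
        "crc32": crc,
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1))
    return path


def load_lite_weights(path: str | Path) -> tuple[MLPWeights, InputConfig, list[tuple[float, float]]]:
    """Load a portable weight file back into backend weight arrays.

    The returned weights carry the file's float32 values, so a forward pass
    through them is directly comparable with the pure-Python interpreter.
    """
    from . import lite  # shared validation

    doc = lite._read_and_check(Path(path))
    ws, bs, acts = [], [], []
    for layer in doc["layers"]:
        n_in, n_out = layer["shape"]
        w = np.frombuffer(base64.b64decode(layer["weights_b64"]), dtype="<f4").reshape(n_in, n_out)
        b = np.frombuffer(base64.b64decode(layer["bias_b64"]), dtype="<f4")
        ws.append(w.astype(float))
        bs.append(b.astype(float))
        acts.append(layer["activation"])
    cfg = InputConfig(use_zenith=doc["inputs"]["use_zenith"], use_month=doc["inputs"]["use_month"])
    norm = [(float(o), float(s)) for o, s in doc["normalization"]]
    return MLPWeights(tuple(ws), tuple(bs), tuple(acts)), cfg, norm
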