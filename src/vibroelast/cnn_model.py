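"""The wavefield patch classifier.

Architecture (one convolutional block feeding a two-layer dense head):

    input 71×11×2
    → conv 3×3, stride 1, no padding            → 69×9×F
    → ReLU → batch norm → max-pool 2×2 stride 2 → 34×4×F
    → flatten (34·4·F)
    → dense 1024 → ReLU
    → dropout 0.5
    → dense 512 → ReLU
    → dense n_classes → softmax

Pooling floor-divides odd spatial sizes (69→34, 9→4). The final dense +
softmax pair is the "softmax classifier" that the fine-tuning protocol
discards and re-initializes. The number of conv feature maps is
configurable (default 16, selected on validation accuracy with a
parsimony tie-break).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .errors import ConfigError, InvalidParameterError
from .patches import PATCH_SHAPE

# conv width is a free parameter of the architecture; 16/32/64 are
# indistinguishable on validation accuracy for both tasks, so the smallest
# (and fastest) width is the default
DEFAULT_N_FILTERS = 16


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the classifier."""

    n_classes: int
    n_filters: int = DEFAULT_N_FILTERS
    kernel: int = 3
    dense_sizes: tuple[int, int] = (1024, 512)
    dropout: float = 0.5
    input_shape: tuple[int, int, int] = PATCH_SHAPE

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigError(f"n_classes must be ≥ 2, got {self.n_classes}")
        if self.n_filters < 1:
            raise ConfigError(f"n_filters must be ≥ 1, got {self.n_filters}")
        h, w, _ = self.input_shape
        if h < self.kernel or w < self.kernel:
            raise ConfigError(
                f"input {h}×{w} smaller than the {self.kernel}×{self.kernel} kernel"
            )

    @property
    def conv_out_shape(self) -> tuple[int, int, int]:
        h, w, _ = self.input_shape
        return (h - self.kernel + 1, w - self.kernel + 1, self.n_filters)

    @property
    def pool_out_shape(self) -> tuple[int, int, int]:
        ch, cw, f = self.conv_out_shape
        return (ch // 2, cw // 2, f)

    @property
    def flat_features(self) -> int:
        ph, pw, f = self.pool_out_shape
        return ph * pw * f


@dataclass
class Prediction:
    """Class probabilities and the argmax decision for one sample."""

    probabilities: np.ndarray
    predicted_label: int


class CNNClassifier:
    """Sequential classifier with named, freezable parameters."""

    #: parameter names belonging to the frozen stage during fine-tuning
    CONV_BLOCK_PARAMS = ("conv.W", "conv.b", "bn.gamma", "bn.beta")
    HEAD_PARAMS = ("head.W", "head.b")

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        d1, d2 = spec.dense_sizes
        self.conv = _nn.Conv2D(spec.input_shape[2], spec.n_filters, spec.kernel,
                               rng, name="conv")
        self.relu1 = _nn.ReLU()
        self.bn = _nn.BatchNorm(spec.n_filters, name="bn")
        self.pool = _nn.MaxPool2()
        self.flatten = _nn.Flatten()
        self.dense1 = _nn.Dense(spec.flat_features, d1, rng, name="dense1")
        self.relu2 = _nn.ReLU()
        self.dropout = _nn.Dropout(spec.dropout)
        self.dropout.rng = np.random.default_rng(rng.integers(2**31))
        self.dense2 = _nn.Dense(d1, d2, rng, name="dense2")
        self.relu3 = _nn.ReLU()
        self.head = _nn.Dense(d2, spec.n_classes, rng, name="head")
        self.layers = [
            self.conv, self.relu1, self.bn, self.pool, self.flatten,
            self.dense1, self.relu2, self.dropout, self.dense2, self.relu3,
            self.head,
        ]

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self.layers:
            out.update(layer.params())
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self.layers:
            out.update(layer.grads())
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self.layers:
            out.update(layer.buffers())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params().values())

    # -- forward / backward -------------------------------------------------

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=_nn.DTYPE)
        if X.ndim == 3:
            X = X[None]
        if X.ndim != 4 or X.shape[1:] != self.spec.input_shape:
            raise InvalidParameterError(
                f"expected input of shape (n, {self.spec.input_shape}), got {X.shape}"
            )
        return X

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch of patches."""
        out = self._check_input(X)
        for layer in self.layers:
            out = layer.forward(out, training=training)
        return out

    def backward(self, dlogits: np.ndarray, stop_index: int = 0) -> None:
        """Backpropagate; layers below ``stop_index`` are skipped (valid only
        when everything below is frozen, e.g. during fine-tuning)."""
        dout = dlogits
        for i in range(len(self.layers) - 1, stop_index - 1, -1):
            dout = self.layers[i].backward(dout)

    def lowest_trainable_index(self, trainable: set[str]) -> int:
        """Index of the deepest layer holding a trainable parameter."""
        for i, layer in enumerate(self.layers):
            if any(name in trainable for name in layer.params()):
                return i
        return len(self.layers)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities in inference mode (dropout off, running-stat
        batch norm), hence invariant to batch partitioning."""
        return _nn.softmax(self.forward(X, training=False))

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- persistence --------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {**{k: v.copy() for k, v in self.params().items()},
                **{k: v.copy() for k, v in self.buffers().items()}}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        for k, v in state.items():
            if k in params:
                params[k][...] = v
            elif k == "bn.running_mean":
                self.bn.running_mean = np.array(v)
            elif k == "bn.running_var":
                self.bn.running_var = np.array(v)
            else:
                raise KeyError(f"unknown state entry {k}")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path,
            __spec__=np.frombuffer(
                json.dumps(asdict(self.spec)).encode(), dtype=np.uint8
            ),
            __seed__=np.array(self.seed),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CNNClassifier":
        with np.load(Path(path)) as data:
            raw = json.loads(bytes(data["__spec__"].tobytes()).decode())
            raw["dense_sizes"] = tuple(raw["dense_sizes"])
            raw["input_shape"] = tuple(raw["input_shape"])
            spec = ModelSpec(**raw)
            model = cls(spec, seed=int(data["__seed__"]))
            state = {k: data[k] for k in data.files
                     if k not in ("__spec__", "__seed__")}
        model.load_state_dict(state)
        return model

    def summary(self) -> str:
        s = self.spec
        buf = io.StringIO()
        rows = [
            ("input", s.input_shape, 0),
            ("conv 3×3 valid", s.conv_out_shape,
             s.kernel * s.kernel * s.input_shape[2] * s.n_filters + s.n_filters),
            ("relu", s.conv_out_shape, 0),
            ("batchnorm", s.conv_out_shape, 2 * s.n_filters),
            ("maxpool 2×2", s.pool_out_shape, 0),
            ("flatten", (s.flat_features,), 0),
            ("dense+relu", (s.dense_sizes[0],),
             s.flat_features * s.dense_sizes[0] + s.dense_sizes[0]),
            (f"dropout {s.dropout}", (s.dense_sizes[0],), 0),
            ("dense+relu", (s.dense_sizes[1],),
             s.dense_sizes[0] * s.dense_sizes[1] + s.dense_sizes[1]),
            ("dense+softmax", (s.n_classes,),
             s.dense_sizes[1] * s.n_classes + s.n_classes),
        ]
        total = 0
        for name, shape, n in rows:
            total += n
            buf.write(f"{name:<16} {str(shape):<16} {n:>10,}\n")
        buf.write(f"{'total':<16} {'':<16} {total:>10,}\n")
        return buf.getvalue()


def build_model(spec: ModelSpec, seed: int = 0) -> CNNClassifier:
    """Construct a freshly initialized classifier (seeded weight init)."""
    return CNNClassifier(spec, seed=seed)


def predict(model: CNNClassifier, samples: np.ndarray) -> list[Prediction]:
    """Per-sample predictions (probabilities sum to 1, argmax decision)."""
    probs = model.predict_proba(samples)
    return [Prediction(p, int(p.argmax())) for p in probs]
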