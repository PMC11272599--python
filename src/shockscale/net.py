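"""The hybrid 2D-CNN + GRU classifier, its ablation variants and parameter accounting.

The full variant stacks five 3x3 convolution blocks (ReLU, 2x2 max pooling,
with dropout after the last three pools), a global average pooling layer, a
reshape of the pooled feature vector into a sequence of scalar steps, a GRU
whose final hidden state feeds a ReLU dense layer and a softmax output.
``cnn_only`` drops the GRU (GAP feeds the dense head directly); ``gru_only``
feeds raw image rows as a sequence straight into the GRU.

:func:`gru_step` is a deliberately independent, bias-free reference of one GRU
update (update gate, reset gate, candidate state, blend) used to pin down the
gate conventions the trainable layer must reproduce.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from shockscale import _layers
from shockscale._layers import Sequential


@dataclass
class GRUParams:
    """Bias-free gate matrices acting on the concatenation ``[h_prev, x]``.

    Each of ``W_z``, ``W_r``, ``W`` has shape ``(units, units + input_size)``.
    """

    W_z: np.ndarray
    W_r: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.W_z, self.W_r, self.W)}
        if len(shapes) != 1:
            raise ValueError("gate matrices must share one shape")
        u, ud = self.W_z.shape
        if ud <= u:
            raise ValueError("gate matrices must have shape (units, units + input_size)")

    @property
    def hidden_size(self) -> int:
        return self.W_z.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_z.shape[1] - self.W_z.shape[0]


def gru_step(
    p: GRUParams, h_prev: np.ndarray, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One bias-free GRU update; returns ``(z, r, h_tilde, h)``.

    z = sigmoid(W_z [h_prev, x]);  r = sigmoid(W_r [h_prev, x]);
    h_tilde = tanh(W [r*h_prev, x]);  h = (1 - z)*h_prev + z*h_tilde.
    """
    h_prev = np.asarray(h_prev, dtype=float)
    x = np.asarray(x, dtype=float)
    if h_prev.shape != (p.hidden_size,) or x.shape != (p.input_size,):
        raise ValueError(
            f"expected h_prev of shape ({p.hidden_size},) and x of shape ({p.input_size},), "
            f"got {h_prev.shape} and {x.shape}"
        )
    hx = np.concatenate([h_prev, x])
    z = 1.0 / (1.0 + np.exp(-(p.W_z @ hx)))
    r = 1.0 / (1.0 + np.exp(-(p.W_r @ hx)))
    h_tilde = np.tanh(p.W @ np.concatenate([r * h_prev, x]))
    h = (1.0 - z) * h_prev + z * h_tilde
    return z, r, h_tilde, h


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The five conv filter counts, the three dropout rates (applied after pools
    3, 4 and 5), the GRU width and the dense width default to a configuration
    that respects the published structural constraints while staying within
    the printed 208k trainable-parameter budget.
    """

    input_size: int = 227
    conv_filters: tuple[int, ...] = (16, 32, 64, 64, 128)
    dropout_rates: tuple[float, ...] = (0.25, 0.25, 0.5)
    gru_units: int = 128
    dense_units: int = 128
    n_classes: int = 4
    variant: str = "full"

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 5:
            raise ValueError("exactly 5 conv blocks are expected")
        if len(self.dropout_rates) != 3:
            raise ValueError("exactly 3 dropout layers are expected")
        if not all(0.0 < r < 1.0 for r in self.dropout_rates):
            raise ValueError("dropout rates must lie in (0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.variant not in ("full", "cnn_only", "gru_only"):
            raise ValueError("variant must be 'full', 'cnn_only' or 'gru_only'")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["conv_filters"] = tuple(d["conv_filters"])
        d["dropout_rates"] = tuple(d["dropout_rates"])
        return cls(**d)


def spatial_sizes(input_size: int, n_pools: int = 5) -> list[int]:
    """Feature-map side lengths after each 2x2 pool (floor-halving chain)."""
    sizes = []
    s = input_size
    for _ in range(n_pools):
        s //= 2
        sizes.append(s)
    return sizes


def build_model(cfg: ModelConfig, seed: int = 0) -> Sequential:
    """Instantiate the network for the requested variant with seeded init.

    Raises
    ------
    ValueError
        If ``input_size`` is too small to survive five poolings (< 32).
    """
    if cfg.variant in ("full", "cnn_only") and cfg.input_size < 32:
        raise ValueError("input_size must be at least 32 to allow five 2x2 poolings")
    rng = np.random.default_rng(seed)
    layers: list[_layers.Layer] = []
    if cfg.variant in ("full", "cnn_only"):
        c_in = 3
        drop_iter = iter(cfg.dropout_rates)
        for i, f in enumerate(cfg.conv_filters, start=1):
            layers.append(_layers.Conv2D(c_in, f, rng, name=f"conv{i}"))
            layers.append(_layers.MaxPool2x2(name=f"pool{i}"))
            if i >= 3:
                layers.append(_layers.Dropout(next(drop_iter), rng, name=f"dropout{i - 2}"))
            c_in = f
        layers.append(_layers.GlobalAvgPool(name="gap"))
        if cfg.variant == "full":
            layers.append(_layers.VectorToSequence(name="reshape"))
            layers.append(_layers.GRU(1, cfg.gru_units, rng, name="gru"))
            head_in = cfg.gru_units
        else:
            head_in = cfg.conv_filters[-1]
    else:  # gru_only: image rows as a sequence of width*3 features
        layers.append(_layers.RowsToSequence(name="rows"))
        layers.append(_layers.GRU(cfg.input_size * 3, cfg.gru_units, rng, name="gru"))
        head_in = cfg.gru_units
    layers.append(_layers.Dense(head_in, cfg.dense_units, rng, relu=True, name="dense1"))
    layers.append(_layers.Dense(cfg.dense_units, cfg.n_classes, rng, name="dense2"))
    return Sequential(layers)


def count_parameters(cfg: ModelConfig, include_biases: bool = True) -> int:
    """Closed-form trainable-parameter total for ``cfg``.

    Conv block i contributes ``(9*c_in + bias)*f_i``; the GRU contributes
    ``3*(u*(u+d) + bias*u)`` with ``d`` the per-step feature count (1 for the
    full variant); dense layers are standard affine counts.  With
    ``include_biases=False`` the bias-free convention of the reference gate
    equations is reported instead.
    """
    b = 1 if include_biases else 0
    total = 0
    if cfg.variant in ("full", "cnn_only"):
        c_in = 3
        for f in cfg.conv_filters:
            total += (9 * c_in + b) * f
            c_in = f
    if cfg.variant == "full":
        d, head_in = 1, cfg.gru_units
    elif cfg.variant == "gru_only":
        d, head_in = cfg.input_size * 3, cfg.gru_units
    else:
        d, head_in = None, cfg.conv_filters[-1]
    if d is not None:
        u = cfg.gru_units
        total += 3 * (u * (u + d) + b * u)
    total += head_in * cfg.dense_units + b * cfg.dense_units
    total += cfg.dense_units * cfg.n_classes + b * cfg.n_classes
    return total


@dataclass
class ModelBundle:
    """A built model plus its config, for checkpointing."""

    config: ModelConfig
    model: Sequential = field(repr=False, default=None)

    def save(self, path) -> None:
        arrays = {f"w{i}": w for i, w in enumerate(self.model.get_weights())}
        np.savez(str(path), config=self.config.to_json(), **arrays)

    @classmethod
    def load(cls, path, seed: int = 0) -> "ModelBundle":
        data = np.load(str(path), allow_pickle=False)
        cfg = ModelConfig.from_json(str(data["config"]))
        model = build_model(cfg, seed=seed)
        model.set_weights([data[f"w{i}"] for i in range(len(model.get_weights()))])
        return cls(config=cfg, model=model)
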