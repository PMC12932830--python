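"""The three lung-nodule classifier architectures and their training loop.

* ``simple_cnn`` — three 3x3 conv layers (32, 64, 128 filters), each
  followed by 2x2 max pooling, then global average pooling to a 128-dim
  vector.  Convolutional backbone: 92,672 trainable parameters.
* ``simple_coatnet`` — three 3x3 conv layers with 128 filters each,
  interleaved with pooling and dropout, plus a parameter-free scaled
  dot-product token-mixing step on the final feature map before global
  average pooling.  Convolutional backbone: 296,448 trainable parameters.
* ``attention_fusion_cnn`` — two parallel conv branches whose feature
  maps are concatenated and passed through channel attention then spatial
  attention, global average pooling (128-dim, also used for deep-feature
  export) and a Dense 128 -> Dropout -> Dense 64 -> Dense 1 head.

All heads end in a single sigmoid unit trained with binary cross-entropy
under Adam.  The printed backbone parameter counts pin the architectures:
they require a single input channel ((3*3*1+1)*32 = 320 for the first
simple-CNN conv) and cover the convolutional stack only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, ChannelAttention, Conv2D, Dense, Dropout,
                 GlobalAvgPool2D, Layer, MaxPool2D, ReLU, SelfAttention2D,
                 Sequential, SpatialAttention, bce_loss_and_grad, sigmoid)

ARCHITECTURES = ("simple_cnn", "simple_coatnet", "attention_fusion_cnn")


class SpecificationError(ValueError):
    """Raised when a model spec cannot reproduce the pinned architecture."""


@dataclass(frozen=True)
class ModelSpec:
    architecture: str
    input_size: int = 128
    input_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise SpecificationError(
                f"architecture must be one of {ARCHITECTURES}, got {self.architecture!r}")
        if self.input_channels != 1:
            raise SpecificationError(
                "input_channels must be 1 (the printed parameter counts "
                "require grayscale input)")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters (Adam, binary cross-entropy, sigmoid
    output; dropout 0.5; 60 epochs by default, 20 for the initial
    active-learning model)."""

    epochs: int = 60
    batch_size: int = 64
    learning_rate: float = 1e-3
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _as_batch(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=float)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    elif x.ndim != 4:
        raise ValueError("images must be (H,W), (N,H,W) or (N,1,H,W)")
    return x


def _center(x: np.ndarray) -> np.ndarray:
    """Fixed affine input scaling: [0, 1] intensities -> [-1, 1].

    Centering the input keeps the early conv activations balanced around
    zero, which markedly speeds up optimization; it is a constant
    transform, not a learned layer.
    """
    return (x - 0.5) * 2.0


def _make_head(rng: np.random.Generator, dropout: float = 0.5) -> Sequential:
    return Sequential([
        Dense(128, 128, rng), ReLU(), Dropout(dropout, rng),
        Dense(128, 64, rng), ReLU(),
        Dense(64, 1, rng),
    ])


class CNNClassifier:
    """Common machinery: a backbone ending in a 128-wide global average
    pool, a dense head ending in one sigmoid unit, Grad-CAM hooks."""

    pooled_width = 128

    def __init__(self, spec: ModelSpec) -> None:
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)

    # --- architecture-specific hooks -----------------------------------
    def backbone_modules(self) -> list[Layer]:
        raise NotImplementedError

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward_from_logit(self, dlogit: np.ndarray) -> None:
        raise NotImplementedError

    def gradcam_features(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Target-layer feature maps and d(logit)/d(maps), shape (N,C,h,w)."""
        raise NotImplementedError

    # --- shared API -----------------------------------------------------
    def params(self) -> list[np.ndarray]:
        return [p for m in self.all_modules() for p in m.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for m in self.all_modules() for g in m.grads()]

    def zero_grads(self) -> None:
        for g in self.grads():
            g[...] = 0.0

    def all_modules(self) -> list[Layer]:
        raise NotImplementedError

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class-1 probabilities, one per image; dropout inactive."""
        x = _as_batch(images)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(sigmoid(self.forward_logits(x[i:i + batch_size])).reshape(-1))
        return np.concatenate(out)

    def pooled_features(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """The 128-dim global-average-pooled representation per image."""
        x = _as_batch(images)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self._pooled(x[i:i + batch_size]))
        feats = np.concatenate(out)
        if feats.shape[1] != self.pooled_width:
            raise SpecificationError(
                f"pooled layer width {feats.shape[1]} != {self.pooled_width}")
        return feats

    def _pooled(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _SequentialCNN(CNNClassifier):
    """Backbone as one flat layer stack; used by simple_cnn / coatnet."""

    def __init__(self, spec: ModelSpec, backbone: Sequential,
                 conv_layer_count: int, gradcam_index: int) -> None:
        super().__init__(spec)
        self.backbone = backbone
        self.head = _make_head(self.rng)
        self._n_convs = conv_layer_count
        self.gradcam_index = gradcam_index

    def all_modules(self) -> list[Layer]:
        return [self.backbone, self.head]

    def backbone_modules(self) -> list[Layer]:
        return self.backbone.layers

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.head.forward(self.backbone.forward(_center(x), training), training)

    def backward_from_logit(self, dlogit: np.ndarray) -> None:
        self.backbone.backward(self.head.backward(dlogit))

    def _pooled(self, x: np.ndarray) -> np.ndarray:
        return self.backbone.forward(_center(x))

    def gradcam_features(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = _as_batch(images)
        idx = self.gradcam_index
        a = _center(x)
        for l in self.backbone.layers[:idx + 1]:
            a = l.forward(a)
        h = a
        for l in self.backbone.layers[idx + 1:]:
            h = l.forward(h)
        logit = self.head.forward(h)
        d = self.head.backward(np.ones_like(logit))
        for l in reversed(self.backbone.layers[idx + 1:]):
            d = l.backward(d)
        return a, d


def build_simple_cnn(spec: ModelSpec) -> _SequentialCNN:
    """conv32 -> pool -> conv64 -> pool -> conv128 -> pool -> GAP -> head."""
    if spec.architecture != "simple_cnn":
        raise SpecificationError("spec.architecture must be 'simple_cnn'")
    rng = np.random.default_rng(spec.seed)
    backbone = Sequential([
        Conv2D(1, 32, 3, rng), ReLU(), MaxPool2D(),
        Conv2D(32, 64, 3, rng), ReLU(), MaxPool2D(),
        Conv2D(64, 128, 3, rng), ReLU(), MaxPool2D(),
        GlobalAvgPool2D(),
    ])
    return _SequentialCNN(spec, backbone, conv_layer_count=3, gradcam_index=7)


def build_simple_coatnet(spec: ModelSpec) -> _SequentialCNN:
    """Three conv128 layers with pooling and dropout, a parameter-free
    self-attention token-mixing step on the final map, then GAP."""
    if spec.architecture != "simple_coatnet":
        raise SpecificationError("spec.architecture must be 'simple_coatnet'")
    rng = np.random.default_rng(spec.seed)
    backbone = Sequential([
        Conv2D(1, 128, 3, rng), ReLU(), MaxPool2D(), Dropout(0.5, rng),
        Conv2D(128, 128, 3, rng), ReLU(), MaxPool2D(), Dropout(0.5, rng),
        Conv2D(128, 128, 3, rng), ReLU(),
        SelfAttention2D(),
        GlobalAvgPool2D(),
    ])
    return _SequentialCNN(spec, backbone, conv_layer_count=3, gradcam_index=9)


class AttentionFusionCNN(CNNClassifier):
    """Two parallel conv branches, channel + spatial attention on the
    concatenated maps, GAP, dense head."""

    def __init__(self, spec: ModelSpec, reduction: int = 8,
                 attention_enabled: bool = True) -> None:
        super().__init__(spec)
        rng = self.rng

        def branch() -> Sequential:
            return Sequential([
                Conv2D(1, 32, 3, rng), ReLU(), MaxPool2D(),
                Conv2D(32, 64, 3, rng), ReLU(), MaxPool2D(),
            ])

        self.branch_a = branch()
        self.branch_b = branch()
        self.channel_attn = ChannelAttention(128, reduction, rng)
        self.spatial_attn = SpatialAttention(7, rng)
        self.gap = GlobalAvgPool2D()
        self.head = _make_head(rng)
        self.attention_enabled = attention_enabled

    def all_modules(self) -> list[Layer]:
        return [self.branch_a, self.branch_b, self.channel_attn,
                self.spatial_attn, self.head]

    def backbone_modules(self) -> list[Layer]:
        return (self.branch_a.layers + self.branch_b.layers
                + [self.channel_attn, self.spatial_attn, self.gap])

    def _fused(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = _center(x)
        fa = self.branch_a.forward(x, training)
        fb = self.branch_b.forward(x, training)
        return np.concatenate([fa, fb], axis=1)

    def _attended(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        f = self._fused(x, training)
        if self.attention_enabled:
            f = self.channel_attn.forward(f, training)
            f = self.spatial_attn.forward(f, training)
        return f

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        pooled = self.gap.forward(self._attended(x, training), training)
        return self.head.forward(pooled, training)

    def backward_from_logit(self, dlogit: np.ndarray) -> None:
        d = self.gap.backward(self.head.backward(dlogit))
        if self.attention_enabled:
            d = self.channel_attn.backward(self.spatial_attn.backward(d))
        da, db = d[:, :64], d[:, 64:]
        self.branch_a.backward(da)
        self.branch_b.backward(db)

    def _pooled(self, x: np.ndarray) -> np.ndarray:
        return self.gap.forward(self._attended(x))

    def gradcam_features(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = _as_batch(images)
        a = self._attended(x)
        logit = self.head.forward(self.gap.forward(a))
        d = self.gap.backward(self.head.backward(np.ones_like(logit)))
        return a, d


def build_attention_fusion_cnn(spec: ModelSpec, reduction: int = 8) -> AttentionFusionCNN:
    if spec.architecture != "attention_fusion_cnn":
        raise SpecificationError("spec.architecture must be 'attention_fusion_cnn'")
    return AttentionFusionCNN(spec, reduction=reduction)


def build_model(spec: ModelSpec) -> CNNClassifier:
    return {
        "simple_cnn": build_simple_cnn,
        "simple_coatnet": build_simple_coatnet,
        "attention_fusion_cnn": build_attention_fusion_cnn,
    }[spec.architecture](spec)


# ---------------------------------------------------------------------------
# attention operators as standalone functions
# ---------------------------------------------------------------------------

def channel_attention(feature_maps: np.ndarray, reduction: int = 8,
                      layer: ChannelAttention | None = None,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Channel gate values in (0, 1) for one (C, H, W) feature stack."""
    x = np.asarray(feature_maps, dtype=float)[None]
    c = x.shape[1]
    if layer is None:
        layer = ChannelAttention(c, reduction, rng or np.random.default_rng(0))
    return layer.gates(x)[0]


def spatial_attention(feature_maps: np.ndarray, kernel: int = 7,
                      layer: SpatialAttention | None = None,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """(H, W) spatial gate map in (0, 1) for one (C, H, W) feature stack."""
    x = np.asarray(feature_maps, dtype=float)[None]
    if x.shape[2] < kernel or x.shape[3] < kernel:
        raise ValueError("feature maps smaller than the attention kernel")
    if layer is None:
        layer = SpatialAttention(kernel, rng or np.random.default_rng(0))
    return layer.gate_map(x)[0, 0]


# ---------------------------------------------------------------------------
# parameter counting and training
# ---------------------------------------------------------------------------

def count_trainable_parameters(obj, scope: str = "all") -> int:
    """Exact count of trainable scalars.

    ``scope='backbone'`` restricts a classifier to its convolutional
    backbone (the scope for which the pinned counts 92,672 and 296,448
    hold); layers and layer lists are counted directly.
    """
    if isinstance(obj, CNNClassifier):
        modules = obj.backbone_modules() if scope == "backbone" else obj.all_modules()
        return int(sum(m.n_params() for m in modules))
    if isinstance(obj, Layer):
        return obj.n_params()
    if isinstance(obj, (list, tuple)):
        return int(sum(m.n_params() for m in obj))
    raise TypeError(f"cannot count parameters of {type(obj)!r}")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


def _eval_loss_acc(model: CNNClassifier, X: np.ndarray, y: np.ndarray,
                   batch_size: int) -> tuple[float, float]:
    p = model.predict_proba(X, batch_size=batch_size)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    acc = float(np.mean((p >= 0.5).astype(int) == y))
    return loss, acc


def train_model(model: CNNClassifier, train: tuple[np.ndarray, np.ndarray],
                val: tuple[np.ndarray, np.ndarray] | None,
                config: TrainConfig) -> TrainHistory:
    """Minibatch Adam on binary cross-entropy; returns per-epoch history."""
    X, y = _as_batch(train[0]), np.asarray(train[1], dtype=float).reshape(-1)
    if len(X) == 0:
        raise ValueError("training set is empty")
    if len(X) != len(y):
        raise ValueError("images and labels differ in length")
    opt = Adam(model.params(), model.grads(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    for _ in range(config.epochs):
        order = rng.permutation(len(X))
        losses, correct = [], 0
        for i in range(0, len(X), config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = model.forward_logits(X[idx], training=True)
            loss, dlogit = bce_loss_and_grad(logits, y[idx])
            model.zero_grads()
            model.backward_from_logit(dlogit)
            opt.step()
            losses.append(loss)
            correct += int(((sigmoid(logits.reshape(-1)) >= 0.5) == y[idx]).sum())
        history.train_loss.append(float(np.mean(losses)))
        history.train_acc.append(correct / len(X))
        if val is not None and len(val[0]) > 0:
            vl, va = _eval_loss_acc(model, _as_batch(val[0]),
                                    np.asarray(val[1], dtype=float).reshape(-1),
                                    config.batch_size)
            history.val_loss.append(vl)
            history.val_acc.append(va)
    return history


def predict_proba(model: CNNClassifier, images: np.ndarray) -> np.ndarray:
    """Module-level convenience wrapper (inference mode)."""
    return model.predict_proba(images)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: CNNClassifier, path) -> None:
    """Checkpoint: parameter arrays plus a JSON architecture descriptor."""
    import dataclasses
    import json
    meta = json.dumps(dataclasses.asdict(model.spec))
    arrays = {f"p{i}": p for i, p in enumerate(model.params())}
    np.savez_compressed(path, _spec=np.array(meta), **arrays)


def load_model(path) -> CNNClassifier:
    import json
    with np.load(path, allow_pickle=False) as z:
        spec = ModelSpec(**json.loads(str(z["_spec"])))
        model = build_model(spec)
        for i, p in enumerate(model.params()):
            p[...] = z[f"p{i}"]
    return model
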