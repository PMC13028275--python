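"""Backbone branches, the hybrid fusion head, and the baseline transfer head.

The hybrid classifier fuses two parallel representations of the same image:

* a vision-transformer branch whose output ``z_t`` is the final-layer class
  token (the reference configuration, DeiT-Small, has ``D_t = 384``);
* a CNN branch whose output ``z_c`` is the global average pool of the last
  convolutional feature maps (EfficientNet-B7: ``D_c = 2560``).

Fusion concatenates transformer-first, ``z_concat = [z_t; z_c]``, projects it
with a trainable linear map ``z_p = W z_concat + b`` into a ``P``-dimensional
latent space (default ``P = 2048``), and classifies with a final fully
connected layer plus softmax over the three cell types.

All layers are NumPy implementations.  Branches act as (by default frozen)
feature extractors initialized from a seed; only head parameters carry
gradients, which keeps the mixed image/embedding training regime exact: a
synthetic fusion-point embedding can never influence branch weights.
Pretrained ImageNet weights are not bundled; requesting
``weights_source="pretrained"`` raises with an explanatory message.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from fusecyte.constants import N_CLASSES

__all__ = [
    "BranchSpec", "FusionHeadParams", "TransformerBranch", "CNNBranch",
    "BaselineHead", "HybridModel", "FreezeAudit", "ShapeError",
    "transformer_branch_forward", "cnn_branch_forward", "fuse_project",
    "classify", "baseline_head_forward", "apply_freeze_policy", "softmax",
]


class ShapeError(ValueError):
    pass


@dataclass(frozen=True)
class BranchSpec:
    """Declaration of one backbone branch."""

    branch_kind: str  # "transformer" | "cnn"
    name: str
    embed_dim: int
    input_size: int
    weights_source: str = "random"

    def __post_init__(self) -> None:
        if self.branch_kind not in ("transformer", "cnn"):
            raise ValueError("branch_kind must be 'transformer' or 'cnn'")
        if self.embed_dim <= 0 or self.input_size <= 0:
            raise ValueError("embed_dim and input_size must be positive")
        if self.weights_source not in ("pretrained", "random"):
            raise ValueError("weights_source must be 'pretrained' or 'random'")


#: Reference branch declarations matching the production configuration.
DEIT_SMALL = BranchSpec("transformer", "deit_small", embed_dim=384, input_size=224,
                        weights_source="pretrained")
EFFICIENTNET_B7 = BranchSpec("cnn", "efficientnet_b7", embed_dim=2560, input_size=448,
                             weights_source="pretrained")


def tiny_transformer_spec(embed_dim: int = 32, input_size: int = 64) -> BranchSpec:
    return BranchSpec("transformer", "tiny_vit", embed_dim, input_size)


def tiny_cnn_spec(embed_dim: int = 64, input_size: int = 96) -> BranchSpec:
    return BranchSpec("cnn", "tiny_cnn", embed_dim, input_size)


class Layer:
    """One named parameter group of a backbone, freezable as a unit."""

    def __init__(self, name: str, params: dict[str, np.ndarray], is_bn: bool = False):
        self.name = name
        self.params = params
        self.is_bn = is_bn
        self.trainable = True

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _check_pretrained(spec: BranchSpec) -> None:
    if spec.weights_source == "pretrained":
        raise NotImplementedError(
            f"branch {spec.name!r} requests pretrained weights, which are not "
            "bundled with this package; use weights_source='random' or load a "
            "checkpoint")


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite logits")
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + np.tanh(math.sqrt(2 / math.pi) * (x + 0.044715 * x ** 3)))


def _layer_norm(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return gamma * (x - mu) / np.sqrt(var + 1e-6) + beta


class TransformerBranch:
    """Small ViT: patch embedding, encoder blocks, class-token readout.

    ``forward`` returns the final-layer class-token vector after the last
    layer norm.  In train mode each residual sublayer may be dropped with
    probability ``stochastic_depth_rate`` (stochastic depth); eval mode is a
    pure deterministic function of the input.
    """

    def __init__(self, spec: BranchSpec, patch_size: int = 16, depth: int = 2,
                 n_heads: int = 2, mlp_ratio: float = 2.0, seed: int = 0,
                 stochastic_depth_rate: float = 0.1):
        _check_pretrained(spec)
        if spec.input_size % patch_size != 0:
            raise ValueError("input_size must be divisible by patch_size")
        if spec.embed_dim % n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.spec = spec
        self.patch_size = patch_size
        self.depth = depth
        self.n_heads = n_heads
        self.stochastic_depth_rate = stochastic_depth_rate
        d = spec.embed_dim
        n_tokens = (spec.input_size // patch_size) ** 2
        rng = np.random.default_rng(seed)

        def w(*shape, scale=None):
            scale = scale or 1.0 / math.sqrt(shape[0])
            return rng.normal(0.0, scale, size=shape)

        self.layers: list[Layer] = []
        pe = {"W": w(patch_size * patch_size * 3, d), "b": np.zeros(d),
              "cls": rng.normal(0, 0.02, size=d),
              "pos": rng.normal(0, 0.02, size=(n_tokens + 1, d))}
        self.layers.append(Layer("patch_embed", pe))
        self.blocks = []
        for i in range(depth):
            attn = {"ln_g": np.ones(d), "ln_b": np.zeros(d),
                    "qkv_W": w(d, 3 * d), "qkv_b": np.zeros(3 * d),
                    "proj_W": w(d, d), "proj_b": np.zeros(d)}
            hidden = int(d * mlp_ratio)
            mlp = {"ln_g": np.ones(d), "ln_b": np.zeros(d),
                   "fc1_W": w(d, hidden), "fc1_b": np.zeros(hidden),
                   "fc2_W": w(hidden, d), "fc2_b": np.zeros(d)}
            la, lm = Layer(f"block{i}_attn", attn), Layer(f"block{i}_mlp", mlp)
            self.layers += [la, lm]
            self.blocks.append((la, lm))
        self.final_ln = Layer("final_ln", {"g": np.ones(d), "b": np.zeros(d)})
        self.layers.append(self.final_ln)

    def _attention(self, x: np.ndarray, p: dict[str, np.ndarray]) -> np.ndarray:
        B, T, D = x.shape
        h = self.n_heads
        dh = D // h
        qkv = x @ p["qkv_W"] + p["qkv_b"]
        q, k, v = np.split(qkv, 3, axis=-1)
        q = q.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
        k = k.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
        v = v.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
        att = softmax(q @ k.transpose(0, 1, 3, 2) / math.sqrt(dh), axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return out @ p["proj_W"] + p["proj_b"]

    def forward(self, x: np.ndarray, train_mode: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """(B, S, S, 3) -> (B, embed_dim) class-token embeddings."""
        x = np.asarray(x, dtype=np.float64)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        B, H, W, C = x.shape
        S, p = self.spec.input_size, self.patch_size
        if (H, W, C) != (S, S, 3):
            raise ShapeError(f"expected view of shape ({S}, {S}, 3), got {(H, W, C)}")
        pe = self.layers[0].params
        n = S // p
        patches = x.reshape(B, n, p, n, p, 3).transpose(0, 1, 3, 2, 4, 5).reshape(
            B, n * n, p * p * 3)
        tok = patches @ pe["W"] + pe["b"]
        cls = np.broadcast_to(pe["cls"], (B, 1, self.spec.embed_dim))
        z = np.concatenate([cls, tok], axis=1) + pe["pos"]
        drop = self.stochastic_depth_rate if train_mode else 0.0
        if drop > 0 and rng is None:
            raise ValueError("train_mode with stochastic depth requires an rng")
        for la, lm in self.blocks:
            if not (drop > 0 and rng.random() < drop):
                z = z + self._attention(
                    _layer_norm(z, la.params["ln_g"], la.params["ln_b"]), la.params)
            if not (drop > 0 and rng.random() < drop):
                h = _layer_norm(z, lm.params["ln_g"], lm.params["ln_b"])
                h = _gelu(h @ lm.params["fc1_W"] + lm.params["fc1_b"])
                z = z + h @ lm.params["fc2_W"] + lm.params["fc2_b"]
        z = _layer_norm(z, self.final_ln.params["g"], self.final_ln.params["b"])
        out = z[:, 0, :]
        return out[0] if squeeze else out


def _conv2d(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int = 2) -> np.ndarray:
    """3x3 same-padded strided convolution via shift-and-matmul. x: (B,H,W,Cin)."""
    B, H, Wd, Cin = x.shape
    kh, kw, _, Cout = W.shape
    pad = kh // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (Wd + 2 * pad - kw) // stride + 1
    out = np.broadcast_to(b, (B, Ho, Wo, Cout)).copy()
    for i in range(kh):
        for j in range(kw):
            sl = xp[:, i:i + stride * Ho:stride, j:j + stride * Wo:stride, :]
            out += sl @ W[i, j]
    return out


class CNNBranch:
    """Small strided conv stack with BN; output is the GAP descriptor ``z_c``.

    ``forward`` can also return the pre-pool feature maps, which feed the
    baseline transfer-learning head.  BN layers keep running statistics and,
    per the freeze policy, default to those statistics even in train mode.
    """

    def __init__(self, spec: BranchSpec, channels: tuple[int, ...] = (16, 32, 64),
                 seed: int = 0):
        _check_pretrained(spec)
        if channels[-1] != spec.embed_dim:
            raise ValueError(
                f"last channel count {channels[-1]} must equal embed_dim {spec.embed_dim}")
        self.spec = spec
        self.channels = tuple(channels)
        rng = np.random.default_rng(seed)
        self.layers: list[Layer] = []
        cin = 3
        for i, cout in enumerate(channels):
            scale = math.sqrt(2.0 / (9 * cin))
            conv = {"W": rng.normal(0, scale, size=(3, 3, cin, cout)),
                    "b": np.zeros(cout)}
            bn = {"gamma": np.ones(cout), "beta": np.zeros(cout),
                  "running_mean": np.zeros(cout), "running_var": np.ones(cout)}
            self.layers.append(Layer(f"conv{i}", conv))
            self.layers.append(Layer(f"bn{i}", bn, is_bn=True))
            cin = cout

    def forward(self, x: np.ndarray, train_mode: bool = False,
                return_maps: bool = False):
        """(B, S, S, 3) -> (B, embed_dim) GAP descriptor (optionally with maps)."""
        x = np.asarray(x, dtype=np.float64)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        S = self.spec.input_size
        if x.shape[1:] != (S, S, 3):
            raise ShapeError(f"expected view of shape ({S}, {S}, 3), got {x.shape[1:]}")
        for i in range(0, len(self.layers), 2):
            conv, bn = self.layers[i], self.layers[i + 1]
            x = _conv2d(x, conv.params["W"], conv.params["b"], stride=2)
            p = bn.params
            if train_mode and bn.trainable:  # batch statistics only when BN unfrozen
                mu = x.mean(axis=(0, 1, 2))
                var = x.var(axis=(0, 1, 2))
                p["running_mean"] = 0.9 * p["running_mean"] + 0.1 * mu
                p["running_var"] = 0.9 * p["running_var"] + 0.1 * var
            else:
                mu, var = p["running_mean"], p["running_var"]
            x = p["gamma"] * (x - mu) / np.sqrt(var + 1e-5) + p["beta"]
            x = np.maximum(x, 0.0)
        z = x.mean(axis=(1, 2))
        if squeeze:
            x, z = x[0], z[0]
        return (x, z) if return_maps else z


def transformer_branch_forward(view: np.ndarray, branch: TransformerBranch) -> np.ndarray:
    """Eval-mode class-token embedding ``z_t`` for one view or a batch."""
    return branch.forward(view, train_mode=False)


def cnn_branch_forward(view: np.ndarray, branch: CNNBranch) -> np.ndarray:
    """Eval-mode GAP descriptor ``z_c`` for one view or a batch."""
    return branch.forward(view, train_mode=False)


@dataclass
class FusionHeadParams:
    """Trainable fusion-head parameters: projection and classifier.

    ``input_mean`` / ``input_std`` are non-trainable normalization buffers
    applied to the concatenated embedding before the projection.  They
    default to the identity and are typically calibrated once on the
    training-fold embedding statistics (see :meth:`calibrate`); as a fixed
    affine map they commute with SMOTE's convex interpolation, so balancing
    may equivalently run on raw or normalized embeddings.
    """

    W: np.ndarray             # (P, D_t + D_c)
    b: np.ndarray             # (P,)
    classifier_W: np.ndarray  # (3, P)
    classifier_b: np.ndarray  # (3,)
    input_mean: np.ndarray | None = None  # (D_t + D_c,), frozen buffer
    input_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        P, D = self.W.shape
        if self.b.shape != (P,) or self.classifier_W.shape != (N_CLASSES, P) \
                or self.classifier_b.shape != (N_CLASSES,):
            raise ShapeError("fusion head parameter shapes are mutually inconsistent")
        for buf in (self.input_mean, self.input_std):
            if buf is not None and buf.shape != (D,):
                raise ShapeError("normalization buffers must match the input width")

    def calibrate(self, embeddings: np.ndarray) -> None:
        """Freeze per-dimension input statistics from training embeddings."""
        X = np.asarray(embeddings, dtype=np.float64)
        self.input_mean = X.mean(axis=0)
        self.input_std = X.std(axis=0) + 1e-8

    def normalize_input(self, z: np.ndarray) -> np.ndarray:
        if self.input_mean is None:
            return z
        return (z - self.input_mean) / self.input_std

    @property
    def projection_dim(self) -> int:
        return self.W.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W.shape[1]

    @classmethod
    def init(cls, d_t: int, d_c: int, projection_dim: int = 2048,
             seed: int = 0) -> "FusionHeadParams":
        rng = np.random.default_rng(seed)
        D = d_t + d_c
        return cls(W=rng.normal(0, 1 / math.sqrt(D), size=(projection_dim, D)),
                   b=np.zeros(projection_dim),
                   classifier_W=rng.normal(0, 1 / math.sqrt(projection_dim),
                                           size=(N_CLASSES, projection_dim)),
                   classifier_b=np.zeros(N_CLASSES))

    def as_dict(self) -> dict[str, np.ndarray]:
        """Trainable parameters only (normalization buffers are frozen)."""
        return {"W": self.W, "b": self.b,
                "classifier_W": self.classifier_W, "classifier_b": self.classifier_b}

    def copy(self) -> "FusionHeadParams":
        out = FusionHeadParams(**{k: v.copy() for k, v in self.as_dict().items()})
        out.input_mean = None if self.input_mean is None else self.input_mean.copy()
        out.input_std = None if self.input_std is None else self.input_std.copy()
        return out


def fuse_project(z_t: np.ndarray, z_c: np.ndarray,
                 params: FusionHeadParams) -> np.ndarray:
    """Project the fused embedding: ``z_p = W [z_t; z_c] + b``.

    Concatenation order is transformer first, CNN second.
    """
    z_t = np.asarray(z_t, dtype=np.float64)
    z_c = np.asarray(z_c, dtype=np.float64)
    z = np.concatenate([z_t, z_c], axis=-1)
    if z.shape[-1] != params.input_dim:
        raise ShapeError(
            f"fusion head expects concatenated width {params.input_dim}, "
            f"received {z.shape[-1]} (= {z_t.shape[-1]} + {z_c.shape[-1]})")
    return params.normalize_input(z) @ params.W.T + params.b


def classify(z_p: np.ndarray, params: FusionHeadParams) -> np.ndarray:
    """Softmax class probabilities from the projected embedding."""
    z_p = np.asarray(z_p, dtype=np.float64)
    if z_p.shape[-1] != params.projection_dim:
        raise ShapeError(
            f"classifier expects width {params.projection_dim}, received {z_p.shape[-1]}")
    return softmax(z_p @ params.classifier_W.T + params.classifier_b, axis=-1)


class BaselineHead:
    """Transfer-learning head: GAP -> FC -> BN -> ReLU -> dropout -> FC(3) -> softmax.

    In eval mode dropout is the identity and BN uses running statistics.
    """

    def __init__(self, in_channels: int, hidden: int = 64, dropout: float = 0.3,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.dropout = dropout
        self.params = {
            "fc1_W": rng.normal(0, 1 / math.sqrt(in_channels), size=(hidden, in_channels)),
            "fc1_b": np.zeros(hidden),
            "bn_gamma": np.ones(hidden), "bn_beta": np.zeros(hidden),
            "bn_mean": np.zeros(hidden), "bn_var": np.ones(hidden),
            "fc2_W": rng.normal(0, 1 / math.sqrt(hidden), size=(N_CLASSES, hidden)),
            "fc2_b": np.zeros(N_CLASSES),
        }

    def forward(self, feature_maps: np.ndarray, train_mode: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        x = np.asarray(feature_maps, dtype=np.float64)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        z = x.mean(axis=(1, 2))  # GAP
        p = self.params
        h = z @ p["fc1_W"].T + p["fc1_b"]
        if train_mode and x.shape[0] > 1:
            mu, var = h.mean(axis=0), h.var(axis=0)
            p["bn_mean"] = 0.9 * p["bn_mean"] + 0.1 * mu
            p["bn_var"] = 0.9 * p["bn_var"] + 0.1 * var
        else:
            mu, var = p["bn_mean"], p["bn_var"]
        h = p["bn_gamma"] * (h - mu) / np.sqrt(var + 1e-5) + p["bn_beta"]
        h = np.maximum(h, 0.0)
        if train_mode and self.dropout > 0:
            if rng is None:
                raise ValueError("train_mode dropout requires an rng")
            mask = rng.random(h.shape) >= self.dropout
            h = h * mask / max(1e-12, 1.0 - self.dropout)
        probs = softmax(h @ p["fc2_W"].T + p["fc2_b"], axis=-1)
        return probs[0] if squeeze else probs


def baseline_head_forward(feature_maps: np.ndarray, head: BaselineHead,
                          train_mode: bool = False,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    return head.forward(feature_maps, train_mode=train_mode, rng=rng)


@dataclass
class FreezeAudit:
    """Outcome of applying a freeze policy to a backbone."""

    n_trainable_params: int
    n_frozen_params: int
    layers: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"n_trainable_params": self.n_trainable_params,
                "n_frozen_params": self.n_frozen_params, "layers": self.layers}


def apply_freeze_policy(backbone, trainable_tail_fraction: float,
                        freeze_bn: bool = True) -> FreezeAudit:
    """Freeze the leading layers of a backbone; optionally freeze all BN.

    Layers in the leading ``1 - trainable_tail_fraction`` portion of the
    ordered layer list become non-trainable.  With ``freeze_bn`` every batch
    normalization layer is frozen regardless of position and locked to its
    running statistics (the forward passes consult ``layer.trainable``).
    """
    if not 0.0 <= trainable_tail_fraction <= 1.0:
        raise ValueError("trainable_tail_fraction must lie in [0, 1]")
    layers: list[Layer] = backbone.layers
    n = len(layers)
    cutoff = math.floor((1.0 - trainable_tail_fraction) * n)
    n_trainable = n_frozen = 0
    rows = []
    for idx, layer in enumerate(layers):
        layer.trainable = idx >= cutoff
        if freeze_bn and layer.is_bn:
            layer.trainable = False
        (rows.append({"name": layer.name, "trainable": layer.trainable,
                      "is_bn": layer.is_bn, "n_params": layer.n_params}))
        if layer.trainable:
            n_trainable += layer.n_params
        else:
            n_frozen += layer.n_params
    return FreezeAudit(n_trainable, n_frozen, rows)


class HybridModel:
    """Dual-backbone fusion classifier: transformer + CNN branches and head."""

    def __init__(self, t_branch: TransformerBranch, c_branch: CNNBranch,
                 head: FusionHeadParams | None = None, projection_dim: int = 2048,
                 seed: int = 0):
        self.t_branch = t_branch
        self.c_branch = c_branch
        d_t, d_c = t_branch.spec.embed_dim, c_branch.spec.embed_dim
        self.head = head or FusionHeadParams.init(d_t, d_c, projection_dim, seed=seed)
        if self.head.input_dim != d_t + d_c:
            raise ShapeError(f"head expects input width {self.head.input_dim}, "
                             f"branches produce {d_t + d_c}")

    @property
    def fusion_input_dim(self) -> int:
        return self.t_branch.spec.embed_dim + self.c_branch.spec.embed_dim

    @classmethod
    def tiny(cls, seed: int = 0, projection_dim: int = 64,
             t_input: int = 64, c_input: int = 96) -> "HybridModel":
        """Small random-weight hybrid for desk-scale training and tests."""
        t = TransformerBranch(tiny_transformer_spec(input_size=t_input), seed=seed)
        c = CNNBranch(tiny_cnn_spec(input_size=c_input), seed=seed + 1)
        return cls(t, c, projection_dim=projection_dim, seed=seed + 2)

    def embed_views(self, tv: np.ndarray, cv: np.ndarray, train_mode: bool = False,
                    rng: np.random.Generator | None = None) -> np.ndarray:
        z_t = self.t_branch.forward(tv, train_mode=train_mode, rng=rng)
        z_c = self.c_branch.forward(cv, train_mode=train_mode)
        return np.concatenate([np.atleast_2d(z_t), np.atleast_2d(z_c)], axis=-1)

    def head_forward(self, z_concat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fusion-point embedding batch -> (z_p, probs)."""
        zn = self.head.normalize_input(z_concat)
        z_p = zn @ self.head.W.T + self.head.b
        probs = softmax(z_p @ self.head.classifier_W.T + self.head.classifier_b, axis=-1)
        return z_p, probs

    def head_backward(self, z_concat: np.ndarray, z_p: np.ndarray,
                      dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the head parameters given d loss / d logits."""
        grads = {
            "classifier_W": dlogits.T @ z_p,
            "classifier_b": dlogits.sum(axis=0),
        }
        dzp = dlogits @ self.head.classifier_W
        grads["W"] = dzp.T @ self.head.normalize_input(z_concat)
        grads["b"] = dzp.sum(axis=0)
        return grads

    def predict_proba(self, tv: np.ndarray, cv: np.ndarray) -> np.ndarray:
        z = self.embed_views(tv, cv)
        return self.head_forward(z)[1]

    def forward_views(self, tv: np.ndarray, cv: np.ndarray) -> np.ndarray:
        return self.predict_proba(tv, cv)

    def branch_param_snapshot(self) -> np.ndarray:
        """Flat copy of every branch parameter, for isolation assertions."""
        chunks = [p.ravel().copy()
                  for br in (self.t_branch, self.c_branch)
                  for layer in br.layers for p in layer.params.values()]
        return np.concatenate(chunks)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays: dict[str, np.ndarray] = {}
        for tag, br in (("t", self.t_branch), ("c", self.c_branch)):
            for layer in br.layers:
                for k, v in layer.params.items():
                    arrays[f"{tag}.{layer.name}.{k}"] = v
        for k, v in self.head.as_dict().items():
            arrays[f"head.{k}"] = v
        if self.head.input_mean is not None:
            arrays["head.input_mean"] = self.head.input_mean
            arrays["head.input_std"] = self.head.input_std
        np.savez_compressed(directory / "params.npz", **arrays)
        meta = {
            "transformer": vars(self.t_branch.spec) | {
                "patch_size": self.t_branch.patch_size,
                "depth": self.t_branch.depth, "n_heads": self.t_branch.n_heads},
            "cnn": vars(self.c_branch.spec) | {"channels": list(self.c_branch.channels)},
            "projection_dim": self.head.projection_dim,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=1, default=str),
                                              encoding="utf-8")

    def load_params(self, directory: str | Path) -> None:
        arrays = np.load(Path(directory) / "params.npz")
        for tag, br in (("t", self.t_branch), ("c", self.c_branch)):
            for layer in br.layers:
                for k in layer.params:
                    layer.params[k] = arrays[f"{tag}.{layer.name}.{k}"]
        for k in self.head.as_dict():
            setattr(self.head, k, arrays[f"head.{k}"])
        if "head.input_mean" in arrays:
            self.head.input_mean = arrays["head.input_mean"]
            self.head.input_std = arrays["head.input_std"]
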