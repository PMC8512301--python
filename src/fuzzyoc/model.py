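"""The network Phi: a pluggable backbone with normal and overclustering heads.

The backbone maps an image to a fixed-length feature vector; on top of it sit
two families of linear softmax heads:

* *normal* heads with ``k_GT`` outputs (one per ground-truth class);
* *overclustering* heads with ``k > k_GT`` outputs, exposing substructure
  within ambiguous classes.

Each family ships several independently initialized copies (default 5) that
share the backbone; training averages over the copies and evaluation selects
the best copy on validation data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "HeadConfig",
    "BackboneSpec",
    "MultiHeadNetwork",
    "build_model",
    "select_best_head",
    "sobel_channels",
]

NORMAL = "normal"
OVER = "overclustering"


@dataclass(frozen=True)
class HeadConfig:
    """One family of output heads."""

    kind: str  # "normal" | "overclustering"
    n_outputs: int
    copies: int = 5

    def __post_init__(self) -> None:
        if self.kind not in (NORMAL, OVER):
            raise ValueError(f"unknown head kind {self.kind!r}")
        if self.n_outputs < 2:
            raise ValueError("heads need at least 2 outputs")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")


@dataclass(frozen=True)
class BackboneSpec:
    """Architecture of the feature extractor.

    ``tiny_cnn`` is a small stack of strided 3x3 convolutions over the raw
    input channels (RGB, or 2 for sobel-filtered input), sized for CPU
    training on small images.

    ``shape_color`` runs the same convolution stack over the *value* channel
    (per-pixel max over RGB) only and appends the pooled mean color of the
    foreground to the feature vector.  Shape features are thereby
    structurally independent of hue -- the same decoupling motive behind
    feeding sobel-filtered images to networks trained without pretrained
    weights -- which matters when the training colors cover only a few hues
    but test images span the whole hue circle.

    ``pretrained`` optionally points at a checkpoint whose backbone weights
    are loaded (never downloaded implicitly).
    """

    name: str = "shape_color"
    in_channels: int = 3
    channels: tuple[int, ...] = (12, 24, 48)
    pool: str = "flatten"  # "flatten" keeps the spatial layout, "avg" pools it
    image_size: int = 16
    pretrained: str | None = None

    @property
    def cnn_dim(self) -> int:
        if self.pool == "avg":
            return self.channels[-1]
        side = self.image_size // (2 ** len(self.channels))
        return self.channels[-1] * side * side

    @property
    def feature_dim(self) -> int:
        return self.cnn_dim + (3 if self.name == "shape_color" else 0)


def sobel_channels(image: np.ndarray) -> np.ndarray:
    """Fixed 2-channel horizontal/vertical Sobel gradient transform.

    Kernels: Gx = [[-1,0,1],[-2,0,2],[-1,0,1]], Gy = Gx^T, applied to the
    luminance (channel mean) of an (H, W, C) or (H, W) image in [0, 1].
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    gx_k = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float32)
    padded = np.pad(img, 1, mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, (3, 3))
    gx = (win * gx_k).sum(axis=(-1, -2))
    gy = (win * gx_k.T).sum(axis=(-1, -2))
    return np.stack([gx, gy], axis=-1)


def _build_backbone(spec: BackboneSpec, rng: np.random.Generator) -> nn.Sequential:
    if spec.name not in ("tiny_cnn", "shape_color"):
        raise ValueError(f"unknown backbone {spec.name!r}")
    layers: list[nn.Layer] = []
    c_in = 1 if spec.name == "shape_color" else spec.in_channels
    for i, c_out in enumerate(spec.channels):
        layers.append(
            nn.Conv2d(c_in, c_out, kernel_size=3, stride=2, rng=rng, input_grad=i > 0)
        )
        layers.append(nn.ReLU())
        c_in = c_out
    if spec.pool == "avg":
        layers.append(nn.GlobalAvgPool())
    elif spec.pool == "flatten":
        layers.append(nn.Flatten())
    else:
        raise ValueError(f"unknown pool {spec.pool!r}")
    return nn.Sequential(*layers)


class MultiHeadNetwork:
    """Backbone + multiple softmax heads of both kinds."""

    def __init__(
        self,
        backbone_spec: BackboneSpec,
        head_configs: list[HeadConfig],
        seed: int = 0,
    ) -> None:
        self.backbone_spec = backbone_spec
        self.head_configs = list(head_configs)
        self.seed = seed
        rng = np.random.default_rng([seed, 0])
        self.backbone = _build_backbone(backbone_spec, rng)
        self.heads: dict[str, list[nn.Linear]] = {NORMAL: [], OVER: []}
        head_id = 0
        for cfg in head_configs:
            for _copy in range(cfg.copies):
                # independent initialization per copy
                head_rng = np.random.default_rng([seed, 1, head_id])
                self.heads[cfg.kind].append(
                    nn.Linear(backbone_spec.feature_dim, cfg.n_outputs, rng=head_rng)
                )
                head_id += 1
        self._probs_cache: dict[str, list[np.ndarray]] = {}

    # -- forward / backward -------------------------------------------------

    def features(self, x: np.ndarray) -> np.ndarray:
        """Backbone features for a (N, H, W, C) float32 batch.

        For the ``shape_color`` backbone the convolution stack sees only the
        value channel; the mean foreground color (mean RGB divided by the
        foreground area) is appended to the feature vector.
        """
        if self.backbone_spec.name == "shape_color":
            v = x.max(axis=-1, keepdims=True)
            f = self.backbone.forward(np.ascontiguousarray(v))
            area = np.maximum(v.mean(axis=(1, 2)), 1e-3)
            stats = (x.mean(axis=(1, 2)) / area).astype(np.float32)
            return np.concatenate([f, stats], axis=1)
        return self.backbone.forward(x)

    def backbone_backward(self, grad_features: np.ndarray) -> None:
        """Backward through the backbone, dropping the color-stat columns."""
        if self.backbone_spec.name == "shape_color":
            grad_features = np.ascontiguousarray(
                grad_features[:, : self.backbone_spec.cnn_dim]
            )
        self.backbone.backward(grad_features)

    def head_probs(self, features: np.ndarray, kind: str) -> list[np.ndarray]:
        """Softmax outputs of every head copy of the given kind."""
        probs = [nn.softmax(h.forward(features)) for h in self.heads[kind]]
        self._probs_cache[kind] = probs
        return probs

    def predict_probs(self, x: np.ndarray, kind: str, head: int) -> np.ndarray:
        """Inference-mode class probabilities of one head (deterministic)."""
        return nn.softmax(self.heads[kind][head].forward(self.features(x)))

    # -- stacked fast path (all copies of one family in single matmuls) ----

    def head_probs_stacked(self, features: np.ndarray, kind: str) -> np.ndarray:
        """(n_copies, N, k) softmax outputs via one fused matmul."""
        heads = self.heads[kind]
        W = np.stack([h.W for h in heads])  # (H, k, F)
        b = np.stack([h.b for h in heads])  # (H, k)
        logits = np.einsum("nf,hkf->hnk", features, W, optimize=True) + b[:, None, :]
        z = logits - logits.max(axis=-1, keepdims=True)
        np.exp(z, out=z)
        z /= z.sum(axis=-1, keepdims=True)
        self._stack_cache = (kind, features, z)
        return z

    def heads_backward_stacked(
        self, kind: str, grad_probs: np.ndarray, grad_logits: np.ndarray
    ) -> np.ndarray:
        """Backward for the stacked path; accumulates per-head grads, returns
        the summed feature gradient."""
        ckind, features, probs = self._stack_cache
        assert ckind == kind
        dot = (grad_probs * probs).sum(axis=-1, keepdims=True)
        dz = probs * (grad_probs - dot) + grad_logits  # (H, N, k)
        heads = self.heads[kind]
        dW = np.einsum("hnk,nf->hkf", dz, features, optimize=True)
        for h, dWh, dbh in zip(heads, dW, dz.sum(axis=1)):
            h.dW += dWh
            h.db += dbh
        W = np.stack([h.W for h in heads])
        return np.einsum("hnk,hkf->nf", dz, W, optimize=True)

    def heads_backward(
        self,
        kind: str,
        grad_probs: list[np.ndarray],
        grad_logits: list[np.ndarray] | None = None,
    ) -> np.ndarray:
        """Backprop per-copy gradients through softmax+linear; sum feature grads.

        ``grad_probs`` flows through the softmax Jacobian; ``grad_logits``
        (e.g. the fused cross-entropy gradient) is added directly to the
        logit gradient of the matching head copy.
        """
        probs = self._probs_cache[kind]
        grad_features = None
        for i, (head, p, g) in enumerate(zip(self.heads[kind], probs, grad_probs)):
            gz = nn.softmax_backward(p, g)
            if grad_logits is not None:
                gz = gz + grad_logits[i]
            gf = head.backward(gz)
            grad_features = gf if grad_features is None else grad_features + gf
        return grad_features

    # -- parameter access ---------------------------------------------------

    def head_params(self, kind: str | None = None) -> list[dict]:
        kinds = [kind] if kind else [NORMAL, OVER]
        return [p for k in kinds for h in self.heads[k] for p in h.params()]

    def all_params(self) -> list[dict]:
        return self.backbone.params() + self.head_params()

    def zero_grads(self) -> None:
        for p in self.all_params():
            p["grad"][...] = 0.0

    def n_heads(self, kind: str) -> int:
        return len(self.heads[kind])

    @property
    def k_gt(self) -> int:
        return self.heads[NORMAL][0].b.size if self.heads[NORMAL] else 0

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        """Save weights + config (and optional metadata) to an .npz + .json pair."""
        path = Path(path)
        arrays = {}
        for i, p in enumerate(self.all_params()):
            arrays[f"param_{i}"] = p["value"]
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "backbone": {
                "name": self.backbone_spec.name,
                "in_channels": self.backbone_spec.in_channels,
                "channels": list(self.backbone_spec.channels),
            },
            "heads": [
                {"kind": c.kind, "n_outputs": c.n_outputs, "copies": c.copies}
                for c in self.head_configs
            ],
            "seed": self.seed,
            "extra": extra or {},
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MultiHeadNetwork":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        spec = BackboneSpec(
            name=meta["backbone"]["name"],
            in_channels=meta["backbone"]["in_channels"],
            channels=tuple(meta["backbone"]["channels"]),
        )
        heads = [
            HeadConfig(kind=h["kind"], n_outputs=h["n_outputs"], copies=h["copies"])
            for h in meta["heads"]
        ]
        model = cls(spec, heads, seed=meta["seed"])
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(model.all_params()):
            p["value"][...] = data[f"param_{i}"]
        return model


def build_model(
    backbone: BackboneSpec,
    heads: list[HeadConfig],
    seed: int = 0,
) -> MultiHeadNetwork:
    """Construct the multi-head network, validating the head configuration.

    The full framework needs at least one normal and one overclustering head;
    every overclustering head must have strictly more outputs than the
    normal (k_GT-way) heads.
    """
    k_gt_values = {c.n_outputs for c in heads if c.kind == NORMAL}
    if len(k_gt_values) > 1:
        raise ValueError("all normal heads must share the same output count")
    k_gt = k_gt_values.pop() if k_gt_values else None
    if k_gt is not None:
        for c in heads:
            if c.kind == OVER and c.n_outputs <= k_gt:
                raise ValueError(
                    f"overclustering head k={c.n_outputs} must exceed k_GT={k_gt}"
                )
    return MultiHeadNetwork(backbone, heads, seed=seed)


def select_best_head(per_head_validation_scores) -> int:
    """Index of the head with the highest validation score (ties: lowest index)."""
    scores = list(per_head_validation_scores)
    if not scores:
        raise ValueError("empty score list")
    return int(np.argmax(scores))
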