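"""Training orchestration: warm-up, alternating head training, fine-tuning.

The framework trains a shared backbone with two families of heads under the
combined loss ``L = lambda_s * Ls + lambda_u * Lu`` where

* Ls is cross-entropy on the normal heads and inverse cross-entropy on the
  overclustering heads (supervised triplets only);
* Lu is the negated mutual information of the batch joint distribution of
  the two augmented views, for both head families.

Head families are trained in alternation, one family per epoch.  Three
variants are supported:

* ``foc``        -- warm-up (lambda_s = 0, no supervised augmentations, the
                    mutual-information pretext task), then a heads-only
                    phase with a frozen backbone at a higher learning rate,
                    then full fine-tuning;
* ``foc-light``  -- lambda_u = 0 and no warm-up: supervised CE + CE^-1 only,
                    without repetitions (they exist to stabilize the joint
                    estimate, which FOC-Light does not use);
* ``warmup-only``-- the pretext task alone (lambda_s = 0 throughout).

The public entry point is the :class:`FuzzyOverclustering` model object whose
``fit()`` returns a :class:`FOCResults` with per-head validation scores,
unlabeled-split metrics, the training history and a ``summary()`` table.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import evaluation, losses, model as model_mod, pipeline
from .model import NORMAL, OVER

__all__ = [
    "TrainConfig",
    "TrainData",
    "Trainer",
    "FuzzyOverclustering",
    "FOCResults",
    "preset",
    "warmup",
    "finetune",
    "train_epoch",
]

VARIANTS = ("foc", "foc-light", "warmup-only")
PHASES = ("warmup", "heads_only", "full")


@dataclass(frozen=True)
class TrainConfig:
    """Every knob of a training run; YAML round-trippable."""

    variant: str = "foc"
    lambda_s: float = 1.0
    lambda_u: float = 1.0
    warmup_epochs: int = 4
    heads_only_epochs: int = 4
    main_epochs: int = 60
    lr_warmup: float = 3e-3
    lr_main: float = 3e-3
    lr_heads_only: float = 3e-3
    batch: pipeline.BatchSpec = field(
        default_factory=lambda: pipeline.BatchSpec(batch_size=252)
    )
    seed: int = 0
    image_size: int = 16
    overcluster_k: int = 30
    head_copies: int = 5
    backbone_name: str = "shape_color"
    backbone_channels: tuple[int, ...] = (16, 32, 64)
    augment_policy: str = "weak"
    aspect_jitter: float = 0.33
    lr_decay: str = "none"  # "cosine" anneals lr over the main phase, "none" keeps it flat
    mapping_split: str = "unlabeled"  # reference split for the cluster mapping
    eps: float = losses.DEFAULT_EPS

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.lambda_s < 0 or self.lambda_u < 0:
            raise ValueError("loss weights must be non-negative")
        if self.variant == "foc-light" and (self.lambda_u != 0 or self.warmup_epochs != 0):
            raise ValueError("foc-light requires lambda_u = 0 and no warm-up")
        if self.variant == "warmup-only" and self.lambda_s != 0:
            raise ValueError("warmup-only requires lambda_s = 0")
        if self.mapping_split not in ("train", "unlabeled"):
            raise ValueError("mapping_split must be 'train' or 'unlabeled'")

    @property
    def weights(self) -> losses.LossWeights:
        return losses.LossWeights(self.lambda_s, self.lambda_u)

    def to_yaml(self) -> str:
        d = self.__dict__.copy()
        d["batch"] = {
            "batch_size": self.batch.batch_size,
            "unlabeled_ratio": self.batch.unlabeled_ratio,
            "repetitions": self.batch.repetitions,
            "max_batches_per_epoch": self.batch.max_batches_per_epoch,
        }
        d["backbone_channels"] = list(self.backbone_channels)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        d = yaml.safe_load(text)
        if "batch" in d:
            d["batch"] = pipeline.BatchSpec(**d["batch"])
        if "backbone_channels" in d:
            d["backbone_channels"] = tuple(d["backbone_channels"])
        return cls(**d)


def preset(name: str = "desk", variant: str = "foc", seed: int = 0) -> TrainConfig:
    """Shipped configurations.

    ``desk`` trains a tiny CNN on 16x16 inputs with short schedules so a full
    run completes in minutes on one CPU; ``paper`` mirrors the published
    schedule (500 warm-up + 500 main epochs, 100 heads-only at 1e-3,
    learning rate 1e-4, 64x64 inputs, a wider backbone).
    """
    if name == "desk":
        base = TrainConfig(seed=seed)
    elif name == "paper":
        base = TrainConfig(
            warmup_epochs=500,
            heads_only_epochs=100,
            main_epochs=500,
            lr_warmup=1e-4,
            lr_main=1e-4,
            lr_heads_only=1e-3,
            image_size=64,
            backbone_channels=(32, 64, 128),
            seed=seed,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    if variant == "foc":
        return base
    if variant == "foc-light":
        return replace(
            base,
            variant="foc-light",
            lambda_u=0.0,
            warmup_epochs=0,
            heads_only_epochs=0,
            main_epochs=60 if name == "desk" else 500,
            batch=pipeline.BatchSpec(
                batch_size=42 if name == "desk" else base.batch.batch_size,
                unlabeled_ratio=0.0,  # no loss term consumes unlabeled data
                repetitions=1,
            ),
        )
    if variant == "warmup-only":
        return replace(
            base, variant="warmup-only", lambda_s=0.0, heads_only_epochs=0, main_epochs=0
        )
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# data container


def downsample(images: np.ndarray, size: int) -> np.ndarray:
    """Block-mean downsampling of (N, H, W, C) images to (N, size, size, C)."""
    n, h, w, c = images.shape
    if h == size and w == size:
        return images.astype(np.float32)
    if h % size or w % size:
        raise ValueError(f"image size {h}x{w} not divisible by {size}")
    f = h // size
    return (
        images.reshape(n, size, f, size, f, c).mean(axis=(2, 4)).astype(np.float32)
    )


@dataclass
class TrainData:
    """Images and labels in the form the trainer consumes (float32, [0, 1])."""

    labeled_images: np.ndarray
    labels: np.ndarray
    unlabeled_images: np.ndarray
    val_images: np.ndarray
    val_labels: np.ndarray
    eval_images: np.ndarray
    eval_labels: np.ndarray
    k_gt: int

    def __post_init__(self) -> None:
        self.class_indices = [
            np.flatnonzero(self.labels == c) for c in range(self.k_gt)
        ]
        self.other_class_indices = [
            np.flatnonzero(self.labels != c) for c in range(self.k_gt)
        ]

    @classmethod
    def from_splits(cls, train, validation, unlabeled, image_size: int) -> "TrainData":
        """Build trainer arrays from SYN-CE style splits.

        Labeled data are the train-split samples carrying a hard label; the
        unlabeled pool is the unlabeled split plus any unlabeled train-split
        samples (the fuzzy-mode case).  Evaluation truth on the unlabeled
        split is the most-likely class of each soft label.
        """

        def prep(images: np.ndarray) -> np.ndarray:
            return downsample(np.asarray(images, dtype=np.float32) / 255.0, image_size)

        k_gt = train.samples[0].soft_label.size
        lab = [s for s in train.samples if s.hard_label is not None]
        unl_extra = [s for s in train.samples if s.hard_label is None]
        val = [s for s in validation.samples if s.hard_label is not None]
        unl_imgs = np.stack(
            [s.image for s in unlabeled.samples] + [s.image for s in unl_extra]
        )
        return cls(
            labeled_images=prep(np.stack([s.image for s in lab])),
            labels=np.array([s.hard_label for s in lab]),
            unlabeled_images=prep(unl_imgs),
            val_images=prep(np.stack([s.image for s in val])),
            val_labels=np.array([s.hard_label for s in val]),
            eval_images=prep(unlabeled.images()),
            eval_labels=unlabeled.eval_labels(),
            k_gt=k_gt,
        )


# ---------------------------------------------------------------------------
# vectorized weak augmentation (used on whole batches for speed)


def _augment_batch(
    images: np.ndarray, rng: np.random.Generator, max_stretch: float = 0.18
) -> np.ndarray:
    """Vectorized weak augmentation: flip, affine jitter, brightness.

    The affine part combines a translation (~10% of the extent) with a mild
    anisotropic rescale (aspect jitter as in standard random-resized-crop
    pipelines), realized as one nearest-neighbour gather with zero fill.
    """
    x = images.copy()
    n, h, w, _ = x.shape
    flip = rng.random(n) < 0.5
    x[flip] = x[flip, :, ::-1]
    d = max(1, round(0.1 * h))
    ls = np.log(1.0 + max_stretch)
    sy = np.exp(rng.uniform(-ls, ls, n))
    sx = np.exp(rng.uniform(-ls, ls, n))
    ty = rng.integers(-d, d + 1, n)
    tx = rng.integers(-d, d + 1, n)
    c = (h - 1) / 2.0
    grid = np.arange(h)
    src_y = np.round((grid[None, :] - c) / sy[:, None] + c + ty[:, None]).astype(int)
    src_x = np.round((grid[None, :] - c) / sx[:, None] + c + tx[:, None]).astype(int)
    ok = (
        ((src_y >= 0) & (src_y < h))[:, :, None]
        & ((src_x >= 0) & (src_x < w))[:, None, :]
    )
    src_y = np.clip(src_y, 0, h - 1)
    src_x = np.clip(src_x, 0, w - 1)
    x = x[np.arange(n)[:, None, None], src_y[:, :, None], src_x[:, None, :]]
    x *= ok[..., None]
    scale = rng.uniform(0.8, 1.2, size=n).astype(np.float32)
    return np.clip(x * scale[:, None, None, None], 0.0, 1.0)


def _as_batch(x: np.ndarray) -> np.ndarray:
    """Network input: contiguous NHWC float32."""
    return np.ascontiguousarray(x, dtype=np.float32)


# ---------------------------------------------------------------------------
# trainer


class Trainer:
    """Runs the phase schedule on a model over TrainData."""

    def __init__(self, model: model_mod.MultiHeadNetwork, data: TrainData, config: TrainConfig):
        self.model = model
        self.data = data
        self.config = config
        self.history: list[dict] = []
        self.planner = pipeline.BatchPlanner(
            n_labeled=len(data.labels),
            n_unlabeled=len(data.unlabeled_images),
            spec=config.batch,
            seed=config.seed,
        )
        self._epoch_counter = 0
        self._optimizers: dict = {}
        self._best: dict = {}  # head kind -> (val score, param snapshot)

    # -- optimizers ---------------------------------------------------------

    def _make_optimizers(self, lr: float, heads_only: bool) -> None:
        from .nn import Adam

        self._optimizers = {
            NORMAL: Adam(self.model.head_params(NORMAL), lr=lr),
            OVER: Adam(self.model.head_params(OVER), lr=lr),
        }
        if not heads_only:
            self._optimizers["backbone"] = Adam(self.model.backbone.params(), lr=lr)

    # -- one batch ----------------------------------------------------------

    def _batch_sources(self, lab_idx, unl_idx, rng, supervised_augmentation: bool):
        """Resolve anchor/x2/x3 source indices for one batch (before repetition)."""
        d = self.data
        n_lab = len(lab_idx)
        x2_lab = np.empty(n_lab, dtype=int)
        x3_lab = np.empty(n_lab, dtype=int)
        for i, a in enumerate(lab_idx):
            y = d.labels[a]
            same = d.class_indices[y]
            if supervised_augmentation and len(same) > 1:
                while True:
                    j = same[rng.integers(len(same))]
                    if j != a:
                        break
            else:
                j = a
            x2_lab[i] = j
            other = d.other_class_indices[y]
            if len(other) == 0:
                raise ValueError("cannot draw an inverse example: only one class present")
            x3_lab[i] = other[rng.integers(len(other))]
        return x2_lab, x3_lab

    def _train_batch(
        self,
        head_type: str,
        lab_idx: np.ndarray,
        unl_idx: np.ndarray,
        rng: np.random.Generator,
        lam_s: float,
        lam_u: float,
        supervised_augmentation: bool,
        heads_only: bool,
        repetitions: int,
    ) -> dict:
        d, cfg = self.data, self.config
        n_lab, n_unl = len(lab_idx), len(unl_idx)
        need_x3 = lam_s > 0 and head_type == OVER and n_lab > 0

        x2_lab, x3_lab = self._batch_sources(lab_idx, unl_idx, rng, supervised_augmentation)

        # anchor and x2 source images, repeated `repetitions` times each; every
        # repetition is augmented independently
        anchor = np.concatenate(
            [d.labeled_images[lab_idx], d.unlabeled_images[unl_idx]]
            if n_unl
            else [d.labeled_images[lab_idx]]
        )
        x2_src = np.concatenate(
            [d.labeled_images[x2_lab], d.unlabeled_images[unl_idx]]
            if n_unl
            else [d.labeled_images[x2_lab]]
        )
        if not supervised_augmentation:
            x2_src = anchor
        reps = repetitions
        anchor_r = np.repeat(anchor, reps, axis=0)
        x2_r = np.repeat(x2_src, reps, axis=0)
        B = anchor_r.shape[0]
        n_sup = n_lab * reps
        y = np.repeat(d.labels[lab_idx], reps)

        # all streams are augmented in one vectorized call
        sources = [anchor_r, x2_r]
        if need_x3:
            sources.append(np.repeat(d.labeled_images[x3_lab], reps, axis=0))
        X = _as_batch(
            _augment_batch(np.concatenate(sources), rng, cfg.aspect_jitter)
        )

        feats = self.model.features(X)
        # all head copies of the family in one fused matmul: (H, rows, k)
        probs = self.model.head_probs_stacked(feats, head_type)
        H = probs.shape[0]
        g = np.zeros_like(probs)  # gradient wrt probabilities
        gz = np.zeros_like(probs)  # gradient wrt logits (fused CE)
        p1, p2 = probs[:, :B], probs[:, B : 2 * B]

        loss_sup_total = 0.0
        loss_mi_total = 0.0
        contributed = False
        if lam_s > 0 and n_sup > 0:
            rows = np.arange(n_sup)
            if head_type == NORMAL:
                # fused softmax+CE gradient, applied directly in logit space
                for off in (0, B):
                    sub = probs[:, off : off + n_sup]
                    picked = sub[:, rows, y]
                    loss_sup_total += 0.5 * float(
                        -np.log(np.maximum(picked, cfg.eps)).mean()
                    )
                    dz = sub.copy()
                    dz[:, rows, y] -= 1.0
                    gz[:, off : off + n_sup] += (0.5 * lam_s / (n_sup * H)) * dz
            else:
                p3 = probs[:, 2 * B :]
                one_minus = np.maximum(1.0 - p3, cfg.eps)
                log_om = np.log(one_minus)
                live = (1.0 - p3) > cfg.eps
                gq = np.zeros_like(p3)
                for off in (0, B):
                    ps = probs[:, off : off + n_sup]
                    loss_sup_total += 0.5 * float(-(ps * log_om).sum() / (n_sup * H))
                    g[:, off : off + n_sup] += (-0.5 * lam_s / (n_sup * H)) * log_om
                    gq += np.where(live, ps / one_minus, 0.0)
                g[:, 2 * B :] += (0.5 * lam_s / (n_sup * H)) * gq
            contributed = True
        if lam_u > 0:
            # per-head batch joint distributions and the negated MI
            Q = np.einsum("hbk,hbl->hkl", p1, p2, optimize=True) / B
            P = (Q + Q.transpose(0, 2, 1)) / 2.0
            m = P.sum(axis=2)
            logm = np.log(np.maximum(m, losses.MI_EPS))
            logs = (
                np.log(np.maximum(P, losses.MI_EPS))
                - logm[:, :, None]
                - logm[:, None, :]
            )
            loss_mi_total = -float((P * logs).sum() / H)
            dQ = -(logs - 1.0)  # d(-I)/dQ, symmetric
            g[:, :B] += (lam_u / (B * H)) * np.einsum(
                "hbl,hkl->hbk", p2, dQ, optimize=True
            )
            g[:, B : 2 * B] += (lam_u / (B * H)) * np.einsum(
                "hbk,hkl->hbl", p1, dQ, optimize=True
            )
            contributed = True
        total = lam_s * loss_sup_total + lam_u * loss_mi_total
        if not np.isfinite(total):
            raise RuntimeError(
                f"non-finite loss (sup={loss_sup_total}, mi={loss_mi_total}) "
                f"in {head_type} head training"
            )

        if contributed:
            self.model.zero_grads()
            grad_feats = self.model.heads_backward_stacked(head_type, g, gz)
            if not heads_only:
                self.model.backbone_backward(grad_feats)
                self._optimizers["backbone"].step()
            self._optimizers[head_type].step()
        return {"loss": total, "loss_sup": loss_sup_total, "loss_mi": loss_mi_total}

    # -- epochs and phases --------------------------------------------------

    def train_epoch(self, head_type: str, phase: str = "full") -> dict:
        """One pass over the labeled anchors, training one head family."""
        cfg = self.config
        lam_s = 0.0 if phase == "warmup" else cfg.lambda_s
        lam_u = cfg.lambda_u
        sup_aug = phase != "warmup"
        heads_only = phase == "heads_only"
        epoch = self._epoch_counter
        self._epoch_counter += 1
        if lam_s == 0 and lam_u == 0:
            row = {
                "epoch": epoch, "phase": phase, "head_type": head_type,
                "loss": 0.0, "loss_sup": 0.0, "loss_mi": 0.0, "n_batches": 0,
            }
            self.history.append(row)
            return row
        sums = {"loss": 0.0, "loss_sup": 0.0, "loss_mi": 0.0}
        n_batches = 0
        for b, (lab_idx, unl_idx) in enumerate(self.planner.epoch(epoch)):
            rng = np.random.default_rng([cfg.seed, 13, epoch, b])
            logs = self._train_batch(
                head_type, lab_idx, unl_idx, rng, lam_s, lam_u,
                supervised_augmentation=sup_aug, heads_only=heads_only,
                repetitions=cfg.batch.repetitions,
            )
            for k in sums:
                sums[k] += logs[k]
            n_batches += 1
        row = {
            "epoch": epoch,
            "phase": phase,
            "head_type": head_type,
            **{k: v / max(n_batches, 1) for k, v in sums.items()},
            "n_batches": n_batches,
        }
        self.history.append(row)
        return row

    def _alternate(self, n_epochs: int, phase: str) -> None:
        for i in range(n_epochs):
            head_type = NORMAL if i % 2 == 0 else OVER
            self.train_epoch(head_type, phase=phase)

    def warmup(self) -> None:
        """Mutual-information pretext training (lambda_s = 0, plain view pairs)."""
        if self.config.warmup_epochs == 0:
            return
        self._make_optimizers(self.config.lr_warmup, heads_only=False)
        self._alternate(self.config.warmup_epochs, "warmup")

    def finetune(self, track_best: bool = True) -> None:
        """Heads-only phase at the high learning rate, then full fine-tuning."""
        cfg = self.config
        if cfg.heads_only_epochs:
            self._make_optimizers(cfg.lr_heads_only, heads_only=True)
            self._alternate(cfg.heads_only_epochs, "heads_only")
        if cfg.main_epochs:
            self._make_optimizers(cfg.lr_main, heads_only=False)
            for i in range(cfg.main_epochs):
                if cfg.lr_decay == "cosine":
                    lr = cfg.lr_main * 0.5 * (
                        1.0 + np.cos(np.pi * i / max(cfg.main_epochs - 1, 1))
                    )
                    for opt in self._optimizers.values():
                        opt.lr = max(lr, cfg.lr_main / 30.0)
                head_type = NORMAL if i % 2 == 0 else OVER
                self.train_epoch(head_type, phase="full")
                if track_best and (i % 2 == 1 or i == cfg.main_epochs - 1):
                    self._track_best()
        if self._best:
            self.restore_best()

    def run(self) -> None:
        self.warmup()
        self.finetune()

    # -- model selection ----------------------------------------------------

    def _track_best(self) -> None:
        """Snapshot the parameters at each head family's best validation score.

        The two families peak at different epochs; keeping one snapshot per
        family means each is later evaluated at its own validation optimum,
        and selection of the normal heads is not polluted by the (noisier)
        overclustering validation signal.
        """
        scores = evaluate_heads(self.model, self.data, self.config)
        for kind in (NORMAL, OVER):
            score = max(scores[kind]["val_macro_f1"])
            if kind not in self._best or score > self._best[kind][0]:
                snapshot = [p["value"].copy() for p in self.model.all_params()]
                self._best[kind] = (score, snapshot)

    def restore_best(self, kind: str | None = None) -> None:
        """Load the snapshot with the best validation score (of one family,
        or of the better family when ``kind`` is None)."""
        if not self._best:
            return
        if kind is None:
            kind = max(self._best, key=lambda k: self._best[k][0])
        for p, saved in zip(self.model.all_params(), self._best[kind][1]):
            p["value"][...] = saved


# ---------------------------------------------------------------------------
# evaluation protocol


def _features_chunked(model, images: np.ndarray, chunk: int = 512) -> np.ndarray:
    X = _as_batch(images)
    return np.concatenate(
        [model.features(X[i : i + chunk]) for i in range(0, X.shape[0], chunk)]
    )


def evaluate_heads(model, data: TrainData, config: TrainConfig) -> dict:
    """Per-head validation and unlabeled-split metrics.

    Normal heads are scored directly; overclustering heads are first mapped
    to classes by majority vote on the mapping reference split (the unlabeled
    split for fuzzy data, the labeled training data otherwise).  Backbone
    features are computed once per image set and shared across heads.
    """
    from . import nn

    val_feats = _features_chunked(model, data.val_images)
    eval_feats = _features_chunked(model, data.eval_images)
    if config.mapping_split == "unlabeled":
        map_feats, map_truths = eval_feats, data.eval_labels
    else:
        map_feats, map_truths = _features_chunked(model, data.labeled_images), data.labels
    res: dict = {}
    for kind in (NORMAL, OVER):
        val_scores, eval_f1, eval_acc, mappings = [], [], [], []
        for head in model.heads[kind]:
            val_pred = np.argmax(nn.softmax(head.forward(val_feats)), axis=1)
            eval_pred = np.argmax(nn.softmax(head.forward(eval_feats)), axis=1)
            if kind == OVER:
                map_pred = (
                    eval_pred
                    if config.mapping_split == "unlabeled"
                    else np.argmax(nn.softmax(head.forward(map_feats)), axis=1)
                )
                mapping = evaluation.majority_mapping(
                    map_pred, map_truths, n_clusters=head.b.size
                )
                val_pred = mapping(val_pred)
                eval_pred = mapping(eval_pred)
                mappings.append(mapping)
            val_scores.append(evaluation.macro_f1(val_pred, data.val_labels, data.k_gt))
            eval_f1.append(evaluation.macro_f1(eval_pred, data.eval_labels, data.k_gt))
            eval_acc.append(evaluation.accuracy(eval_pred, data.eval_labels))
        res[kind] = {
            "val_macro_f1": val_scores,
            "unlabeled_macro_f1": eval_f1,
            "unlabeled_accuracy": eval_acc,
            "mappings": mappings or None,
        }
    return res


# ---------------------------------------------------------------------------
# spec-surface convenience wrappers


def warmup(model, data: TrainData, config: TrainConfig):
    """Run only the warm-up phase on a model; returns the model."""
    if config.variant == "foc-light":
        raise ValueError("foc-light does not use a warm-up")
    t = Trainer(model, data, config)
    t.warmup()
    return model


def finetune(model, data: TrainData, config: TrainConfig):
    """Run the heads-only + full fine-tuning schedule; returns the model."""
    t = Trainer(model, data, config)
    t._make_optimizers(config.lr_main, heads_only=False)
    t.finetune(track_best=False)
    return model


def train_epoch(model, data: TrainData, config: TrainConfig, head_type: str, phase: str = "full"):
    """One epoch of one head family; returns (model, log row)."""
    t = Trainer(model, data, config)
    t._make_optimizers(
        config.lr_heads_only if phase == "heads_only" else config.lr_main,
        heads_only=(phase == "heads_only"),
    )
    row = t.train_epoch(head_type, phase=phase)
    return model, row


# ---------------------------------------------------------------------------
# model-object facade


class FuzzyOverclustering:
    """Fuzzy-overclustering model bound to dataset splits.

    Parameters
    ----------
    data : TrainData
        Prepared images and labels (see :meth:`from_splits`).
    config : TrainConfig, optional
        Training configuration; defaults to the desk preset of the ``foc``
        variant.
    """

    def __init__(self, data: TrainData, config: TrainConfig | None = None):
        self.data = data
        self.config = config or preset("desk", "foc")

    @classmethod
    def from_splits(cls, train, validation, unlabeled, config: TrainConfig | None = None):
        config = config or preset("desk", "foc")
        data = TrainData.from_splits(train, validation, unlabeled, config.image_size)
        return cls(data, config)

    @classmethod
    def from_directory(cls, path, config: TrainConfig | None = None):
        from .synce import read_manifest

        train, val, unl = read_manifest(path)
        return cls.from_splits(train, val, unl, config)

    def fit(self, seed: int | None = None) -> "FOCResults":
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        heads = [
            model_mod.HeadConfig(NORMAL, self.data.k_gt, cfg.head_copies),
            model_mod.HeadConfig(OVER, cfg.overcluster_k, cfg.head_copies),
        ]
        net = model_mod.build_model(
            model_mod.BackboneSpec(
                name=cfg.backbone_name,
                channels=cfg.backbone_channels,
                image_size=cfg.image_size,
            ),
            heads,
            seed=cfg.seed,
        )
        t0 = time.time()
        trainer = Trainer(net, self.data, cfg)
        trainer.run()
        elapsed = time.time() - t0
        if trainer._best:
            # evaluate each head family at its own best-validation snapshot,
            # then leave the better family's weights in the returned model
            scores = {}
            for kind in (NORMAL, OVER):
                trainer.restore_best(kind)
                scores[kind] = evaluate_heads(net, self.data, cfg)[kind]
            trainer.restore_best()
        else:
            scores = evaluate_heads(net, self.data, cfg)
        return FOCResults(
            model=net,
            config=cfg,
            data=self.data,
            history=pd.DataFrame(trainer.history),
            head_scores=scores,
            fit_seconds=elapsed,
        )


@dataclass
class FOCResults:
    """Fitted framework: weights, per-head scores, diagnostics."""

    model: model_mod.MultiHeadNetwork
    config: TrainConfig
    data: TrainData
    history: pd.DataFrame
    head_scores: dict
    fit_seconds: float = 0.0

    @property
    def best_heads(self) -> dict:
        """Validation-selected head index per family (ties: lowest index)."""
        return {
            kind: model_mod.select_best_head(self.head_scores[kind]["val_macro_f1"])
            for kind in (NORMAL, OVER)
        }

    @property
    def unlabeled_macro_f1(self) -> dict:
        """Unlabeled-split macro-F1 of the validation-selected head, per family."""
        return {
            kind: self.head_scores[kind]["unlabeled_macro_f1"][self.best_heads[kind]]
            for kind in (NORMAL, OVER)
        }

    @property
    def headline_macro_f1(self) -> float:
        """Best unlabeled-split macro-F1 over the two head families."""
        return max(self.unlabeled_macro_f1.values())

    def predict(self, images: np.ndarray, kind: str = NORMAL, head: int | None = None):
        """Class/cluster probabilities for (N, H, W, 3) images in [0, 255] or [0, 1]."""
        imgs = np.asarray(images, dtype=np.float32)
        if imgs.max() > 1.5:
            imgs = imgs / 255.0
        imgs = downsample(imgs, self.config.image_size)
        h = self.best_heads[kind] if head is None else head
        return self.model.predict_probs(_as_batch(imgs), kind, h)

    def summary(self) -> str:
        rows = []
        for kind in (NORMAL, OVER):
            s = self.head_scores[kind]
            b = self.best_heads[kind]
            rows.append(
                f"  {kind:<15} best head {b}   "
                f"val F1 {s['val_macro_f1'][b]:.4f}   "
                f"unlabeled F1 {s['unlabeled_macro_f1'][b]:.4f}   "
                f"unlabeled acc {s['unlabeled_accuracy'][b]:.4f}"
            )
        lines = [
            "Fuzzy Overclustering results",
            "=" * 64,
            f"variant: {self.config.variant}   seed: {self.config.seed}   "
            f"lambda_s={self.config.lambda_s} lambda_u={self.config.lambda_u}",
            f"epochs: warmup {self.config.warmup_epochs}, heads-only "
            f"{self.config.heads_only_epochs}, main {self.config.main_epochs}"
            f"   fit time: {self.fit_seconds:.1f}s",
            f"labeled n={len(self.data.labels)}  unlabeled n="
            f"{len(self.data.unlabeled_images)}  k_GT={self.data.k_gt}  "
            f"k_over={self.config.overcluster_k}",
            "-" * 64,
            *rows,
            "-" * 64,
            f"headline unlabeled macro-F1: {self.headline_macro_f1:.4f}",
        ]
        return "\n".join(lines)
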