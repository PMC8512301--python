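"""Triplet construction and batch assembly.

Every training example is a triplet (x1, x2, x3) derived from one anchor
image x:

* unlabeled x: x1 and x2 are two independent augmentations of x, and x3 is
  an augmentation of a random other image from the full pool;
* labeled x: x1 is an augmentation of x, x2 is a *supervised augmentation* --
  an augmentation of a different image sharing x's label, mocking an ideal
  label-preserving transformation -- and x3 is an *inverse example*, an
  augmentation of an image whose label differs from x's.

Batches bound the unlabeled fraction by a ratio r (unlabeled data helps but
dominates runtime) and repeat each selected anchor several times with fresh
augmentations, which stabilizes the batch estimate of the joint cluster
distribution.  Unlabeled anchors are consumed from a seeded rotation over
reshuffled permutations, so every unlabeled image is eventually seen even
though each epoch touches only a part of the pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Sample",
    "Triplet",
    "BatchSpec",
    "augment",
    "make_triplet",
    "assemble_batches",
    "BatchPlanner",
]

LABELED = "labeled"
UNLABELED = "unlabeled"


@dataclass
class Sample:
    """One image with an optional hard label and a stable identity."""

    image: np.ndarray
    label: int | None
    origin: str  # labeled | unlabeled
    index: int = 0


@dataclass
class Triplet:
    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray
    supervised: bool
    y: int | None = None
    y_prime: int | None = None


@dataclass(frozen=True)
class BatchSpec:
    batch_size: int = 126
    unlabeled_ratio: float = 0.5
    repetitions: int = 3
    #: optional cap on batches per epoch (fixed compute per epoch); with a
    #: cap, large labeled pools are covered across epochs via the per-epoch
    #: reshuffle rather than within one epoch
    max_batches_per_epoch: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.unlabeled_ratio <= 1.0):
            raise ValueError("unlabeled_ratio must be in [0, 1]")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.batch_size < self.repetitions:
            raise ValueError("batch size must be >= repetitions")
        if self.max_batches_per_epoch is not None and self.max_batches_per_epoch < 1:
            raise ValueError("max_batches_per_epoch must be >= 1")

    @property
    def unique_per_batch(self) -> int:
        return self.batch_size // self.repetitions

    @property
    def unlabeled_per_batch(self) -> int:
        return int(np.floor(self.unlabeled_ratio * self.unique_per_batch))

    @property
    def labeled_per_batch(self) -> int:
        return self.unique_per_batch - self.unlabeled_per_batch


# ---------------------------------------------------------------------------
# augmentation


def _aug_identity(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return x.copy()


def _aug_hflip(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return x[:, ::-1].copy()


def _shift(x: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Translate with zero fill (the background is black)."""
    out = np.zeros_like(x)
    h, w = x.shape[:2]
    ys, yd = (dy, 0) if dy >= 0 else (0, -dy)
    xs, xd = (dx, 0) if dx >= 0 else (0, -dx)
    out[yd : h - ys, xd : w - xs] = x[ys:h - yd, xs:w - xd]
    return out


def _aug_weak(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random flip + random translation (~10% extent) + brightness jitter.

    Deliberately hue-preserving: on data whose class identity is carried by
    color, hue jitter would not be label-preserving in effect.
    """
    h, w = x.shape[:2]
    if rng.random() < 0.5:
        x = x[:, ::-1]
    max_d = max(1, round(0.1 * h))
    dy, dx = rng.integers(-max_d, max_d + 1, size=2)
    x = _shift(np.ascontiguousarray(x), int(dy), int(dx))
    scale = rng.uniform(0.8, 1.2)
    return np.clip(x.astype(np.float32) * scale, 0.0, 1.0 if x.max() <= 1.0 else 255.0)


AUGMENTATIONS = {
    "identity": _aug_identity,
    "hflip": _aug_hflip,
    "weak": _aug_weak,
}


def augment(x: np.ndarray, policy: str, rng: np.random.Generator) -> np.ndarray:
    """Apply a registered stochastic, seed-reproducible, label-preserving policy."""
    if policy not in AUGMENTATIONS:
        raise ValueError(f"unknown augmentation policy {policy!r}")
    return AUGMENTATIONS[policy](np.asarray(x), rng)


# ---------------------------------------------------------------------------
# triplets


def make_triplet(
    x: Sample,
    labeled_pool: list[Sample],
    full_pool: list[Sample],
    rng: np.random.Generator,
    policy: str = "weak",
    supervised_augmentation: bool = True,
) -> Triplet:
    """Build the three inputs for one anchor sample.

    With ``supervised_augmentation=False`` (warm-up) labeled anchors are
    treated like unlabeled ones for x1/x2, while x3 remains an inverse
    example when a label is available.
    """
    supervised = x.label is not None
    x1 = augment(x.image, policy, rng)
    if supervised and supervised_augmentation:
        same = [s for s in labeled_pool if s.label == x.label and s.index != x.index]
        source2 = same[rng.integers(len(same))] if same else x
        x2 = augment(source2.image, policy, rng)
    else:
        x2 = augment(x.image, policy, rng)
    if supervised:
        different = [s for s in labeled_pool if s.label != x.label]
        if not different:
            raise ValueError("cannot draw an inverse example: only one class present")
        source3 = different[rng.integers(len(different))]
        return Triplet(
            x1=x1,
            x2=x2,
            x3=augment(source3.image, policy, rng),
            supervised=True,
            y=x.label,
            y_prime=source3.label,
        )
    others = [s for s in full_pool if s.index != x.index]
    source3 = others[rng.integers(len(others))] if others else x
    return Triplet(x1=x1, x2=x2, x3=augment(source3.image, policy, rng), supervised=False)


# ---------------------------------------------------------------------------
# batch assembly


class BatchPlanner:
    """Index-level batch schedule with the restricted unlabeled ratio.

    Labeled anchors are reshuffled every epoch and each appears once per
    epoch; unlabeled anchors come from an endless rotation over reshuffled
    permutations of the unlabeled pool (permutation j is seeded by
    (seed, j)), so coverage of the whole pool is guaranteed over epochs and
    the schedule is reproducible from (seed, epoch index) alone.
    """

    def __init__(self, n_labeled: int, n_unlabeled: int, spec: BatchSpec, seed: int = 0):
        if n_labeled == 0 and spec.labeled_per_batch > 0:
            raise ValueError("labeled pool must be non-empty")
        self.n_labeled = n_labeled
        self.n_unlabeled = n_unlabeled
        self.spec = spec
        self.seed = seed
        lab = spec.labeled_per_batch
        if lab > 0 and n_labeled > 0:
            self.batches_per_epoch = max(1, n_labeled // min(lab, n_labeled))
        else:
            self.batches_per_epoch = max(1, n_unlabeled // spec.unique_per_batch)
        if spec.max_batches_per_epoch is not None:
            self.batches_per_epoch = min(
                self.batches_per_epoch, spec.max_batches_per_epoch
            )

    def _unlabeled_at(self, position: int) -> int:
        """Index of the rotation's ``position``-th unlabeled draw."""
        cycle, offset = divmod(position, self.n_unlabeled)
        if getattr(self, "_perm_cycle", None) != cycle:
            self._perm = np.random.default_rng(
                [self.seed, 7, cycle]
            ).permutation(self.n_unlabeled)
            self._perm_cycle = cycle
        return int(self._perm[offset])

    def epoch(self, epoch_index: int):
        """Yield (labeled_indices, unlabeled_indices) per batch for one epoch."""
        spec = self.spec
        lab_n = min(spec.labeled_per_batch, self.n_labeled)
        unl_n = spec.unlabeled_per_batch if self.n_unlabeled else 0
        rng = np.random.default_rng([self.seed, 11, epoch_index])
        lab_perm = rng.permutation(self.n_labeled) if self.n_labeled else np.array([], int)
        base = epoch_index * self.batches_per_epoch * unl_n
        for b in range(self.batches_per_epoch):
            lab_idx = lab_perm[b * lab_n : (b + 1) * lab_n]
            unl_idx = np.array(
                [self._unlabeled_at(base + b * unl_n + i) for i in range(unl_n)],
                dtype=int,
            )
            yield lab_idx, unl_idx


def assemble_batches(
    labeled: list[Sample],
    unlabeled: list[Sample],
    spec: BatchSpec,
    seed: int = 0,
    n_epochs: int = 1,
):
    """Stream batches of Samples over ``n_epochs`` epochs.

    Each selected anchor appears ``spec.repetitions`` times consecutively in
    its batch; every batch holds at most ``floor(r * batch_size)`` unlabeled
    entries.
    """
    if not labeled and spec.labeled_per_batch > 0:
        raise ValueError("labeled pool must be non-empty")
    planner = BatchPlanner(len(labeled), len(unlabeled), spec, seed=seed)
    for epoch in range(n_epochs):
        for lab_idx, unl_idx in planner.epoch(epoch):
            batch: list[Sample] = []
            for i in lab_idx:
                batch.extend([labeled[i]] * spec.repetitions)
            for i in unl_idx:
                batch.extend([unlabeled[i]] * spec.repetitions)
            yield batch
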