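"""SYN-CE: a synthetic benchmark of colored circles and ellipses with fuzzy labels.

Each image shows a single filled "bubble" (an ellipse, possibly a circle) on a
black background.  Two continuous generative factors determine the class:

* the hue of the bubble's color -- red (0 deg), green (120 deg) and blue
  (240 deg) are the *certain* anchors;
* the ratio of the major to the minor axis -- 1 (circle) and 2 (ellipse) are
  the certain anchors.

The soft ground-truth label over the six classes (red/green/blue x
circle/ellipse) is the outer product of a color distribution ``p_c``
(piecewise-linear interpolation of the hue between its two neighbouring
primaries) and a geometry distribution ``p_g`` (linear interpolation of the
axis ratio between circle and ellipse).  A sample is *certain* exactly when
both factors sit on an anchor, i.e. when the label is one-hot.

Three labeling modes turn the soft labels into the hard labels used for
training:

* ``ideal`` -- every sample is labeled with the argmax of its soft label;
* ``real``  -- every sample's hard label is drawn from its soft label,
  emulating a single (possibly "wrong") annotation;
* ``fuzzy`` -- only certain samples receive hard labels; fuzzy samples are
  left unlabeled and are consumed as unlabeled data.
"""

from __future__ import annotations

import colorsys
import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "CLASS_NAMES",
    "PRIMARY_HUES",
    "BubbleSpec",
    "SynCESample",
    "SynCESplit",
    "color_distribution",
    "geometry_distribution",
    "fuzzy_label",
    "render_bubble",
    "generate_splits",
    "write_dataset",
    "read_manifest",
]

#: Fixed class order: colors row-major, geometry fastest.
CLASS_NAMES = (
    "red-circle",
    "red-ellipse",
    "green-circle",
    "green-ellipse",
    "blue-circle",
    "blue-ellipse",
)

PRIMARY_HUES = (0.0, 120.0, 240.0)

N_CLASSES = 6

#: hue margin (degrees) / axis-ratio margin kept clear of the certain anchors
#: when sampling fuzzy factors, so fuzzy labels are never one-hot.
FUZZY_HUE_MARGIN = 5.0
FUZZY_RATIO_MARGIN = 0.05


# ---------------------------------------------------------------------------
# label geometry


def color_distribution(hue: float) -> np.ndarray:
    """Probabilities over (red, green, blue) for a hue in degrees.

    The mass is shared between the two primary hues adjacent to ``hue``,
    linearly in angular distance; hues in (240, 360) interpolate blue and red
    around the hue circle.  One-hot exactly at 0, 120 and 240 degrees.
    """
    hue = float(hue)
    if not (0.0 <= hue < 360.0):
        raise ValueError(f"hue must be in [0, 360), got {hue}")
    p = np.zeros(3)
    if hue <= 120.0:  # red -> green
        t = hue / 120.0
        p[0], p[1] = 1.0 - t, t
    elif hue <= 240.0:  # green -> blue
        t = (hue - 120.0) / 120.0
        p[1], p[2] = 1.0 - t, t
    else:  # blue -> red (wraps at 360)
        t = (hue - 240.0) / 120.0
        p[2], p[0] = 1.0 - t, t
    return p


def geometry_distribution(axis_ratio: float) -> np.ndarray:
    """Probabilities over (circle, ellipse) for a major/minor axis ratio in [1, 2]."""
    axis_ratio = float(axis_ratio)
    if not (1.0 <= axis_ratio <= 2.0):
        raise ValueError(f"axis_ratio must be in [1, 2], got {axis_ratio}")
    return np.array([2.0 - axis_ratio, axis_ratio - 1.0])


def fuzzy_label(pc: np.ndarray, pg: np.ndarray) -> np.ndarray:
    """Soft label over the six classes: the flattened outer product pc x pg."""
    pc = np.asarray(pc, dtype=float)
    pg = np.asarray(pg, dtype=float)
    if pc.shape != (3,) or pg.shape != (2,):
        raise ValueError("pc must have 3 entries, pg 2")
    for name, v in (("pc", pc), ("pg", pg)):
        if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} is not a probability vector: {v}")
    return np.outer(pc, pg).ravel()


# ---------------------------------------------------------------------------
# rendering


@dataclass(frozen=True)
class BubbleSpec:
    """Geometry and color of a single bubble on a square canvas."""

    hue: float
    axis_ratio: float
    center: tuple[float, float]
    major_axis: float
    rotation: float = 0.0
    image_size: int = 64

    def __post_init__(self) -> None:
        if not (0.0 <= self.hue < 360.0):
            raise ValueError(f"hue must be in [0, 360), got {self.hue}")
        if not (1.0 <= self.axis_ratio <= 2.0):
            raise ValueError(f"axis_ratio must be in [1, 2], got {self.axis_ratio}")
        if self.major_axis <= 0:
            raise ValueError("major_axis must be positive")
        # conservative containment: bound by the semi-major axis regardless of
        # rotation
        a = self.major_axis / 2.0
        cx, cy = self.center
        s = self.image_size
        if cx - a < 0 or cy - a < 0 or cx + a > s - 1 or cy + a > s - 1:
            raise ValueError("bubble does not fit inside the image")

    @property
    def rgb(self) -> tuple[float, float, float]:
        """Full saturation/value RGB color of the bubble, in [0, 1]."""
        return colorsys.hsv_to_rgb(self.hue / 360.0, 1.0, 1.0)


def render_bubble(spec: BubbleSpec, rng_seed: int = 0) -> np.ndarray:
    """Render a bubble as an (H, W, 3) uint8 RGB image on a black background.

    Rendering is a pure function of the spec; ``rng_seed`` is accepted for
    interface stability (stochastic render effects are not used).
    """
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    cx, cy = spec.center
    theta = np.deg2rad(spec.rotation)
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    a = spec.major_axis / 2.0
    b = a / spec.axis_ratio
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    img = np.zeros((s, s, 3), dtype=np.uint8)
    color = np.round(np.array(spec.rgb) * 255).astype(np.uint8)
    img[mask] = color
    return img


# ---------------------------------------------------------------------------
# dataset generation


@dataclass
class SynCESample:
    """One generated image with its full ground truth."""

    image: np.ndarray
    soft_label: np.ndarray
    certain: bool
    hard_label: int | None
    hue: float
    axis_ratio: float
    spec: BubbleSpec

    @property
    def eval_label(self) -> int:
        """Most-likely class, used as evaluation ground truth (ties: lowest id)."""
        return int(np.argmax(self.soft_label))


@dataclass
class SynCESplit:
    """A train/validation/unlabeled split of SYN-CE samples."""

    samples: list[SynCESample]
    role: str  # train | validation | unlabeled
    mode: str  # ideal | real | fuzzy

    def __len__(self) -> int:
        return len(self.samples)

    def images(self) -> np.ndarray:
        return np.stack([s.image for s in self.samples])

    def soft_labels(self) -> np.ndarray:
        return np.stack([s.soft_label for s in self.samples])

    def eval_labels(self) -> np.ndarray:
        return np.array([s.eval_label for s in self.samples])

    def hard_labels(self) -> list[int | None]:
        return [s.hard_label for s in self.samples]

    @property
    def n_certain(self) -> int:
        return sum(s.certain for s in self.samples)

    @property
    def n_fuzzy(self) -> int:
        return len(self.samples) - self.n_certain


def _sample_factors(certain: bool, rng: np.random.Generator) -> tuple[float, float]:
    """Draw (hue, axis_ratio); certain factors sit on anchors, fuzzy ones off."""
    if certain:
        hue = float(rng.choice(PRIMARY_HUES))
        ratio = float(rng.choice([1.0, 2.0]))
        return hue, ratio
    while True:
        hue = float(rng.uniform(0.0, 360.0))
        # distance on the hue circle to the nearest primary
        dist = min(min(abs(hue - h), 360.0 - abs(hue - h)) for h in PRIMARY_HUES)
        if dist >= FUZZY_HUE_MARGIN:
            break
    ratio = float(
        rng.uniform(1.0 + FUZZY_RATIO_MARGIN, 2.0 - FUZZY_RATIO_MARGIN)
    )
    return hue, ratio


def _make_sample(
    certain: bool, mode: str, image_size: int, rng: np.random.Generator
) -> SynCESample:
    hue, ratio = _sample_factors(certain, rng)
    major = rng.uniform(0.3, 0.6) * image_size
    a = major / 2.0
    cx = rng.uniform(a, image_size - 1 - a)
    cy = rng.uniform(a, image_size - 1 - a)
    rotation = rng.uniform(0.0, 180.0)
    spec = BubbleSpec(
        hue=hue,
        axis_ratio=ratio,
        center=(cx, cy),
        major_axis=major,
        rotation=rotation,
        image_size=image_size,
    )
    label = fuzzy_label(color_distribution(hue), geometry_distribution(ratio))
    if mode == "ideal":
        hard: int | None = int(np.argmax(label))
    elif mode == "real":
        hard = int(rng.choice(N_CLASSES, p=label))
    elif mode == "fuzzy":
        hard = int(np.argmax(label)) if certain else None
    else:
        raise ValueError(f"unknown subset mode {mode!r}")
    return SynCESample(
        image=render_bubble(spec),
        soft_label=label,
        certain=certain,
        hard_label=hard,
        hue=hue,
        axis_ratio=ratio,
        spec=spec,
    )


def generate_splits(
    n_certain: int = 1800,
    n_fuzzy: int = 1000,
    subset_mode: str = "fuzzy",
    seed: int = 0,
    image_size: int = 64,
) -> tuple[SynCESplit, SynCESplit, SynCESplit]:
    """Generate the train, validation and unlabeled splits of SYN-CE.

    Each split holds ``n_certain`` certain and ``n_fuzzy`` fuzzy images, drawn
    independently.  The ``subset_mode`` (ideal/real/fuzzy) controls how hard
    labels are assigned; in fuzzy mode the fuzzy samples of every split carry
    no hard label and are used as unlabeled data only.  Fully reproducible
    from ``seed``.
    """
    if n_certain <= 0 or n_fuzzy <= 0:
        raise ValueError("sample counts must be positive")
    if subset_mode not in ("ideal", "real", "fuzzy"):
        raise ValueError(f"unknown subset mode {subset_mode!r}")
    splits = []
    for i, role in enumerate(("train", "validation", "unlabeled")):
        rng = np.random.default_rng([seed, i])
        samples = [
            _make_sample(True, subset_mode, image_size, rng) for _ in range(n_certain)
        ] + [
            _make_sample(False, subset_mode, image_size, rng) for _ in range(n_fuzzy)
        ]
        splits.append(SynCESplit(samples=samples, role=role, mode=subset_mode))
    return tuple(splits)


# ---------------------------------------------------------------------------
# on-disk format: PNG directory + CSV manifest

MANIFEST_COLUMNS = (
    ["filename", "split", "certain", "hard_label"]
    + [f"p_{name}" for name in CLASS_NAMES]
    + ["hue", "axis_ratio", "seed"]
)


def write_dataset(
    splits: tuple[SynCESplit, SynCESplit, SynCESplit],
    outdir: str | Path,
    seed: int = 0,
) -> Path:
    """Write PNG images plus a ``manifest.csv`` carrying the ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for split in splits:
        split_dir = outdir / split.role
        split_dir.mkdir(exist_ok=True)
        for j, s in enumerate(split.samples):
            fname = f"{split.role}/{j:05d}.png"
            Image.fromarray(s.image).save(outdir / fname)
            rows.append(
                [fname, split.role, int(s.certain),
                 "" if s.hard_label is None else s.hard_label]
                + [f"{p:.8f}" for p in s.soft_label]
                + [f"{s.hue:.6f}", f"{s.axis_ratio:.6f}", seed]
            )
    with open(outdir / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(MANIFEST_COLUMNS)
        w.writerows(rows)
    return outdir / "manifest.csv"


def read_manifest(path: str | Path, load_images: bool = True):
    """Read a manifest (and optionally its images) back into SynCESplit objects."""
    import pandas as pd

    path = Path(path)
    if path.is_dir():
        path = path / "manifest.csv"
    df = pd.read_csv(path, keep_default_na=False)
    root = path.parent
    splits = {}
    mode = "fuzzy"  # mode is implicit in the labeling; carried for bookkeeping
    for role in ("train", "validation", "unlabeled"):
        sub = df[df["split"] == role]
        samples = []
        for _, row in sub.iterrows():
            img = (
                np.asarray(Image.open(root / row["filename"]).convert("RGB"))
                if load_images
                else None
            )
            soft = np.array([row[f"p_{n}"] for n in CLASS_NAMES], dtype=float)
            hard = row["hard_label"]
            hard = None if hard == "" else int(hard)
            samples.append(
                SynCESample(
                    image=img,
                    soft_label=soft,
                    certain=bool(int(row["certain"])),
                    hard_label=hard,
                    hue=float(row["hue"]),
                    axis_ratio=float(row["axis_ratio"]),
                    spec=None,  # not reconstructed from disk
                )
            )
        splits[role] = SynCESplit(samples=samples, role=role, mode=mode)
    return splits["train"], splits["validation"], splits["unlabeled"]
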