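"""Evaluation: micro accuracy, macro F1, cluster-to-class mapping, consistency.

Overclustering heads predict into k > k_GT clusters, so classification metrics
need a surjective map from clusters to ground-truth classes first.  The map
assigns every non-empty cluster to the majority true class among its members
(ties: lowest class id).  On fuzzy datasets the map is derived on the
unlabeled split, where the fuzzy images live.

Accuracy is micro-averaged over per-class confusion counts; the F1 score is
macro-averaged (unweighted mean of per-class F1) because the class
distribution of fuzzy data is typically skewed.  A class absent from both
predictions and truths contributes F1 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "ClusterMapping",
    "ConsistencyReport",
    "confusion_counts",
    "accuracy",
    "macro_f1",
    "majority_mapping",
    "consistency",
    "consistency_from_csv",
]

UNMAPPED = -1


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class one-vs-rest confusion counts."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n_samples(self) -> int:
        return int(self.tp[0] + self.tn[0] + self.fp[0] + self.fn[0])


def _check_inputs(predictions, truths) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predictions, dtype=int)
    t = np.asarray(truths, dtype=int)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("predictions and truths must be equal-length 1-d arrays")
    if p.size == 0:
        raise ValueError("empty input")
    return p, t


def confusion_counts(predictions, truths, n_classes: int | None = None) -> ConfusionCounts:
    p, t = _check_inputs(predictions, truths)
    k = int(n_classes) if n_classes is not None else int(max(p.max(), t.max())) + 1
    tp = np.zeros(k, dtype=int)
    fp = np.zeros(k, dtype=int)
    fn = np.zeros(k, dtype=int)
    for c in range(k):
        tp[c] = np.sum((p == c) & (t == c))
        fp[c] = np.sum((p == c) & (t != c))
        fn[c] = np.sum((p != c) & (t == c))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(predictions, truths) -> float:
    """Micro-averaged accuracy: per-class counts are summed before the ratio.

    For single-label classification the summed counts give the fraction of
    correct predictions (sum TP over classes divided by the sample count,
    since every error is one FP plus one FN), which also equals the
    micro-averaged F1 score 2*TP / (2*TP + FP + FN).
    """
    p, t = _check_inputs(predictions, truths)
    c = confusion_counts(p, t)
    tp, fp, fn = c.tp.sum(), c.fp.sum(), c.fn.sum()
    return float(2 * tp / (2 * tp + fp + fn))


def macro_f1(predictions, truths, n_classes: int | None = None) -> float:
    """Unweighted mean over classes of F1 = 2TP / (2TP + FP + FN).

    Classes absent from both predictions and truths (zero denominator)
    contribute F1 = 0.
    """
    c = confusion_counts(predictions, truths, n_classes)
    den = 2 * c.tp + c.fp + c.fn
    f1 = np.where(den > 0, 2 * c.tp / np.maximum(den, 1), 0.0)
    return float(f1.mean())


@dataclass(frozen=True)
class ClusterMapping:
    """Surjective map cluster id -> class id; UNMAPPED marks empty clusters."""

    mapping: np.ndarray

    def __call__(self, cluster_assignments) -> np.ndarray:
        clusters = np.asarray(cluster_assignments, dtype=int)
        return self.mapping[clusters]

    @property
    def n_clusters(self) -> int:
        return self.mapping.size


def majority_mapping(
    cluster_assignments, truths, n_clusters: int | None = None
) -> ClusterMapping:
    """Map each non-empty cluster to its most frequent true class.

    Ties break to the lowest class id; empty clusters get the UNMAPPED
    sentinel and their (non-existent) members are excluded from metrics.
    """
    z, t = _check_inputs(cluster_assignments, truths)
    k = int(n_clusters) if n_clusters is not None else int(z.max()) + 1
    k_gt = int(t.max()) + 1
    counts = np.zeros((k, k_gt), dtype=int)
    np.add.at(counts, (z, t), 1)
    mapping = np.where(counts.sum(axis=1) > 0, counts.argmax(axis=1), UNMAPPED)
    return ClusterMapping(mapping=mapping)


@dataclass(frozen=True)
class ConsistencyReport:
    """Expert-judged consistency of images with their predicted cluster."""

    overall: float
    per_cluster: dict = field(default_factory=dict)

    @property
    def per_cluster_mean(self) -> float:
        return float(np.mean(list(self.per_cluster.values())))

    @property
    def per_cluster_std(self) -> float:
        """Population standard deviation of the per-cluster ratios."""
        return float(np.std(list(self.per_cluster.values())))


def consistency(
    cluster_assignments, consistency_judgments, exclude=None
) -> ConsistencyReport:
    """Fraction of images judged visually consistent with their cluster.

    ``consistency_judgments`` is a boolean per image (supplied by raters, e.g.
    read from a CSV -- never simulated here).  ``exclude`` optionally masks
    out images (e.g. those of a catch-all class) before scoring.  Per-cluster
    ratios are reported for non-empty clusters only.
    """
    z = np.asarray(cluster_assignments, dtype=int)
    j = np.asarray(consistency_judgments, dtype=bool)
    if z.shape != j.shape or z.ndim != 1:
        raise ValueError("assignments and judgments must be equal-length 1-d arrays")
    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool)
        z, j = z[keep], j[keep]
    if z.size == 0:
        raise ValueError("no images left to score")
    per_cluster = {
        int(c): float(j[z == c].mean()) for c in np.unique(z)
    }
    return ConsistencyReport(overall=float(j.mean()), per_cluster=per_cluster)


def consistency_from_csv(path, exclude_class=None) -> ConsistencyReport:
    """Score rater judgments stored as CSV with columns
    ``image, cluster, consistent`` and optionally ``class``.

    ``exclude_class`` drops the images of one class (e.g. a catch-all
    class whose visual similarity cannot be judged) before scoring.
    """
    import pandas as pd

    df = pd.read_csv(path)
    exclude = None
    if exclude_class is not None:
        if "class" not in df.columns:
            raise ValueError("judgment table has no 'class' column to exclude by")
        exclude = (df["class"] == exclude_class).to_numpy()
    return consistency(
        df["cluster"].to_numpy(),
        df["consistent"].astype(bool).to_numpy(),
        exclude=exclude,
    )
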