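"""Centroid-based evaluation of a segmentation against ground truth.

Each ground-truth centroid is matched greedily (ascending GT index) to the
nearest unmatched segmentation centroid within a spherical neighbourhood of
``match_radius`` voxels (default 12).  Matched pairs are true positives;
``FP = N_SC - TP`` and ``FN = N_GT - TP``.  Recall, precision and the
F score (harmonic mean) follow from the counts.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = ["MatchResult", "Metrics", "match_centroids", "compute_metrics", "centroids_of_labels"]


@dataclasses.dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    n_sc: int
    n_gt: int
    pairs: list[tuple[int, int]]
    match_radius: float = 12.0


@dataclasses.dataclass
class Metrics:
    recall: float
    precision: float
    f_score: float

    def rounded(self, ndigits: int = 2) -> "Metrics":
        return Metrics(*(round(v, ndigits) for v in (self.recall, self.precision, self.f_score)))


def match_centroids(
    gt: np.ndarray, seg: np.ndarray, radius: float = 12.0
) -> MatchResult:
    """Greedy one-pass matching of ground-truth to segmentation centroids.

    For each GT centroid in index order, unmatched segmentation centroids
    within ``radius`` are candidates and the nearest one becomes the TP
    partner (ties broken by lower segmentation index) and leaves the pool.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    gt = np.asarray(gt, dtype=np.float64).reshape(-1, 3) if np.size(gt) else np.empty((0, 3))
    seg = np.asarray(seg, dtype=np.float64).reshape(-1, 3) if np.size(seg) else np.empty((0, 3))
    available = np.ones(len(seg), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for gi, g in enumerate(gt):
        if not available.any():
            break
        d = np.linalg.norm(seg - g, axis=1)
        d[~available] = np.inf
        si = int(np.argmin(d))  # argmin takes the lowest index on ties
        if d[si] <= radius:
            pairs.append((gi, si))
            available[si] = False
    tp = len(pairs)
    return MatchResult(
        tp=tp, fp=len(seg) - tp, fn=len(gt) - tp,
        n_sc=len(seg), n_gt=len(gt), pairs=pairs, match_radius=radius,
    )


def compute_metrics(m: MatchResult) -> Metrics:
    """Recall, precision and F score from a match result.

    Undefined denominators (no GT points for recall, no segmentation points
    for precision) yield ``nan`` rather than 0.
    """
    recall = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else math.nan
    precision = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else math.nan
    if math.isnan(recall) or math.isnan(precision) or (precision + recall) == 0:
        f = math.nan if (math.isnan(recall) or math.isnan(precision)) else 0.0
    else:
        f = 2 * precision * recall / (precision + recall)
    return Metrics(recall=recall, precision=precision, f_score=f)


def centroids_of_labels(labels: np.ndarray) -> np.ndarray:
    """(n, 3) centroid array of a label image, ordered by label id."""
    from scipy import ndimage

    ids = np.arange(1, int(labels.max()) + 1)
    if ids.size == 0:
        return np.empty((0, 3))
    return np.asarray(ndimage.center_of_mass(labels > 0, labels, ids), dtype=np.float64)
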