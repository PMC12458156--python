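"""Detection evaluation: matching, precision/recall/F1, and particle IoU.

Predicted and ground-truth particles are matched one-to-one by greedy
ascending center distance within a threshold (default: half the particle
diameter).  From the match counts:

    precision = TP / (TP + FP)      recall = TP / (TP + FN)
    F1 = 2 P R / (P + R)

IoU is computed spatially: both sets are rasterized as unions of disks at
the ground-truth diameter and the foreground intersection / union pixel
counts are taken.  Degenerate denominators (no predictions, no ground
truth, empty union) return 0 and set the ``degenerate`` flag rather than
raising, so dataset means stay defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masks import rasterize_disks
from .particles import ParticleSet

__all__ = [
    "MatchResult",
    "match_particles",
    "precision",
    "recall",
    "f1",
    "particle_iou",
    "evaluate_picks",
    "aggregate_report",
]


@dataclass
class MatchResult:
    """One-to-one matching between predicted and ground-truth particles."""

    tp: int
    fp: int
    fn: int
    #: (pred index, gt index, center distance) per matched pair
    pairs: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_pred(self) -> int:
        return self.tp + self.fp

    @property
    def n_gt(self) -> int:
        return self.tp + self.fn


def match_particles(
    pred: ParticleSet, gt: ParticleSet, threshold: float
) -> MatchResult:
    """Greedy one-to-one matching by ascending center distance.

    Candidate pairs within ``threshold`` are sorted by (distance,
    prediction index, ground-truth index) and accepted greedily; each
    particle matches at most once.
    """
    if threshold < 0:
        raise ValueError(f"match threshold must be non-negative, got {threshold}")
    np_, ng = len(pred), len(gt)
    if np_ == 0 or ng == 0:
        return MatchResult(tp=0, fp=np_, fn=ng)
    diff = pred.coords[:, None, :] - gt.coords[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    pi, gi = np.nonzero(dist <= threshold)
    order = np.lexsort((gi, pi, dist[pi, gi]))
    used_p = np.zeros(np_, dtype=bool)
    used_g = np.zeros(ng, dtype=bool)
    pairs: list[tuple[int, int, float]] = []
    for k in order:
        i, j = int(pi[k]), int(gi[k])
        if used_p[i] or used_g[j]:
            continue
        used_p[i] = used_g[j] = True
        pairs.append((i, j, float(dist[i, j])))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=np_ - tp, fn=ng - tp, pairs=pairs)


def precision(match: MatchResult) -> float:
    """TP / (TP + FP); 0 when there are no predictions."""
    return match.tp / match.n_pred if match.n_pred else 0.0


def recall(match: MatchResult) -> float:
    """TP / (TP + FN); 0 when there is no ground truth."""
    return match.tp / match.n_gt if match.n_gt else 0.0


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    return 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0


def particle_iou(
    pred: ParticleSet,
    gt: ParticleSet,
    image_size: int | tuple[int, int],
    diameter: float,
) -> float:
    """Pixel IoU of the two sets rasterized as unions of disks.

    Both sets use the ground-truth ``diameter``; returns 0 for an empty
    union.
    """
    shape = (
        (image_size, image_size) if np.isscalar(image_size) else tuple(image_size)
    )
    a = rasterize_disks(pred.coords, shape, diameter)
    b = rasterize_disks(gt.coords, shape, diameter)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def evaluate_picks(
    pred: ParticleSet,
    gt: ParticleSet,
    image_size,
    diameter: float,
    threshold: float | None = None,
) -> dict:
    """Per-micrograph metric row: precision, recall, F1, IoU, counts.

    ``threshold`` defaults to half the particle diameter.
    """
    if threshold is None:
        threshold = diameter / 2.0
    m = match_particles(pred, gt, threshold)
    p, r = precision(m), recall(m)
    return {
        "precision": p,
        "recall": r,
        "f1": f1(p, r),
        "iou": particle_iou(pred, gt, image_size, diameter),
        "tp": m.tp,
        "fp": m.fp,
        "fn": m.fn,
        "degenerate": m.n_pred == 0 or m.n_gt == 0,
    }


METRIC_COLUMNS = ("precision", "recall", "f1", "iou")


def aggregate_report(rows) -> pd.Series:
    """Unweighted arithmetic means of the metric columns across rows.

    ``rows`` is a DataFrame or list of dicts with at least the columns
    precision/recall/f1/iou (extra columns are ignored).
    """
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("aggregate_report requires at least one row")
    cols = [c for c in METRIC_COLUMNS if c in df.columns]
    return df[cols].mean()
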