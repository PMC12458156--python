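"""Mask-to-coordinate extraction: distance transform, multi-scale peaks,
watershed splitting, geometric filtering, and a dual-pass recovery pass.

The pipeline converts a dense segmentation mask into particle centers:

1. threshold the logits into a binary mask;
2. Euclidean distance transform (maxima approximate blob centers);
3. peak detection at several minimum-separation scales, merged and
   deduplicated, to seed one marker per particle even when particles
   touch;
4. marker-controlled watershed on the negated distance map to split
   touching particles into one region per seed;
5. geometric filtering by area (multiples of the expected particle area
   pi (d/2)^2) and circularity 4 pi A / P^2;
6. a second, more permissive pass over the residual mask recovers
   closely packed particles rejected by the strict first pass, followed
   by center deduplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .model import LogitMap
from .particles import ParticleSet

__all__ = [
    "PostprocParams",
    "LabeledRegions",
    "binarize",
    "distance_map",
    "detect_peaks_multiscale",
    "watershed_split",
    "region_filter",
    "extract_particles",
]


@dataclass(frozen=True)
class PostprocParams:
    """Tunable thresholds of the extraction pipeline.

    ``peak_scales``, ``area_bounds`` and ``dedup_dist`` are expressed
    relative to the expected particle diameter ``d`` (area bounds as
    multiples of the ideal disk area pi (d/2)^2).
    """

    diameter: float
    logit_threshold: float = 0.0
    peak_scales: tuple[float, ...] = (0.5, 0.75)
    area_bounds: tuple[float, float] = (0.3, 2.5)
    circularity_min_pass1: float = 0.6
    circularity_min_pass2: float = 0.4
    dedup_dist: float = 0.5

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if not self.peak_scales:
            raise ValueError("peak_scales must be non-empty")
        lo, hi = self.area_bounds
        if not lo < hi:
            raise ValueError(f"area bounds must satisfy min < max, got {self.area_bounds}")
        for c in (self.circularity_min_pass1, self.circularity_min_pass2):
            if not 0.0 < c <= 1.0:
                raise ValueError("circularity thresholds must lie in (0, 1]")
        if self.circularity_min_pass2 > self.circularity_min_pass1:
            raise ValueError("pass-2 circularity threshold must be <= pass-1")


@dataclass
class LabeledRegions:
    """Watershed output: integer label grid plus per-region geometry."""

    labels: np.ndarray  # 0 = background
    areas: np.ndarray = field(default_factory=lambda: np.empty(0))
    perimeters: np.ndarray = field(default_factory=lambda: np.empty(0))
    centroids: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))  # (x, y)

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "LabeledRegions":
        props = regionprops(labels)
        areas = np.array([p.area for p in props], dtype=float)
        perims = np.array([p.perimeter for p in props], dtype=float)
        cents = np.array(
            [[p.centroid[1], p.centroid[0]] for p in props], dtype=float
        ).reshape(-1, 2)
        return cls(labels=labels, areas=areas, perimeters=perims, centroids=cents)

    @property
    def n_regions(self) -> int:
        return len(self.areas)

    def circularities(self) -> np.ndarray:
        """4 pi A / P^2 per region, capped at 1 (rasterization can exceed it)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            c = 4.0 * np.pi * self.areas / self.perimeters**2
        # tiny regions can have zero perimeter; call them perfectly round
        c[~np.isfinite(c)] = 1.0
        return np.minimum(c, 1.0)


def binarize(logits, threshold: float = 0.0) -> np.ndarray:
    """Foreground where logit > threshold."""
    vals = logits.values if isinstance(logits, LogitMap) else np.asarray(logits)
    return vals > threshold


def distance_map(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance to the nearest background pixel."""
    return ndimage.distance_transform_edt(np.asarray(mask, dtype=bool))


def detect_peaks_multiscale(
    dist: np.ndarray, params: PostprocParams
) -> np.ndarray:
    """Union of local maxima at each min-separation scale, deduplicated.

    Returns seed points as an ``(n, 2)`` array of ``(row, col)`` indices,
    ordered by decreasing distance value.  Seeds closer than
    ``dedup_dist * d`` collapse onto the highest-valued one.
    """
    d = params.diameter
    coords: list[np.ndarray] = []
    for scale in params.peak_scales:
        min_dist = max(1, int(round(scale * d)))
        pk = peak_local_max(
            dist, min_distance=min_dist, threshold_abs=1e-9, exclude_border=False
        )
        if len(pk):
            coords.append(pk)
    if not coords:
        return np.empty((0, 2), dtype=int)
    seeds = np.unique(np.concatenate(coords, axis=0), axis=0)
    values = dist[seeds[:, 0], seeds[:, 1]]
    return _dedup_points(seeds, values, params.dedup_dist * d)


def _dedup_points(
    points: np.ndarray, priority: np.ndarray, min_dist: float
) -> np.ndarray:
    """Greedy dedup: keep highest-priority points pairwise >= min_dist apart.

    Ties broken deterministically by (row, col) order.
    """
    if len(points) == 0:
        return points
    order = np.lexsort((points[:, 1], points[:, 0], -priority))
    kept: list[np.ndarray] = []
    for i in order:
        p = points[i]
        if all(np.hypot(*(p - q)) >= min_dist for q in kept):
            kept.append(p)
    return np.array(kept)


def watershed_split(mask: np.ndarray, seeds: np.ndarray) -> LabeledRegions:
    """Partition the foreground into one region per seed.

    Marker-controlled watershed on the negated distance map with
    8-connectivity.  Seeds falling on background are dropped with a
    warning.
    """
    mask = np.asarray(mask, dtype=bool)
    seeds = np.asarray(seeds, dtype=int).reshape(-1, 2)
    if len(seeds):
        on_fg = mask[seeds[:, 0], seeds[:, 1]]
        if not on_fg.all():
            warnings.warn(
                f"dropping {int((~on_fg).sum())} seed(s) on background",
                stacklevel=2,
            )
            seeds = seeds[on_fg]
    if len(seeds) == 0:
        return LabeledRegions.from_labels(np.zeros(mask.shape, dtype=int))
    markers = np.zeros(mask.shape, dtype=int)
    markers[seeds[:, 0], seeds[:, 1]] = np.arange(1, len(seeds) + 1)
    labels = watershed(-distance_map(mask), markers=markers, mask=mask, connectivity=2)
    return LabeledRegions.from_labels(labels)


def region_filter(
    regions: LabeledRegions, params: PostprocParams, circularity_min: float
) -> LabeledRegions:
    """Keep regions plausible as single particles: area and circularity.

    Area must lie within ``area_bounds`` multiples of the ideal disk area
    ``pi (d/2)^2`` and circularity ``4 pi A / P^2`` must reach
    ``circularity_min``.
    """
    ideal = np.pi * (params.diameter / 2.0) ** 2
    lo, hi = params.area_bounds
    keep = (
        (regions.areas >= lo * ideal)
        & (regions.areas <= hi * ideal)
        & (regions.circularities() >= circularity_min)
    )
    kept_labels = np.flatnonzero(keep) + 1
    label_map = np.zeros(regions.n_regions + 1, dtype=int)
    label_map[kept_labels] = np.arange(1, len(kept_labels) + 1)
    return LabeledRegions(
        labels=label_map[regions.labels],
        areas=regions.areas[keep],
        perimeters=regions.perimeters[keep],
        centroids=regions.centroids[keep],
    )


def _single_pass(
    mask: np.ndarray, params: PostprocParams, circularity_min: float
) -> LabeledRegions:
    dist = distance_map(mask)
    seeds = detect_peaks_multiscale(dist, params)
    regions = watershed_split(mask, seeds)
    return region_filter(regions, params, circularity_min)


def extract_particles(logits, params: PostprocParams) -> ParticleSet:
    """Full dual-pass extraction from logits to particle coordinates.

    Pass 1 applies the strict circularity threshold; accepted regions are
    removed from the mask, and pass 2 re-runs the pipeline on the residual
    with the relaxed threshold to recover closely packed particles.
    Final centers are region centroids, deduplicated at
    ``dedup_dist * d`` (larger region wins).
    """
    mask = binarize(logits, params.logit_threshold)
    kept1 = _single_pass(mask, params, params.circularity_min_pass1)
    residual = mask & (kept1.labels == 0)
    kept2 = _single_pass(residual, params, params.circularity_min_pass2)

    centers = np.concatenate([kept1.centroids, kept2.centroids], axis=0)
    areas = np.concatenate([kept1.areas, kept2.areas])
    if len(centers):
        # dedup operates on (x, y); reuse the (row, col) helper by swapping
        kept = _dedup_points(
            centers[:, ::-1], areas, params.dedup_dist * params.diameter
        )[:, ::-1]
    else:
        kept = centers
    return ParticleSet(coords=kept, diameter=params.diameter, space="model")
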