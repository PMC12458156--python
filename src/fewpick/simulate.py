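"""Synthetic low-SNR micrograph generator with exact ground truth.

Emulates the appearance of single-particle cryo-EM data at the level the
picking pipeline cares about: faint, roughly disk-shaped particles of a
known diameter scattered over a noisy background, a controllable fraction
of close particle pairs, per-particle contrast variation, and occasional
bright ice-like contaminant blobs.  Each simulated micrograph comes with
exact particle coordinates and the rasterized ground-truth mask, so every
downstream stage (training, post-processing, evaluation) is testable
without external data.

What is deliberately *not* modeled: the contrast transfer function,
defocus, radiation damage, carbon edges, or real particle projections.
Particles are rendered bright on a dark background; real cryo-EM particles
are dark, but the pipeline is sign-agnostic because the segmentation model
learns the contrast from the annotated shots.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .masks import rasterize_disks
from .particles import Micrograph, ParticleSet

__all__ = [
    "SimParams",
    "GroundTruth",
    "simulate_micrograph",
    "render_gt_mask",
    "make_fewshot_dataset",
]

#: base particle amplitude before contrast jitter; noise sd is derived
#: from it as ``amplitude / snr``.
PARTICLE_AMPLITUDE = 1.0


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated micrograph.

    Attributes
    ----------
    image_size
        Square image side in pixels.
    n_particles
        Number of particles to place.
    particle_diameter
        Particle diameter in pixels (ground-truth disk diameter).
    snr
        Ratio of particle amplitude to background noise standard deviation.
    overlap_fraction
        Fraction of particles placed within one diameter of another
        particle (center distance uniform in ``[0.5, 1.0] * diameter``).
    n_ice_blobs
        Number of high-contrast contaminant blobs (2-5x particle
        amplitude, radius 0.5-3x particle radius).
    contrast_jitter
        Multiplicative spread of per-particle amplitude:
        ``A_k = A * (1 + jitter * U(-1, 1))``.
    seed
        Seed for the generator; fixed seed gives bit-identical output.
    """

    image_size: int = 128
    n_particles: int = 25
    particle_diameter: float = 16.0
    snr: float = 2.0
    overlap_fraction: float = 0.1
    n_ice_blobs: int = 2
    contrast_jitter: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 2 * self.particle_diameter:
            raise ValueError(
                "invalid SimParams: image_size must be >= 2 * particle_diameter "
                f"(got {self.image_size} < 2 * {self.particle_diameter})"
            )
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError(
                "invalid SimParams: overlap_fraction must lie in [0, 1], got "
                f"{self.overlap_fraction}"
            )
        if self.snr <= 0:
            raise ValueError(f"invalid SimParams: snr must be > 0, got {self.snr}")
        if self.n_particles < 0 or self.n_ice_blobs < 0:
            raise ValueError("invalid SimParams: counts must be non-negative")
        if self.contrast_jitter < 0 or self.contrast_jitter >= 1:
            raise ValueError(
                "invalid SimParams: contrast_jitter must lie in [0, 1), got "
                f"{self.contrast_jitter}"
            )


@dataclass
class GroundTruth:
    """Exact ground truth for one simulated micrograph."""

    particles: ParticleSet
    mask: np.ndarray
    #: list of ``(x, y, radius)`` contaminant blobs (excluded from the mask)
    contaminants: list[tuple[float, float, float]] = field(default_factory=list)


def render_gt_mask(
    particles: ParticleSet, image_size: int, diameter: float
) -> np.ndarray:
    """Rasterize a particle set as a binary union-of-disks mask.

    Rejects particle centers outside ``[0, image_size)`` on either axis.
    """
    c = particles.coords
    if c.size and ((c < 0).any() or (c >= image_size).any()):
        bad = c[((c < 0) | (c >= image_size)).any(axis=1)][0]
        raise ValueError(
            f"particle center {tuple(bad)} is outside the {image_size}x"
            f"{image_size} image bounds"
        )
    return rasterize_disks(c, (image_size, image_size), diameter)


def _place_centers(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Place particle centers: a spaced base set plus deliberate close pairs."""
    n = params.n_particles
    if n == 0:
        return np.empty((0, 2))
    d = params.particle_diameter
    margin = d / 2.0
    lo, hi = margin, params.image_size - margin
    n_overlap = int(round(params.overlap_fraction * n))
    n_base = max(1, n - n_overlap)
    n_overlap = n - n_base

    centers: list[np.ndarray] = []
    max_attempts = 2000 * n
    attempts = 0
    while len(centers) < n_base:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "could not place particles with min spacing one diameter: "
                "image too dense (reduce n_particles or diameter)"
            )
        p = rng.uniform(lo, hi, size=2)
        if all(np.hypot(*(p - q)) > d for q in centers):
            centers.append(p)
    for _ in range(n_overlap):
        anchor = centers[rng.integers(len(centers))]
        theta = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(0.5, 1.0) * d
        p = anchor + dist * np.array([np.cos(theta), np.sin(theta)])
        centers.append(np.clip(p, lo, hi))
    return np.array(centers)


def _soft_disk(
    image: np.ndarray, x: float, y: float, radius: float, amplitude: float
) -> None:
    """Add a truncated-Gaussian disk profile to ``image`` in place.

    The profile is ``A * exp(-r^2 / (2 sigma^2))`` with ``sigma = radius/2``,
    cut off at ``radius`` (soft-edged, maximal at the center).
    """
    h, w = image.shape
    sigma = radius / 2.0
    r0 = max(0, int(np.floor(y - radius)))
    r1 = min(h, int(np.ceil(y + radius)) + 1)
    c0 = max(0, int(np.floor(x - radius)))
    c1 = min(w, int(np.ceil(x + radius)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1, dtype=np.float64)[:, None]
    cols = np.arange(c0, c1, dtype=np.float64)[None, :]
    rr2 = (cols - x) ** 2 + (rows - y) ** 2
    prof = amplitude * np.exp(-rr2 / (2.0 * sigma * sigma))
    prof[rr2 > radius * radius] = 0.0
    image[r0:r1, c0:c1] += prof


def simulate_micrograph(params: SimParams) -> tuple[Micrograph, GroundTruth]:
    """Simulate one micrograph and its exact ground truth.

    Deterministic given ``params.seed``.  The noiseless image is a sum of
    soft-edged particle disks (amplitude ``1 +/- contrast_jitter``) and
    contaminant blobs; i.i.d. Gaussian noise of standard deviation
    ``amplitude / snr`` is then added.
    """
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    d = params.particle_diameter
    r = d / 2.0

    centers = _place_centers(params, rng)
    amplitudes = PARTICLE_AMPLITUDE * (
        1.0 + params.contrast_jitter * rng.uniform(-1.0, 1.0, size=len(centers))
    )

    image = np.zeros((size, size), dtype=np.float64)
    for (x, y), a in zip(centers, amplitudes):
        _soft_disk(image, x, y, r, a)

    contaminants: list[tuple[float, float, float]] = []
    for _ in range(params.n_ice_blobs):
        br = rng.uniform(0.5, 3.0) * r
        bx, by = rng.uniform(br, size - br, size=2) if size > 2 * br else (
            rng.uniform(0, size, size=2)
        )
        amp = rng.uniform(2.0, 5.0) * PARTICLE_AMPLITUDE
        _soft_disk(image, bx, by, br, amp)
        contaminants.append((float(bx), float(by), float(br)))

    noise_sd = PARTICLE_AMPLITUDE / params.snr
    image += rng.normal(0.0, noise_sd, size=(size, size))

    particles = ParticleSet(coords=centers, diameter=d, space="native")
    gt = GroundTruth(
        particles=particles,
        mask=rasterize_disks(centers, (size, size), d),
        contaminants=contaminants,
    )
    return Micrograph(data=image), gt


def child_seed(parent_seed: int, index: int) -> int:
    """Deterministically derive a distinct child seed from (parent, index)."""
    ss = np.random.SeedSequence([int(parent_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def make_fewshot_dataset(
    k: int, params: SimParams
) -> list[tuple[Micrograph, GroundTruth]]:
    """Simulate ``k`` independent micrographs for few-shot training.

    Child seeds are derived deterministically from ``params.seed`` and the
    micrograph index, so repeated calls are bit-identical while the ``k``
    micrographs are mutually distinct.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    out = []
    for i in range(k):
        p = dataclasses.replace(params, seed=child_seed(params.seed, i))
        out.append(simulate_micrograph(p))
    return out
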