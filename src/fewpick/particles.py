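"""Core containers: micrographs, particle sets, and coordinate frames.

Conventions used throughout the package:

* images are 2-D ``float`` arrays indexed ``[row, col]``;
* particle coordinates are ``(x, y)`` with ``x = column``, ``y = row``,
  0-based, origin at the top-left pixel center;
* two coordinate *spaces* exist: ``native`` (original micrograph pixels)
  and ``model`` (the resized square grid the segmentation model sees).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Micrograph",
    "ParticleSet",
    "CoordinateFrame",
    "convert_frame",
]


@dataclass
class Micrograph:
    """A single 2-D micrograph.

    Parameters
    ----------
    data
        Intensity grid, shape ``(height, width)``.
    pixel_size
        Physical pixel size in Angstrom per pixel, if known.
    """

    data: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"micrograph must be 2-D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # (height, width)


@dataclass
class ParticleSet:
    """Particle centers (+ one shared diameter) in a declared coordinate space.

    ``coords`` has shape ``(n, 2)`` with columns ``(x, y)``.
    """

    coords: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    diameter: float | None = None
    space: str = "native"

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=np.float64)
        if c.size == 0:
            c = c.reshape(0, 2)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError(f"coords must have shape (n, 2), got {c.shape}")
        self.coords = c

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.coords[:, 1]


@dataclass(frozen=True)
class CoordinateFrame:
    """A pixel coordinate frame: a named space with known extent.

    Origin is the top-left, ``x`` runs along columns, ``y`` along rows,
    0-based indexing.  Scaling between frames is the ratio of extents.
    """

    width: float
    height: float
    space: str = "native"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"frame extent must be positive, got {self.width} x {self.height}"
            )


def convert_frame(
    particles: ParticleSet, src: CoordinateFrame, dst: CoordinateFrame
) -> ParticleSet:
    """Linearly rescale particle coordinates (and diameter) between frames.

    The diameter is scaled by the geometric mean of the per-axis factors,
    which reduces to the common factor for isotropic resizing.
    """
    sx = dst.width / src.width
    sy = dst.height / src.height
    coords = particles.coords * np.array([sx, sy])
    diameter = None
    if particles.diameter is not None:
        diameter = float(particles.diameter * np.sqrt(sx * sy))
    return ParticleSet(coords=coords, diameter=diameter, space=dst.space)


def scaled_particles(particles: ParticleSet, factor: float) -> ParticleSet:
    """Uniformly scale coordinates and diameter by ``factor``."""
    return replace(
        particles,
        coords=particles.coords * factor,
        diameter=None if particles.diameter is None else particles.diameter * factor,
    )
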