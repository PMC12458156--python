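"""Rasterization of particle disks into binary masks."""

from __future__ import annotations

import numpy as np

__all__ = ["rasterize_disks"]


def rasterize_disks(
    coords: np.ndarray, shape: tuple[int, int], diameter: float
) -> np.ndarray:
    """Binary union of disks of ``diameter`` centered at ``coords``.

    A pixel ``(row, col)`` is foreground when its center lies within
    ``diameter / 2`` of any particle center: ``(col-x)^2 + (row-y)^2 <= r^2``.
    Disks extending past the image edge are clipped.

    Parameters
    ----------
    coords
        ``(n, 2)`` array of ``(x, y)`` centers.
    shape
        ``(height, width)`` of the output mask.
    diameter
        Disk diameter in pixels.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 2)
    if coords.size == 0:
        return mask
    r = diameter / 2.0
    r2 = r * r
    for x, y in coords:
        # restrict to the disk's bounding box; n and r are small
        r0 = max(0, int(np.floor(y - r)))
        r1 = min(h, int(np.ceil(y + r)) + 1)
        c0 = max(0, int(np.floor(x - r)))
        c1 = min(w, int(np.ceil(x + r)) + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rows = np.arange(r0, r1, dtype=np.float64)[:, None]
        cols = np.arange(c0, c1, dtype=np.float64)[None, :]
        mask[r0:r1, c0:c1] |= (cols - x) ** 2 + (rows - y) ** 2 <= r2
    return mask
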