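"""Micrograph and coordinate file I/O.

Micrographs are read from MRC (mode 2, float32) or PNG/TIFF.  Particle
coordinates are exchanged as STAR files — the labeled-loop text format
used throughout cryo-EM software — with RELION-dialect column names
(``_rlnCoordinateX`` / ``_rlnCoordinateY``).

Coordinate convention for STAR output: 0-based, origin at the top-left,
x = column, y = row, written in native pixels with 6-decimal floats.
Downstream tools differ in their conventions; this one is documented here
deliberately.

The MRC reader/writer is a minimal struct-level implementation of the
MRC2014 header covering the mode-2 single-image case this package
produces and consumes.
"""

from __future__ import annotations

import struct
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .particles import CoordinateFrame, Micrograph, ParticleSet, convert_frame

__all__ = [
    "read_micrograph",
    "write_mrc",
    "write_star",
    "read_star",
    "StarFormatError",
]

_MRC_HEADER_SIZE = 1024


class StarFormatError(ValueError):
    """Raised for malformed or unusable STAR files."""


def write_mrc(path, image: np.ndarray, pixel_size: float = 1.0) -> None:
    """Write a 2-D image as a single-section MRC mode-2 (float32) file."""
    data = np.asarray(image, dtype="<f4")
    if data.ndim != 2:
        raise ValueError(f"expected 2-D image, got shape {data.shape}")
    ny, nx = data.shape
    header = bytearray(_MRC_HEADER_SIZE)
    struct.pack_into("<10i", header, 0, nx, ny, 1, 2, 0, 0, 0, nx, ny, 1)
    struct.pack_into(
        "<6f", header, 40, nx * pixel_size, ny * pixel_size, pixel_size,
        90.0, 90.0, 90.0,
    )
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<2i", header, 88, 0, 0)  # ispg, nsymbt
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0, 0])  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(data.tobytes())


def _read_mrc(path) -> Micrograph:
    raw = Path(path).read_bytes()
    if len(raw) < _MRC_HEADER_SIZE:
        raise ValueError(
            f"{path}: truncated MRC file ({len(raw)} bytes, header needs 1024)"
        )
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    if not (0 < nx < 1 << 20 and 0 < ny < 1 << 20 and 0 < nz < 1 << 20):
        raise ValueError(f"{path}: corrupt MRC header (nx={nx}, ny={ny}, nz={nz})")
    if mode != 2:
        raise ValueError(
            f"{path}: unsupported MRC mode {mode} (only mode 2 float32 is read)"
        )
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    cella_x, _cella_y, _cella_z = struct.unpack_from("<3f", raw, 40)
    (mx,) = struct.unpack_from("<i", raw, 28)
    offset = _MRC_HEADER_SIZE + nsymbt
    count = nx * ny * nz
    if len(raw) < offset + 4 * count:
        raise ValueError(
            f"{path}: truncated MRC data (need {offset + 4 * count} bytes, "
            f"have {len(raw)})"
        )
    data = np.frombuffer(raw, dtype="<f4", count=count, offset=offset)
    data = data.reshape(nz, ny, nx)[0]
    pixel_size = cella_x / mx if mx > 0 and cella_x > 0 else None
    return Micrograph(data=data.astype(np.float64), pixel_size=pixel_size)


def read_micrograph(path) -> Micrograph:
    """Read an MRC (mode 2) or PNG/TIFF micrograph.

    Intensities are returned as floats without normalization (the trainer
    normalizes); 8-bit image values stay in [0, 255].
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".mrcs", ".map"):
        return _read_mrc(path)
    if suffix in (".png", ".tif", ".tiff"):
        try:
            data = np.asarray(iio.imread(path), dtype=np.float64)
        except Exception as exc:  # noqa: BLE001 - diagnose, don't crash
            raise ValueError(f"{path}: unreadable image file ({exc})") from exc
        if data.ndim == 3:  # collapse RGB(A) to gray
            data = data[..., :3].mean(axis=-1)
        return Micrograph(data=data)
    raise ValueError(
        f"{path}: unsupported micrograph format {suffix!r} "
        "(expected .mrc, .png, or .tif)"
    )


# ---------------------------------------------------------------------------
# STAR coordinate files

_COORD_X_LABELS = ("_rlncoordinatex",)
_COORD_Y_LABELS = ("_rlncoordinatey",)


def write_star(
    particles: ParticleSet,
    path,
    frame: CoordinateFrame | None = None,
    native_frame: CoordinateFrame | None = None,
    block_name: str = "particles",
) -> None:
    """Write particle coordinates as a RELION-dialect STAR file.

    Coordinates are written in the native frame: if ``frame`` (the frame
    the particles are currently in) and ``native_frame`` are both given,
    the particles are converted first.  Floats use 6 decimals.
    """
    if frame is not None and native_frame is not None:
        particles = convert_frame(particles, frame, native_frame)
    lines = [
        f"data_{block_name}",
        "",
        "loop_",
        "_rlnCoordinateX #1",
        "_rlnCoordinateY #2",
    ]
    for x, y in particles.coords:
        lines.append(f"{x:.6f} {y:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_star(path) -> ParticleSet:
    """Read particle coordinates from a STAR file's first loop.

    Extra columns are ignored; missing coordinate columns or malformed
    numeric cells are rejected with a diagnostic.
    """
    text = Path(path).read_text()
    labels: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    header_done = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("data_"):
            continue
        if line == "loop_":
            if header_done:
                break  # only the first loop is read
            in_loop = True
            continue
        if in_loop and line.startswith("_"):
            if header_done:
                break
            labels.append(line.split()[0])
            continue
        if in_loop and labels:
            header_done = True
            fields = line.split()
            if len(fields) != len(labels):
                raise StarFormatError(
                    f"{path}:{lineno}: row has {len(fields)} fields, "
                    f"expected {len(labels)}"
                )
            rows.append((lineno, fields))
    if not labels:
        raise StarFormatError(f"{path}: no loop_ block with column labels found")

    lowered = [lab.lower() for lab in labels]

    def find(cands, axis):
        for c in cands:
            if c in lowered:
                return lowered.index(c)
        raise StarFormatError(
            f"{path}: no {axis} coordinate column; available labels: "
            + ", ".join(labels)
        )

    ix = find(_COORD_X_LABELS, "X")
    iy = find(_COORD_Y_LABELS, "Y")

    coords = np.empty((len(rows), 2), dtype=np.float64)
    for i, (lineno, fields) in enumerate(rows):
        try:
            coords[i, 0] = float(fields[ix])
            coords[i, 1] = float(fields[iy])
        except ValueError as exc:
            raise StarFormatError(
                f"{path}:{lineno}: malformed numeric cell ({exc})"
            ) from exc
    return ParticleSet(coords=coords, space="native")
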