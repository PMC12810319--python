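"""Read/write class-average stacks (MRC/MRCS) and per-class metadata tables (STAR/CSV).

Image stacks use the MRC2014 layout: a fixed 1024-byte header followed by
``nz`` contiguous ``ny x nx`` sections.  All writes use mode 2 (32-bit
float); reads accept modes 0/1/2/6 and convert to float32.  The pixel size
is carried in the header cell dimensions (``cella.x / mx``, in Angstrom per
pixel).

Score tables are written as a single STAR ``data_`` block with one
``loop_``, inspectable with ``relion_display``.  Class indices are 0-based
everywhere in memory and 1-based only inside ``N@file`` image references
(the RELION convention).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClassAverageStack",
    "ClassRecord",
    "read_class_stack",
    "write_class_stack",
    "write_scores_star",
    "read_star_table",
    "ingest_metadata",
    "make_image_ref",
    "SCORE_COLUMN",
    "REFERENCE_COLUMN",
]

#: STAR column holding the continuous quality score (fixed interchange name).
SCORE_COLUMN = "_cryosiftScore"
#: STAR column holding the 1-based "N@file" image reference.
REFERENCE_COLUMN = "_rlnReferenceImage"

_HEADER_SIZE = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


@dataclass
class ClassAverageStack:
    """A stack of square 2D class averages sharing one pixel size.

    Parameters
    ----------
    images
        Array of shape ``(n, side, side)``, float32.
    pixel_size
        Angstrom per pixel, strictly positive.
    source_id
        Free-text provenance tag (e.g. the originating file name).
    """

    images: np.ndarray
    pixel_size: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim == 2:
            self.images = self.images[None]
        if self.images.ndim != 3:
            raise ValueError(f"images must be (n, side, side); got ndim={self.images.ndim}")
        n, h, w = self.images.shape
        if n < 1:
            raise ValueError("stack must contain at least one image")
        if h != w:
            raise ValueError(f"non-square sections: {h}x{w}")
        if h < 1:
            raise ValueError("side must be >= 1")
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError(f"pixel_size must be positive and finite; got {self.pixel_size}")

    @property
    def n(self) -> int:
        return int(self.images.shape[0])

    @property
    def side(self) -> int:
        return int(self.images.shape[1])


@dataclass
class ClassRecord:
    """Metadata for one 2D class average.

    ``class_index`` is 0-based; ``image_ref`` uses the 1-based ``N@file``
    syntax.  Mass features and score/grade are optional and filled in by the
    mass estimator and scorer respectively.
    """

    class_index: int
    image_ref: str = ""
    pixel_size: float = float("nan")
    frc_resolution: float = float("nan")
    class_distribution: float = float("nan")
    est_mass: float | None = None
    dev_mean_mass: float | None = None
    dev_median_mass: float | None = None
    dev_mode_mass: float | None = None
    score: float | None = None
    grade: str | None = None

    def __post_init__(self) -> None:
        if self.grade is not None and self.grade not in {"A", "B", "C", "D", "F"}:
            raise ValueError(f"grade must be one of A,B,C,D,F; got {self.grade!r}")
        if np.isfinite(self.class_distribution) and not (0.0 <= self.class_distribution <= 1.0 + 1e-9):
            raise ValueError(f"class_distribution must lie in [0, 1]; got {self.class_distribution}")


def make_image_ref(class_index: int, stack_path: str | Path) -> str:
    """1-based ``N@file`` reference for a 0-based class index."""
    return f"{class_index + 1:06d}@{Path(stack_path).name}"


# ---------------------------------------------------------------------------
# MRC2014


def _build_header(n: int, side: int, pixel_size: float, data: np.ndarray) -> bytes:
    h = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", h, 0, side, side, n)          # nx, ny, nz
    struct.pack_into("<i", h, 12, 2)                      # mode 2 = float32
    struct.pack_into("<3i", h, 16, 0, 0, 0)               # nxstart..
    struct.pack_into("<3i", h, 28, side, side, n)         # mx, my, mz
    cell = (side * pixel_size, side * pixel_size, n * pixel_size)
    struct.pack_into("<3f", h, 40, *cell)                 # cella
    struct.pack_into("<3f", h, 52, 90.0, 90.0, 90.0)      # cellb
    struct.pack_into("<3i", h, 64, 1, 2, 3)               # mapc, mapr, maps
    struct.pack_into("<3f", h, 76, float(data.min()), float(data.max()), float(data.mean()))
    struct.pack_into("<i", h, 88, 0)                      # ispg = 0 (image stack)
    struct.pack_into("<i", h, 92, 0)                      # nsymbt
    struct.pack_into("<i", h, 108, 20140)                 # nversion
    h[208:212] = b"MAP "
    h[212:216] = bytes((0x44, 0x44, 0x00, 0x00))          # little-endian machine stamp
    struct.pack_into("<f", h, 216, float(data.std()))     # rms
    struct.pack_into("<i", h, 220, 1)                     # nlabl
    h[224:224 + 80] = b"Created by sift2d".ljust(80)
    return bytes(h)


def write_class_stack(stack: ClassAverageStack, path: str | Path) -> None:
    """Write a stack as MRC2014 mode 2 (32-bit float)."""
    path = Path(path)
    data = np.ascontiguousarray(stack.images, dtype="<f4")
    with open(path, "wb") as fh:
        fh.write(_build_header(stack.n, stack.side, stack.pixel_size, data))
        fh.write(data.tobytes())


def read_class_stack(path: str | Path) -> ClassAverageStack:
    """Read an MRC/MRCS image or image stack.

    Accepts MRC2014 modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16);
    values are returned as float32.  The pixel size is taken from the header
    voxel size along x.  Sections must be square.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack file: {path}")
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise ValueError(f"truncated MRC header in {path}")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        cella = struct.unpack_from("<3f", header, 40)
        (nsymbt,) = struct.unpack_from("<i", header, 92)
        if mode not in _MODE_DTYPES:
            raise ValueError(f"unsupported MRC mode {mode} in {path} (supported: 0, 1, 2, 6)")
        if nx != ny:
            raise ValueError(f"non-square sections in {path}: {ny}x{nx}")
        if nz < 1 or nx < 1:
            raise ValueError(f"invalid dimensions in {path}: nx={nx}, ny={ny}, nz={nz}")
        fh.seek(_HEADER_SIZE + max(nsymbt, 0))
        dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
        count = nx * ny * nz
        data = np.frombuffer(fh.read(count * dtype.itemsize), dtype=dtype, count=count)
    images = data.reshape(nz, ny, nx).astype(np.float32)
    pixel_size = cella[0] / mx if mx > 0 else 0.0
    if pixel_size <= 0:
        pixel_size = 1.0  # headers written without cell information
    return ClassAverageStack(images=images, pixel_size=float(pixel_size), source_id=path.name)


# ---------------------------------------------------------------------------
# STAR


def _format_star_value(v: object) -> str:
    if isinstance(v, float):
        return f"{v:.6f}"
    return str(v)


def write_star_table(df: pd.DataFrame, path: str | Path, block: str = "data_") -> None:
    """Write a DataFrame as one STAR data block with a single loop_.

    Column names must already carry their leading underscore
    (e.g. ``_rlnReferenceImage``).
    """
    lines = ["", block, "", "loop_"]
    for i, col in enumerate(df.columns, start=1):
        lines.append(f"{col} #{i}")
    for _, row in df.iterrows():
        lines.append(" ".join(_format_star_value(v) for v in row))
    lines.append("")
    Path(path).write_text("\n".join(lines))


def read_star_table(path: str | Path) -> pd.DataFrame:
    """Parse the first loop_ of the first data block of a STAR file."""
    path = Path(path)
    labels: list[str] = []
    rows: list[list[str]] = []
    state = "seek_loop"
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            if state == "rows" and rows:
                break
            continue
        if state == "seek_loop":
            if line == "loop_":
                state = "labels"
            continue
        if state == "labels":
            if line.startswith("_"):
                labels.append(line.split()[0])
                continue
            state = "rows"
        if state == "rows":
            if line.startswith(("data_", "loop_")):
                break
            rows.append(line.split())
    if not labels:
        raise ValueError(f"no loop_ block found in {path}")
    df = pd.DataFrame(rows, columns=labels)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            pass
    return df


def write_scores_star(records: Sequence[ClassRecord], path: str | Path) -> None:
    """Write per-class quality scores as a relion_display-inspectable STAR file.

    Every record must carry a score and an image reference; row order is
    preserved.
    """
    for rec in records:
        if rec.score is None:
            raise ValueError(f"record for class_index {rec.class_index} has no score")
        if not rec.image_ref:
            raise ValueError(f"record for class_index {rec.class_index} has no image_ref")
    df = pd.DataFrame(
        {
            REFERENCE_COLUMN: [r.image_ref for r in records],
            SCORE_COLUMN: [float(r.score) for r in records],
        }
    )
    write_star_table(df, path, block="data_")


# ---------------------------------------------------------------------------
# Metadata ingestion

_COLUMN_ALIASES = {
    "class_index": ("class_index", "class", "_sift2dClassIndex", "_rlnClassNumber"),
    "frc_resolution": ("frc_resolution", "resolution", "est_res_a", "_rlnEstimatedResolution"),
    "class_distribution": ("class_distribution", "distribution", "_rlnClassDistribution"),
    "pixel_size": ("pixel_size", "psize_a", "_rlnImagePixelSize", "_rlnDetectorPixelSize"),
}


def _find_column(df: pd.DataFrame, key: str) -> str:
    lowered = {c.lower(): c for c in df.columns}
    for alias in _COLUMN_ALIASES[key]:
        if alias.lower() in lowered:
            return lowered[alias.lower()]
    raise ValueError(f"missing column for {key!r}; accepted names: {_COLUMN_ALIASES[key]}")


def ingest_metadata(table_path: str | Path) -> list[ClassRecord]:
    """Load per-class metadata from a CSV or STAR table.

    The table must name columns for the class index, FRC resolution (A),
    class distribution and pixel size (A/px); common RELION-style aliases
    are accepted.  Distributions are renormalized to sum to 1 when the raw
    sum is within 1% of 1, and rejected otherwise.
    """
    table_path = Path(table_path)
    if table_path.suffix.lower() == ".star":
        df = read_star_table(table_path)
    else:
        df = pd.read_csv(table_path)
    cols = {key: _find_column(df, key) for key in _COLUMN_ALIASES}
    resolution = df[cols["frc_resolution"]].to_numpy(dtype=float)
    if np.any(resolution <= 0):
        raise ValueError("FRC resolution must be positive (Angstrom)")
    dist = df[cols["class_distribution"]].to_numpy(dtype=float)
    total = dist.sum()
    if abs(total - 1.0) > 0.01:
        raise ValueError(f"class distributions sum to {total:.4f}, deviating > 1% from 1")
    dist = dist / total
    class_index = df[cols["class_index"]].to_numpy(dtype=int)
    if class_index.min() == 1 and class_index.max() == len(df):
        class_index = class_index - 1  # 1-based table (RELION convention)
    pixel_size = df[cols["pixel_size"]].to_numpy(dtype=float)
    return [
        ClassRecord(
            class_index=int(ci),
            pixel_size=float(ps),
            frc_resolution=float(res),
            class_distribution=float(d),
        )
        for ci, ps, res, d in zip(class_index, pixel_size, resolution, dist)
    ]
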