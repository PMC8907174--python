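"""Reading and writing B-scan volumes, metadata sidecars, and choroid boundaries.

A volume scan is an ordered stack of grayscale B-scans (multi-page TIFF, or a
directory of lexicographically numbered PNGs) with a JSON metadata sidecar
carrying the physical scales, the inter-scan spacing, the foveal scan index,
and the scanner signal-strength score.  Choroid segmentation boundaries are
stored as a long-format CSV, one row per (scan, column), giving the depth row
of the RPE-Bruch's membrane complex (upper) and the choroid-scleral interface
(lower).  Row 0 is the top of the B-scan (vitreous side); rows increase with
depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError, VolumeLoadError

METADATA_KEYS = (
    "eye_id",
    "scale_x_mm",
    "scale_y_mm",
    "spacing_um",
    "fovea_index",
    "signal_strength",
)

BOUNDARY_COLUMNS = ("scan", "column", "upper_row", "lower_row")


@dataclass
class BScan:
    """One OCT cross-section: an 8-bit intensity grid plus its physical scales.

    Rows index depth (row 0 = vitreous side), columns index lateral position.
    ``scale_x`` and ``scale_y`` are mm per pixel laterally and axially;
    ``index`` is the 1-based position of the scan in its volume.
    """

    pixels: np.ndarray
    scale_x: float
    scale_y: float
    index: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("B-scan pixels must form a non-empty 2D grid")
        if not (self.scale_x > 0 and self.scale_y > 0):
            raise ValidationError("pixel scales must be positive")
        if self.index < 1:
            raise ValidationError("scan index is 1-based and must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class VolumeScan:
    """An ordered stack of B-scans covering the macula.

    ``spacing_um`` is the inter-scan distance T in micrometres (one scalar per
    volume), ``fovea_index`` the 1-based index of the foveal B-scan, and
    ``signal_strength`` the scanner's acquisition-quality score.
    """

    scans: list[BScan]
    spacing_um: float
    fovea_index: int
    signal_strength: float
    eye_id: str = "eye"

    def __post_init__(self) -> None:
        if not self.scans:
            raise ValidationError("volume contains no scans")
        shape = self.scans[0].shape
        sx, sy = self.scans[0].scale_x, self.scans[0].scale_y
        for i, s in enumerate(self.scans, start=1):
            if s.shape != shape:
                raise ValidationError(
                    f"scan {i} has shape {s.shape}, expected {shape}"
                )
            if (s.scale_x, s.scale_y) != (sx, sy):
                raise ValidationError(f"scan {i} has inconsistent pixel scales")
            if s.index != i:
                raise ValidationError("scan indices must be consecutive from 1")
        if not self.spacing_um > 0:
            raise ValidationError("spacing_um must be positive")
        if not 1 <= self.fovea_index <= len(self.scans):
            raise ValidationError("fovea_index outside the volume")

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    @property
    def scan_shape(self) -> tuple[int, int]:
        return self.scans[0].shape

    @property
    def scale_x(self) -> float:
        return self.scans[0].scale_x

    @property
    def scale_y(self) -> float:
        return self.scans[0].scale_y


@dataclass
class ChoroidBoundaries:
    """Per-scan, per-column depth rows of the choroid's two borders.

    ``upper[s, c]`` is the row of the RPE-Bruch's complex and ``lower[s, c]``
    the row of the choroid-scleral interface on scan ``s`` (0-based here),
    column ``c``.  The invariant ``0 <= upper <= lower <= n_rows`` holds
    everywhere; the choroid ROI on a scan is the half-open band
    ``upper <= row < lower``.
    """

    upper: np.ndarray
    lower: np.ndarray

    def __post_init__(self) -> None:
        self.upper = np.asarray(self.upper, dtype=int)
        self.lower = np.asarray(self.lower, dtype=int)
        if self.upper.shape != self.lower.shape or self.upper.ndim != 2:
            raise SchemaError("upper and lower must be 2D arrays of equal shape")
        if np.any(self.upper < 0):
            raise ValidationError("negative boundary row")
        bad = np.argwhere(self.upper > self.lower)
        if bad.size:
            s, c = bad[0]
            raise ValidationError(
                f"upper boundary below lower boundary at scan {s + 1}, column {c}"
            )

    @property
    def n_scans(self) -> int:
        return self.upper.shape[0]

    @property
    def n_columns(self) -> int:
        return self.upper.shape[1]

    def validate_against(self, volume: VolumeScan) -> None:
        rows, cols = volume.scan_shape
        if self.n_scans != volume.n_scans:
            raise SchemaError(
                f"boundaries cover {self.n_scans} scans, volume has {volume.n_scans}"
            )
        if self.n_columns != cols:
            raise SchemaError(
                f"boundaries cover {self.n_columns} columns, scans have {cols}"
            )
        if np.any(self.lower > rows):
            raise ValidationError("lower boundary extends below the image")


@dataclass
class QcResult:
    """Outcome of acquisition quality control with a machine-readable reason."""

    passed: bool
    reason: str = ""


def _to_uint8(img: np.ndarray) -> np.ndarray:
    """Convert an intensity image to 8 bits; 16-bit input is linearly
    min-max rescaled, mirroring the standard pre-thresholding conversion."""
    if img.dtype == np.uint8:
        return img
    img = img.astype(np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round((img - lo) / (hi - lo) * 255.0).astype(np.uint8)


def read_volume(path: str | Path, metadata_path: str | Path) -> VolumeScan:
    """Load a B-scan stack plus its JSON metadata sidecar.

    ``path`` is either a multi-page TIFF file or a directory of numbered PNG
    files (sorted lexicographically).  Pixels are converted to 8 bits on read.
    """
    path = Path(path)
    meta = _read_metadata(metadata_path)
    frames = _read_frames(path)
    scans = [
        BScan(
            pixels=_to_uint8(frame),
            scale_x=meta["scale_x_mm"],
            scale_y=meta["scale_y_mm"],
            index=i,
        )
        for i, frame in enumerate(frames, start=1)
    ]
    return VolumeScan(
        scans=scans,
        spacing_um=meta["spacing_um"],
        fovea_index=int(meta["fovea_index"]),
        signal_strength=meta["signal_strength"],
        eye_id=str(meta["eye_id"]),
    )


def _read_metadata(metadata_path: str | Path) -> dict:
    metadata_path = Path(metadata_path)
    if not metadata_path.exists():
        raise SchemaError(f"metadata file not found: {metadata_path}")
    with open(metadata_path) as fh:
        meta = json.load(fh)
    missing = [k for k in METADATA_KEYS if k not in meta]
    if missing:
        raise SchemaError(f"metadata missing required fields: {missing}")
    return meta


def _read_frames(path: Path) -> list[np.ndarray]:
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not files:
            raise VolumeLoadError(f"no image files found in {path}")
        import imageio.v3 as iio

        frames = []
        for f in files:
            try:
                frames.append(np.asarray(iio.imread(f)))
            except Exception as exc:  # pragma: no cover - backend specific
                raise VolumeLoadError(f"could not read {f}: {exc}") from exc
    elif path.is_file():
        import tifffile

        try:
            frames = [page.asarray() for page in tifffile.TiffFile(path).pages]
        except Exception as exc:
            raise VolumeLoadError(f"could not read TIFF stack {path}: {exc}") from exc
    else:
        raise VolumeLoadError(f"volume path does not exist: {path}")

    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise VolumeLoadError(f"ragged stack: frame shapes {sorted(shapes)}")
    if frames[0].ndim != 2:
        raise VolumeLoadError("frames must be single-channel grayscale")
    return frames


def write_volume(volume: VolumeScan, path: str | Path, metadata_path: str | Path) -> None:
    """Write a volume as a multi-page TIFF plus a JSON metadata sidecar."""
    import tifffile

    stack = np.stack([s.pixels for s in volume.scans])
    tifffile.imwrite(Path(path), stack)
    meta = {
        "eye_id": volume.eye_id,
        "scale_x_mm": volume.scale_x,
        "scale_y_mm": volume.scale_y,
        "spacing_um": volume.spacing_um,
        "fovea_index": volume.fovea_index,
        "signal_strength": volume.signal_strength,
    }
    with open(metadata_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_boundaries(path: str | Path, volume: VolumeScan) -> ChoroidBoundaries:
    """Load a long-format boundary CSV and validate it against ``volume``."""
    df = pd.read_csv(path)
    missing = [c for c in BOUNDARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"boundary table missing columns: {missing}")
    n_scans = volume.n_scans
    rows, cols = volume.scan_shape
    upper = np.full((n_scans, cols), -1, dtype=int)
    lower = np.full((n_scans, cols), -1, dtype=int)
    scan_idx = df["scan"].to_numpy(dtype=int) - 1
    col_idx = df["column"].to_numpy(dtype=int)
    if scan_idx.min(initial=0) < 0 or scan_idx.max(initial=-1) >= n_scans:
        raise SchemaError("boundary scan index outside the volume")
    if col_idx.min(initial=0) < 0 or col_idx.max(initial=-1) >= cols:
        raise SchemaError("boundary column index outside the scan width")
    upper[scan_idx, col_idx] = df["upper_row"].to_numpy(dtype=int)
    lower[scan_idx, col_idx] = df["lower_row"].to_numpy(dtype=int)
    if np.any(upper < 0) or np.any(lower < 0):
        raise SchemaError("boundary table does not cover every (scan, column)")
    boundaries = ChoroidBoundaries(upper=upper, lower=lower)
    boundaries.validate_against(volume)
    return boundaries


def write_boundaries(boundaries: ChoroidBoundaries, path: str | Path) -> None:
    """Write boundaries as long-format CSV (scan, column, upper_row, lower_row)."""
    n_scans, cols = boundaries.upper.shape
    scan = np.repeat(np.arange(1, n_scans + 1), cols)
    column = np.tile(np.arange(cols), n_scans)
    pd.DataFrame(
        {
            "scan": scan,
            "column": column,
            "upper_row": boundaries.upper.ravel(),
            "lower_row": boundaries.lower.ravel(),
        }
    ).to_csv(path, index=False)


def qc_filter(volume: VolumeScan, min_signal: float = 20.0) -> QcResult:
    """Acquisition QC: a volume is eligible iff its signal strength reaches
    ``min_signal`` (default 20, the conventional eligibility floor)."""
    if volume.signal_strength >= min_signal:
        return QcResult(passed=True)
    return QcResult(
        passed=False,
        reason=(
            f"signal_strength {volume.signal_strength} below minimum {min_signal}"
        ),
    )
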