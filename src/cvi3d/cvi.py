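"""Areas, volumes, and the 2D/3D choroidal vascularity index.

The choroidal vascularity index (CVI) is the luminal fraction of the choroid:
in 2D, luminal area over total choroidal area of one B-scan; in 3D, luminal
volume over total choroidal volume of a stack.  Per-scan pixel counts become
physical areas through the lateral and axial scales,

    Area_n [mm^2] = count [px] * scale_x [mm/px] * scale_y [mm/px],

and areas become volumes by summing inter-scan slabs, each slab the mean of
its two bounding areas times the inter-scan distance:

    Vol_total = sum_n ((Area_n + Area_{n+1}) / 2) * T_mm,

i.e. trapezoidal quadrature of the area profile with the spacing converted
from micrometres to millimetres so volumes are true mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binarize import BinarisationParams, classify_luminal, rasterize_roi
from .errors import UndefinedValueError, ValidationError
from .io import ChoroidBoundaries, VolumeScan


@dataclass(frozen=True)
class ScanAreas:
    """Total (TCA), luminal (LA), and stromal (SA) choroidal area of one B-scan,
    in mm^2; SA = TCA - LA by construction."""

    scan_index: int
    tca_mm2: float
    la_mm2: float
    sa_mm2: float


@dataclass(frozen=True)
class CviResult:
    """3D CVI of a named macular region: luminal and total choroidal volume
    in mm^3 and their ratio as a percentage."""

    region: str
    luminal_volume_mm3: float
    total_volume_mm3: float
    cvi_percent: float


@dataclass(frozen=True)
class RegionPartition:
    """Contiguous superior / central / inferior blocks of 1-based scan indices."""

    superior: tuple[int, ...]
    central: tuple[int, ...]
    inferior: tuple[int, ...]


@dataclass(frozen=True)
class ThicknessProfile:
    """Choroidal thickness in µm per (scan, column), plus the subfoveal
    summary ``sfct_um`` (mean over a 1-mm-diameter neighbourhood of the
    fovea column on the foveal scan)."""

    ct_um: np.ndarray
    sfct_um: float


def compute_scan_areas(
    roi: np.ndarray,
    luminal: np.ndarray,
    scale_x: float,
    scale_y: float,
    scan_index: int = 1,
) -> ScanAreas:
    """Convert ROI and luminal pixel counts to physical areas in mm^2."""
    roi = np.asarray(roi, dtype=bool)
    luminal = np.asarray(luminal, dtype=bool)
    if roi.shape != luminal.shape:
        raise ValidationError("masks must share shape")
    if np.any(luminal & ~roi):
        raise ValidationError("luminal mask extends outside the ROI")
    px_area = scale_x * scale_y
    tca = float(roi.sum()) * px_area
    la = float(luminal.sum()) * px_area
    return ScanAreas(scan_index=scan_index, tca_mm2=tca, la_mm2=la, sa_mm2=tca - la)


def cvi_2d(areas: ScanAreas) -> float:
    """2D CVI of a single B-scan: 100 * LA / TCA (scale-invariant)."""
    if areas.tca_mm2 <= 0:
        raise UndefinedValueError("2D CVI undefined for zero total choroidal area")
    return 100.0 * areas.la_mm2 / areas.tca_mm2


def integrate_volume(areas_mm2: Sequence[float], spacing_um: float) -> float:
    """Integrate an ordered per-scan area profile into a volume in mm^3.

    Each of the N-1 inter-scan slabs contributes the mean of its two bounding
    areas times the spacing (converted µm -> mm); at least two scans are
    required for a slab to exist.
    """
    areas = np.asarray(areas_mm2, dtype=np.float64)
    if areas.ndim != 1 or areas.size < 2:
        raise ValidationError("volume integration needs at least two scan areas")
    if not spacing_um > 0:
        raise ValidationError("spacing_um must be positive")
    spacing_mm = spacing_um / 1000.0
    return float(np.sum((areas[:-1] + areas[1:]) / 2.0) * spacing_mm)


def cvi_3d(
    areas: Sequence[ScanAreas], spacing_um: float, label: str = "region"
) -> CviResult:
    """3D CVI of a scan series: luminal volume over total choroidal volume."""
    if len(areas) < 2:
        raise ValidationError("3D CVI needs at least two scans")
    total = integrate_volume([a.tca_mm2 for a in areas], spacing_um)
    luminal = integrate_volume([a.la_mm2 for a in areas], spacing_um)
    if total <= 0:
        raise UndefinedValueError("3D CVI undefined for zero total choroidal volume")
    return CviResult(
        region=label,
        luminal_volume_mm3=luminal,
        total_volume_mm3=total,
        cvi_percent=100.0 * luminal / total,
    )


def partition_regions(
    n_scans: int, custom: tuple[int, int, int] | None = None
) -> RegionPartition:
    """Split a volume into superior / central / inferior blocks of scans.

    For the standard 31-scan macular volume the blocks are the superior 10,
    central 11, and inferior 10 B-scans (scan 1 = superior-most).  Other scan
    counts require an explicit ``custom`` block-size triple summing to
    ``n_scans``.
    """
    if custom is None:
        if n_scans != 31:
            raise ValidationError(
                "standard region partition is defined for 31 scans; "
                "supply custom block sizes otherwise"
            )
        sizes = (10, 11, 10)
    else:
        sizes = tuple(int(s) for s in custom)
        if len(sizes) != 3 or any(s < 1 for s in sizes) or sum(sizes) != n_scans:
            raise ValidationError(
                f"custom block sizes {sizes} must be positive and sum to {n_scans}"
            )
    a, b, c = sizes
    return RegionPartition(
        superior=tuple(range(1, a + 1)),
        central=tuple(range(a + 1, a + b + 1)),
        inferior=tuple(range(a + b + 1, a + b + c + 1)),
    )


def central_subset(n_scans: int, k: int, fovea_index: int) -> tuple[int, ...]:
    """The k consecutive scan indices centred on the foveal scan (k odd)."""
    if k % 2 == 0 or k < 1:
        raise ValidationError("subset size k must be odd and positive")
    if k > n_scans:
        raise ValidationError(f"subset size {k} exceeds {n_scans} scans")
    half = k // 2
    lo, hi = fovea_index - half, fovea_index + half
    if lo < 1 or hi > n_scans:
        raise ValidationError(
            f"{k}-scan subset centred on scan {fovea_index} falls outside 1..{n_scans}"
        )
    return tuple(range(lo, hi + 1))


def thickness_profile(
    boundaries: ChoroidBoundaries,
    scale_y: float,
    scale_x: float,
    fovea_index: int,
    fovea_column: int | None = None,
) -> ThicknessProfile:
    """Choroidal thickness map in µm plus the subfoveal thickness (SFCT).

    CT(scan, c) = (lower - upper) * scale_y * 1000.  SFCT averages CT over
    the columns within 0.5 mm of the fovea column (default: central column)
    on the foveal scan — a 1-D analogue of the central ETDRS subfield.
    """
    ct_um = (boundaries.lower - boundaries.upper).astype(np.float64) * scale_y * 1000.0
    n_cols = boundaries.n_columns
    if fovea_column is None:
        fovea_column = n_cols // 2
    if not 0 <= fovea_column < n_cols:
        raise ValidationError("fovea column outside the image")
    if not 1 <= fovea_index <= boundaries.n_scans:
        raise ValidationError("fovea scan index outside the volume")
    half_cols = int(round(0.5 / scale_x))
    lo = max(0, fovea_column - half_cols)
    hi = min(n_cols, fovea_column + half_cols + 1)
    sfct = float(ct_um[fovea_index - 1, lo:hi].mean())
    return ThicknessProfile(ct_um=ct_um, sfct_um=sfct)


#: Columns of the per-eye record, the schema consumed by the statistics layer.
EYE_RECORD_COLUMNS = (
    "eye_id",
    "cvi2d_subfoveal",
    "cvi3d_whole",
    "cvi3d_superior",
    "cvi3d_central",
    "cvi3d_inferior",
    "cvi3d_11",
    "cvi3d_21",
    "cvi3d_31",
    "sfct_um",
)


def measure_eye(
    volume: VolumeScan,
    boundaries: ChoroidBoundaries,
    params: BinarisationParams | None = None,
) -> dict:
    """Run binarisation and CVI measurement over a full volume scan.

    Returns a per-eye record with the subfoveal 2D CVI, 3D CVI for the whole
    macula and for the superior/central/inferior regions (each region
    integrating only its own interior slabs), 3D CVI for the 11-, 21- and
    31-scan subsets centred on the fovea, and the SFCT, plus a provenance
    block with the binarisation parameters used.
    """
    if params is None:
        params = BinarisationParams()
    boundaries.validate_against(volume)
    shape = volume.scan_shape

    areas: list[ScanAreas] = []
    for scan in volume.scans:
        roi = rasterize_roi(
            boundaries.upper[scan.index - 1], boundaries.lower[scan.index - 1], shape
        )
        luminal = classify_luminal(scan.pixels, roi, params)
        areas.append(
            compute_scan_areas(
                roi, luminal, volume.scale_x, volume.scale_y, scan_index=scan.index
            )
        )

    spacing = volume.spacing_um
    regions = partition_regions(volume.n_scans)
    pick = lambda idx: [areas[i - 1] for i in idx]

    record: dict = {"eye_id": volume.eye_id}
    record["cvi2d_subfoveal"] = cvi_2d(areas[volume.fovea_index - 1])
    record["cvi3d_whole"] = cvi_3d(areas, spacing, "whole").cvi_percent
    for name, idx in (
        ("superior", regions.superior),
        ("central", regions.central),
        ("inferior", regions.inferior),
    ):
        record[f"cvi3d_{name}"] = cvi_3d(pick(idx), spacing, name).cvi_percent
    for k in (11, 21, 31):
        idx = central_subset(volume.n_scans, k, volume.fovea_index)
        record[f"cvi3d_{k}"] = cvi_3d(pick(idx), spacing, f"central_{k}").cvi_percent
    record["sfct_um"] = thickness_profile(
        boundaries, volume.scale_y, volume.scale_x, volume.fovea_index
    ).sfct_um
    record["provenance"] = {
        "binarisation": params.as_dict(),
        "spacing_um": spacing,
        "fovea_index": volume.fovea_index,
        "n_scans": volume.n_scans,
    }
    return record
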