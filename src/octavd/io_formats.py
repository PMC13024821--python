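"""Reading and writing of en-face scans, annotation sidecars, and results.

The raster convention used throughout the package is fixed here once:
coordinates are 0-based and pixel-centred, x increases rightward, y increases
downward.  Annotation coordinates (in particular the fovea) may lie outside
the raster bounds; only the BMO contour itself must fit on the scan.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely
import tifffile
from pydantic import BaseModel

__all__ = [
    "EnFaceScan",
    "ScanAnnotation",
    "VDResult",
    "AnnotationError",
    "ScanError",
    "read_enface",
    "read_annotation",
    "write_result",
    "read_results",
    "write_mask",
    "read_mask",
    "write_overlay",
    "RESULT_COLUMNS",
]

SECTOR_NAMES = ("s1", "s2", "s3", "s4")

#: Exact column order of the results CSV.  ``vd_mean_unweighted`` (the
#: arithmetic mean of the four sector densities, as opposed to the
#: pixel-weighted ``vd_mean``) is appended after the primary columns.
RESULT_COLUMNS = (
    ["scan_id", "subject_id", "laterality", "vd_mean", "vd_s1", "vd_s2", "vd_s3", "vd_s4"]
    + [f"n_px_{s}" for s in SECTOR_NAMES]
    + [f"n_vessel_{s}" for s in SECTOR_NAMES]
    + ["otsu_threshold", "params_hash", "vd_mean_unweighted"]
)


class ScanError(ValueError):
    """Raised for unreadable or inconsistent en-face scan input."""


class AnnotationError(ValueError):
    """Raised for annotation sidecars violating the BMO/fovea contract."""


@dataclass
class EnFaceScan:
    """An en-face OCT-A angiogram with its physical metadata.

    Intensities are kept exactly as read from disk (8- or 16-bit); any
    normalisation is the vesselness filter's concern, not I/O's.
    """

    pixels: np.ndarray
    px_size_um: float
    laterality: str = "OD"
    scan_id: str = ""
    subject_id: str = ""
    width_mm: Optional[float] = None
    height_mm: Optional[float] = None
    quality_pass: bool = True

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ScanError(f"expected a single-channel 2D raster, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 32 or self.pixels.shape[1] < 32:
            raise ScanError(f"raster {self.pixels.shape} smaller than the 32 x 32 minimum")
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=float))):
            raise ScanError("raster contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ScanError("raster contains negative intensities")
        if not (self.px_size_um > 0):
            raise ScanError(f"px_size_um must be > 0, got {self.px_size_um}")
        if self.laterality not in ("OD", "OS"):
            raise ScanError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")
        tol_mm = 0.5 * self.px_size_um / 1000.0
        rows, cols = self.pixels.shape
        if self.width_mm is not None:
            if abs(cols * self.px_size_um / 1000.0 - self.width_mm) > tol_mm:
                raise ScanError(
                    f"declared width {self.width_mm} mm inconsistent with "
                    f"{cols} px at {self.px_size_um} um/px"
                )
        if self.height_mm is not None:
            if abs(rows * self.px_size_um / 1000.0 - self.height_mm) > tol_mm:
                raise ScanError(
                    f"declared height {self.height_mm} mm inconsistent with "
                    f"{rows} px at {self.px_size_um} um/px"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ScanAnnotation:
    """48-point BMO contour plus the fovea landmark, in pixel coordinates.

    The fovea is roughly 4 mm from the disc centre while the scan spans
    2.9 mm, so ``fovea_xy`` typically lies outside the raster; that is valid
    and expected.  The fovea must however lie strictly outside the closed
    BMO polygon.
    """

    bmo_points: np.ndarray  # (N, 2) float, x then y
    fovea_xy: tuple[float, float]
    laterality: str
    n_scan_lines: int = 24
    scan_id: str = ""
    px_size_um: Optional[float] = None
    quality_pass: bool = True
    allow_any_count: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.bmo_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise AnnotationError(f"bmo_points must be an (N, 2) array, got shape {pts.shape}")
        if not self.allow_any_count and pts.shape[0] != 48:
            raise AnnotationError(
                f"expected 48 BMO positions (2 per each of {self.n_scan_lines} scan lines), "
                f"got {pts.shape[0]}"
            )
        if pts.shape[0] < 3:
            raise AnnotationError("BMO contour needs at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise AnnotationError("BMO points contain non-finite coordinates")
        self.bmo_points = pts
        if self.laterality not in ("OD", "OS"):
            raise AnnotationError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")
        poly = self.polygon
        if not poly.is_valid:
            raise AnnotationError("BMO contour is self-intersecting (not a simple polygon)")
        if poly.area <= 0:
            raise AnnotationError("BMO polygon has zero area")
        fx, fy = self.fovea_xy
        if not np.all(np.isfinite([fx, fy])):
            raise AnnotationError("fovea coordinate is non-finite")
        if shapely.intersects_xy(poly, fx, fy):
            raise AnnotationError("fovea inside BMO polygon")

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.bmo_points)


@dataclass
class VDResult:
    """Overall and sectorial vessel density of one scan.

    Densities are derived properties of the raw pixel counts so that
    ``vd_sk == 100 * n_vessel[k] / n_total[k]`` holds exactly by
    construction.  ``vd_mean`` is the pixel-weighted density over the whole
    peripapillary region of interest; ``vd_mean_unweighted`` is the plain
    average of the four sector densities, reported alongside for
    comparability with sector-averaged conventions.
    """

    n_vessel: tuple[int, int, int, int]
    n_total: tuple[int, int, int, int]
    threshold_used: float
    params_hash: str
    scan_id: str = ""
    subject_id: str = ""
    laterality: str = "OD"

    def __post_init__(self) -> None:
        self.n_vessel = tuple(int(v) for v in self.n_vessel)
        self.n_total = tuple(int(v) for v in self.n_total)
        if len(self.n_vessel) != 4 or len(self.n_total) != 4:
            raise ValueError("n_vessel and n_total must each have 4 entries (S1..S4)")
        for k, (nv, nt) in enumerate(zip(self.n_vessel, self.n_total), start=1):
            if nt <= 0:
                raise ValueError(f"sector S{k} contains no pixels")
            if not (0 <= nv <= nt):
                raise ValueError(f"sector S{k}: vessel count {nv} outside [0, {nt}]")

    def vd_sector(self, k: int) -> float:
        """Vessel density of sector S``k`` (k in 1..4), in percent."""
        return 100.0 * self.n_vessel[k - 1] / self.n_total[k - 1]

    @property
    def vd_s1(self) -> float:
        return self.vd_sector(1)

    @property
    def vd_s2(self) -> float:
        return self.vd_sector(2)

    @property
    def vd_s3(self) -> float:
        return self.vd_sector(3)

    @property
    def vd_s4(self) -> float:
        return self.vd_sector(4)

    @property
    def vd_mean(self) -> float:
        return 100.0 * sum(self.n_vessel) / sum(self.n_total)

    @property
    def vd_mean_unweighted(self) -> float:
        return sum(self.vd_sector(k) for k in range(1, 5)) / 4.0

    def to_row(self) -> dict:
        row = {
            "scan_id": self.scan_id,
            "subject_id": self.subject_id,
            "laterality": self.laterality,
            "vd_mean": round(self.vd_mean, 2),
            "vd_s1": round(self.vd_s1, 2),
            "vd_s2": round(self.vd_s2, 2),
            "vd_s3": round(self.vd_s3, 2),
            "vd_s4": round(self.vd_s4, 2),
        }
        for i, s in enumerate(SECTOR_NAMES):
            row[f"n_px_{s}"] = self.n_total[i]
        for i, s in enumerate(SECTOR_NAMES):
            row[f"n_vessel_{s}"] = self.n_vessel[i]
        row["otsu_threshold"] = self.threshold_used
        row["params_hash"] = self.params_hash
        row["vd_mean_unweighted"] = round(self.vd_mean_unweighted, 2)
        return row


# ---------------------------------------------------------------------------
# annotation sidecar schema
# ---------------------------------------------------------------------------


class _AnnotationSidecar(BaseModel):
    """JSON schema of the per-scan annotation sidecar."""

    scan_id: str = ""
    laterality: str
    px_size_um: Optional[float] = None
    bmo_points: list[tuple[float, float]]
    fovea_xy: tuple[float, float]
    n_scan_lines: int = 24
    quality_pass: bool = True
    subject_id: str = ""
    width_mm: Optional[float] = None
    height_mm: Optional[float] = None


def read_annotation(json_path: str | Path, allow_any_count: bool = False) -> ScanAnnotation:
    """Read and validate an annotation sidecar JSON.

    Raises :class:`AnnotationError` on point counts other than 48 (unless
    ``allow_any_count``), self-intersecting contours, or a fovea inside the
    BMO polygon.
    """
    path = Path(json_path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise AnnotationError(f"cannot read annotation {path}: {exc}") from exc
    try:
        sidecar = _AnnotationSidecar.model_validate(payload)
    except Exception as exc:  # pydantic ValidationError
        raise AnnotationError(f"annotation {path} does not match the schema: {exc}") from exc
    return ScanAnnotation(
        bmo_points=np.asarray(sidecar.bmo_points, dtype=float),
        fovea_xy=tuple(sidecar.fovea_xy),
        laterality=sidecar.laterality,
        n_scan_lines=sidecar.n_scan_lines,
        scan_id=sidecar.scan_id,
        px_size_um=sidecar.px_size_um,
        quality_pass=sidecar.quality_pass,
        allow_any_count=allow_any_count,
    )


def write_annotation(ann: ScanAnnotation, json_path: str | Path) -> None:
    """Write an annotation sidecar JSON (inverse of :func:`read_annotation`)."""
    payload = {
        "scan_id": ann.scan_id,
        "laterality": ann.laterality,
        "px_size_um": ann.px_size_um,
        "bmo_points": [[float(x), float(y)] for x, y in ann.bmo_points],
        "fovea_xy": [float(ann.fovea_xy[0]), float(ann.fovea_xy[1])],
        "n_scan_lines": ann.n_scan_lines,
        "quality_pass": ann.quality_pass,
    }
    Path(json_path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


def _load_raster(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return np.asarray(arr)


def read_enface(image_path: str | Path, meta: Optional[dict] = None, **overrides) -> EnFaceScan:
    """Read a grayscale 8/16-bit TIFF or PNG en-face scan.

    ``meta`` (typically the parsed annotation sidecar) supplies px_size_um,
    laterality etc.; keyword ``overrides`` win over ``meta``.  Intensities
    are preserved losslessly — no rescaling or clipping happens here.
    """
    path = Path(image_path)
    if not path.exists():
        raise ScanError(f"image not found: {path}")
    try:
        arr = _load_raster(path)
    except Exception as exc:
        raise ScanError(f"cannot read raster {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ScanError(f"{path}: expected single-channel raster, got shape {arr.shape}")
    if arr.dtype not in (np.uint8, np.uint16):
        raise ScanError(f"{path}: expected 8- or 16-bit raster, got dtype {arr.dtype}")

    merged: dict = {}
    if meta:
        merged.update({k: v for k, v in meta.items() if v is not None})
    merged.update({k: v for k, v in overrides.items() if v is not None})
    fields = {
        k: merged[k]
        for k in (
            "px_size_um",
            "laterality",
            "scan_id",
            "subject_id",
            "width_mm",
            "height_mm",
            "quality_pass",
        )
        if k in merged
    }
    fields.setdefault("px_size_um", 5.7)
    fields.setdefault("quality_pass", True)
    return EnFaceScan(pixels=arr, **fields)


def write_mask(mask: np.ndarray, png_path: str | Path) -> None:
    """Write a binary mask as an 8-bit {0, 255} PNG."""
    mask = np.asarray(mask)
    out = np.where(mask.astype(bool), np.uint8(255), np.uint8(0))
    iio.imwrite(Path(png_path), out)


def read_mask(png_path: str | Path) -> np.ndarray:
    """Read a {0, 255} PNG back into a boolean mask."""
    arr = iio.imread(Path(png_path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr > 0


# ---------------------------------------------------------------------------
# results CSV
# ---------------------------------------------------------------------------


def write_result(results: VDResult | Sequence[VDResult], csv_path: str | Path) -> None:
    """Write one CSV row per scan, in the documented column order.

    Percentages are formatted to 2 decimals; pixel counts and the Otsu
    threshold are written at full precision.
    """
    if isinstance(results, VDResult):
        results = [results]
    df = pd.DataFrame([r.to_row() for r in results], columns=RESULT_COLUMNS)
    for col in ("vd_mean", "vd_s1", "vd_s2", "vd_s3", "vd_s4", "vd_mean_unweighted"):
        df[col] = df[col].map(lambda v: f"{v:.2f}")
    df["otsu_threshold"] = df["otsu_threshold"].map(repr)
    df.to_csv(csv_path, index=False)


def read_results(csv_path: str | Path) -> list[VDResult]:
    """Read a results CSV back into :class:`VDResult` objects.

    Pixel counts are integers in the CSV, so the reconstructed densities are
    exact; the formatted vd_* columns agree with them to 2 decimals.
    """
    df = pd.read_csv(csv_path, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            VDResult(
                n_vessel=tuple(int(row[f"n_vessel_{s}"]) for s in SECTOR_NAMES),
                n_total=tuple(int(row[f"n_px_{s}"]) for s in SECTOR_NAMES),
                threshold_used=float(row["otsu_threshold"]),
                params_hash=str(row["params_hash"]),
                scan_id=str(row["scan_id"]),
                subject_id=str(row["subject_id"]),
                laterality=str(row["laterality"]),
            )
        )
    return out


def write_overlay(scan: EnFaceScan, grid, mask, png_path: str | Path) -> None:
    """Render a QC overlay: scan, vessel mask, sector boundaries, BMO contour.

    The overlay is for visual inspection only; nothing downstream reads it.
    """
    from skimage.draw import line as sk_line

    img = np.asarray(scan.pixels, dtype=float)
    vmax = img.max() if img.max() > 0 else 1.0
    base = (img / vmax * 180.0).astype(np.uint8)
    rgb = np.stack([base, base, base], axis=-1)

    mask_arr = getattr(mask, "mask", mask)
    if mask_arr is not None:
        m = np.asarray(mask_arr, dtype=bool)
        rgb[m, 0] = np.minimum(255, rgb[m, 0].astype(int) + 75).astype(np.uint8)

    if grid is not None:
        labels = grid.labels
        # sector boundaries: label changes between neighbours
        edge = np.zeros_like(labels, dtype=bool)
        edge[:, 1:] |= labels[:, 1:] != labels[:, :-1]
        edge[1:, :] |= labels[1:, :] != labels[:-1, :]
        rgb[edge] = (0, 200, 255)
        cx, cy = grid.bmoc_xy
        fx = cx + 40.0 * np.cos(grid.axis_angle_rad)
        fy = cy + 40.0 * np.sin(grid.axis_angle_rad)
        rr, cc = sk_line(int(round(cy)), int(round(cx)), int(round(fy)), int(round(fx)))
        keep = (rr >= 0) & (rr < rgb.shape[0]) & (cc >= 0) & (cc < rgb.shape[1])
        rgb[rr[keep], cc[keep]] = (0, 255, 0)

    iio.imwrite(Path(png_path), rgb)
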