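"""Image, ROI and results-table input/output, and the shared spatial types.

Unit conventions used throughout the package
--------------------------------------------
* Pixel rasters are indexed ``[row, col]``; geometry uses continuous
  0-based pixel coordinates with ``x = column``, ``y = row`` and
  ``(0.0, 0.0)`` at the **center** of the top-left pixel.
* ``pixel_size`` is the physical edge length of one pixel in micrometers.
* Lengths are reported in µm, areas in µm², densities in µm⁻¹.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon
from skimage.draw import line as _draw_line

__all__ = [
    "Image2D",
    "PolygonROI",
    "ResultRecord",
    "UnsupportedImageError",
    "MissingCalibrationError",
    "InvalidROIError",
    "RESULTS_COLUMNS",
    "read_image",
    "write_image",
    "read_rois",
    "write_rois",
    "write_results_table",
    "read_results_table",
    "write_overlay",
]


class UnsupportedImageError(ValueError):
    """Raised for images that are not single-channel 2D rasters."""


class MissingCalibrationError(ValueError):
    """Raised when no physical pixel size can be determined for an image."""


class InvalidROIError(ValueError):
    """Raised for polygons that are degenerate or self-intersecting."""


@dataclass
class Image2D:
    """A single-channel 2D micrograph (or rendered phantom) with calibration.

    Parameters
    ----------
    pixels
        2D array of intensities, arbitrary units. Integer or float.
    pixel_size
        Physical edge length of one pixel, µm.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise UnsupportedImageError(
                f"expected a 2D single-channel raster, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise UnsupportedImageError(
                f"raster must be at least 2x2, got {self.pixels.shape}"
            )
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise MissingCalibrationError(
                f"pixel_size must be a positive finite number, got {self.pixel_size}"
            )
        if np.issubdtype(self.pixels.dtype, np.floating) and not np.all(
            np.isfinite(self.pixels)
        ):
            raise UnsupportedImageError("image intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class PolygonROI:
    """A simple polygon delimiting a plan-view capillary area.

    Vertices are ``(x, y)`` pairs in continuous pixel coordinates.
    """

    id: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidROIError(
                f"ROI {self.id!r}: need >= 3 (x, y) vertices, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidROIError(f"ROI {self.id!r}: vertices must be finite")
        poly = Polygon(v)
        if not poly.is_simple or not poly.is_valid:
            raise InvalidROIError(f"ROI {self.id!r}: polygon is self-intersecting")
        if poly.area <= 0:
            raise InvalidROIError(f"ROI {self.id!r}: polygon has zero area")
        self.vertices = v

    def to_shapely(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class ResultRecord:
    """One ROI's measurements: total SD length, area, and their ratio."""

    subject_id: str
    glomerulus_id: str
    roi_id: str
    l_sd: float  # µm
    area: float  # µm²
    density: float  # µm⁻¹
    d_fp_values: Optional[list[float]] = field(default=None)

    def __post_init__(self) -> None:
        for name in ("l_sd", "area", "density"):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {val}")
        expected = self.l_sd / self.area if self.area > 0 else 0.0
        scale = max(abs(expected), 1e-300)
        if abs(self.density - expected) > 1e-9 * scale + 1e-15:
            raise ValueError(
                f"density {self.density} inconsistent with l_sd/area = {expected}"
            )


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

_UM_PER_UNIT = {2: 25_400.0, "INCH": 25_400.0, 3: 10_000.0, "CENTIMETER": 10_000.0}


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> Optional[float]:
    page = tf.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    unit = tags.get("ResolutionUnit")
    if xres is None or unit is None:
        return None
    num, den = xres.value
    if num == 0:
        return None
    unit_val = getattr(unit.value, "value", unit.value)
    um = _UM_PER_UNIT.get(unit_val)
    if um is None:
        return None
    return um * den / num  # resolution is pixels per unit


def read_image(path: str | Path, pixel_size_override: Optional[float] = None) -> Image2D:
    """Read a single-channel 2D TIFF into an :class:`Image2D`.

    The physical pixel size is taken from ``pixel_size_override`` if given,
    otherwise from the TIFF resolution tags; if neither is available a
    :class:`MissingCalibrationError` is raised — the pixel size is never
    silently assumed.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if data.ndim != 2:
            raise UnsupportedImageError(
                f"{path.name}: expected single-channel 2D image, got shape {data.shape}"
            )
        if pixel_size_override is not None:
            pixel_size = float(pixel_size_override)
        else:
            meta = _pixel_size_from_tiff(tf)
            if meta is None:
                raise MissingCalibrationError(
                    f"{path.name}: no resolution metadata and no pixel-size override"
                )
            pixel_size = meta
    return Image2D(pixels=data, pixel_size=pixel_size)


def write_image(image: Image2D, path: str | Path) -> None:
    """Write an :class:`Image2D` as a TIFF with resolution metadata (px/cm)."""
    px_per_cm = 10_000.0 / image.pixel_size
    tifffile.imwrite(
        Path(path),
        image.pixels,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------


def read_rois(path: str | Path) -> list[PolygonROI]:
    """Read ROIs from the JSON dialect ``{"rois": [{"id":..., "vertices": [[x,y],...]}]}``."""
    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, dict) or "rois" not in payload:
        raise InvalidROIError(f"{path}: missing top-level 'rois' key")
    rois = []
    for entry in payload["rois"]:
        rois.append(PolygonROI(id=str(entry["id"]), vertices=np.asarray(entry["vertices"], dtype=float)))
    return rois


def write_rois(rois: Sequence[PolygonROI], path: str | Path) -> None:
    payload = {"rois": [{"id": r.id, "vertices": np.asarray(r.vertices).tolist()} for r in rois]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

RESULTS_COLUMNS = [
    "subject_id",
    "glomerulus_id",
    "roi_id",
    "l_sd_um",
    "area_um2",
    "density_per_um",
]


def write_results_table(records: Sequence[ResultRecord], path: str | Path) -> None:
    """Write measurement records as CSV, sorted by (subject, glomerulus, roi)."""
    rows = sorted(records, key=lambda r: (r.subject_id, r.glomerulus_id, r.roi_id))
    frame = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "glomerulus_id": r.glomerulus_id,
                "roi_id": r.roi_id,
                "l_sd_um": r.l_sd,
                "area_um2": r.area,
                "density_per_um": r.density,
            }
            for r in rows
        ],
        columns=RESULTS_COLUMNS,
    )
    frame.to_csv(path, index=False, float_format="%.8g", lineterminator="\n")


def read_results_table(path: str | Path) -> list[ResultRecord]:
    frame = pd.read_csv(path, dtype={c: str for c in RESULTS_COLUMNS[:3]})
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            ResultRecord(
                subject_id=row.subject_id,
                glomerulus_id=row.glomerulus_id,
                roi_id=row.roi_id,
                l_sd=float(row.l_sd_um),
                area=float(row.area_um2),
                # re-derive to stay consistent after CSV rounding
                density=float(row.l_sd_um) / float(row.area_um2) if float(row.area_um2) > 0 else 0.0,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Overlays
# ---------------------------------------------------------------------------


def _to_uint8(pixels: np.ndarray) -> np.ndarray:
    data = pixels.astype(np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        return np.zeros(data.shape, dtype=np.uint8)
    return np.clip((data - lo) / (hi - lo) * 255.0, 0, 255).astype(np.uint8)


def _draw_polyline(rgb: np.ndarray, points_xy: np.ndarray, color: tuple[int, int, int]) -> None:
    h, w = rgb.shape[:2]
    pts = np.rint(np.asarray(points_xy, dtype=float)).astype(int)
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = _draw_line(y0, x0, y1, x1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rgb[rr[keep], cc[keep]] = color


def write_overlay(image: Image2D, ridges, roi: Optional[PolygonROI], path: str | Path) -> None:
    """Render the segmentation on top of the micrograph as an RGB PNG.

    Segmented polylines are drawn in red, the ROI outline (if given) in
    yellow. The output has the same pixel dimensions as the input.
    """
    gray = _to_uint8(image.pixels)
    rgb = np.stack([gray, gray, gray], axis=-1)
    if ridges is not None:
        for seg in ridges.segments:
            pts = np.array([[p.x, p.y] for p in seg])
            if len(pts) >= 2:
                _draw_polyline(rgb, pts, (255, 0, 0))
    if roi is not None:
        closed = np.vstack([roi.vertices, roi.vertices[:1]])
        _draw_polyline(rgb, closed, (255, 255, 0))
    iio.imwrite(Path(path), rgb, extension=".png")
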