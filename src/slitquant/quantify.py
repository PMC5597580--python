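"""Diagnostic measurements: SD density (l_SD/A) and foot-process width (d_FP).

SD density is the total length of the segmented slit diaphragm inside a
plan-view capillary ROI divided by the ROI area, in µm⁻¹. Healthy
capillaries pack many narrow foot processes per area, so their slit
meander is long and the density high; effacement widens the processes,
straightens the slit and lowers the density.

Foot-process width is measured per profile line as the peak-to-peak
distance between the two slit-diaphragm intensity maxima flanking one
foot process, with subpixel quadratic peak refinement. Profile placement
is the operator's job, as in practice; only the density measurement is
automated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage, signal
from shapely.geometry import GeometryCollection, LineString, MultiLineString, Point

from .io_formats import Image2D, InvalidROIError, PolygonROI
from .ridge_detect import (
    DetectionParams,
    RidgeMap,
    RidgePoint,
    detect,
    polyline_length,
)

__all__ = [
    "DensityResult",
    "ProfileLine",
    "FootProcessWidth",
    "SubjectAggregate",
    "NoSlitPairError",
    "AmbiguousProfileError",
    "polygon_area",
    "clip_to_roi",
    "sd_density",
    "extract_profile",
    "measure_fp_width",
    "aggregate_subject",
]


class NoSlitPairError(ValueError):
    """Profile does not contain two slit-diaphragm peaks."""


class AmbiguousProfileError(ValueError):
    """Both detected peaks lie on one side of the profile midpoint."""


@dataclass(frozen=True)
class DensityResult:
    """SD length, area and density for one ROI."""

    l_sd: float  # µm
    area: float  # µm²
    density: float  # µm⁻¹

    def __post_init__(self) -> None:
        if self.l_sd < 0 or self.area < 0 or self.density < 0:
            raise ValueError("all density-result quantities must be >= 0")
        if abs(self.density * self.area - self.l_sd) > 1e-9 * max(self.l_sd, 1e-300):
            raise ValueError("density * area must equal l_sd")


@dataclass(frozen=True)
class ProfileLine:
    """Bilinear intensity samples along a straight line."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    step: float  # px between samples
    samples: np.ndarray


@dataclass(frozen=True)
class FootProcessWidth:
    """One peak-to-peak width measurement.

    ``peak_positions`` are the two refined peak positions along the
    profile, in px from its start.
    """

    d_fp: float  # µm
    peak_positions: tuple[float, float]


@dataclass(frozen=True)
class SubjectAggregate:
    """Per-subject summary built from per-glomerulus means."""

    subject_mean: float
    glomerulus_means: dict[str, float]
    n_glomeruli: int
    n_per_glomerulus: dict[str, int]


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def polygon_area(roi: PolygonROI, pixel_size: float) -> float:
    """ROI area in µm² (orientation-independent)."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return roi.to_shapely().area * pixel_size * pixel_size


def _interp_attributes(
    seg: Sequence[RidgePoint], coords: np.ndarray
) -> list[RidgePoint]:
    """Ridge points at `coords`, attributes taken from the nearest original point."""
    orig = np.array([[p.x, p.y] for p in seg])
    cum = np.concatenate([[0.0], np.cumsum(np.hypot(*(np.diff(orig, axis=0).T)))])
    line = LineString(orig)
    out = []
    for x, y in coords:
        s = line.project(Point(x, y))
        idx = int(np.argmin(np.abs(cum - s)))
        out.append(
            RidgePoint(x=float(x), y=float(y), normal_angle=seg[idx].normal_angle, strength=seg[idx].strength)
        )
    return out


def clip_to_roi(ridges: RidgeMap, roi: PolygonROI) -> RidgeMap:
    """Intersect every segment with the ROI polygon.

    Boundary crossings are cut at the exact segment–edge intersection
    point; sub-segments keep the original point order. Attributes of
    inserted boundary points are copied from the nearest original point.
    """
    poly = roi.to_shapely()
    clipped: list[list[RidgePoint]] = []
    for seg in ridges.segments:
        if len(seg) < 2:
            continue
        line = LineString([(p.x, p.y) for p in seg])
        inter = line.intersection(poly)
        parts: list[LineString] = []
        if inter.is_empty:
            continue
        if isinstance(inter, LineString):
            parts = [inter]
        elif isinstance(inter, (MultiLineString, GeometryCollection)):
            parts = [g for g in inter.geoms if isinstance(g, LineString)]
        # keep traversal order along the original line
        parts.sort(key=lambda g: line.project(g.interpolate(0.0)))
        for part in parts:
            coords = np.asarray(part.coords)
            if len(coords) < 2:
                continue
            clipped.append(_interp_attributes(seg, coords))
    return RidgeMap(segments=clipped, params=ridges.params)


def _roi_within_image(roi: PolygonROI, image: Image2D) -> bool:
    h, w = image.shape
    v = roi.vertices
    return bool(
        (v[:, 0] >= -0.5).all()
        and (v[:, 0] <= w - 0.5).all()
        and (v[:, 1] >= -0.5).all()
        and (v[:, 1] <= h - 0.5).all()
    )


def sd_density(
    image: Image2D,
    roi: PolygonROI,
    params: Optional[DetectionParams] = None,
    ridges: Optional[RidgeMap] = None,
) -> DensityResult:
    """Slit-diaphragm density l_SD/A inside one plan-view ROI.

    Runs detection (unless a precomputed ``ridges`` map is supplied),
    clips the segmentation to the ROI, and divides the clipped length by
    the full polygon area.
    """
    if not _roi_within_image(roi, image):
        raise InvalidROIError(f"ROI {roi.id!r} extends outside the image bounds")
    area = polygon_area(roi, image.pixel_size)
    if area <= 0:
        raise InvalidROIError(f"ROI {roi.id!r} has zero area")
    if ridges is None:
        ridges = detect(image, params)
    inside = clip_to_roi(ridges, roi)
    l_sd = sum(
        polyline_length(seg, image.pixel_size) for seg in inside.segments if len(seg) >= 2
    )
    return DensityResult(l_sd=l_sd, area=area, density=l_sd / area)


# ---------------------------------------------------------------------------
# Foot-process width
# ---------------------------------------------------------------------------


def extract_profile(
    image: Image2D,
    p0: tuple[float, float],
    p1: tuple[float, float],
    step: float = 0.25,
) -> ProfileLine:
    """Bilinearly interpolated intensity profile from p0 to p1 (px coords)."""
    if step <= 0:
        raise ValueError("step must be > 0")
    x0, y0 = p0
    x1, y1 = p1
    dist = math.hypot(x1 - x0, y1 - y0)
    if dist < 8 * step:
        raise ValueError(
            f"profile too short: |p1-p0| = {dist:.3f} px < 8 * step = {8 * step:.3f} px"
        )
    n = int(math.floor(dist / step)) + 1
    ts = np.arange(n) * step / dist
    xs = x0 + ts * (x1 - x0)
    ys = y0 + ts * (y1 - y0)
    samples = ndimage.map_coordinates(
        np.asarray(image.pixels, dtype=np.float64),
        np.vstack([ys, xs]),
        order=1,
        mode="nearest",
    )
    return ProfileLine(p0=(x0, y0), p1=(x1, y1), step=step, samples=samples)


def _refine_peak(samples: np.ndarray, i: int) -> float:
    """Quadratic subpixel refinement through samples i-1, i, i+1."""
    if i <= 0 or i >= len(samples) - 1:
        return float(i)
    a, b, c = samples[i - 1], samples[i], samples[i + 1]
    denom = a - 2 * b + c
    if abs(denom) < 1e-300:
        return float(i)
    delta = 0.5 * (a - c) / denom
    return float(i + np.clip(delta, -0.5, 0.5))


def measure_fp_width(profile: ProfileLine, pixel_size: float) -> FootProcessWidth:
    """Peak-to-peak foot-process width from one profile.

    Local maxima are refined to subpixel positions by a quadratic fit;
    the two retained peaks are the maxima nearest to, and on opposite
    sides of, the profile midpoint (the foot-process center).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    samples = profile.samples
    peaks, _ = signal.find_peaks(samples)
    if len(peaks) < 2:
        raise NoSlitPairError(
            f"found {len(peaks)} local maxima; need one slit peak on each side"
        )
    mid = (len(samples) - 1) / 2.0
    refined = np.array([_refine_peak(samples, int(i)) for i in peaks])
    left = refined[refined < mid]
    right = refined[refined >= mid]
    if len(left) == 0 or len(right) == 0:
        raise AmbiguousProfileError(
            "all detected peaks lie on one side of the profile midpoint"
        )
    p_left = left.max()
    p_right = right.min()
    d_fp = (p_right - p_left) * profile.step * pixel_size
    return FootProcessWidth(
        d_fp=float(d_fp),
        peak_positions=(float(p_left * profile.step), float(p_right * profile.step)),
    )


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def aggregate_subject(per_glomerulus: Mapping[str, Sequence[float]]) -> SubjectAggregate:
    """Subject-level mean as the unweighted mean of per-glomerulus means.

    Mirrors the sampling design of scoring a fixed number of foot
    processes per glomerulus and several glomeruli per subject: each
    glomerulus contributes equally regardless of how many measurements it
    holds.
    """
    if not per_glomerulus:
        raise ValueError("need at least one glomerulus")
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for gid, values in per_glomerulus.items():
        vals = np.asarray(list(values), dtype=float)
        if vals.size == 0:
            raise ValueError(f"glomerulus {gid!r} has no measurements")
        means[gid] = float(vals.mean())
        counts[gid] = int(vals.size)
    subject_mean = float(np.mean(list(means.values())))
    return SubjectAggregate(
        subject_mean=subject_mean,
        glomerulus_means=means,
        n_glomeruli=len(means),
        n_per_glomerulus=counts,
    )
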