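"""Ground-truthed synthetic micrographs of interdigitating foot processes.

Healthy podocyte foot processes interlock like the fingers of two folded
hands, with the slit diaphragm (SD) tracing a meander between them. The
generator models that meander as a comb: vertical fingers of width
``d_fp_true`` alternating from two sides, connected by rounded turns, with
per-finger width jitter. Several comb rows are stacked to fill the field,
mimicking adjacent foot-process territories separated by major processes.

Rendering treats the ~30 nm SD as a sub-resolution line: the imaged
cross-section is the microscope point spread function, so the path is
rasterized as a line-integrated Gaussian ridge of the requested PSF FWHM,
plus background, optional out-of-focus haze, Poisson shot noise and
Gaussian read noise.

A separate sampler emulates the geometric bias of measuring foot-process
width on thin physical sections (TEM): sections rarely cut a process
orthogonally, so the apparent width is the true width divided by the sine
of the section obliquity angle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .io_formats import Image2D

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "OPTICS_PRESETS",
    "optics_preset",
    "generate_interdigitation_path",
    "render_phantom",
    "simulate",
    "write_truth",
    "sample_apparent_widths",
]

#: PSF full width at half maximum (µm) emulating each imaging mode. The
#: widefield value sits at the diffraction limit of a high-NA objective;
#: structured illumination roughly halves it; deconvolution of widefield
#: stacks lands in between — enough to sharpen the image but, at healthy
#: foot-process spacing, not enough to separate neighboring slits.
OPTICS_PRESETS = {
    "sim": 0.12,
    "widefield": 0.25,
    "deconvolved_widefield": 0.18,
}


def optics_preset(name: str) -> float:
    """PSF FWHM (µm) for an imaging-mode preset."""
    try:
        return OPTICS_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown optics preset {name!r}; choose from {sorted(OPTICS_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic micrograph.

    Geometric parameters are in µm; intensities in arbitrary counts.

    ``photon_gain`` is the number of detected photons per intensity unit:
    shot noise is Poisson in photons, so the relative noise at intensity I
    is ``1/sqrt(photon_gain * I)`` and ``photon_gain = inf`` disables it.
    """

    d_fp_true: float = 0.25
    finger_length: float = 2.0
    region: tuple[float, float] = (16.4864, 16.4864)  # (width, height), µm
    meander_amplitude_jitter: float = 0.10
    pixel_size: float = 0.0322
    psf_fwhm: float = 0.12
    background_level: float = 10.0
    signal_level: float = 100.0
    photon_gain: float = 1.0
    read_noise_sd: float = 2.0
    haze_fraction: float = 0.10
    row_spacing: float = 0.40  # gap between comb rows (major process), µm
    margin: float = 0.50  # keep the path this far from the region edge, µm
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_fp_true", "finger_length", "pixel_size", "psf_fwhm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.region[0] <= 0 or self.region[1] <= 0:
            raise ValueError("region dimensions must be > 0")
        if not (0 <= self.haze_fraction < 1):
            raise ValueError("haze_fraction must be in [0, 1)")
        if self.d_fp_true >= self.finger_length:
            raise ValueError("d_fp_true must be smaller than finger_length")
        if not (0 <= self.meander_amplitude_jitter < 1):
            raise ValueError("meander_amplitude_jitter must be in [0, 1)")


@dataclass
class PhantomTruth:
    """Generator-side ground truth for a rendered phantom.

    ``sd_paths`` are polylines in µm coordinates with the origin at the
    region's top-left corner; ``true_density = sd_length / region_area``.
    """

    sd_paths: list[np.ndarray]
    sd_length: float  # µm
    region_area: float  # µm²
    d_fp_true: float  # µm
    true_density: float = field(init=False)

    def __post_init__(self) -> None:
        self.true_density = self.sd_length / self.region_area


def _rounded_comb_row(
    x_positions: np.ndarray, y_bottom: float, y_top: float, radius: float
) -> np.ndarray:
    """One comb meander: verticals at x_positions, alternating turns, rounded corners."""
    pts: list[tuple[float, float]] = []
    n_arc = 8  # samples per quarter turn; chord error << pixel size for r ~ d_fp/4

    def arc(cx: float, cy: float, a0: float, a1: float) -> None:
        for a in np.linspace(a0, a1, n_arc + 1):
            pts.append((cx + radius * math.cos(a), cy + radius * math.sin(a)))

    m = len(x_positions)
    for k, x in enumerate(x_positions):
        going_up = k % 2 == 0
        y_start, y_end = (y_bottom, y_top) if going_up else (y_top, y_bottom)
        first, last = k == 0, k == m - 1
        # vertical run, shortened by the corner radius at connected ends
        y0 = y_start + (0 if first else radius) * (1 if going_up else -1)
        y1 = y_end - (0 if last else radius) * (1 if going_up else -1)
        pts.append((x, y0))
        pts.append((x, y1))
        if not last:
            x_next = x_positions[k + 1]
            if going_up:  # turn over the top: left arc then right arc
                arc(x + radius, y_top - radius, math.pi, math.pi / 2)
                pts.append((x_next - radius, y_top))
                arc(x_next - radius, y_top - radius, math.pi / 2, 0.0)
            else:  # turn under the bottom
                arc(x + radius, y_bottom + radius, math.pi, 3 * math.pi / 2)
                pts.append((x_next - radius, y_bottom))
                arc(x_next - radius, y_bottom + radius, 3 * math.pi / 2, 2 * math.pi)
    out = np.array(pts)
    # collapse consecutive duplicates introduced by arc endpoints
    keep = np.ones(len(out), dtype=bool)
    keep[1:] = np.hypot(*(np.diff(out, axis=0).T)) > 1e-12
    return out[keep]


def _polyline_length_um(path: np.ndarray) -> float:
    return float(np.sum(np.hypot(*(np.diff(path, axis=0).T))))


def generate_interdigitation_path(spec: PhantomSpec) -> PhantomTruth:
    """Comb-meander SD ground truth for the given phantom parameters.

    Finger widths are jittered multiplicatively by up to
    ``±meander_amplitude_jitter`` (seeded); corner radius is
    ``d_fp_true / 4``; the truth length is the exact polyline length.
    """
    width, height = spec.region
    rng = np.random.default_rng(spec.seed)
    radius = spec.d_fp_true / 4.0
    usable_w = width - 2 * spec.margin
    usable_h = height - 2 * spec.margin
    if usable_w < 2 * spec.d_fp_true or usable_h < spec.finger_length:
        raise ValueError(
            "region too small for one full meander period at these parameters"
        )

    row_pitch = spec.finger_length + spec.row_spacing
    n_rows = int((usable_h + spec.row_spacing) // row_pitch)
    paths: list[np.ndarray] = []
    for row in range(max(n_rows, 1)):
        y_bottom = spec.margin + row * row_pitch
        y_top = y_bottom + spec.finger_length
        xs = [spec.margin]
        while True:
            jitter = 1.0 + spec.meander_amplitude_jitter * rng.uniform(-1.0, 1.0)
            nxt = xs[-1] + spec.d_fp_true * jitter
            if nxt > width - spec.margin:
                break
            xs.append(nxt)
        if len(xs) < 2:
            raise ValueError("region too small for one full meander period")
        paths.append(_rounded_comb_row(np.array(xs), y_bottom, y_top, radius))

    total = sum(_polyline_length_um(p) for p in paths)
    return PhantomTruth(
        sd_paths=paths,
        sd_length=total,
        region_area=width * height,
        d_fp_true=spec.d_fp_true,
    )


def _deposit_path(canvas: np.ndarray, path_px: np.ndarray, step_px: float = 0.2) -> None:
    """Accumulate line length onto the raster with bilinear weights."""
    h, w = canvas.shape
    for (x0, y0), (x1, y1) in zip(path_px[:-1], path_px[1:]):
        seg_len = math.hypot(x1 - x0, y1 - y0)
        if seg_len < 1e-12:
            continue
        n = max(int(math.ceil(seg_len / step_px)), 1)
        ts = (np.arange(n) + 0.5) / n
        xs = x0 + ts * (x1 - x0)
        ys = y0 + ts * (y1 - y0)
        wgt = seg_len / n  # px of length per sample
        ix = np.floor(xs).astype(int)
        iy = np.floor(ys).astype(int)
        fx = xs - ix
        fy = ys - iy
        for dx, dy, ww in (
            (0, 0, (1 - fx) * (1 - fy)),
            (1, 0, fx * (1 - fy)),
            (0, 1, (1 - fx) * fy),
            (1, 1, fx * fy),
        ):
            cx = ix + dx
            cy = iy + dy
            ok = (cx >= 0) & (cx < w) & (cy >= 0) & (cy < h)
            np.add.at(canvas, (cy[ok], cx[ok]), wgt * ww[ok])


def render_phantom(truth: PhantomTruth, spec: PhantomSpec) -> Image2D:
    """Render the ground-truth path as a noisy fluorescence micrograph.

    The SD path is a line-integrated Gaussian ridge of FWHM ``psf_fwhm``
    whose crest (for an isolated straight stretch) reaches ``signal_level``
    above the background. Haze adds ``haze_fraction`` of the signal blurred
    at 10× the PSF width. Shot noise is Poisson via ``photon_gain`` and the
    read noise is additive Gaussian. Fully seeded and reproducible.
    """
    width, height = spec.region
    n_cols = int(round(width / spec.pixel_size))
    n_rows = int(round(height / spec.pixel_size))
    sigma_px = spec.psf_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / spec.pixel_size

    # rasterize on a supersampled grid, blur with the PSF there, then
    # integrate over each camera pixel (area binning); this keeps the
    # rendered crest independent of the subpixel phase of the path
    ss = 4
    fine_ps = spec.pixel_size / ss
    density = np.zeros((n_rows * ss, n_cols * ss), dtype=np.float64)
    for path in truth.sd_paths:
        path_px = path / fine_ps - 0.5  # µm frame -> fine-pixel-center coords
        _deposit_path(density, path_px, step_px=0.5)

    sigma_fine = sigma_px * ss
    fine = ndimage.gaussian_filter(density, sigma_fine, mode="constant")
    binned = fine.reshape(n_rows, ss, n_cols, ss).mean(axis=(1, 3))
    # crest normalization for an isolated straight line: the rendered
    # cross-section is the PSF widened by the deposit footprint (tent,
    # variance 1/6 fine px²) and the pixel aperture (box, variance ss²/12)
    sigma_eff = math.sqrt(sigma_fine**2 + 1.0 / 6.0 + ss * ss / 12.0)
    ridge = binned * math.sqrt(2.0 * math.pi) * sigma_eff * spec.signal_level
    if spec.haze_fraction > 0:
        ridge = ridge + spec.haze_fraction * ndimage.gaussian_filter(
            ridge, 10.0 * sigma_px, mode="constant"
        )
    ideal = ridge + spec.background_level

    rng = np.random.default_rng(spec.seed + 1)  # independent of the geometry stream
    if math.isfinite(spec.photon_gain):
        noisy = rng.poisson(np.clip(ideal, 0, None) * spec.photon_gain) / spec.photon_gain
    else:
        noisy = ideal
    if spec.read_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, spec.read_noise_sd, size=ideal.shape)
    return Image2D(pixels=noisy.astype(np.float64), pixel_size=spec.pixel_size)


def simulate(spec: PhantomSpec) -> tuple[Image2D, PhantomTruth]:
    """Generate ground truth and render it; the one-call phantom entry point."""
    truth = generate_interdigitation_path(spec)
    return render_phantom(truth, spec), truth


def write_truth(truth: PhantomTruth, spec: PhantomSpec, path: str | Path) -> None:
    """Save the ground truth (and the generating parameters) as JSON."""
    payload = {
        "sd_length_um": truth.sd_length,
        "area_um2": truth.region_area,
        "true_density_per_um": truth.true_density,
        "d_fp_true_um": truth.d_fp_true,
        "seed": spec.seed,
        "spec": asdict(spec),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def sample_apparent_widths(
    true_width: float, n: int, seed: Optional[int] = None
) -> np.ndarray:
    """Apparent foot-process widths on randomly oriented thin sections.

    The section obliquity angle θ is drawn with density ∝ sin²θ on
    (0, π/2] (a section plane meets a cylindrical process with probability
    weighted by the projected cross-section), and the apparent width is
    ``true_width / sin θ`` — always an overestimate. The harmonic mean of
    these apparent widths times 8/(3π) recovers the true width.
    """
    if true_width <= 0:
        raise ValueError("true_width must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n, dtype=np.float64)
    filled = 0
    while filled < n:
        m = max(int((n - filled) * 2.2), 1024)
        theta = rng.uniform(0.0, math.pi / 2.0, size=m)
        accept = rng.uniform(0.0, 1.0, size=m) < np.sin(theta) ** 2
        take = theta[accept][: n - filled]
        out[filled : filled + take.size] = true_width / np.sin(take)
        filled += take.size
    return out
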