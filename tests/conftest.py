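"""Shared fixtures: phantom renderings and geometry helpers."""

from __future__ import annotations

import numpy as np
import pytest

from slitquant import Image2D, PhantomSpec, PolygonROI, simulate
from slitquant.phantom import PhantomTruth, render_phantom
from slitquant.ridge_detect import default_sigma

SIM_PIXEL_SIZE = 0.0322  # µm/px
SIM_PSF_FWHM = 0.12  # µm
SIM_SIGMA_PX = default_sigma(SIM_PSF_FWHM / SIM_PIXEL_SIZE)


def full_image_roi(image: Image2D, roi_id: str = "full") -> PolygonROI:
    h, w = image.shape
    return PolygonROI(
        id=roi_id,
        vertices=np.array(
            [[-0.5, -0.5], [w - 0.5, -0.5], [w - 0.5, h - 0.5], [-0.5, h - 0.5]]
        ),
    )


def noise_free_spec(**overrides) -> PhantomSpec:
    kwargs = dict(
        photon_gain=float("inf"), read_noise_sd=0.0, haze_fraction=0.0, seed=0
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def render_straight_line(
    p0_px: tuple[float, float],
    p1_px: tuple[float, float],
    spec: PhantomSpec,
) -> tuple[Image2D, float]:
    """Render one straight Gaussian ridge; returns (image, true length µm)."""
    ps = spec.pixel_size
    path = np.array(
        [
            [(p0_px[0] + 0.5) * ps, (p0_px[1] + 0.5) * ps],
            [(p1_px[0] + 0.5) * ps, (p1_px[1] + 0.5) * ps],
        ]
    )
    length = float(np.hypot(*(path[1] - path[0])))
    truth = PhantomTruth(
        sd_paths=[path],
        sd_length=length,
        region_area=spec.region[0] * spec.region[1],
        d_fp_true=spec.d_fp_true,
    )
    return render_phantom(truth, spec), length


@pytest.fixture(scope="session")
def healthy_phantom():
    """Default-noise SIM-optics phantom at healthy foot-process width."""
    spec = PhantomSpec(d_fp_true=0.25, seed=1)
    image, truth = simulate(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free SIM-optics phantom at healthy foot-process width."""
    spec = noise_free_spec(d_fp_true=0.25, seed=1)
    image, truth = simulate(spec)
    return spec, image, truth
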