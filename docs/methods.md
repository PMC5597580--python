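# Methods

## Ridge model and detector

The slit diaphragm (SD) is ~30 nm wide — far below the resolution of any
light microscope used here — so its imaged cross-section is the point
spread function (PSF) itself: a curvilinear ridge of Gaussian profile with
FWHM equal to the PSF width. Detection follows the classic scale-space
line-extraction recipe:

1. **Derivative fields.** The image is convolved with 1D Gaussian
   derivative kernels (separable; reflection boundaries) at scale
   `sigma` px. The sampled kernels are renormalized to be exact on
   polynomials — the smoother sums to 1, derivative kernels have zero DC
   response, unit response to a ramp / parabola — so a constant image
   yields exactly zero derivatives despite kernel truncation.
2. **Line points.** At each pixel the Hessian `[[rxx, rxy], [rxy, ryy]]`
   is eigen-decomposed; the eigenvector of the maximum-magnitude
   eigenvalue is the ridge normal, and for bright ridges that eigenvalue
   must be negative. The first derivative along the normal is extrapolated
   to its zero: `t = −(rx·nx + ry·ny) / (rxx·nx² + 2rxy·nx·ny + ryy·ny²)`;
   the pixel holds a line point if the subpixel position stays inside the
   pixel (`|t·nx| ≤ 0.5`, `|t·ny| ≤ 0.5`, with 10⁻³ px slack for crests
   sitting numerically on a pixel boundary). Ridge strength is the
   magnitude of the Hessian eigenvalue.
3. **Linking.** Segments are seeded at unvisited points with strength at
   or above the upper threshold (strongest first; ties by (y, x)) and
   grown in both directions along the local tangent, stepping to the
   nearest unvisited point within `max_link_distance` whose normal
   orientation differs by less than `max_link_angle` and whose strength
   clears the lower threshold, with forward progress required. Each point
   is used at most once; crossings therefore split into separate segments,
   which leaves length sums unaffected. Segments shorter than
   `min_segment_length` are discarded.

### Detection parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `sigma` | `fwhm_px/(2√3) + 0.5` | px | line-detector scale convention for a line of width `fwhm_px`; 1.58 px for SIM optics at 0.0322 µm/px |
| `lower/upper_threshold` | calibrated | intensity·px⁻² | see below |
| `min_segment_length` | 5 | px | suppresses isolated noise responses |
| `max_link_distance` | 2.5 | px | must bridge the 2 px gap left when a single crest pixel drops out (noise flips the subpixel test); 1.8 px fragments chains that the 5 px filter then discards (~6% length loss on noisy renders) |
| `max_link_angle` | 30 | deg | tangent continuity; tolerates curvature down to ~2 px radius at ~1 px steps |
| `polarity` | bright | — | fluorescent line on dark background |

**Threshold calibration.** When thresholds are not given they are set per
image as fixed fractions (0.15 and 0.30) of the 0.995-quantile of the
ridge-strength map. The high quantile sits at the crest-level response of
whatever structure the image contains, so the thresholds scale with
intensity and PSF; fractions of it transfer across images whose ridge
coverage differs (a fixed-rank quantile such as 0.95 lands in noise on a
sparse image and inside the signal on a dense one). The fractions leave a
wide margin on both sides at realistic SNR: crest responses are tens of
times the noise-floor response. On a pure-noise image with self-calibrated
thresholds the detector will, like any self-scaling detector, report some
structure; thresholds calibrated on a structured image and carried over
suppress it.

### Accuracy and known limitations

* Straight noise-free ridges: length within ~1%, mean perpendicular
  localization error well below 0.1 px; a 50 px-radius circle within 0.5%.
* Detected segments overshoot line endpoints by roughly the combined
  Gaussian scale (the across-line criterion stays valid slightly beyond
  the end), and U-turns with curvature radius below the PSF width are
  localized poorly — on the comb phantom both effects together bias total
  length by −3% to −6% at default noise.
* A ridge crest lying exactly on a pixel boundary is a degenerate case:
  the quadratic zero-crossing estimate overshoots 0.5 px in both adjacent
  pixels and the crest can be missed. Measure-zero in real data; avoided
  in the test geometry.

## Density and width measurement

`l_SD/A` intersects every detected polyline with the ROI polygon (exact
edge-crossing cuts, via shapely), sums clipped lengths, and divides by the
full polygon area. The area deliberately includes slit-free patches inside
the ROI — the denominator is the capillary area, not the stained area.
ROIs use 0-based continuous pixel coordinates with (0, 0) at the center of
the top-left pixel.

`d_FP` is measured along operator-placed profile lines (bilinear
sampling, default step 0.25 px): local maxima are refined by a quadratic
fit through three neighboring samples, and the two peaks retained are the
maxima nearest to, and on opposite sides of, the profile midpoint — the
foot process center, mirroring the convention of measuring at the FP
half-length. Bilinear interpolation is piecewise linear between pixel
centers, so raw sub-grid sampling snaps maxima toward pixel nodes; the
quadratic refinement restores subpixel accuracy where samples align with
the grid, and residual snapping is bounded by half a pixel (~0.016 µm at
SIM sampling), small against the ~0.07 µm biological spread of healthy
`d_FP`.

Subject-level values are unweighted means of per-glomerulus means,
matching the sampling design of a fixed number of FP per glomerulus and
several glomeruli per subject; both per-glomerulus and per-subject values
are available to the statistics layer.

## Statistics

* Summaries report mean, median (midpoint convention), sample (n−1) SD.
* Mann–Whitney U is reported as `min(U1, U2)` with midrank tie handling.
  For combined samples of ≤ 16 values the two-sided p is exact:
  enumeration of all label assignments over the pooled midranks,
  `p = P(min(U1, U2) ≤ observed)` (enumeration handles ties exactly, so
  the exact path is not restricted to tie-free data). Larger samples use
  the normal approximation with tie and continuity corrections; the
  `method` field records which path was taken.
* Student's t is the two-sided pooled-variance test; OLS regression
  reports `R² = 1 − SS_res/SS_tot`, with a constant response treated as a
  perfect flat fit (slope 0, R² 0) rather than an error.
* Severity is `(control mean − value) / control SD`, positive below
  control; invariant under common rescaling.

## Stereology of section-based width measurement

A thin section meets a foot process at obliquity angle θ and shows an
apparent width `w/sin θ ≥ w`. The angle density is taken ∝ sin²θ on
(0, π/2] — the unique power-law weighting whose harmonic-mean correction
factor `E[sin θ] = (∫sin³)/(∫sin²) = 8/(3π) ≈ 0.849` matches the
classical correction used for TEM morphometry. `gundersen_true_mean`
multiplies the harmonic mean of apparent widths by 8/(3π);
`sample_apparent_widths` draws from the model by rejection sampling
(uniform θ proposals, acceptance ∝ sin²θ, ~50% acceptance), and
`obliquity_correction_factor` recomputes the constant by quadrature or
Monte Carlo. The model presumes straight, cylinder-like processes and
isotropic sectioning; it is a bias demonstration, not a reconstruction of
any particular specimen geometry.

## Phantom generator

The generator emulates the plan-view appearance of interdigitating FP: the
SD path is a comb meander — vertical fingers of width `d_fp_true`
alternating from two sides, finger length 2 µm, corners rounded at radius
`d_fp_true/4`, per-finger width jittered multiplicatively by ±10%
(seeded) — stacked in rows separated by a 0.4 µm gap standing in for major
processes. Ground truth (exact polyline length, region area, their ratio)
is exported alongside.

Rendering: the path is rasterized on a 4× supersampled grid (bilinear
length deposition), blurred with a Gaussian PSF, and integrated over each
camera pixel; the crest of an isolated straight stretch is normalized to
`signal_level` above `background_level` accounting for the deposit and
aperture footprints, which keeps the crest independent of the path's
subpixel phase to well under 1%. Optional haze adds a fraction of the
signal blurred at 10× the PSF width (an out-of-focus-light proxy). Shot
noise is Poisson with `photon_gain` detected photons per intensity unit
(relative noise `1/√(gain·I)`; `gain = inf` disables it), followed by
additive Gaussian read noise. All randomness flows from a single seed;
geometry and noise use separate streams derived from it.

### Default study conditions

| parameter | value | note |
|---|---|---|
| canvas | 512 × 512 px at 0.0322 µm/px (16.5 µm field) | preserves the acquisition sampling at desk scale |
| PSF FWHM | 0.12 µm (SIM), 0.25 µm (widefield), 0.18 µm (deconvolved) | widefield at the cited ~200 nm diffraction limit plus realistic objective margin; SIM at the two-fold improvement; deconvolution in between |
| `d_fp_true` | 0.25 µm default; series 0.25–0.70 µm | healthy group mean ≈ 0.25 µm, effaced ≈ 0.68 µm |
| signal/background | 100 / 10 counts | crest SNR ≈ 10 with `photon_gain` 1 |
| read noise | 2 counts | sCMOS-like |
| haze | 10% of signal | mild reconstruction/out-of-focus artifact proxy |

At these conditions the comb truth density is ≈ 3.0 µm⁻¹ at
`d_fp = 0.25` µm and ≈ 1.3 µm⁻¹ at 0.675 µm — the same regime as
clinically reported healthy (≈ 3.1 µm⁻¹) and effaced (≈ 1.8 µm⁻¹) values.

**What the phantom does not emulate:** capillary curvature (the meander is
planar), SIM reconstruction artifacts beyond the haze term, heterogeneous
staining intensity, branching major processes, or out-of-plane slits.
Passing phantom tests demonstrates that the measurement chain is unbiased
on images satisfying the ridge model at realistic SNR; it does not certify
performance on tissue with strong reconstruction artifacts, which is why a
human checkpoint before segmentation remains part of the intended
workflow.

## Numerical conventions

* All geometry in 0-based pixel-center coordinates (x = column, y = row);
  physical calibration enters only when lengths/areas are converted to µm.
* Results CSV rows are sorted by (subject, glomerulus, roi) and written
  with 8 significant digits, so identical inputs give byte-identical
  files; CLI outputs are written to a temporary file and renamed, so
  failures leave no partial outputs.
* Pixel size precedence: explicit override > TIFF resolution metadata;
  never a silent default.
* Degenerate inputs: blank images yield empty ridge maps and zero
  density; zero-area or self-intersecting ROIs, sub-2-point polylines,
  constant-x regressions and zero-variance controls raise typed errors.

## Problem sizes used in the test suite

Phantom-based checks run on the 512² default canvas (the scale-consistency
check also renders a 750² field at half the pixel size); the stereology
closure uses 10⁶ draws and the acceptance script 10⁷; exact Mann–Whitney
oracles enumerate all group assignments for n₁, n₂ ≤ 4. These sizes hold
every stochastic tolerance with wide margin while keeping the full suite
under a minute of compute on one core.
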