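# slitquant

Quantification of podocyte foot-process effacement from plan-view
super-resolution micrographs of the slit diaphragm.

## The problem

Minimal change disease and related nephrotic syndromes show essentially one
morphological hallmark: effacement (flattening and widening) of podocyte
foot processes (FP) on the glomerular capillaries. Healthy FP are ~200–250 nm
wide — below the diffraction limit — so diagnosis traditionally requires
transmission electron microscopy of thin sections. Structured illumination
microscopy (SIM) of nephrin-stained sections resolves the slit diaphragm
(SD), the junction bridging adjacent FP, directly in plan view: a long,
tightly meandering line over healthy capillaries that straightens and
shortens as FP efface.

`slitquant` implements the image-analysis side of this diagnostic route for
pathologists and image analysts:

* **SD segmentation** — a Steger-style subpixel curvilinear ridge detector
  (Gaussian derivative scale space, Hessian line-point criterion, hysteresis
  linking) extracts the SD as polylines.
* **SD density** — `l_SD/A`: total segmented SD length per plan-view
  capillary area (µm⁻¹), the automated effacement readout. Healthy tissue
  has high density; effacement lowers it.
* **Foot-process width** — `d_FP`: peak-to-peak distance between the two SD
  intensity maxima flanking one FP along an operator-placed profile line,
  with subpixel quadratic peak refinement.
* **Severity scoring & statistics** — per-subject aggregation (mean of
  per-glomerulus means), Mann–Whitney U (exact by enumeration at small n),
  Student's t, OLS regression, and severity expressed as control-group
  standard deviations below the control mean:
  `severity = (mean_control − value) / SD_control`.
* **Stereology** — the section-obliquity bias of TEM width measurement:
  apparent width = true width / sin θ with section angles θ distributed
  ∝ sin²θ, and the harmonic-mean correction
  `d_true = (8 / 3π) × harmonic mean of apparent widths`, 8/(3π) ≈ 0.849.
* **Phantom generator** — ground-truthed synthetic micrographs of
  interdigitating FP (comb meander of width `d_FP`, rendered as a
  PSF-width Gaussian ridge with shot/read noise and haze) under SIM
  (0.12 µm FWHM), widefield (0.25 µm) and deconvolved-widefield (0.18 µm)
  optics presets, which makes every stage testable without patient data.

## Worked example

Simulate a healthy-pattern phantom (true FP width 0.25 µm, SIM optics) and
measure its SD density:

```sh
$ slitquant simulate --dfp 0.25 --optics sim --seed 1 \
      --out healthy.tif --truth healthy_truth.json
$ slitquant density --image healthy.tif --roi full --pixel-size 0.0322 \
      --out healthy.csv --overlay healthy.png
... INFO detected 239 segments (24000 points) at sigma=1.576 px
... INFO ROI full: l_SD=765.501 µm, A=271.801 µm², density=2.8164 µm⁻¹
```

The detector recovered 765.5 µm of slit over a 271.8 µm² field, a density
of 2.82 µm⁻¹ against a generator ground truth of 3.02 µm⁻¹ (−7%; the
residual is corner curvature below the PSF width plus noise-induced
dropouts). An effaced phantom (`--dfp 0.675`) measures ≈1.2 µm⁻¹ — the
healthy/effaced contrast that drives the diagnosis.

The TEM sectioning bias and its correction:

```sh
$ slitquant tem-bias --width 0.25 --n 1000000 --seed 7
true width:              0.2500 µm
apparent mean (biased):  0.3186 µm
harmonic mean:           0.2946 µm
corrected (x 8/3π):      0.2500 µm
```

Random section obliquity inflates the arithmetic mean width by ~27%; the
harmonic-mean correction recovers the true width.

For real micrographs, pass a single-channel TIFF (pixel size from TIFF
resolution tags or `--pixel-size`) and a ROI file delimiting plan-view
capillary areas:
`{"rois": [{"id": "g1_roi1", "vertices": [[x, y], ...]}]}` in 0-based
pixel coordinates. Results are written as CSV
(`subject_id,glomerulus_id,roi_id,l_sd_um,area_um2,density_per_um`);
`slitquant stats --control a.csv --case b.csv` compares groups and scores
severity. `slitquant fpwidth` measures `d_FP` along `--line x0,y0,x1,y1`
profiles.

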