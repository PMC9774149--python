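# spherotrack

Analysis pipeline for drug-response experiments on matrix-embedded 3D
tumor spheroids imaged in brightfield. It segments one spheroid per well,
extracts a sub-pixel boundary contour, computes shape morphometrics, and
aggregates per-well time series into growth and drug-response endpoints.
A synthetic phantom generator with analytic ground truth makes every
stage testable without microscope data.

## What it computes

Per image (one spheroid per well per day):

- **S** — cross-sectional area at the focal plane (shoelace integral of
  the sub-pixel contour, μm²)
- **P_o** — actual boundary perimeter (μm)
- **P_e = 2·√(π·S)** — equivalent perimeter (circle of the same area)
- **EPI = (P_o − P_e)/P_e** — excess perimeter index; 0 for a circle,
  rising with invasive, lobed boundaries
- **roughness** — coefficient of variation of centroid-to-boundary radii
- **d = 2·√(S/π)** — equivalent-circle diameter (μm)
- **V = (4/3)·π·(d/2)³** — spherical volume (μm³)

Per well / group:

- **RTV = V_terminal / V_original** (terminal day defaults to 7)
- **TGI% = (RTV_control − RTV_treatment)/RTV_control × 100**, with the
  vehicle group of the same oxygen condition as control
- day-7 / day-1 diameter ratio
- viability% from background-subtracted A570 − A600 absorbance,
  normalized to the vehicle control
- invasiveness class: *less-invasive* iff EPI < 0.5 (strict, configurable)
- 4-parameter logistic dose-response fits with an explicit
  `ic50-not-reached` status when no viability crosses 50%

## Command line

```sh
# synthesize a phantom plate (images + layout/absorbance/truth CSVs)
spherotrack generate --out plate/ --seed 1 --replicates 6 --days 7

# measure images and summarize endpoints
spherotrack measure --images plate/images --layout plate/layout.csv \
    --absorbance plate/absorbance.csv --out results/

# summarize an existing metrics.csv
spherotrack summarize --metrics results/metrics.csv \
    --absorbance plate/absorbance.csv --layout plate/layout.csv --out results/

# end-to-end demo (generate + measure + summarize)
spherotrack run --out demo/ --seed 1
```

Images are discovered by the `{well}_{day:02d}.tif|.png` filename
pattern. Per-well segmentation failures are logged and recorded in
`manifest.json`; they never abort a run. Identical inputs, config, and
seed reproduce byte-identical outputs.

## Output tables

Written to the results directory with deterministic column order:

- `metrics.csv` — well, day, S, P_o, P_e, EPI, roughness, d, V
- `timecourse.csv` — per (condition, dose, day) mean ± SEM of viability,
  diameter, roughness, EPI
- `day7_summary.csv` — terminal-day cross-section, diameter ratio, and
  invasiveness class
- `tgi.csv` — per (condition, dose) RTV means, TGI%, group sizes
- `dose_response.csv` — per condition 4PL parameters or status
- `manifest.json` — config, version, inputs, per-well errors

## Phantom generator

`spherotrack.phantom` simulates the full study design: daily logistic
radius growth damped by a Hill inhibition of dose, protrusion amplitude
as the invasiveness knob, hypoxia as multiplicative factors on growth /
invasion / drug effect, linear absorbance readouts, and rendered
brightfield-like rasters whose analytic boundary polygon is returned
alongside each image. Per-well seeds derive from a stable hash of
(master seed, well id), so any well regenerates independently.

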