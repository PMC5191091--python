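# svoct — speckle-variance OCT analysis of trans-nail drug delivery

Topical drugs barely cross the human nail plate: its dense dorsal layer is
an effective permeation barrier. Drilling an array of microthermal ablation
zones (MAZs) with a fractional CO₂ laser opens inverted-pyramid channels
through the plate, and optical coherence tomography (OCT) can watch the
drug move through them — diffusing particles decorrelate the speckle
pattern between frames, so the temporal **speckle variance (SV)** of
time-series B-scans maps where the drug is moving.

`svoct` is that analysis as a tested Python pipeline, for researchers in
biomedical optics and transungual drug delivery:

- **Speckle variance** against the reference frame at drug application,
  with m = (I_t0 + I_tn)/2:
  `SV(x,z) = sqrt(((I_t0−m)² + (I_tn−m)²)/2) = |I_t0 − I_tn|/2`,
  a depth-cumulative **shadow correction**
  `SVR = SV · exp(±(1/γ) Σ_{i≤z} SV(x,i))`, and a noise-floor threshold
  (fixed 0.05 on normalized intensity, or an empirical percentile of the
  pre-application frames).
- **Segmentation & realignment**: per-A-scan surface detection, per-column
  integer realignment of the series to the reference surface (the drug
  film adds a spurious optical path), nail-bed delineation and plate
  masking with an MAZ include/exclude policy.
- **MAZ morphometry**: crater detection and per-energy penetration depth /
  aperture diameter statistics.
- **Diffusion quantification**: ROI time courses (Region I at crater tips,
  II upper nail, III between craters), onset and saturation times, and the
  SV center-of-mass depth trajectory whose descent rate compares drug
  formulations (liquid vs cream).
- **A synthetic phantom** with full ground truth — layered nail, craters,
  a finite-difference drug-concentration field, fully developed speckle
  with closed-form frame-to-frame decorrelation `ρ = exp(−g·C·Δt)`,
  shadowing, attenuation and bulk motion — so every stage is verifiable
  without the (undeposited) in-vivo scans.

## Worked example

```python
from svoct import phantom
from svoct.pipeline import run_pipeline
from svoct.diffusion import compare_formulations

courses = {}
for preset in ("liquid_like", "cream_like"):
    series, truth = phantom.make_fixture(preset, seed=0)   # 46 frames, 0.5 s apart
    result = run_pipeline(series)                          # realign → SV → ROIs
    courses[preset] = result.timecourse
    print(preset, result.timecourse.onset_s)

cmp = compare_formulations(courses["liquid_like"], courses["cream_like"])
print("COM descent-rate ratio:", round(cmp.com_rate_ratio, 2))
```

prints

```
liquid_like {'I': 1.0, 'II': 0.5, 'III': 1.0}
cream_like {'I': 2.5, 'II': 0.5, 'III': 2.0}
COM descent-rate ratio: 1.18
```

Reading: SV at the crater tips (Region I) rises at 1.0 s for the liquid
but only at 2.5 s for the viscous cream (slower crater filling); midway
between craters (Region III) the liquid arrives at ~1 s vs ~2 s for the
cream; and the liquid's SV center of mass descends ~1.2× faster — the
liquid formulation penetrates the plate faster, which is what the contrast
in diffusivity and fill velocity between the presets encodes.

The numbered drivers under `analysis/` run the same steps as a narrative
(`01` simulate phantoms → `02` crater morphometry per laser energy → `03`
static null control → `04` liquid-vs-cream comparison) and write their
tables under `results/`. The command-line interface wraps the identical
pipeline, e.g.

```bash
svoct run --preset liquid_like --policy exclude-maz --seed 0 --outdir out/
```

## Layout

```
src/svoct/        phantom, oct_io, segmentation, speckle_variance,
                  morphometry, diffusion, pipeline, cli
analysis/         numbered narrative drivers writing results/
tests/            unit + property + acceptance suites (pytest)
docs/methods.md   models, parameter rationale, limitations
```
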