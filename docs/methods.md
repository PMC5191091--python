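# Methods

`svoct` quantifies drug transport through laser-drilled human nail from
time-series OCT B-scans, using temporal speckle variance as the motion
contrast. Because no in-vivo scans are distributed with the package, every
stage is developed and verified against a synthetic dynamic-speckle phantom
with full ground truth. This note records the models, the parameter choices
that matter, and what the synthetic results do and do not show.

## Speckle-variance contrast

Each frame I_tn is compared against the reference frame I_t0 acquired at
drug application. With m = (I_t0 + I_tn)/2 the per-pixel two-frame speckle
variance is

    SV(x,z) = sqrt( ((I_t0 − m)² + (I_tn − m)²) / 2 ) = |I_t0 − I_tn| / 2 .

SV is computed on *linear* intensity normalized to [0, 1]. The published
noise threshold of 0.05 is only meaningful on a bounded scale, which is the
reason for the normalization; whether the original analysis used log or
linear intensity is not stated, and linear was chosen as the convention
under which the fixed threshold is interpretable.

Scattering by aggregated drug particles shadows the tissue beneath them and
suppresses SV at depth. The correction rescales each pixel by an
exponential of the depth-cumulative SV of the same frame:

    SVR(x,z) = SV(x,z) · exp( s · (1/γ) · Σ_{i=1..z} SV(x,i) ),

with attenuation coefficient γ > 0 and sign s. The printed form has s = +1
(amplifying); because the correction's stated purpose is to *reduce* the
shadowing effect, the sign is configurable and +1 is the default. No value
of γ is published. The default is automatic and per frame: γ = 10× the
median (over columns) of the depth-integrated raw SV, which keeps the
correction factor of order e^0.1 regardless of how much SV a frame carries;
the factor is additionally capped at e³. A fixed γ can be supplied instead.

Thresholding zeroes SV below the noise floor and outside the nail-plate
mask. Two threshold policies exist: the published constant 0.05, and an
empirical 99th percentile of raw SV pooled over all pre-application frames
against the reference. On the static phantom the two agree in effect (both
zero out essentially the whole plate).

## Segmentation and realignment

The drug film on the nail adds an optical path length that would read as
spurious SV, so every frame is realigned axially to the reference surface
before SV is computed. Choices that proved load-bearing:

- **Detection.** Per A-scan, the surface is the first crossing of an
  adaptive (Otsu) threshold on a lightly smoothed image (σ = 1.5 px axially
  and laterally), refined to the strongest local axial gradient, then
  median-filtered across columns (window 7). The detection threshold is
  computed once on the reference frame and frozen for the whole series:
  drug-induced histogram drift otherwise moves first crossings coherently
  across long column runs, which the realignment would misread as motion.
- **Integer shifts only.** Subpixel interpolation would itself change
  intensities and inject SV.
- **Shift smoothing.** Bulk motion is global and the nail surface is
  transversely smooth, so the per-column shift profile is median-filtered
  (window 31 columns). Without this, ±1 px detector jitter on the wetted
  surface voxel shifts single columns and every shifted column contributes
  full-depth spurious SV — an artifact that, left uncontrolled, swamps the
  drug signal.
- **Craters carry no surface.** Columns inside open ablation craters have
  no stable nail surface (the detector follows the crater wall, which
  moves as wall speckle decorrelates); their shifts are interpolated from
  the flanking intact-surface columns.
- **Envelope.** For masking and morphometry the nail surface proper is
  recovered from the detected interface by a grey-scale morphological
  opening (window 49 columns) that removes crater dips while preserving
  tilt.

The plate/bed boundary is the strongest negative axial gradient within an
expected-thickness window (600 ± 105 µm) below the surface, found in two
stages: a global offset from the median surface-aligned gradient profile,
then a per-column refinement within ±3 px. Columns without a negative
extremum fall back to the expected thickness and are flagged.

## Ablation-zone morphometry

Craters appear as low-backscatter inverted-pyramid voids open to the
surface. Candidates are connected regions below 0.5× the frame's Otsu
threshold (a relative criterion, so measurements are invariant to global
intensity rescaling), restricted to a 500 µm band below the surface and
required to touch it. Detection smooths at σ = 1 px for robustness to
speckle, then refines each candidate's boundary on a σ = 0.5 px image
within a 3-px dilation — the heavier smoothing otherwise erodes the one-
pixel apex and the aperture edges and biases depth low by ~2 px.
Penetration depth is (deepest candidate row − local surface row)·(7 µm);
aperture diameter is the candidate's transverse extent at the surface
row·(5 µm). Whether the published diameters were taken at the surface or at
the widest point is unstated; the surface aperture is used.

## ROI time courses, onset, saturation, center of mass

Three regions are monitored, three squares (default 10×10 px) each: Region
I at the crater tips, Region II in the upper nail between/flanking the
apertures (12 px below the surface), Region III midway between crater pairs
at mid-plate depth. Per region and time point the summed SV per square is
averaged; the sd across the three squares is the error bar. Onset and
saturation criteria are not published and were fixed as: onset = first time
the curve exceeds the pre-application baseline mean + 3 sd for two
consecutive samples; saturation = first time the curve reaches 95 % of its
plateau (mean of the final 10 % of samples) and stays above 90 % thereafter.

The SV center of mass (COM) is Σ z·SV / Σ SV over the masked plate,
referenced to the local surface so bulk position does not bias depth, in
µm. Frames with zero total SV are undefined (NaN).

**Descent rate.** The COM descent rate that compares formulations is a
weighted least-squares slope *anchored through zero depth at drug
application* over a common 10 s window, weighted per frame by total
suprathreshold SV. The anchor is exact by construction — before any SV has
accumulated the COM sits at the surface — and makes the statistic the mean
front velocity on a common clock. A free-intercept slope fitted inside each
formulation's own active window was tried first and rejected: it
self-normalizes the contrast away (a slow formulation traverses the same
plate span over a proportionally longer window and shows the same local
slope), to the point of inverting the expected ordering. Frames with
little SV get little weight because their COM is correspondingly noisy.

## The phantom

The generator emulates the nail experiments at desk scale: a layered plate
(dorsal/intermediate/ventral reflectivities 0.55/0.45/0.50 over a 0.35 bed)
of 600 µm over a nail bed, 5/7 µm transverse/axial pixels matching the
system resolutions, exponential depth attenuation (µ = 0.0018 /µm), and
inverted-pyramid craters with the per-energy depth/width presets
(372/321/290/255 µm × 203/183/171/137 µm for 50/40/30/20 mJ).

**Speckle.** Fully developed speckle is the intensity of a spatially
low-pass-filtered complex circular-Gaussian field (exponential intensity
marginal), filtered to the stated resolutions. Frames evolve by AR(1)
blending of the complex field with mixing chosen so the *intensity*
correlation between adjacent frames is exactly ρ = exp(−g·C·Δt), where C is
the local drug concentration and g = 0.35 s⁻¹ the decorrelation gain.
Static tissue (C = 0) is frozen speckle plus sensor noise (σ = 0.002).
A per-frame integer bulk axial shift (σ = 0.3 px) and a shadow factor
exp(−0.008 · Σ_above C) complete the frame model. The shadow gain is set so
shadow dimming alone stays below the 0.05 SV floor (it is an artifact the
correction addresses, not a stand-in for the drug signal) while still
localizing visibly under high-concentration columns.

**Transport.** C(x,z,t) obeys ∂C/∂t = D∇²C on the plate (explicit FD,
internally sub-stepped below the CFL limit), with no-flux lateral and
air-side boundaries and an absorbing nail bed. Sources are Dirichlet: the
crater walls at full strength, gated by a top-down fill front moving at a
formulation-dependent velocity (a wall voxel becomes a source when the
front passes its depth); and the exposed surface at 0.3× wall strength —
the intact dorsal layer is the permeation barrier whose existence motivates
laser-assisted delivery in the first place.

**Preset dynamics** were fixed once from t ≈ L²/4D arithmetic against the
emulation targets (earlier onset for the liquid by roughly a factor two;
Region I saturating on the ~15 s scale) and then frozen:

| parameter | liquid_like | cream_like |
|---|---|---|
| D (µm²/s) | 1800 | 900 |
| crater fill (µm/s) | 400 | 150 |

Region II sits ~85 µm under the weak surface source and Region III ~160 µm
from the nearest wall, giving onsets of ~0.5–1 s (liquid) vs ~1.5–2.5 s
(cream) and Region I saturation near 15 s in the rendered series. Presets
use three 50 mJ craters at a 360 µm pitch, 0.5 s frames, 5 pre-application
frames and 41 post frames (20 s); the observation grid is far coarser than
the instrument's 100 frames/s because the analysis operates on a
seconds-scale process.

**What the phantom does not contain:** physical beam propagation or photon
transport, polarization, blood flow under the nail bed, non-Fickian or
concentration-dependent transport, drug aggregation (the bright moving
spots seen in vivo), and real nail-surface roughness. Passing tests
therefore demonstrate the *pipeline's* correctness and its robustness to
speckle, sensor noise, bulk motion and shadowing — not that the transport
model describes any particular drug.

## Numerical choices and degenerate inputs

- Diffusion CFL: sub-step at 0.9× the stability limit; requested output
  times need not be stable steps themselves.
- All randomness flows from one seeded `numpy` generator per rendered
  series; identical config + seed reproduces series bit-for-bit.
- Realignment shifts beyond ¼ of the image depth flag the frame as
  motion-corrupted; the frame passes through unshifted.
- Surface detection on an all-zero or constant image raises; a uniform
  image in bed detection yields the expected-thickness fallback with every
  column flagged.
- An empty measurement list produces an empty (but typed) summary table;
  single measurements report sd 0.
- Zero-SV frames yield NaN COM entries, written as empty CSV cells.
- Time courses shorter than 2 (onset) or 10 (saturation) samples leave
  those times undefined rather than guessing.

## Known limitations

- Integer-pixel realignment leaves sub-pixel residual motion; with the
  default noise floor it is invisible, but a much lower threshold would
  expose it.
- The shadow correction's printed positive exponent amplifies deep SV; the
  package follows the print by default but both signs are available.
- Crater diameters during active diffusion are biased a few percent wide by
  the drug-darkened wall voxels.
- On tilted surfaces the morphological envelope is exact only for tilts
  that change by <1 px across the opening window (49 columns ≈ 245 µm).
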