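# Methods

This package models and quantifies the acoustic clutter that a microscope's
optical window injects into a co-registered ultrasound image, together with
the acoustic and optical characterization used to choose a better window
material. Everything runs off synthetic data; the generators stand in for
the instrument and are first-class, tested code.

## Substitution-method material characterization

A single-element transducer insonifies the film at normal incidence through
water. Echoes are gated with a 0.115 µs rectangular window and their
magnitude spectra averaged over repetitions. With `S_ff`, `S_bf` the
front/back-face spectra of the sample, and `S0bar` the location-averaged
reference spectrum from a plexiglass plate of known reflectivity
`Γ₀ = 0.37`:

- reflection:   `|Γ_s| = |Γ₀| · S_ff(f_c) / S0bar(f_c)`, evaluated at the
  discrete bin nearest `f_c = 30 MHz`;
- impedance:    `Z_s = Z_w (1 + |Γ_s|) / (1 − |Γ_s|)`, with water fixed at
  `Z_w = 1.48 MRayl` (ρ = 1000 kg/m³, c = 1480 m/s);
- attenuation:  per frequency in the reference's −3 dB band (19–34 MHz),
  `α(f) = 8.686 · ln[(S_bf²/S_ff²) · K] / (−4d)` with `d` the thickness in
  cm; `K = 1/(1−Γ²)²` for symmetric faces, and
  `K = Γ_ff² / ((1−Γ_ff²)² Γ_bf²)` when the two faces reflect differently
  (gloss/matte films). An unweighted least-squares line
  `α(f) = α_s (f − 30) + α₃₀` gives the slope (dB·cm⁻¹·MHz⁻¹) and the
  30 MHz intercept (dB·cm⁻¹).

`S` is treated as the *amplitude* spectrum throughout: Γ is an amplitude
ratio and round-trip power loss is `e^(−4αd)`, which is the unique reading
that makes the reflection and attenuation estimators dimensionally
consistent and reproduces the published impedance column exactly.

Numerical choices: the gated segment is zero-padded to 4096 points before
the rFFT — a 0.115 µs gate alone yields an 8.7 MHz grid, far too coarse for
the 19–34 MHz fit, and padding a gate that contains the entire echo is
exact rather than interpolative. `f_c` stays "nearest bin", with no peak
interpolation. Non-positive spectral ratios (possible under noise) are
dropped from the fit and counted. Gate centers are supplied by the caller;
the CLI locates them by peak-envelope detection.

The plate forward model (`gen_plate_pulse_echo`) emits a Gaussian 30 MHz,
80 % fractional-bandwidth pulse (a broadband immersion transducer excited
by a nanosecond spike), scales the front echo by `Γ_ff`, the back echo by
`(1−Γ_ff²)Γ_bf`, applies the linear attenuation law in the frequency
domain over the round trip `2d`, adds per-location multiplicative jitter
(default 0.3 %, matching the published standard errors) and white noise
(default 1 % of the pulse peak, i.e. 40 dB SNR), with 5 locations × 500
repetitions as the default acquisition. The law is extrapolated over the
whole DFT band without clamping; for steep slopes this implies a fraction
of a dB of sub-band gain across a sub-millimeter film and keeps the
generator an exact inverse of the estimator. Because the model applies
exactly the physics the estimators invert, noiseless recovery is
essentially exact (≪ 1 %); the tests exercise a (Γ, α_s, α₃₀) grid and the
asymmetric-face case at a 2 % tolerance. Thin fast materials (coverslip
glass) fold the back-face echo into the front gate — the generator flags
overlapping echoes, and the analysis driver characterizes glass at slide
thickness instead.

## Echo matrices and beamforming

A 128-element, 0.1 mm pitch linear array sampled at 62.5 MHz for 28.656 µs
(1792 samples, `round(f_s·T)+1`) is the default geometry; c = 1480 m/s maps
samples to depth via `d = t·c/2`. Two acquisitions fill the same
`[transmit × receive × time]` container:

- **FRM** (focused response matrix): rayline transmissions, one f/6
  aperture per center element, focused at 8 mm. Aperture width is
  `focal/f#`; the element count is the largest odd integer ≤ width/pitch
  (13 at f/6, 8 mm), clipped at the array edges (transmission #3 keeps
  elements 1–9). Focusing delays come from per-element path lengths to the
  focal point, offset so the minimum is zero.
- **IRM** (inter-element response matrix): one element pulsed at a time.

`to_analytic` applies a Hilbert transform along time; envelopes are
`|analytic|` and log compression is `20·log10(env + 1)` — the +1 keeps
zeros finite and defines the 0 dB floor.

`irm_to_frm` synthesizes the focused acquisition by delaying IRM transmit
slices with the physical aperture's delays and summing. Fractional delays
use an exact FFT phase ramp (zero-padded against wrap-around). Two-point
linear interpolation — kept as an option — attenuates an 18 MHz carrier at
62.5 MHz sampling by up to cos(πf/f_s) ≈ 0.62 at half-sample shifts, which
by itself would swamp the few-percent physical/synthetic equivalency this
module is meant to demonstrate.

`das_receive` forms one A-line per transmission with dynamic receive
focusing: at depth `z` the aperture spans `z/f#` about the rayline axis
(clipped, never empty), element traces are delayed by
`t_tx + (z + √(z² + Δx²))/c` (transmit time referenced to the aperture
center's firing instant), gathered with linear interpolation on the
analytic signal, summed, envelope-detected and log-compressed. Since the
same interpolation acts on both reconstruction routes it cancels in their
comparison. No transmit or receive apodization is applied, and element
directivity is not modeled — the sensitivity half-angle α = 0.34 rad enters
only through the matched-aperture rule `f# = 1/(2 tan α) ≈ 1.41`.

Noise floors are estimated from the matched transmit/receive traces over
1–6 mm of anechoic water (central 81 transmissions at full scale) and
subtracted per beamformer kind and per receive f/#, so every image and
clutter number is referenced to its own floor at 0 dB.

## The ringing-window scene model

The imaging scene holds a specular plate (the optical window), point
scatterers, optional Poisson/Gaussian speckle, and white electronic noise.
Element emission is an omnidirectional point source with 1/r spreading
(distances in mm); the plate reflects via its image source (front face
∝ `Γ_ff`; back face ∝ `(1−Γ_ff²)Γ_bf`, attenuated through the film and
delayed by its internal round trip).

Ringing is phenomenological, motivated by the drum analogy: when a
transmit wavefront strikes the plate, every surface point within a lateral
extent (default 6 mm) of the beam axis re-emits a damped sinusoid
`a(t) = A_ring · p_inc · e^(−t/τ) · sin(2πf_r t)` with `f_r` defaulting to
the pulse center frequency (18 MHz), decay τ = 1 µs, and `p_inc` the
incident pressure at the point. Two modeling commitments matter:

1. **Onset.** Each firing element starts the drum when its wavefront first
   reaches the plate (`t = delay + depth/c`); the strike propagates across
   the plate effectively instantaneously (in-plate wave speeds are several
   times the water speed). Off-axis elements therefore receive ring energy
   beginning at the window-depth round-trip time — which is where off-axis
   clutter is observed in RF frames, and what lets wide receive apertures
   fold it into pixels *above* the window. A pure water-path onset would
   instead place all off-axis energy strictly below the window.
2. **Drive.** The coupling scales as
   `A_ring · [Γ_ff + (1−Γ_ff²)·Γ_bf·10^(−α(f_r)·2d/20)]`: the front-face
   term falls with window reflectivity, and the back-face term falls when
   water replaces air behind the window (`Γ_bf` drops from ≈0.95 to the
   window/water value). This single expression produces all four
   directional findings: low-Γ windows ring less, wet coupling rings less,
   single-element (synthetic-aperture) transmissions ring ∝ 1/13 of a
   13-element focus, and f/1 receive admits more off-axis energy than f/2.

The model is linear in scatterer and ringing amplitudes, and every
generator is a pure function of (parameters, seed). Because the re-emission
is linear in `p_inc`, a synthesized FRM carries the same coherent ring as a
physical FRM — so the synthetic-aperture acquisition's pre-beamforming
clutter is measured on its *raw single-element frames*, which is also the
acquisition a user would inspect. What the model does **not** attempt:
plate vibro-acoustic modes, grating-lobe-accurate element fields,
absolute pressure calibration, or the unexplained high-gain
synthetic-aperture clutter reported for the real instrument. Passing tests
therefore demonstrate the *directions and mechanics* of clutter reduction,
not the instrument's absolute decibel levels.

## Clutter quantification

- **Pre-beamforming**: per RF frame, the maximum of the log-compressed
  envelope in an ROI at the window depth (± one 0.115 µs pulse length in
  depth) on receive elements farther than 5 mm (full scale) from the
  transmit axis, minus the noise floor; mean/std over the central
  transmissions. Works on FRM (rayline) and IRM (synthetic aperture)
  frames alike.
- **Post-beamforming**: the mean floor-referenced B-mode level in a
  0.45 mm × 4 mm ROI whose lower border sits 0.15 mm above the window
  front face, laterally centered.
- **Normalization**: condition means are expressed relative to the
  glass/rayline/dry reference; re-normalizing an already-normalized result
  against the same reference is a no-op.

Comparisons across conditions use one-sided pooled-variance two-sample
t-tests (the MATLAB `ttest2` convention), validated against a label-
permutation oracle.

## Optical PSF

Bead z-stacks (0.2 µm steps, 0.125 µm pixels) are summed over z, x/y
profiles taken through the brightest pixel, and the FWHM read as
(last − first sample strictly above half max) × spacing, with no
background subtraction and no sub-sample interpolation — faithfully the
field workflow. This index rule deterministically under-reads the
continuous FWHM by 0–2 spacings (≈1.2 on average over sub-pixel bead
positions); tests assert that sharp bound rather than pretending the
estimator is unbiased. Small-n summaries are medians and ranges. The bead
generator emits 3D Gaussians with configurable lateral FWHMs, a random
sub-voxel center, axial FWHM 1.6 µm, and additive noise.

## Problem sizes

Full-scale simulation (128×128×1792 per condition) is supported but the
test and analysis profiles run a scaled study — 64 elements, 768 samples,
window at 4 mm, off-axis rule at 2.6 mm, central 32 transmissions — chosen
so every geometric relation (f/6 aperture arithmetic, ROI placement
relative to the window, ring extent vs array span) carries over while a
ten-seed condition grid simulates in minutes. The speckle/Rayleigh check
runs on a 16-element profile with >10 scatterers per resolution cell.

## Known limitations

- The ringing model's amplitude is linear in incident pressure; radiation-
  force (intensity-driven) excitation would be quadratic and would further
  separate focused from unfocused transmissions. Directional conclusions
  are unaffected; absolute dB differences between transmit schemes are not
  comparable to instrument measurements.
- No frequency-dependent water attenuation or element directivity; both
  are negligible for the ≤ 10 mm paths and small angles exercised here.
- The substitution method carries no diffraction/focusing correction, and
  overlapping face echoes (thin, fast films) bias Γ upward — flagged, not
  corrected.
- Depth-of-field effects along z in the bead stacks are a pure Gaussian;
  aberration (e.g. matte film surfaces) is out of scope.
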