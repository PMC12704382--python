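# Methods

This note documents the models, parameter choices and numerical conventions
behind `tipflux`, and what the synthetic validation does and does not show.

## Acquisition model

All defaults mirror a standard confocal tip-growth acquisition: 135 frames at
4.455 s (10 min including t₀), 7.3759 px/µm (0.1356 µm pixels, 0.0184 µm² per
pixel), a 295×224 px field. Every operation takes the calibration explicitly,
so other geometries work unchanged; several tests use a reduced 176×120 px
field to render many movies cheaply — only the empty margins shrink, the cell
geometry and noise are identical.

## Synthetic movies

The generator renders the statistical structure the analysis assumes, not
photorealistic optics (no PSF beyond Gaussian spots, no photobleaching, no
branching):

- **Geometry.** The hypha is an axis-aligned tube (default width 2.5 µm)
  entering from the field edge, capped by a half-disc; the tip is the extreme
  cap point and advances at the configured elongation rate (0.104–0.753
  µm/min in cohorts). Pixel-center coordinates, origin top-left, tip
  positions stored as floats.
- **Intensity.** Detector baseline 100 plus diffuse cytosolic fluorescence
  (60 above baseline) inside the cell; i.i.d. Gaussian noise (SD 5)
  everywhere, clipped at 0; float32 frames, optional 16-bit quantization on
  write.
- **Spitzenkörper regime.** A Gaussian spot (2σ = 0.8 µm) centered 0.5 µm
  behind the tip, peak 600 above cytosol, modulated as 1 + a·sin(2πt/p) with
  a uniformly random phase. The spot offset and diameter are calibration
  choices — they are not measured quantities.
- **Crescent regime.** The same spot placed on the apical dome at an angular
  position performing a reflected Gaussian random walk on ±80° (step SD 0.2
  rad/frame): each frame shows a submembranous spot; the time projection
  shows an arc. The step size is chosen so that the resulting apical-mean
  variability stays at the level of cytosolic fluctuation, matching the
  observation that crescent-type hyphae are temporally indistinguishable from
  cytosolic controls.
- **Control regime.** Cytosol only, at a brighter diffuse level (110) than
  the reporter strains. This mirrors free cytosolic eGFP being diffusely
  brighter than an endogenous fusion, and matters because the TDC features
  are not scale-free: temporal indistinguishability between controls and
  crescent hyphae presumes comparable intensity scales.
- **Cohort amplitude law.** In cohorts the relative oscillation amplitude is
  a(p) = 0.42·(p/44.55 s)². The quadratic growth encodes a constant vesicle
  influx integrated over longer cycles and released in more pronounced
  pulses; practically, it compensates the sampling cadence and the
  detrend-filter response (both attenuate slow oscillations' frame-to-frame
  differences) so the oscillatory regime forms one coherent
  temporal-variability cluster — the defining property of that regime.
  Periods are drawn uniformly from 31.39–64.93 s; oscillatory hyphae draw
  rates from the faster half of the rate range, the others from the slower
  half, reproducing the positive roundness-rate association at cohort level.

What passing tests show: every stage recovers its generating parameter
(track within 1 px, rate within 10%, period within 1 s, regime separation by
clustering) under realistic noise. What they do not show: robustness to
optical aberrations, focal drift, photobleaching, curved or branching hyphae,
or intensity distributions unlike the Gaussian model.

## Tracking

The tracking criterion is deterministic and auditable: foreground is the
largest connected component of pixels ≥ the extracellular threshold, after a
3×3 binary majority filter that removes the ~2% of noise pixels an
(mean + 2 SD) threshold necessarily passes without displacing the boundary.
The growth axis is the major axis of the frame-0 foreground, signed toward
the extreme point farther from the image border (the base enters from a
border). Per frame, the centerline is estimated from the leading 10-px band
and the tip is the mean per-row boundary crossing (+0.5 px) over the rows
within 1.4 px of the centerline — sub-pixel and robust against single
boundary speckles. Displacement is clamped to 5 px/frame; the 50×50 ROI
anchors the tip 1 µm from its leading edge and is clamped inside the field.
Losing the foreground, or the tip reaching the border, raises a track-lost
error carrying the last valid frame.

Elongation rate is the OLS slope (with standard error) of tip displacement
projected on the net growth direction, in µm vs minutes.

## Footprint

The time projection is the NaN-aware pixel mean with per-pixel counts; the
accumulation region keeps pixels at or above the (100−p)th percentile
(linear interpolation between order statistics; ties included, so the mask
can slightly exceed p%). Roundness uses the ellipse-fit definition
4·area/(π·major_axis²) on the largest connected component; areas ≤ 0.5 µm²
are flagged unreliable since single-pixel changes dominate there. Width is
the mean of three mask transects perpendicular to the axis at 2.1/3.3/4.5 µm
behind the tip. Curvature comes from a smoothing-spline fit (cubic,
s = n·(0.02 µm)²) to the 0.5-level contour of the Gaussian-smoothed (σ=1 px)
mask over a 10 µm arc centered on the apex, evaluated at the most apical
point; on noise-free hemispherical caps it recovers 1/r within 10%, with
noise within ~20%.

## Time series and filtering

Threshold technique 1 (extracellular, 50×50 ROI auto-placed at the corner
farthest from the cell, all frames) feeds the clustering dataset; technique 2
(cytosolic, 16×16 ROI auto-placed 5 µm behind the frame-0 tip, first 20
frames) feeds the spectral dataset. Both are mean + 2 SD; below-threshold
pixels become NaN; the two datasets are produced independently.

The apical region is the half-plane within 4 µm of the tip along the growth
axis, intersected with the crop. Because tracking pins the tip at a fixed
crop position, the cut is placed at the per-movie median tip-in-crop: the
measured pixel set is then constant across frames and sub-pixel tracking
jitter cannot masquerade as intensity dynamics. Per-frame means never
impute; masked-pixel counts are reported and all-masked frames yield NaN.

Detrending subtracts a Savitzky-Golay trend (window 10, degree 2), no
normalization. The even window is handled as a local least-squares fit
evaluated at the sample itself (asymmetric window, half a sample shifted;
boundary windows shift inside the series), which reproduces polynomials up
to the filter degree exactly. Note the consequence: the trend filter's gain
at a 10-sample period (44.55 s at the default cadence) is |H| ≈ 0.76, so
detrending retains only ≈ 29% of such a sinusoid's amplitude — the spectral
peak survives (the procedure is a band-pass, not an amplitude-preserving
transform), but absolute amplitudes are convention-dependent. Window 11 is
available; it agrees with window 10 on polynomial trends but differs by
~19% RMS on oscillatory signals, so the window is part of the method
definition, not a free knob. Spectral smoothing applies the same filter plus
a centered 3-point moving average (combined gain ≈ 0.66 at 10 samples).

## TDC

u = (T−1)^(2/3)/ln ln(T−1) with natural logs (the quotient reading yields a
small tail of extreme events; at T = 135, u ≈ 16.48, I_q ≈ 0.877, and the
strict-above tail holds 17 of 134 differences). The split uses the
linear-interpolation empirical quantile; "above" is strict; with a fully
tied tail the tail mean falls back to the maximal difference so
μ_tail ≥ μ_main always. σ_main is the sample SD (ddof 1). The minimal
admissible length (u < T−1 and the double log defined) is T = 7, found by
direct scan. k-means runs 50 seeded restarts per k in 2..N−1 on the raw
(unstandardized) features — the features' common intensity scale is part of
the method; a z-scored variant is available behind a flag. Selection takes
the highest silhouette, ties (within 1e-12) to fewer clusters; identical
feature vectors raise a degeneracy error rather than clustering noise.

## Spectra and sinusoid

A(f) = 2·√(Re²+Im²)/N with N the pre-padding length, so an integer-cycle
unit sinusoid measures exactly 1.0. Zero-padding to 16 384 points
interpolates the spectrum (it adds no information); the retained band is
min period = ceil(2·Δt) = 9 s (a hard Nyquist guard of 2·Δt is enforced
regardless of configuration) to max period = floor(T·Δt/4) = 150 s (at least
four full cycles per record). Dominant-peak ties break toward the longer
period (the grid is stored descending, so argmax does this by construction).
The STFT uses a periodic Hann window, 32-point segments, hop 16, the same
padding, per-segment max normalization to [0, 1], periods < 150 s.

The sinusoid model is A_p·sin(2π(t−φ)/p) with φ = θ·p/360, θ on a 2° grid
excluding 360°, chosen by minimal MSE against the series. The time-shift
parameterization is adopted because φ carries time units; over the θ grid it
is equivalent to a phase-offset form. Predicted-peak windows are the
intervals where the model exceeds 70% of A_p (configurable).

## Statistics

OLS with intercept (statsmodels); Cook's distance with the 4/N influence
threshold; leave-one-out refits report per-iteration Pearson r, p and slope.
The two-group tree: Shapiro-Wilk per group at α = 0.05; both normal →
Bartlett chooses Student (equal variances) vs Welch; otherwise a one-sided
Mann-Whitney U in the direction of the observed mean difference (recorded in
the decision path, since the direction is otherwise unspecified).
Significance stars at 0.05/0.01/0.001. The z-motion control standardizes
both series (population SD), computes the full cross-correlation normalized
by the point count and extracts lag 0 — algebraically Pearson's r, asserted
to 1e-12 in the tests.

## Pipeline

Per acquisition: threshold 1 → track → threshold 2 → masked crops → time
projection and footprint (on the technique-1 masked crop) → width/curvature
(frame 0) → both series → detrend. Cohort level: TDC clustering of the
technique-1 features; the cluster with the larger mean μ_tail is the
oscillatory one, and only its members get FFT, dominant period and sinusoid
fits. Failures are quarantined per acquisition with reasons; statistics run
on survivors. Reports embed the package version and a SHA-256 config hash.

## Problem sizes

The default cohort (18 movies, 135 frames, 295×224 px) analyzes in ~20 s on
one core. The test suite renders repeated cohorts on the reduced 176×120 px
field and reuses one fully analyzed default cohort across tests; the whole
suite runs in about a minute.

## Known limitations

- The footprint area of the top-4.5% mask is a fixed fraction of the crop
  (~2.1 µm² for a 50×50 crop), so absolute areas are crop-size conventions;
  roundness, which the analysis relies on, is not.
- Curvature estimates degrade to ~20% error under pixel noise at this
  resolution.
- Detrended amplitudes (and hence fitted A_p) are filter-convention
  dependent, as discussed above; periods and phases are not.
- The tracker assumes one hypha per field whose base enters from a border,
  and a single growth axis estimated at frame 0; it re-estimates nothing
  mid-movie and will not follow strongly curving growth.
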