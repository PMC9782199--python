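# Methods

## Signal model and conditioning

The pipeline treats the chest surface as an array of i = 1..72 acoustic
channels s_i(n) sampled synchronously (10 kHz by default) plus one ECG
channel s_ECG(n). Normal heart sounds concentrate in 20–200 Hz, which fixes
the band-pass; everything the map displays is the instantaneous modulus
|s_i,D(n)| of the conditioned signals.

**Normalization.** s_i,D(n) = (s_i(n) − m_i)/(Dmax − Dmin) with per-channel
means m_i but *ensemble* extrema Dmax, Dmin taken over all channels jointly.
The global denominator is deliberate: the acoustic map encodes spatial
amplitude differences between channels, and a per-channel range would
flatten that gradient. A constant ensemble (Dmax = Dmin) is rejected as
degenerate. Statistics are computed over the whole record; no acquisition
transient is trimmed first.

**Band-pass.** Order-4 Butterworth, 20–200 Hz, applied forward–backward
(`sosfiltfilt`), so the net phase is zero and the effective magnitude
response is the square of the single-pass response. Edge transients are
handled by scipy's odd reflection padding proportional to the filter order.

**Wavelet denoising.** Per channel: coif5 decomposition to 7 levels
(symmetric boundary extension), soft thresholding of the detail coefficients
at the universal threshold T = σ̂·√(2 ln N), reconstruction trimmed to N.
At 10 kHz the level-7 detail band is 39.0625–78.125 Hz and level 8 is
19.53–39.06 Hz; levels 7–8 carry most heart-sound energy, which motivates
the depth of 7. The noise scale σ̂ defaults to the robust estimate
median(|d1|)/0.6745 from the finest detail level — the standard companion of
this threshold rule; setting `WaveletSpec(sigma=1.0)` gives the literal
T = √(2 ln N). The threshold degenerates to 0 on an identically zero channel,
in which case coefficients pass through unchanged.

## ECG anchoring

Conditioning is a down–filter–up chain: polyphase resampling to 200 Hz,
zero-phase order-4 Butterworth 0.5–40 Hz (baseline and mains rejection while
keeping the QRS energy), polyphase resampling to 10 kHz. Note the 0.5 Hz
corner has a multi-second step transient; steady state is reached well
inside a record but not at its edges.

R-detection is Pan–Tompkins at its native 200 Hz design rate: 5–15 Hz
band-pass (zero-phase, so no group delay to compensate), five-point
derivative, squaring, 150 ms moving-window integration, adaptive dual
thresholds (SPKI/NPKI with 0.125/0.875 updates), RR-based search-back at
1.66× the running RR mean, and a 200 ms refractory period. Because the
integration window trails the R-wave, each fiducial is snapped to the
dominant excursion of the band-passed trace within the preceding window,
then refined to the local maximum of the full-rate trace within ±12.5 ms;
on synthetic ECG at ≈20 dB SNR this recovers R times to well under 10 ms.
Flat or all-noise input returns an empty index list, not an error.

## Sensor localisation

Marker extraction: HSV thresholding (hue window, saturation ≥ 0.4,
value ≥ 0.25 by default) yields a binary mask per colour; each connected
component large enough to be a disc is validated by a Circle Hough transform
over the configured radius range (per-component, which keeps 72 discs
tractable), and its centre is refined to sub-pixel precision by the
component centroid. On rendered discs with anti-aliased edges this recovers
centres to < 0.1 px.

Landmark roles are assigned geometrically: topmost = sternoclavicular
joint, bottommost = right 10th rib, and the middle pair by image x
(anatomical right appears on the image left in a frontal view). The
transform chain is estimated from the four pairs: baseline angles θ1, θ2 of
the 6th-rib chord in each image (arctangent of the chord slope — the angle
with the horizontal); rotation of the chest points by Δθ = θ2 − θ1 about
the chest right-6th-rib landmark; axis scales η_x from the 6th-rib x-span
and η_y from the joint-to-10th-rib y-span; translations φ_x, φ_y anchoring
the right 6th rib in x and the joint in y. For landmark sets related by a
true similarity transform this chain recovers the mapping exactly, and the
consistent mode is analytically invertible.

A second mode, `paper_literal`, replaces the rotation step by the
coordinate products w·cos(θ1)·cos(θ2) and h·sin(θ1)·sin(θ2). That operator
is not a rotation — it zeroes the y coordinate when both angles are zero
and does not reduce to the identity — but it is preserved verbatim for
comparison and archaeology. The default is the consistent mode.

Pixel convention throughout: (x, y) = (column, row), origin top-left, y
increasing downward, identical in both images. Detected sensors are given
channel ids row-major (rows clustered with a tolerance of half the median
nearest-neighbour distance, then sorted by x).

## Mapping and colour

The scattered moduli Z(w_i, h_i, e_i(n)) are interpolated with the
Clough–Tocher piecewise-cubic C1 interpolant on the Delaunay triangulation
(gradient-estimation tolerance 1e-10), which is exact at the sensor nodes
and reproduces planar fields to machine-level accuracy; when the registered
layout happens to be a complete rectilinear grid a tensor-product bicubic
spline is used instead. No extrapolation is performed: pixels outside the
sensor convex hull are masked and show the background.

Colour: ε_g(n) = E(n)/Em clipped to [0, 1] (cubic interpolation can
overshoot the node range), hue ε(n) = 240·(1 − ε_g), saturation 1.0,
lightness 0.5, standard HSL→RGB conversion to 8-bit. Em defaults to the
maximum interpolated modulus over the *rendered window* so that one modulus
maps to one colour across all frames of a sequence; per-frame and
whole-recording scopes are options. Frames are alpha-composited over the
skeleton background with α = 0.6 (a display choice only). A window
[t_start, t_end] at interval Δt renders ⌊(t_end − t_start)/Δt⌋ + 1 frames,
endpoints inclusive.

## Sensor characterisation

f_c = 1/(2πRC) for the two coupling networks; amplifier chains sum in dB;
SNR = 10·log10(P1/P2) with both powers required positive. Consistency
difference rates use the B sensor as reference: δ_V = |V_A − V_B|/V_B and
δ_f = |f_A − f_B|/f_B — the ratio reading, since the quantities are
dimensionless rates. Centre frequencies come from a Welch PSD (Hann window,
2 s segments, 50% overlap, mirroring a 40 s bench sweep at 2 kHz) with
parabolic sub-bin refinement on log power; tone amplitude is √(2·P) from
the mean power of the demeaned record.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* the pipeline depends on: S1/S2
Gabor bursts (cosine phase, so the burst centre is the amplitude maximum;
default 60 Hz centre, 25 Hz bandwidth, inside the 20–200 Hz band) timed at
R + s1_delay and R + s2_delay (defaults 40 ms and 340 ms — S1 follows the
R-wave closely, S2 sits near the T-wave); spatial amplitude decay
exp(−d/L) from virtual point sources (default L = 120 px against a 40 px
sensor pitch, a visible but not cliff-like gradient); white Gaussian
channel noise drawn in channel order from one seeded generator (bitwise
reproducibility); a PQRST-like ECG built from Gaussian bumps with a
dominant R spike; anti-aliased coloured discs on a near-white background.

It does *not* model thoracic acoustics (no wave equation, dispersion,
reverberation or frequency-dependent attenuation), murmurs or arrhythmias,
photographic lighting/perspective, or sensor contact artefacts. Passing
tests therefore demonstrate correctness of the processing chain under
controlled conditions — exact normalization, phase, thresholds, geometry
and colour arithmetic — not clinical performance on real recordings.

## Problem sizes and numerical choices

Tests and the acceptance script run the synthetic array at 2 kHz with 3–10
beats on the 8×9 grid (72 channels), and single-channel filter checks at
10 kHz; these sizes exercise every code path with the default parameters.
Ties and degenerate inputs: constant ensembles, zero-length landmark
baselines, collinear layouts, non-positive Em, empty time windows and
sub-Nyquist source rates are all rejected with specific errors; empty
detection results (blank image, flat ECG) are returned as empty collections
rather than exceptions.

## Known limitations

- The literal transform mode cannot be inverted and is excluded from the
  invertibility guarantees.
- The universal threshold assumes approximately white noise after
  band-passing; strongly coloured noise would need a level-dependent σ̂.
- Channel-id assignment assumes the photographed grid is roughly axis
  aligned; a heavily rotated chest photo could permute rows.
- Circle Hough validation assumes markers are filled discs well separated
  from each other; overlapping discs merge into one component and are
  rejected or mis-centred.
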