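# phonomap

Multichannel phonocardiogram (PCG) processing and cardiac acoustic mapping.

Heart sounds reach the chest surface with spatial structure: S1 (mitral and
tricuspid valve closure) and S2 (aortic and pulmonary valve closure) are
strongest over different intercostal spaces, and their intensity pattern
shifts within each sound. A wearable array of 72 chest-surface acoustic
sensors plus one ECG channel makes that structure visible as a *cardiac
acoustic map*: an image of the heart-sound modulus |s_i(n)| over the chest
at one sample instant, rendered on a standard skeleton image and animated
over the cardiac cycle. `phonomap` implements the full software pipeline for
building such maps, for researchers studying heart-sound propagation and for
engineers building multichannel auscultation hardware.

## The pipeline

1. **Signal conditioning** (`phonomap.preprocess`). The ensemble
   s_i(n), i = 1..72, is mean-range normalized with a *global* scale,
   s_i,D(n) = (s_i(n) − m_i) / (Dmax − Dmin), where Dmax/Dmin are extrema
   over all channels jointly — this removes baseline drift while preserving
   the inter-channel amplitude gradient the map encodes. The signals are
   then band-passed 20–200 Hz with an order-4 Butterworth filter applied
   forward–backward (zero net phase, squared magnitude response), and
   denoised by wavelet shrinkage (coif5, 7 levels, soft thresholding at the
   universal threshold T = σ̂·√(2 ln N)).
2. **Cycle anchoring** (`phonomap.ecg`). The ECG is resampled to 200 Hz,
   band-passed 0.5–40 Hz (zero phase), returned to 10 kHz, and R-waves are
   detected with the Pan–Tompkins algorithm (derivative → squaring → 150 ms
   moving-window integration → adaptive dual thresholds with search-back and
   a 200 ms refractory period). R-to-R intervals segment the cardiac cycles.
3. **Sensor localisation** (`phonomap.registration`). Sensor positions
   (green discs on a chest photograph) and four anatomical landmarks (red
   discs: sternoclavicular joint, right 10th rib, right and left 6th ribs)
   are extracted by HSV thresholding plus a Circle Hough transform, and a
   rotate/scale/translate chain estimated from the landmark pairs maps the
   sensor coordinates onto the skeleton image.
4. **Mapping** (`phonomap.mapping`). At each rendered instant the moduli
   e_i(n) = |s_i,D(n)| are interpolated with a piecewise-cubic C1 spline
   over the pixel grid, normalised as ε_g = E/Em and coloured by hue
   ε = 240·(1 − ε_g) (blue → red with increasing modulus, saturation 1.0,
   lightness 0.5 in HSL), converted to RGB and alpha-composited over the
   skeleton background.
5. **Sensor characterisation** (`phonomap.sensorcal`). Closed-form RC
   cut-offs f_c = 1/(2πRC) and dB gain chains for the analogue front end,
   PSD-based centre-frequency estimation, two-sensor consistency difference
   rates δ_V = |V_A − V_B|/V_B, δ_f = |f_A − f_B|/f_B, and
   SNR = 10·log10(P1/P2).

Because real 72-channel recordings need the wearable hardware, the package
ships a first-class synthetic generator (`phonomap.fixtures`): Gabor-atom
S1/S2 bursts radiating from virtual sources with exponential spatial decay,
a PQRST-like ECG phase-locked to the bursts, and marker images with known
disc centres — every stage is testable against exact ground truth.

## Worked example

```python
import numpy as np
import phonomap as pm
from phonomap.fixtures import make_registration_scene

# 1. synthesize a 72-channel recording with a known source
layout = pm.generate_sensor_layout(8, 9, 40.0, (120.0, 140.0))
schedule = pm.BeatSchedule.regular(3, rr=1.0)
source = pm.SourceSpec(position=(240.0, 300.0), decay_length=120.0)
rec = pm.generate_pcg_array(layout, schedule, [source], fs=2000.0,
                            noise_sd=0.01, seed=7)

# 2. condition the ensemble
normed, stats = pm.normalize_channels(rec)
banded = pm.bandpass_zero_phase(normed)
denoised = pm.wavelet_denoise(banded, pm.WaveletSpec(level=5))
print(f"ensemble range: Dmax={stats.d_max:.3f}, Dmin={stats.d_min:.3f}")

# 3. anchor the cardiac cycle on the ECG
ecg = pm.generate_ecg(schedule, fs=2000.0, noise_sd=0.02, seed=8,
                      duration=rec.duration)
cond = pm.preprocess_ecg(ecg)
r_peaks = pm.detect_r_peaks(cond)
print(f"R-peaks detected: {len(r_peaks)} at "
      f"{[round(float(r) / cond.fs, 3) for r in r_peaks]} s")

# 4. register the sensors onto a skeleton image
scene = make_registration_scene(layout)
registered = pm.locate_channels(scene["chest_image"], scene["skeleton_image"])

# 5. render the acoustic map around the first S1 burst
bg = np.full((620, 620, 3), 255, np.uint8)
res = pm.render_sequence(denoised, layout, bg, 0.52, 0.56, 0.002,
                         grid_step=2.0)
k = int(np.argmin(np.abs(res.times - 0.54)))
af = res.acoustic_frames[k]
j, i = np.unravel_index(np.argmax(np.where(af.mask, af.values, -1)),
                        af.values.shape)
print(f"{len(res.frames)} frames; Em={res.em:.4f}; "
      f"peak modulus at ({af.grid_x[i]:.0f}, {af.grid_y[j]:.0f}) px")
```

Output:

```
ensemble range: Dmax=1.010, Dmin=-0.495
R-peaks detected: 3 at [0.5, 1.5, 2.5] s
21 frames; Em=0.6252; peak modulus at (240, 300) px
```

All three beats are anchored at their true R times, the registered layout
lands within 0.1 px of ground truth, and the brightest map pixel at the S1
burst centre falls exactly on the configured source position — the acoustic
map localises the virtual source.

The same pipeline is scriptable from the shell:

```sh
phonomap --seed 7 simulate --out-dir fixtures/
phonomap preprocess fixtures/pcg.wav --out denoised.wav
phonomap ecg fixtures/ecg.wav --out rpeaks.json
phonomap register fixtures/chest.png fixtures/skeleton.png --out layout.json
phonomap render denoised.wav layout.json fixtures/skeleton.png \
    --t-start 0.52 --t-end 0.56 --interval 0.002 --out-dir frames/
```

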