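# fmcw-vitals

Non-contact respiration- and heart-rate monitoring with FMCW
(frequency-modulated continuous-wave) radar: a simulator for raw
intermediate-frequency (IF) data cubes, a mixed-modal target-state detector
that picks the range bin carrying the cardiopulmonary signal, and the phase
processing chain that turns sub-millimetre chest motion into breaths- and
beats-per-minute.

It is aimed at people building or evaluating radar vital-sign pipelines —
every stage runs end to end on synthetic scenes with per-frame ground
truth, so detector and estimator behaviour can be tested without hardware.

## Method

An FMCW chirp sweeping with slope γ from a carrier band centred on f_c
mixes its echo from a reflector at range R into an IF tone

    s_IF(t) ≈ A·exp(j·2π(f_IF·t + f_c·τ)),   f_IF = γτ,   τ = 2R/c.

An FFT over the chirp's ADC samples (the *range FFT*) localises the
reflector in a range bin, and the bin's phase φ = 4πR/λ resolves chest
micro-displacement x(t) far below the bin width: Δφ = 4πx/λ (≈ 1.07 rad
per millimetre at 25.5 GHz).

Per frame the pipeline:

1. averages the frame's M chirps (phase-noise suppression) and takes the
   range FFT, X_m(k);
2. removes static clutter with the recursive filter
   X′_m = αX_m + (1−α)X′_{m−1}, Y_m = X_m − X′_m;
3. computes a CFAR-style **confidence value** V = P_D / P_T — peak-bin
   energy over the averaged energy of T training cells per side, G guard
   cells excluded, edges wrapped circularly — and compares its trailing
   v-frame sum against a threshold trained on an empty room (presence
   test);
4. computes the sample variance s² of the peak-bin index over a 2-s
   window (low ⇒ the body is holding still, high ⇒ large random motion),
   classifies each frame as unmanned / motion / stable, and only switches
   the emitted state when one raw state fills > 80 % of a 2-s buffer;
5. in stable runs, selects the target bin as a 2-s running median of the
   peak bin, unwraps and differences the bin's phase, separates
   respiration (0.1–0.6 Hz) and heartbeat (0.8–4 Hz) with 4th-order
   Butterworth biquad cascades, and reads both rates off zero-padded FFT
   spectra over 20-s windows stepped by 1 s — rejecting spectral peaks
   that sit on integer harmonics of the respiration frequency before
   picking the heart rate.

Estimates are scored against a reference with MAE, RMSE and banded
accuracy (fraction within 2 BPM for respiration, 5 BPM for heart rate).

## Worked example

```python
import dataclasses
import numpy as np
import fmcw_vitals as fv
from fmcw_vitals import detect, io, preprocess

radar = fv.RadarConfig()  # 25.5 GHz, 2.5 GHz sweep, 20 frames/s

# 1. train the presence threshold on an empty room
background = fv.Scenario(duration=20.0, segments=[(0.0, 20.0, "unmanned")],
                         target_amplitude=0.0, seed=99)
profiles = preprocess.preprocess_cube(fv.synthesize_if_cube(radar, background))
threshold = detect.calibrate_from_profiles(profiles, fv.ConfidenceConfig())
print(f"presence threshold: {threshold:.1f}")

# 2. a subject sits down at 1 m, breathes at 15 BPM, heart at 75 BPM
scene = fv.Scenario(
    duration=60.0,
    segments=[(0.0, 10.0, "unmanned"), (10.0, 60.0, "stable")],
    target_range=1.0, fr=0.25, fh=1.25, noise_sigma=0.1, seed=7)
cube = fv.synthesize_if_cube(radar, scene)

cfg = io.PipelineConfig()
cfg.confidence = dataclasses.replace(cfg.confidence, threshold=threshold)
track, vitals, report = io.run_pipeline(cube, cfg)

for tr in report["transitions"]:
    print(f"state {tr['from']} -> {tr['to']} at {tr['time_s']:.2f} s")
sel = track.selected_bin[np.isfinite(track.selected_bin)]
print(f"selected range bin: {np.median(sel):.0f} "
      f"({radar.bin_to_range(int(np.median(sel)), 64):.2f} m)")
ok = np.isfinite(vitals.rr)
print(f"windows with estimates: {ok.sum()} of {len(vitals)}")
print(f"median RR: {np.median(vitals.rr[ok]):.2f} BPM, "
      f"median HR: {np.median(vitals.hr[ok]):.2f} BPM")
```

prints

```
presence threshold: 41.6
state unmanned -> stable at 11.60 s
selected range bin: 17 (1.02 m)
windows with estimates: 29 of 41
median RR: 14.94 BPM, median HR: 75.00 BPM
```

The detector flags the arrival 1.6 s after the subject sits down (the 2-s
decision buffer has to fill), locks onto bin 17 — the bin covering 1 m —
and recovers both rates on every 20-s window that lies fully inside the
stable span (the first valid window ends 20 s after the stable state
begins, hence 29 of 41). The residual RR error (14.94 vs 15 BPM) is the
spectral grid spacing.

The same workflow is available from the shell:

```sh
fmcw-vitals simulate scene.yaml cube.h5
fmcw-vitals calibrate background.h5           # prints the trained threshold
fmcw-vitals process cube.h5 --threshold 41.6  # states.csv + vitals.csv
fmcw-vitals evaluate vitals.csv reference.csv # metrics JSON
```

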