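# Methods

## Signal model

The simulator generates the post-mixer IF model directly rather than mixing
RF waveforms. For a reflector at instantaneous range R = R₀ + x(t), sample
n of a chirp holds

    A·exp(j·2π(f_IF·t_n + f_start·τ)),   f_IF = γτ,   τ = 2R/c,  t_n = n/f_adc,

summed over reflectors, plus circularly-symmetric complex Gaussian noise
(i.i.d. per sample, standard deviation `noise_sigma` split evenly between
quadratures). The quadratic delay term of the mixer product is negligible
at indoor ranges (τ ≈ 10 ns) and is not generated. Chest motion is below
5 Hz, hence quasi-static over a 50-ms frame: x(t) is evaluated at each
frame start and frozen across the frame's chirps.

**Carrier convention.** `fc` is the *centre* frequency of the sampled
sweep; the chirp starts at `f_start = fc − γ(N−1)/(2·f_adc)`. The phase of
the range-FFT peak across frames then moves by exactly 4πx/λ with
λ = c/fc. (With `fc` taken as the sweep start, the effective phase
sensitivity corresponds to the mid-sweep wavelength and overshoots 4πx/λ
by B/2fc — about 5 % for the default 2.5-GHz sweep.)

### Radar defaults

| parameter | default | why |
|---|---|---|
| `fc` | 25.5 GHz | centre of a 23.5–27.5 GHz operating band |
| `gamma` | 7.8125·10¹³ Hz/s | 2.5-GHz sweep over the 32-µs sampled chirp; puts a target at 1.5 m near bin 25, ~6 cm/bin |
| `n_samples` | 64 | ADC samples per chirp at 2 MHz |
| `n_chirps` | 32 | chirps per frame, averaged for phase-noise suppression |
| `frame_period` | 50 ms | 20-Hz slow-time sampling — comfortably above twice the 4-Hz heartbeat band edge |

## Scene model

A scenario is a list of segments tagged `unmanned`, `stable` or `motion`
tiling the record. In stable segments the chest displacement is

    x(t) = A_r·sin(2π f_r t) + A_h·sin(2π f_h t)

with defaults A_r = 1 mm, A_h = 0.1 mm, f_r = 0.25 Hz (15 breaths/min),
f_h = 1.25 Hz (75 beats/min) — typical resting adult values; respiratory
chest excursion is an order of magnitude above the cardiac one.

Motion segments add two components on top of the vitals:

* a **mean-reverting random walk** (step sd `motion_amp` = 5 cm/frame,
  reversion factor 0.95/frame toward the seat position). A pure random
  walk drifts until it hits the simulator's range clamp and then sits
  there — a *stationary* target, the opposite of what the state is meant
  to exercise;
* **white frame-scale jitter** (sd `motion_jitter` = 5 cm), reproducing
  the frame-to-frame scatter of the detected peak bin that a moving body
  produces. This scatter, not the gross trajectory, is what the 2-s
  bin-variance discriminant keys on.

Default noise (`noise_sigma` = 0.1 against a unit-amplitude target, 20 dB)
represents a moderate indoor SNR.

What the generator does **not** emulate: range sidelobes of real antenna
patterns, multipath, multiple people, respiration waveform asymmetry
(real breathing is not sinusoidal), respiratory harmonics intrinsic to
the chest motion, amplitude modulation of the echo, or thermal drift.
Passing tests therefore demonstrate correctness of the processing chain
under the stated model, not field performance.

## Detector

* **Confidence value.** Energy ratio of the peak bin to the averaged
  energy of T training cells per side with G guard cells excluded
  (defaults G = 2, T = 4). Edge bins are handled by circular indexing
  (conceptually tiling the profile three times and evaluating on the
  middle copy). The two per-side averages are *summed*, so a flat profile
  scores exactly 0.5; the trained threshold absorbs this scale. The
  training-cell sums use strictly-training cells (offsets G+1 … G+T):
  the guard-boundary cell is excluded by construction, since training
  cells estimate background noise. A floor of 10⁻¹²·max-energy (plus the
  smallest positive float) keeps silent profiles at V = 0 instead of 0/0.
  Argmax ties break to the lowest bin.
* **Accumulation.** A causal trailing sum over v = 8 frames (0.4 s) —
  accumulation averages out single-frame noise spikes, lowering the false
  alarm rate at matched threshold.
* **Threshold training.** mean + k·sd (k = 3) of the accumulated
  confidence over an empty-room recording; k is exposed because faint
  targets argue for a lower threshold.
* **Bin variance.** Unbiased sample variance of the peak-bin index over a
  40-frame window. The index history only accumulates over frames where
  presence is detected and is cleared when presence drops: a window
  straddling an arrival would otherwise mix meaningless noise-era argmax
  bins into the variance and delay the stable verdict by a full window.
  With fewer than two observations s² = 0 (a single observation carries
  no dispersion evidence).
* **`var_threshold` = 0.3 bin².** Calibrated from the two conditional
  distributions under the default scene model: a stationary subject at
  20 dB SNR keeps the argmax locked (s² = 0, with an outlier floor of
  ≈ 0.1 bin² if a single frame in the window jumps two bins), while even
  slow wandering motion produces s² ≳ 0.5 bin². The value sits between
  the two; redeployments with different bin widths or SNR should
  recalibrate it the same way.
* **State buffer.** Raw per-frame states (unmanned if the accumulated
  confidence is at or below threshold; else stable/motion by s²) fill a
  40-frame buffer; the emitted state switches only when one raw state
  strictly exceeds 80 % of the buffer, otherwise the previous emitted
  state is retained (hysteresis; ties change nothing). The emitted state
  starts as unmanned. Worst-case decision latency is the raw-state flip
  delay plus ⌈0.8·40⌉ frames ≈ 2 s.
* **Bin selection.** Running median of the peak bin over a 40-frame
  window, restarted at each stable run's start and truncated at its
  edges; no bin is emitted outside stable runs.

## Rate estimation

The phase is read from the **raw** range FFT at the selected bin — the
clutter filter subtracts a complex running mean, which distorts the phase
of the target bin, so it feeds only the detector. Unwrapped phase is
differenced (suppressing slow drift), band-passed with 4th-order
Butterworth filters in two cascaded biquad sections (0.1–0.6 Hz and
0.8–4 Hz; Butterworth for its flat passband), and each 20-s window
(1-s step) is Hann-windowed and zero-padded to ≥ 4096 points
(≤ 0.3 BPM grid at 20 Hz) before peak picking. Differencing tilts the
spectrum by +6 dB/octave but moves no peak within these narrow bands.
Windows overlapping any non-stable frame yield gap records.

**Harmonic rejection.** Among the 4 largest local maxima of the
heartbeat-band spectrum, a peak within ±0.04 Hz of k·f_r (integer k ≥ 2,
f_r the same window's respiration estimate) is discarded. Two guards:

* the tolerance is ±0.04 Hz, not wider, because plausible rate pairs can
  put the true cardiac line within 0.05 Hz of a harmonic (f_r = 0.3 Hz,
  f_h = 1.25 Hz vs 4·f_r = 1.2 Hz) — a wider band would reject the true
  peak in favour of the actual harmonic;
* a surviving peak must reach at least 30 % of the largest candidate's
  magnitude. When the true heart rate coincides *exactly* with a harmonic
  (75 BPM at 15 breaths/min is 5·f_r), every credible peak is rejected
  and the estimator falls back to the largest peak, flagging the window
  (`fallback_harmonic`). Without the magnitude floor, a small noise bump
  that happens not to be a harmonic would win instead.

A time-domain cross-check (median inter-peak interval) is available but
is not the primary estimator. An all-zero window returns a no-estimate
sentinel (NaN).

## Evaluation

MAE and RMSE use the standard definitions (so MAE ≤ RMSE always, by
Jensen's inequality — a report where "RMSE" is below MAE is quoting an
error standard deviation, not an RMSE). Banded accuracy is the fraction
of estimates within 2 BPM (respiration) or 5 BPM (heart rate) of the
reference. Radar and reference series are aligned by nearest timestamp
within ±0.5 s; unmatched or NaN points are dropped and counted. Minute
averaging marks a trailing partial segment.

## Problem sizes

The test suite and the acceptance script run scenes of 20–120 s at
20 frames/s (400–2400 frames, 64-bin profiles) — long enough for several
20-s estimation windows and stable statistics on state agreement, while
keeping a full run in seconds on one CPU.

## Known limitations

* Single target; no angle processing, no multipath, no interferer model.
* The harmonic-rejection fallback cannot distinguish a true
  harmonic-coincident heart rate from a dominant respiratory harmonic
  with a silent cardiac line; it reports the largest peak and flags it.
* The variance threshold is deployment-specific (bin width and SNR
  dependent); the shipped default is calibrated for the shipped scene
  model.
* Respiration estimates inherit the spectral grid (±0.06 BPM at the
  default padding), and 20-s windows smear any rate change within the
  window.
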