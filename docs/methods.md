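# Methods

## The control problem

A finger PPG sensor measures transmitted light v(t), an inverse surrogate of
arterial blood volume: rising volume absorbs more light, so v falls.  If the
sensor's contact pressure p_c equals mean arterial pressure, the artery is
"unloaded": pulse amplitude is maximal and inflow and outflow of blood
balance over each heart cycle, so the integral of the pulsatile volume
signal over one beat vanishes.  Below that pressure the pulses become "fat"
(the negative half-wave dominates, beat integral < 0); above it they become
"spiky" (beat integral > 0).  The volume control technique (VCT) servoes p_c
on this imbalance once per heartbeat, which is why the actuator only needs
the speed of mean-pressure changes (≤ 30 mmHg/s) rather than the ~1500
mmHg/s of pulsatile volume clamping.

## Signal decomposition

v(t) is sampled at 250 Hz and split by a cascade of first-order IIR low-pass
stages, `y_i = (1−UC)·y_{i−1} + UC·x_i`.  Very slow stages advance only
every 25th sample on the *mean* of the preceding block (anti-alias
averaging; advancing on instantaneous samples phase-locks to the cardiac
cycle at rational HR ratios and biases the baseline — an error the setpoint
integrator would amplify into a heart-rate-dependent offset) and hold their
output in between.

| output | realisation | band |
|---|---|---|
| `v_Pulse` | two subtractive high-pass stages, per-stage corner 0.644·0.5 Hz so the cascade −3 dB point sits at 0.5 Hz | > 0.5 Hz |
| `v_Rhythm` | 3 one-pole low-passes at 0.5 Hz, then two decimated subtractive high-pass stages at 0.01 Hz | 0.01–0.5 Hz |
| `v_dRhythm` | scaled first difference of `v_Rhythm`, low-passed at 0.5 Hz | band-limited derivative |
| `v_VCT` | **one** decimated subtractive high-pass stage, corner 1.1·0.01 Hz | > 0.01 Hz, pulses retained |

Content below 0.01 Hz is removed everywhere because at those frequencies the
light level is dominated by vasomotor tone, not blood pressure.  The v_VCT
branch deliberately uses a *single* (first-order) very-low-frequency edge:
the setpoint memory reconstructs slow pressure drifts by integrating the
high-passed signal, and the loop gain of that path at frequency f scales
like |HP(f)|/f.  A first-order edge keeps this finite toward DC (≈ 86% of a
15 mmHg / 15 min drift is recovered); a second-order edge makes the loop
gain vanish quadratically and loses ~60% of such drifts.  The corner sits at
1.1× the nominal cutoff so the response at 0.01 Hz is a −3.4 dB corner.

All coefficients are exposed in `FilterBankConfig`, so a different published
stage set can be dropped in verbatim.

## Beat detection

Systole is a local *minimum* of `v_Pulse`.  The offline detector
(`detect_beats`) normalises by a rolling 2-s amplitude estimate, finds
minima above half the local swing, re-runs with a rate-adaptive refractory
of 0.7 median pulse intervals (rejecting dicrotic double-detections, which
are largest near the balance point), and rescans long gaps at a lower
threshold so attenuated beats are still caught.  The streaming detector in
the closed-loop kernel mirrors this with an amplitude EMA (updated only on
plausible intervals, decaying automatically during silence so weak pulses
can be re-acquired) and a refractory of 0.72× a pulse-interval EMA.
Confirmation happens when the signal has risen 45% of a beat amplitude off
the minimum — roughly 100–200 ms after systole for normal pulse shapes.

## Oscillometric initialization

A 0→200 mmHg ramp at 2 mmHg/s sweeps the artery while each beat contributes
an (amplitude, mean p_c) point.  Amplitudes are median-binned on a pressure
grid (robust to interleaved spurious detections), the binned peak locates
the envelope maximum, and a robust (soft-L1) two-stage least-squares fit is
applied to the raw points: first a symmetric Gaussian on the near-peak
region (≥ 85% of the peak, where the envelope is locally quadratic) for the
centre μ, then the two side widths σ₋, σ₊ with the centre frozen.  μ is the
maximum-oscillation estimate of mBP and becomes the setpoint P₀; the
low-passed light value there is its companion v₀.  sBP and dBP are read off
the fitted envelope at amplitude ratios r_sys = 0.55 (above μ, using σ₊)
and r_dia = 0.85 (below μ, using σ₋) — literature-typical defaults that are
*unvalidated* for this geometry and exposed in `EnvelopeFitConfig`.

A two-sided ("Gaussian-style") envelope rather than a single symmetric
Gaussian is the default because the arctangent plant produces a skewed
envelope; a symmetric fit over the full curve is biased by +3…+8 mmHg.  On
points sampled from an exact symmetric Gaussian both stages recover (A, μ,
σ) to machine precision.

## Closed loop

After the ramp the actuator descends to P₀, the filter memories are seeded
with v₀ (so a constant input at v₀ produces zero in every band), and the
loop runs per-sample at 250 Hz in a numba kernel: plant → filters →
streaming beat detector → controller → antiresonance notch → actuator.

* Beat path: `P_n = P_0 − c_BBI·ΣV̄ − c_BBP·V̄_n` with
  `V̄_n = (1/PI)∫v_VCT dt`.  The running sum is accumulated *sample-wise* as
  `v_VCT / PI_ema` — identical to the per-beat summation when every beat is
  detected cleanly (the windows telescope), but immune to detection jitter,
  split beats and artifact-gapped windows.  `update_setpoint()` implements
  the literal per-beat form and is the unit-tested reference.
* Rhythm path: `y_PD = c_P·v_Rhythm + c_D·v_dRhythm`, `y_I = c_I·Σy_PD`
  every sample; command `p_c = P_n − y_I − y_PD`, clamped to
  [20, 250] mmHg (20 mmHg is the minimum light-coupling pressure).  The
  integrators freeze while the command is clamped (anti-windup) and during
  artifacts.
* Engagement: control engages 60 s after initialization.  The grace period
  lets the detector settle and lets the very-low-frequency baseline absorb
  the residual error of the finite v₀ average — the integrator would
  otherwise turn a few-thousandths light mismatch into a lasting setpoint
  offset (ΔP ≈ c_BBI·τ_VLF·Δv/PI, several mmHg per 0.005 light units).
* Robustness: artifact samples (known mask from the noise model, held for
  1.5 s) freeze the controller and feed the filters their own slow baseline
  — freezing on a raw sample, possibly caught mid-systole, would bleed a
  false DC into the volume-balance path.  Losing all beats for 10 s resets
  the controller memory to P₀ (pressure left the pulsatile region).

Negative-feedback signs throughout: a pressure rise increases finger volume,
decreases v, makes the beat integral negative and y_PD negative — both raise
p_c.

### Antiresonance

The deliberately slow actuator plus band-limited feedback makes the loop
conditionally stable; respiratory-band excitation (0.2–0.3 Hz) can pump a
resonance.  Every 5 s the trailing 30 s of applied pressure is searched for
a dominant spectral line in 0.1–min(0.9, 0.8·f_beat) Hz (capped below the
cardiac frequency — beat ripple is not a loop resonance); a persistent line
above 1.5 mmHg tunes a second-order IIR notch (unity DC gain, 0.1 Hz
bandwidth) in the command path, seeded at the current command level to avoid
an engagement transient.  The notch is latched and retuned at most every
10 s when the detected frequency moves by more than a bandwidth.  In a
resonance-prone configuration (actuator slowed to 5 mmHg/s, c_P = 50,
c_D = 0, HR 65, 3 mmHg respiration at 0.25 Hz) enabling the notch reduces
the 0.1–1 Hz band power of p_c by ≈ 12 dB, deterministically.

### Controller constants

The device constants are not derivable from first principles here; they were
tuned once against shortened standard scenarios (`scripts/tune_gains.py`)
and frozen: `c_BBI = 30`, `c_BBP = 15` (mmHg per unit volume integral),
`c_P = 40`, `c_D = 6`, `c_I = 0.0012` (per sample), no integral leak.  The
binding constraint is stability at high heart rate: the beat-based integral
gain per unit time scales with HR, so gains stable at 120 bpm are modest at
60 bpm (slower step recovery, ~25 s for a 20 mmHg step).

### Operation modes

`start → initial → measure ⇄ interpolate` per the mode machine
(`mode_step`), with default durations 120 s measure and 13 min
interpolation.  During interpolation the pressure drops to the coupling
floor and mBP is estimated by a deliberately simple per-session linear model
(features: beat pulse amplitude and baseline light; trained on measure-mode
beats) — a stand-in, flagged "interpolated" in the output.  `run_closed_loop`
defaults to continuous measure mode; cycling is enabled by flag and covered
by an integration test.

## The synthetic finger

* **Arterial pressure**: beat onsets from a (piecewise) heart-rate profile;
  per-beat sBP/dBP from baselines plus respiratory (default 0.25 Hz) and
  Mayer (0.1 Hz) sinusoidal modulation plus step / ramp / 4-phase
  Valsalva-like events; the waveform is a two-Gaussian systolic/dicrotic
  template scaled to [dBP, sBP], exponent-calibrated so its mean is exactly
  1/3 — making the true beat mean equal the standard dBP + PP/3 estimate.
* **Pressure–volume/light transfer**:
  `v = v_low(tone) + (v_high − v_low)·(arctan((p_c − p_a)/w)/π + ½)` with
  `v_low = 0.15 + 0.25·tone` (vasoconstriction squeezes blood out and raises
  the lower asymptote; the fully-occluded upper asymptote is
  tone-independent) and a transmural-sign-dependent width: w = 8 mmHg on the
  distension side (p_c < p_a), 1 mmHg on the collapse side.  The asymmetry
  is what makes the maximum-oscillation rule point at mBP: with a symmetric
  kernel the max–min amplitude envelope peaks at (sBP+dBP)/2, ~PP/6 above
  mBP.  The collapse width was chosen once so the *measured* envelope peak
  (through the pulse high-pass) lands on mBP for a 40 mmHg pulse pressure;
  across 25–50 mmHg pulse pressures the residual model bias is within about
  ±1 mmHg.  Setting both widths equal recovers the scalar-width model.
* **Tone**: commanded steps/ramps smoothed by a 10-s first-order lag.
* **Actuator**: slew limit 30 mmHg/s, 0.1 mmHg resolution implemented as a
  motion deadband (the motor holds — zero duty cycle — until the command
  leaves the deadband, then moves at the slew rate; applied |dp/dt| never
  exceeds the limit), 20 ms transport delay, range 0–250 mmHg.
* **Noise**: additive white noise at a configured SNR (measured against the
  detrended signal power) and Poisson motion-artifact bursts (0.8 s, ~8
  pulse standard deviations) with a ground-truth mask.
* **standard-10 suite**: ten seeded 30-minute scenarios — constant, ±steps,
  slow drift, respiratory-heavy (6 mmHg @ 0.3 Hz), Mayer-heavy (5 mmHg @
  0.1 Hz), tone ramp 0.3→0.7, tone+pressure+Valsalva, artifact-laden
  (SNR 20 dB, 1 burst/min), tachycardia (120 bpm), hypotension (mBP
  ~56 mmHg) — spanning the clinical mBP range of roughly 45–113 mmHg.
  Sub-seeds derive from one suite seed via `numpy.random.SeedSequence`.

### What the simulator does not emulate

Beer–Lambert finger optics, probe geometry and light-coupling loss below
20 mmHg, beat-to-beat waveform variability beyond the fixed template,
baroreflex coupling between tone and pressure, real motion-artifact
morphology (bursts are white), and sensor drift.  Passing the simulated
acceptance therefore demonstrates that the *control and estimation stack* is
correct and robust against the modelled disturbances — it is not clinical
evidence.

## Evaluation statistics

Tracked-vs-true pairs are averaged over non-overlapping 10-s windows
(windows with < 50% valid samples dropped — initialization, artifacts,
clamps).  Agreement uses Bland–Altman limits `bias ± 1.96·sd`; with repeated
measures per subject/scenario, sd comes from a one-way variance-component
decomposition (between component `(MSB − MSW)/m_h` with the ANOVA k−1
convention, within component MSW).  Trending uses the fraction of 5-min
pressure changes with agreeing sign, formed at a 30-step lag on the 10-s
grid with 10-s stride (overlapping); the small-delta exclusion zone defaults
to 0 mmHg.  The power budget sums the wearable component set (actuator
45.19, PPG 5.64, Bluetooth MCU 1.66, motion sensor 6.21 mW → 58.7 mW,
1408.8 mWh/24 h) under the 45 s initial + 2 min measure + 13 min
interpolation duty cycle.

## Numerical and procedural choices

* fs = 250 Hz everywhere; kernel state is a flat float64 vector; the loop
  runs in 5-s chunks (multiples of the 25-sample decimation) so resonance
  detection and mode switching can run between chunks in Python.
* Runs are deterministic given (scenario, seed): one `default_rng(seed)`
  drives ramp noise, then loop noise; re-running reproduces outputs
  bit-identically (tested).
* Problem sizes: acceptance statistics use the full ten 30-minute scenarios
  (≈ 4.5 M samples); unit and property tests use 10 s–8 min signals.
* Degenerate inputs are rejected with diagnostics: non-finite samples,
  empty signals, non-domed envelopes, sub-refractory beats, degenerate
  calibration pulses, illegal mode transitions.

## Known limitations

* Strong Mayer modulation (5 mmHg at 0.1 Hz — a 20 mmHg wavelength along
  the 2 mmHg/s ramp) biases the envelope centre by up to ≈ +5 mmHg in that
  scenario; the pooled suite statistics remain well inside the 5 ± 8 mmHg
  band.  A modulation-aware amplitude average would be needed to remove it.
* Absolute accuracy is anchored at P₀: the loop reconstructs *changes*; any
  initialization error persists until re-initialization (as in the modelled
  device, which re-enters the initial phase periodically).
* The interpolation-mode estimator is a linear stand-in; its accuracy is
  reported, not asserted.
* Heart-rate steps larger than ~40% between beats can transiently halve the
  detector's confirmation rate (the rate-adaptive refractory follows with a
  few-beat lag).
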