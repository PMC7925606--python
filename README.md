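# vctbp — volume-control-technique blood pressure

Continuous noninvasive **mean arterial blood pressure (mBP)** from a finger
photo-plethysmographic (PPG) signal, using the **volume control technique
(VCT)**: instead of clamping arterial volume within every heartbeat (the
classic vascular unloading / volume-clamp method, which needs pumps and
valves), the contact pressure of the light sensor is adjusted only *between*
beats so that blood inflow and outflow balance over each cardiac cycle.  The
actuator then only has to move as fast as mean pressure itself — slow enough
for a wearable finger-ring.

The package is a desk-scale implementation of the full control stack plus a
synthetic finger-hemodynamics simulator so the loop can be initialized, run,
stressed, and evaluated without hardware:

* `vctbp.signal_core` — sampled-signal container, the one-pole IIR cascade
  (`y_i = (1-UC)·y_{i-1} + UC·x_i`, with decimated stages for very low
  cutoffs) that splits v(t) into `v_Pulse`, `v_Rhythm`, `v_dRhythm`, `v_VCT`,
  and beat detection;
* `vctbp.oscillometry` — open-loop self-calibration: 0→200 mmHg ramp at
  2 mmHg/s, pulse-amplitude envelope, Gaussian-style fit whose peak marks mBP
  (maximum-oscillation rule), initial setpoint (P₀, v₀) and ratio-derived
  sBP/dBP;
* `vctbp.controller` — the closed-loop core:

  ```
  P_n  = P_0 − c_BBI·Σ V̄_n − c_BBP·V̄_n        beat-based setpoint control
  V̄_n  = (1/PI) ∫ v_VCT dt                      per-beat volume balance
  y_PD = c_P·v_Rhythm + c_D·v_dRhythm           continuous rhythm PID
  y_I  = c_I·Σ y_PD
  p_c  = P_n − y_I − y_PD                       contact-pressure command
  p_C2G = p_c + k·v_Pulse,  k = (sBP₀−dBP₀)/(v_sys−v_dia)   waveform
  ```

  plus the adaptive antiresonance notch (the deliberately slow actuator makes
  the loop prone to 0.1–1 Hz oscillation), hydrostatic heart-level correction
  and the measure/interpolate operation-mode machine;
* `vctbp.simulator` — beat-template arterial pressure generator with
  respiratory and Mayer-wave modulation and step/ramp/Valsalva-like events, a
  vasomotor tone trajectory, the S-shaped arctangent pressure–volume/light
  transfer, a slew-limited deadband actuator, noise/artifact injection, and
  the numba-compiled 250 Hz closed-loop harness (`run_closed_loop`) together
  with the seeded ten-scenario "standard-10" suite;
* `vctbp.evaluation` — 10-s window averaging, Bland–Altman limits of
  agreement (with the repeated-measures variance-component variant), 5-min
  delta concordance, actuator-speed statistics, and the wearable power
  budget;
* `vctbp.interface` — a thin `click` CLI (`vctbp simulate | run-loop |
  oscillometry | evaluate | power-budget | scenarios`), YAML run
  configurations and reproducible output snapshots.

## Worked example

Track a +20 mmHg pressure step through self-calibration and the closed loop:

```python
import vctbp as v
from vctbp import evaluation as ev

scn = v.SimulationScenario(
    "demo",
    v.BPTrajectoryConfig(duration=420.0, sbp=120, dbp=80, resp_depth=2.0,
                         events=(v.BPEvent("step", 240.0, +20.0),)),
    noise=v.NoiseConfig(snr_db=25.0), seed=7)
res = v.run_closed_loop(scn, seed=7)

print(res.envelope.P0)                       # 95.1  mmHg oscillometric setpoint
print(res.calib.sBP_init, res.calib.dBP_init)  # 116.7 87.0  ratio-derived
print(res.calib.k)                           # -35.7 mmHg per light unit

t, tracked, true, valid = res.tracked_vs_true()
# mean tracking error before / after the step (mmHg):
#   pre-step  +2.17     post-step +0.46
stats = ev.actuator_speed_stats(res.p_c, res.beats)
# median 0.86 / max 8.77 mmHg per beat of actuator motion
```

`res.envelope.P0` is the pressure at the oscillometric envelope peak — the
maximum-oscillation estimate of mBP and the loop's starting setpoint.  The
calibration slope `k` is negative because rising blood volume absorbs light
(systole is a `v_Pulse` minimum); `p_C2G = p_c + k·v_Pulse` therefore turns
the light pulse back into a pressure waveform whose pulse pressure equals
`sBP_init − dBP_init` on the calibration beat.  After the step the beat-based
integral accumulates the imbalance and re-converges within ~25 s; the
actuator statistics confirm that tracking mean pressure needs only ~1 mmHg of
motion per beat.

The same run from the shell:

```bash
vctbp run-loop --scenario standard-02 --seed 7 --out loop_out
vctbp power-budget
```

## Scope

Finger-level pressures only (no brachial transfer function), no cardiac
output or stroke-volume analysis (the per-beat `p_C2G` waveform is the hook
for external pulse-wave analysis), and no hardware drivers: the arctangent
pressure–volume transfer *is* the modeling contract.  See `docs/methods.md`
for the model details, parameter choices, and known limitations.
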