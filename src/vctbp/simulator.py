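"""Synthetic finger hemodynamics and the closed-loop harness.

The plant emulates what the optical sensor sees: a pulsatile arterial pressure
``p_a(t)`` (beat template scaled to per-beat sBP/dBP, modulated by respiration
and Mayer waves, perturbed by step/ramp/Valsalva-like events), a vasomotor
tone trajectory, and an S-shaped arctangent pressure-volume/light transfer

    v = v_low(tone) + (v_high - v_low(tone)) * (arctan((p_c - p_a)/w)/pi + 1/2)

whose lower asymptote rises with vasoconstriction while the upper asymptote
(all blood squeezed out) is tone-independent.  The transition width ``w`` is
sign-dependent (sharper on the collapse side ``p_c > p_a`` than on the
distension side), which is what makes the maximum-oscillation rule point at
mean pressure rather than at (sBP+dBP)/2.  A slew-rate-limited, deadband
(resolution)-gated, delayed actuator applies the contact pressure.

The closed loop runs sample-by-sample at 250 Hz in a numba kernel: plant ->
filter cascade -> streaming beat detector -> beat-based setpoint + rhythm PID
-> antiresonance notch -> actuator.  Chunked execution lets the Python layer
run resonance detection and operation-mode switching between chunks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import controller as ctl
from . import oscillometry as osc
from .signal_core import (DEFAULT_FS, Beat, FilterBankConfig, SampledSignal,
                          decompose, detect_beats, init_filter_states)

__all__ = [
    "BPEvent",
    "BPTrajectoryConfig",
    "PVModelConfig",
    "ActuatorConfig",
    "NoiseConfig",
    "SimulationScenario",
    "ClosedLoopResult",
    "generate_arterial_bp",
    "pv_transfer",
    "fat_spiky_check",
    "actuate",
    "add_noise_artifacts",
    "run_closed_loop",
    "standard_scenarios",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BPEvent:
    """A hemodynamic maneuver: step / ramp / valsalva-like excursion of mBP,
    or a commanded vasomotor tone change (``tone_step`` / ``tone_ramp``)."""

    type: str            # step | ramp | valsalva | tone_step | tone_ramp
    onset: float         # s
    magnitude: float     # mmHg for BP events, target tone for tone events
    duration: float = 0.0

    def __post_init__(self):
        if self.type not in ("step", "ramp", "valsalva", "tone_step", "tone_ramp"):
            raise ValueError(f"unknown event type {self.type!r}")


@dataclass
class BPTrajectoryConfig:
    duration: float = 300.0
    hr_bpm: float | tuple = 60.0          # scalar or piecewise [(t, bpm), ...]
    sbp: float = 120.0
    dbp: float = 80.0
    resp_freq: float = 0.25               # Hz, in [0.15, 0.4]
    resp_depth: float = 0.0               # mmHg
    mayer_freq: float = 0.1               # Hz
    mayer_depth: float = 0.0              # mmHg
    events: tuple = ()
    tone_base: float = 0.4
    tone_tau: float = 10.0                # s, first-order tone lag
    seed: int = 0
    fs: float = DEFAULT_FS

    def __post_init__(self):
        if not (self.dbp < self.dbp + (self.sbp - self.dbp) / 3.0 < self.sbp):
            raise ValueError("require dBP < mBP < sBP")
        if not (0.15 <= self.resp_freq <= 0.4):
            raise ValueError("respiratory frequency must lie in [0.15, 0.4] Hz")
        if not (0.0 <= self.tone_base <= 1.0):
            raise ValueError("tone must lie in [0, 1]")

    @property
    def mbp(self) -> float:
        return self.dbp + (self.sbp - self.dbp) / 3.0


@dataclass
class PVModelConfig:
    """Arctangent pressure-volume/light transfer.

    ``w_distension`` acts for transmural over-filling (p_c < p_a),
    ``w_collapse`` for the sharper collapse side (p_c > p_a); equal values
    recover the scalar-width model.  ``v_low = v_low0 + v_low_slope * tone``
    rises with vasoconstriction; ``v_high`` is tone-independent.
    """

    v_high: float = 1.0
    v_low0: float = 0.15
    v_low_slope: float = 0.25
    w_distension: float = 8.0    # mmHg
    w_collapse: float = 1.0      # mmHg

    def __post_init__(self):
        if not (self.v_low0 >= 0 and self.v_low0 + self.v_low_slope < self.v_high):
            raise ValueError("require v_low(tone) < v_high for all tone in [0,1]")
        if self.v_low_slope <= 0:
            raise ValueError("v_low must increase with vasoconstriction")
        if min(self.w_distension, self.w_collapse) <= 0:
            raise ValueError("widths must be positive")

    def v_low(self, tone) -> float:
        return self.v_low0 + self.v_low_slope * np.asarray(tone, float)


@dataclass
class ActuatorConfig:
    max_rate: float = 30.0       # mmHg/s
    resolution: float = 0.1      # mmHg, deadband below which the motor holds
    delay: float = 0.02          # s
    p_min: float = 0.0
    p_max: float = 250.0


@dataclass
class NoiseConfig:
    snr_db: float = math.inf     # white noise on v(t), relative to pulse power
    artifact_rate: float = 0.0   # bursts per minute
    artifact_duration: float = 0.8   # s
    artifact_scale: float = 8.0  # burst amplitude in pulse standard deviations


@dataclass
class SimulationScenario:
    name: str
    bp: BPTrajectoryConfig
    pv: PVModelConfig = field(default_factory=PVModelConfig)
    actuator: ActuatorConfig = field(default_factory=ActuatorConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0


@dataclass
class ClosedLoopResult:
    """Signals, per-beat records and bookkeeping of one closed-loop run."""

    p_a: SampledSignal
    p_c: SampledSignal
    v: SampledSignal
    p_c2g: SampledSignal
    quality: np.ndarray              # per-sample: 0 ok, 1 artifact, 2 clamped, 3 init
    beats: list
    beat_records: "np.ndarray"       # structured: t, PI, Pn, Vbar, tracked/true mBP
    envelope: "osc.OscillometricEnvelope"
    calib: "ctl.CalibrationState"
    event_log: list
    seed: int
    scenario: SimulationScenario
    failed: bool = False

    def tracked_vs_true(self, grid: float = 1.0):
        """(t, tracked mBP, true mBP, valid) on a uniform grid (default 1 s).

        Tracked mBP is the window-mean contact pressure in measure mode and
        the model estimate during interpolation; windows containing artifact
        or initialization samples are marked invalid.
        """
        n = int(self.p_c.duration // grid)
        k = int(round(grid * self.p_c.fs))
        t = self.p_c.t0 + (np.arange(n) + 0.5) * grid
        pc = self.p_c.values[: n * k].reshape(n, k)
        q = self.quality[: n * k].reshape(n, k)
        tracked = pc.mean(axis=1)
        valid = (q == 0).mean(axis=1) >= 0.5
        rec = self.beat_records
        if rec.size:
            interp_mask = rec["interpolated"] > 0
            if interp_mask.any():
                est_t = rec["t"][interp_mask]
                est_v = rec["mbp_est"][interp_mask]
                for j in range(n):
                    m = np.abs(est_t - t[j]) <= grid
                    if m.any():
                        tracked[j] = est_v[m].mean()
            true = np.interp(t, rec["t"], rec["mbp_true"])
        else:
            true = np.full(n, np.nan)
            valid[:] = False
        return t, tracked, true, valid


# ---------------------------------------------------------------------------
# arterial pressure generator
# ---------------------------------------------------------------------------

_TEMPLATE_N = 2048
_template_cache: dict[str, np.ndarray] = {}


def _pulse_template() -> np.ndarray:
    """Beat waveform on [0,1): systolic upstroke plus dicrotic bump, scaled to
    [0,1] and exponent-calibrated so its mean is exactly 1/3 (making the beat
    mean of ``dBP + PP*T`` equal to the standard dBP + PP/3 estimate)."""
    if "T" in _template_cache:
        return _template_cache["T"]
    phi = np.arange(_TEMPLATE_N) / _TEMPLATE_N
    s = (np.exp(-0.5 * ((phi - 0.30) / 0.11) ** 2)
         + 0.38 * np.exp(-0.5 * ((phi - 0.62) / 0.09) ** 2))
    s = (s - s.min()) / (s.max() - s.min())
    lo, hi = 0.2, 8.0
    for _ in range(80):                       # bisection on the exponent
        g = 0.5 * (lo + hi)
        if (s ** g).mean() > 1.0 / 3.0:
            lo = g
        else:
            hi = g
    T = s ** (0.5 * (lo + hi))
    _template_cache["T"] = T
    return T


def _hr_at(hr_bpm, t: float) -> float:
    if np.isscalar(hr_bpm):
        return float(hr_bpm)
    pts = sorted(hr_bpm)
    out = pts[0][1]
    for tt, bpm in pts:
        if t >= tt:
            out = bpm
    return float(out)


def _event_offset(events, t) -> np.ndarray:
    """Additive mBP offset of all BP events at times ``t`` (vectorised)."""
    t = np.asarray(t, float)
    off = np.zeros_like(t)
    for ev in events:
        if ev.type == "step":
            off += np.where(t >= ev.onset, ev.magnitude, 0.0)
        elif ev.type == "ramp":
            dur = max(ev.duration, 1e-9)
            frac = np.clip((t - ev.onset) / dur, 0.0, 1.0)
            off += ev.magnitude * frac
        elif ev.type == "valsalva":
            # 4-phase excursion: brief rise, dip below baseline, overshoot, recovery
            dur = ev.duration if ev.duration > 0 else 30.0
            x = (t - ev.onset) / dur
            shape = (np.exp(-0.5 * ((x - 0.1) / 0.07) ** 2)
                     - 1.2 * np.exp(-0.5 * ((x - 0.45) / 0.15) ** 2)
                     + 0.8 * np.exp(-0.5 * ((x - 0.8) / 0.12) ** 2))
            off += np.where((x >= 0) & (x <= 1.4), ev.magnitude * shape, 0.0)
    return off


def tone_trajectory(cfg: BPTrajectoryConfig) -> np.ndarray:
    """Commanded tone from tone events, smoothed by a first-order lag."""
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    cmd = np.full(n, cfg.tone_base)
    for ev in cfg.events:
        if ev.type == "tone_step":
            cmd = np.where(t >= ev.onset, ev.magnitude, cmd)
        elif ev.type == "tone_ramp":
            dur = max(ev.duration, 1e-9)
            frac = np.clip((t - ev.onset) / dur, 0.0, 1.0)
            cmd = np.where(t >= ev.onset, cmd * (1 - frac) + ev.magnitude * frac, cmd)
    uc = 1.0 - math.exp(-1.0 / (cfg.tone_tau * cfg.fs))
    tone = np.empty(n)
    y = cmd[0]
    for i in range(n):                 # short python loop is fine at config time
        y += uc * (cmd[i] - y)
        tone[i] = y
    return np.clip(tone, 0.0, 1.0)


def generate_arterial_bp(cfg: BPTrajectoryConfig):
    """Beat-by-beat arterial pressure waveform plus per-beat ground truth.

    Returns ``(p_a, truth)`` where truth is a structured array with fields
    ``t`` (beat onset), ``sbp``, ``dbp``, ``mbp``.  Reproducible by seed (the
    generator itself is deterministic; the seed feeds noise elsewhere).
    """
    fs = cfg.fs
    n = int(round(cfg.duration * fs))
    T = _pulse_template()

    onsets, sbps, dbps = [], [], []
    t = 0.0
    while t < cfg.duration:
        onsets.append(t)
        t += 60.0 / _hr_at(cfg.hr_bpm, t)
    onsets = np.asarray(onsets)
    mod = (cfg.resp_depth * np.sin(2 * np.pi * cfg.resp_freq * onsets)
           + cfg.mayer_depth * np.sin(2 * np.pi * cfg.mayer_freq * onsets + 1.0)
           + _event_offset(cfg.events, onsets))
    sbps = cfg.sbp + mod
    dbps = cfg.dbp + mod
    mbps = dbps + (sbps - dbps) / 3.0

    p_a = np.empty(n)
    idx = np.arange(n)
    beat_idx = np.searchsorted(onsets, idx / fs, side="right") - 1
    beat_idx = np.clip(beat_idx, 0, onsets.size - 1)
    next_onset = np.append(onsets[1:], cfg.duration + 60.0 / _hr_at(cfg.hr_bpm, cfg.duration))
    pi = next_onset - onsets
    phi = (idx / fs - onsets[beat_idx]) / pi[beat_idx]
    tv = T[np.clip((phi * _TEMPLATE_N).astype(np.int64), 0, _TEMPLATE_N - 1)]
    p_a = dbps[beat_idx] + (sbps[beat_idx] - dbps[beat_idx]) * tv

    truth = np.zeros(onsets.size, dtype=[("t", float), ("sbp", float),
                                         ("dbp", float), ("mbp", float)])
    truth["t"], truth["sbp"], truth["dbp"], truth["mbp"] = onsets, sbps, dbps, mbps
    sig = SampledSignal(p_a, fs=fs, unit="mmHg", label="p_a")
    return sig, truth


# ---------------------------------------------------------------------------
# pressure-volume transfer and pulse-shape check
# ---------------------------------------------------------------------------

def pv_transfer(p_a, p_c, tone, cfg: PVModelConfig):
    """Light signal from the S-shaped arctangent transfer (vectorised)."""
    x = np.asarray(p_c, float) - np.asarray(p_a, float)
    w = np.where(x >= 0, cfg.w_collapse, cfg.w_distension)
    vl = cfg.v_low(tone)
    return vl + (cfg.v_high - vl) * (np.arctan(x / w) / np.pi + 0.5)


def fat_spiky_check(v_pulse_beat: np.ndarray, fs: float = DEFAULT_FS,
                    tol_frac: float = 0.02) -> str:
    """Classify a beat's pulse shape from its normalised integral.

    Below mBP the negative half-wave dominates ("fat", negative integral);
    above mBP the pulse is "spiky" (positive); at balance the integral
    vanishes.  ``tol_frac`` is the balance tolerance as a fraction of the
    peak-to-trough amplitude.
    """
    seg = np.asarray(v_pulse_beat, float)
    amp = seg.max() - seg.min()
    if amp <= 0:
        return "balanced"
    pi_s = seg.size / fs
    integral = np.trapezoid(seg, dx=1.0 / fs) / pi_s
    if integral < -tol_frac * amp:
        return "fat"
    if integral > tol_frac * amp:
        return "spiky"
    return "balanced"


# ---------------------------------------------------------------------------
# actuator
# ---------------------------------------------------------------------------

@njit(cache=True)
def _slew_kernel(cmd, pos0, max_step, deadband, delay_n, p_min, p_max):
    n = cmd.size
    out = np.empty(n)
    pos = pos0
    for i in range(n):
        j = i - delay_n
        target = cmd[j] if j >= 0 else cmd[0]
        target = min(max(target, p_min), p_max)
        d = target - pos
        if abs(d) > deadband:
            if d > max_step:
                d = max_step
            elif d < -max_step:
                d = -max_step
            pos += d
        out[i] = pos
    return out


def actuate(command: SampledSignal, cfg: ActuatorConfig | None = None,
            initial: float | None = None) -> SampledSignal:
    """Slew-limited, deadband-gated, delayed application of a pressure command.

    The motor holds (zero duty cycle) while the command stays within the
    resolution deadband, and otherwise moves toward it at ``max_rate``; motion
    starts after a transport delay.  The applied |dp/dt| never exceeds
    ``max_rate``.
    """
    cfg = cfg or ActuatorConfig()
    fs = command.fs
    pos0 = float(command.values[0]) if initial is None else float(initial)
    out = _slew_kernel(command.values, pos0, cfg.max_rate / fs, cfg.resolution,
                       int(round(cfg.delay * fs)), cfg.p_min, cfg.p_max)
    return SampledSignal(out, fs=fs, t0=command.t0, unit="mmHg", label="p_c applied")


def add_noise_artifacts(v: SampledSignal, cfg: NoiseConfig,
                        rng: np.random.Generator):
    """Additive white noise at the configured SNR plus short motion bursts.

    Returns ``(signal, artifact_mask)``.  SNR is measured against the
    detrended (pulsatile) signal power.
    """
    x = v.values.copy()
    n = x.size
    mask = np.zeros(n, dtype=bool)
    if np.isfinite(cfg.snr_db):
        ac = x - x.mean()
        p_sig = float(np.mean(ac ** 2))
        sigma = math.sqrt(p_sig / (10.0 ** (cfg.snr_db / 10.0)))
        x = x + rng.normal(0.0, sigma, n)
    if cfg.artifact_rate > 0:
        n_bursts = rng.poisson(cfg.artifact_rate * v.duration / 60.0)
        std = float(np.std(v.values - v.values.mean())) or 1.0
        for _ in range(n_bursts):
            i0 = rng.integers(0, n)
            i1 = min(n, i0 + int(cfg.artifact_duration * v.fs))
            burst = cfg.artifact_scale * std * rng.standard_normal(i1 - i0)
            x[i0:i1] += burst
            mask[i0:i1] = True
    return v.with_values(x), mask


# ---------------------------------------------------------------------------
# closed-loop kernel
# ---------------------------------------------------------------------------
# controller/plant state vector layout (float64); slots 0..12 are the filter
# cascade memory in signal_core's layout, the rest is loop state.  Module
# constants keep the kernel readable; numba folds them at compile time.

S_DEC = 13        # decimation phase counter
S_P0 = 14         # initial setpoint
S_PN = 15         # current beat setpoint
S_SUMV = 16       # running sum of beat volume integrals
S_YI = 17         # continuous integral term
S_YPD = 18        # continuous PD term
S_POS = 19        # actuator position
S_ACCV = 20       # v_VCT accumulator since last beat
S_ACCP = 21       # p_c accumulator since last beat
S_ACCL = 22       # light accumulator since last beat
S_MIN = 23        # running v_Pulse minimum (systole candidate)
S_MINI = 24       # its global sample index
S_MAX = 25        # running v_Pulse maximum since last beat
S_AMP = 26        # beat amplitude EMA
S_LASTD = 27      # global index of last beat detection
S_LASTS = 28      # global index of last confirmed systole
S_NZ1 = 29        # notch biquad state 1
S_NZ2 = 30        # notch biquad state 2
S_CLAMP = 31      # command clamped flag
S_HOLD = 32       # artifact hold-off samples remaining
S_LASTV = 33      # last valid light sample
S_PIEMA = 34      # pulse-interval EMA (samples)
S_ACCX = 35       # block accumulator: raw input (VLF anti-alias mean)
S_ACCR = 36       # block accumulator: rhythm LP output
N_STATE = 37
_NONE = -1.0e18


@njit(cache=True)
def _loop_kernel(p_a, tone, noise, artifact, cmd_override, control_enabled,
                 coef, pv, act, gains, notch_b, notch_a, notch_on, det,
                 floor, ceil, g0, n_rhythm_lp, ST, out_v, out_vp, out_vvct,
                 out_pc, out_cmd, out_q, b_t, b_pi, b_vbar, b_pn, b_amp,
                 b_pcm, b_vm):
    uc_p, uc_r, uc_v, uc_d, decf, uc_v1 = coef
    dec = int(decf)
    vl0, vls, vh, wm, wp = pv
    max_step, deadband, delay_nf = act
    delay_n = int(delay_nf)
    c_bbi, c_bbp, c_p, c_d, c_i, leak = gains
    refractory, rise_frac, gate_frac, hold_samples = det
    fs = 250.0
    nb = 0
    n = p_a.size
    for i in range(n):
        g = g0 + i
        # ---- plant ----
        pos = ST[S_POS]
        x_t = pos - p_a[i]
        w = wp if x_t >= 0.0 else wm
        vl = vl0 + vls * tone[i]
        v = vl + (vh - vl) * (np.arctan(x_t / w) / np.pi + 0.5) + noise[i]
        out_v[i] = v
        # ---- artifact gating ----
        if artifact[i]:
            ST[S_HOLD] = hold_samples
        invalid = ST[S_HOLD] > 0.0
        if invalid:
            ST[S_HOLD] -= 1.0
            # feed the filters their own slow baseline: freezing on a raw
            # sample (possibly mid-systole) would bleed a false DC into the
            # volume-balance path that the integrator amplifies
            x = ST[9]
        else:
            x = v
            ST[S_LASTV] = v
        # ---- filter cascade ----
        ST[0] += uc_p * (x - ST[0])
        h1 = x - ST[0]
        ST[1] += uc_p * (h1 - ST[1])
        v_pulse = h1 - ST[1]
        ST[2] += uc_r * (x - ST[2])
        ST[3] += uc_r * (ST[2] - ST[3])
        ST[4] += uc_r * (ST[3] - ST[4])
        if n_rhythm_lp == 5:
            ST[5] += uc_r * (ST[4] - ST[5])
            ST[6] += uc_r * (ST[5] - ST[6])
            r_lp = ST[6]
        else:
            r_lp = ST[4]
        # decimated very-low-frequency stages advance on block means of
        # their inputs (anti-alias averaging): instantaneous sampling would
        # phase-lock to the cardiac cycle at some heart rates and bias the
        # baseline away from the true mean
        at_update = int(ST[S_DEC]) == 0
        if at_update:
            if ST[S_ACCX] != 0.0:
                mx = ST[S_ACCX] / dec
                mr = ST[S_ACCR] / dec
            else:
                mx = x
                mr = r_lp
            r1m = mr - ST[7]
            ST[7] += uc_v * (mr - ST[7])
            ST[8] += uc_v * (r1m - ST[8])
            ST[9] += uc_v1 * (mx - ST[9])
            ST[S_ACCX] = 0.0
            ST[S_ACCR] = 0.0
        ST[S_ACCX] += x
        ST[S_ACCR] += r_lp
        v_rhythm = (r_lp - ST[7]) - ST[8]
        v_vct = x - ST[9]
        ST[S_DEC] += 1.0
        if int(ST[S_DEC]) >= dec:
            ST[S_DEC] = 0.0
        d = (v_rhythm - ST[11]) * fs
        ST[11] = v_rhythm
        ST[12] += uc_d * (d - ST[12])
        v_drhythm = ST[12]
        out_vp[i] = v_pulse
        out_vvct[i] = v_vct
        # ---- volume-balance memory ----
        # the running sum of beat integrals is accumulated sample-wise
        # (each sample contributes v_VCT / PI): identical to the per-beat
        # summation when every beat is detected cleanly, but immune to
        # detection jitter, split beats and windows discarded as implausible
        if control_enabled == 1 and ST[S_CLAMP] == 0.0 and not invalid:
            pi_n = ST[S_PIEMA] if ST[S_PIEMA] > 0.0 else fs
            ST[S_SUMV] += v_vct / pi_n
        # ---- beat accumulators ----
        ST[S_ACCV] += v_vct
        ST[S_ACCP] += pos
        ST[S_ACCL] += v
        if v_pulse > ST[S_MAX]:
            ST[S_MAX] = v_pulse
        if v_pulse < ST[S_MIN]:
            ST[S_MIN] = v_pulse
            ST[S_MINI] = g
        # no confirmations for a while: relax the amplitude gate so weak
        # pulses (e.g. far from the balance point) can be re-acquired
        last_ref = ST[S_LASTD] if ST[S_LASTD] > _NONE else 0.0
        if ST[S_PIEMA] > 0.0 and g - last_ref > 2.0 * ST[S_PIEMA]:
            ST[S_AMP] *= 1.0 - 1.0 / fs
        # ---- beat confirmation (refractory adapts to the running PI) ----
        refr_eff = refractory if ST[S_PIEMA] <= 0.0 \
            else max(refractory, 0.72 * ST[S_PIEMA])
        if (not invalid
                and v_pulse > ST[S_MIN] + rise_frac * ST[S_AMP]
                and ST[S_MAX] - ST[S_MIN] >= gate_frac * ST[S_AMP]
                and g - ST[S_LASTS] >= refr_eff
                and ST[S_MINI] > ST[S_LASTS]):
            # window length is detection-to-detection (that is what the
            # accumulators cover); the physiological pulse interval is
            # systole-to-systole (detection latency varies, systole does not)
            pi_det = g - ST[S_LASTD] if ST[S_LASTD] > _NONE else -1.0
            pi_samp = ST[S_MINI] - ST[S_LASTS] if ST[S_LASTS] > _NONE else -1.0
            amp = ST[S_MAX] - ST[S_MIN]
            accepted = False
            if 0.25 * fs <= pi_samp <= 3.0 * fs and pi_det > 0.0:
                vbar = ST[S_ACCV] / pi_det
                # PI memory ignores outlier intervals (missed/split beats)
                if ST[S_PIEMA] <= 0.0:
                    ST[S_PIEMA] = pi_samp
                    accepted = True
                elif 0.72 * ST[S_PIEMA] <= pi_samp <= 1.6 * ST[S_PIEMA]:
                    ST[S_PIEMA] = 0.8 * ST[S_PIEMA] + 0.2 * pi_samp
                    accepted = True
                if ST[S_PIEMA] < 0.3 * fs:
                    ST[S_PIEMA] = 0.3 * fs
                elif ST[S_PIEMA] > 2.5 * fs:
                    ST[S_PIEMA] = 2.5 * fs
                ST[S_PN] = ST[S_P0] - c_bbi * ST[S_SUMV] - c_bbp * vbar
                if nb < b_t.size:
                    b_t[nb] = g / fs
                    b_pi[nb] = pi_samp / fs
                    b_vbar[nb] = vbar
                    b_pn[nb] = ST[S_PN]
                    b_amp[nb] = amp
                    b_pcm[nb] = ST[S_ACCP] / pi_det
                    b_vm[nb] = ST[S_ACCL] / pi_det
                    nb += 1
            if 0.25 * fs <= pi_samp <= 3.0 * fs and accepted:
                ST[S_AMP] = 0.8 * ST[S_AMP] + 0.2 * amp
            ST[S_LASTD] = g
            ST[S_LASTS] = ST[S_MINI]
            ST[S_ACCV] = 0.0
            ST[S_ACCP] = 0.0
            ST[S_ACCL] = 0.0
            ST[S_MIN] = v_pulse
            ST[S_MINI] = g
            ST[S_MAX] = v_pulse
        # ---- continuous PID ----
        ST[S_YPD] = c_p * v_rhythm + c_d * v_drhythm
        if control_enabled == 1 and ST[S_CLAMP] == 0.0 and not invalid:
            ST[S_YI] = (1.0 - leak) * ST[S_YI] + c_i * ST[S_YPD]
        # ---- command ----
        if control_enabled == 1:
            cmd = ST[S_PN] - ST[S_YI] - ST[S_YPD]
        else:
            cmd = cmd_override[i]
        if notch_on == 1:
            y = notch_b[0] * cmd + ST[S_NZ1]
            ST[S_NZ1] = notch_b[1] * cmd - notch_a[1] * y + ST[S_NZ2]
            ST[S_NZ2] = notch_b[2] * cmd - notch_a[2] * y
            cmd = y
        if cmd < floor:
            cmd = floor
            ST[S_CLAMP] = 1.0
        elif cmd > ceil:
            cmd = ceil
            ST[S_CLAMP] = 1.0
        else:
            ST[S_CLAMP] = 0.0
        out_cmd[i] = cmd
        # ---- actuator (transport delay via command history) ----
        j = i - delay_n
        target = out_cmd[j] if j >= 0 else cmd
        dlt = target - pos
        if abs(dlt) > deadband:
            if dlt > max_step:
                dlt = max_step
            elif dlt < -max_step:
                dlt = -max_step
            pos += dlt
        ST[S_POS] = pos
        out_pc[i] = pos
        q = 0
        if invalid:
            q = 1
        elif ST[S_CLAMP] == 1.0:
            q = 2
        out_q[i] = q
    return nb


def _init_loop_state(filter_states: np.ndarray, P0: float, p_c0: float,
                     amp_est: float, pi_est_samples: float = 0.0) -> np.ndarray:
    ST = np.zeros(N_STATE)
    ST[0:13] = filter_states
    ST[S_P0] = P0
    ST[S_PN] = P0
    ST[S_POS] = p_c0
    ST[S_MIN] = np.inf
    ST[S_MAX] = -np.inf
    ST[S_AMP] = amp_est
    ST[S_LASTD] = _NONE
    ST[S_LASTS] = _NONE
    ST[S_PIEMA] = pi_est_samples
    return ST


# ---------------------------------------------------------------------------
# closed-loop harness
# ---------------------------------------------------------------------------

def _open_loop_init(scn: SimulationScenario, p_a: SampledSignal, tone: np.ndarray,
                    rng: np.random.Generator, fb: FilterBankConfig,
                    ramp_rate: float = 2.0, settle: float = 10.0):
    """Oscillometric ramp + settle at P0; returns initialization bundle."""
    fs = p_a.fs
    ramp = osc.ramp_protocol(0.0, 200.0, ramp_rate, fs=fs,
                             max_rate=scn.actuator.max_rate)
    n_ramp = len(ramp)
    p_cmd = ramp.values
    # descend to a provisional setpoint, refined after the envelope fit
    n_desc = int(5.0 * fs)
    n_settle = int(settle * fs)
    n_init = n_ramp + n_desc + n_settle
    if n_init > len(p_a):
        raise ValueError("scenario too short for the oscillometric initialization")

    applied = actuate(SampledSignal(p_cmd, fs=fs, unit="mmHg"), scn.actuator,
                      initial=p_cmd[0])
    v_ramp = pv_transfer(p_a.values[:n_ramp], applied.values, tone[:n_ramp], scn.pv)
    v_sig, art = add_noise_artifacts(
        SampledSignal(v_ramp, fs=fs), scn.noise, rng)
    bank = decompose(v_sig, fb)
    beats = detect_beats(bank.v_Pulse)
    # beats touched by a motion artifact are unusable for the envelope
    beats = [b for b in beats
             if not art[v_sig.index_at(b.t_onset):v_sig.index_at(b.t_end) + 1].any()]
    pts = osc.extract_amplitudes(bank.v_Pulse, applied, beats)
    baselines = []
    for b in beats:
        i0, i1 = v_sig.index_at(b.t_onset), v_sig.index_at(b.t_end)
        baselines.append(float(np.mean(v_sig.values[i0:i1 + 1])))
    baselines = baselines[: len(pts)]
    env = osc.fit_envelope(pts, v_baseline=np.asarray(baselines))
    sbp0, dbp0 = osc.estimate_sbp_dbp(env)
    P0 = env.P0

    # descend from 200 mmHg to P0 and settle there
    cmd2 = np.full(n_desc + n_settle, P0)
    app2 = actuate(SampledSignal(cmd2, fs=fs, unit="mmHg"), scn.actuator,
                   initial=applied.values[-1])
    sl = slice(n_ramp, n_init)
    v2 = pv_transfer(p_a.values[sl], app2.values, tone[sl], scn.pv)
    v2_sig, art2 = add_noise_artifacts(SampledSignal(v2, fs=fs), scn.noise, rng)
    bank2 = decompose(v2_sig, fb, states=bank.states)
    tail = slice(n_desc + n_settle // 2, n_desc + n_settle)
    clean_tail = ~art2[tail]
    v0 = float(np.mean(v2_sig.values[tail][clean_tail])) \
        if clean_tail.any() else float(np.mean(v2_sig.values[tail]))
    settle_beats = [b for b in detect_beats(bank2.v_Pulse)
                    if b.t_sys >= (n_desc + n_settle // 2) / fs
                    and not art2[v2_sig.index_at(b.t_onset):
                                 v2_sig.index_at(b.t_end) + 1].any()]
    if settle_beats:
        v_sys_ref = float(np.mean([b.v_sys for b in settle_beats]))
        v_dia_ref = float(np.mean([b.v_dia for b in settle_beats]))
        amp_est = v_dia_ref - v_sys_ref
        pi_est = float(np.median([b.PI for b in settle_beats]))
    else:  # pathological settle (e.g. heavy artifact); fall back to envelope
        amp_est = env.A
        v_sys_ref, v_dia_ref = -0.5 * env.A, 0.5 * env.A
        pi_est = 0.0
    env.v0 = v0
    # the settle amplitude cannot plausibly exceed the envelope peak; a
    # contaminated reference would permanently blind the streaming detector
    amp_est = min(amp_est, 1.5 * env.A)
    calib = ctl.CalibrationState(sBP_init=sbp0, dBP_init=dbp0,
                                 v_sys_ref=v_sys_ref, v_dia_ref=v_dia_ref)
    pc_init = np.concatenate([applied.values, app2.values])
    v_init = np.concatenate([v_sig.values, v2_sig.values])
    return dict(env=env, calib=calib, v0=v0, amp_est=max(amp_est, 1e-6),
                pi_est=pi_est, n_init=n_init, pc_init=pc_init, v_init=v_init,
                p_c_end=float(app2.values[-1]), filter_states=bank2.states)


def run_closed_loop(scenario: SimulationScenario,
                    gains: ctl.ControllerGains | None = None,
                    fb: FilterBankConfig | None = None,
                    seed: int | None = None,
                    antiresonance: bool = True,
                    enable_mode_cycling: bool = False,
                    mode_cfg: ctl.ModeConfig | None = None,
                    chunk_s: float = 5.0) -> ClosedLoopResult:
    """Run oscillometric initialization followed by the closed VCT loop.

    Deterministic given ``(scenario, seed)``.  Resonance detection and
    operation-mode switching run between 5-s kernel chunks.  A run whose
    contact pressure stays pinned at a range limit for more than 10 s is
    flagged failed rather than raising.
    """
    gains = gains or ctl.ControllerGains()
    fb = fb or FilterBankConfig(fs=scenario.bp.fs)
    mode_cfg = mode_cfg or ctl.ModeConfig()
    seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    fs = scenario.bp.fs

    p_a, truth = generate_arterial_bp(scenario.bp)
    tone = tone_trajectory(scenario.bp)
    event_log: list[tuple[float, str]] = [(0.0, "mode start -> initial")]

    init = _open_loop_init(scenario, p_a, tone, rng, fb)
    env, calib = init["env"], init["calib"]
    n_init, n_total = init["n_init"], len(p_a)
    event_log.append((n_init / fs, f"envelope fit: P0={env.P0:.1f} mmHg; mode initial -> measure"))

    # noise for the closed-loop phase, pre-generated for determinism
    rest = SampledSignal(pv_transfer(p_a.values[n_init:], env.P0,
                                     tone[n_init:], scenario.pv), fs=fs)
    noisy, artifact = add_noise_artifacts(rest, scenario.noise, rng)
    noise_arr = noisy.values - rest.values

    states = init_filter_states(init["v0"], fb)
    ST = _init_loop_state(states, env.P0, init["p_c_end"], init["amp_est"],
                          pi_est_samples=init["pi_est"] * fs)
    ST[S_LASTV] = init["v0"]

    n_rest = n_total - n_init
    out_v = np.empty(n_rest)
    out_vp = np.empty(n_rest)
    out_vvct = np.empty(n_rest)
    out_pc = np.empty(n_rest)
    out_cmd = np.empty(n_rest)
    out_q = np.zeros(n_rest, dtype=np.int8)
    max_beats = int(n_rest / (0.25 * fs)) + 2
    b_arr = [np.zeros(max_beats) for _ in range(7)]
    b_t, b_pi, b_vbar, b_pn, b_amp, b_pcm, b_vm = b_arr

    notch_b = np.zeros(3)
    notch_a = np.zeros(3)
    notch_on = 0
    coef = fb.coefficients()
    pv = np.array([scenario.pv.v_low0, scenario.pv.v_low_slope,
                   scenario.pv.v_high, scenario.pv.w_distension,
                   scenario.pv.w_collapse])
    act = np.array([scenario.actuator.max_rate / fs, scenario.actuator.resolution,
                    float(int(round(scenario.actuator.delay * fs)))])
    g_arr = np.array([gains.c_BBI, gains.c_BBP, gains.c_P, gains.c_D,
                      gains.c_I, gains.i_leak])
    det = np.array([0.25 * fs, 0.45, 0.50, 1.5 * fs])
    floor, ceil = ctl.COUPLING_FLOOR, ctl.PRESSURE_CEILING

    chunk = int(chunk_s * fs)
    chunk -= chunk % fb.vlf_decimation
    ares = ctl.AntiresonanceState(enabled=antiresonance)
    last_retune = -10 ** 9
    mode = ctl.OperationMode.MEASURE
    mode_t = n_init / fs
    interp_model = ctl.InterpolationModel()
    interp_flags = np.zeros(max_beats)
    mbp_est = np.full(max_beats, np.nan)
    nb_total = 0
    pinned = 0
    failed = False
    watchdog_t = 0.0
    i = 0
    # detector settling plus VLF-baseline absorption of the residual v0
    # averaging error before the setpoint integrator engages (the integrator
    # would otherwise turn a few-thousandths light mismatch into a lasting
    # setpoint offset)
    grace = int(60 * fs)
    while i < n_rest:
        j = min(i + chunk, n_rest)
        control = 1 if mode == ctl.OperationMode.MEASURE else 0
        if mode == ctl.OperationMode.INTERPOLATE:
            override = np.full(j - i, floor)
        elif i < grace:
            control = 0
            override = np.full(j - i, env.P0)
        else:
            override = np.zeros(j - i)
        nb_before = nb_total
        nb_total += _loop_kernel(
            p_a.values[n_init + i:n_init + j], tone[n_init + i:n_init + j],
            noise_arr[i:j], artifact[i:j].astype(np.uint8), override, control,
            coef, pv, act, g_arr, notch_b, notch_a, notch_on, det,
            floor, ceil, i, fb.n_rhythm_lp,
            ST, out_v[i:j], out_vp[i:j], out_vvct[i:j], out_pc[i:j],
            out_cmd[i:j], out_q[i:j],
            b_t[nb_total:], b_pi[nb_total:], b_vbar[nb_total:], b_pn[nb_total:],
            b_amp[nb_total:], b_pcm[nb_total:], b_vm[nb_total:])
        if mode == ctl.OperationMode.INTERPOLATE:
            interp_flags[nb_before:nb_total] = 1.0
            if interp_model.coef is not None:
                for kk in range(nb_before, nb_total):
                    mbp_est[kk] = interp_model.predict(b_amp[kk], b_vm[kk])
        # divergence check: pinned at a range limit
        pinned = pinned + (j - i) if np.all(out_q[i:j] == 2) else 0
        if pinned > 10 * fs:
            failed = True
        # pulse-lost watchdog: losing beats means the contact pressure has
        # left the pulsatile region (e.g. after a transient runaway); reset
        # the controller memory to the oscillometric setpoint and re-engage
        last_beat_t = b_t[nb_total - 1] if nb_total > 0 else 0.0
        if (mode == ctl.OperationMode.MEASURE
                and j / fs - max(last_beat_t, watchdog_t) > 10.0):
            ST[S_SUMV] = 0.0
            ST[S_YI] = 0.0
            ST[S_PN] = ST[S_P0]
            ST[S_AMP] = init["amp_est"]
            watchdog_t = j / fs
            event_log.append((n_init / fs + j / fs,
                              "pulse lost >10 s: controller reset to P0"))
        # antiresonance: inspect the trailing 30 s.  The detection band stays
        # below the cardiac frequency (beat-synchronous ripple is not a loop
        # resonance), and retuning is rate-limited to avoid chatter.
        if antiresonance and j >= int(30 * fs):
            win = SampledSignal(out_pc[j - int(30 * fs):j], fs=fs, unit="mmHg")
            f_beat = fs / ST[S_PIEMA] if ST[S_PIEMA] > 0 else 10.0
            band_hi = min(0.9, 0.8 * f_beat)
            hit = ctl.detect_resonance(win, band=(0.1, band_hi),
                                       amp_threshold=1.5) \
                if band_hi > 0.1 else None
            if hit is not None:
                f_r, a_r = hit
                retune = (ares.notch_freq is None
                          or abs(f_r - ares.notch_freq) > ares.notch_bandwidth)
                retune = retune and (j - last_retune) >= int(10 * fs)
                if retune:
                    last_retune = j
                    ares.detected_freq, ares.detected_amp = f_r, a_r
                    ares.notch_freq = min(max(f_r, 0.05), 1.5)
                    nb_c, na_c = ctl.design_notch(ares.notch_freq,
                                                  ares.notch_bandwidth, fs)
                    notch_b[:], notch_a[:] = nb_c, na_c
                    notch_on = 1
                    # seed the biquad at the current command level so the
                    # unity-DC-gain notch engages without a step transient
                    lvl = out_cmd[j - 1]
                    ST[S_NZ1] = lvl * ((notch_b[1] - notch_a[1]) + (notch_b[2] - notch_a[2]))
                    ST[S_NZ2] = lvl * (notch_b[2] - notch_a[2])
                    event_log.append((n_init / fs + j / fs,
                                      f"antiresonance notch tuned to {f_r:.2f} Hz"
                                      f" (amplitude {a_r:.1f} mmHg)"))
        # operation-mode cycling
        if enable_mode_cycling:
            t_now = (n_init + j) / fs
            if mode == ctl.OperationMode.MEASURE and \
                    t_now - mode_t >= mode_cfg.measure_duration:
                sel = slice(max(0, nb_total - 400), nb_total)
                try:
                    interp_model.fit(b_amp[sel], b_vm[sel], b_pcm[sel])
                    mode = ctl.mode_step(mode, "measure_timer_elapsed")
                    mode_t = t_now
                    event_log.append((t_now, "mode measure -> interpolate"))
                except ValueError:
                    pass  # not enough beats yet; stay in measure mode
            elif mode == ctl.OperationMode.INTERPOLATE and \
                    t_now - mode_t >= mode_cfg.interpolate_duration:
                mode = ctl.OperationMode.MEASURE
                mode_t = t_now
                ST[S_PN] = ST[S_P0] - g_arr[0] * ST[S_SUMV]   # resume from the setpoint memory
                event_log.append((t_now, "mode interpolate -> measure (timer)"))
        i = j

    # assemble full-length signals (initialization phase prepended)
    pc_full = np.concatenate([init["pc_init"], out_pc])
    v_full = np.concatenate([init["v_init"], out_v])
    vp_full = np.concatenate([np.zeros(n_init), out_vp])
    q_full = np.concatenate([np.full(n_init, 3, dtype=np.int8), out_q])
    p_c = SampledSignal(pc_full, fs=fs, unit="mmHg", label="p_c")
    v_sig = SampledSignal(v_full, fs=fs, label="v")
    p_c2g = ctl.calibrate_waveform(p_c, SampledSignal(vp_full, fs=fs), calib)

    rec = np.zeros(nb_total, dtype=[("t", float), ("PI", float), ("Pn", float),
                                    ("Vbar", float), ("amp", float),
                                    ("pc_mean", float), ("v_mean", float),
                                    ("mbp_true", float), ("mbp_est", float),
                                    ("interpolated", float)])
    if nb_total:
        rec["t"] = b_t[:nb_total] + n_init / fs
        rec["PI"] = b_pi[:nb_total]
        rec["Pn"] = b_pn[:nb_total]
        rec["Vbar"] = b_vbar[:nb_total]
        rec["amp"] = b_amp[:nb_total]
        rec["pc_mean"] = b_pcm[:nb_total]
        rec["v_mean"] = b_vm[:nb_total]
        rec["mbp_true"] = np.interp(rec["t"], truth["t"], truth["mbp"])
        rec["mbp_est"] = mbp_est[:nb_total]
        rec["interpolated"] = interp_flags[:nb_total]

    beats = detect_beats(SampledSignal(out_vp, fs=fs, t0=n_init / fs))
    return ClosedLoopResult(
        p_a=p_a, p_c=p_c, v=v_sig, p_c2g=p_c2g, quality=q_full,
        beats=beats, beat_records=rec, envelope=env, calib=calib,
        event_log=event_log, seed=seed, scenario=scenario, failed=failed)


# ---------------------------------------------------------------------------
# standard scenario suite
# ---------------------------------------------------------------------------

def standard_scenarios(seed: int = 0, duration: float = 1800.0
                       ) -> list[SimulationScenario]:
    """The seeded "standard-10" suite: 10 thirty-minute scenarios spanning
    constant pressure, steps, drift, rhythm-heavy, vasomotor, artifact-laden,
    tachycardic and hypotensive conditions (clinical mBP range ~45-113 mmHg).
    """
    ss = np.random.SeedSequence(seed).spawn(10)
    sub = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    mk = lambda i, name, bp, **kw: SimulationScenario(
        name=name, bp=bp, seed=sub[i], **kw)
    noise = NoiseConfig(snr_db=25.0)
    scns = [
        mk(0, "constant",
           BPTrajectoryConfig(duration=duration, sbp=120, dbp=80,
                              resp_depth=2.0, resp_freq=0.25),
           noise=noise),
        mk(1, "steps",
           BPTrajectoryConfig(duration=duration, sbp=120, dbp=80, resp_depth=2.0,
                              events=(BPEvent("step", 420.0, +20.0),
                                      BPEvent("step", 1020.0, -40.0),
                                      BPEvent("step", 1500.0, +20.0))),
           noise=noise),
        mk(2, "drift",
           BPTrajectoryConfig(duration=duration, sbp=115, dbp=75, resp_depth=2.0,
                              events=(BPEvent("ramp", 300.0, +15.0, 900.0),)),
           noise=noise),
        mk(3, "respiratory",
           BPTrajectoryConfig(duration=duration, sbp=120, dbp=80,
                              resp_depth=6.0, resp_freq=0.3),
           noise=noise),
        mk(4, "mayer",
           BPTrajectoryConfig(duration=duration, sbp=120, dbp=80,
                              resp_depth=2.0, mayer_depth=5.0),
           noise=noise),
        mk(5, "tone-ramp",
           BPTrajectoryConfig(duration=duration, sbp=120, dbp=80, resp_depth=2.0,
                              tone_base=0.3,
                              events=(BPEvent("tone_ramp", 600.0, 0.7, 60.0),)),
           noise=noise),
        mk(6, "tone-and-bp",
           BPTrajectoryConfig(duration=duration, sbp=120, dbp=80, resp_depth=2.0,
                              tone_base=0.3,
                              events=(BPEvent("tone_ramp", 500.0, 0.6, 60.0),
                                      BPEvent("step", 900.0, +15.0),
                                      BPEvent("valsalva", 1300.0, 25.0, 30.0))),
           noise=noise),
        mk(7, "artifacts",
           BPTrajectoryConfig(duration=duration, sbp=120, dbp=80, resp_depth=2.0),
           noise=NoiseConfig(snr_db=20.0, artifact_rate=1.0)),
        mk(8, "tachycardia",
           BPTrajectoryConfig(duration=duration, sbp=125, dbp=85, hr_bpm=120.0,
                              resp_depth=2.0),
           noise=noise),
        mk(9, "hypotension",
           BPTrajectoryConfig(duration=duration, sbp=78, dbp=45, resp_depth=2.0,
                              events=(BPEvent("step", 900.0, +8.0),)),
           noise=noise),
    ]
    return scns
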