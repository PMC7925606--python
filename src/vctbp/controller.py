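"""Closed-loop volume-control-technique (VCT) core.

Instead of clamping arterial volume within each heartbeat (vascular unloading),
the VCT balances blood inflow and outflow over whole beats, so the contact
pressure only needs to move as fast as mean blood pressure:

* beat-based setpoint control: the per-beat integral of v_VCT measures whether
  pulses have gone "fat" (pressure below mBP, negative half-wave dominates) or
  "spiky" (above mBP); its running sum is the long-term memory that
  reconstructs the very-low-frequency blood-pressure information removed by
  the filters::

      P_n = P_0 - c_BBI * sum(V_n) - c_BBP * V_n,
      V_n = (1/PI) * integral of v_VCT over the beat;

* a continuous PID on the rhythm band keeps respiratory/Mayer-wave content of
  the light signal small::

      y_PD = c_P * v_Rhythm + c_D * v_dRhythm,   y_I = c_I * sum(y_PD),
      p_c  = P_n - y_I - y_PD;

* an adaptive antiresonance notch suppresses control-loop oscillation
  (0.1-1 Hz) caused by the deliberately slow actuator;
* the pulsatile waveform is reconstructed by scaling v_Pulse back to pressure
  with the calibration factor k = (sBP_init - dBP_init)/(v_sys - v_dia).

All negative-feedback signs follow the inverse light-volume convention: a
blood-pressure rise increases finger volume and *decreases* v, which must
*raise* the contact pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.signal import lfilter

from .signal_core import Beat, SampledSignal

__all__ = [
    "ControllerGains",
    "ControllerState",
    "CalibrationState",
    "AntiresonanceState",
    "HeartLevelOffset",
    "OperationMode",
    "ModeConfig",
    "InterpolationModel",
    "beat_volume_integral",
    "update_setpoint",
    "pid_rhythm",
    "contact_pressure_command",
    "detect_resonance",
    "design_notch",
    "notch_filter",
    "calibrate_waveform",
    "hydrostatic_correct",
    "mode_step",
    "interpolation_estimate",
]

PRESSURE_CEILING = 250.0      # mmHg, actuator range top
COUPLING_FLOOR = 20.0         # mmHg, minimum pressure for reliable light coupling


@dataclass
class ControllerGains:
    """Control constants (all non-negative; signs fixed for negative feedback).

    c_BBI / c_BBP convert the dimensionless beat volume integral into mmHg of
    setpoint correction (integral resp. proportional beat-based terms); c_P,
    c_D, c_I are the continuous rhythm-PID constants applied every sample.
    Defaults were frozen after a one-off tuning run against the standard
    scenario suite (scripts/tune_gains.py).
    """

    c_BBI: float = 30.0
    c_BBP: float = 15.0
    c_P: float = 40.0
    c_D: float = 6.0
    c_I: float = 0.0012
    i_leak: float = 0.0   # optional forgetting factor for y_I, 0 = pure sum

    def __post_init__(self):
        for name in ("c_BBI", "c_BBP", "c_P", "c_D", "c_I"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.i_leak < 1.0):
            raise ValueError("i_leak must lie in [0, 1)")


class OperationMode(str, Enum):
    START = "start"
    INITIAL = "initial"
    MEASURE = "measure"
    INTERPOLATE = "interpolate"


@dataclass
class CalibrationState:
    """Pulse-waveform calibration (k maps light units to mmHg, negative)."""

    sBP_init: float
    dBP_init: float
    v_sys_ref: float
    v_dia_ref: float
    k: float = field(init=False)

    def __post_init__(self):
        if self.v_sys_ref == self.v_dia_ref:
            raise ValueError("degenerate pulse: v_sys equals v_dia")
        if not self.dBP_init < self.sBP_init:
            raise ValueError("require dBP_init < sBP_init")
        self.k = (self.sBP_init - self.dBP_init) / (self.v_sys_ref - self.v_dia_ref)


@dataclass
class AntiresonanceState:
    """Latched resonance detection plus the tuned notch memory."""

    detected_freq: float | None = None
    detected_amp: float = 0.0
    notch_freq: float | None = None
    notch_bandwidth: float = 0.1
    enabled: bool = True
    zi: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        if self.notch_freq is not None and not (0.05 <= self.notch_freq <= 1.5):
            raise ValueError("notch frequency must lie in [0.05, 1.5] Hz")


@dataclass
class HeartLevelOffset:
    """Hydrostatic finger-heart column; d_v > 0 means finger below heart."""

    d_v: float = 0.0        # cm
    rho_g: float = 0.78     # mmHg per cm of blood column

    def __post_init__(self):
        if abs(self.d_v) > 100:
            raise ValueError("|d_v| must not exceed 100 cm")


@dataclass
class ControllerState:
    """Everything the closed loop carries between beats and samples."""

    P0: float
    Pn: float
    sum_V: float = 0.0
    y_PD: float = 0.0
    y_I: float = 0.0
    beat_count: int = 0
    mode: OperationMode = OperationMode.START
    antires: AntiresonanceState = field(default_factory=AntiresonanceState)
    calib: CalibrationState | None = None
    clamped: bool = False

    def __post_init__(self):
        if not np.isfinite(self.Pn):
            raise ValueError("Pn must be finite")


# ---------------------------------------------------------------------------
# beat-based setpoint control
# ---------------------------------------------------------------------------

def beat_volume_integral(v_vct: SampledSignal, beat: Beat) -> float:
    """Normalised beat integral ``V_n = (1/PI) * int v_VCT dt`` (trapezoidal).

    The window is the pulse interval ending at the beat's systole.  A balanced
    pulse (equal positive and negative half-wave areas) integrates to zero; a
    fat pulse is negative, a spiky pulse positive.
    """
    if beat.PI <= 0:
        raise ValueError("pulse interval must be positive")
    t_start = beat.t_sys - beat.PI
    if t_start < v_vct.t0 or beat.t_sys > v_vct.t0 + (len(v_vct) - 1) / v_vct.fs + 1e-9:
        raise ValueError("beat not fully inside the signal")
    i0 = v_vct.index_at(t_start)
    i1 = v_vct.index_at(beat.t_sys)
    seg = v_vct.values[i0:i1 + 1]
    if seg.size < 2:
        raise ValueError("beat window too short")
    return float(np.trapezoid(seg, dx=1.0 / v_vct.fs) / beat.PI)


def update_setpoint(state: ControllerState, v_bar: float,
                    gains: ControllerGains) -> float:
    """Per-beat setpoint update ``P_n = P_0 - c_BBI*sum(V) - c_BBP*V_n``.

    The running sum is the memory that reconstructs slow blood-pressure
    changes; a negative beat integral (fat pulse) therefore raises P_n.
    """
    if not state.clamped:        # anti-windup: freeze the memory while clamped
        state.sum_V += v_bar
    state.beat_count += 1
    state.Pn = state.P0 - gains.c_BBI * state.sum_V - gains.c_BBP * v_bar
    return state.Pn


def pid_rhythm(v_rhythm: float, v_drhythm: float, state: ControllerState,
               gains: ControllerGains) -> tuple[float, float]:
    """Per-sample rhythm PID terms (y_PD, y_I)."""
    state.y_PD = gains.c_P * v_rhythm + gains.c_D * v_drhythm
    if not state.clamped:
        state.y_I = (1.0 - gains.i_leak) * state.y_I + gains.c_I * state.y_PD
    return state.y_PD, state.y_I


def contact_pressure_command(state: ControllerState,
                             notch_coeffs: tuple | None = None) -> float:
    """Contact-pressure command ``p_c = P_n - y_I - y_PD``, notched and clamped."""
    cmd = state.Pn - state.y_I - state.y_PD
    ar = state.antires
    if notch_coeffs is None and ar.enabled and ar.notch_freq is not None:
        notch_coeffs = design_notch(ar.notch_freq, ar.notch_bandwidth, fs=250.0)
    if notch_coeffs is not None:
        b, a = notch_coeffs
        y, ar.zi = lfilter(b, a, [cmd], zi=ar.zi)
        cmd = float(y[0])
    clamped = not (COUPLING_FLOOR <= cmd <= PRESSURE_CEILING)
    state.clamped = clamped
    return float(min(max(cmd, COUPLING_FLOOR), PRESSURE_CEILING))


# ---------------------------------------------------------------------------
# antiresonance
# ---------------------------------------------------------------------------

def detect_resonance(p_c: SampledSignal, band: tuple[float, float] = (0.1, 1.0),
                     amp_threshold: float = 2.0,
                     min_cycles: float = 3.0) -> tuple[float, float] | None:
    """Dominant oscillation of p_c within the resonance band, if persistent.

    Returns (frequency Hz, amplitude mmHg) when the largest spectral line in
    the band exceeds ``amp_threshold`` and at least ``min_cycles`` cycles fit
    into the window; otherwise ``None``.
    """
    x = p_c.values
    if x.size / p_c.fs < 30.0:
        raise ValueError("resonance detection needs a window of at least 30 s")
    x = x - np.polyval(np.polyfit(np.arange(x.size), x, 1), np.arange(x.size))
    win = np.hanning(x.size)
    spec = np.fft.rfft(x * win)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / p_c.fs)
    # amplitude of a sinusoid under a Hann window: 2|X| / sum(win)
    amps = 2.0 * np.abs(spec) / win.sum()
    sel = (freqs >= band[0]) & (freqs <= band[1]) & (freqs >= min_cycles / (x.size / p_c.fs))
    if not sel.any():
        return None
    i = np.flatnonzero(sel)[np.argmax(amps[sel])]
    if amps[i] < amp_threshold:
        return None
    return float(freqs[i]), float(amps[i])


def design_notch(freq: float, bandwidth: float, fs: float = 250.0):
    """Second-order IIR notch (unity DC gain, zero at ``freq``)."""
    if not (0.0 < freq < fs / 2):
        raise ValueError("notch frequency must lie in (0, fs/2)")
    w0 = 2.0 * math.pi * freq / fs
    q = freq / max(bandwidth, 1e-6)
    alpha = math.sin(w0) / (2.0 * q)
    b = np.array([1.0, -2.0 * math.cos(w0), 1.0]) / (1.0 + alpha)
    a = np.array([1.0, -2.0 * math.cos(w0) / (1.0 + alpha),
                  (1.0 - alpha) / (1.0 + alpha)])
    return b, a


def notch_filter(x, freq: float, bandwidth: float, fs: float = 250.0) -> np.ndarray:
    """Apply the antiresonance notch to a sample sequence."""
    b, a = design_notch(freq, bandwidth, fs)
    return lfilter(b, a, np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# waveform calibration and corrections
# ---------------------------------------------------------------------------

def calibrate_waveform(p_c: SampledSignal, v_pulse: SampledSignal,
                       calib: CalibrationState) -> SampledSignal:
    """Superimpose the pulsatile waveform: ``p_C2G(t) = p_c(t) + k * v_Pulse(t)``.

    k is negative under the inverse light-volume convention, so systole (a
    v_Pulse minimum) becomes a pressure maximum; during the calibration beat
    the reconstructed pulse pressure equals sBP_init - dBP_init exactly.
    """
    if len(p_c) != len(v_pulse) or p_c.fs != v_pulse.fs:
        raise ValueError("p_c and v_Pulse must share grid")
    values = p_c.values + calib.k * v_pulse.values
    return SampledSignal(values, fs=p_c.fs, t0=p_c.t0, unit="mmHg", label="p_C2G")


def hydrostatic_correct(p, offset: HeartLevelOffset):
    """Heart-level correction: subtract the finger-heart blood column."""
    return p - offset.d_v * offset.rho_g


# ---------------------------------------------------------------------------
# operation modes (start -> initial -> measure <-> interpolate)
# ---------------------------------------------------------------------------

@dataclass
class ModeConfig:
    measure_duration: float = 120.0       # s of VCT phase before interpolation
    interpolate_duration: float = 780.0   # 13 min of low-power interpolation
    initial_duration: float = 45.0        # open-loop oscillometric phase


_TRANSITIONS: dict[tuple[OperationMode, str], OperationMode] = {
    (OperationMode.START, "started"): OperationMode.INITIAL,
    (OperationMode.INITIAL, "envelope_done"): OperationMode.MEASURE,
    (OperationMode.MEASURE, "measure_timer_elapsed"): OperationMode.INTERPOLATE,
    (OperationMode.INTERPOLATE, "interp_timer_elapsed"): OperationMode.INITIAL,
    (OperationMode.INTERPOLATE, "morphology_change"): OperationMode.INITIAL,
}


def mode_step(mode: OperationMode, event: str) -> OperationMode:
    """Advance the operation-mode state machine; illegal transitions raise."""
    key = (mode, event)
    if key not in _TRANSITIONS:
        raise ValueError(f"illegal transition: event {event!r} in mode {mode.value!r}")
    return _TRANSITIONS[key]


# ---------------------------------------------------------------------------
# interpolation-mode estimator (deliberately simple linear stand-in)
# ---------------------------------------------------------------------------

class InterpolationModel:
    """Per-session linear map from PPG beat features to mBP.

    Trained on measure-mode beats (features: pulse amplitude and baseline
    light level; target: tracked mBP); a stand-in for whatever model a device
    would ship.  Estimates are flagged "interpolated" quality downstream.
    """

    def __init__(self):
        self.coef: np.ndarray | None = None
        self._feature_mean: np.ndarray | None = None

    def fit(self, amplitudes, baselines, mbp, min_duration_beats: int = 60):
        X = np.column_stack([np.asarray(amplitudes, float),
                             np.asarray(baselines, float)])
        y = np.asarray(mbp, float)
        if y.size < min_duration_beats:
            raise ValueError("need at least ~60 s of measure-mode beats to train")
        self._feature_mean = X.mean(axis=0)
        Xc = X - self._feature_mean
        A = np.column_stack([np.ones(y.size), Xc])
        self.coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return self

    def predict(self, amplitude: float, baseline: float) -> float:
        if self.coef is None:
            raise RuntimeError("interpolation model untrained: run measure mode first")
        x = np.array([amplitude, baseline]) - self._feature_mean
        return float(self.coef[0] + x @ self.coef[1:])


def interpolation_estimate(model: InterpolationModel, amplitude: float,
                           baseline: float) -> float:
    """Per-beat mBP estimate during interpolation mode (quality: interpolated)."""
    return model.predict(amplitude, baseline)
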