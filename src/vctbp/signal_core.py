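"""Core signal types and the PPG filter cascade.

The raw photo-plethysmographic light signal v(t) is an inverse surrogate of
finger arterial blood volume: rising volume absorbs more light, so v falls.
A cascade of first-order IIR low-pass stages (``y_i = (1-UC)*y_{i-1} + UC*x_i``,
optionally decimated with sample-and-hold to reach very low cutoffs) splits
v(t) into the four control components:

* ``v_Pulse``  — cardiac pulses, content above ~0.5 Hz (high-pass);
* ``v_Rhythm`` — respiratory and Mayer-wave band, ~0.01-0.5 Hz (band-pass);
* ``v_dRhythm``— band-limited derivative of v_Rhythm (non-pulsatile);
* ``v_VCT``    — everything above the very-low-frequency cutoff (~0.01 Hz),
  pulses retained; its per-beat integral is the volume-balance control signal.

Content below ~0.01 Hz is dominated by vasomotor tone rather than blood
pressure and is removed from every control path.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks, lfilter

DEFAULT_FS = 250.0

__all__ = [
    "DEFAULT_FS",
    "SampledSignal",
    "FilterStageConfig",
    "FilterBankConfig",
    "FilterBankOutput",
    "Beat",
    "iir_stage",
    "init_filter_states",
    "decompose",
    "frequency_response",
    "detect_beats",
    "read_signal",
    "write_signal",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SampledSignal:
    """Uniformly sampled time series.

    Parameters
    ----------
    values : array-like
        Sample values; must be finite.
    fs : float
        Sampling frequency in Hz (default 250).
    t0 : float
        Time of the first sample in seconds.
    unit : str
        Either ``"mmHg"`` or ``"dimensionless"``.
    label : str
        Free-text description.
    """

    values: np.ndarray
    fs: float = DEFAULT_FS
    t0: float = 0.0
    unit: str = "dimensionless"
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not np.isfinite(self.values).all():
            raise ValueError("all samples must be finite")
        if not (self.fs > 0):
            raise ValueError("fs must be positive")
        if self.unit not in ("mmHg", "dimensionless"):
            raise ValueError(f"unknown unit {self.unit!r}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (clipped to range)."""
        i = int(round((t - self.t0) * self.fs))
        return min(max(i, 0), self.values.size - 1)

    def with_values(self, values, label: str | None = None) -> "SampledSignal":
        return replace(self, values=np.asarray(values, float),
                       label=self.label if label is None else label)


@dataclass(frozen=True)
class FilterStageConfig:
    """One first-order IIR low-pass stage.

    ``UC`` is the update coefficient in (0, 1]; ``decimation`` down-samples the
    recursion (the state advances only every ``decimation``-th input sample and
    the output is held in between), which keeps UC in a numerically sensible
    range for very low cutoffs.
    """

    UC: float
    decimation: int = 1

    def __post_init__(self):
        if not (0.0 < self.UC <= 1.0):
            raise ValueError("UC must be in (0, 1]")
        if self.decimation < 1 or int(self.decimation) != self.decimation:
            raise ValueError("decimation must be a positive integer")

    @staticmethod
    def from_cutoff(fc: float, fs: float, decimation: int = 1) -> "FilterStageConfig":
        """Stage whose -3 dB point sits at ``fc`` for sampling rate ``fs``."""
        uc = 1.0 - math.exp(-2.0 * math.pi * fc / (fs / decimation))
        return FilterStageConfig(UC=uc, decimation=decimation)


# per-stage cutoff multiplier so a 2-stage subtractive high-pass cascade has
# its -3 dB point at the nominal cutoff: |HP1|^2 = 2^-1/2 at f_c gives
# (f_c/f_stage)^2 = 1/(sqrt(2)-1), i.e. f_stage = sqrt(sqrt(2)-1)*f_c
_HP2_CUTOFF_SCALE = math.sqrt(math.sqrt(2.0) - 1.0)  # = 0.6436


@dataclass
class FilterBankConfig:
    """Configuration of the four-output decomposition cascade."""

    fs: float = DEFAULT_FS
    cutoff_vlf: float = 0.01
    cutoff_pulse: float = 0.5
    rhythm_band: tuple[float, float] = (0.01, 0.5)
    dRhythm_band: tuple[float, float] = (0.05, 0.5)
    vlf_decimation: int = 25
    n_rhythm_lp: int = 3

    def __post_init__(self):
        if not (self.cutoff_vlf < self.rhythm_band[1] <= self.cutoff_pulse):
            raise ValueError("require cutoff_vlf < rhythm_band high <= cutoff_pulse")
        if self.rhythm_band[0] < self.cutoff_vlf:
            raise ValueError("rhythm band must not extend below the VLF cutoff")
        if not (0 < self.cutoff_vlf and self.cutoff_pulse < self.fs / 2):
            raise ValueError("cutoffs must lie in (0, fs/2)")
        if self.n_rhythm_lp not in (3, 5):
            raise ValueError("this cascade realisation supports a rhythm "
                             "low-pass depth of 3 or 5 stages")

    # stage definitions, in the order the streaming kernel runs them
    @property
    def pulse_stage(self) -> FilterStageConfig:
        return FilterStageConfig.from_cutoff(
            _HP2_CUTOFF_SCALE * self.cutoff_pulse, self.fs)

    @property
    def rhythm_stage(self) -> FilterStageConfig:
        return FilterStageConfig.from_cutoff(self.cutoff_pulse, self.fs)

    @property
    def vlf_stage(self) -> FilterStageConfig:
        return FilterStageConfig.from_cutoff(
            self.cutoff_vlf, self.fs, decimation=self.vlf_decimation)

    @property
    def vct_vlf_stage(self) -> FilterStageConfig:
        # single-stage removal for the v_VCT branch: first-order behaviour
        # near DC is what lets the beat-integral memory reconstruct very slow
        # pressure drifts (a second-order edge would null the loop gain at DC);
        # the stage corner sits slightly above the nominal cutoff so the
        # response at cutoff_vlf is a -3 dB-like corner
        return FilterStageConfig.from_cutoff(
            1.1 * self.cutoff_vlf, self.fs, decimation=self.vlf_decimation)

    @property
    def drhythm_stage(self) -> FilterStageConfig:
        return FilterStageConfig.from_cutoff(self.dRhythm_band[1], self.fs)

    def coefficients(self) -> np.ndarray:
        """Flat coefficient vector [UC_pulse, UC_rhythm, UC_vlf, UC_d, decim].

        Shared by the vectorised ``decompose`` and the per-sample closed-loop
        kernel so both paths realise the same cascade.
        """
        return np.array([
            self.pulse_stage.UC,
            self.rhythm_stage.UC,
            self.vlf_stage.UC,
            self.drhythm_stage.UC,
            float(self.vlf_decimation),
            self.vct_vlf_stage.UC,
        ])


N_FILTER_STATES = 13
# state slots: 0 lp_p1, 1 lp_p2, 2..6 lp_r1..5, 7 lp_rv1, 8 lp_rv2,
#              9 lp_v1, 10 lp_v2, 11 prev_rhythm, 12 lp_d


@dataclass
class FilterBankOutput:
    """The four decomposed components plus the cascade memory."""

    v_Pulse: SampledSignal
    v_Rhythm: SampledSignal
    v_dRhythm: SampledSignal
    v_VCT: SampledSignal
    states: np.ndarray = field(default_factory=lambda: np.zeros(N_FILTER_STATES))


@dataclass(frozen=True)
class Beat:
    """One cardiac cycle located on v_Pulse.

    With transmitted light, systole (maximal arterial volume) is a local
    *minimum* of v_Pulse, so ``v_sys < v_dia``.
    """

    t_onset: float
    t_sys: float
    t_end: float
    PI: float
    v_sys: float
    v_dia: float

    def __post_init__(self):
        if not (self.t_onset < self.t_sys < self.t_end):
            raise ValueError("require t_onset < t_sys < t_end")
        if self.PI <= 0.25:
            raise ValueError("pulse interval must exceed the 250 ms refractory")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _one_pole(x: np.ndarray, uc: float, y0: float, decimation: int = 1) -> np.ndarray:
    """Run one low-pass stage over ``x`` (vectorised; hold between updates)."""
    if decimation == 1:
        y, _ = lfilter([uc], [1.0, -(1.0 - uc)], x, zi=[(1.0 - uc) * y0])
        return y
    # anti-alias block means feed the decimated recursion (instantaneous
    # sampling would phase-lock to periodic inputs); update k consumes the
    # mean of the preceding block, the first update sees only x[0]
    d = decimation
    n_up = (x.size + d - 1) // d
    xs = np.empty(n_up)
    xs[0] = x[0]
    if n_up > 1:
        full = (n_up - 1) * d
        xs[1:] = np.add.reduceat(x[:full], np.arange(0, full, d)) / d
    ys, _ = lfilter([uc], [1.0, -(1.0 - uc)], xs, zi=[(1.0 - uc) * y0])
    return np.repeat(ys, d)[: x.size]


def iir_stage(x, cfg: FilterStageConfig, initial_state: float = 0.0) -> np.ndarray:
    """Apply a single first-order IIR low-pass stage.

    ``y_i = (1 - UC) * y_{i-1} + UC * x_i`` seeded with ``initial_state``; with
    ``decimation > 1`` the recursion advances only on every decimation-th input
    sample and the output is held in between.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("input must be non-empty")
    if not np.isfinite(x).all():
        bad = int(np.flatnonzero(~np.isfinite(x))[0])
        raise ValueError(f"non-finite input sample at index {bad}")
    return _one_pole(x, cfg.UC, float(initial_state), cfg.decimation)


def init_filter_states(v0: float, cfg: FilterBankConfig) -> np.ndarray:
    """Seed every cascade memory with the open-loop setpoint companion ``v0``.

    After seeding, a constant input equal to ``v0`` produces exactly zero in
    all band-limited outputs from the first sample.
    """
    if not np.isfinite(v0):
        raise ValueError("v0 must be finite")
    s = np.zeros(N_FILTER_STATES)
    s[0] = v0          # pulse LP 1 (sees raw input)
    s[2:7] = v0        # rhythm LP chain
    s[7] = v0          # rhythm VLF baseline (sees the LP chain output)
    s[9] = v0          # VCT VLF baseline (sees raw input)
    # the remaining slots see already-high-passed signals and start at zero
    return s


def decompose(v: SampledSignal, cfg: FilterBankConfig,
              states: np.ndarray | None = None) -> FilterBankOutput:
    """Split v(t) into v_Pulse, v_Rhythm, v_dRhythm and v_VCT.

    ``states`` carries the cascade memory between calls (streaming use); pass
    ``None`` to seed every stage with the first sample, which suppresses the
    start-up transient for a signal that begins near its baseline.
    """
    if v.unit != "dimensionless":
        raise ValueError("decompose expects the dimensionless light signal")
    if v.fs != cfg.fs:
        raise ValueError(f"signal rate {v.fs} does not match filter design rate {cfg.fs}")
    x = v.values
    if x.size == 0:
        raise ValueError("empty signal")
    if states is None:
        states = init_filter_states(float(x[0]), cfg)
    s = np.asarray(states, dtype=float).copy()
    uc_p, uc_r, uc_v, uc_d, dec, uc_v1 = cfg.coefficients()
    dec = int(dec)

    # pulse path: two subtractive high-pass stages
    lp1 = _one_pole(x, uc_p, s[0])
    h1 = x - lp1
    lp2 = _one_pole(h1, uc_p, s[1])
    v_pulse = h1 - lp2

    # rhythm path: cascade of one-pole low-passes, then two decimated VLF
    # removals (the depth of the chain sets how well cardiac pulses are kept
    # out of the rhythm controller)
    n_r = cfg.n_rhythm_lp
    r_chain = [x]
    for j in range(n_r):
        r_chain.append(_one_pole(r_chain[-1], uc_r, s[2 + j]))
    r_c = r_chain[-1]
    bv1 = _one_pole(r_c, uc_v, s[7], dec)
    r1 = r_c - bv1
    bv2 = _one_pole(r1, uc_v, s[8], dec)
    v_rhythm = r1 - bv2

    # VCT path: single-stage VLF removal from the raw signal, pulses retained
    bw1 = _one_pole(x, uc_v1, s[9], dec)
    v_vct = x - bw1
    bw2 = np.array([s[10]])   # slot kept for layout compatibility

    # dRhythm: scaled first difference of v_Rhythm, low-passed
    d = np.empty_like(v_rhythm)
    d[0] = (v_rhythm[0] - s[11]) * cfg.fs
    d[1:] = np.diff(v_rhythm) * cfg.fs
    v_drhythm = _one_pole(d, uc_d, s[12])

    # decimated stages store the last *updated* value, which the hold already
    # exposes at the final sample
    r_tail = [r_chain[j + 1][-1] for j in range(n_r)] + [0.0] * (5 - n_r)
    new_states = np.array(
        [lp1[-1], lp2[-1]] + r_tail
        + [bv1[-1], bv2[-1], bw1[-1], bw2[-1], v_rhythm[-1], v_drhythm[-1]])
    mk = lambda y, lab: SampledSignal(y, fs=v.fs, t0=v.t0, unit="dimensionless", label=lab)
    return FilterBankOutput(
        v_Pulse=mk(v_pulse, "v_Pulse"),
        v_Rhythm=mk(v_rhythm, "v_Rhythm"),
        v_dRhythm=mk(v_drhythm, "v_dRhythm"),
        v_VCT=mk(v_vct, "v_VCT"),
        states=new_states,
    )


def frequency_response(cfg: FilterBankConfig, f) -> dict[str, np.ndarray]:
    """Complex gain of each output at the frequencies ``f`` (Hz).

    Evaluates the discrete-time cascade transfer functions; decimated stages
    are modelled at their decimated rate (the sample-and-hold ripple at
    frequencies far above a decimated stage's cutoff is negligible because the
    stage gain is already tiny there).
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))
    if np.any(f <= 0) or np.any(f >= cfg.fs / 2):
        raise ValueError("frequencies must lie strictly inside (0, fs/2)")
    uc_p, uc_r, uc_v, uc_d, dec, uc_v1 = cfg.coefficients()

    def H_lp(uc, d=1):
        z = np.exp(-1j * 2 * np.pi * f * d / cfg.fs)
        return uc / (1.0 - (1.0 - uc) * z)

    hp_pulse = (1.0 - H_lp(uc_p)) ** 2
    lp_rhythm = H_lp(uc_r) ** cfg.n_rhythm_lp
    hp_vlf = (1.0 - H_lp(uc_v, int(dec))) ** 2
    hp_vct = 1.0 - H_lp(uc_v1, int(dec))
    diff = (1.0 - np.exp(-1j * 2 * np.pi * f / cfg.fs)) * cfg.fs
    return {
        "v_Pulse": hp_pulse,
        "v_Rhythm": lp_rhythm * hp_vlf,
        "v_dRhythm": lp_rhythm * hp_vlf * diff * H_lp(uc_d),
        "v_VCT": hp_vct,
    }


def detect_beats(v_pulse: SampledSignal, refractory: float = 0.25,
                 rel_prominence: float = 0.5,
                 rescan_prominence: float = 0.15) -> list[Beat]:
    """Locate cardiac cycles on the high-pass-filtered pulse signal.

    Systole is the local *minimum* of v_Pulse (maximal arterial volume under
    the inverse light-volume convention).  Detection is two-pass: a strict
    amplitude threshold (fraction of the robust signal swing, high enough to
    reject dicrotic dips) finds the regular beats, then gaps longer than
    1.6 pulse intervals are rescanned at a lower threshold so attenuated
    beats (e.g. a transient amplitude dropout) are still caught.  A 250 ms
    refractory prevents double detection; a flat signal yields no beats.
    """
    x = v_pulse.values
    fs = v_pulse.fs
    lo, hi = np.percentile(x, [2.0, 98.0])
    swing = hi - lo
    if swing <= 0 or not np.isfinite(swing):
        return []
    # normalise by a rolling amplitude estimate so the threshold adapts to
    # slowly varying pulse size (e.g. along an oscillometric ramp); a floor at
    # 5% of the global swing keeps near-flat regions from amplifying noise
    block = max(int(2.0 * fs), 1)
    nb = max(x.size // block, 1)
    cores = x[: nb * block].reshape(nb, block)
    env = np.percentile(cores, 98.0, axis=1) - np.percentile(cores, 2.0, axis=1)
    centers = (np.arange(nb) + 0.5) * block
    amp_env = np.interp(np.arange(x.size), centers, env)
    amp_env = np.maximum(amp_env, 0.05 * swing)
    xn = x / amp_env
    distance = max(int(round(refractory * fs)), 1)
    peaks, _ = find_peaks(-xn, distance=distance, prominence=rel_prominence)
    if peaks.size >= 3:
        # rate-adaptive second pass: a refractory of 0.7 pulse intervals
        # suppresses dicrotic double-detections that clear the amplitude
        # threshold near the volume-balance point
        med_pi = float(np.median(np.diff(peaks)))
        distance2 = max(distance, int(0.7 * med_pi))
        peaks, _ = find_peaks(-xn, distance=distance2,
                              prominence=0.6 * rel_prominence)
        med_pi = float(np.median(np.diff(peaks))) if peaks.size >= 3 else med_pi
        extras = []
        for a, b in zip(peaks[:-1], peaks[1:]):
            if b - a > 1.6 * med_pi:
                pad = int(0.6 * med_pi)
                seg = xn[a + pad:b - pad + 1]
                if seg.size > 3:
                    sub, _ = find_peaks(-seg, distance=distance2,
                                        prominence=rescan_prominence)
                    extras.extend(a + pad + sub)
        if extras:
            merged = np.sort(np.concatenate([peaks, np.asarray(extras, int)]))
            kept = [int(merged[0])]
            for q in merged[1:]:
                if q - kept[-1] >= distance2:
                    kept.append(int(q))
            peaks = np.asarray(kept)
    if peaks.size < 2:
        return []
    beats: list[Beat] = []
    t = v_pulse.t0
    for k in range(1, peaks.size):
        i_prev, i_sys = peaks[k - 1], peaks[k]
        seg = x[i_prev:i_sys]
        i_on = i_prev + int(np.argmax(seg))
        if k + 1 < peaks.size:
            i_end = peaks[k] + int(np.argmax(x[peaks[k]:peaks[k + 1]]))
        else:
            i_end = min(x.size - 1, i_sys + (i_sys - i_prev))
        if not (i_on < i_sys < i_end) or (i_sys - i_prev) / fs <= 0.2501:
            continue
        beats.append(Beat(
            t_onset=t + i_on / fs,
            t_sys=t + i_sys / fs,
            t_end=t + i_end / fs,
            PI=(i_sys - i_prev) / fs,
            v_sys=float(x[i_sys]),
            v_dia=float(x[i_on]),
        ))
    return beats


# ---------------------------------------------------------------------------
# file I/O: UTF-8 CSV `time_s,value` + JSON sidecar {fs, unit, label, t0}
# ---------------------------------------------------------------------------

def write_signal(sig: SampledSignal, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s,value\n")
        for t, v in zip(sig.times, sig.values):
            fh.write(f"{t:.6f},{v:.9g}\n")
    meta = {"fs": sig.fs, "unit": sig.unit, "label": sig.label, "t0": sig.t0}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta), encoding="utf-8")


def read_signal(path) -> SampledSignal:
    """Read a signal CSV (tolerating '#' comment lines) plus its JSON sidecar."""
    path = Path(path)
    values = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("time_s"):
                continue
            values.append(float(line.split(",")[1]))
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text(encoding="utf-8")) if sidecar.exists() else {}
    return SampledSignal(
        np.asarray(values), fs=float(meta.get("fs", DEFAULT_FS)),
        t0=float(meta.get("t0", 0.0)), unit=meta.get("unit", "dimensionless"),
        label=meta.get("label", ""),
    )
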