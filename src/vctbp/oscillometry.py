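"""Open-loop oscillometric initialization.

A slow contact-pressure ramp sweeps the finger artery from unloaded to fully
occluded while the pulse amplitude of the light signal is recorded beat by
beat.  The amplitude-versus-pressure envelope is fitted with a Gaussian-style
curve whose peak marks mean blood pressure (maximum-oscillation rule); that
pressure becomes the starting setpoint P0 of the closed loop, and the
low-passed light value there its companion v0.  Systolic and diastolic
pressure can additionally be read off the fitted envelope at configurable
amplitude ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .signal_core import Beat, SampledSignal

__all__ = [
    "AmplitudePoint",
    "OscillometricEnvelope",
    "EnvelopeFitConfig",
    "EnvelopeFitError",
    "ramp_protocol",
    "extract_amplitudes",
    "fit_envelope",
    "estimate_sbp_dbp",
]


@dataclass(frozen=True)
class AmplitudePoint:
    """Pulse amplitude of v_Pulse at one beat's mean contact pressure."""

    pressure: float   # mmHg
    amplitude: float  # dimensionless, peak-to-trough of v_Pulse

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


class EnvelopeFitError(RuntimeError):
    """Raised when the amplitude envelope cannot be fitted."""


@dataclass
class EnvelopeFitConfig:
    """Envelope fitting knobs.

    ``symmetric=False`` fits a two-sided Gaussian (shared peak and centre,
    separate widths below/above the centre), which tracks the skewed envelope
    produced by asymmetric arterial compliance; a single symmetric Gaussian is
    available for envelopes that are known to be symmetric.  Only points whose
    (smoothed) amplitude exceeds ``fit_fraction`` of the smoothed peak enter
    the fit, and points below ``coupling_floor`` are excluded because light
    coupling is unreliable there.

    The systolic/diastolic amplitude ratios are literature defaults and
    UNVALIDATED for this sensor geometry.
    """

    symmetric: bool = False
    fit_fraction: float = 0.85     # near-peak window for the centre fit
    wide_fraction: float = 0.25    # window for the side-width fit
    smooth_points: int = 9
    coupling_floor: float = 20.0   # mmHg
    r_sys: float = 0.55            # UNVALIDATED default
    r_dia: float = 0.85            # UNVALIDATED default


@dataclass
class OscillometricEnvelope:
    """Fitted Gaussian-style envelope and the derived pressures."""

    A: float
    mu: float
    sigma: float
    sigma_low: float
    sigma_high: float
    points: list[AmplitudePoint]
    fit_rmse: float
    mBP: float = field(init=False)
    P0: float = field(init=False)
    v0: float = float("nan")
    sBP: float | None = None
    dBP: float | None = None

    def __post_init__(self):
        if not (self.A > 0 and self.sigma > 0):
            raise ValueError("require A > 0 and sigma > 0")
        self.mBP = self.mu
        self.P0 = self.mu
        if self.sBP is not None and self.dBP is not None:
            if not (self.dBP < self.mBP < self.sBP):
                raise ValueError("require dBP < mBP < sBP")


def ramp_protocol(start: float = 0.0, stop: float = 200.0, rate: float = 2.0,
                  fs: float = 250.0, max_rate: float = 30.0) -> SampledSignal:
    """Monotone contact-pressure ramp command (default 0-200 mmHg at 2 mmHg/s)."""
    if not (0.0 <= start <= stop <= 300.0):
        raise ValueError("require 0 <= start <= stop <= 300 mmHg")
    if not (0.5 <= rate <= 10.0):
        raise ValueError("ramp rate must lie in [0.5, 10] mmHg/s")
    if rate > max_rate:
        raise ValueError("ramp rate exceeds the actuator slew limit")
    n = int(round((stop - start) / rate * fs))
    values = start + rate * np.arange(max(n, 1)) / fs
    if n == 0:
        values = np.array([start])
    return SampledSignal(np.minimum(values, stop), fs=fs, unit="mmHg",
                         label=f"ramp {start}->{stop} mmHg @ {rate} mmHg/s")


def extract_amplitudes(v_pulse: SampledSignal, p_c: SampledSignal,
                       beats: list[Beat]) -> list[AmplitudePoint]:
    """One amplitude point per beat: mean p_c over the beat vs max-min of v_Pulse."""
    points = []
    for b in beats:
        i0 = v_pulse.index_at(b.t_onset)
        i1 = v_pulse.index_at(b.t_end)
        if b.t_onset < v_pulse.t0 or b.t_end > v_pulse.t0 + v_pulse.duration or i1 <= i0:
            continue  # beat outside signal range: skip
        seg = v_pulse.values[i0:i1 + 1]
        pseg = p_c.values[p_c.index_at(b.t_onset):p_c.index_at(b.t_end) + 1]
        if pseg.size == 0:
            continue
        points.append(AmplitudePoint(pressure=float(pseg.mean()),
                                     amplitude=float(seg.max() - seg.min())))
    return points


def _gauss2(p, A, mu, sl, sr):
    s = np.where(p < mu, sl, sr)
    return A * np.exp(-(p - mu) ** 2 / (2.0 * s ** 2))


def _gauss1(p, A, mu, s):
    return A * np.exp(-(p - mu) ** 2 / (2.0 * s ** 2))


def fit_envelope(points: list[AmplitudePoint],
                 cfg: EnvelopeFitConfig | None = None,
                 v_baseline: np.ndarray | None = None) -> OscillometricEnvelope:
    """Least-squares Gaussian-style fit of the oscillometric envelope.

    ``v_baseline`` optionally carries the low-passed light value at each
    point's beat; the value at the beat nearest the fitted centre becomes v0.
    Raises :class:`EnvelopeFitError` when the envelope has no interior maximum
    ("not domed") or the fit diverges.
    """
    cfg = cfg or EnvelopeFitConfig()
    pts = [q for q in points if q.pressure >= cfg.coupling_floor]
    if len(pts) < 8:
        raise EnvelopeFitError("need at least 8 amplitude points above the coupling floor")
    order = np.argsort([q.pressure for q in pts])
    p = np.array([q.pressure for q in pts])[order]
    a = np.array([q.amplitude for q in pts])[order]
    if p[-1] - p[0] < 40.0:
        raise EnvelopeFitError("amplitude points must span at least 40 mmHg")

    # robust envelope shape: median amplitude on a pressure grid (kills
    # interleaved spurious detections), lightly smoothed, defines the peak
    # neighbourhood; the fits below always use the raw points
    bin_w = max((p[-1] - p[0]) / 60.0, 2.0)
    edges = np.arange(p[0], p[-1] + bin_w, bin_w)
    which = np.clip(np.digitize(p, edges) - 1, 0, edges.size - 2)
    centers, med = [], []
    for j in range(edges.size - 1):
        m = which == j
        if m.any():
            centers.append(0.5 * (edges[j] + edges[j + 1]))
            med.append(np.median(a[m]))
    centers = np.asarray(centers)
    med = np.asarray(med)
    if centers.size >= 5:
        norm = np.convolve(np.ones_like(med), np.ones(3), mode="same")
        med = np.convolve(med, np.ones(3), mode="same") / norm
    i_pk = int(np.argmax(med))
    if i_pk <= 0 or i_pk >= centers.size - 1:
        raise EnvelopeFitError("envelope not domed: no interior maximum")
    a_max, p_pk = float(med[i_pk]), float(centers[i_pk])
    a_of_p = lambda q: np.interp(q, centers, med)
    a_s = a_of_p(p)      # smoothed envelope value at each point's pressure

    try:
        if cfg.symmetric:
            sel = a_s >= cfg.wide_fraction * a_max
            popt, _ = curve_fit(_gauss1, p[sel], a[sel], p0=[a_max, p_pk, 10.0],
                                bounds=([0.0, p[0], 2.0], [np.inf, p[-1], 80.0]),
                                maxfev=20000)
            A, mu, sl = popt
            sr = sl
            resid = a[sel] - _gauss1(p[sel], *popt)
        else:
            # stage 1: the centre from a symmetric fit of the near-peak region
            # (the envelope is locally quadratic there, so this estimates the
            # peak location without being pulled by the skewed flanks)
            sel1 = (a_s >= cfg.fit_fraction * a_max) & (np.abs(p - p_pk) <= 25.0)
            if sel1.sum() < 4:
                sel1 = (a_s >= 0.75 * a_max) & (np.abs(p - p_pk) <= 30.0)
            popt1, _ = curve_fit(_gauss1, p[sel1], a[sel1],
                                 p0=[a_max, p_pk, 10.0],
                                 bounds=([0.0, p_pk - 12.0, 2.0],
                                         [np.inf, p_pk + 12.0, 40.0]),
                                 method="trf", loss="soft_l1",
                                 f_scale=max(0.05 * a_max, 1e-6),
                                 maxfev=20000)
            mu = float(popt1[1])
            # stage 2: side widths with the centre frozen
            sel = a_s >= cfg.wide_fraction * a_max
            model = lambda q, A, sl, sr: _gauss2(q, A, mu, sl, sr)
            popt2, _ = curve_fit(model, p[sel], a[sel],
                                 p0=[popt1[0], popt1[2], popt1[2]],
                                 bounds=([0.0, 2.0, 2.0], [np.inf, 80.0, 80.0]),
                                 method="trf", loss="soft_l1",
                                 f_scale=max(0.05 * a_max, 1e-6),
                                 maxfev=20000)
            A, sl, sr = popt2
            resid = a[sel] - model(p[sel], *popt2)
    except RuntimeError as exc:
        raise EnvelopeFitError(f"envelope fit diverged: {exc}") from exc
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    v0 = float("nan")
    if v_baseline is not None:
        vb = np.asarray(v_baseline, float)[order]
        v0 = float(vb[int(np.argmin(np.abs(p - mu)))])
    env = OscillometricEnvelope(
        A=float(A), mu=float(mu), sigma=float(0.5 * (sl + sr)),
        sigma_low=float(sl), sigma_high=float(sr),
        points=list(points), fit_rmse=rmse, v0=v0)
    return env


def estimate_sbp_dbp(env: OscillometricEnvelope, r_sys: float = 0.55,
                     r_dia: float = 0.85) -> tuple[float, float]:
    """Ratio-derived systolic/diastolic pressures from the fitted envelope.

    sBP is where the envelope falls to ``r_sys * A`` above the centre,
    dBP where it falls to ``r_dia * A`` below; closed form
    ``mu ± sigma * sqrt(-2 ln r)`` using the side-specific width.
    """
    if not (0.0 < r_sys <= 1.0 and 0.0 < r_dia <= 1.0):
        raise ValueError("amplitude ratios must lie in (0, 1]")
    sbp = env.mu + env.sigma_high * math.sqrt(-2.0 * math.log(r_sys))
    dbp = env.mu - env.sigma_low * math.sqrt(-2.0 * math.log(r_dia))
    return sbp, dbp
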