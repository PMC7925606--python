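"""Method-comparison statistics and engineering diagnostics.

Paired test/reference mean-pressure series are averaged over non-overlapping
10-s windows (decorrelating consecutive samples), compared with Bland-Altman
limits of agreement — with a repeated-measures variant that partitions within-
and between-subject variance — and with the concordance of pressure changes
over a 5-minute lag.  Engineering diagnostics cover per-beat actuator speed
statistics and the wearable power budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .signal_core import Beat, SampledSignal

__all__ = [
    "PairedSeries",
    "AgreementResult",
    "PowerBudget",
    "DEFAULT_POWER_COMPONENTS",
    "average_windows",
    "bland_altman",
    "concordance_5min",
    "actuator_speed_stats",
    "power_budget",
]


@dataclass
class PairedSeries:
    """Time-aligned (test, reference) mBP pairs for one subject."""

    subject: str
    t: np.ndarray          # s
    test: np.ndarray       # mmHg
    ref: np.ndarray        # mmHg
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.test = np.asarray(self.test, float)
        self.ref = np.asarray(self.ref, float)
        if not (self.t.size == self.test.size == self.ref.size):
            raise ValueError("t, test and ref must have equal length")
        if self.valid is None:
            self.valid = np.ones(self.t.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, bool)


@dataclass
class AgreementResult:
    """Bland-Altman agreement: bias ± SD and 95% limits of agreement."""

    bias: float
    sd: float
    loa_low: float = field(init=False)
    loa_high: float = field(init=False)
    n_pairs: int = 0
    per_subject_bias: dict = field(default_factory=dict)
    method: str = "simple"

    def __post_init__(self):
        self.loa_low = self.bias - 1.96 * self.sd
        self.loa_high = self.bias + 1.96 * self.sd


def average_windows(series: PairedSeries, window: float = 10.0) -> PairedSeries:
    """Non-overlapping window means; windows with <50% valid samples dropped."""
    if window <= 0:
        raise ValueError("window must be positive")
    if series.t.size < 2:
        return series
    dt = float(np.median(np.diff(series.t)))
    k = max(int(round(window / dt)), 1)
    n = series.t.size // k
    if n == 0:
        return PairedSeries(series.subject, np.empty(0), np.empty(0), np.empty(0))
    sh = (n, k)
    t = series.t[: n * k].reshape(sh).mean(axis=1)
    valid_frac = series.valid[: n * k].reshape(sh).mean(axis=1)
    keep = valid_frac >= 0.5

    def vmean(x):
        w = series.valid[: n * k].reshape(sh)
        xm = np.where(w, x[: n * k].reshape(sh), 0.0)
        cnt = np.maximum(w.sum(axis=1), 1)
        return xm.sum(axis=1) / cnt

    return PairedSeries(series.subject, t[keep], vmean(series.test)[keep],
                        vmean(series.ref)[keep])


def bland_altman(series, repeated: bool = True) -> AgreementResult:
    """Limits of agreement across one or more subjects.

    With ``repeated=True`` the SD of the differences is estimated by a one-way
    variance-component decomposition (multiple measurements per subject): the
    between-subject component is ``(MSB - MSW) / m_h`` from the ANOVA mean
    squares with ``m_h`` the effective per-subject count, the within component
    is MSW, and ``sd = sqrt(between + within)``.  With a single subject the
    method falls back to the simple estimator with a warning in the result's
    ``method`` field.
    """
    if isinstance(series, PairedSeries):
        series = [series]
    diffs = [s.test - s.ref for s in series if s.t.size > 0]
    if not diffs:
        raise ValueError("no pairs to compare")
    d_all = np.concatenate(diffs)
    n_pairs = d_all.size
    per_subject = {s.subject: float(np.mean(s.test - s.ref))
                   for s in series if s.t.size > 0}
    if not repeated or len(diffs) < 2:
        method = "simple" if not repeated else "simple (single subject fallback)"
        sd = float(np.std(d_all, ddof=1)) if n_pairs > 1 else 0.0
        return AgreementResult(bias=float(np.mean(d_all)), sd=sd,
                               n_pairs=n_pairs, per_subject_bias=per_subject,
                               method=method)
    # one-way ANOVA decomposition on the differences, subject as the factor
    k = len(diffs)
    n_i = np.array([d.size for d in diffs], float)
    m_i = np.array([d.mean() for d in diffs])
    grand = float(d_all.mean())
    ssb = float(np.sum(n_i * (m_i - grand) ** 2))
    ssw = float(sum(np.sum((d - d.mean()) ** 2) for d in diffs))
    msb = ssb / (k - 1)
    n_tot = n_i.sum()
    msw = ssw / (n_tot - k) if n_tot > k else 0.0
    m_h = (n_tot - np.sum(n_i ** 2) / n_tot) / (k - 1)
    var_between = max((msb - msw) / m_h, 0.0)
    sd = math.sqrt(var_between + msw)
    return AgreementResult(bias=grand, sd=sd, n_pairs=int(n_tot),
                           per_subject_bias=per_subject, method="repeated")


def concordance_5min(test, ref, dt: float = 10.0, lag: float = 300.0,
                     exclusion: float = 0.0) -> float:
    """Fraction of 5-min pressure changes with agreeing sign.

    Delta pairs are formed at ``lag`` seconds on the ``dt`` grid with a stride
    of one grid step (overlapping, mirroring how spontaneous changes are
    counted); ``exclusion`` removes small reference/test deltas before
    counting (default 0: none).
    """
    test = np.asarray(test, float)
    ref = np.asarray(ref, float)
    if test.size != ref.size:
        raise ValueError("series must be aligned")
    m = int(round(lag / dt))
    if test.size <= m:
        raise ValueError("series must cover at least the delta lag (>=10 min for 5-min deltas)")
    d_test = test[m:] - test[:-m]
    d_ref = ref[m:] - ref[:-m]
    keep = (np.abs(d_test) > exclusion) & (np.abs(d_ref) > exclusion)
    if exclusion == 0.0:
        keep = np.ones(d_test.size, bool)
    if not keep.any():
        return float("nan")
    agree = np.sign(d_test[keep]) == np.sign(d_ref[keep])
    return float(np.mean(agree))


def actuator_speed_stats(p_c: SampledSignal, beats: list[Beat]) -> dict:
    """Median/max of |change in beat-mean contact pressure| per beat and per s."""
    if len(beats) < 2:
        raise ValueError("need at least 2 beats")
    means, pis = [], []
    for b in beats:
        i0 = p_c.index_at(b.t_sys - b.PI)
        i1 = p_c.index_at(b.t_sys)
        means.append(float(np.mean(p_c.values[i0:i1 + 1])))
        pis.append(b.PI)
    d = np.abs(np.diff(means))
    per_s = d / np.asarray(pis[1:])
    return {
        "median_mmHg_per_beat": float(np.median(d)),
        "max_mmHg_per_beat": float(np.max(d)),
        "median_mmHg_per_s": float(np.median(per_s)),
        "max_mmHg_per_s": float(np.max(per_s)),
        "n_beats": len(beats),
    }


# wearable component budget (mW): actuator, PPG front end, BLE MCU, motion sensor
DEFAULT_POWER_COMPONENTS = {
    "actuator": 45.19,
    "ppg": 5.64,
    "mcu_bluetooth": 1.66,
    "motion_sensor": 6.21,
}


@dataclass
class PowerBudget:
    components: dict
    duty_cycle: str = ""
    total_mW: float = field(init=False)
    energy_24h_mWh: float = field(init=False)

    def __post_init__(self):
        self.total_mW = float(sum(self.components.values()))
        self.energy_24h_mWh = self.total_mW * 24.0


def power_budget(components: dict | None = None,
                 duty_cycle: str = "45 s initial + 2 min measure + 13 min interpolation"
                 ) -> PowerBudget:
    """Total average power and 24-h energy for the wearable component set."""
    components = DEFAULT_POWER_COMPONENTS if components is None else components
    if any(p < 0 for p in components.values()):
        raise ValueError("component powers must be non-negative")
    return PowerBudget(components=dict(components), duty_cycle=duty_cycle)
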