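import numpy as np
import pytest

import vctbp as v


@pytest.fixture(scope="session")
def fb():
    return v.FilterBankConfig()


@pytest.fixture(scope="session")
def fs(fb):
    return fb.fs


def make_pulse_train(freq_hz=1.0, duration=60.0, fs=250.0, amp=1.0,
                     dropout_at=None, dropout_scale=0.4):
    """Synthetic v_Pulse-like train: systole is a sharp *minimum* each cycle."""
    t = np.arange(int(duration * fs)) / fs
    phase = (t * freq_hz) % 1.0
    shape = -np.exp(-0.5 * ((phase - 0.3) / 0.06) ** 2)
    x = amp * (shape - shape.mean())
    if dropout_at is not None:
        cyc = np.floor(t * freq_hz).astype(int)
        x[cyc == dropout_at] *= dropout_scale
    return v.SampledSignal(x, fs=fs, label="pulse train")


@pytest.fixture
def pulse_train():
    return make_pulse_train


@pytest.fixture(scope="session")
def clamped_run():
    """Open-loop runner: fixed contact pressure against the simulated finger,
    filters seeded at the balanced light level for the balance pressure."""
    from vctbp.signal_core import init_filter_states
    from vctbp.simulator import pv_transfer

    def run(p_clamp, sbp=120.0, dbp=80.0, duration=30.0, hr=60.0,
            balance_at=None, tone=0.4):
        fbk = v.FilterBankConfig()
        bp = v.BPTrajectoryConfig(duration=duration, sbp=sbp, dbp=dbp,
                                  hr_bpm=hr)
        p_a, truth = v.generate_arterial_bp(bp)
        pv = v.PVModelConfig()
        mbp = bp.mbp
        p_ref = mbp if balance_at is None else balance_at
        v_ref = pv_transfer(p_a.values, p_ref, tone, pv)
        v0 = float(v_ref[int(5 * fbk.fs):].mean())
        v_sig = v.SampledSignal(
            pv_transfer(p_a.values, p_clamp, tone, pv), fs=fbk.fs)
        out = v.decompose(v_sig, fbk, states=init_filter_states(v0, fbk))
        return out, v_sig, truth, mbp

    return run
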