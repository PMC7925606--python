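"""Signal types, IIR cascade, frequency response and beat detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vctbp as v
from vctbp.signal_core import FilterStageConfig, init_filter_states


# ---------------------------------------------------------------------------
# SampledSignal
# ---------------------------------------------------------------------------

class TestSampledSignal:
    def test_validation(self):
        with pytest.raises(ValueError):
            v.SampledSignal(np.array([1.0, np.nan]))
        with pytest.raises(ValueError):
            v.SampledSignal(np.array([]))
        with pytest.raises(ValueError):
            v.SampledSignal(np.zeros(4), fs=-1.0)
        with pytest.raises(ValueError):
            v.SampledSignal(np.zeros(4), unit="volts")

    def test_time_axis(self):
        s = v.SampledSignal(np.zeros(5), fs=10.0, t0=1.0)
        assert np.allclose(s.times, 1.0 + np.arange(5) / 10.0)
        assert s.index_at(1.25) == 2  # nearest sample

    def test_csv_roundtrip(self, tmp_path):
        s = v.SampledSignal(np.sin(np.arange(100)), fs=50.0, t0=2.0,
                            unit="mmHg", label="demo")
        v.write_signal(s, tmp_path / "sig.csv")
        r = v.read_signal(tmp_path / "sig.csv")
        assert r.fs == 50.0 and r.t0 == 2.0 and r.unit == "mmHg"
        assert np.allclose(r.values, s.values, atol=1e-8)


# ---------------------------------------------------------------------------
# single IIR stage
# ---------------------------------------------------------------------------

class TestIirStage:
    def test_identity_when_uc_is_one(self):
        x = np.random.default_rng(0).normal(size=100)
        y = v.iir_stage(x, FilterStageConfig(UC=1.0))
        assert np.allclose(y, x)

    def test_constant_fixed_point(self):
        y = v.iir_stage(np.full(50, 3.7), FilterStageConfig(UC=0.2),
                        initial_state=3.7)
        assert np.allclose(y, 3.7)

    def test_step_response_matches_geometric_closed_form(self):
        # y_i = 1 - (1-UC)^(i+1) for a unit step from zero state
        y = v.iir_stage(np.ones(20), FilterStageConfig(UC=0.1))
        expect = 1.0 - 0.9 ** (np.arange(20) + 1)
        assert np.allclose(y, expect)
        assert y[9] == pytest.approx(0.6513, abs=1e-4)

    def test_decimation_holds_output_between_updates(self):
        x = np.arange(20.0)
        y = v.iir_stage(x, FilterStageConfig(UC=0.5, decimation=5))
        # piecewise constant over each 5-sample block
        assert np.allclose(y.reshape(4, 5), y.reshape(4, 5)[:, :1])

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            v.iir_stage(np.array([1.0, np.inf]), FilterStageConfig(UC=0.5))
        with pytest.raises(ValueError):
            v.iir_stage(np.array([]), FilterStageConfig(UC=0.5))
        with pytest.raises(ValueError):
            FilterStageConfig(UC=0.0)


# ---------------------------------------------------------------------------
# decomposition cascade
# ---------------------------------------------------------------------------

class TestDecompose:
    def test_dc_rejection(self, fb, fs):
        x = np.full(int(600 * fs), 2.5)
        out = v.decompose(v.SampledSignal(x, fs=fs), fb)
        tail = slice(int(500 * fs), None)
        for sig in (out.v_Pulse, out.v_Rhythm, out.v_dRhythm, out.v_VCT):
            assert np.max(np.abs(sig.values[tail])) < 1e-6

    @pytest.mark.parametrize("freq, pulse_lo, pulse_hi, rhythm_lo, rhythm_hi", [
        (1.2, 0.9, 1.1, 0.0, 0.1),    # cardiac band goes to v_Pulse
        (0.1, 0.0, 0.1, 0.7, 1.1),    # Mayer band goes to v_Rhythm
    ])
    def test_band_separation(self, fb, fs, freq, pulse_lo, pulse_hi,
                             rhythm_lo, rhythm_hi):
        t = np.arange(int(120 * fs)) / fs
        out = v.decompose(v.SampledSignal(np.sin(2 * np.pi * freq * t), fs=fs), fb)
        tail = slice(int(60 * fs), None)
        gp = np.ptp(out.v_Pulse.values[tail]) / 2
        gr = np.ptp(out.v_Rhythm.values[tail]) / 2
        assert pulse_lo <= gp <= pulse_hi
        assert rhythm_lo <= gr <= rhythm_hi

    def test_outputs_share_grid_with_input(self, fb, fs):
        x = np.random.default_rng(1).normal(size=int(10 * fs))
        out = v.decompose(v.SampledSignal(x, fs=fs), fb)
        for sig in (out.v_Pulse, out.v_Rhythm, out.v_dRhythm, out.v_VCT):
            assert len(sig) == x.size and sig.fs == fs

    def test_linearity_of_the_cascade(self, fb, fs):
        rng = np.random.default_rng(2)
        x = rng.normal(size=int(20 * fs))
        y = rng.normal(size=int(20 * fs))
        a, b = 2.0, -0.7
        oa = v.decompose(v.SampledSignal(x, fs=fs), fb,
                         states=np.zeros(13))
        ob = v.decompose(v.SampledSignal(y, fs=fs), fb,
                         states=np.zeros(13))
        oc = v.decompose(v.SampledSignal(a * x + b * y, fs=fs), fb,
                         states=np.zeros(13))
        for tap in ("v_Pulse", "v_Rhythm", "v_dRhythm", "v_VCT"):
            lhs = getattr(oc, tap).values
            rhs = a * getattr(oa, tap).values + b * getattr(ob, tap).values
            assert np.allclose(lhs, rhs, atol=1e-9)

    def test_bibo_bound_from_gains(self, fb, fs):
        # bounded input of amplitude 1 -> outputs bounded by the worst-case
        # gain over the band (<= 1.5 for the linear taps, derivative excepted)
        rng = np.random.default_rng(3)
        x = np.clip(rng.normal(scale=0.5, size=int(60 * fs)), -1, 1)
        out = v.decompose(v.SampledSignal(x, fs=fs), fb)
        for tap in ("v_Pulse", "v_Rhythm", "v_VCT"):
            assert np.max(np.abs(getattr(out, tap).values)) <= 2.0

    def test_rhythm_plus_pulse_reconstructs_detrended_amplitudes(self, fb, fs):
        # stationary input: the VLF-detrended signal splits into the rhythm
        # and pulse bands.  Agreement is asserted on per-band amplitudes
        # (each within 15%); sample-wise agreement is limited by the phase
        # response of the subtractive high-pass stages and is not asserted.
        t = np.arange(int(300 * fs)) / fs
        x = 0.5 + 0.1 * np.sin(2 * np.pi * 0.1 * t) + 0.2 * np.sin(2 * np.pi * 1.1 * t)
        out = v.decompose(v.SampledSignal(x, fs=fs), fb)
        tail = slice(int(200 * fs), None)
        recon = out.v_Rhythm.values[tail] + out.v_Pulse.values[tail]

        def amp_at(y, f0):
            n = y.size
            win = np.hanning(n)
            freqs = np.fft.rfftfreq(n, 1 / fs)
            amps = 2 * np.abs(np.fft.rfft(y * win)) / win.sum()
            return amps[np.argmin(np.abs(freqs - f0))]

        assert amp_at(recon, 0.1) == pytest.approx(0.1, rel=0.15)
        assert amp_at(recon, 1.1) == pytest.approx(0.2, rel=0.15)

    def test_empty_and_mismatched_inputs_rejected(self, fb, fs):
        with pytest.raises(ValueError):
            v.decompose(v.SampledSignal(np.zeros(4), fs=fs, unit="mmHg"), fb)
        with pytest.raises(ValueError):
            v.decompose(v.SampledSignal(np.zeros(4), fs=100.0), fb)


class TestInitFilterStates:
    def test_zero_seed(self, fb):
        assert np.allclose(init_filter_states(0.0, fb), 0.0)

    def test_constant_input_at_seed_gives_exact_zeros(self, fb, fs):
        states = init_filter_states(5.0, fb)
        out = v.decompose(v.SampledSignal(np.full(int(4 * fs), 5.0), fs=fs),
                          fb, states=states)
        assert np.allclose(out.v_Pulse.values, 0.0, atol=1e-12)
        assert np.allclose(out.v_VCT.values, 0.0, atol=1e-12)
        assert np.allclose(out.v_Rhythm.values, 0.0, atol=1e-12)

    def test_step_from_seed_decays_in_vct(self, fb, fs):
        states = init_filter_states(5.0, fb)
        out = v.decompose(v.SampledSignal(np.full(int(600 * fs), 6.0), fs=fs),
                          fb, states=states)
        y = out.v_VCT.values
        assert y[int(1 * fs)] > 0.5          # transient reflects the step
        assert abs(y[-1]) < 0.05             # and decays toward zero

    def test_non_finite_seed_rejected(self, fb):
        with pytest.raises(ValueError):
            init_filter_states(np.nan, fb)


class TestFrequencyResponse:
    def test_rhythm_vanishes_near_nyquist(self, fb):
        g = v.frequency_response(fb, [float(fb.fs / 2 - 1.0)])
        assert np.abs(g["v_Rhythm"][0]) < 0.01

    def test_vct_cutoff_is_a_minus3db_corner(self, fb):
        g = v.frequency_response(fb, [fb.cutoff_vlf])
        assert 0.3 <= np.abs(g["v_VCT"][0]) <= 0.7

    def test_no_unintended_amplification(self, fb):
        f = np.geomspace(0.002, fb.fs / 2 - 1, 300)
        g = v.frequency_response(fb, f)
        for tap in ("v_Pulse", "v_Rhythm", "v_VCT"):
            assert np.max(np.abs(g[tap])) <= 1.5

    def test_out_of_range_frequencies_rejected(self, fb):
        with pytest.raises(ValueError):
            v.frequency_response(fb, [0.0])
        with pytest.raises(ValueError):
            v.frequency_response(fb, [fb.fs])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.002, max_value=100.0))
    def test_gain_bound_property(self, f):
        fbk = v.FilterBankConfig()
        g = v.frequency_response(fbk, [f])
        for tap in ("v_Pulse", "v_Rhythm", "v_VCT"):
            assert np.abs(g[tap][0]) <= 1.5


# ---------------------------------------------------------------------------
# beat detection
# ---------------------------------------------------------------------------

class TestDetectBeats:
    def test_counts_one_hz_train(self, pulse_train):
        beats = v.detect_beats(pulse_train(freq_hz=1.0, duration=60.0))
        assert 59 <= len(beats) + 1 <= 61   # n-1 intervals for n systoles

    def test_pulse_interval_at_two_hz(self, pulse_train):
        beats = v.detect_beats(pulse_train(freq_hz=2.0, duration=60.0))
        pis = np.array([b.PI for b in beats])
        assert np.all(np.abs(pis - 0.5) <= 0.02)

    def test_dropout_beat_recovered_without_double_detection(self, pulse_train):
        sig = pulse_train(freq_hz=1.0, duration=60.0, dropout_at=30,
                          dropout_scale=0.4)
        beats = v.detect_beats(sig)
        pis = np.array([b.PI for b in beats])
        # the attenuated beat is either caught (PI stays ~1 s) or flagged as a
        # single long interval; never split into sub-refractory intervals
        assert np.all(pis > 0.5)
        assert np.sum(pis > 1.5) <= 1
        assert 57 <= len(beats) <= 60

    def test_flat_signal_yields_no_beats(self, fs):
        assert v.detect_beats(v.SampledSignal(np.zeros(int(10 * fs)), fs=fs)) == []

    def test_systole_is_the_minimum(self, pulse_train):
        sig = pulse_train(freq_hz=1.0, duration=20.0)
        for b in v.detect_beats(sig):
            assert b.v_sys < b.v_dia
            assert b.t_onset < b.t_sys < b.t_end

    @pytest.mark.parametrize("snr_db, min_f1", [(np.inf, 0.99), (10.0, 0.95)])
    def test_f1_against_known_systoles(self, pulse_train, fs, snr_db, min_f1):
        sig = pulse_train(freq_hz=1.0, duration=120.0)
        x = sig.values.copy()
        if np.isfinite(snr_db):
            p = np.mean(x ** 2)
            x = x + np.random.default_rng(7).normal(
                0.0, np.sqrt(p / 10 ** (snr_db / 10)), x.size)
        beats = v.detect_beats(v.SampledSignal(x, fs=fs))
        truth = np.arange(0.3, 120.0, 1.0)  # template minimum at phase 0.3
        det = np.array([b.t_sys for b in beats])
        tp = sum(np.min(np.abs(det - tt)) < 0.15 for tt in truth[1:-1])
        fp = len(det) - tp
        fn = len(truth) - 2 - tp
        f1 = 2 * tp / (2 * tp + fp + max(fn, 0))
        assert f1 >= min_f1

    def test_beat_invariants_enforced(self):
        with pytest.raises(ValueError):
            v.Beat(t_onset=1.0, t_sys=0.5, t_end=2.0, PI=1.0, v_sys=-1, v_dia=1)
        with pytest.raises(ValueError):
            v.Beat(t_onset=0.0, t_sys=0.1, t_end=0.2, PI=0.2, v_sys=-1, v_dia=1)
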