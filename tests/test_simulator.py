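"""Arterial waveform generator, pressure-volume transfer, actuator, noise
model and the closed-loop harness."""

import dataclasses

import numpy as np
import pytest

import vctbp as v
from vctbp.simulator import pv_transfer, tone_trajectory


class TestArterialGenerator:
    def test_constant_conditions_give_standard_mean_pressure(self):
        bp = v.BPTrajectoryConfig(duration=60.0, sbp=120, dbp=80, hr_bpm=60.0)
        p_a, truth = v.generate_arterial_bp(bp)
        assert np.allclose(truth["mbp"], 93.333, atol=0.01)
        # the waveform's own beat means agree with dBP + PP/3
        fs = bp.fs
        for onset in truth["t"][5:15]:
            i0 = int(onset * fs)
            beat = p_a.values[i0:i0 + int(fs)]
            assert beat.mean() == pytest.approx(93.333, abs=0.1)
        assert p_a.values.max() == pytest.approx(120.0, abs=0.2)
        assert p_a.values.min() == pytest.approx(80.0, abs=0.2)

    def test_respiratory_modulation_appears_at_its_frequency(self):
        bp = v.BPTrajectoryConfig(duration=240.0, resp_depth=4.0, resp_freq=0.25)
        _, truth = v.generate_arterial_bp(bp)
        t, m = truth["t"], truth["mbp"] - truth["mbp"].mean()
        grid = np.arange(0.0, 240.0, 0.5)
        mg = np.interp(grid, t, m)
        freqs = np.fft.rfftfreq(grid.size, 0.5)
        spec = np.abs(np.fft.rfft(mg * np.hanning(grid.size)))
        assert freqs[np.argmax(spec)] == pytest.approx(0.25, abs=0.02)

    def test_step_event_shifts_truth_by_its_magnitude(self):
        bp = v.BPTrajectoryConfig(duration=120.0,
                                  events=(v.BPEvent("step", 60.0, +20.0),))
        _, truth = v.generate_arterial_bp(bp)
        before = truth["mbp"][truth["t"] < 55].mean()
        after = truth["mbp"][truth["t"] > 65].mean()
        assert after - before == pytest.approx(20.0, abs=0.01)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            v.BPTrajectoryConfig(sbp=80, dbp=90)
        with pytest.raises(ValueError):
            v.BPTrajectoryConfig(resp_freq=0.6)

    def test_hr_profile_changes_beat_rate(self):
        bp = v.BPTrajectoryConfig(duration=120.0, hr_bpm=((0.0, 60.0), (60.0, 120.0)))
        _, truth = v.generate_arterial_bp(bp)
        pis = np.diff(truth["t"])
        assert np.median(pis[truth["t"][:-1] < 55]) == pytest.approx(1.0, abs=0.01)
        assert np.median(pis[truth["t"][:-1] > 65]) == pytest.approx(0.5, abs=0.01)


class TestPvTransfer:
    def test_occlusion_reaches_tone_independent_upper_asymptote(self):
        cfg = v.PVModelConfig()
        for tone in (0.0, 0.5, 1.0):
            assert pv_transfer(90.0, 90.0 + 5000.0, tone, cfg) \
                == pytest.approx(cfg.v_high, abs=1e-3)

    def test_inflection_at_equal_pressures(self):
        cfg = v.PVModelConfig()
        tone = 0.4
        mid = 0.5 * (cfg.v_low(tone) + cfg.v_high)
        assert pv_transfer(90.0, 90.0, tone, cfg) == pytest.approx(float(mid))

    def test_vasoconstriction_raises_light_at_fixed_offset(self):
        cfg = v.PVModelConfig()
        lo = pv_transfer(90.0, 60.0, 0.2, cfg)
        hi = pv_transfer(90.0, 60.0, 0.8, cfg)
        assert hi > lo

    def test_strictly_increasing_in_contact_pressure(self):
        cfg = v.PVModelConfig()
        p = np.linspace(0, 250, 500)
        vals = pv_transfer(90.0, p, 0.4, cfg)
        assert np.all(np.diff(vals) > 0)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            v.PVModelConfig(v_low0=0.9, v_low_slope=0.2)
        with pytest.raises(ValueError):
            v.PVModelConfig(w_collapse=0.0)


class TestVolumeBalance:
    """The core pulse-shape mechanism: fat below mBP, spiky above."""

    def _beat_segments(self, out, fs, n_skip=3, n_take=6):
        from vctbp import detect_beats
        beats = v.detect_beats(out.v_Pulse)[n_skip:n_skip + n_take]
        segs = []
        for b in beats:
            i0 = out.v_VCT.index_at(b.t_sys - b.PI)
            i1 = out.v_VCT.index_at(b.t_sys)
            segs.append(out.v_VCT.values[i0:i1 + 1])
        return segs, beats

    def test_balance_at_true_mean_pressure(self, clamped_run, fs):
        out, _, _, mbp = clamped_run(p_clamp=93.333)
        segs, beats = self._beat_segments(out, fs)
        amp = np.ptp(out.v_Pulse.values[int(3 * fs):int(10 * fs)])
        for seg, b in zip(segs, beats):
            vbar = np.trapezoid(seg, dx=1 / fs) / b.PI
            assert abs(vbar) <= 0.01 * amp

    @pytest.mark.parametrize("offset, sign, label", [
        (-15.0, -1, "fat"), (+15.0, +1, "spiky")])
    def test_sign_flips_across_the_balance_point(self, clamped_run, fs,
                                                 offset, sign, label):
        out, _, _, mbp = clamped_run(p_clamp=93.333 + offset)
        segs, beats = self._beat_segments(out, fs, n_skip=1, n_take=4)
        vbars = [np.trapezoid(s, dx=1 / fs) / b.PI for s, b in zip(segs, beats)]
        assert np.sign(np.mean(vbars)) == sign
        assert v.fat_spiky_check(np.concatenate(segs), fs=fs) == label

    def test_balanced_label_at_mean_pressure(self, clamped_run, fs):
        out, _, _, _ = clamped_run(p_clamp=93.333)
        segs, _ = self._beat_segments(out, fs)
        assert v.fat_spiky_check(np.concatenate(segs), fs=fs, tol_frac=0.02) \
            == "balanced"

    def test_tone_and_pressure_move_baseline_in_opposite_directions(self):
        # vasoconstriction raises v while a blood-pressure rise lowers it
        cfg = v.PVModelConfig()
        base = np.mean(pv_transfer(np.linspace(80, 120, 100), 93.3, 0.4, cfg))
        constricted = np.mean(pv_transfer(np.linspace(80, 120, 100), 93.3, 0.7, cfg))
        hypertensive = np.mean(pv_transfer(np.linspace(95, 135, 100), 93.3, 0.4, cfg))
        assert constricted > base
        assert hypertensive < base


class TestActuator:
    def test_step_reached_at_slew_rate(self):
        fs = 250.0
        cmd = v.SampledSignal(np.concatenate([np.full(int(fs), 90.0),
                                              np.full(int(2 * fs), 100.0)]),
                              fs=fs, unit="mmHg")
        out = v.actuate(cmd, v.ActuatorConfig(max_rate=30.0, delay=0.0))
        # the motor stops inside its resolution deadband of the target
        crossing = np.argmax(out.values >= 100.0 - 0.15) - int(fs)
        assert crossing / fs == pytest.approx(10.0 / 30.0, abs=0.02)
        assert out.values[-1] == pytest.approx(100.0, abs=0.15)

    def test_constant_command_holds_position(self):
        cmd = v.SampledSignal(np.full(500, 90.0), unit="mmHg")
        out = v.actuate(cmd)
        assert np.all(out.values == 90.0)

    def test_fast_sinusoid_is_slew_limited(self):
        fs = 250.0
        t = np.arange(int(10 * fs)) / fs
        cmd = v.SampledSignal(90 + 20 * np.sin(2 * np.pi * 1.0 * t), fs=fs,
                              unit="mmHg")
        out = v.actuate(cmd, v.ActuatorConfig(max_rate=30.0))
        rates = np.abs(np.diff(out.values)) * fs
        assert rates.max() <= 30.0 + 1e-9
        assert rates.max() == pytest.approx(30.0, rel=0.01)

    def test_deadband_ignores_sub_resolution_commands(self):
        fs = 250.0
        cmd = v.SampledSignal(90 + 0.05 * np.sin(np.arange(int(4 * fs))), fs=fs,
                              unit="mmHg", t0=0.0)
        out = v.actuate(cmd, v.ActuatorConfig(resolution=0.1), initial=90.0)
        assert np.all(out.values == 90.0)


class TestNoiseAndArtifacts:
    def test_infinite_snr_is_identity(self):
        sig = v.SampledSignal(np.sin(np.arange(1000) / 10.0))
        out, mask = v.add_noise_artifacts(sig, v.NoiseConfig(),
                                          np.random.default_rng(0))
        assert np.array_equal(out.values, sig.values)
        assert not mask.any()

    def test_snr_within_one_db_of_requested(self, fs):
        t = np.arange(int(120 * fs)) / fs
        sig = v.SampledSignal(np.sin(2 * np.pi * 1.0 * t))
        out, _ = v.add_noise_artifacts(sig, v.NoiseConfig(snr_db=20.0),
                                       np.random.default_rng(1))
        noise = out.values - sig.values
        snr = 10 * np.log10(np.mean(sig.values ** 2) / np.mean(noise ** 2))
        assert snr == pytest.approx(20.0, abs=1.0)

    def test_artifact_bursts_are_masked(self, fs):
        sig = v.SampledSignal(np.sin(np.arange(int(300 * fs)) / 40.0), fs=fs)
        cfg = v.NoiseConfig(artifact_rate=2.0, artifact_duration=0.8)
        out, mask = v.add_noise_artifacts(sig, cfg, np.random.default_rng(2))
        assert mask.any()
        assert np.abs(out.values[mask]).max() > 3 * np.abs(sig.values).max()


class TestClosedLoop:
    def test_seeded_determinism_is_bit_exact(self):
        scn = v.SimulationScenario(
            "det", v.BPTrajectoryConfig(duration=150.0, resp_depth=2.0),
            noise=v.NoiseConfig(snr_db=25.0), seed=5)
        a = v.run_closed_loop(scn, seed=5)
        b = v.run_closed_loop(scn, seed=5)
        assert np.array_equal(a.p_c.values, b.p_c.values)
        assert np.array_equal(a.v.values, b.v.values)
        assert np.array_equal(a.beat_records["Vbar"], b.beat_records["Vbar"])

    def test_constant_scenario_tracks_within_three_mmhg(self):
        scn = v.SimulationScenario(
            "const", v.BPTrajectoryConfig(duration=300.0, sbp=120, dbp=80,
                                          resp_depth=2.0),
            noise=v.NoiseConfig(snr_db=25.0), seed=1)
        res = v.run_closed_loop(scn, seed=1)
        t, tracked, true, valid = res.tracked_vs_true()
        m = valid & (t > 200.0)
        assert not res.failed
        assert np.abs(np.mean(tracked[m] - true[m])) <= 3.0

    def test_step_reconverges_within_thirty_seconds(self):
        scn = v.SimulationScenario(
            "step", v.BPTrajectoryConfig(duration=330.0, sbp=120, dbp=80,
                                         resp_depth=2.0,
                                         events=(v.BPEvent("step", 240.0, 20.0),)),
            noise=v.NoiseConfig(snr_db=25.0), seed=2)
        res = v.run_closed_loop(scn, seed=2)
        t, tracked, true, valid = res.tracked_vs_true()
        m = valid & (t >= 272.0) & (t <= 300.0)
        assert np.abs(np.mean(tracked[m] - true[m])) <= 3.0

    def test_pressure_step_never_drives_contact_pressure_down(self):
        scn = v.SimulationScenario(
            "step", v.BPTrajectoryConfig(duration=300.0, sbp=120, dbp=80,
                                         resp_depth=2.0,
                                         events=(v.BPEvent("step", 200.0, 10.0),)),
            noise=v.NoiseConfig(snr_db=25.0), seed=3)
        res = v.run_closed_loop(scn, seed=3)
        t, tracked, _, valid = res.tracked_vs_true()
        before = np.mean(tracked[valid & (t > 170) & (t < 198)])
        after = np.mean(tracked[valid & (t > 230) & (t < 290)])
        assert after - before > 0.0   # negative-feedback direction

    def test_artifact_burst_recovery(self):
        scn = v.SimulationScenario(
            "art", v.BPTrajectoryConfig(duration=300.0, sbp=120, dbp=80,
                                        resp_depth=2.0),
            noise=v.NoiseConfig(snr_db=25.0, artifact_rate=1.0), seed=4)
        res = v.run_closed_loop(scn, seed=4)
        q = res.quality
        # each burst invalidates at most ~5 s before the quality flag recovers
        runs, cur = [], 0
        for flag in (q == 1):
            cur = cur + 1 if flag else (runs.append(cur) if cur else None) or 0
        assert max(runs, default=0) <= 5 * res.p_c.fs
        assert (q == 0).mean() > 0.5

    def test_beat_records_respect_equation_form(self):
        # the recorded setpoints follow P_n = P_0 - c_BBI*sum - c_BBP*V_n with
        # the continuously accumulated memory between beats
        scn = v.SimulationScenario(
            "eq", v.BPTrajectoryConfig(duration=200.0, sbp=120, dbp=80),
            seed=6)
        g = v.ControllerGains()
        res = v.run_closed_loop(scn, gains=g, seed=6)
        rec = res.beat_records
        implied_sum = (res.envelope.P0 - rec["Pn"] - g.c_BBP * rec["Vbar"]) / g.c_BBI
        assert np.all(np.isfinite(implied_sum))
        # memory moves slowly: consecutive implied sums differ by less than
        # a plausible single-beat volume integral
        assert np.max(np.abs(np.diff(implied_sum))) < 0.5

    def test_mode_cycling_enters_interpolation_and_returns(self):
        scn = v.SimulationScenario(
            "modes", v.BPTrajectoryConfig(duration=500.0, sbp=120, dbp=80,
                                          resp_depth=2.0),
            noise=v.NoiseConfig(snr_db=25.0), seed=8)
        cfg = v.ModeConfig(measure_duration=90.0, interpolate_duration=120.0)
        res = v.run_closed_loop(scn, seed=8, enable_mode_cycling=True,
                                mode_cfg=cfg)
        log = " | ".join(m for _, m in res.event_log)
        assert "measure -> interpolate" in log
        assert "interpolate -> measure" in log
        assert (res.beat_records["interpolated"] > 0).any()
        # during interpolation the contact pressure rests at the coupling floor
        from vctbp.controller import COUPLING_FLOOR
        assert np.any(np.isclose(res.p_c.values, COUPLING_FLOOR, atol=1.0))


class TestStandardScenarios:
    def test_ten_seeded_scenarios(self):
        scns = v.standard_scenarios(seed=0)
        assert len(scns) == 10
        assert len({s.name for s in scns}) == 10
        assert all(s.bp.duration == 1800.0 for s in scns)
        again = v.standard_scenarios(seed=0)
        assert [s.seed for s in scns] == [s.seed for s in again]
        assert v.standard_scenarios(seed=1)[0].seed != scns[0].seed

    def test_scenarios_cover_the_clinical_pressure_range(self):
        mbps = [s.bp.mbp for s in v.standard_scenarios(seed=0)]
        assert min(mbps) < 60.0 and max(mbps) > 95.0


class TestToneTrajectory:
    def test_tone_ramp_reaches_target_with_lag(self):
        bp = v.BPTrajectoryConfig(duration=300.0, tone_base=0.3,
                                  events=(v.BPEvent("tone_ramp", 100.0, 0.7, 60.0),))
        tone = tone_trajectory(bp)
        fs = bp.fs
        assert tone[int(90 * fs)] == pytest.approx(0.3, abs=0.01)
        assert tone[-1] == pytest.approx(0.7, abs=0.01)
        assert np.all((tone >= 0.0) & (tone <= 1.0))
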