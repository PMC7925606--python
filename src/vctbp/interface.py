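"""Command-line interface, configuration and run reproducibility.

Every run writes its resolved configuration snapshot (including the seed) next
to its outputs, so re-executing from the snapshot reproduces the outputs
bit-identically; no run depends on ambient state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import click
import numpy as np
import yaml

from . import controller as ctl
from . import evaluation as ev
from . import oscillometry as osc
from . import simulator as sim
from .signal_core import FilterBankConfig, read_signal, write_signal

log = logging.getLogger("vctbp")


def _setup_logging(outdir: Path | None = None):
    handlers = [logging.StreamHandler(sys.stderr)]
    if outdir is not None:
        handlers.append(logging.FileHandler(outdir / "run.log"))
    logging.basicConfig(level=logging.INFO, handlers=handlers, force=True,
                        format="%(asctime)s %(levelname)s %(name)s: %(message)s")


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def snapshot_config(outdir: Path, **sections) -> str:
    """Persist the resolved run configuration; returns its hash."""
    payload = json.dumps(_to_jsonable(sections), sort_keys=True, default=str)
    digest = hashlib.sha256(payload.encode()).hexdigest()[:12]
    (outdir / "config_snapshot.json").write_text(payload, encoding="utf-8")
    return digest


def load_run_config(path) -> dict:
    """Load a YAML run configuration with filter_bank/controller/... sections."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = {}
    if "filter_bank" in raw:
        cfg["filter_bank"] = FilterBankConfig(**raw["filter_bank"])
    if "controller" in raw:
        cfg["controller"] = ctl.ControllerGains(**raw["controller"])
    if "actuator" in raw:
        cfg["actuator"] = sim.ActuatorConfig(**raw["actuator"])
    if "scenario" in raw:
        s = dict(raw["scenario"])
        events = tuple(sim.BPEvent(**e) for e in s.pop("events", []))
        noise = sim.NoiseConfig(**s.pop("noise", {}))
        bp = sim.BPTrajectoryConfig(events=events, **s.pop("bp", {}))
        cfg["scenario"] = sim.SimulationScenario(
            name=s.pop("name", "custom"), bp=bp, noise=noise,
            seed=int(s.pop("seed", 0)))
    cfg["seed"] = int(raw.get("seed", 0))
    return cfg


def _scenario_by_name(name: str, seed: int) -> sim.SimulationScenario:
    scns = sim.standard_scenarios(seed)
    for i, s in enumerate(scns):
        if s.name == name or name == f"standard-{i + 1:02d}":
            return s
    raise click.ClickException(
        f"unknown scenario {name!r}; choose one of "
        + ", ".join(f"standard-{i + 1:02d} ({s.name})" for i, s in enumerate(scns)))


def write_loop_csvs(res: sim.ClosedLoopResult, outdir: Path,
                    stride: int = 25) -> None:
    """Stream CSV (decimated for file size) and per-beat CSV."""
    mode = np.where(res.quality == 3, "initial", "measure")
    with open(outdir / "stream.csv", "w", encoding="utf-8") as fh:
        fh.write("time_s,p_c_mmHg,p_c2g_mmHg,mode,quality\n")
        t = res.p_c.times
        for i in range(0, len(res.p_c), stride):
            fh.write(f"{t[i]:.3f},{res.p_c.values[i]:.2f},"
                     f"{res.p_c2g.values[i]:.2f},{mode[i]},{int(res.quality[i])}\n")
    rec = res.beat_records
    with open(outdir / "beats.csv", "w", encoding="utf-8") as fh:
        fh.write("t_beat,PI_s,Pn_mmHg,Vbar,mBP_mmHg\n")
        for r in rec:
            fh.write(f"{r['t']:.3f},{r['PI']:.3f},{r['Pn']:.2f},"
                     f"{r['Vbar']:.6g},{r['pc_mean']:.2f}\n")


@click.group()
def cli():
    """Volume-control-technique blood-pressure toolbox."""


@cli.command()
def scenarios():
    """List the standard scenario suite."""
    for i, s in enumerate(sim.standard_scenarios(0)):
        click.echo(f"standard-{i + 1:02d}  {s.name:<12} "
                   f"{s.bp.sbp:.0f}/{s.bp.dbp:.0f} mmHg, HR "
                   f"{s.bp.hr_bpm if np.isscalar(s.bp.hr_bpm) else 'profile'} bpm, "
                   f"{s.bp.duration / 60:.0f} min")


@cli.command()
@click.option("--scenario", "name", default="standard-01")
@click.option("--seed", default=0, type=int)
@click.option("--duration", default=None, type=float, help="override duration (s)")
@click.option("--out", "outdir", default="sim_out", type=click.Path())
def simulate(name, seed, duration, outdir):
    """Generate a scenario's signals and ground truth (open loop, no control)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    scn = _scenario_by_name(name, seed)
    if duration:
        scn = dataclasses.replace(scn, bp=dataclasses.replace(scn.bp, duration=duration))
    digest = snapshot_config(outdir, scenario=scn, seed=seed)
    p_a, truth = sim.generate_arterial_bp(scn.bp)
    tone = sim.tone_trajectory(scn.bp)
    write_signal(p_a, outdir / "p_a.csv")
    with open(outdir / "truth.csv", "w", encoding="utf-8") as fh:
        fh.write("t_beat,sBP,dBP,mBP,tone\n")
        for r in truth:
            fh.write(f"{r['t']:.3f},{r['sbp']:.2f},{r['dbp']:.2f},{r['mbp']:.2f},"
                     f"{tone[min(int(r['t'] * scn.bp.fs), tone.size - 1)]:.3f}\n")
    log.info("scenario %s written to %s (config %s)", scn.name, outdir, digest)


@cli.command("run-loop")
@click.option("--scenario", "name", default="standard-01")
@click.option("--seed", default=0, type=int)
@click.option("--duration", default=None, type=float)
@click.option("--config", "config_path", default=None, type=click.Path(exists=True))
@click.option("--out", "outdir", default="loop_out", type=click.Path())
def run_loop(name, seed, duration, config_path, outdir):
    """Run oscillometric initialization + closed VCT loop on a scenario."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    cfg = load_run_config(config_path) if config_path else {}
    scn = cfg.get("scenario") or _scenario_by_name(name, seed)
    if duration:
        scn = dataclasses.replace(scn, bp=dataclasses.replace(scn.bp, duration=duration))
    gains = cfg.get("controller") or ctl.ControllerGains()
    digest = snapshot_config(outdir, scenario=scn, gains=gains, seed=seed)
    t0 = time.time()
    res = sim.run_closed_loop(scn, gains=gains, seed=seed)
    write_loop_csvs(res, outdir)
    t, tracked, true, valid = res.tracked_vs_true()
    err = tracked[valid] - true[valid]
    report = {
        "config_hash": digest, "seed": seed, "failed": res.failed,
        "P0_mmHg": res.envelope.P0,
        "bias_mmHg": float(np.mean(err)) if err.size else float("nan"),
        "sd_mmHg": float(np.std(err)) if err.size else float("nan"),
        "events": [[round(tt, 1), msg] for tt, msg in res.event_log],
        "runtime_s": round(time.time() - t0, 2),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2), encoding="utf-8")
    log.info("run-loop %s: bias %.2f mmHg sd %.2f mmHg", scn.name,
             report["bias_mmHg"], report["sd_mmHg"])
    if res.failed:
        raise click.ClickException("controller divergence: contact pressure pinned")


@cli.command()
@click.option("--ramp", default="0,200,2", help="start,stop,rate (mmHg, mmHg, mmHg/s)")
@click.option("--scenario", "name", default="standard-01")
@click.option("--seed", default=0, type=int)
@click.option("--out", "outpath", default="envelope.json", type=click.Path())
def oscillometry(ramp, name, seed, outpath):
    """Open-loop oscillometric ramp and envelope fit on a simulated finger."""
    start, stop, rate = (float(x) for x in ramp.split(","))
    scn = _scenario_by_name(name, seed)
    bp = dataclasses.replace(scn.bp, duration=(stop - start) / rate + 30.0)
    scn = dataclasses.replace(scn, bp=bp)
    rng = np.random.default_rng(seed)
    p_a, _ = sim.generate_arterial_bp(scn.bp)
    tone = sim.tone_trajectory(scn.bp)
    fb = FilterBankConfig(fs=scn.bp.fs)
    init = sim._open_loop_init(scn, p_a, tone, rng, fb, ramp_rate=rate)
    env = init["env"]
    payload = {
        "A": env.A, "mu": env.mu, "sigma": env.sigma,
        "sigma_low": env.sigma_low, "sigma_high": env.sigma_high,
        "mBP": env.mBP, "P0": env.P0, "v0": env.v0,
        "sBP": init["calib"].sBP_init, "dBP": init["calib"].dBP_init,
        "fit_rmse": env.fit_rmse,
        "points": [[q.pressure, q.amplitude] for q in env.points],
    }
    Path(outpath).write_text(json.dumps(payload, indent=2), encoding="utf-8")
    click.echo(f"mBP {env.mBP:.1f} mmHg (P0), sBP {payload['sBP']:.1f}, "
               f"dBP {payload['dBP']:.1f}, rmse {env.fit_rmse:.4g}")


@cli.command()
@click.option("--test", "test_path", required=True, type=click.Path(exists=True))
@click.option("--ref", "ref_path", required=True, type=click.Path(exists=True))
@click.option("--report", "report_path", default="report.json", type=click.Path())
def evaluate(test_path, ref_path, report_path):
    """Agreement statistics between a test and a reference mBP series."""
    test = read_signal(test_path)
    ref = read_signal(ref_path)
    n = min(len(test), len(ref))
    t = test.times[:n]
    pair = ev.PairedSeries("subject-1", t, test.values[:n], ref.values[:n])
    avg = ev.average_windows(pair)
    agg = ev.bland_altman([avg], repeated=False)
    out = {
        "bias_mmHg": agg.bias, "sd_mmHg": agg.sd,
        "loa_mmHg": [agg.loa_low, agg.loa_high], "n_pairs": agg.n_pairs,
    }
    try:
        out["concordance_5min"] = ev.concordance_5min(avg.test, avg.ref)
    except ValueError:
        out["concordance_5min"] = None
    Path(report_path).write_text(json.dumps(out, indent=2), encoding="utf-8")
    click.echo(json.dumps(out, indent=2))


@cli.command("power-budget")
@click.option("--config", "config_path", default=None, type=click.Path(exists=True))
def power_budget_cmd(config_path):
    """Wearable power budget (defaults: actuator + PPG + MCU + motion sensor)."""
    comps = None
    if config_path:
        with open(config_path, encoding="utf-8") as fh:
            comps = (yaml.safe_load(fh) or {}).get("components")
    pb = ev.power_budget(comps)
    for name, p in pb.components.items():
        click.echo(f"{name:<16}{p:8.2f} mW")
    click.echo(f"{'total':<16}{pb.total_mW:8.2f} mW")
    click.echo(f"{'24 h energy':<16}{pb.energy_24h_mWh:8.1f} mWh")


if __name__ == "__main__":
    cli()
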