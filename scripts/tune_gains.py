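#!/usr/bin/env python
"""One-off tuning of the controller constants against the scenario suite.

The control constants (c_BBI, c_BBP for the beat-based setpoint path; c_P,
c_D, c_I for the continuous rhythm PID) are device constants: this script
evaluates candidate sets on shortened versions of the standard scenarios and
prints per-scenario bias/sd plus the pooled repeated-measures agreement, from
which the defaults in ``vctbp.controller.ControllerGains`` were frozen.

    python scripts/tune_gains.py [--duration 600] [--seed 0]
"""

from __future__ import annotations

import argparse
import itertools

import vctbp as v
from vctbp import evaluation as ev

CANDIDATES = {
    "c_BBI": [20.0, 30.0, 60.0],
    "c_BBP": [10.0, 15.0],
    "c_P": [40.0, 60.0],
    "c_D": [6.0],
    "c_I": [0.0012, 0.0018],
}


def evaluate(gains: v.ControllerGains, duration: float, seed: int):
    pairs = []
    per = {}
    for scn in v.standard_scenarios(seed=seed, duration=duration):
        res = v.run_closed_loop(scn, gains=gains)
        t, tracked, true, valid = res.tracked_vs_true()
        ps = ev.average_windows(ev.PairedSeries(scn.name, t, tracked, true,
                                                valid=valid))
        pairs.append(ps)
        err = ps.test - ps.ref
        per[scn.name] = (float(err.mean()), float(err.std()), res.failed)
    agg = ev.bland_altman(pairs, repeated=True)
    return agg, per


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--duration", type=float, default=600.0)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    best = None
    keys = list(CANDIDATES)
    for combo in itertools.product(*CANDIDATES.values()):
        gains = v.ControllerGains(**dict(zip(keys, combo)))
        agg, per = evaluate(gains, args.duration, args.seed)
        worst = max(abs(b) + s for b, s, _ in per.values())
        failed = any(f for _, _, f in per.values())
        print(f"{dict(zip(keys, combo))}: bias={agg.bias:+.2f} sd={agg.sd:.2f} "
              f"worst|bias|+sd={worst:.2f} failed={failed}")
        score = (failed, abs(agg.bias) + agg.sd, worst)
        if best is None or score < best[0]:
            best = (score, combo)
    print("\nselected:", dict(zip(keys, best[1])))


if __name__ == "__main__":
    main()
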