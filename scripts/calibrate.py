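#!/usr/bin/env python
"""One-off calibration of the free response parameters.

Two model constants are not pinned by measurements: the topoisomerase
per-visit catalytic ceiling ``kcat_max`` (the saturating-linear k_cat(sigma)
stand-in) and the plectoneme coexistence torque ``tau0`` implied by the
torque-response free-energy coefficient ``g``.  This script sweeps both
over a coarse grid and prints, for each candidate, the features of the
single-gene cooperation experiment (rise and plateau of the empirical
elongation-initiation curve, adjacent-RNAP spacing and co-transcribing
load at the plateau onset), the open-DNA Fano factor, and the
looped-domain burst contrast — the behaviours the defaults were frozen
against (see docs/methods.md).  It is a documentation of procedure, not a
fitting loop: the shipped defaults (kcat_max = 600 /s, tau0 = 5.5 pN nm)
were selected once from this output.

Usage: python scripts/calibrate.py [--quick]
"""

from __future__ import annotations

import argparse
import sys

import numpy as np

import topocoil as tc
from topocoil import observables as obs
from topocoil.engine import RunControl, run_replicates
from topocoil.scenarios import looping_domain_scenario, single_gene_scenario


def mech_for_tau0(tau0: float) -> tc.MechanicsParams:
    base = tc.MechanicsParams()
    # g sets the coexistence torque: tau0 = sqrt(2 p g/(1 - p/cs))/omega0
    g = tau0**2 * base.omega0**2 * (1 - base.p / base.cs) / (2 * base.p)
    return tc.MechanicsParams(g=g)


def cooperation_features(kcat: float, tau0: float, reps: int, seed: int = 4000):
    mech = mech_for_tau0(tau0)
    rows = []
    for j, km in enumerate((0.005, 0.02, 0.05, 0.1, 0.2)):
        sc = single_gene_scenario(km, kcat_max=kcat, mechanics=mech)
        run = RunControl(t_end=sc.run.t_end, seed=seed + 100 * j, n_replicates=reps)
        trajs = run_replicates(sc.config, run, engine="fast")
        x = obs.empirical_initiation_rate(trajs, sc.window)
        y = obs.empirical_elongation_rate(trajs, sc.window)
        sp, ld = obs.adjacent_spacing_and_load(
            trajs, sc.window, segment_range=obs.report_window_segments(sc.config)
        )
        rows.append((km, x, y, sp, ld))
        print(
            f"  k_max={km:5g}: init={x:.4f}/s elong={y if y else float('nan'):5.1f} bp/s "
            f"spacing={sp if sp else float('nan'):6.0f} bp load={ld if ld else float('nan'):5.2f}",
            flush=True,
        )
    pts = [(x, y) for _, x, y, _, _ in rows if y is not None]
    fit = obs.piecewise_linear_fit(*zip(*pts)) if len(pts) >= 4 else None
    if fit:
        print(f"  hinge: slope={fit.slope:.0f} x*={fit.breakpoint:.4f} r2={fit.r_squared:.2f}")
    return rows, fit


def noise_features(kcat: float, tau0: float, reps: int, seed: int = 8000):
    mech = mech_for_tau0(tau0)
    out = {}
    for km, mode in ((0.1, "open"), (0.1, "dynamic")):
        sc = looping_domain_scenario(km, mode, kcat_max=kcat, mechanics=mech)
        run = RunControl(t_end=sc.run.t_end, seed=seed, n_replicates=reps)
        trajs = run_replicates(sc.config, run, engine="fast")
        fano, mean = obs.ensemble_fano(trajs)
        out[mode] = (mean, fano)
        print(f"  strong promoter {mode}: mean mRNA={mean:.1f} Fano={fano:.2f}", flush=True)
    return out


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--quick", action="store_true", help="fewer replicates")
    args = ap.parse_args()
    reps = 6 if args.quick else 20
    for kcat in (2.0, 100.0, 600.0):
        for tau0 in (7.0, 5.5):
            print(f"kcat_max={kcat:g} /s, coexistence torque tau0={tau0:g} pN nm:", flush=True)
            cooperation_features(kcat, tau0, reps)
            noise_features(kcat, tau0, reps)
    return 0


if __name__ == "__main__":
    sys.exit(main())
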