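#!/usr/bin/env python
"""Normalized individuality scores across scales and mutation rates.

For each rate, species are rank-aligned across the ensemble and groups of
K ranks are scored by their normalized self-prediction A*/K.  The optimal
scale per rate tracks where selection effectively operates: groups of
several species below the error transition, single species inside it.
The demo ensemble supports scales up to K = 4 at a configured 5:1
ensemble-to-dimension ratio; larger scales are reported as refusals
unless RUNS in step 01 is raised.
"""

import importlib

import pandas as pd

step01 = importlib.import_module("01_simulate_sweep")
from tanainfo.pipeline import run_pipeline

if __name__ == "__main__":
    cfg = step01.config
    cfg.stages = ["simulate", "individuality"]
    cfg.k_max = 6
    cfg.subset_limit = 20
    cfg.min_ratio = 5.0
    run_pipeline(cfg)
    tab = pd.read_csv(f"{cfg.outdir}/individuality.csv")
    ok = tab[tab.status == "ok"]
    print(ok.pivot(index="p_mut", columns="scale", values="score").round(4)
          .to_string())
    best = ok.groupby("p_mut").optimal_scale.first()
    print("\noptimal scale per rate:")
    print(best.to_string())
    n_refused = (tab.status != "ok").sum()
    if n_refused:
        print(f"\n({n_refused} scale/rate combinations refused: ensemble too "
              "small for the joint dimension; raise RUNS in step 01)")
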