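#!/usr/bin/env python
"""Species-environment information flow and integration across rates.

Transfer entropy between top-ranked species and their environment (the
rest of the ecosystem's population), in both directions, plus integrated
information (Phi_WMS and its redundancy-corrected revision Phi_R) at the
single-species level.  Expected phenomenology: information flows mostly
from environment to species, and Phi_R stays positive with a peak in the
error-transition region.
"""

import importlib

import pandas as pd

step01 = importlib.import_module("01_simulate_sweep")
from tanainfo.pipeline import run_pipeline

if __name__ == "__main__":
    cfg = step01.config
    cfg.stages = ["simulate", "infodyn"]
    run_pipeline(cfg)
    tab = pd.read_csv(f"{cfg.outdir}/infodyn.csv")
    ok = tab[(tab.status == "ok") & (tab.scale == 1)]
    if ok.empty:
        raise SystemExit("all scale-1 estimates were refused; raise RUNS in "
                         "step 01 so the ensemble supports joint dimension 4")
    piv = ok.pivot(index="p_mut", columns="measure", values="value").round(4)
    print(piv.to_string())
    if (piv["Phi_R"] > 0).all():
        print("\nPhi_R is positive at every rate: species and environment "
              "jointly co-evolve at all mutation rates tested.")
    peak = piv["Phi_R"].idxmax()
    print(f"Phi_R peaks at p_mut = {peak:g}")
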