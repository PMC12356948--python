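#!/usr/bin/env python
"""Simulate a desk-scale mutation-rate sweep of the Tangled Nature model.

Writes one columnar trajectory file per rate under results/analysis/ (the
later analysis steps and the pipeline manifest resume from these files).
The full study conditions are 10,000 runs of 1e5 generations per rate;
this driver uses a reduced ensemble so the whole analysis chain runs in
minutes.  Raise RUNS / GENERATIONS (or use `tanainfo pipeline`) to rerun
at larger scale.
"""

from tanainfo.pipeline import PipelineConfig, run_pipeline

RATES = [0.005, 0.01, 0.03, 0.04, 0.045, 0.06]
RUNS = 40
GENERATIONS = 800

config = PipelineConfig(
    grid=RATES,
    n_runs=RUNS,
    n_generations=GENERATIONS,
    master_seed=11,
    outdir="results/analysis",
    stages=["simulate"],
)

if __name__ == "__main__":
    manifest = run_pipeline(config)
    status = manifest["stages"]["simulate"]
    print(f"simulated {len(RATES)} rates x {RUNS} runs x {GENERATIONS} "
          f"generations: {status['status']}")
    print("per-rate seeds:", manifest["rate_seeds"])
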