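# tanainfo

At what level does natural selection effectively operate — the single
species, or self-perpetuating groups of species? `tanainfo` addresses that
question quantitatively for the **Tangled Nature (TaNa) model** of
co-evolving species, combining a fast compiled simulator with
information-theoretic analyses of *individuality*: a group of species is an
effective evolutionary unit to the extent that its joint population vector
predicts its own future.

It is written for researchers in evolutionary ecology and complex systems
who want a tested, reproducible pipeline for mutation-rate sweeps of the
model and for ensemble estimation of information measures on co-evolving
populations.

## Model and measures

Species are binary pangenomes (`L` bits, `2^L` possible species) coupled by
a random interaction web `J` (entries `U(-1,1)`, each permitted with
probability `Θ`). Species `i` has fitness

    H_i(t) = (k/N(t)) Σ_j J_ij n_j(t) − μ N(t),

reproduces with probability `1/(1+e^{−H_i})` (parent replaced by two
daughters, each genome bit mutating with probability `p_mut`), and dies at
rate `p_kill`. The dynamics self-organize into metastable epochs (q-ESS)
punctuated by reorganizations; beyond the error threshold
`p* = 1 − ((1+p_kill)/2)^{1/L} ≈ 0.05` no species population is stable.

On ensembles of runs, the package estimates (Gaussian estimators across
ensemble members at fixed generation, averaged over generations, in nats):

- **organismal individuality** `A* = I(S(t); S(t+1))` of a rank-aligned
  group `S` of `K` species, and the normalized score `A*/K`;
- **colonial** `A = I(S(t); S(t+1) | E(t))` and **environment-determined**
  `nC = I(E(t); S(t+1) | S(t))` individuality, with environment
  `E = N − Σ_{i∈S} n_i`;
- **transfer entropy** `TE(S→E) = I(S(t); E(t+1) | E(t))` in both
  directions;
- **integrated information** `Φ_WMS` and its redundancy-corrected revision
  `Φ_R = Φ_WMS + min_{i,j} I(X_i(t); X_j(t+1))`.

Population-level panels (Hill diversity, normalized entropy, q-ESS /
reorganization segmentation) locate the error threshold; the scale sweep of
`A*/K` identifies the optimal level of organization per mutation rate.
See `docs/methods.md` for definitions, calibrations, and limitations.

## Worked example

```bash
python analysis/01_simulate_sweep.py     # 6 rates x 40 runs x 800 generations
python analysis/02_population_sweep.py
```

prints (ensemble means per mutation rate):

```
statistic  hill_diversity  n_qess_segments  normalized_entropy  reorg_fraction  total_population
p_mut
0.005               5.631            3.050               0.494           0.001          1609.774
0.010               9.578            2.550               0.600           0.001          1401.041
0.030              36.174           17.200               0.853           0.062           623.146
0.040              48.551            9.675               0.963           0.773           295.662
0.045              47.067            2.175               0.980           0.962           252.128
0.060              39.496            0.000               0.990           1.000           229.195

diversity peaks at p_mut = 0.04 (D = 48.6)
rates with no metastable segments: [0.06]
```

Read: the total population falls monotonically with mutation rate and
collapses above 0.04; the effective number of established species (Hill
diversity) peaks at 0.04; beyond the threshold the population distribution
becomes near-uniform (entropy → 1) and no metastable epoch survives at
0.06. Step `03` sweeps the normalized individuality score across scales on
the same trajectories (at this demo scale the optimal scale is ≥ 2 — a
group of species, not a single one — at every rate below the threshold),
and step `04` prints the species–environment transfer-entropy / Φ profile
(`Phi_R` positive at every rate, peaking at 0.04 in the transition
region). `tanainfo --help` exposes the same stages as a CLI
(`simulate | popstats | individuality | infodyn | pipeline`).

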