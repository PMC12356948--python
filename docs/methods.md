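# Methods

## The Tangled Nature model

Species are binary pangenomes of length `L` (ids in `[0, 2^L)`; `L = 10`
gives 1024 possible species). The ecosystem state is the vector of
population counts `n_i(t)`; `N(t)` is the total population. A random
interaction web `J` (entries `Uniform(-1, 1)`, each directed off-diagonal
entry permitted independently with coupling probability `Θ`, diagonal zero)
fixes who influences whom. The fitness of species `i` is

    H_i(t) = (k / N(t)) · Σ_j J_ij n_j(t)  −  μ N(t)

— a population-weighted sum of influences from co-existing species, minus a
resource-constraint term in which `μ` acts as the inverse carrying capacity.
Reproduction probability is logistic in fitness, `p_off = 1/(1 + e^{−H})`.

Each elementary timestep: (1) with probability `p_kill` a uniformly chosen
individual dies; (2) a uniformly chosen individual reproduces with
probability `p_off(H)` of its species. A successful reproduction replaces
the parent with **two daughters**, each of whose genome bits flips
independently with probability `p_mut`. The two-daughter rule is what
places the error threshold where the model's phenomenology has it: a
wild-type count is stable only while

    p_off · (2 (1 − p_mut)^L − 1) ≥ p_kill ,

so even at `p_off → 1` no species can persist beyond
`p* = 1 − ((1 + p_kill)/2)^{1/L} ≈ 0.0498` at the standard parameters. A
single-offspring variant (offspring added next to the surviving parent)
moves the threshold to `p ≈ 0.15` and destroys the diversity peak at 0.04;
we verified both variants in pilot simulations and use the two-daughter
rule throughout.

The state is recorded once per *generation* = `round(N(t)/p_kill)`
timesteps (minimum 1), with `N(t)` taken at the generation's start — the
expected number of timesteps needed to kill every currently living
individual. Runs whose population hits zero stop early and are flagged;
ensemble statistics exclude them.

Standard parameters (all configurable): `L = 10`, `Θ = 0.25`,
`p_kill = 0.2`, `p_mut` swept, `k = 33`, `μ = 1/143`. Initial condition:
`n0 = 500` individuals spread uniformly over `n0_species = 10` distinct
random species. Each ensemble member draws its own interaction web and
initial condition by default (a config switch shares one web across the
ensemble); all per-run seeds derive from one master seed via
`SeedSequence` and are recorded, so every trajectory is bit-reproducible.

The neutral control replaces every permitted interaction weight with one
constant (default 0.1, chosen so the neutral ecosystem equilibrates at a
population comparable to a mildly mutualistic community); with identical
weights there is no interaction structure for selection to discover.

## Population statistics

* **Hill diversity**: `exp` of the Shannon index (natural log) of the
  population distribution — the effective number of species.
* **Normalized entropy**: Shannon entropy divided by `log` of the number of
  existing species; defined as 0 for a single species.
* **Established species**: sweep-level diversity/entropy are computed over
  species with at least 2 individuals. Single-copy mutants are transient by
  construction (above the threshold more than half of all births are
  one-off mutants); including them makes the snapshot diversity of the
  post-threshold mutant soup grow without bound in the churn rate and mask
  the collapse of the established community. With the `≥ 2` convention the
  sweep reproduces the known phenomenology — diversity peaking at
  `p_mut = 0.04`, entropy ≈ 1 beyond it — while both operations remain
  threshold-free for callers who pass their own distribution.
* **Burn-in**: the first 10 % of generations (capped at 1000) are excluded
  from all summaries.

### q-ESS detection

The model's metastable epochs (quasi-evolutionary stable strategies) are
detected with a core-set stability rule: counts are smoothed with a
centered 11-generation moving average; a species is in the generation's
*core* if its smoothed count is ≥ `max(5, 0.02 · N(t))`; consecutive
generations chain while the Jaccard similarity of their cores is ≥ 0.6;
chains of ≥ 10 generations are metastable (`qess`), everything else is
reorganization. Two empty cores count as dissimilar — a regime with no
identifiable stable core is reorganization by definition.

The smoothing and the thresholds were calibrated on pilot runs against the
model's known behaviour: with raw (unsmoothed) counts and a small
high-occupancy core, the binomial flicker of individual wild-types around
the cutoff shatters epochs that are visibly stable, labelling half of a
frozen low-rate run as reorganization. With the defaults above, runs at
`p_mut ≤ 0.01` are almost entirely metastable, the reorganization fraction
crosses ½ just above 0.03–0.04, and no metastable segment survives at
`p_mut ≥ 0.06` — while detection remains deterministic given the trajectory
and parameters. All four knobs (and the smoothing window) are exposed;
`reorg_fraction` is monotone in the similarity threshold by construction.

## Ensemble information estimation

The model is non-stationary, so no single time series yields a stationary
distribution. All information measures are therefore estimated *across
ensemble members at a fixed generation*: the cross-realization samples at
`t` (and `t+1`) feed a Gaussian estimator, and the per-generation values
are averaged over the post-burn-in window. Estimates are in nats.

Gaussian MI and conditional MI come from log-determinants of sample
covariance blocks, each block regularized with a relative ridge
`1e-9 · trace/dim` (count data can be locally degenerate). Estimates are
clamped at 0. Two refusal rules protect against silent nonsense:

* an estimate above `0.25·ln(1/ridge) ≈ 5.2` nats per effective dimension
  can only come from a numerically degenerate (near-duplicated) block and
  raises an error instead of returning a number;
* an ensemble smaller than 10× the joint dimension (configurable ratio) is
  refused. Analyses that deliberately run closer to the limit pass an
  explicit lower ratio and say so.

Population counts are treated as continuous variables under the Gaussian
model; no discretization. The lag is one generation everywhere. For subset
sweeps, one covariance of the full augmented variable vector is computed
per generation and every measure is evaluated on sub-blocks (identical
results to the per-subset path, verified in tests, at a fraction of the
cost); linear functionals such as the environment count are handled by a
linear map of the same covariance.

## Individuality across scales

Species identities are incomparable across runs (each run evolves its own
community under its own web), so groups are defined over **rank
positions**: within each run, species are ranked by time-averaged
population over the analysis window (ties broken by species id), and rank
`r` becomes a cross-ensemble random variable. Ranks are fixed per run for
the whole window rather than re-ranked per generation, which would inject
label-switching noise directly into the lag-1 measures. This alignment is
the package's declared interpretive choice.

Groups of `K` ranks are enumerated best-first by total rank mass, starting
with ranks `{1..K}`, truncated at a configurable subset limit (default
10,000 per scale; up to 1e5 supported). For the group vector `S(t)` and
its scalar environment `E(t) = N(t) − Σ_{i∈S} n_i(t)`:

* organismal individuality `A* = I(S(t); S(t+1))`
* colonial individuality `A = I(S(t); S(t+1) | E(t))`
* environment-determined individuality `nC = I(E(t); S(t+1) | S(t))`,
  identical to the transfer entropy `TE(E → S)`.

The **normalized score** `A*/K` (nats per species) compensates the
dimension-driven growth of multivariate MI; the optimal scale at a rate is
the argmax of the mean score over sampled groups, ties broken toward the
smaller scale. Because the raw Gaussian estimator carries a small positive
bias that grows with dimension (≈ `K²/2n` nats at ensemble size `n`), a
caller can pass a tie tolerance so that an all-noise ensemble resolves to
scale 1 rather than to the most biased scale; the default comparison is
strict.

## Transfer entropy and integrated information

`TE(S → E) = I(S(t); E(t+1) | E(t))` under the one-step Markov condition;
multivariate sources are supported. For a two-part system `X = (n_i, E)`:

    Φ_WMS = I(X(t); X(t+1)) − Σ_i I(X_i(t); X_i(t+1))
    Φ_R   = Φ_WMS + min_{i,j} I(X_i(t); X_j(t+1))

`Φ_WMS` can be negative for strongly correlated parts; the correction term
runs over all ordered pairs including `i = j` (the printed form is
unrestricted; a cross-pairs-only switch exists). Since the correction is a
clamped MI, `Φ_R ≥ Φ_WMS` holds exactly. The species–environment profile
reports TE both ways at scales 1 and 6 and Φ at scale 1 only, averaged
over the six top-ranked species (configurable).

## Synthetic fixtures with exact ground truth

Estimator validation uses stationary VAR(1) ensembles
`X(t+1) = A X(t) + ε`, `ε ~ N(0, Q)`: the stationary covariance solves the
discrete Lyapunov equation `S = A S Aᵀ + Q`, and the joint covariance of
`(X(t), X(t+1))` is `[[S, SAᵀ], [AS, S]]`, from which every measure above
has a closed form. The oracle (`analytic_info`) evaluates those closed
forms with its own self-contained determinant code, independent of the
estimator path it validates. Realizations are initialized from the exact
stationary distribution, so every generation is a valid stationary sample.

The parameter-recovery fixture plants a cyclically rotating block of `K0`
ranks (`x_i(t+1) = c · x_{i+1 mod K0}(t) + noise`): each member alone is
unpredictable (zero lag-1 autocovariance for `K0 ≥ 2`) while the block
jointly carries `−K0/2 · ln(1 − c²)` nats about its own future, so the
normalized score has a strict maximum exactly at scale `K0`. Remaining
ranks are temporally independent noise; affine shifts emulate positive,
rank-ordered magnitudes. Fixtures are continuous Gaussian processes by
design — ground truth must be exact under the estimation model — so they
probe the estimators, not the count nature or the non-stationary q-ESS
structure of the simulator (that is what the simulator tests are for).

## Problem sizes and what the desk-scale results show

The study conditions are ensembles of 10,000 runs × 1e5 generations per
mutation rate; that is far beyond a single-CPU session. The package's own
reduced conditions are:

* acceptance sweep (`scripts/acceptance.py`): 20 runs × 2000 generations
  per rate on the grid {0.005, 0.01, 0.02, 0.03, 0.04, 0.042, 0.045,
  0.05}, plus 10 runs at {0.001, 0.06, 0.08} (≈ 10 minutes total);
* test-suite phenomenology: 40 runs × 800 generations per rate;
  individuality crossover: 124 runs × 800 generations at
  {0.02, 0.04, 0.045}.

Two caveats follow from the reduced scale. First, q-ESS epochs lengthen as
the system ages; young (≤ a few thousand generations) ecosystems at
`p_mut = 0.03–0.045` spend visibly more time reorganizing than aged ones,
so reorganization fractions in that band read high relative to the
full-scale study and the reorganization-½ crossing lands at the lower edge
of the transition region. Second, at ensemble sizes of order 100 the
Gaussian MI bias at scale 6 (≈ 0.14 nats, ≈ 0.023 nats/species) is not
negligible against the score differences between scales; the crossover
direction (group scale dominant at low rates, single species dominant in
the transition region) is reproduced, but the exact optimal scale near
`p_mut = 0.04` is not stable at this ensemble size — young systems there
are already transition-like and score scale 1 highest.

## Known limitations

* The q-ESS detector is a calibrated stand-in; segmentation-derived
  numbers (reorganization fractions, metastability loss points) are
  detector-sensitive, and the defaults are tuned to the model's known
  phenomenology, not derived from first principles.
* Rank alignment is this package's mechanism for making species comparable
  across runs; other alignments (e.g. shared webs plus identity alignment)
  are supported via `share_interactions` but not the default.
* Gaussian estimators only (no kNN/kernel MI); adequate here because the
  estimand is defined under the Gaussian model, but absolute values on
  strongly non-Gaussian count data inherit model error.
* No spatial structure, sexual reproduction, or changepoint/HMM-based
  segmentation.
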