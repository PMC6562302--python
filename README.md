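# movescape

Movement-behavior and space-use analysis for GPS telemetry of
territory-holding carnivores along an urbanization gradient.

Urban coyotes (and other synanthropic-to-misanthropic carnivores) reveal how
they perceive a landscape through two complementary signatures: *how* they
move (behavioral states expressed in step lengths and turning angles) and
*where* they concentrate their activity (home-range size and fragmentation).
`movescape` implements the full analysis chain for both, plus a synthetic
track generator with known ground truth so that every stage can be verified
by parameter recovery and brute-force oracles.

## What it computes

**Hidden Markov movement models.** A burst of GPS fixes at 15-min intervals
yields a bivariate series of step lengths `L_t ≥ 0` and turning angles
`φ_t ∈ (−π, π]`. Conditional on a K-state Markov chain `S_t` with transition
matrix Γ (initial law fixed to the stationary distribution δ of Γ):

- `L_t | S_t = k` is zero with probability `z_k` (zero inflation), otherwise
  gamma with mean `μ_k` and SD `σ_k` (shape `μ_k²/σ_k²`, scale `σ_k²/μ_k`);
- `φ_t | S_t = k` is von Mises with mean direction `m_k` and concentration
  `κ_k`; angles undefined at the series start or next to zero-length steps
  are marginalized out.

Models with K = 1–4 states are fitted by multi-start quasi-Newton
maximization of the exact (scaled-forward) likelihood, decoded by Viterbi
and forward–backward, and assessed by three criteria: biological
plausibility of the state parameters, a predictive-power index (mean
max-posterior probability; strong if ≥ 0.90), and AIC. Two-state models
separate *encamped* from *moving*; three-state models split moving into
*foraging* (intermediate steps, sharp turns) and *traveling* (long steps,
directed).

**Home ranges.** Percent minimum convex polygons (MCP) measure overall
space use; adaptive local convex hulls (a-LoCoH, sphere of influence `a` =
maximum pairwise distance) measure useable space at the 95% (home range) and
50% (core) isopleths. Their mismatch is the complexity index
`C = (MCP − LoCoH) / MCP ∈ [0, 1)`; noncontiguous-polygon counts and
imperviousness-based landscape classes (<20% natural fragment, 20–50%
suburban, >50% highly urbanized) complete the space-use picture.

**Pipeline.** Cleaning (>10 km/h review flags, >50 km/h spike removal),
7.25-h subsampling for home ranges, ≥24-h 15-min burst extraction for
behavior, per-landscape pooled model fitting, decoding, time budgets, the
foraging:traveling ratio, and seeded permutation tests between landscape
classes, all orchestrated by `run_pipeline` into reproducible report tables.

## Worked example

```python
import numpy as np
import movescape as ms

# 2-state model: encamped (7.6 m steps) vs moving (319 m steps), 58% of
# time encamped at stationarity
config = ms.SimulationConfig(
    n_states=2, step_means=[7.6, 319], step_sds=[7.2, 256],
    zero_mass=[0.01, 0.01], angle_means=[np.pi, 0.0], kappas=[0.5, 1.5],
    tmat=ms.transition_matrix_for_stationary([0.58, 0.42]),
    n_steps=5000, seed=1)
track = ms.simulate_hmm_track(config)
series = ms.steps_and_angles(track)

result = ms.MovementHMM([series], n_states=2).fit()
print(result.summary())
```

```
Movement HMM, K=2 states, 5000 steps in 1 burst(s)
log-likelihood -32598.222   AIC 65220.4   free params 12
predictive power 0.989 (strong)   plausible: True

state         mean (m)    SD (m)    zero  angle mean   kappa  stationary
encamped           7.7       7.2   0.009       -3.08    0.50       0.597
moving           318.0     259.0   0.012       -0.02    1.46       0.403

transition matrix (states ordered by mean step length):
  0.880  0.120
  0.178  0.822
```

The fit recovers the generating regime: per-state means within a few
percent, zero-mass near 0.01, and a stationary law near 0.58/0.42. Viterbi
decoding (`result.decode()`) then assigns each step a behavioral state, and
`ms.time_budget` turns pooled decoded states into activity budgets.

A full simulated three-landscape study runs with:

```sh
movescape run --seed 1 --out-dir demo_out
```

which writes `space_use.csv` (home-range size/complexity per landscape),
`movement.csv` (per-state step summaries and time budgets), polygons as
GeoJSON, and a JSON summary including model-selection verdicts.

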