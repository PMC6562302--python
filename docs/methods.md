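# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `movescape`. It is the package's own account of its
science; every number mentioned here is computed by the test suite or the
acceptance script, not asserted from memory.

## Movement model

Observations are per-step pairs (step length, turning angle) derived from
bursts of GPS fixes at a nominal 15-min interval. The generative model is a
K-state hidden Markov model:

- **States** follow a Markov chain with row-stochastic transition matrix Γ.
  The initial distribution δ is *tied* to the stationary distribution of Γ
  (δΓ = δ) rather than estimated — the standard choice for movement HMMs
  fitted to bursts that start at arbitrary times in an animal's routine. δ
  therefore contributes no free parameters.
- **Step lengths** are zero-inflated gamma: state k emits `L = 0` with
  probability `z_k`, otherwise a gamma variate parameterized by mean `μ_k`
  (m) and SD `σ_k` (m). Externally everything is mean/SD because field
  studies report "mean (SD)"; internally shape = `μ²/σ²`, scale = `σ²/μ`.
  Zero-mass parameters are included only when the data actually contain
  zero-length steps.
- **Turning angles** are von Mises with mean direction `m_k` and
  concentration `κ_k` (κ = 0 is the circular uniform). The density is
  evaluated as `exp(κ(cos(φ−m)−1)) / (2π·I0e(κ))` with the exponentially
  scaled Bessel function, stable for large κ.
- **Missing angles** — the first angle of a burst, and any angle adjacent to
  a zero-length step (the heading is undefined when the animal did not
  move) — contribute likelihood factor 1 (marginalized). Treating them as 0
  instead would manufacture spurious angular concentration.

Free-parameter count: `p = 4K + K·[zeros present] + K(K−1)`;
`AIC = −2 log L + 2p`.

### Fitting

The likelihood is maximized by L-BFGS-B on a working scale: log μ, log σ,
logit z, raw angle mean (wrapped to (−π, π] on unpacking), log κ, and
row-wise multinomial logits for Γ with the diagonal as reference. Loose box
bounds on the working scale prevent numerical overflow; the von Mises
concentration is capped at 700, far above anything biologically
interpretable. The forward recursion is scaled (not log-space) and jitted
with numba; one likelihood evaluation on 5,000 steps and 3 states takes
about a millisecond, which is what makes dense multi-start optimization
affordable.

Multi-start: the default grid is the Cartesian product of two
quantile-derived per-state step-mean vectors (evenly spaced interior
quantiles, and a wider 5%–95% spread; SD candidates equal the means), two
angle-mean candidates {0, π}, and two concentration candidates {0.5, 2},
with Γ started at 0.9 on the diagonal — 8 starts. Every start is optimized
to convergence (relative function tolerance 1e-10); failed starts are
recorded and skipped; the best final likelihood wins. On 5,000-step
simulations from well-separated regimes all 8 starts converge to the same
optimum to ~1e-5, which is the practical check that the global maximum was
found.

### Decoding and assessment

Viterbi runs in log space with ties broken toward the lower state index
(determinism); forward–backward posteriors are computed with the same
scaling constants as the forward pass. Three assessment criteria:

1. **Plausibility**: states ordered by mean step length are labeled
   encamped / (foraging / searching) / traveling. The screen fails if any
   consecutive ordered means differ by less than a separation ratio
   (default 2 — a declared surrogate for expert judgment, tunable), or if
   the traveling state is not the most directed (highest κ) of the moving
   states.
2. **Predictive power**: the mean over steps of the maximum posterior state
   probability; "strong" at ≥ 0.90. The boundary is inclusive and
   evaluated with a 1e-12 guard so that a mean that is exactly 0.90 up to
   floating-point accumulation passes.
3. **AIC** among models passing both screens.

## Preprocessing

- Segment speeds are straight-line distance over elapsed time. Fixes
  adjacent to segments over 10 km/h are *flagged* (advisory only); fixes
  producing speeds over 50 km/h are *removed* by an iterative spike test:
  a fix is deleted when both adjacent segments are impossibly fast
  (out-and-back spike), or — only if no such unambiguous tip exists — when
  one adjacent segment is impossibly fast and bridging over the fix brings
  the speed back under the threshold. Checking the unambiguous pattern
  first prevents the bridging rule from deleting the innocent neighbor of a
  spike. The filter is idempotent, and on simulated tracks with injected
  teleportation errors it restores the original fix set exactly.
- Subsampling to one fix per ~7.25 h uses a time grid anchored at the first
  fix, keeping the nearest fix within tolerance per slot. Tolerances
  (±2 min on the 15-min schedule, ±30 min on the 7.25-h schedule) are
  declared conventions for collar jitter.
- Bursts are maximal runs of fixes whose gaps stay within 15 min ± 2 min;
  runs shorter than 24 h are dropped. Burst durations are unbounded above.
- Turning angles wrap to (−π, π] with left turns positive.

## Home ranges

- **MCP**: the percent-MCP retains the `p`% of points nearest the
  arithmetic centroid (stable sort; ties keep the earlier fix) and takes
  their convex hull. Degenerate (zero-area) hulls are errors.
- **a-LoCoH**: the sphere of influence `a` defaults to the exact maximum
  pairwise distance. Each root point's local hull covers the root plus the
  maximal prefix of distance-sorted neighbors whose cumulative distance
  stays within `a`; zero-distance duplicates are always included. Local
  hulls are merged cumulatively in ascending *area* order (ties by enclosed
  count): the density-first construction, in which dense-core hulls enter
  before sparse peripheral ones. With `a` equal to the data diameter,
  peripheral roots produce few-point but *large* hulls; merging by enclosed
  count instead would admit exactly those first and inflate every isopleth
  beyond the matched MCP (measured on anchored test tracks: complexity
  −0.54 under count-first versus +0.20 under area-first ordering), which
  contradicts the complexity index's intended range. Each requested
  isopleth is the cumulative union whose enclosed-point fraction is nearest
  the target ("nearest to 95%" read literally).
- **Complexity**: `C = (MCP − LoCoH)/MCP` at matched isopleth levels,
  clamped below at 0 with a warning (LoCoH can exceed a *peeled* MCP
  through boundary effects). Component counting treats polygons touching at
  a single point as connected.
- **Deduplication**: home ranges overlapping by more than 90% of the
  *smaller* range (the declared reading of "share of space used") drop the
  member with less temporal coverage, greedily in descending overlap order;
  a pair with an already-dropped member is skipped.
- **Landscape classes** come from the mean imperviousness of raster cells
  whose centers fall inside the 95% LoCoH polygon; boundary means of
  exactly 20% or 50% classify as suburban.
- Home ranges are only computed for tracks monitored more than 90 days
  (`allow_short` overrides); shorter monitoring underestimates range size.

All geometry is planar meters (areas ×1e-6 to km²); the package never
handles geographic coordinate systems.

## Synthetic data

The generator is the exact inverse of the movement model, plus the
machinery needed to emulate field conditions:

- states from the Markov chain (stationary start unless forced), step
  lengths from the zero-inflated gamma, turning angles from the von Mises,
  integrated into headings from a uniform initial heading;
- mixed collar schedules (15-min windows embedded in a 7.25-h baseline)
  and Bernoulli fix dropout;
- teleportation spikes displacing interior fixes by a fixed distance in a
  random direction (what the >50 km/h rule must catch);
- territorial anchoring: each step's heading is, with probability `w`,
  redirected toward an anchor with von Mises scatter (concentration 2)
  around the bearing. The scatter matters: a deterministic beeline makes
  the overridden angles degenerate and lets a fitted state collapse onto
  them with unbounded concentration. Multiple anchors with periodic
  switching (a den plus satellite patches) produce the patchy, bounded
  space use that gives the complexity index something to measure; a single
  isotropic anchor yields convex use with complexity ≈ 0.
- gridded imperviousness rasters (uniform, west–east gradient, or seeded
  patches) at a default 30-m cell.

Ground truth (states, step lengths, angles) rides along on every simulated
track; identical seeds give bit-identical output.

**What the generator does not emulate**: street networks, impermeable
barriers, resource selection, autocorrelated GPS error, or fix-success
varying with habitat. Passing tests therefore demonstrate that the
estimators recover the *model's* structure under realistic sampling, not
that the model captures everything in real urban telemetry.

## Demo study and problem sizes

The packaged demo (`demo_config`) simulates two animals in each of three
landscape classes positioned along an imperviousness gradient (anchors at
mean imperviousness ≈ 10 / 35 / 60%): natural-fragment animals move by a
2-state regime (means 7.4/306 m, 57% encamped), suburban and highly
urbanized animals by 3-state regimes (7.6/130/528 m and 7.5/122/625 m),
attraction weight 0.3, 100 days of monitoring, three 36-h 15-min burst
windows per animal (~900 pooled steps per class), and two injected 15-km
spikes per track. These sizes are deliberate desk-scale reductions of a
field data set (which would have thousands of steps per class); they are
large enough that model selection behaves qualitatively as expected — the
3-state model beats the 2-state model by AIC exactly in the classes
generated from 3 states, and the 4-state model is never accepted — while a
full run stays under a few minutes. With ~900 steps per class the
4-state model occasionally passes the plausibility screen in one class and
is then excluded by AIC instead; both exclusion routes are logged.

Group comparisons use a seeded two-sided permutation test on the difference
of group means (exact enumeration below 20,000 assignments), reported as
such; the original analysis's test is not named in its source, so the
report labels the test it actually ran.

## Known limitations

- No standard errors for HMM parameters (point estimates and AIC only) and
  no covariates on transition probabilities.
- The plausibility screen codifies expert judgment as a mean-ratio and
  κ-ordering rule; borderline models near the ratio threshold are decided
  mechanically.
- a-LoCoH is O(n²) in fixes (distance matrix plus incremental unions) —
  fine for hundreds of subsampled fixes, not for raw 15-min tracks.
- With ~300–600 subsampled fixes the LoCoH isopleths are coarse: the
  achieved fraction moves in hull-sized jumps around the target.
- One documented inconsistency in the source material: the suburban mean
  home range is printed both as 2.31 km² (table) and 1.25 km² (text); the
  report convention here follows the table.

## Validation problem sizes

Parameter-recovery checks refit 5,000-step simulations of each reference
regime (per-state means recovered within 10%, decoded time budgets within
0.03). The model-selection study simulates 20 replicate 800-step data sets
from the 3-state regime and requires AIC to prefer 3 states over 2 in at
least 80% of replicates; 800 steps per replicate keeps the full study at a
few minutes while leaving AIC margins comfortably larger than the
18-unit parameter-count penalty difference. Oracle-equivalence checks run
50 random parameter draws against exhaustive path enumeration at T ≤ 8,
K ≤ 3 (tolerance 1e-8).
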