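# Methods

## Model

`axomem` simulates associative memory recall in a recurrent attractor
network whose neurons can be impaired by focal axonal swellings (FAS) —
localized axonal enlargements that follow traumatic brain injury and
accompany several neurodegenerative diseases, and that distort or abolish
the spike trains an axon carries.

### Network and patterns

Each of `N` neurons occupies one of `q` discrete activity levels
(`q = 2`: classical binary units; `q = 8`: "grayscale" units used for
image-like memories).  Levels are embedded affinely on the bipolar scale,
`v(l) = -1 + 2l/(q-1)`, and a level maps to a firing rate via
`r = (v + 1)/2 ∈ [0, 1]`.

A memory is a length-`N` level vector `ξ^μ`.  Overlap between two level
vectors is the fraction of positions with identical level
(`1 - normalized Hamming distance`); it is the recall-accuracy measure
everywhere in the package.  Two generators provide controlled ensembles:

* `generate_random_memories` — each pattern activates an exact
  `round(a·N)` subset (levels uniform on `[1, q-1]`), the rest at level 0.
  Closed forms used in tests: expected equal-level overlap
  `(1-a)² + a²/(q-1)`; expected shared-active fraction `a²`.  At the
  defaults (`q=2`, `a=0.5`) this is the balanced ensemble of the classical
  `M ≈ 0.14 N` storage capacity; its equal-level overlap is 0.5 and its
  shared-active fraction 0.25.  (A quoted "~20–25% overlap" for such
  ensembles can only refer to the shared-active statistic: 0.5 is the
  *minimum* possible expected equal-level overlap over binary patterns.)
* `generate_correlated_family` — all patterns copy a common random template
  on a *shared* mask of `round(c·N)` positions and are i.i.d. uniform
  elsewhere, so every pair has expected overlap `c + (1-c)/q`; `c` is
  solved from the requested target (0.65 by default, emulating a set of
  similar grayscale face images without any image data).

Cue corruption (`add_cue_noise`) reassigns an exact `round(noise·N)` subset
of positions to a uniformly random *different* level, so a "20% noise" cue
has overlap 0.80 with its memory by construction, not merely in
expectation.

### Training

Two rules are provided, both symmetric with zero diagonal:

* **Hebbian outer product** `w = V^T V/(N·c)` with `c = mean(v²)` over the
  training set.  The `1/c` gain places each stored pattern's local field on
  the pattern itself; for fully active binary patterns `c = 1` and the rule
  is the textbook `1/N` one, with the classical capacity `M ≈ 0.14 N`.
  Crosstalk grows with inter-pattern correlation, so this rule is reserved
  for (near-)uncorrelated ensembles.
* **Projection (pseudo-inverse)** `W = V^T Q^{-1} V / N`, `Q = V V^T / N`.
  Stored patterns are exact fixed points regardless of mutual correlation,
  which is indispensable for the correlated family (plain Hebbian crosstalk
  at 65% overlap destroys retrieval outright) and keeps the random-pattern
  task in its robust-recall regime at `M = 126`, `N = 900`.

### Recall dynamics

Asynchronous sweeps in a fresh random permutation order.  For neuron `i`:

1. local field `h_i = Σ_j w_ij ṽ_j` against the current (partially
   updated) *effective* outputs `ṽ`;
2. divisive gain `g = rms(v_train)/rms(h)`, recomputed once per sweep;
3. perturbation `ε ~ Normal(0, σ²)` per neuron update ("Brownian"
   fluctuations accumulating over the trajectory);
4. the neuron moves to the level whose bipolar value is nearest to
   `clamp(g·h_i + ε, -1, 1)`, ties toward the lower level.

The divisive gain is a rate-normalization step: the zero diagonal shrinks
fields by `(1 - M/N)` and a degraded cue shrinks them further by its
quality factor, uniformly.  For `q = 2` the update is sign(`h`) and the
gain is an exact no-op; for graded levels it is essential — without it the
uniform shrinkage mis-bins every interior level and stored grayscale
patterns are not even metastable.

Convergence: one unchanged sweep suffices at `σ = 0` (deterministic descent
cannot leave a fixed point); with noise, two consecutive unchanged sweeps
are required.  `max_sweeps` defaults to 100; non-convergence is a valid
outcome that feeds the recognition score.  With `σ = 0` and no injury the
dynamics are a descent of the usual energy `E = -½ Σ_{i≠j} w_ij v_i v_j`
at `q = 2` (asserted over random trajectories in the tests); for graded
levels nearest-level quantization is not exactly the local energy minimizer
and monotonicity is not guaranteed.

### Injury model

The injury level `p` is the fraction of neurons bearing a swelling; exactly
`round(p·N)` neurons are chosen without replacement (exact counts remove
one source of replicate variance).  Each injured neuron draws one regime
from a "pie-chart" distribution and keeps it for the whole trial.  A
regime transforms the *firing rate* a neuron transmits:

| regime | effect on transmitted rate |
|---|---|
| healthy / transmission | unchanged |
| filtering | `r` for `r ≤ θ_f`; `θ_f + κ(r - θ_f)` above (defaults `θ_f = 0.5`, `κ = 0.25`) |
| reflection | `0.5 r` (a reflected spike annihilates an oncoming one) |
| blockage | nothing transmitted |

The filtering map is a deterministic piecewise-linear soft cap standing in
for pile-up attenuation, whose true quantitative form is not pinned down by
the available calibrations; `θ_f`, `κ` are exposed in config, and a
stochastic variant (cap applied with probability `r`) is provided.

Transmitting regimes drive their postsynaptic targets with `ṽ = 2r̃ - 1`.
A **blocked** axon is different in kind: it transmits *nothing*, so its
effective drive is the neutral value 0 — not the bipolar embedding of rate
zero (−1), which would turn silence into a maximally inhibitory signal.
With this convention an all-blockage injury yields exactly zero fields, and
blockage-only injury coincides with the classical lesion model in which
neurons are deleted from the network (verified against an independently
simulated reduced network in the tests).  Blocked neurons are additionally
frozen: cut off from recurrent input, they cannot adapt to the collective
dynamics, so they hold whatever state the cue left them in.  Since all
regime maps are deterministic per level, the entire injury enters the
dynamics through a per-neuron `(N × q)` lookup table of effective outputs,
which keeps sweeps cheap.

Bundled pie-charts: the three filtering/blockage mixtures 60/40, 40/60,
20/80 used for the deterioration-rate experiments, plus named empty slots
for morphometry-derived distributions (adult-rat optic nerve at 12/24/48 h;
infant-mouse cortex at 30 min/5/16/24 h) to be filled from a calibration;
the loader enforces the empirical constraint that such experimental
distributions keep blockage below 50% of injured neurons.

### Recognition score

A trial cues a stored memory with `add_cue_noise`, relaxes the network, and
compares the final state to every memory.  The classification is
*significant* when the best overlap is ≥ `θ = 0.75` and leads the runner-up
by ≥ `δ = 0.10`; significant retrieval of the cued memory is **correct**,
of another memory **confused**, anything else **none**.  The raw score of a
trial set is the mean of: overlap-with-cued for correct trials, 0 for
none, minus the (wrong) best overlap for confused trials — so both error
types depress it and confusion is penalized hardest.  Scores are normalized
by the healthy (`p = 0`) raw score at the same cue-noise level and clamped
to `[0, 1]`; a cell whose healthy baseline is non-positive (e.g. binary
cues at 50% noise, which are pure chance) has no performance to normalize
against and is reported as NaN and excluded from fits.  This score is a
reconstruction — defined by the properties above, not by a published
formula — and `θ`, `δ` are exposed in config.

Sweeps evaluate a (cue-noise × injury) grid with a fresh injury assignment
per replicate; per-cell/per-replicate random streams derive from a master
seed via `SeedSequence([master, noise_idx, injury_idx, replicate])`, so
cells are independent, order-insensitive, and bit-reproducible.

### Deterioration law

The decline of `R` with injury level is summarized by `R(p) = A - B e^p`,
fit by OLS on the regressor `e^p` (linear in `(A, B)`, hence exact, with
standard OLS standard errors via statsmodels).  Pooled fits use every grid
cell; per-noise-level fits are also available.  `p` is a dimensionless
fraction, so `e^p ∈ [1, 1.65]` over the experimental range and `B` is
small even for substantial declines.

## Bundled protocols and their parameters

* **Correlated (face-style) task**: `N = 1080`, `q = 8`, `M = 3` at 65%
  overlap; projection training; noise amplitude σ *calibrated* by bisection
  so the healthy network recalls 90% of 20%-corrupted cues (σ ≈ 0.13 at
  these conditions; calibration and measurement use disjoint seed streams).
  At this operating point the remaining ~10% of trials fail by
  non-convergence and none by confusion.
* **Random-pattern task**: `N = 900`, `q = 2`, `M = 126` (the 0.14 N load),
  projection training, 20% cue noise (the study's reference corruption
  level), `σ = 0`.  The deterministic choice is deliberate: at `q = 2` the
  ±1 margins make any σ well below the level spacing inert in healthy
  retrieval, while in heavily lesioned marginal states it acts only as an
  ignition source for the breakdown transition described below; replicate
  variation comes from cue corruption and fresh injury assignments.  The
  deterioration experiment sweeps `p = 0 … 0.5` (step 0.05 by default) with
  3 replicates × 25 cued memories per point and pools the per-cell
  normalized scores into one fit per pie-chart.

Problem sizes were chosen so the full test suite and the acceptance run
complete on a single CPU in minutes; `scale < 1` smoke tiers shrink `N`
(and `M` proportionally for the random task, preserving the load).

## What the generators emulate — and what they do not

The correlated family reproduces the *statistical* signature of a set of
similar grayscale images (controlled pairwise overlap, graded levels) but
none of their spatial structure: real images have long-range pixel
correlations, so Hebbian/projection crosstalk is not homogeneous across
neurons as it is here.  The random ensemble is exactly the exchangeable
balanced-pattern model of the capacity literature.  Passing tests therefore
demonstrate the injury phenomenology on these idealized ensembles; absolute
recall rates on real image data would differ, though the regime ordering
(more blockage ⇒ faster deterioration) rests only on the lesion mechanics.

## Numerical choices and degenerate inputs

Nearest-level ties break toward the lower level index (deterministic,
reduces to sign with ties at −1 for `q = 2`).  The sweep kernel maintains
fields incrementally (`h ← h + w_i Δṽ_i`), making a sweep `O(N + cN)` for
`c` changed neurons after the initial `O(N²)` field build; it is jit-
compiled with numba when available, with the identical pure-Python body as
fallback.  Generators require an explicit seed; omitting it is an error.
Degenerate requests fail loudly: empty images, non-positive dimensions,
target overlaps below `1/q`, memory counts above twice the capacity limit
(a warning above the limit itself), linearly dependent patterns under
projection training, singular (single-`p`) fit designs.

## Known limitations

* At exactly `M = 0.14 N` the outer-product network is marginally above
  its asynchronous critical capacity (`α_c ≈ 0.138`): clean-cue recall at
  the 0.97-overlap criterion holds for ~85% of memories at `N = 900`, not
  more — a finite-size fact about the classical model, not a property of
  the injury machinery.
* Heavily blockage-dominated injury drives a collective breakdown: once the
  surviving-network load `M/(N(1 - p·b))` approaches the stability
  boundary (for the 20/80 mixture, around `p ≈ 0.4`), recall collapses and
  `R(p)` departs from the exponential law, inflating pooled `B` for that
  mixture well beyond its pre-breakdown value.  Below the transition the
  decline is dominated by the frozen blocked neurons holding their noisy
  cue levels, giving `B` almost proportional to the blockage share.
* Multi-state retrieval by nearest-level quantization is dynamically
  fragile at high load: at `q = 8`, `M = 126`, a lesion of a few percent
  stalls the error-correcting relaxation.  The graded-level machinery is
  therefore exercised at low load (few correlated memories), which is the
  image-recognition setting it models.
* Single swellings are represented only by their regime-level consequence
  (the rate transfer function); no spike-train or cable-equation dynamics
  are simulated, and pie-charts are inputs, not derived from morphometry.
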