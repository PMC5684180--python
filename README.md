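# axomem

Associative memory under axonal injury: a multi-state Hopfield network whose
neurons can be impaired by **focal axonal swellings** (FAS) — the localized
axonal enlargements that follow traumatic brain injury and accompany
Alzheimer's, Parkinson's, and multiple sclerosis.  The package is for
computational neuroscientists who want to ask, quantitatively: *how fast
does memory recall deteriorate as a growing fraction of neurons carries
swellings of a given severity mix?*

## Model

Memories `ξ^μ` are length-`N` vectors of discrete activity levels
(`q` shades of gray), stored as fixed points of a recurrent network with
symmetric, zero-diagonal couplings — either the Hebbian outer product
`w_ij ∝ Σ_μ v^μ_i v^μ_j` (classical capacity `M ≈ 0.14 N`) or the
projection rule `W = V^T (V V^T/N)^{-1} V / N` for correlated memory
families.  Recall runs asynchronous nearest-level updates of the noisy
local field.

An injury of level `p` puts a swelling on a fraction `p` of neurons; each
injured neuron's axon operates in one regime drawn from a pie-chart
distribution, acting on the firing rate `S` it transmits (`S̃ = F(S, β)`):
unimpaired transmission, filtering (soft cap on high rates), reflection
(`S̃ = 0.5 S`), or blockage (`S̃ = 0`; the neuron is silenced and frozen).
Recall trials on noisy cues are scored by a recognition score
`R ∈ [0, 1]` that rewards accurate retrieval, scores non-convergence as
zero, penalizes retrieving the *wrong* memory, and is normalized by the
healthy network's score.  Deterioration with injury follows
`R(p) = A − B·e^p`; the decay coefficient `B` — fit by ordinary least
squares on the regressor `e^p` — is the headline number, and it grows with
the blockage share of the pie-chart.

## Worked example

Store three correlated grayscale patterns (a stand-in for a face-
recognition memory set: N = 1080 neurons, 8 gray levels, ~65% pairwise
overlap), then recall one from a cue with 20% of positions corrupted:

```python
import numpy as np
import axomem as ax

memories = ax.generate_correlated_family(1080, 3, n_levels=8,
                                         target_overlap=0.65, seed=2)
W = ax.projection_train(memories)
rng = np.random.default_rng(0)
trial = ax.run_trial(W, memories, cue_index=0, noise_level=0.2,
                     noise_sigma=0.05, rng=rng)
print(f"outcome={trial.outcome}  "
      f"overlap_with_cued={trial.final_overlap_correct:.3f}")
```

```
outcome=correct  overlap_with_cued=0.997
```

The healthy network cleans a 20%-corrupted cue back to 99.7% agreement
with the stored pattern and the trial is classified as a correct
retrieval (best overlap above the 0.75 significance threshold, with a
clear margin over the other two memories).

The deterioration-rate table for the random-pattern task (900 neurons,
126 binary memories, injury `p` swept 0→0.5 per pie-chart) comes from the
command line:

```bash
$ axomem report --seed 1 --out-dir rates --replicates 3
FAS distribution        deterioration rate
f20b80                  R(p) = 1.38 - 0.34 e^p
f40b60                  R(p) = 1.16 - 0.15 e^p
f60b40                  R(p) = 1.06 - 0.06 e^p
```

Reading: with injured neurons split 60/40 between filtering and blockage
(`f60b40`), the recognition score declines gently (`B = 0.06` — about a 4%
loss of normalized performance at p = 0.5); shifting the mix toward
blockage (`f40b60`, `f20b80`) makes deterioration strictly faster, and at
80% blockage the network additionally crosses a stability boundary near
p ≈ 0.4 where recall breaks down collectively (see `docs/methods.md`).

Other entry points: `axomem generate` (memory sets), `axomem sweep`
(noise × injury grids from a YAML config, with tidy CSV records, run
manifest, and optional heatmap), `axomem fit` (fit `R(p)` to any sweep
output).  Every command takes `--seed`, and identical seed + config
reproduces byte-identical outputs.

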