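"""Shipped experiment protocols: the two recall tasks and their presets.

Two benchmark tasks are bundled:

* **Correlated (face-style) task** — N = 1080 neurons, q = 8 gray levels,
  3 correlated memories at ~65% pairwise overlap standing in for a set of
  similar facial images.  Trained with the projection rule (plain Hebbian
  crosstalk destroys retrieval of correlated memories); recall runs with a
  Brownian-noise amplitude calibrated so the healthy network recalls ~90%
  of 20%-corrupted cues.
* **Random-pattern task** — N = 900 neurons, q = 2, 126 balanced random
  memories (the 0.14 N load of the classical capacity limit).  The shipped
  deterioration protocol trains with the projection rule so the healthy
  network recalls reliably, cues with 20% noise, and runs the recall
  dynamics deterministically: replicate-to-replicate variation comes from
  cue corruption and fresh injury assignments.

``run_deterioration_experiment`` reproduces the deterioration-rate table:
for each filtering/blockage pie-chart it sweeps the injury level
p = 0 ... 0.5, normalizes recognition scores by the healthy baseline, and
fits R(p) = A - B e^p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .deterioration import DeteriorationFit, fit_rate
from .injury import TABLE1_PIECHARTS, FASDistribution
from .network import WeightMatrix, train
from .patterns import MemorySet, generate_correlated_family, generate_random_memories
from .recognition import RecognitionResult, SweepSpec, calibrate_noise_sigma, run_trial, sweep

__all__ = [
    "FACE_TASK",
    "RANDOM_TASK",
    "TaskPreset",
    "build_task",
    "run_face_recall_experiment",
    "run_deterioration_experiment",
]


@dataclass(frozen=True)
class TaskPreset:
    """A named memory-task configuration."""

    name: str
    n_neurons: int
    n_memories: int
    n_levels: int
    generator: str  # "correlated" | "random"
    overlap_or_activity: float  # target overlap (correlated) / active fraction
    training_rule: str
    noise_sigma: float | str  # fixed value, or "calibrated"
    cue_noise: float = 0.2
    noise_grid: tuple = (0.0, 0.3, 0.01)  # (start, stop, step)
    injury_grid: tuple = (0.0, 0.3, 0.01)
    replicates: int = 12
    n_cues: int | None = None


# study conditions for the two tasks
FACE_TASK = TaskPreset(
    name="face",
    n_neurons=1080,
    n_memories=3,
    n_levels=8,
    generator="correlated",
    overlap_or_activity=0.65,
    training_rule="projection",
    noise_sigma="calibrated",
    noise_grid=(0.0, 0.3, 0.01),
    injury_grid=(0.0, 0.3, 0.01),
    replicates=12,
    n_cues=None,
)

RANDOM_TASK = TaskPreset(
    name="random",
    n_neurons=900,
    n_memories=126,
    n_levels=2,
    generator="random",
    overlap_or_activity=0.5,
    training_rule="projection",
    noise_sigma=0.0,
    noise_grid=(0.0, 0.5, 0.02),
    injury_grid=(0.0, 0.5, 0.02),
    replicates=7,
    n_cues=25,
)


def build_task(preset: TaskPreset, seed: int, scale: float = 1.0) -> tuple[MemorySet, WeightMatrix]:
    """Generate the preset's memory set and train its weight matrix.

    ``scale`` < 1 shrinks N (and, for the random task, M proportionally so
    the load M/N is preserved) for quick smoke runs.
    """
    n = int(round(preset.n_neurons * scale))
    m = preset.n_memories
    if preset.generator == "random":
        if scale != 1.0:
            # floor keeps the load at or below the preset's M/N ratio
            m = max(2, int(preset.n_memories * scale))
        memories = generate_random_memories(
            n, m, preset.n_levels, preset.overlap_or_activity, seed=seed
        )
    else:
        memories = generate_correlated_family(
            n, m, preset.n_levels, preset.overlap_or_activity, seed=seed
        )
    return memories, train(memories, preset.training_rule)


def run_face_recall_experiment(
    seed: int,
    n_trials: int = 200,
    cue_noise: float = 0.2,
    calibration_trials: int = 150,
    scale: float = 1.0,
) -> dict:
    """Healthy-network recall benchmark on the correlated task.

    Calibrates the Brownian-noise amplitude to the 90%-recall operating
    point (on its own seed stream), then measures the fraction of fresh
    trials recalled correctly / unclassified / confused at ``cue_noise``
    corruption.  Returns a dict with the calibrated sigma and the outcome
    fractions.
    """
    root = np.random.SeedSequence([int(seed), 101])
    s_mem, s_cal, s_meas = (int(x) for x in root.generate_state(3) >> np.uint32(1))
    memories, W = build_task(FACE_TASK, seed=s_mem, scale=scale)
    sigma = calibrate_noise_sigma(
        W,
        memories,
        cue_noise=cue_noise,
        target_correct=0.9,
        n_trials=calibration_trials,
        iterations=9,
        seed=s_cal,
    )
    counts = {"correct": 0, "none": 0, "confused": 0}
    for k in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence([s_meas, k]))
        t = run_trial(
            W, memories, k % len(memories), cue_noise, noise_sigma=sigma, rng=rng
        )
        counts[t.outcome] += 1
    return dict(
        noise_sigma=float(sigma),
        n_trials=n_trials,
        fraction_correct=counts["correct"] / n_trials,
        fraction_none=counts["none"] / n_trials,
        fraction_confused=counts["confused"] / n_trials,
        n_neurons=memories.n_neurons,
        n_memories=len(memories),
    )


def run_deterioration_experiment(
    seed: int,
    distributions: dict[str, FASDistribution] | None = None,
    injury_step: float = 0.05,
    replicates: int = 3,
    n_cues: int = 25,
    cue_noise: float = 0.2,
    scale: float = 1.0,
) -> tuple[dict[str, DeteriorationFit], dict[str, RecognitionResult]]:
    """Deterioration-rate table for the random-pattern task.

    One network is generated and trained per call; each pie-chart gets its
    own injury sweep p = 0, ``injury_step``, ..., 0.5 at fixed ``cue_noise``
    with ``replicates`` fresh injury assignments per level, and a pooled
    OLS fit of R(p) = A - B e^p on the normalized per-cell scores.
    Returns (fits, sweep results) keyed by pie-chart label.
    """
    if distributions is None:
        distributions = TABLE1_PIECHARTS
    root = np.random.SeedSequence([int(seed), 202])
    s_mem, s_sweep = (int(x) for x in root.generate_state(2) >> np.uint32(1))
    memories, W = build_task(RANDOM_TASK, seed=s_mem, scale=scale)
    injury_levels = tuple(np.round(np.arange(0.0, 0.5 + injury_step / 2, injury_step), 10))
    fits: dict[str, DeteriorationFit] = {}
    results: dict[str, RecognitionResult] = {}
    for i, (label, dist) in enumerate(sorted(distributions.items())):
        spec = SweepSpec(
            noise_levels=(cue_noise,),
            injury_levels=injury_levels,
            distribution=dist,
            replicates=replicates,
            n_cues=min(n_cues, len(memories)),
            noise_sigma=RANDOM_TASK.noise_sigma,
            master_seed=s_sweep + i,
        )
        res = sweep(W, memories, spec)
        agg = res.aggregate()
        fits[label] = fit_rate(agg[["injury_level", "score"]].to_numpy())
        results[label] = res
    return fits, results
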