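"""Recall trials, outcome classification, recognition score, and sweeps.

A trial presents a noise-corrupted cue of one stored memory to the (possibly
injured) network and lets the dynamics run.  The final state is compared to
every stored memory by overlap (fraction of positions at identical level):
the classification is *significant* when the best overlap clears a threshold
``theta`` and beats the runner-up by a margin ``delta``.  Significant recall
of the cued memory is *correct*, of a different memory *confused*; anything
else counts as *none* (the non-convergence error).  The recognition score R
aggregates a set of trials, crediting correct recalls by their accuracy,
scoring non-convergence as zero and penalizing confusion, then normalizes by
the healthy-network score at the same cue-noise level so that R = 1 means
"as good as uninjured".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import injury as injury_mod
from .injury import FASDistribution, FilterSpec, InjuryAssignment, sample_assignment
from .network import NetworkState, WeightMatrix, run_to_convergence
from .patterns import MemorySet, add_cue_noise

__all__ = [
    "TrialOutcome",
    "classify",
    "run_trial",
    "recognition_score",
    "raw_score",
    "SweepSpec",
    "RecognitionResult",
    "sweep",
    "calibrate_noise_sigma",
]

OUTCOMES = ("correct", "none", "confused")


@dataclass(frozen=True)
class TrialOutcome:
    cued_memory: int
    best_match: int | None
    outcome: str  # "correct" | "none" | "confused"
    final_overlap_correct: float
    final_overlap_best: float
    converged: bool
    sweeps_used: int

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")
        if self.outcome == "correct" and self.best_match != self.cued_memory:
            raise ValueError("correct outcome requires best_match == cued_memory")
        if self.outcome == "confused" and (
            self.best_match is None or self.best_match == self.cued_memory
        ):
            raise ValueError("confused outcome requires a different best_match")


def _overlaps_with_memories(levels: np.ndarray, memories: MemorySet) -> np.ndarray:
    return np.mean(memories.to_array() == levels[None, :], axis=1)


def classify(
    final: NetworkState | np.ndarray,
    memories: MemorySet,
    cued_memory: int,
    theta: float = 0.75,
    delta: float = 0.10,
) -> tuple[int | None, str, float, float]:
    """Classify a final state against the stored memories.

    Returns ``(best_match_or_None, outcome, overlap_with_cued, best_overlap)``.
    Significance requires the best overlap >= ``theta`` and a lead of at
    least ``delta`` over the second best (with a single memory the margin
    condition is vacuous).
    """
    if len(memories) == 0:
        raise ValueError("empty memory set")
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")
    if delta < 0.0:
        raise ValueError("delta must be >= 0")
    levels = final.levels if isinstance(final, NetworkState) else np.asarray(final)
    ov = _overlaps_with_memories(levels, memories)
    best = int(np.argmax(ov))
    best_ov = float(ov[best])
    second = float(np.partition(ov, -2)[-2]) if len(memories) > 1 else -np.inf
    significant = best_ov >= theta and (best_ov - second) >= delta
    if significant:
        outcome = "correct" if best == cued_memory else "confused"
        return best, outcome, float(ov[cued_memory]), best_ov
    return None, "none", float(ov[cued_memory]), best_ov


def run_trial(
    W: WeightMatrix,
    memories: MemorySet,
    cue_index: int,
    noise_level: float,
    injury: InjuryAssignment | None = None,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    theta: float = 0.75,
    delta: float = 0.10,
    max_sweeps: int = 100,
    filter_spec: FilterSpec | None = None,
) -> TrialOutcome:
    """One recall trial: corrupt the cue, relax the network, classify."""
    if not 0 <= cue_index < len(memories):
        raise ValueError("cue_index out of range")
    if rng is None:
        raise ValueError("an rng is required (reproducibility)")
    cue = add_cue_noise(memories[cue_index], noise_level, seed=rng)
    final, converged, sweeps = run_to_convergence(
        W,
        NetworkState.from_pattern(cue),
        noise_sigma=noise_sigma,
        injury=injury,
        max_sweeps=max_sweeps,
        rng=rng,
        filter_spec=filter_spec,
    )
    best, outcome, ov_cued, ov_best = classify(final, memories, cue_index, theta, delta)
    return TrialOutcome(cue_index, best, outcome, ov_cued, ov_best, converged, sweeps)


def raw_score(outcomes: Sequence[TrialOutcome]) -> float:
    """Un-normalized recognition score over a set of trials.

    Correct recalls contribute their overlap with the cued memory, trials
    with no significant classification contribute 0, and confused trials
    contribute minus their (wrong) best overlap.
    """
    if len(outcomes) == 0:
        raise ValueError("need at least one trial outcome")
    s = 0.0
    for t in outcomes:
        if t.outcome == "correct":
            s += t.final_overlap_correct
        elif t.outcome == "confused":
            s -= t.final_overlap_best
    return s / len(outcomes)


def recognition_score(outcomes: Sequence[TrialOutcome], baseline: float | None = None) -> float:
    """Recognition score R in [0, 1].

    ``R = clamp(raw / baseline, 0, 1)`` where ``baseline`` is the healthy
    (injury-free) raw score at the same cue-noise level; without a baseline
    the raw score is clamped directly.
    """
    r = raw_score(outcomes)
    if baseline is not None:
        if baseline <= 0:
            raise ValueError("baseline must be positive")
        r = r / baseline
    return float(np.clip(r, 0.0, 1.0))


@dataclass(frozen=True)
class SweepSpec:
    """Configuration of a (cue-noise x injury-level) recognition sweep.

    ``n_cues=None`` cycles every memory once per replicate (the correlated
    face-style task); an integer draws that many cued memories per replicate
    without replacement (the random-pattern task, where cycling all 126
    memories per cell is the slow "full" option).  Per-cell, per-replicate
    random streams are derived from ``master_seed`` with a counter-based
    scheme, so cells are independent and order-insensitive.
    """

    noise_levels: tuple
    injury_levels: tuple
    distribution: FASDistribution
    replicates: int = 7
    n_cues: int | None = None
    noise_sigma: float = 0.1
    theta: float = 0.75
    delta: float = 0.10
    max_sweeps: int = 100
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    master_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "noise_levels", tuple(float(x) for x in self.noise_levels))
        object.__setattr__(self, "injury_levels", tuple(float(x) for x in self.injury_levels))
        if len(self.noise_levels) == 0 or len(self.injury_levels) == 0:
            raise ValueError("noise and injury grids must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @classmethod
    def from_dict(cls, cfg: dict) -> "SweepSpec":
        cfg = dict(cfg)
        dist = injury_mod.load_piechart(cfg.pop("distribution"))
        fs = cfg.pop("filter_spec", None)
        spec_fs = FilterSpec(**fs) if isinstance(fs, dict) else (fs or FilterSpec())
        grid = {}
        for key in ("noise_levels", "injury_levels"):
            val = cfg.pop(key)
            if isinstance(val, dict):  # {start, stop, step} inclusive grid
                val = np.arange(
                    val["start"], val["stop"] + 0.5 * val["step"], val["step"]
                ).round(10)
            grid[key] = tuple(val)
        return cls(distribution=dist, filter_spec=spec_fs, **grid, **cfg)


@dataclass(frozen=True)
class RecognitionResult:
    """Tidy per-trial records plus the aggregated (noise, injury) grid."""

    records: pd.DataFrame  # one row per trial
    spec: SweepSpec

    def aggregate(self) -> pd.DataFrame:
        """Per-cell outcome fractions, raw score, and baseline-normalized R.

        The baseline for each cue-noise level is the replicate-averaged raw
        score of the healthy (p = 0) cell at that noise level; if the sweep
        does not include p = 0 the raw score is clamped to [0, 1] unscaled.
        """
        df = self.records
        rows = []
        for (noise, p), cell in df.groupby(["noise_level", "injury_level"], sort=True):
            n = len(cell)
            frac = {f"fraction_{o}": float(np.mean(cell["outcome"] == o)) for o in OUTCOMES}
            contrib = np.where(
                cell["outcome"] == "correct",
                cell["final_overlap_correct"],
                np.where(cell["outcome"] == "confused", -cell["final_overlap_best"], 0.0),
            )
            raw = float(np.mean(contrib))
            rows.append(
                dict(
                    noise_level=noise,
                    injury_level=p,
                    n_trials=n,
                    raw_score=raw,
                    mean_accuracy=float(np.mean(cell["final_overlap_correct"])),
                    mean_sweeps=float(np.mean(cell["sweeps_used"])),
                    fraction_converged=float(np.mean(cell["converged"])),
                    **frac,
                )
            )
        agg = pd.DataFrame(rows)
        base = agg[agg["injury_level"] == 0.0].set_index("noise_level")["raw_score"]

        def _norm(row):
            b = base.get(row["noise_level"], None)
            if b is None:
                return float(np.clip(row["raw_score"], 0.0, 1.0))
            if b <= 0:
                # the healthy network itself fails at this cue-noise level
                # (e.g. binary cues at 50% noise are pure chance); there is
                # no performance left to normalize against
                return float("nan")
            return float(np.clip(row["raw_score"] / b, 0.0, 1.0))

        agg["score"] = agg.apply(_norm, axis=1)
        return agg


def _cell_rng(master_seed: int, noise_idx: int, injury_idx: int, replicate: int, lane: int = 0):
    ss = np.random.SeedSequence([int(master_seed), noise_idx, injury_idx, replicate, lane])
    return np.random.default_rng(ss)


def sweep(
    W: WeightMatrix,
    memories: MemorySet,
    spec: SweepSpec,
    checkpoint=None,
) -> RecognitionResult:
    """Run the full (cue-noise x injury-level) Monte-Carlo sweep.

    Every cell runs ``replicates`` independent replicates; each replicate
    draws a fresh injury assignment, then cues either every memory once or a
    random subsample of ``n_cues`` memories.  All randomness derives from
    ``master_seed`` via per-(cell, replicate) seed sequences, so cells are
    independent of execution order.

    ``checkpoint`` names an optional CSV: completed (cell, replicate)
    batches are appended there as they finish, and a rerun skips batches
    already on disk — an interrupted sweep resumes where it stopped and
    still yields the identical result.
    """
    from pathlib import Path

    done: set[tuple] = set()
    old_rows: list[pd.DataFrame] = []
    ckpt = Path(checkpoint) if checkpoint is not None else None
    if ckpt is not None and ckpt.exists():
        prior = pd.read_csv(ckpt)
        if len(prior):
            old_rows.append(prior)
            done = set(
                map(tuple, prior[["noise_idx", "injury_idx", "replicate"]].drop_duplicates().to_numpy())
            )
    rows = []
    n = memories.n_neurons
    for j, p in enumerate(spec.injury_levels):
        for i, noise in enumerate(spec.noise_levels):
            for rep in range(spec.replicates):
                if (i, j, rep) in done:
                    continue
                batch = []
                rng = _cell_rng(spec.master_seed, i, j, rep)
                assignment = (
                    None
                    if p == 0
                    else sample_assignment(n, p, spec.distribution, seed=rng)
                )
                if spec.n_cues is None:
                    cues = range(len(memories))
                else:
                    k = min(spec.n_cues, len(memories))
                    cues = rng.choice(len(memories), size=k, replace=False)
                for k, cue in enumerate(cues):
                    t = run_trial(
                        W,
                        memories,
                        int(cue),
                        noise,
                        injury=assignment,
                        noise_sigma=spec.noise_sigma,
                        rng=rng,
                        theta=spec.theta,
                        delta=spec.delta,
                        max_sweeps=spec.max_sweeps,
                        filter_spec=spec.filter_spec,
                    )
                    batch.append(
                        dict(
                            noise_idx=i,
                            injury_idx=j,
                            noise_level=noise,
                            injury_level=p,
                            replicate=rep,
                            trial=k,
                            cued_memory=t.cued_memory,
                            best_match=-1 if t.best_match is None else t.best_match,
                            outcome=t.outcome,
                            final_overlap_correct=t.final_overlap_correct,
                            final_overlap_best=t.final_overlap_best,
                            converged=t.converged,
                            sweeps_used=t.sweeps_used,
                        )
                    )
                if ckpt is not None:
                    pd.DataFrame(batch).to_csv(
                        ckpt, mode="a", header=not ckpt.exists(), index=False
                    )
                rows.extend(batch)
    records = pd.concat([*old_rows, pd.DataFrame(rows)], ignore_index=True)
    records = records.sort_values(
        ["injury_idx", "noise_idx", "replicate", "trial"], kind="stable"
    ).reset_index(drop=True)
    return RecognitionResult(records, spec)


def calibrate_noise_sigma(
    W: WeightMatrix,
    memories: MemorySet,
    cue_noise: float = 0.2,
    target_correct: float = 0.9,
    n_trials: int = 60,
    bracket: tuple[float, float] = (0.0, 1.0),
    iterations: int = 8,
    seed: int = 0,
    theta: float = 0.75,
    delta: float = 0.10,
    max_sweeps: int = 100,
) -> float:
    """Bisect the dynamical noise amplitude to a target healthy recall rate.

    The correct-recall fraction of the healthy network decreases (noisily
    but monotonically in expectation) with ``noise_sigma``; this finds the
    sigma at which recall from cues with ``cue_noise`` corruption succeeds
    in a fraction ``target_correct`` of trials.  Each candidate sigma is
    evaluated with common random numbers (same seed stream) to keep the
    bisection stable.  If even the upper bracket recalls above target, the
    upper bracket is returned.
    """

    def rate(sigma: float) -> float:
        correct = 0
        for k in range(n_trials):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), 7919, k])
            )
            t = run_trial(
                W, memories, k % len(memories), cue_noise,
                injury=None, noise_sigma=sigma, rng=rng,
                theta=theta, delta=delta, max_sweeps=max_sweeps,
            )
            correct += t.outcome == "correct"
        return correct / n_trials

    lo, hi = bracket
    if rate(hi) > target_correct:
        return hi
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if rate(mid) >= target_correct:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
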