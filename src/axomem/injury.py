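"""Focal axonal swelling (FAS) injury model.

A swelling distorts the spike train an axon transmits.  Depending on the
swelling's geometry the axon operates in one of four regimes: unimpaired
transmission, rate filtering (pile-up attenuation of high firing rates),
spike reflection (reflected spikes annihilate oncoming ones, halving the
rate), or full blockage (no signal passes; the neuron's effective rate is
zero and it stops adapting to the collective dynamics).  At injury level
``p`` each neuron independently bears a swelling with probability ``p``; the
regime of an injured neuron is drawn from a "pie-chart" distribution
calibrated from swelling-morphometry experiments.

The transfer function acts on firing rates in [0, 1].  Network state values
live on the bipolar scale [-1, 1]; they are mapped to rates via
``r = (v + 1) / 2``, transformed, and mapped back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "REGIME_NAMES",
    "HEALTHY",
    "TRANSMISSION",
    "FILTERING",
    "REFLECTION",
    "BLOCKAGE",
    "FilterSpec",
    "FASDistribution",
    "InjuryAssignment",
    "sample_assignment",
    "transfer",
    "apply_to_state",
    "effective_output_table",
    "TABLE1_PIECHARTS",
    "EXPERIMENTAL_SLOTS",
    "load_piechart",
]

# regime codes (beta indices)
HEALTHY = 0       # no swelling on the axon
TRANSMISSION = 1  # swelling present, spike train unaffected
FILTERING = 2     # firing rate attenuated, more strongly at high rates
REFLECTION = 3    # reflected spikes annihilate oncoming ones: rate halved
BLOCKAGE = 4      # no signal passes: effective rate zero, neuron frozen

REGIME_NAMES = {
    HEALTHY: "healthy",
    TRANSMISSION: "transmission",
    FILTERING: "filtering",
    REFLECTION: "reflection",
    BLOCKAGE: "blockage",
}


@dataclass(frozen=True)
class FilterSpec:
    """Piecewise-linear soft cap for the filtering regime.

    Rates below ``threshold`` pass unchanged; the excess above it is
    compressed by ``slope`` (< 1), modelling spike pile-up that hits high
    firing rates hardest.  With ``stochastic=True`` the cap is applied with
    probability equal to the rate (higher rates have a stronger *chance* of
    decreasing); the deterministic map is the default.
    """

    threshold: float = 0.5
    slope: float = 0.25
    stochastic: bool = False

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if not 0.0 <= self.slope <= 1.0:
            raise ValueError("slope must lie in [0, 1]")


@dataclass(frozen=True)
class FASDistribution:
    """Pie-chart of regime probabilities among injured neurons."""

    transmission: float = 0.0
    filtering: float = 0.0
    reflection: float = 0.0
    blockage: float = 0.0
    label: str = ""

    def __post_init__(self):
        probs = self.probs
        if np.any(probs < 0):
            raise ValueError("regime probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"regime probabilities must sum to 1, got {probs.sum()!r}")

    @property
    def probs(self) -> np.ndarray:
        """Probabilities over regimes (transmission, filtering, reflection, blockage)."""
        return np.array(
            [self.transmission, self.filtering, self.reflection, self.blockage],
            dtype=float,
        )

    def validate_experimental(self) -> "FASDistribution":
        """Enforce the empirical constraint that blockage stays a minority.

        Every pie-chart derived from swelling morphometry has fewer than 50%
        of injured neurons in the blockage regime; presets entered as
        experimental calibrations must respect that.
        """
        if self.blockage >= 0.5:
            raise ValueError(
                f"experimental pie-chart {self.label or '<unnamed>'!r} has "
                f"blockage={self.blockage} >= 0.5; morphometry-derived "
                "distributions keep blockage below 50%"
            )
        return self


# The three filtering/blockage mixtures used for the random-pattern
# deterioration-rate experiments (transmission = reflection = 0).
TABLE1_PIECHARTS = {
    "f60b40": FASDistribution(filtering=0.6, blockage=0.4, label="f60b40"),
    "f40b60": FASDistribution(filtering=0.4, blockage=0.6, label="f40b60"),
    "f20b80": FASDistribution(filtering=0.2, blockage=0.8, label="f20b80"),
}

# Named slots for morphometry-derived pie-charts (adult-rat optic nerve at
# 12/24/48 h; infant-mouse cortex at 30 min/5/16/24 h).  The numeric values
# are not shipped; fill them from a calibration via `load_piechart` — the
# loader applies `validate_experimental` to these names.
EXPERIMENTAL_SLOTS = (
    "Wang-12h",
    "Wang-24h",
    "Wang-48h",
    "Dikranian-30min",
    "Dikranian-5h",
    "Dikranian-16h",
    "Dikranian-24h",
)


def load_piechart(source, label: str = "") -> FASDistribution:
    """Build a pie-chart from a mapping or a YAML/JSON file path.

    Keys: transmission, filtering, reflection, blockage (missing keys are 0);
    fractions are normalized to sum to 1.  Labels matching an experimental
    slot are validated against the blockage-minority constraint.
    """
    if isinstance(source, FASDistribution):
        dist = source
    else:
        if not isinstance(source, dict):
            import yaml
            from pathlib import Path

            source = yaml.safe_load(Path(source).read_text())
        extra = set(source) - {"transmission", "filtering", "reflection", "blockage", "label"}
        if extra:
            raise ValueError(f"unknown pie-chart keys: {sorted(extra)}")
        label = source.get("label", label)
        vals = np.array(
            [float(source.get(k, 0.0)) for k in ("transmission", "filtering", "reflection", "blockage")]
        )
        total = vals.sum()
        if total <= 0:
            raise ValueError("pie-chart fractions must have a positive sum")
        vals = vals / total  # normalize; proportions are what matters
        dist = FASDistribution(*vals, label=label)
    if dist.label in EXPERIMENTAL_SLOTS:
        dist.validate_experimental()
    return dist


@dataclass(frozen=True)
class InjuryAssignment:
    """Per-neuron regime labels at a given injury level ``p``."""

    regimes: np.ndarray  # length-N int array over {0..4}
    injury_level: float
    distribution: FASDistribution
    seed: int | None = None

    def __post_init__(self):
        regimes = np.asarray(self.regimes, dtype=np.int64)
        object.__setattr__(self, "regimes", regimes)
        if regimes.min(initial=0) < 0 or regimes.max(initial=0) > 4:
            raise ValueError("regimes must be codes in {0,...,4}")

    @property
    def n_neurons(self) -> int:
        return int(self.regimes.size)

    @property
    def frozen(self) -> np.ndarray:
        """Mask of neurons that no longer update (blockage regime)."""
        return self.regimes == BLOCKAGE

    def counts(self) -> dict:
        return {
            REGIME_NAMES[k]: int(np.sum(self.regimes == k)) for k in REGIME_NAMES
        }


def sample_assignment(
    n_neurons: int,
    injury_level: float,
    dist: FASDistribution,
    seed=None,
) -> InjuryAssignment:
    """Draw an injury assignment: exactly ``round(p*N)`` injured neurons.

    The injured subset is chosen uniformly without replacement (an exact
    count rather than Bernoulli sampling, which removes one source of
    between-replicate variance); each injured neuron's regime is then drawn
    independently from the pie-chart.
    """
    if n_neurons <= 0:
        raise ValueError("n_neurons must be positive")
    if not 0.0 <= injury_level <= 1.0:
        raise ValueError("injury_level must lie in [0, 1]")
    if isinstance(seed, np.random.Generator):
        rng, seed_out = seed, None
    elif seed is None:
        raise ValueError("a seed is required for reproducibility")
    else:
        rng, seed_out = np.random.default_rng(seed), int(seed)
    regimes = np.zeros(n_neurons, dtype=np.int64)
    n_injured = int(round(injury_level * n_neurons))
    if n_injured > 0:
        injured = rng.choice(n_neurons, size=n_injured, replace=False)
        regimes[injured] = rng.choice(4, size=n_injured, p=dist.probs) + 1
    return InjuryAssignment(regimes, injury_level, dist, seed_out)


def transfer(value, regime: int, filter_spec: FilterSpec | None = None, rng=None):
    """Map a pre-injury firing rate in [0, 1] to its post-injury value.

    Healthy axons and swellings in the transmission regime pass the rate
    unchanged; reflection halves it; blockage zeroes it; filtering applies
    the piecewise-linear soft cap of ``filter_spec``.
    """
    spec = filter_spec or FilterSpec()
    v = np.asarray(value, dtype=float)
    if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
        raise ValueError("firing rates must lie in [0, 1]")
    if regime in (HEALTHY, TRANSMISSION):
        out = v
    elif regime == REFLECTION:
        out = 0.5 * v
    elif regime == BLOCKAGE:
        out = np.zeros_like(v)
    elif regime == FILTERING:
        capped = np.where(v <= spec.threshold, v, spec.threshold + spec.slope * (v - spec.threshold))
        if spec.stochastic:
            if rng is None:
                raise ValueError("stochastic filtering requires an rng")
            apply = rng.random(v.shape) < v
            out = np.where(apply, capped, v)
        else:
            out = capped
    else:
        raise ValueError(f"unknown regime code {regime!r}")
    return float(out) if np.isscalar(value) else out


def effective_output_table(
    assignment: InjuryAssignment | None,
    level_values: np.ndarray,
    n_neurons: int | None = None,
    filter_spec: FilterSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron lookup of effective bipolar output for each level.

    Returns ``(outmap, frozen)`` where ``outmap[i, l]`` is the bipolar value
    neuron ``i`` broadcasts when its level is ``l``, after its regime's
    transfer function, and ``frozen`` marks blocked neurons.  Since each
    regime's transfer is a deterministic function of the rate, the whole
    injury enters the dynamics through this table.
    """
    level_values = np.asarray(level_values, dtype=float)
    q = level_values.size
    if assignment is None:
        if n_neurons is None:
            raise ValueError("n_neurons required when assignment is None")
        outmap = np.broadcast_to(level_values, (n_neurons, q)).copy()
        return outmap, np.zeros(n_neurons, dtype=bool)
    n = assignment.n_neurons
    if n_neurons is not None and n_neurons != n:
        raise ValueError("assignment size does not match n_neurons")
    rates = (level_values + 1.0) / 2.0
    per_regime = np.stack(
        [2.0 * np.asarray(transfer(rates, k, filter_spec)) - 1.0 for k in range(5)]
    )  # (5, q)
    # A blocked axon transmits nothing, so it exerts no synaptic drive at
    # all: its effective output is the neutral value 0 (classical lesion
    # semantics), not the bipolar embedding of rate zero (-1), which would
    # turn silence into a maximally inhibitory signal.
    per_regime[BLOCKAGE, :] = 0.0
    outmap = per_regime[assignment.regimes]  # (N, q)
    return np.ascontiguousarray(outmap), assignment.frozen.copy()


def apply_to_state(state, assignment: InjuryAssignment | None, filter_spec: FilterSpec | None = None) -> np.ndarray:
    """Effective (post-injury) output vector for a network state.

    Each neuron's bipolar value is pushed through its regime's transfer
    function on the rate scale.  The result feeds the local fields of other
    neurons; it never overwrites the neuron's own stored level.
    """
    levels = np.asarray(state.levels)
    outmap, _ = effective_output_table(
        assignment, state.level_values, n_neurons=levels.size, filter_spec=filter_spec
    )
    if assignment is not None and outmap.shape[0] != levels.size:
        raise ValueError("assignment and state sizes differ")
    return outmap[np.arange(levels.size), levels]
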