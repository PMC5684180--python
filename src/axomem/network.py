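"""Multi-state Hopfield network: Hebbian training and stochastic recall.

Neurons take one of ``q`` discrete activity levels, embedded affinely on the
bipolar scale as ``level_values = linspace(-1, 1, q)`` (for ``q=2`` this is
the classical +/-1 network).  Training stores a memory set as fixed points
via the Hebbian outer-product rule; recall runs asynchronous sweeps in which
each neuron moves to the level nearest its (optionally noise-perturbed,
clamped) local field.  Axonal injury enters only through the effective
outputs neurons broadcast — a blocked neuron emits a zero firing rate and is
frozen, but its stored level is never overwritten by the injury itself.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .injury import FilterSpec, InjuryAssignment, effective_output_table

__all__ = [
    "level_values",
    "WeightMatrix",
    "NetworkState",
    "hebbian_train",
    "projection_train",
    "train",
    "local_field",
    "update_sweep",
    "run_to_convergence",
    "energy",
    "save_weights",
    "load_weights",
]


def level_values(n_levels: int) -> np.ndarray:
    """Bipolar embedding of the q activity levels: linspace(-1, 1, q)."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    return np.linspace(-1.0, 1.0, n_levels)


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric zero-diagonal couplings encoding a memory set.

    ``gain_ref`` is the root-mean-square bipolar value of the training set;
    recall dynamics rescale local fields to this amplitude (divisive gain
    normalization) before quantizing, which is an exact no-op for binary
    (q = 2, sign-invariant) networks but essential for graded levels, where
    a noisy cue shrinks field amplitudes uniformly and would otherwise
    mis-bin every intermediate level.
    """

    weights: np.ndarray
    n_levels: int
    gain_ref: float = 1.0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have zero diagonal")

    @property
    def n_neurons(self) -> int:
        return int(self.weights.shape[0])

    @property
    def level_values(self) -> np.ndarray:
        return level_values(self.n_levels)


@dataclass(frozen=True)
class NetworkState:
    """Current activity levels of all neurons."""

    levels: np.ndarray
    n_levels: int
    step_count: int = 0

    def __post_init__(self):
        lv = np.asarray(self.levels, dtype=np.int64)
        object.__setattr__(self, "levels", lv)
        if lv.min(initial=0) < 0 or lv.max(initial=0) >= self.n_levels:
            raise ValueError("levels out of range")

    @property
    def n_neurons(self) -> int:
        return int(self.levels.size)

    @property
    def level_values(self) -> np.ndarray:
        return level_values(self.n_levels)

    @property
    def values(self) -> np.ndarray:
        """Bipolar values of the current levels."""
        return self.level_values[self.levels]

    @classmethod
    def from_pattern(cls, pattern) -> "NetworkState":
        return cls(pattern.levels.copy(), pattern.n_levels)


def _bipolar(memories) -> np.ndarray:
    return level_values(memories.n_levels)[memories.to_array()]


def hebbian_train(memories) -> WeightMatrix:
    """Store a memory set with the Hebbian outer-product rule.

    ``w_ij = (1 / (N c)) * sum_mu v^mu_i v^mu_j`` for ``i != j``, where
    ``v^mu`` is the bipolar embedding of pattern ``mu`` and
    ``c = mean(v^2)`` over the training set is a gain normalization that
    places each stored pattern's local field at the pattern itself (for
    fully active binary patterns ``c = 1`` and this is the textbook
    ``1/N`` rule).  Without the gain, graded (q > 2) patterns would sit at
    fields shrunk by ``mean(v^2)`` and quantize toward the middle levels
    instead of being fixed points.

    The outer-product rule is the one with the classical ``M ~ 0.14 N``
    storage capacity, but it degrades badly for strongly correlated
    memories (crosstalk grows with the pairwise overlap); use
    :func:`projection_train` for correlated families.
    """
    v = _bipolar(memories)
    n = memories.n_neurons
    c = float(np.mean(v**2))
    if c == 0:
        raise ValueError("degenerate memory set: all values zero")
    w = v.T @ v / (n * c)
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(w, memories.n_levels, gain_ref=float(np.sqrt(c)))


def projection_train(memories) -> WeightMatrix:
    """Store a memory set with the projection (pseudo-inverse) rule.

    ``W = V^T Q^{-1} V / N`` with ``Q = V V^T / N`` the pattern Gram
    matrix, so the stored patterns are exact fixed points of the noiseless
    dynamics regardless of their mutual correlations.  This is the standard
    choice for correlated memory families (e.g. sets of similar grayscale
    images), for which plain Hebbian crosstalk destroys retrieval.
    """
    v = _bipolar(memories)
    n = memories.n_neurons
    q_gram = v @ v.T / n
    if np.linalg.matrix_rank(q_gram) < len(memories):
        raise ValueError("memory set contains linearly dependent patterns")
    w = v.T @ np.linalg.solve(q_gram, v) / n
    w = 0.5 * (w + w.T)  # symmetrize away solve round-off
    np.fill_diagonal(w, 0.0)
    c = float(np.mean(v**2))
    return WeightMatrix(w, memories.n_levels, gain_ref=float(np.sqrt(c)))


def train(memories, rule: str = "hebbian") -> WeightMatrix:
    """Train with the named rule: ``"hebbian"`` or ``"projection"``."""
    if rule == "hebbian":
        return hebbian_train(memories)
    if rule == "projection":
        return projection_train(memories)
    raise ValueError(f"unknown training rule {rule!r}")


def _effective_outputs(state: NetworkState, injury, filter_spec):
    outmap, frozen = effective_output_table(
        injury, state.level_values, n_neurons=state.n_neurons, filter_spec=filter_spec
    )
    veff = outmap[np.arange(state.n_neurons), state.levels]
    return outmap, frozen, veff


def local_field(
    W: WeightMatrix,
    state: NetworkState,
    injury: InjuryAssignment | None = None,
    filter_spec: FilterSpec | None = None,
) -> np.ndarray:
    """Local fields ``h_i = sum_j w_ij v~_j`` from injury-transformed outputs."""
    if W.n_neurons != state.n_neurons:
        raise ValueError("weight matrix and state sizes differ")
    _, _, veff = _effective_outputs(state, injury, filter_spec)
    return W.weights @ veff


def _sweep_kernel(levels, veff, h, W, outmap, frozen, order, eps, q, gain):
    """One asynchronous pass; updates levels/veff/h in place, returns #changed.

    ``h`` carries the running fields against the current effective outputs;
    when a neuron's output changes by ``delta`` the fields get a rank-one
    update ``h += W[i] * delta`` (W symmetric, zero diagonal).  Ties in the
    nearest-level quantization break toward the lower level index.
    """
    spacing = 2.0 / (q - 1)
    changed = 0
    for k in range(order.shape[0]):
        i = order[k]
        if frozen[i]:
            continue
        z = gain * h[i] + eps[i]
        if z < -1.0:
            z = -1.0
        elif z > 1.0:
            z = 1.0
        d = (z + 1.0) / spacing
        lo = math.floor(d)
        idx = int(lo)
        if d - lo > 0.5:
            idx += 1
        if idx > q - 1:
            idx = q - 1
        if idx != levels[i]:
            levels[i] = idx
            new_out = outmap[i, idx]
            delta = new_out - veff[i]
            if delta != 0.0:
                h += W[i] * delta
                veff[i] = new_out
            changed += 1
    return changed


try:  # jit-compile the inner loop when numba is available; same code path
    from numba import njit

    _sweep_kernel = njit(cache=False)(_sweep_kernel)
except ImportError:  # pragma: no cover - exercised only without numba
    pass


class _Dynamics:
    """Mutable recall-dynamics workspace (levels, effective outputs, fields)."""

    def __init__(self, W: WeightMatrix, state: NetworkState, injury, filter_spec):
        if W.n_neurons != state.n_neurons:
            raise ValueError("weight matrix and state sizes differ")
        self.W = W
        self.q = W.n_levels
        self.levels = state.levels.copy()
        self.outmap, self.frozen, self.veff = _effective_outputs(state, injury, filter_spec)
        self.h = W.weights @ self.veff
        self.step_count = state.step_count

    def sweep(self, noise_sigma: float, rng: np.random.Generator) -> int:
        n = self.levels.size
        order = rng.permutation(n)
        if noise_sigma > 0:
            eps = rng.normal(0.0, noise_sigma, n)
        else:
            eps = np.zeros(n)
        # divisive gain control, fixed over the sweep: rescale fields to the
        # training-set amplitude (sign-invariant, hence a no-op for q = 2)
        rms = float(np.sqrt(np.mean(self.h**2)))
        gain = self.W.gain_ref / rms if rms > 1e-12 else 1.0
        changed = _sweep_kernel(
            self.levels, self.veff, self.h, self.W.weights,
            self.outmap, self.frozen, order, eps, self.q, gain,
        )
        self.step_count += 1
        return changed

    def state(self) -> NetworkState:
        return NetworkState(self.levels.copy(), self.q, self.step_count)


def update_sweep(
    W: WeightMatrix,
    state: NetworkState,
    noise_sigma: float = 0.0,
    injury: InjuryAssignment | None = None,
    rng: np.random.Generator | None = None,
    filter_spec: FilterSpec | None = None,
) -> NetworkState:
    """One asynchronous sweep in a random permutation order.

    Each neuron in turn is set to the level whose bipolar value is nearest
    to ``clamp(h_i + eps, -1, 1)`` with ``eps ~ Normal(0, noise_sigma^2)``
    drawn independently per neuron update (Brownian-type fluctuations), the
    field being computed against the partially updated state.  Blocked
    neurons are skipped.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if rng is None:
        raise ValueError("an rng is required (reproducibility)")
    dyn = _Dynamics(W, state, injury, filter_spec)
    dyn.sweep(noise_sigma, rng)
    return dyn.state()


def run_to_convergence(
    W: WeightMatrix,
    initial: NetworkState,
    noise_sigma: float = 0.0,
    injury: InjuryAssignment | None = None,
    max_sweeps: int = 100,
    rng: np.random.Generator | None = None,
    filter_spec: FilterSpec | None = None,
) -> tuple[NetworkState, bool, int]:
    """Iterate sweeps until the level vector stops changing.

    Noiseless dynamics are declared converged after one unchanged sweep
    (asynchronous updates with symmetric zero-diagonal weights cannot leave
    a fixed point); with noise, two consecutive unchanged sweeps are
    required so a single quiet pass is not mistaken for an attractor.
    Returns ``(final_state, converged, sweeps_used)``.
    """
    if max_sweeps < 1:
        raise ValueError("max_sweeps must be >= 1")
    if rng is None:
        raise ValueError("an rng is required (reproducibility)")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    needed = 1 if noise_sigma == 0 else 2
    dyn = _Dynamics(W, initial, injury, filter_spec)
    quiet = 0
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        changed = dyn.sweep(noise_sigma, rng)
        quiet = quiet + 1 if changed == 0 else 0
        if quiet >= needed:
            return dyn.state(), True, sweeps
    return dyn.state(), False, sweeps


def energy(W: WeightMatrix, state: NetworkState) -> float:
    """Hopfield energy ``E = -1/2 sum_{i != j} w_ij v_i v_j`` (diagnostic).

    A Lyapunov function of the noiseless healthy asynchronous dynamics.
    """
    if W.n_neurons != state.n_neurons:
        raise ValueError("weight matrix and state sizes differ")
    v = state.values
    return float(-0.5 * v @ W.weights @ v)


def save_weights(W: WeightMatrix, csv_path, sidecar_path=None, memory_hash: str = "") -> None:
    csv_path = Path(csv_path)
    np.savetxt(csv_path, W.weights, delimiter=",")
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = dict(
        n_neurons=W.n_neurons,
        n_levels=W.n_levels,
        level_values=W.level_values.tolist(),
        memory_set_hash=memory_hash,
    )
    sidecar.write_text(json.dumps(meta, indent=2))


def load_weights(csv_path, sidecar_path=None) -> WeightMatrix:
    csv_path = Path(csv_path)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    w = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    return WeightMatrix(w, meta["n_levels"])
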