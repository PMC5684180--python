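"""Memory patterns: generation, encoding, corruption, and overlap statistics.

A memory pattern is a length-``N`` vector of discrete activity levels in
``[0, q-1]`` (``q`` grayscale states per neuron).  Two generators provide the
statistical structure the recall tasks assume: sparse uncorrelated patterns
near the Hopfield capacity limit, and correlated families built around a
shared template (a stand-in for sets of similar grayscale images such as
faces).  Overlap between two patterns is defined throughout as the fraction
of positions with identical level, i.e. ``1 - normalized Hamming distance``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MemoryPattern",
    "MemorySet",
    "generate_random_memories",
    "generate_correlated_family",
    "encode_image",
    "load_grayscale_image",
    "add_cue_noise",
    "overlap",
    "pairwise_overlap",
    "shared_active_fraction",
    "save_memory_set",
    "load_memory_set",
]

CAPACITY_RATIO = 0.14  # classical Hopfield storage capacity, M ~ 0.14 N


def _as_rng(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("a seed (or numpy Generator) is required for reproducibility")
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class MemoryPattern:
    """One stored memory: integer activity levels in ``[0, n_levels-1]``."""

    levels: np.ndarray
    n_levels: int
    label: str = ""

    def __post_init__(self):
        levels = np.asarray(self.levels, dtype=np.int64)
        object.__setattr__(self, "levels", levels)
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if levels.ndim != 1 or levels.size == 0:
            raise ValueError("levels must be a non-empty 1-D sequence")
        if levels.min() < 0 or levels.max() >= self.n_levels:
            raise ValueError(f"levels must lie in [0, {self.n_levels - 1}]")

    @property
    def n_neurons(self) -> int:
        return int(self.levels.size)


@dataclass(frozen=True)
class MemorySet:
    """A family of ``M`` patterns sharing ``N`` and ``q``."""

    patterns: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        patterns = tuple(self.patterns)
        object.__setattr__(self, "patterns", patterns)
        if len(patterns) < 1:
            raise ValueError("a memory set needs at least one pattern")
        n, q = patterns[0].n_neurons, patterns[0].n_levels
        for pat in patterns[1:]:
            if pat.n_neurons != n or pat.n_levels != q:
                raise ValueError("all patterns must share n_neurons and n_levels")

    def __len__(self) -> int:
        return len(self.patterns)

    def __getitem__(self, idx) -> MemoryPattern:
        return self.patterns[idx]

    @property
    def n_neurons(self) -> int:
        return self.patterns[0].n_neurons

    @property
    def n_levels(self) -> int:
        return self.patterns[0].n_levels

    @property
    def labels(self) -> list:
        return [p.label for p in self.patterns]

    def to_array(self) -> np.ndarray:
        """Stack levels into an (M, N) integer array."""
        return np.stack([p.levels for p in self.patterns])


def generate_random_memories(
    n_neurons: int,
    n_memories: int,
    n_levels: int = 2,
    active_fraction: float = 0.5,
    seed=None,
) -> MemorySet:
    """Generate sparse, uncorrelated random memories.

    Each pattern has ``round(active_fraction * N)`` active neurons (levels
    drawn uniformly from ``[1, q-1]``); the rest rest at level 0.  With the
    defaults (``q=2``, ``active_fraction=0.5``) this is the balanced binary
    ensemble whose storage capacity is the classical ``M ~ 0.14 N``.  The
    expected fraction of positions two patterns share at identical level is
    ``(1-a)^2 + a^2/(q-1)``; the expected fraction active in both is ``a^2``.
    """
    if n_neurons <= 0 or n_memories <= 0:
        raise ValueError("n_neurons and n_memories must be positive")
    if not 0 < active_fraction <= 1:
        raise ValueError("active_fraction must lie in (0, 1]")
    rng = _as_rng(seed)
    capacity = CAPACITY_RATIO * n_neurons
    if n_memories > 2 * int(np.ceil(capacity)):
        raise ValueError(
            f"n_memories={n_memories} exceeds twice the capacity limit "
            f"(~{capacity:.0f} for N={n_neurons})"
        )
    if n_memories > capacity:
        warnings.warn(
            f"n_memories={n_memories} is above the ~0.14 N capacity limit "
            f"({capacity:.0f}); recall will be unreliable",
            stacklevel=2,
        )
    n_active = int(round(active_fraction * n_neurons))
    patterns = []
    for mu in range(n_memories):
        levels = np.zeros(n_neurons, dtype=np.int64)
        active = rng.choice(n_neurons, size=n_active, replace=False)
        levels[active] = rng.integers(1, n_levels, size=n_active)
        patterns.append(MemoryPattern(levels, n_levels, label=f"random-{mu}"))
    meta = dict(
        generator="random",
        n_neurons=n_neurons,
        n_memories=n_memories,
        n_levels=n_levels,
        active_fraction=active_fraction,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )
    return MemorySet(tuple(patterns), meta)


def generate_correlated_family(
    n_neurons: int,
    n_memories: int,
    n_levels: int = 8,
    target_overlap: float = 0.65,
    seed=None,
) -> MemorySet:
    """Generate a correlated family of patterns around a shared template.

    All patterns copy a common random template at the same ``round(c*N)``
    positions and draw the remaining positions i.i.d. uniform over the ``q``
    levels, where the copy fraction ``c`` solves
    ``target_overlap = c + (1-c)/q``.  Because the copy mask is shared, that
    relation holds for every pattern pair, so the expected pairwise overlap
    equals ``target_overlap``.  This emulates sets of highly similar
    grayscale images (e.g. different faces) without any image data.
    """
    if n_neurons <= 0 or n_memories <= 0:
        raise ValueError("n_neurons and n_memories must be positive")
    q = n_levels
    if not (1.0 / q) < target_overlap < 1.0 + 1e-12:
        raise ValueError(
            f"target_overlap must lie in (1/q, 1] = ({1.0 / q:.3f}, 1] for q={q}"
        )
    rng = _as_rng(seed)
    copy_fraction = (target_overlap - 1.0 / q) / (1.0 - 1.0 / q)
    copy_fraction = min(copy_fraction, 1.0)
    n_copy = int(round(copy_fraction * n_neurons))
    template = rng.integers(0, q, size=n_neurons)
    mask = rng.choice(n_neurons, size=n_copy, replace=False)
    patterns = []
    for mu in range(n_memories):
        levels = rng.integers(0, q, size=n_neurons)
        levels[mask] = template[mask]
        patterns.append(MemoryPattern(levels, q, label=f"correlated-{mu}"))
    meta = dict(
        generator="correlated",
        n_neurons=n_neurons,
        n_memories=n_memories,
        n_levels=q,
        target_overlap=target_overlap,
        copy_fraction=copy_fraction,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )
    return MemorySet(tuple(patterns), meta)


def encode_image(pixels, n_levels: int, label: str = "") -> MemoryPattern:
    """Quantize a 2-D grayscale image (intensities 0..255) into a pattern.

    Pixels are flattened row-major; each intensity ``x`` maps to level
    ``floor(x * q / 256)`` clamped to ``q - 1``, so ``q=256`` is the identity
    and ``q=2`` thresholds at 128.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("pixels must be a non-empty 2-D grayscale array")
    levels = np.floor_divide(arr.astype(np.int64) * n_levels, 256)
    levels = np.clip(levels, 0, n_levels - 1)
    return MemoryPattern(levels.ravel(), n_levels, label=label)


def load_grayscale_image(path) -> np.ndarray:
    """Read a PGM (P2/P5) or PNG image as a 2-D uint8 intensity array."""
    from PIL import Image

    with Image.open(path) as img:
        return np.asarray(img.convert("L"), dtype=np.uint8)


def add_cue_noise(pattern: MemoryPattern, noise_level: float, seed=None) -> MemoryPattern:
    """Corrupt exactly ``round(noise_level * N)`` positions of a pattern.

    Each corrupted position is reassigned a uniformly random level different
    from its current one, so the overlap with the original is exactly
    ``1 - round(noise_level*N)/N`` by construction (for ``q=2`` and
    ``noise_level=1`` this is the bitwise complement).
    """
    if not 0.0 <= noise_level <= 1.0:
        raise ValueError("noise_level must lie in [0, 1]")
    q = pattern.n_levels
    n = pattern.n_neurons
    n_flip = int(round(noise_level * n))
    levels = pattern.levels.copy()
    if n_flip > 0:
        rng = _as_rng(seed)
        pos = rng.choice(n, size=n_flip, replace=False)
        # uniform over the q-1 levels different from the current one
        shift = rng.integers(1, q, size=n_flip)
        levels[pos] = (levels[pos] + shift) % q
    return MemoryPattern(levels, q, label=pattern.label)


def overlap(a, b) -> float:
    """Fraction of positions where two level vectors agree (1 - Hamming/N)."""
    av = a.levels if isinstance(a, MemoryPattern) else np.asarray(a)
    bv = b.levels if isinstance(b, MemoryPattern) else np.asarray(b)
    if av.shape != bv.shape:
        raise ValueError("patterns must have equal length")
    return float(np.mean(av == bv))


def pairwise_overlap(memory_set: MemorySet) -> np.ndarray:
    """M x M symmetric matrix of pairwise overlaps; diagonal is 1."""
    arr = memory_set.to_array()
    m = len(memory_set)
    out = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = float(np.mean(arr[i] == arr[j]))
    return out


def shared_active_fraction(memory_set: MemorySet) -> np.ndarray:
    """M x M matrix of the fraction of positions active (level > 0) in both.

    For sparse patterns this is the natural overlap-of-supports statistic:
    its expectation for independent patterns with active fraction ``a`` is
    ``a**2``.
    """
    active = memory_set.to_array() > 0
    m = len(memory_set)
    out = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            out[i, j] = float(np.mean(active[i] & active[j]))
    return out


def save_memory_set(memory_set: MemorySet, csv_path, sidecar_path=None) -> None:
    """Write one row of integer levels per pattern, plus a JSON sidecar."""
    csv_path = Path(csv_path)
    arr = memory_set.to_array()
    np.savetxt(csv_path, arr, fmt="%d", delimiter=",")
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = dict(memory_set.meta)
    meta.update(
        n_neurons=memory_set.n_neurons,
        n_levels=memory_set.n_levels,
        n_memories=len(memory_set),
        labels=memory_set.labels,
    )
    sidecar.write_text(json.dumps(meta, indent=2))


def load_memory_set(csv_path, sidecar_path=None) -> MemorySet:
    csv_path = Path(csv_path)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    arr = np.loadtxt(csv_path, dtype=np.int64, delimiter=",", ndmin=2)
    labels = meta.get("labels") or [""] * arr.shape[0]
    patterns = tuple(
        MemoryPattern(row, meta["n_levels"], label=lab) for row, lab in zip(arr, labels)
    )
    return MemorySet(patterns, meta)
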