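"""Training rules, recall dynamics, energy bookkeeping."""

import numpy as np
import pytest

import axomem as ax
from axomem.network import NetworkState, WeightMatrix, load_weights, save_weights
from axomem.patterns import MemoryPattern


def _state(mem, idx=0):
    return NetworkState.from_pattern(mem[idx])


class TestHebbianTrain:
    def test_single_pattern_outer_product_by_hand(self):
        mem = ax.MemorySet((MemoryPattern(np.array([1, 1, 0, 0]), 2),))
        W = ax.hebbian_train(mem)
        assert W.weights[0, 1] == pytest.approx(0.25)
        assert W.weights[0, 2] == pytest.approx(-0.25)
        assert np.all(np.diag(W.weights) == 0)
        assert np.allclose(W.weights, W.weights.T)

    def test_table3_scale_training(self):
        mem = ax.generate_random_memories(900, 126, 2, 0.5, seed=1)
        W = ax.hebbian_train(mem)
        assert W.weights.shape == (900, 900)
        assert np.allclose(W.weights, W.weights.T)
        assert np.all(np.diag(W.weights) == 0)

    def test_stored_patterns_fixed_below_capacity(self, small_binary_set, small_binary_net):
        rng = np.random.default_rng(0)
        for mu in range(len(small_binary_set)):
            out = ax.update_sweep(small_binary_net, _state(small_binary_set, mu), rng=rng)
            assert np.array_equal(out.levels, small_binary_set[mu].levels)

    def test_graded_single_memory_is_fixed_point(self):
        mem = ax.generate_random_memories(400, 1, 8, 1.0, seed=2)
        W = ax.hebbian_train(mem)
        rng = np.random.default_rng(0)
        out = ax.update_sweep(W, _state(mem), rng=rng)
        assert np.array_equal(out.levels, mem[0].levels)


class TestProjectionTrain:
    def test_correlated_patterns_exact_fixed_points(self, face_like_set, face_like_net):
        rng = np.random.default_rng(0)
        for mu in range(len(face_like_set)):
            final, conv, used = ax.run_to_convergence(
                face_like_net, _state(face_like_set, mu), rng=rng
            )
            assert conv and used == 1
            assert np.array_equal(final.levels, face_like_set[mu].levels)

    def test_dependent_patterns_rejected(self):
        pat = MemoryPattern(np.array([0, 1, 0, 1, 1, 0]), 2)
        with pytest.raises(ValueError, match="dependent"):
            ax.projection_train(ax.MemorySet((pat, pat)))

    def test_train_dispatch(self, small_binary_set):
        assert isinstance(ax.train(small_binary_set, "projection"), WeightMatrix)
        with pytest.raises(ValueError):
            ax.train(small_binary_set, "nope")


class TestLocalField:
    def test_zero_weights_zero_field(self):
        W = WeightMatrix(np.zeros((6, 6)), 2)
        state = NetworkState(np.ones(6, dtype=int), 2)
        assert np.all(ax.local_field(W, state) == 0)

    def test_single_memory_sign_stability(self):
        mem = ax.generate_random_memories(200, 1, 2, 0.5, seed=3)
        W = ax.hebbian_train(mem)
        h = ax.local_field(W, _state(mem))
        v = _state(mem).values
        assert np.all(np.sign(h) == np.sign(v))

    def test_all_blockage_gives_zero_field(self, small_binary_set, small_binary_net):
        assign = ax.sample_assignment(
            200, 1.0, ax.FASDistribution(blockage=1.0), seed=0
        )
        h = ax.local_field(small_binary_net, _state(small_binary_set), injury=assign)
        assert np.all(h == 0)

    def test_dimension_mismatch(self, small_binary_net):
        with pytest.raises(ValueError):
            ax.local_field(small_binary_net, NetworkState(np.zeros(7, dtype=int), 2))


class TestRecallDynamics:
    def test_noisy_cue_recalled_majority(self, small_binary_set, small_binary_net):
        # classical pattern completion: 20% corrupted cues at load 0.05
        hits = 0
        for k in range(20):
            rng = np.random.default_rng(100 + k)
            cue = ax.add_cue_noise(small_binary_set[k % 10], 0.2, seed=rng)
            final, _, _ = ax.run_to_convergence(
                small_binary_net, NetworkState.from_pattern(cue), rng=rng
            )
            hits += ax.overlap(final.levels, small_binary_set[k % 10]) == 1.0
        assert hits >= 15

    def test_noise_dominated_limit_hits_extremes(self, small_binary_net, small_binary_set):
        rng = np.random.default_rng(0)
        out = ax.update_sweep(
            small_binary_net, _state(small_binary_set), noise_sigma=50.0, rng=rng
        )
        # huge field noise: clamped to +-1, so every neuron lands on an extreme
        assert set(np.unique(out.levels)) <= {0, small_binary_net.n_levels - 1}

    def test_convergence_contract(self, small_binary_set, small_binary_net):
        rng = np.random.default_rng(0)
        final, conv, used = ax.run_to_convergence(
            small_binary_net, _state(small_binary_set), rng=rng
        )
        assert conv and used == 1
        with pytest.raises(ValueError):
            ax.run_to_convergence(small_binary_net, _state(small_binary_set),
                                  max_sweeps=0, rng=rng)
        with pytest.raises(ValueError, match="rng"):
            ax.run_to_convergence(small_binary_net, _state(small_binary_set))

    def test_trajectory_bit_reproducible(self, small_binary_set, small_binary_net):
        cue = ax.add_cue_noise(small_binary_set[0], 0.3, seed=4)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(1234)
            final, _, _ = ax.run_to_convergence(
                small_binary_net, NetworkState.from_pattern(cue),
                noise_sigma=0.2, rng=rng,
            )
            runs.append(final.levels)
        assert np.array_equal(runs[0], runs[1])


class TestEnergy:
    def test_zero_weights(self):
        W = WeightMatrix(np.zeros((4, 4)), 2)
        assert ax.energy(W, NetworkState(np.ones(4, dtype=int), 2)) == 0.0

    def test_single_memory_closed_form(self):
        n = 120
        mem = ax.generate_random_memories(n, 1, 2, 0.5, seed=6)
        W = ax.hebbian_train(mem)
        assert ax.energy(W, _state(mem)) == pytest.approx(-(n - 1) / 2)

    def test_noiseless_dynamics_never_increase_energy(self):
        # Lyapunov property of asynchronous sign updates with symmetric
        # zero-diagonal couplings, checked over random binary trajectories
        mem = ax.generate_random_memories(200, 10, 2, 0.5, seed=8)
        W = ax.hebbian_train(mem)
        rng = np.random.default_rng(0)
        for _ in range(100):
            state = NetworkState(rng.integers(0, 2, 200), 2)
            e = ax.energy(W, state)
            for _ in range(6):
                state = ax.update_sweep(W, state, rng=rng)
                e_next = ax.energy(W, state)
                assert e_next <= e + 1e-9
                e = e_next


def test_capacity_limit_recall_majority():
    """At the classical load M = 0.14 N, most memories are still recalled
    essentially intact from clean cues by the outer-product network."""
    mem = ax.generate_random_memories(900, 126, 2, 0.5, seed=1)
    W = ax.hebbian_train(mem)
    rng = np.random.default_rng(0)
    good = 0
    for mu in range(0, 126, 2):
        final, _, _ = ax.run_to_convergence(W, _state(mem, mu), rng=rng)
        good += ax.overlap(final.levels, mem[mu]) >= 0.97
    assert good > 126 // 4  # majority of the 63 sampled


def test_weight_serialization_roundtrip(tmp_path, small_binary_net):
    path = tmp_path / "w.csv"
    save_weights(small_binary_net, path, memory_hash="abc")
    back = load_weights(path)
    assert np.allclose(back.weights, small_binary_net.weights)
    assert back.n_levels == small_binary_net.n_levels


def test_weight_matrix_invariants_enforced():
    bad = np.ones((3, 3))
    with pytest.raises(ValueError):
        WeightMatrix(bad, 2)  # nonzero diagonal
    asym = np.zeros((3, 3))
    asym[0, 1] = 1.0
    with pytest.raises(ValueError):
        WeightMatrix(asym, 2)
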