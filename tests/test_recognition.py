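"""Trial classification, recognition score, and sweep machinery."""

import numpy as np
import pandas as pd
import pytest

import axomem as ax
from axomem.recognition import TrialOutcome, raw_score


def _outcome(kind, ov_correct=1.0, ov_best=1.0, cued=0):
    best = {"correct": cued, "none": None, "confused": cued + 1}[kind]
    return TrialOutcome(cued, best, kind, ov_correct, ov_best, True, 3)


class TestClassify:
    def test_exact_cued_memory_is_correct(self, small_binary_set):
        best, outcome, ov_c, ov_b = ax.classify(
            small_binary_set[2].levels, small_binary_set, cued_memory=2,
            theta=0.9, delta=0.1,
        )
        assert (best, outcome, ov_c, ov_b) == (2, "correct", 1.0, 1.0)

    def test_other_memory_is_confused(self, small_binary_set):
        best, outcome, *_ = ax.classify(
            small_binary_set[3].levels, small_binary_set, cued_memory=2,
        )
        assert best == 3 and outcome == "confused"

    def test_low_overlap_is_none(self, small_binary_set):
        rng = np.random.default_rng(0)
        best, outcome, _, ov_b = ax.classify(
            rng.integers(0, 2, 200), small_binary_set, cued_memory=0, theta=0.9
        )
        assert best is None and outcome == "none" and ov_b < 0.9

    def test_margin_condition(self, face_like_set):
        # a state equal to one pattern still clears the margin over its
        # ~65%-overlapping siblings; an impossible margin forces "none"
        levels = face_like_set[1].levels
        _, outcome, *_ = ax.classify(levels, face_like_set, 1, theta=0.75, delta=0.10)
        assert outcome == "correct"
        best, outcome, *_ = ax.classify(levels, face_like_set, 1, theta=0.75, delta=0.9)
        assert best is None and outcome == "none"

    def test_parameter_validation(self, small_binary_set):
        with pytest.raises(ValueError):
            ax.classify(small_binary_set[0].levels, small_binary_set, 0, theta=1.5)
        with pytest.raises(ValueError):
            ax.classify(small_binary_set[0].levels, small_binary_set, 0, delta=-0.1)


class TestTrialOutcome:
    def test_consistency_enforced(self):
        with pytest.raises(ValueError):
            TrialOutcome(0, 1, "correct", 1.0, 1.0, True, 1)
        with pytest.raises(ValueError):
            TrialOutcome(0, 0, "confused", 1.0, 1.0, True, 1)
        with pytest.raises(ValueError):
            TrialOutcome(0, None, "maybe", 1.0, 1.0, True, 1)


class TestRunTrial:
    def test_clean_cue_healthy_is_perfect(self, small_binary_set, small_binary_net):
        rng = np.random.default_rng(0)
        t = ax.run_trial(small_binary_net, small_binary_set, 4, 0.0, rng=rng)
        assert t.outcome == "correct"
        assert t.final_overlap_correct == 1.0
        assert t.converged

    def test_cue_index_validated(self, small_binary_set, small_binary_net):
        with pytest.raises(ValueError):
            ax.run_trial(small_binary_net, small_binary_set, 99, 0.1,
                         rng=np.random.default_rng(0))


class TestRecognitionScore:
    def test_all_correct_full_accuracy(self):
        assert ax.recognition_score([_outcome("correct")] * 5) == 1.0

    def test_all_confused_clamps_to_zero(self):
        assert ax.recognition_score([_outcome("confused")] * 5) == 0.0

    def test_mixed_with_baseline_arithmetic(self):
        outcomes = [_outcome("correct")] * 9 + [_outcome("none")]
        assert raw_score(outcomes) == pytest.approx(0.9)
        assert ax.recognition_score(outcomes, baseline=0.9) == 1.0

    def test_baseline_validation(self):
        with pytest.raises(ValueError):
            ax.recognition_score([_outcome("correct")], baseline=0.0)
        with pytest.raises(ValueError):
            ax.recognition_score([])


@pytest.fixture(scope="module")
def small_sweep(small_binary_set, small_binary_net):
    spec = ax.SweepSpec(
        noise_levels=(0.1, 0.2),
        injury_levels=(0.0, 0.2, 0.4),
        distribution=ax.TABLE1_PIECHARTS["f60b40"],
        replicates=2,
        n_cues=6,
        noise_sigma=0.0,
        master_seed=7,
    )
    return ax.sweep(small_binary_net, small_binary_set, spec), spec


class TestSweep:
    def test_trivial_healthy_cell_scores_one(self, small_binary_set, small_binary_net):
        spec = ax.SweepSpec(
            noise_levels=(0.0,), injury_levels=(0.0,),
            distribution=ax.TABLE1_PIECHARTS["f60b40"],
            replicates=1, noise_sigma=0.0, master_seed=0,
        )
        agg = ax.sweep(small_binary_net, small_binary_set, spec).aggregate()
        assert agg.loc[0, "score"] == 1.0

    def test_outcome_fractions_sum_to_one(self, small_sweep):
        agg, _ = small_sweep[0].aggregate(), small_sweep[1]
        total = agg.fraction_correct + agg.fraction_none + agg.fraction_confused
        assert np.allclose(total, 1.0)

    def test_grid_and_trial_counts(self, small_sweep):
        result, spec = small_sweep
        agg = result.aggregate()
        assert len(agg) == len(spec.noise_levels) * len(spec.injury_levels)
        assert np.all(agg.n_trials == spec.replicates * spec.n_cues)

    def test_bit_for_bit_reproducible(self, small_binary_set, small_binary_net, small_sweep):
        result, spec = small_sweep
        again = ax.sweep(small_binary_net, small_binary_set, spec)
        pd.testing.assert_frame_equal(result.records, again.records)

    def test_score_non_increasing_in_injury(self, small_binary_set, small_binary_net):
        spec = ax.SweepSpec(
            noise_levels=(0.1,),
            injury_levels=(0.0, 0.1, 0.2, 0.3, 0.4),
            distribution=ax.TABLE1_PIECHARTS["f20b80"],
            replicates=3, n_cues=8, noise_sigma=0.0, master_seed=3,
        )
        agg = ax.sweep(small_binary_net, small_binary_set, spec).aggregate()
        r = agg.sort_values("injury_level")["score"].to_numpy()
        assert np.all(np.diff(r) <= 0.03)  # Monte-Carlo slack

    def test_checkpoint_resume_reproduces_full_run(
        self, tmp_path, small_binary_set, small_binary_net, small_sweep
    ):
        result, spec = small_sweep
        ckpt = tmp_path / "partial.csv"
        first = ax.sweep(small_binary_net, small_binary_set, spec, checkpoint=ckpt)
        pd.testing.assert_frame_equal(first.records, result.records)
        # drop two completed batches from the checkpoint and resume
        partial = pd.read_csv(ckpt)
        trimmed = partial[~((partial.injury_idx == 2) & (partial.replicate == 1))]
        ckpt.write_text("")
        trimmed.to_csv(ckpt, index=False)
        resumed = ax.sweep(small_binary_net, small_binary_set, spec, checkpoint=ckpt)
        pd.testing.assert_frame_equal(resumed.records, result.records)

    def test_from_dict_grid_expansion(self):
        spec = ax.SweepSpec.from_dict(
            dict(
                distribution={"filtering": 0.6, "blockage": 0.4},
                noise_levels={"start": 0.0, "stop": 0.2, "step": 0.1},
                injury_levels=[0.0, 0.5],
                replicates=2,
                master_seed=1,
            )
        )
        assert spec.noise_levels == (0.0, 0.1, 0.2)
        assert spec.distribution.blockage == pytest.approx(0.4)


def test_calibration_hits_target_band(face_like_net, face_like_set):
    sigma = ax.calibrate_noise_sigma(
        face_like_net, face_like_set, n_trials=40, iterations=6, seed=2
    )
    assert 0.0 < sigma < 1.0
    # at the calibrated amplitude, healthy recall sits near the 90% target
    hits = 0
    for k in range(60):
        rng = np.random.default_rng(5000 + k)
        t = ax.run_trial(face_like_net, face_like_set, k % 3, 0.2,
                         noise_sigma=sigma, rng=rng)
        hits += t.outcome == "correct"
    assert 0.7 <= hits / 60 <= 1.0
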