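"""Tests for the staircase/MOCS experiment engine."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr
from scipy.stats import norm

from huemem import (
    Condition,
    InvalidParameterError,
    PmfFit,
    StaircaseExhaustedError,
    StaircaseState,
    StimulusPresentation,
    mocs_needs_adjustment,
    run_mocs_block,
    run_staircase_block,
    sample_distractors,
    select_mocs_levels,
    staircase_update,
)

REFS = (2.9, 3.2, 3.5)


def pmf_observer(pse: float, spread: float, seed: int = 0):
    """Observer whose P(test bluer) is exactly a cumulative normal."""
    rng = np.random.default_rng(seed)

    def respond(reference, test, _rng):
        return bool(rng.random() < ndtr((test.hue - pse) / spread))

    return respond


class TestCondition:
    @pytest.mark.parametrize(
        "sym, delay, distract, name",
        [
            ("symmetric_gray", "simultaneous", "none", "baseline"),
            ("asymmetric", "simultaneous", "none", "constancy"),
            ("symmetric_blue", "delay_2s", "none", "memory"),
            ("asymmetric", "delay_2s", "none", "joint"),
            ("asymmetric", "delay_2s", "present", "joint_distractors"),
        ],
    )
    def test_names(self, sym, delay, distract, name):
        assert Condition(sym, delay, distract).name == name

    def test_distractors_require_delay(self):
        with pytest.raises(InvalidParameterError):
            Condition("asymmetric", "simultaneous", "present")


class TestStaircaseUpdate:
    def make(self, target=0.8, level=0.0, step=0.1, factor=1.0):
        return StaircaseState(
            target_percentile=target, current_level=level, final_step=step,
            initial_factor=factor,
        )

    def test_weighted_up_down_step_sizes(self):
        """Target 80%: 'test bluer' moves down by the small step; the up
        step is 4x so the equilibrium sits at the 80th percentile."""
        s = self.make(target=0.8)
        down = staircase_update(s, True)
        assert down.current_level == pytest.approx(-0.1)
        up = staircase_update(s, False)
        assert up.current_level == pytest.approx(0.4)
        # target 20%: mirror-image asymmetry
        s2 = self.make(target=0.2)
        assert staircase_update(s2, True).current_level == pytest.approx(-0.4)
        assert staircase_update(s2, False).current_level == pytest.approx(0.1)

    def test_reversal_bookkeeping(self):
        """Alternating responses add one reversal per direction flip."""
        s = self.make()
        responses = [True, False, True, False, True]
        for r in responses:
            s = staircase_update(s, r)
        assert len(s.reversal_levels) == len(responses) - 1

    def test_initial_step_scaling_halves_at_reversals(self):
        s = self.make(factor=3.0)
        assert s.base_step == pytest.approx(0.3)
        s = staircase_update(s, True)   # no reversal yet
        assert s.base_step == pytest.approx(0.3)
        s = staircase_update(s, False)  # 1st reversal
        assert s.base_step == pytest.approx(0.15)
        s = staircase_update(s, True)   # 2nd reversal
        assert s.base_step == pytest.approx(0.1)  # floored at final step
        s = staircase_update(s, False)
        assert s.base_step == pytest.approx(0.1)

    def test_update_after_exhaustion_raises(self):
        s = self.make()
        for _ in range(20):
            s = staircase_update(s, True)
        with pytest.raises(StaircaseExhaustedError):
            staircase_update(s, True)

    @pytest.mark.parametrize("target", [0.2, 0.8])
    def test_long_run_converges_to_target_percentile(self, target):
        """Weighted up-down equilibrium: post-burn-in mean level approaches
        the analytically inverted target percentile of the observer's PMF."""
        pse, spread = 1.0, 0.2
        expected = pse + spread * norm.ppf(target)
        rng = np.random.default_rng(5)
        s = StaircaseState(
            target_percentile=target, current_level=pse + 0.4,
            final_step=0.02, initial_factor=3.0, max_trials=600,
        )
        levels = []
        for _ in range(600):
            levels.append(s.current_level)
            p = ndtr((s.current_level - pse) / spread)
            s = staircase_update(s, bool(rng.random() < p))
        mean_level = np.mean(levels[150:])
        assert mean_level == pytest.approx(expected, abs=0.05)

    def test_invalid_target_rejected(self):
        with pytest.raises(InvalidParameterError):
            StaircaseState(target_percentile=0.5, current_level=0.0, final_step=0.1)


class TestStaircaseBlock:
    def test_uniform_block_emits_240_trials(self):
        df = run_staircase_block(pmf_observer(3.2, 0.15), Condition("symmetric_gray"), REFS, 1)
        assert len(df) == 240

    def test_asymmetric_block_emits_480_trials(self):
        df = run_staircase_block(pmf_observer(3.2, 0.15), Condition("asymmetric"), REFS, 1)
        assert len(df) == 480

    def test_wrong_reference_count_rejected(self):
        with pytest.raises(InvalidParameterError):
            run_staircase_block(pmf_observer(3.2, 0.15), Condition("asymmetric"), (3.0, 3.2), 1)

    def test_interleaving_fairness(self):
        """Every staircase advances exactly 20 times in any interleaving."""
        df = run_staircase_block(pmf_observer(3.2, 0.15), Condition("asymmetric"), REFS, 9)
        counts = df.groupby(["staircase_id"]).size()
        assert len(counts) == 24
        assert (counts == 20).all()

    def test_terminal_levels_bracket_the_reference(self):
        """For an observer with PSE at the reference, the 20% staircases end
        below it and the 80% staircases end above it."""
        ref = 3.2

        def noiseless(reference, test, rng):
            return bool(test.hue > ref)

        df = run_staircase_block(
            noiseless, Condition("symmetric_gray"), (ref - 0.3, ref, ref + 0.3), 3,
            final_step=0.02,
        )
        # per reference, the 4 staircases are created in target order
        # (0.2, 0.2, 0.8, 0.8), so the two lowest ids track the 20th percentile
        sids = sorted(df[df["reference_hue"] == ref]["staircase_id"].unique())
        assert len(sids) == 4
        for rank, sid in enumerate(sids):
            last = df[df["staircase_id"] == sid].sort_values("trial_index").iloc[-1]
            terminal = last["test_hue"]
            if rank < 2:
                assert terminal < ref
            else:
                assert terminal > ref

    def test_pooled_staircase_responses_span_both_sides_of_pse(self):
        """Monte-Carlo coverage: pooled responses include both choices and
        sampled levels fall on both sides of the observer's PSE."""
        df = run_staircase_block(pmf_observer(3.2, 0.1, seed=7), Condition("symmetric_gray"), REFS, 7)
        mid = df[df["reference_hue"] == 3.2]
        assert mid["response_test_bluer"].nunique() == 2
        assert (mid["test_hue"] < 3.2).any() and (mid["test_hue"] > 3.2).any()

    def test_asymmetric_sides_follow_backgrounds(self):
        df = run_staircase_block(pmf_observer(3.2, 0.15), Condition("asymmetric"), REFS, 2)
        gray = df[df["reference_background"] == "gray"]
        blue = df[df["reference_background"] == "blue"]
        assert (gray["reference_side"] == "left").all()
        assert (blue["reference_side"] == "right").all()
        assert len(gray) == len(blue) == 240

    def test_same_seed_reproduces_block(self):
        a = run_staircase_block(pmf_observer(3.2, 0.15), Condition("symmetric_blue"), REFS, 11)
        b = run_staircase_block(pmf_observer(3.2, 0.15), Condition("symmetric_blue"), REFS, 11)
        pd.testing.assert_frame_equal(a, b)


class TestMocsLevels:
    def test_standard_normal_quantile_endpoints(self):
        fit = PmfFit(0.0, 1.0, 0.0, 0.0, 100, True)
        levels = select_mocs_levels(fit)
        assert levels[0] == pytest.approx(norm.ppf(0.01), abs=1e-9)
        assert levels[-1] == pytest.approx(norm.ppf(0.99), abs=1e-9)
        assert np.allclose(np.diff(levels), np.diff(levels)[0])
        assert (np.diff(levels) > 0).all()

    def test_spacing_scales_with_spread(self):
        narrow = select_mocs_levels(PmfFit(0.0, 0.5, 0.0, 0.0, 100, True))
        wide = select_mocs_levels(PmfFit(0.0, 1.0, 0.0, 0.0, 100, True))
        assert np.allclose(np.diff(narrow), np.diff(wide) / 2)

    def test_levels_symmetric_about_location(self):
        levels = select_mocs_levels(PmfFit(1.3, 0.4, 0.0, 0.0, 100, True))
        assert np.allclose(levels + levels[::-1], 2 * 1.3)

    def test_degenerate_fit_rejected(self):
        with pytest.raises(InvalidParameterError):
            select_mocs_levels(PmfFit(0.0, 0.0, 0.0, 0.0, 100, True))


class TestMocsBlock:
    def levels_for(self, condition):
        return {
            (ref, bg): np.linspace(ref - 0.2, ref + 0.2, 5)
            for bg in condition.reference_backgrounds()
            for ref in REFS
        }

    def test_count_arithmetic(self):
        """5 levels x 10 reps x 3 refs x 2 backgrounds = 300 rows."""
        cond = Condition("asymmetric")
        df = run_mocs_block(pmf_observer(3.2, 0.15), cond, self.levels_for(cond), 10, 1)
        assert len(df) == 300

    def test_each_cell_repeated_exactly(self):
        cond = Condition("symmetric_gray")
        df = run_mocs_block(pmf_observer(3.2, 0.15), cond, self.levels_for(cond), 1, 1)
        counts = df.groupby(["reference_hue", "reference_background", "test_hue"]).size()
        assert (counts == 1).all()
        assert len(counts) == 15

    def test_same_seed_same_order(self):
        cond = Condition("symmetric_gray")
        a = run_mocs_block(pmf_observer(3.2, 0.15), cond, self.levels_for(cond), 3, 5)
        b = run_mocs_block(pmf_observer(3.2, 0.15), cond, self.levels_for(cond), 3, 5)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_repetitions_rejected(self):
        cond = Condition("symmetric_gray")
        with pytest.raises(InvalidParameterError):
            run_mocs_block(pmf_observer(3.2, 0.15), cond, self.levels_for(cond), 0, 1)


class TestDistractors:
    def test_degenerate_draw_is_exact_offset(self):
        rng = np.random.default_rng(0)
        assert sample_distractors(1.0, 0.0, rng) == (0.8, 0.8)

    def test_sample_mean_matches_offset(self):
        rng = np.random.default_rng(1)
        draws = np.array([sample_distractors(3.2, 0.1, rng) for _ in range(50_000)])
        se = 0.1 / math.sqrt(draws.size)
        assert draws.mean() == pytest.approx(3.2 - 0.2, abs=3 * se)

    def test_negative_sd_rejected(self):
        with pytest.raises(InvalidParameterError):
            sample_distractors(1.0, -0.1, np.random.default_rng(0))

    def test_distractor_columns_populated_only_when_present(self):
        cond = Condition("symmetric_gray", "delay_2s", "present")
        df = run_staircase_block(pmf_observer(3.2, 0.15), cond, REFS, 1)
        assert df["distractor1_hue"].notna().all()
        plain = run_staircase_block(pmf_observer(3.2, 0.15), Condition("symmetric_gray"), REFS, 1)
        assert plain["distractor1_hue"].isna().all()


class TestMocsAdjustment:
    def test_extreme_proportions_inside_band_trigger_second_pass(self):
        assert mocs_needs_adjustment([0, 1, 2], [10, 10, 10], [4, 5, 10])
        assert not mocs_needs_adjustment([0, 1, 2], [10, 10, 10], [1, 5, 9])
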