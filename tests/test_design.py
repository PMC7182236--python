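"""Session-plan construction: cycle structure, regularity, targets, seeds."""

import dataclasses
import json

import numpy as np
import pytest

from fpvs import design
from fpvs.design import (Condition, ConfigurationError, SchedulingError,
                         build_sequence, build_session_plan, preset,
                         rgb_to_luminance, schedule_targets)


def rng(seed=0):
    return np.random.default_rng(seed)


class TestSequence:
    @pytest.mark.parametrize(
        "name, n_cycles, n_triplets",
        [("pilot1", 57, 19), ("exp1", 42, 14), ("exp2", 42, 14)],
    )
    def test_cycle_counts(self, name, n_cycles, n_triplets):
        spec = preset(name)
        seq = build_sequence(spec.conditions[0], spec, rng())
        assert len(seq.cycles) == n_cycles
        assert seq.n_triplets == n_triplets

    def test_regular_positions_carry_regular_category(self):
        spec = preset("pilot1")
        cond = Condition("upright", "angry")
        seq = build_sequence(cond, spec, rng(1))
        exprs = seq.expressions
        regular_pos = exprs[0::3]
        assert all(e == "angry" for e in regular_pos)
        assert len(regular_pos) == len(exprs) // 3
        # angry appears at exactly one third of cycles and nowhere else
        assert exprs.count("angry") == len(exprs) // 3

    def test_filler_balance_within_trial(self):
        spec = preset("pilot1")
        seq = build_sequence(Condition("upright", "neutral"), spec, rng(2))
        fillers = [e for i, e in enumerate(seq.expressions) if i % 3]
        counts = {e: fillers.count(e) for e in set(fillers)}
        assert set(counts) == {"angry", "happy"}
        assert max(counts.values()) - min(counts.values()) <= 1

    def test_irregular_triplets_all_distinct(self):
        spec = preset("pilot1")
        seq = build_sequence(Condition("upright", "irregular"), spec, rng(3))
        for t in range(seq.n_triplets):
            triplet = seq.expressions[3 * t : 3 * t + 3]
            assert len(set(triplet)) == 3

    @pytest.mark.parametrize("name", ["pilot1", "pilot2"])
    def test_filler_only_categories_never_regular(self, name):
        """Happy/disgusted must not occupy triplet-first positions in any of
        many generated sequences (spot-checks the hard constraint)."""
        spec = design.scaled(preset(name), 1)
        g = rng(4)
        regular_conds = [c for c in spec.conditions if c.regularity != "irregular"]
        for _ in range(300):
            for cond in regular_conds:
                seq = build_sequence(cond, spec, g)
                firsts = set(seq.expressions[0::3])
                assert firsts == {cond.regularity}
                assert not (firsts & set(design.FILLER_ONLY))

    def test_single_identity_trials(self):
        spec = preset("pilot2")
        seq = build_sequence(Condition("upright", "neutral", "high"), spec, rng(5))
        assert len({i for i, _ in seq.cycles}) == 1

    def test_no_token_repeat_across_consecutive_triplets_multi_identity(self):
        spec = preset("pilot1")
        g = rng(6)
        for cond in spec.conditions:
            for _ in range(20):
                seq = build_sequence(cond, spec, g)
                for t in range(seq.n_triplets - 1):
                    a = set(seq.cycles[3 * t : 3 * t + 3])
                    b = set(seq.cycles[3 * t + 3 : 3 * t + 6])
                    assert not (a & b)

    def test_unknown_condition_rejected(self):
        spec = preset("pilot1")
        with pytest.raises(ConfigurationError):
            build_sequence(Condition("upright", "angry", "high"), spec, rng())

    def test_non_triplet_duration_rejected(self):
        with pytest.raises(ConfigurationError):  # 56 cycles: whole, not a triplet multiple
            dataclasses.replace(preset("pilot1"), trial_duration=56 / 15)
        with pytest.raises(ConfigurationError):  # 56.25 cycles: not whole
            dataclasses.replace(preset("pilot1"), trial_duration=3.75)


class TestSessionPlan:
    def test_pilot1_trial_counts(self):
        plan = build_session_plan(preset("pilot1"), rng(7))
        assert len(plan) == 576
        labels = [s.condition.label for s in plan]
        assert all(labels.count(c.label) == 96 for c in preset("pilot1").conditions)

    def test_exp2_trial_counts(self):
        plan = build_session_plan(preset("exp2"), rng(8))
        assert len(plan) == 360
        # 60 per orientation x regularity condition, split over identities
        from collections import Counter

        counts = Counter((s.condition.orientation, s.condition.regularity)
                         for s in plan)
        assert set(counts.values()) == {60}
        assert sum(1 for s in plan if s.target_onsets_ms) == 0

    def test_single_cell_plan(self):
        spec = preset("pilot1")
        spec = dataclasses.replace(
            spec, conditions=(spec.conditions[0],), trials_per_condition=1,
            target_policy=None,
        )
        assert len(build_session_plan(spec, rng())) == 1

    def test_zero_conditions_rejected(self):
        with pytest.raises(ConfigurationError):
            dataclasses.replace(preset("pilot1"), conditions=())

    def test_same_seed_identical_plans(self):
        a = build_session_plan(preset("pilot1"), rng(42))
        b = build_session_plan(preset("pilot1"), rng(42))
        assert [(s.cycles, s.target_onsets_ms) for s in a] == [
            (s.cycles, s.target_onsets_ms) for s in b
        ]
        c = build_session_plan(preset("pilot1"), rng(43))
        assert [s.cycles for s in a] != [s.cycles for s in c]


class TestTargets:
    def test_pilot1_target_counts_and_gaps(self):
        spec = preset("pilot1")
        plan = build_session_plan(spec, rng(9))
        target_trials = [s for s in plan if s.target_onsets_ms]
        assert len(target_trials) == 216  # 36 per 96-trial condition
        for s in target_trials:
            assert 1 <= len(s.target_onsets_ms) <= 3
            gaps = np.diff(s.target_onsets_ms)
            assert np.all(gaps >= 600.0 - 1e-9)
            assert s.target_onsets_ms[-1] <= spec.trial_duration * 1000

    def test_exp1_min_gap_800(self):
        spec = preset("exp1")
        plan = build_session_plan(spec, rng(10))
        gaps = [
            g
            for s in plan
            for g in np.diff(s.target_onsets_ms)
        ]
        assert min(gaps) >= 800.0 - 1e-9

    def test_onsets_on_frame_grid(self):
        spec = preset("pilot1")
        plan = build_session_plan(spec, rng(11))
        frame_ms = 1000.0 / spec.refresh_rate
        for s in plan:
            for o in s.target_onsets_ms:
                assert abs(o / frame_ms - round(o / frame_ms)) < 1e-9

    def test_gap_invariant_over_many_sessions(self):
        """All scheduled gaps respect the configured minimum across many
        simulated (reduced) sessions."""
        spec = design.scaled(preset("pilot1"), 6)
        g = rng(12)
        for _ in range(200):
            plan = build_session_plan(spec, g)
            for s in plan:
                if len(s.target_onsets_ms) > 1:
                    assert np.diff(s.target_onsets_ms).min() >= 600.0 - 1e-9

    def test_absent_policy_is_identity(self):
        spec = preset("exp2")
        plan = [design.build_sequence(c, spec, rng()) for c in spec.conditions]
        out = schedule_targets(plan, spec, rng())
        assert all(not s.target_onsets_ms for s in out)

    def test_infeasible_interval_raises(self):
        spec = preset("pilot1")
        policy = dataclasses.replace(
            spec.target_policy, min_target_interval_ms=10_000.0,
            max_targets_per_trial=1,
        )
        bad = dataclasses.replace(
            spec, target_policy=dataclasses.replace(
                policy, target_duration_frames=500
            )
        )
        with pytest.raises(SchedulingError):
            build_session_plan(bad, rng())


class TestLuminance:
    @pytest.mark.parametrize(
        "rgb, expected",
        [((0, 0, 0), 0.0), ((255, 0, 0), 76.2195), ((100, 100, 100), 99.99)],
    )
    def test_examples(self, rgb, expected):
        assert rgb_to_luminance(*rgb) == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rgb_to_luminance(256, 0, 0)
        with pytest.raises(ValueError):
            rgb_to_luminance(0, -1, 0)

    def test_vectorized(self):
        out = rgb_to_luminance([0, 255], [0, 255], [0, 255])
        assert out == pytest.approx([0.0, 254.9745])


def test_plan_serialization_roundtrip(tmp_path):
    spec = design.scaled(preset("pilot1"), 2)
    plan = build_session_plan(spec, rng(13))
    path = tmp_path / "plan.json"
    design.plan_to_json(plan, path)
    back = design.plan_from_json(path)
    assert [s.cycles for s in back] == [s.cycles for s in plan]
    assert [s.target_onsets_ms for s in back] == [s.target_onsets_ms for s in plan]
    df = design.plan_to_frame(plan)
    assert list(df.columns) == [
        "trial", "condition", "cycle", "identity", "expression",
        "orientation", "target_onsets_ms",
    ]
    assert len(df) == sum(len(s.cycles) for s in plan)
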