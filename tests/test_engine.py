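"""Engine unit and property tests: spawn rules, speeds, handedness,
session mechanics, determinism, and the mirror symmetry of the playfield."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pydantic import ValidationError

from midline_game import (
    Handedness,
    StageConfig,
    ball_speed,
    default_config,
    initial_hat_position,
    mirror_config,
    mirror_x,
    run_session,
    run_session_detailed,
    spawn_position,
)
from midline_game.engine import DEFAULT_PARAMS, _ceil_steps
from midline_game.players import ReachPlayer, ScriptedPlayer, make_profile
from midline_game.session_io import session_to_json


class TestSpawnPosition:
    def test_stage1_is_affine_in_score(self, rng):
        cfg = default_config(1, x0=1.0, incr_dist=0.5)
        assert spawn_position(cfg, 0, rng) == 1.0
        assert spawn_position(cfg, 3, rng) == 2.5

    def test_stage1_clips_at_screen_edge(self, rng):
        cfg = default_config(1, x0=1.0, incr_dist=0.5)
        assert spawn_position(cfg, 100, rng) == cfg.x_max

    def test_stage2_draws_within_variance_band(self, rng):
        cfg = default_config(2, x0=1.5, dist_var=0.5)
        draws = [spawn_position(cfg, 0, rng) for _ in range(10_000)]
        assert min(draws) >= 1.0 and max(draws) <= 2.0

    def test_stage3_is_fixed_at_x0(self, rng):
        cfg = default_config(3, x0=1.5)
        assert all(spawn_position(cfg, s, rng) == 1.5 for s in range(10))

    def test_stage4_spans_the_playfield(self, rng):
        cfg = default_config(4)
        draws = np.array([spawn_position(cfg, 0, rng) for _ in range(10_000)])
        assert draws.min() >= -7.5 and draws.max() <= 7.5
        # continuous uniform over the full span: the extremes are approached
        assert draws.min() < -7.3 and draws.max() > 7.3


class TestBallSpeed:
    def test_constant_stages_ignore_score(self):
        for stage in (1, 2, 4):
            cfg = default_config(stage, constant_speed=2.0)
            assert ball_speed(cfg, 7) == 2.0

    @pytest.mark.parametrize("score,expected", [(0, 2.0), (5, 2.5)])
    def test_stage3_ramps_with_score(self, score, expected):
        cfg = default_config(3, speed0=2.0, incr_speed=0.1)
        assert ball_speed(cfg, score) == pytest.approx(expected)


class TestHandedness:
    def test_right_handed_starts_at_left_edge(self, stage1):
        assert initial_hat_position(Handedness.right, stage1) == -7.5

    def test_left_handed_starts_at_right_edge(self, stage1):
        assert initial_hat_position(Handedness.left, stage1) == 7.5

    def test_start_sides_mirror(self, stage1):
        assert initial_hat_position(Handedness.left, stage1) == -initial_hat_position(
            Handedness.right, stage1
        )


class TestMirror:
    @pytest.mark.parametrize("x,expected", [(1.5, -1.5), (0.0, 0.0)])
    def test_negation(self, x, expected):
        assert mirror_x(x) == expected

    @given(st.floats(-7.5, 7.5, allow_nan=False))
    def test_involution(self, x):
        assert mirror_x(mirror_x(x)) == x


class TestConfigValidation:
    def test_missing_required_parameter_is_rejected(self):
        with pytest.raises(ValidationError, match="incr_dist"):
            StageConfig(stage_id=1, x0=1.0)

    def test_unknown_stage_is_rejected(self):
        with pytest.raises(ValidationError, match="stage_id"):
            StageConfig(stage_id=5)

    def test_asymmetric_playfield_is_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            StageConfig(stage_id=4, x_min=-5.0, x_max=7.5)

    def test_zero_duration_is_rejected(self):
        with pytest.raises(ValidationError, match="duration"):
            StageConfig(stage_id=4, duration_s=0.0)


class TestSessionMechanics:
    def test_identical_inputs_give_byte_identical_records(self, stage1, impaired_severe):
        a = run_session(stage1, Handedness.right, impaired_severe, 7)
        b = run_session(stage1, Handedness.right, impaired_severe, 7)
        assert session_to_json(a) == session_to_json(b)

    def test_never_moving_player_misses_every_ball_at_one_spot(self, stage1):
        frozen = ReachPlayer(lapse_rate=1.0)
        record = run_session(stage1, Handedness.right, frozen, 3)
        assert record.final_score == 0
        assert all(ev.outcome == "missed" for ev in record.events)
        assert len({ev.spawn_x for ev in record.events}) == 1

    def test_miss_respawns_at_same_position_in_stages_1_and_3(self):
        for stage in (1, 3):
            cfg = default_config(stage)
            player = make_profile("impaired", 0.8)
            record = run_session(cfg, Handedness.right, player, 21)
            events = record.events
            assert any(ev.outcome == "missed" for ev in events[:-1])
            for prev, nxt in zip(events, events[1:]):
                if prev.outcome == "missed":
                    assert nxt.spawn_x == prev.spawn_x

    def test_stage1_spawns_are_non_decreasing(self, stage1, unimpaired):
        record = run_session(stage1, Handedness.right, unimpaired, 5)
        xs = [ev.spawn_x for ev in record.events]
        assert xs == sorted(xs)

    def test_stage3_fall_speed_tracks_score_before_each_ball(self, unimpaired):
        cfg = default_config(3)
        record = run_session(cfg, Handedness.right, unimpaired, 9)
        score_before = 0
        for ev in record.events:
            assert ev.fall_speed == pytest.approx(
                cfg.speed0 + cfg.incr_speed * score_before
            )
            score_before = ev.score_after

    def test_constant_speed_stages_have_uniform_fall_speed(self, unimpaired):
        for stage in (1, 2, 4):
            cfg = default_config(stage)
            record = run_session(cfg, Handedness.right, unimpaired, 9)
            assert {ev.fall_speed for ev in record.events} == {cfg.constant_speed}

    def test_score_counts_only_returned_balls(self, stage1, impaired_severe):
        record = run_session(stage1, Handedness.right, impaired_severe, 13)
        returned = sum(ev.return_time_s is not None for ev in record.events)
        assert record.final_score == returned
        scores = [ev.score_after for ev in record.events]
        assert scores == sorted(scores)

    def test_engine_counters_match_event_outcomes(self, stage1, impaired_severe):
        record, state = run_session_detailed(
            stage1, Handedness.right, impaired_severe, 17
        )
        assert state.balls_caught == sum(ev.outcome == "caught" for ev in record.events)
        assert state.balls_missed == sum(ev.outcome == "missed" for ev in record.events)
        assert state.balls_spawned >= len(record.events)
        assert state.score == record.final_score
        assert state.clock_s == stage1.duration_s


def perfect_player_oracle(cfg, params=DEFAULT_PARAMS, hat_speed=6.0, reaction=0.3):
    """Straight-line recomputation of a flawless stage-1 run: per ball,
    fall time plus homeward travel, quantized to the engine step."""
    dt = params.dt
    dur = round(cfg.duration_s / dt)
    home = cfg.x_min
    t, score = 0, 0
    spawns = []
    while t < dur:
        x = min(cfg.x_max, max(cfg.x_min, cfg.x0 + cfg.incr_dist * score))
        arrival = t + _ceil_steps(params.y_top / cfg.constant_speed, dt)
        if arrival > dur:
            break
        # hat leaves home after the reaction delay and waits under the ball
        start = t + _ceil_steps(reaction, dt)
        assert (arrival - start) * dt * hat_speed >= abs(x - home)
        spawns.append(x)
        ret = arrival + _ceil_steps(
            (abs(x - home) - params.return_tolerance) / hat_speed, dt
        )
        if ret > dur:
            break
        score += 1
        t = ret
    return score, spawns


class TestOracles:
    def test_perfect_player_matches_closed_form_cycle_count(self, stage1):
        player = ReachPlayer(lapse_rate=0.0)
        record = run_session(stage1, Handedness.right, player, 1)
        expected_score, expected_spawns = perfect_player_oracle(stage1)
        assert record.final_score == expected_score
        returned = [ev for ev in record.events if ev.return_time_s is not None]
        assert [ev.spawn_x for ev in returned] == expected_spawns

    @pytest.mark.parametrize("stage", [1, 3])
    def test_scripted_outcomes_match_straight_line_recurrences(self, stage):
        script = (True, False, True, True, False, True, False, False, True, True)
        cfg = default_config(stage)
        player = ScriptedPlayer(script=script)
        record = run_session(cfg, Handedness.right, player, 0)

        params = DEFAULT_PARAMS
        dt = params.dt
        dur = round(cfg.duration_s / dt)
        home = cfg.x_min
        t, score, i = 0, 0, 0
        expected = []  # (spawn_x, fall_speed, outcome, score_after)
        while t < dur:
            if stage == 1:
                x = min(cfg.x_max, max(cfg.x_min, cfg.x0 + cfg.incr_dist * score))
                speed = cfg.constant_speed
            else:
                x = cfg.x0
                speed = cfg.speed0 + cfg.incr_speed * score
            arrival = t + _ceil_steps(params.y_top / speed, dt)
            if arrival > dur:
                break
            if script[i % len(script)]:
                ret = arrival + _ceil_steps(
                    (abs(x - home) - params.return_tolerance) / player.hat_speed, dt
                )
                if ret > dur:
                    expected.append((x, speed, "caught", score))
                    break
                score += 1
                expected.append((x, speed, "caught", score))
                t = ret
            else:
                expected.append((x, speed, "missed", score))
                t += _ceil_steps((params.y_top - params.y_bottom) / speed, dt)
            i += 1

        got = [
            (ev.spawn_x, ev.fall_speed, ev.outcome, ev.score_after)
            for ev in record.events
        ]
        assert got == [
            (pytest.approx(x), pytest.approx(s), o, sc) for x, s, o, sc in expected
        ]
        assert record.final_score == score


config_strategy = st.builds(
    lambda stage, x0, dur: default_config(
        stage,
        duration_s=float(dur),
        **({"x0": x0} if stage != 4 else {}),
    ),
    stage=st.sampled_from([1, 2, 3, 4]),
    x0=st.floats(0.5, 4.0, allow_nan=False).map(lambda v: round(v, 2)),
    dur=st.integers(10, 45),
)


class TestSessionProperties:
    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        cfg=config_strategy,
        handed=st.sampled_from([Handedness.left, Handedness.right]),
        severity=st.floats(0, 1, allow_nan=False),
        seed=st.integers(0, 2**20),
    )
    def test_invariants_hold_for_randomized_sessions(self, cfg, handed, severity, seed):
        if handed is Handedness.left:
            cfg = mirror_config(cfg)
        player = make_profile("impaired", severity)
        record = run_session(cfg, handed, player, seed)
        prev_score = 0
        for ev in record.events:
            assert cfg.x_min <= ev.spawn_x <= cfg.x_max
            assert ev.score_after >= prev_score
            assert ev.spawn_time_s <= cfg.duration_s
            prev_score = ev.score_after
        assert record.final_score == sum(
            ev.return_time_s is not None for ev in record.events
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        x0=st.floats(0.5, 4.0, allow_nan=False).map(lambda v: round(v, 2)),
        stage=st.sampled_from([1, 2, 3, 4]),
        severity=st.floats(0, 1, allow_nan=False),
        seed=st.integers(0, 2**20),
    )
    def test_left_handed_play_is_the_exact_reflection(self, x0, stage, severity, seed):
        cfg = default_config(
            stage, duration_s=40.0, **({"x0": x0} if stage != 4 else {})
        )
        player = make_profile("impaired", severity)
        right = run_session(cfg, Handedness.right, player, seed)
        left = run_session(mirror_config(cfg), Handedness.left, player, seed)
        assert len(right.events) == len(left.events)
        for a, b in zip(right.events, left.events):
            assert b.spawn_x == pytest.approx(-a.spawn_x)
            assert (a.outcome, a.spawn_time_s, a.catch_time_s, a.return_time_s) == (
                b.outcome,
                b.spawn_time_s,
                b.catch_time_s,
                b.return_time_s,
            )
        assert right.final_score == left.final_score


def test_ceil_steps_is_exact_on_step_multiples():
    # 5.0 s at 20 ms must be exactly 250 steps despite float division
    assert _ceil_steps(5.0, 0.02) == 250
    assert _ceil_steps(0.0, 0.02) == 0
    assert _ceil_steps(0.021, 0.02) == 2
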