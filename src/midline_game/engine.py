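"""Deterministic, seedable, headless simulation of one game session.

The engine reproduces the serial game loop: a ball spawns at a position
given by the stage rule, falls at the stage's speed, and the player model
steers the hat toward it.  The ball is caught if the hat is within the
catch tolerance at the instant the ball reaches the hat plane; a caught
ball scores a point only once the hat has been carried back to its home
side.  A missed ball continues past the hat and off the bottom of the
screen before the next ball is served.  The spawn rule always uses the
score *after the last completed return*, so in stages 1 and 3 a missed
ball is re-served at the same position.

Time is discretised to a fixed step (default 20 ms) so that a session is
exactly reproducible from ``(config, handedness, player, seed)``; every
recorded time is a multiple of the step.

Internally the simulation always runs in the canonical right-handed frame
(home at ``x_min``, challenge growing rightward).  Left-handed sessions
are produced by mirroring the configuration into that frame, simulating,
and negating every recorded position — left-handed play is by construction
the exact reflection of right-handed play at the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Literal, Optional, Protocol

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .stages import ConfigurationError, Handedness, StageConfig, mirror_config

#: Reference timestamp used when a caller does not supply one; keeping it
#: fixed preserves the byte-identical determinism contract of run_session.
DEFAULT_STARTED_AT = datetime(2021, 11, 1, tzinfo=timezone.utc)


@dataclass(frozen=True)
class EngineParams:
    """Mechanical constants of the game world.

    ``y_top`` is the spawn height of a ball above the hat plane at
    ``y = 0``; with the default constant fall speed of 2 units/s a ball is
    in the air for 5 s, which yields roughly 16-17 catch opportunities in
    a 2-minute session for an engaged player.  ``y_bottom`` is the bottom
    edge of the screen: a missed ball resolves only once it has fallen off
    screen, so disengagement does not shorten the serve cadence.
    """

    dt: float = 0.02
    y_top: float = 10.0
    y_bottom: float = -6.0
    catch_half_width: float = 0.5
    return_tolerance: float = 0.25


DEFAULT_PARAMS = EngineParams()


class MovementPlanLike(Protocol):
    target_x: float
    delay_s: float
    lapse: bool


class Player(Protocol):
    """Anything that can drive the hat.

    ``plan_catch`` is consulted once per ball, at the spawn instant;
    ``return_delay_s`` once per catch, at the catch instant.  Both receive
    positions in the canonical right-handed frame.
    """

    hat_speed: float

    def plan_catch(
        self, hat_x: float, ball_x: float, home_x: float, rng: np.random.Generator
    ) -> MovementPlanLike: ...

    def return_delay_s(self, hat_x: float, home_x: float) -> float: ...


class BallEvent(BaseModel):
    """One served ball and its resolution."""

    model_config = ConfigDict(frozen=True)

    index: int
    spawn_x: float
    spawn_time_s: float
    fall_speed: float
    outcome: Literal["caught", "missed"]
    catch_time_s: float | None = None
    return_time_s: float | None = None
    score_after: int

    @model_validator(mode="after")
    def _validate(self) -> "BallEvent":
        if self.index < 1:
            raise ValueError("index must be >= 1")
        if self.fall_speed <= 0:
            raise ValueError("fall_speed must be positive")
        if self.score_after < 0:
            raise ValueError("score_after must be non-negative")
        if self.outcome == "caught":
            if self.catch_time_s is None:
                raise ValueError("caught ball must record catch_time_s")
            if self.catch_time_s < self.spawn_time_s:
                raise ValueError("catch_time_s must be >= spawn_time_s")
            if self.return_time_s is not None and self.return_time_s < self.catch_time_s:
                raise ValueError("return_time_s must be >= catch_time_s")
        else:
            if self.catch_time_s is not None or self.return_time_s is not None:
                raise ValueError("missed ball cannot record catch or return times")
        return self


class SessionRecord(BaseModel):
    """Complete telemetry of one two-minute session."""

    model_config = ConfigDict(frozen=True)

    session_id: str
    child_id: str
    handedness: Handedness
    stage_config: StageConfig
    events: tuple[BallEvent, ...]
    final_score: int
    rng_seed: int
    started_at: datetime

    @model_validator(mode="after")
    def _validate(self) -> "SessionRecord":
        cfg = self.stage_config
        eps = 1e-9
        prev_score = 0
        prev_time = -math.inf
        for i, ev in enumerate(self.events, start=1):
            if ev.index != i:
                raise ValueError(f"event indices must be consecutive from 1; got {ev.index} at position {i}")
            if ev.spawn_time_s < prev_time:
                raise ValueError("events must be ordered by spawn_time_s")
            if not (cfg.x_min - eps <= ev.spawn_x <= cfg.x_max + eps):
                raise ValueError(f"spawn_x {ev.spawn_x} outside playfield bounds")
            for t in (ev.spawn_time_s, ev.catch_time_s, ev.return_time_s):
                if t is not None and t > cfg.duration_s + eps:
                    raise ValueError("event times must not exceed duration_s")
            expected = prev_score + (1 if ev.return_time_s is not None else 0)
            if ev.score_after != expected:
                raise ValueError(
                    f"score_after {ev.score_after} inconsistent at event {i} (expected {expected})"
                )
            prev_score = ev.score_after
            prev_time = ev.spawn_time_s
        if self.final_score != prev_score:
            raise ValueError("final_score must equal score_after of the last event (0 if none)")
        return self


@dataclass
class GameState:
    """Live counters of a running (or finished) session."""

    score: int = 0
    hat_x: float = 0.0
    home_x: float = 0.0
    clock_s: float = 0.0
    balls_spawned: int = 0
    balls_caught: int = 0
    balls_missed: int = 0
    current_ball: Optional[BallEvent] = None


def mirror_x(x: float) -> float:
    """Reflect a position across the body midline."""
    return -x


def spawn_position(
    config: StageConfig, score: int, rng: np.random.Generator
) -> float:
    """Spawn abscissa for the next ball, given the current score.

    Stage rules (right-handed frame): stage 1 advances ``x0 + incr_dist *
    score``; stage 2 draws uniformly from ``x0 +/- dist_var``; stage 3 is
    fixed at ``x0``; stage 4 draws uniformly over the whole playfield.
    Results are clipped to the playfield bounds.
    """
    if score < 0:
        raise ValueError("score must be non-negative")
    s = config.stage_id
    if s == 1:
        x = config.x0 + config.incr_dist * score
    elif s == 2:
        x = config.x0 + rng.uniform(-config.dist_var, config.dist_var)
    elif s == 3:
        x = config.x0
    elif s == 4:
        x = rng.uniform(config.x_min, config.x_max)
    else:  # pragma: no cover - guarded by StageConfig validation
        raise ConfigurationError(f"unknown stage_id {s}")
    return float(min(config.x_max, max(config.x_min, x)))


def ball_speed(config: StageConfig, score: int) -> float:
    """Fall speed of the next ball: constant except in stage 3, which
    ramps as ``speed0 + incr_speed * score``."""
    if score < 0:
        raise ValueError("score must be non-negative")
    if config.stage_id == 3:
        speed = config.speed0 + config.incr_speed * score
    else:
        speed = config.constant_speed
    if speed <= 0:
        raise ConfigurationError("ball speed must be positive")
    return float(speed)


def initial_hat_position(handedness: Handedness, config: StageConfig) -> float:
    """Home side of the hat: opposite the dominant hand, so the first
    reach crosses the midline."""
    if handedness is Handedness.right:
        return config.x_min
    return config.x_max


def _ceil_steps(seconds: float, dt: float) -> int:
    """Number of whole time steps covering ``seconds`` (tolerant of float
    representation error, so e.g. 5.0 s at dt=0.02 is exactly 250 steps)."""
    return max(0, math.ceil(seconds / dt - 1e-9))


def run_session_detailed(
    config: StageConfig,
    handedness: Handedness,
    player: Player,
    seed: int,
    *,
    session_id: str | None = None,
    child_id: str = "anon",
    started_at: datetime = DEFAULT_STARTED_AT,
    params: EngineParams = DEFAULT_PARAMS,
) -> tuple[SessionRecord, GameState]:
    """Simulate one session and return the record plus final counters.

    Deterministic: identical inputs produce a byte-identical record.  A
    ball still on screen when the clock reaches ``duration_s`` is
    abandoned — counted as spawned but recorded as no event.
    """
    if config.duration_s <= 0:
        raise ConfigurationError("duration_s must be positive")
    dt = params.dt
    canonical = config if handedness is Handedness.right else mirror_config(config)
    sign = 1.0 if handedness is Handedness.right else -1.0

    rng = np.random.default_rng(seed)
    duration_steps = round(canonical.duration_s / dt)
    home = canonical.x_min
    hat = home
    t = 0
    score = 0
    events: list[BallEvent] = []
    state = GameState(home_x=sign * home, hat_x=sign * hat)

    while t < duration_steps:
        sx = spawn_position(canonical, score, rng)
        speed = ball_speed(canonical, score)
        state.balls_spawned += 1
        arrival = t + _ceil_steps(params.y_top / speed, dt)
        plan = player.plan_catch(hat_x=hat, ball_x=sx, home_x=home, rng=rng)
        if arrival > duration_steps:
            break  # ball still in flight at the session end: abandoned

        if plan.lapse:
            pos = hat
        else:
            start = t + _ceil_steps(plan.delay_s, dt)
            avail = max(0, arrival - start) * dt * player.hat_speed
            delta = plan.target_x - hat
            pos = hat + math.copysign(min(abs(delta), avail), delta) if delta else hat

        caught = (not plan.lapse) and abs(pos - sx) <= params.catch_half_width + 1e-9
        index = len(events) + 1
        if caught:
            state.balls_caught += 1
            hat = pos
            rdelay = player.return_delay_s(hat_x=hat, home_x=home)
            travel = max(0.0, abs(hat - home) - params.return_tolerance) / player.hat_speed
            ret = arrival + _ceil_steps(rdelay, dt) + _ceil_steps(travel, dt)
            if ret <= duration_steps:
                score += 1
                hat = home
                events.append(
                    BallEvent(
                        index=index,
                        spawn_x=sign * sx,
                        spawn_time_s=round(t * dt, 9),
                        fall_speed=speed,
                        outcome="caught",
                        catch_time_s=round(arrival * dt, 9),
                        return_time_s=round(ret * dt, 9),
                        score_after=score,
                    )
                )
                t = ret
            else:
                # caught, but the clock ran out before the hat got home
                events.append(
                    BallEvent(
                        index=index,
                        spawn_x=sign * sx,
                        spawn_time_s=round(t * dt, 9),
                        fall_speed=speed,
                        outcome="caught",
                        catch_time_s=round(arrival * dt, 9),
                        score_after=score,
                    )
                )
                t = duration_steps
        else:
            state.balls_missed += 1
            hat = pos
            events.append(
                BallEvent(
                    index=index,
                    spawn_x=sign * sx,
                    spawn_time_s=round(t * dt, 9),
                    fall_speed=speed,
                    outcome="missed",
                    score_after=score,
                )
            )
            t = t + _ceil_steps((params.y_top - params.y_bottom) / speed, dt)

    state.score = score
    state.hat_x = sign * hat
    state.home_x = sign * home
    state.clock_s = canonical.duration_s
    record = SessionRecord(
        session_id=session_id or f"{child_id}-stage{config.stage_id}-seed{seed}",
        child_id=child_id,
        handedness=handedness,
        stage_config=config,
        events=tuple(events),
        final_score=score,
        rng_seed=seed,
        started_at=started_at,
    )
    return record, state


def run_session(
    config: StageConfig,
    handedness: Handedness,
    player: Player,
    seed: int,
    **kwargs,
) -> SessionRecord:
    """Simulate one session; see :func:`run_session_detailed`."""
    record, _ = run_session_detailed(config, handedness, player, seed, **kwargs)
    return record
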