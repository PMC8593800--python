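"""Parametric simulated children that drive the game engine.

Two populations are modelled.  An *unimpaired* child tracks each ball
after a short reaction delay and carries it home, occasionally lapsing
(ignoring a ball outright).  A *midline-crossing-impaired* child shows the
avoidance phenotype therapists look for: when the task demands acting in
contralateral space — a ball past the midline on the side opposite the
child's home side — the child hesitates (``crossing_delay_s``) and, with a
probability growing with how far past the midline the ball lies
(``crossing_penalty`` per game-unit), refuses to cross and stops at the
midline.  The refusal decision is tied to the side of space the ball
occupies rather than to the hat's instantaneous position: a child who has
drifted to the midline is still facing a contralateral task, so avoidance
still applies.

These profiles are test instruments for the engine and score card, not
validated clinical models; no behavioural data for affected children
exist to fit them against.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta

import numpy as np

from .engine import SessionRecord
from .session_io import NotesRecord, RecorderRole

#: Severity-1 impairment: hesitation added to each contralateral movement,
#: and refusal probability per game-unit past the midline.  Frozen after a
#: single run of scripts/tune_profiles.py so that the Table-style score
#: thresholds separate the two populations.
MAX_CROSSING_DELAY_S = 1.5
MAX_CROSSING_PENALTY = 0.5

_UNIMPAIRED = dict(
    hat_speed=6.0,
    reaction_delay_s=0.3,
    lapse_rate=0.02,
    crossing_delay_s=0.0,
    crossing_penalty=0.0,
)

#: Named presets addressable from the CLI: name -> (kind, severity).
PROFILES: dict[str, tuple[str, float]] = {
    "unimpaired": ("unimpaired", 0.0),
    "impaired-mild": ("impaired", 0.35),
    "impaired-severe": ("impaired", 1.0),
}


@dataclass(frozen=True)
class MovementPlan:
    """Where the hat is headed and when it starts moving."""

    target_x: float
    delay_s: float
    lapse: bool = False
    refused: bool = False


@dataclass(frozen=True)
class ReachPlayer:
    """Parametric player model; see the module docstring.

    With ``crossing_delay_s = 0`` and ``crossing_penalty = 0`` the model
    is exactly the unimpaired profile.
    """

    hat_speed: float = 6.0
    reaction_delay_s: float = 0.3
    lapse_rate: float = 0.02
    crossing_delay_s: float = 0.0
    crossing_penalty: float = 0.0

    def __post_init__(self) -> None:
        if self.hat_speed <= 0:
            raise ValueError("hat_speed must be positive")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")
        if self.crossing_delay_s < 0:
            raise ValueError("crossing_delay_s must be non-negative")
        if self.crossing_penalty < 0:
            raise ValueError("crossing_penalty must be non-negative")
        if self.reaction_delay_s < 0:
            raise ValueError("reaction_delay_s must be non-negative")

    @staticmethod
    def _overshoot(ball_x: float, home_x: float) -> float:
        """How far the ball lies past the midline, measured in the
        crossing direction (positive iff the task is contralateral)."""
        direction = 1.0 if home_x < 0 else -1.0
        return ball_x * direction

    def plan_catch(
        self, hat_x: float, ball_x: float, home_x: float, rng: np.random.Generator
    ) -> MovementPlan:
        """Decide the response to a freshly served ball."""
        if self.lapse_rate > 0 and rng.random() < self.lapse_rate:
            return MovementPlan(target_x=hat_x, delay_s=0.0, lapse=True)
        delay = self.reaction_delay_s
        overshoot = self._overshoot(ball_x, home_x)
        if overshoot > 0:
            delay += self.crossing_delay_s
            if self.crossing_penalty > 0:
                p_refuse = min(1.0, self.crossing_penalty * overshoot)
                if rng.random() < p_refuse:
                    return MovementPlan(target_x=0.0, delay_s=delay, refused=True)
        return MovementPlan(target_x=ball_x, delay_s=delay)

    def return_delay_s(self, hat_x: float, home_x: float) -> float:
        """Hesitation before carrying a caught ball home.

        The return is planned while the ball falls, so no reaction delay
        applies; impaired children hesitate again if the homeward move
        starts in contralateral space.
        """
        if self._overshoot(hat_x, home_x) > 0:
            return self.crossing_delay_s
        return 0.0


@dataclass
class ScriptedPlayer:
    """Test instrument replaying a fixed catch/miss outcome sequence.

    ``script[i]`` decides ball ``i`` (True = catch).  The hat is fast
    enough to reach any position, so a True entry always catches provided
    the ball spawns away from the current hat position by more than the
    catch tolerance on a False entry.
    """

    script: tuple[bool, ...]
    hat_speed: float = 1000.0

    def __post_init__(self) -> None:
        self._i = 0

    def plan_catch(
        self, hat_x: float, ball_x: float, home_x: float, rng: np.random.Generator
    ) -> MovementPlan:
        want = self.script[self._i % len(self.script)]
        self._i += 1
        if want:
            return MovementPlan(target_x=ball_x, delay_s=0.0)
        return MovementPlan(target_x=hat_x, delay_s=0.0, lapse=True)

    def return_delay_s(self, hat_x: float, home_x: float) -> float:
        return 0.0


def make_profile(kind: str, severity: float = 0.0, seed: int | None = None) -> ReachPlayer:
    """Build a player from a documented default parameterisation.

    ``severity`` in [0, 1] scales the crossing hesitation and refusal
    penalty linearly from zero; at severity 0 the impaired profile equals
    the unimpaired one.  ``seed`` is accepted for interface stability but
    unused: profiles are deterministic functions of (kind, severity).
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    if kind == "unimpaired":
        return ReachPlayer(**_UNIMPAIRED)
    if kind == "impaired":
        return ReachPlayer(
            **{
                **_UNIMPAIRED,
                "crossing_delay_s": MAX_CROSSING_DELAY_S * severity,
                "crossing_penalty": MAX_CROSSING_PENALTY * severity,
            }
        )
    raise ValueError(f"unknown profile kind {kind!r}")


def profile_by_name(name: str) -> tuple[ReachPlayer, float]:
    """Resolve a CLI preset name to ``(player, severity)``."""
    try:
        kind, severity = PROFILES[name]
    except KeyError:
        raise ValueError(
            f"unknown profile {name!r}; expected one of {sorted(PROFILES)}"
        ) from None
    return make_profile(kind, severity), severity


def synthesize_notes(
    session: SessionRecord,
    severity: float,
    rng: np.random.Generator,
    *,
    recorder_role: RecorderRole = RecorderRole.caretaker,
) -> NotesRecord:
    """Generate the observational notes a caretaker would file.

    Each observational item is independently unfavourable with
    probability ``0.05 + 0.85 * severity``: even a typically developing
    child occasionally needs a verbal cue, while a severely affected child
    shows the avoidance behaviours in nearly every session.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    p_bad = 0.05 + 0.85 * severity
    bad = rng.random(5) < p_bad
    return NotesRecord(
        session_id=session.session_id,
        recorder_role=recorder_role,
        followed_instructions=not bad[0],
        maintained_visual_focus=not bad[1],
        gross_body_adjustments=bool(bad[2]),
        verbal_cues_required=bool(bad[3]),
        distance_pattern_observed=bool(bad[4]),
        free_text="",
        completed_at=session.started_at + timedelta(seconds=session.stage_config.duration_s + 60),
    )
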