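"""The eight-criterion screening score card.

Three criteria come straight from the gameplay telemetry — balls caught
(> 14), balls missed (< 4), and the average time between served balls
(< 7.5 s) — with the printed thresholds read strictly, so a boundary
value earns no point.  Criterion 4 asks whether performance degrades as
the challenge grows: for stages 1, 2 and 4 the challenge is the spawn
distance past the midline, for stage 3 it is the fall speed.  By default
it is scored from the caretaker's observation, matching how the card is
filled in practice; an automated permutation test on the session data is
available as an opt-in, and the provenance of every point is recorded.
Criteria 5-8 are purely observational: instruction-following, sustained
visual focus, absence of gross compensatory body movement, and no need
for verbal cues.

A child scoring at least 4 of the 8 points is classified as showing no
indication of midline-crossing pathology; below that, further assessment
is recommended.  The criteria are designed to be read together — the card
reports every point, not just the total.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING, Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .engine import SessionRecord
from .stages import Handedness

if TYPE_CHECKING:  # pragma: no cover
    from .session_io import NotesRecord

#: The score-card criteria for the assessment stage: (observation, rule).
#: Other stages share the card; only the criterion-4 challenge variable
#: changes (spawn distance for stages 1/2/4, fall speed for stage 3).
CRITERIA: tuple[tuple[str, str], ...] = (
    ("Balls caught", "> 14"),
    ("Balls missed", "< 4"),
    ("Average time between balls", "< 7.5 s"),
    ("Distance increasing", "no pattern of misses with challenge"),
    ("Follow instructions", "yes"),
    ("Eye movements", "maintained visual focus"),
    ("Body movement", "no gross adjustments"),
    ("General behavior", "no verbal cues"),
)

#: Total points needed to report no indication of pathology.
CLASSIFICATION_THRESHOLD = 4

Provenance = Literal["gameplay", "observation", "automated"]


class Classification(str, Enum):
    no_pathology_indicated = "no_pathology_indicated"
    further_assessment_needed = "further_assessment_needed"


class PatternTestError(ValueError):
    """The distance-pattern test was asked of unusable data."""


@dataclass(frozen=True)
class GameplayStats:
    """Per-session aggregates derived deterministically from telemetry.

    ``challenge`` is the spawn distance measured in the crossing
    direction (positive = past the midline on the contralateral side),
    so left- and right-handed sessions are directly comparable.
    ``mean_inter_ball_time_s`` is ``None`` when fewer than two balls were
    served, in which case criterion 3 cannot be scored.
    """

    balls_caught: int = 0
    balls_missed: int = 0
    mean_inter_ball_time_s: float | None = None
    spawn_x: tuple[float, ...] = ()
    outcomes: tuple[str, ...] = ()
    challenge: tuple[float, ...] = ()
    fall_speed: tuple[float, ...] = ()

    @property
    def timing_defined(self) -> bool:
        return self.mean_inter_ball_time_s is not None


class ScoreCard(BaseModel):
    """The filled-in card: eight binary points, their total, and the
    screening classification."""

    model_config = ConfigDict(frozen=True)

    session_id: str | None = None
    stage_id: int
    criterion_points: tuple[int, int, int, int, int, int, int, int]
    total: int
    classification: Classification
    provenance: tuple[str, str, str, str, str, str, str, str]
    incomplete: bool = False

    @model_validator(mode="after")
    def _validate(self) -> "ScoreCard":
        if any(p not in (0, 1) for p in self.criterion_points):
            raise ValueError("criterion points must be 0 or 1")
        if self.total != sum(self.criterion_points):
            raise ValueError("total must equal the sum of criterion points")
        expected = (
            Classification.no_pathology_indicated
            if self.total >= CLASSIFICATION_THRESHOLD
            else Classification.further_assessment_needed
        )
        if self.classification is not expected:
            raise ValueError(
                f"classification inconsistent with total {self.total}"
            )
        return self


def classify(total: int) -> Classification:
    """Screening decision for a card total: >= 4 points means no
    pathology indicated."""
    if total >= CLASSIFICATION_THRESHOLD:
        return Classification.no_pathology_indicated
    return Classification.further_assessment_needed


def assemble_card(
    points,
    *,
    stage_id: int = 1,
    provenance=None,
    session_id: str | None = None,
    incomplete: bool = False,
) -> ScoreCard:
    """Build a consistent :class:`ScoreCard` from eight binary points."""
    points = tuple(int(p) for p in points)
    if len(points) != len(CRITERIA):
        raise ValueError(f"expected {len(CRITERIA)} criterion points")
    if provenance is None:
        provenance = ("gameplay",) * 3 + ("observation",) * 5
    total = sum(points)
    return ScoreCard(
        session_id=session_id,
        stage_id=stage_id,
        criterion_points=points,
        total=total,
        classification=classify(total),
        provenance=tuple(provenance),
        incomplete=incomplete,
    )


def extract_stats(session: SessionRecord) -> GameplayStats:
    """Reduce a session record to the quantities the card scores."""
    events = session.events
    direction = 1.0 if session.handedness is Handedness.right else -1.0
    spawn_x = tuple(ev.spawn_x for ev in events)
    times = [ev.spawn_time_s for ev in events]
    mean_gap = float(np.mean(np.diff(times))) if len(times) >= 2 else None
    return GameplayStats(
        balls_caught=sum(ev.outcome == "caught" for ev in events),
        balls_missed=sum(ev.outcome == "missed" for ev in events),
        mean_inter_ball_time_s=mean_gap,
        spawn_x=spawn_x,
        outcomes=tuple(ev.outcome for ev in events),
        challenge=tuple(x * direction for x in spawn_x),
        fall_speed=tuple(ev.fall_speed for ev in events),
    )


def score_gameplay_criteria(stats: GameplayStats) -> tuple[int, int, int]:
    """Points for criteria 1-3.  Thresholds are strict: caught must
    exceed 14, missed stay below 4, and the mean inter-ball gap stay
    below 7.5 s; landing exactly on a threshold earns no point.  An
    undefined gap (fewer than two balls) scores criterion 3 as 0."""
    p1 = 1 if stats.balls_caught > 14 else 0
    p2 = 1 if stats.balls_missed < 4 else 0
    p3 = (
        1
        if stats.timing_defined and stats.mean_inter_ball_time_s < 7.5
        else 0
    )
    return (p1, p2, p3)


def _challenge_variable(stats: GameplayStats, stage_id: int) -> np.ndarray:
    if stage_id == 3:
        return np.asarray(stats.fall_speed, dtype=float)
    return np.asarray(stats.challenge, dtype=float)


def detect_distance_pattern(
    stats: GameplayStats,
    stage_id: int,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[bool, float]:
    """Automated criterion-4 test: do misses concentrate at higher
    challenge?

    Computes the point-biserial correlation between the per-ball
    challenge variable and the miss indicator, with a one-sided p-value
    from a seeded permutation null (miss labels shuffled across balls).
    A pattern is declared iff the correlation is positive and p < 0.05.
    Degenerate sessions (all balls caught, all missed, or no variation in
    challenge) carry no evidence: ``(False, 1.0)``.
    """
    if n_permutations < 1:
        raise PatternTestError("n_permutations must be >= 1")
    x = _challenge_variable(stats, stage_id)
    y = np.asarray([1.0 if o == "missed" else 0.0 for o in stats.outcomes])
    if x.size != y.size:
        raise PatternTestError("challenge and outcome vectors differ in length")
    if x.size < 2 or np.ptp(y) == 0 or np.ptp(x) == 0:
        return (False, 1.0)

    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    r_obs = float(xc @ yc / denom)

    # Under label permutation the means and variances of x and y are
    # fixed, so comparing the cross-products xc @ y_perm is equivalent to
    # comparing correlations.
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(y, (n_permutations, 1)), axis=1)
    stat_obs = float(xc @ y)
    stat_perm = perms @ xc
    n_ge = int(np.sum(stat_perm >= stat_obs - 1e-12))
    p_value = (1 + n_ge) / (n_permutations + 1)
    pattern = bool(r_obs > 0 and p_value < 0.05)
    return (pattern, float(p_value))


def score_card(
    stats: GameplayStats,
    notes: "NotesRecord | None",
    stage_id: int,
    *,
    session_id: str | None = None,
    use_automated_pattern: bool = False,
    n_permutations: int = 999,
    seed: int = 0,
) -> ScoreCard:
    """Fill in the full card from gameplay stats and observational notes.

    Criterion 4 comes from the notes by default (that is how the card is
    used in practice); pass ``use_automated_pattern=True`` to substitute
    the permutation test.  Missing notes leave criteria 4-8 at 0 and flag
    the card incomplete rather than failing.
    """
    points = list(score_gameplay_criteria(stats))
    provenance: list[str] = ["gameplay"] * 3
    incomplete = not stats.timing_defined

    if use_automated_pattern:
        pattern, _ = detect_distance_pattern(
            stats, stage_id, n_permutations=n_permutations, seed=seed
        )
        points.append(0 if pattern else 1)
        provenance.append("automated")
    elif notes is not None and notes.distance_pattern_observed is not None:
        points.append(0 if notes.distance_pattern_observed else 1)
        provenance.append("observation")
    else:
        points.append(0)
        provenance.append("observation")
        incomplete = True

    if notes is None:
        points.extend([0, 0, 0, 0])
        incomplete = True
    else:
        observations = (
            notes.followed_instructions is True,
            notes.maintained_visual_focus is True,
            notes.gross_body_adjustments is False,
            notes.verbal_cues_required is False,
        )
        points.extend(1 if ok else 0 for ok in observations)
        if not notes.is_complete:
            incomplete = True
    provenance.extend(["observation"] * 4)

    return assemble_card(
        points,
        stage_id=stage_id,
        provenance=provenance,
        session_id=session_id,
        incomplete=incomplete,
    )
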