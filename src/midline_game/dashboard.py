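"""Therapist-facing aggregates for remote monitoring.

Per session: catch counts and rate, serve cadence, the farthest crossing
distance at which a ball was caught and returned, and a miss-by-distance
profile over equal-width bins of the playfield — the view in which a
child who misses more as the distance grows stands out.  Across sessions:
an ordered per-child progress table and an ordinary-least-squares trend
of the score-card total per stage, in points per session.

All metrics are pure functions of their inputs; exports are tidy CSV and
JSON.  Rendering is a thin optional layer over matplotlib.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .engine import SessionRecord
from .scoring import ScoreCard, extract_stats
from .stages import Handedness


class ConsistencyError(ValueError):
    """Inputs that should describe the same session/child do not."""


class DistanceBin(BaseModel):
    model_config = ConfigDict(frozen=True)

    lo: float
    hi: float
    attempts: int
    misses: int


class SessionSummary(BaseModel):
    """One session reduced to the quantities the dashboard charts.

    ``miss_by_distance`` bins the signed crossing distance (positive =
    past the midline on the contralateral side), partitioning the
    playfield; bin attempts sum to ``balls_caught + balls_missed``.
    """

    model_config = ConfigDict(frozen=True)

    session_id: str
    child_id: str
    stage_id: int
    date: datetime
    balls_caught: int
    balls_missed: int
    catch_rate: float | None
    mean_inter_ball_time_s: float | None
    max_distance_reached: float | None
    miss_by_distance: tuple[DistanceBin, ...]
    score_card_total: int
    flagged_empty: bool = False


class SessionPoint(BaseModel):
    model_config = ConfigDict(frozen=True)

    date: datetime
    stage_id: int
    score_card_total: int
    catch_rate: float | None


class ProgressReport(BaseModel):
    """Cross-session view of one child: ordered per-session points and a
    per-stage OLS slope of the score-card total (``None`` with fewer than
    two sessions of that stage)."""

    model_config = ConfigDict(frozen=True)

    child_id: str
    sessions: tuple[SessionPoint, ...]
    trend_slopes: dict[int, float | None]


def summarize_session(
    session: SessionRecord, card: ScoreCard, n_bins: int = 6
) -> SessionSummary:
    """Aggregate one session/card pair into a dashboard row."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if card.session_id is not None and card.session_id != session.session_id:
        raise ConsistencyError(
            f"card is for session {card.session_id!r}, not {session.session_id!r}"
        )
    stats = extract_stats(session)
    resolved = stats.balls_caught + stats.balls_missed
    catch_rate = stats.balls_caught / resolved if resolved else None

    direction = 1.0 if session.handedness is Handedness.right else -1.0
    returned = [
        ev.spawn_x * direction
        for ev in session.events
        if ev.return_time_s is not None
    ]
    max_distance = max(returned) if returned else None

    lo_edge = session.stage_config.x_min
    hi_edge = session.stage_config.x_max
    edges = np.linspace(lo_edge, hi_edge, n_bins + 1)
    bins = []
    challenge = np.asarray(stats.challenge)
    missed = np.asarray([o == "missed" for o in stats.outcomes], dtype=bool)
    # np.digitize puts the right edge of the last bin into bin n; fold it back
    idx = np.clip(np.digitize(challenge, edges) - 1, 0, n_bins - 1)
    for b in range(n_bins):
        mask = idx == b
        bins.append(
            DistanceBin(
                lo=float(edges[b]),
                hi=float(edges[b + 1]),
                attempts=int(mask.sum()),
                misses=int((mask & missed).sum()),
            )
        )

    return SessionSummary(
        session_id=session.session_id,
        child_id=session.child_id,
        stage_id=session.stage_config.stage_id,
        date=session.started_at,
        balls_caught=stats.balls_caught,
        balls_missed=stats.balls_missed,
        catch_rate=catch_rate,
        mean_inter_ball_time_s=stats.mean_inter_ball_time_s,
        max_distance_reached=max_distance,
        miss_by_distance=tuple(bins),
        score_card_total=card.total,
        flagged_empty=resolved == 0,
    )


def build_progress(child_sessions: list[SessionSummary]) -> ProgressReport:
    """Assemble a per-child progress report from session summaries."""
    if not child_sessions:
        raise ConsistencyError("at least one session summary is required")
    child_ids = {s.child_id for s in child_sessions}
    if len(child_ids) > 1:
        raise ConsistencyError(f"mixed child ids: {sorted(child_ids)}")
    ordered = sorted(child_sessions, key=lambda s: (s.date, s.session_id))
    points = tuple(
        SessionPoint(
            date=s.date,
            stage_id=s.stage_id,
            score_card_total=s.score_card_total,
            catch_rate=s.catch_rate,
        )
        for s in ordered
    )
    slopes: dict[int, float | None] = {}
    for stage in sorted({s.stage_id for s in ordered}):
        totals = [s.score_card_total for s in ordered if s.stage_id == stage]
        if len(totals) < 2:
            slopes[stage] = None
        else:
            ordinals = np.arange(len(totals), dtype=float)
            slopes[stage] = float(np.polyfit(ordinals, totals, 1)[0])
    return ProgressReport(
        child_id=child_sessions[0].child_id, sessions=points, trend_slopes=slopes
    )


def summaries_to_csv(summaries: list[SessionSummary], dest) -> None:
    """Tidy CSV, one row per session (bins flattened as ``miss_bin_k``)."""
    rows = []
    for s in summaries:
        row = {
            "session_id": s.session_id,
            "child_id": s.child_id,
            "stage_id": s.stage_id,
            "date": s.date.isoformat(),
            "balls_caught": s.balls_caught,
            "balls_missed": s.balls_missed,
            "catch_rate": s.catch_rate,
            "mean_inter_ball_time_s": s.mean_inter_ball_time_s,
            "max_distance_reached": s.max_distance_reached,
            "score_card_total": s.score_card_total,
        }
        for k, b in enumerate(s.miss_by_distance):
            row[f"attempts_bin_{k}"] = b.attempts
            row[f"misses_bin_{k}"] = b.misses
        rows.append(row)
    pd.DataFrame(rows).to_csv(dest, index=False)


def write_progress(report: ProgressReport, dest) -> None:
    text = json.dumps(report.model_dump(mode="json"), indent=2, sort_keys=True) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text, encoding="utf-8")


def plot_miss_profile(summary: SessionSummary, ax=None):
    """Bar chart of miss fraction per distance bin (convenience layer)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = [(b.lo + b.hi) / 2 for b in summary.miss_by_distance]
    fractions = [
        b.misses / b.attempts if b.attempts else 0.0
        for b in summary.miss_by_distance
    ]
    width = summary.miss_by_distance[0].hi - summary.miss_by_distance[0].lo
    ax.bar(centers, fractions, width=0.9 * width)
    ax.set_xlabel("crossing distance (game units)")
    ax.set_ylabel("miss fraction")
    ax.set_title(f"{summary.session_id}: misses by distance")
    return ax


def plot_progress(report: ProgressReport, ax=None):
    """Score-card totals over sessions, one line per stage."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for stage in sorted({p.stage_id for p in report.sessions}):
        totals = [p.score_card_total for p in report.sessions if p.stage_id == stage]
        ax.plot(range(len(totals)), totals, marker="o", label=f"stage {stage}")
    ax.set_xlabel("session ordinal")
    ax.set_ylabel("score-card total (0-8)")
    ax.set_title(f"progress: {report.child_id}")
    ax.legend()
    return ax
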