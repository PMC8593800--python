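"""Versioned, validated serialization of the telehealth wire format.

Sessions, observational notes, and score cards travel between the home
and the therapist as JSON documents wrapped in a small envelope::

    {"schema": "midline-game/session", "version": "1.0", "record": {...}}

Reads validate every record invariant and reject unknown schema versions
with a clear error; known older versions are migrated forward (notes 1.0
files predate the optional ``distance_pattern_observed`` item and gain it
as ``null``).  Score cards additionally flatten to a one-row-per-session
CSV for the dashboard.  Child identifiers are pseudonymous opaque
strings and timestamps are ISO-8601; no personal data enters the schema.
"""

from __future__ import annotations

import json
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Any, Callable

import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError

from .engine import SessionRecord
from .scoring import CRITERIA, ScoreCard, assemble_card
from .stages import Handedness, StageConfig

SCHEMA_PREFIX = "midline-game"

CURRENT_VERSIONS = {
    "session": "1.0",
    "notes": "1.1",
    "card": "1.0",
}


class SchemaError(ValueError):
    """The document does not match a known schema/version."""


class RecorderRole(str, Enum):
    occupational_therapist = "occupational_therapist"
    caretaker = "caretaker"
    parent = "parent"
    teacher = "teacher"
    guardian = "guardian"


class NotesRecord(BaseModel):
    """The structured notes page completed after each stage.

    The five observational booleans mirror the score card's
    observation-based criteria; ``None`` marks an item the recorder left
    blank.  Incomplete notes are representable — they are flagged, not
    rejected, because a partially filled page still carries information.
    """

    model_config = ConfigDict(frozen=True)

    session_id: str
    recorder_role: RecorderRole
    followed_instructions: bool | None = None
    maintained_visual_focus: bool | None = None
    gross_body_adjustments: bool | None = None
    verbal_cues_required: bool | None = None
    distance_pattern_observed: bool | None = None
    free_text: str = ""
    completed_at: datetime

    @property
    def is_complete(self) -> bool:
        """True when the four core observational items are all present."""
        return None not in (
            self.followed_instructions,
            self.maintained_visual_focus,
            self.gross_body_adjustments,
            self.verbal_cues_required,
        )


def _migrate_notes_1_0(payload: dict) -> dict:
    """Notes 1.0 predates the distance-pattern observation item."""
    payload = dict(payload)
    payload.setdefault("distance_pattern_observed", None)
    return payload


_MIGRATIONS: dict[tuple[str, str], tuple[str, Callable[[dict], dict]]] = {
    ("notes", "1.0"): ("1.1", _migrate_notes_1_0),
}

_MODELS = {
    "session": SessionRecord,
    "notes": NotesRecord,
    "card": ScoreCard,
}


def _dumps(kind: str, record: BaseModel) -> str:
    envelope = {
        "schema": f"{SCHEMA_PREFIX}/{kind}",
        "version": CURRENT_VERSIONS[kind],
        "record": record.model_dump(mode="json"),
    }
    return json.dumps(envelope, indent=2, sort_keys=True) + "\n"


def _write(kind: str, record: BaseModel, dest) -> None:
    text = _dumps(kind, record)
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text, encoding="utf-8")


def _read(kind: str, source) -> BaseModel:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    try:
        envelope = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    if not isinstance(envelope, dict) or "record" not in envelope:
        raise SchemaError("missing envelope with a 'record' field")
    expected_schema = f"{SCHEMA_PREFIX}/{kind}"
    if envelope.get("schema") != expected_schema:
        raise SchemaError(
            f"expected schema {expected_schema!r}, got {envelope.get('schema')!r}"
        )
    version = envelope.get("version")
    payload = envelope["record"]
    while version != CURRENT_VERSIONS[kind]:
        step = _MIGRATIONS.get((kind, version))
        if step is None:
            raise SchemaError(
                f"unsupported {kind} schema version {version!r} "
                f"(current: {CURRENT_VERSIONS[kind]!r})"
            )
        version, migrate = step
        payload = migrate(payload)
    return _MODELS[kind].model_validate(payload)


def write_session(record: SessionRecord, dest) -> None:
    _write("session", record, dest)


def read_session(source) -> SessionRecord:
    return _read("session", source)


def write_notes(record: NotesRecord, dest) -> None:
    _write("notes", record, dest)


def read_notes(source) -> NotesRecord:
    return _read("notes", source)


def write_card(record: ScoreCard, dest) -> None:
    _write("card", record, dest)


def read_card(source) -> ScoreCard:
    return _read("card", source)


def session_to_json(record: SessionRecord) -> str:
    """Serialized form of a session, byte-identical for identical records."""
    return _dumps("session", record)


def json_schemas() -> dict[str, dict]:
    """Published JSON schemas of the four wire-format record types."""
    return {
        "session": SessionRecord.model_json_schema(),
        "notes": NotesRecord.model_json_schema(),
        "card": ScoreCard.model_json_schema(),
        "stage_config": StageConfig.model_json_schema(),
    }


# ---------------------------------------------------------------------------
# Flat CSV export of score cards (comma, UTF-8, header row)

_CARD_COLUMNS = (
    ["session_id", "stage_id"]
    + [f"criterion_{i}" for i in range(1, len(CRITERIA) + 1)]
    + ["total", "classification", "incomplete", "provenance"]
)


def cards_to_csv(cards: list[ScoreCard], dest) -> None:
    """One row per session, re-importable with :func:`cards_from_csv`."""
    rows = []
    for card in cards:
        row: dict[str, Any] = {
            "session_id": card.session_id or "",
            "stage_id": card.stage_id,
        }
        for i, p in enumerate(card.criterion_points, start=1):
            row[f"criterion_{i}"] = p
        row["total"] = card.total
        row["classification"] = card.classification.value
        row["incomplete"] = card.incomplete
        row["provenance"] = "|".join(card.provenance)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=_CARD_COLUMNS)
    frame.to_csv(dest, index=False)


def cards_from_csv(source) -> list[ScoreCard]:
    frame = pd.read_csv(source, keep_default_na=False)
    missing = set(_CARD_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"score-card CSV missing columns: {sorted(missing)}")
    cards = []
    for _, row in frame.iterrows():
        points = [int(row[f"criterion_{i}"]) for i in range(1, len(CRITERIA) + 1)]
        card = assemble_card(
            points,
            stage_id=int(row["stage_id"]),
            provenance=tuple(str(row["provenance"]).split("|")),
            session_id=str(row["session_id"]) or None,
            incomplete=str(row["incomplete"]).lower() in ("true", "1"),
        )
        if card.classification.value != row["classification"]:
            raise SchemaError(
                f"classification column inconsistent with total for "
                f"session {row['session_id']!r}"
            )
        cards.append(card)
    return cards


# ---------------------------------------------------------------------------
# Game configuration files (YAML or JSON)


def load_game_config(source) -> tuple[StageConfig, Handedness | None, int | None]:
    """Read a stage-configuration file.

    Recognised keys are the :class:`StageConfig` fields plus optional
    ``handedness`` and ``seed``; anything else is an error naming the
    offending key.
    """
    import yaml

    if hasattr(source, "read"):
        raw = source.read()
    else:
        raw = Path(source).read_text(encoding="utf-8")
    data = yaml.safe_load(raw)
    if not isinstance(data, dict):
        raise SchemaError("configuration file must contain a mapping")
    data = dict(data)
    handedness = data.pop("handedness", None)
    if handedness is not None:
        handedness = Handedness(handedness)
    seed = data.pop("seed", None)
    if seed is not None:
        seed = int(seed)
    allowed = set(StageConfig.model_fields)
    unknown = set(data) - allowed
    if unknown:
        raise SchemaError(f"unknown configuration keys: {sorted(unknown)}")
    try:
        config = StageConfig(**data)
    except ValidationError as exc:
        raise SchemaError(f"invalid stage configuration: {exc}") from exc
    return config, handedness, seed
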