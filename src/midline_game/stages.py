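"""Stage configuration for the four-stage midline-crossing catch game.

The game takes place on a horizontal axis spanning ``[-7.5, +7.5]`` game
units with the body midline at ``x = 0``.  A hat (the child's avatar) slides
along this axis; balls fall from the top of the screen at stage-dependent
positions and speeds, and a point is earned only after a caught ball is
carried back to the hat's home side.  Every session lasts a fixed two
minutes so that a young child can stay focused for the whole round.

The four stages serve distinct therapeutic roles:

1. **Assessment** — the spawn position starts at ``x0`` and advances by
   ``incr_dist`` for every point scored, probing how far past the midline
   the child will comfortably reach.
2. **Distance intervention** — balls spawn uniformly within
   ``x0 +/- dist_var``, training tolerance around the distance at which the
   child began to struggle.
3. **Speed intervention** — balls always spawn at ``x0`` but fall at
   ``speed0 + incr_speed * score``, ramping up as the child succeeds.
4. **Maintenance** — spawn positions are uniform over the whole playfield
   at constant speed, consolidating the acquired skill.

All stage formulas are expressed in the *right-handed frame*: the hat's
home is the left edge (``x_min``) and challenge distances grow rightward.
Left-handed play is the exact mirror image; see :func:`mirror_config` and
the engine's handedness handling.
"""

from __future__ import annotations

import math
from enum import Enum

from pydantic import BaseModel, ConfigDict, model_validator


class ConfigurationError(ValueError):
    """A stage configuration is inconsistent or incomplete."""


class Handedness(str, Enum):
    """Dominant hand of the child; fixes the hat's home side.

    The hat starts on the side *opposite* the dominant hand so that the
    very first reach already crosses the midline: a right-handed child
    starts at the left edge, a left-handed child at the right edge.
    """

    left = "left"
    right = "right"


#: Valid stage identifiers, in therapeutic order.
STAGE_IDS = (1, 2, 3, 4)

_REQUIRED: dict[int, tuple[str, ...]] = {
    1: ("x0", "incr_dist"),
    2: ("x0", "dist_var"),
    3: ("x0", "speed0", "incr_speed"),
    4: (),
}

_DEFAULTS: dict[int, dict[str, float]] = {
    1: {"x0": 1.0, "incr_dist": 0.5},
    2: {"x0": 1.5, "dist_var": 0.5},
    3: {"x0": 1.5, "speed0": 2.0, "incr_speed": 0.1},
    4: {},
}


class StageConfig(BaseModel):
    """Parameters that define the game environment for one stage.

    Only the parameters relevant to ``stage_id`` are required; the rest may
    stay ``None``.  ``constant_speed`` is the fall speed used by stages 1,
    2 and 4 (stage 3 ramps from ``speed0`` instead).
    """

    model_config = ConfigDict(frozen=True)

    stage_id: int
    x0: float | None = None
    incr_dist: float | None = None
    dist_var: float | None = None
    speed0: float | None = None
    incr_speed: float | None = None
    constant_speed: float = 2.0
    duration_s: float = 120.0
    x_min: float = -7.5
    x_max: float = 7.5

    @model_validator(mode="after")
    def _validate(self) -> "StageConfig":
        if self.stage_id not in STAGE_IDS:
            raise ValueError(
                f"unknown stage_id {self.stage_id}; expected one of {STAGE_IDS}"
            )
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not (self.x_min < 0 < self.x_max):
            raise ValueError("playfield must straddle the midline (x_min < 0 < x_max)")
        if not math.isclose(self.x_min, -self.x_max):
            raise ValueError("playfield must be symmetric about the midline (x_min = -x_max)")
        for name in _REQUIRED[self.stage_id]:
            if getattr(self, name) is None:
                raise ValueError(f"stage {self.stage_id} requires parameter {name!r}")
        if self.constant_speed <= 0:
            raise ValueError("constant_speed must be positive")
        if self.dist_var is not None and self.dist_var < 0:
            raise ValueError("dist_var must be non-negative")
        if self.speed0 is not None and self.speed0 <= 0:
            raise ValueError("speed0 must be positive")
        if self.incr_speed is not None and self.incr_speed < 0:
            raise ValueError("incr_speed must be non-negative")
        if self.x0 is not None and not (self.x_min <= self.x0 <= self.x_max):
            raise ValueError(f"x0 must lie within [{self.x_min}, {self.x_max}]")
        return self


def default_config(stage_id: int, **overrides) -> StageConfig:
    """Return the default :class:`StageConfig` for a stage.

    Defaults are expressed in the right-handed frame (positive ``x0``);
    keyword overrides replace individual fields.
    """
    if stage_id not in STAGE_IDS:
        raise ConfigurationError(
            f"unknown stage_id {stage_id}; expected one of {STAGE_IDS}"
        )
    params: dict = {"stage_id": stage_id, **_DEFAULTS[stage_id]}
    params.update(overrides)
    return StageConfig(**params)


def mirror_config(config: StageConfig) -> StageConfig:
    """Reflect a configuration across the midline (negate ``x0``).

    Stage formulas are written for right-handed play; the mirrored
    configuration describes the identical challenge for a left-handed
    child, whose home side is the right edge.
    """
    if config.x0 is None:
        return config
    return config.model_copy(update={"x0": -config.x0})
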