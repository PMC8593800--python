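# Methods

This note documents the models, mechanics and design choices behind the
toolkit: what is simulated, how the score card is computed, and what the
synthetic players can and cannot stand in for.

## The game

A hat slides along a horizontal axis `x ∈ [−7.5, +7.5]` (game units) with
the body midline at `x = 0`. Balls fall one at a time from the top of the
screen; the child catches a ball by having the hat under it when it
reaches the hat plane, and earns a point only after carrying the caught
ball back to the hat's *home side*. The home side is opposite the child's
dominant hand, so every scoring cycle forces a midline crossing. Each
session lasts a fixed 120 s.

Spawn position and fall speed per stage, where `S` is the current score
(balls caught **and** returned):

| stage | role | spawn position | fall speed |
|---|---|---|---|
| 1 | assessment | `x0 + incr_dist·S` (clipped to the playfield) | `constant_speed` |
| 2 | distance intervention | `x0 + U(−dist_var, +dist_var)` | `constant_speed` |
| 3 | speed intervention | `x0` | `speed0 + incr_speed·S` |
| 4 | maintenance | `U(−7.5, +7.5)` | `constant_speed` |

Because the spawn rule reads the score *after the last completed return*,
a missed ball in stages 1 and 3 is re-served at the same position.

Formulas are defined in the right-handed frame (home at −7.5, challenge
growing rightward). A left-handed session is obtained by reflecting the
configuration (`x0 → −x0`), simulating canonically, and negating every
recorded position — so left-handed play is the exact mirror of
right-handed play at the same seed, which the test suite verifies
event-for-event.

### Mechanics the game rules leave open

These constants are engine parameters (`EngineParams`), chosen once and
configurable:

- **Vertical geometry.** Balls spawn at `y_top = 10` above the hat plane
  at `y = 0`. With the default fall speed of 2 units/s a ball is in the
  air 5 s, giving an engaged player roughly 16–17 catch opportunities per
  session — consistent with the score-card thresholds (>14 caught, <7.5 s
  between balls over 120 s).
- **Miss resolution.** A missed ball keeps falling and resolves when it
  exits the screen at `y_bottom = −6`; the next ball is served at that
  instant (for a caught ball, at the instant the hat reaches home). An
  instant respawn at the hat plane would make missing *faster* than
  catching, so a disengaged child would sail under the
  average-time-between-balls criterion; letting the ball leave the screen
  keeps the serve cadence meaningful.
- **Catch tolerance** 0.5 units either side of the hat centre; **return
  tolerance** 0.25 units from the home edge.
- **Timing.** A fixed 20 ms step; every fall, delay and travel time is
  rounded up to the step, so a session is exactly reproducible from
  `(config, handedness, player, seed)` and serializes byte-identically.
  A single seeded generator drives all randomness in a session and the
  seed is stored in the record for replay.
- **Session end.** A ball still in flight at 120 s is abandoned: counted
  as served, recorded as no event. A ball caught but not yet returned
  scores no point.
- **Returns** start at the catch instant — the child plans the homeward
  carry while tracking the ball — so no reaction delay applies to them;
  impaired profiles do add their crossing hesitation when the carry
  starts in contralateral space.

## Synthetic players

`ReachPlayer` is a parametric child model:

| parameter | default | meaning |
|---|---|---|
| `hat_speed` | 6 units/s | maximum lateral speed |
| `reaction_delay_s` | 0.3 s | delay before responding to a serve |
| `lapse_rate` | 0.02 | probability of ignoring a ball entirely |
| `crossing_delay_s` | 0 (impaired: 1.5·severity) | extra hesitation on contralateral movements |
| `crossing_penalty` | 0 (impaired: 0.5·severity per unit) | refusal-probability slope |

The impairment operationalizes the clinical picture of midline-crossing
inhibition — hesitating at, or declining, actions on the contralateral
side. When a ball lies a distance `d` past the midline on the side
opposite the child's home, the impaired child hesitates
(`crossing_delay_s`) and refuses to cross with probability
`min(1, crossing_penalty · d)`, stopping at the midline instead. The
refusal is keyed to the *side of space the ball occupies*, not to the
hat's instantaneous position: a hand resting at the midline still faces a
contralateral task, and conditioning on the hat position would let a
simulated child camp at the midline and catch "without crossing",
erasing the avoidance phenotype. The linear-in-overshoot refusal is the
simplest monotone model that yields the canonical observations (misses
growing with distance, use of the near side only); it is a modelling
choice, not a fitted law.

Severity scales both impairment parameters linearly; at severity 0 the
impaired profile is identical to the unimpaired one. The unimpaired
defaults and the severity-1 endpoints were calibrated once with
`scripts/tune_profiles.py` and frozen: at the default stage parameters
the unimpaired population passes all three gameplay criteria in ≈99 % of
sessions and the severity-1 population fails all three in 100 %, with the
screening classification separating the populations completely at n=200.

`synthesize_notes` emulates the caretaker's observational notes page:
each of the five observational items is independently unfavourable with
probability `0.05 + 0.85·severity` — even typical children occasionally
need a verbal cue.

**What the synthetic players do not show.** They are test instruments:
they exercise the engine, the score card and the dashboards under known
ground truth. They are not validated against behavioural data from
children (none exist for this task), they have no learning, fatigue or
attention dynamics within a session, and passing tests against them says
nothing about the clinical sensitivity or specificity of the thresholds
in real populations.

## The score card

Eight binary criteria; a total of ≥4 points is reported as *no pathology
indicated*, otherwise *further assessment needed*. Criteria 1–3 are
computed from telemetry with the printed thresholds taken strictly
(boundary values earn no point): balls caught > 14, balls missed < 4,
mean time between successive serves < 7.5 s. "Average time between
balls" is the mean gap between successive spawn times, in seconds; it is
undefined (and scores 0, flagging the card) with fewer than two serves.

Criterion 4 asks whether misses pattern with the challenge — spawn
distance past the midline in stages 1, 2 and 4, fall speed in stage 3.
By default it is scored from the caretaker's observation, matching how
the card is used; an automated alternative computes the point-biserial
correlation between the per-ball challenge and the miss indicator with a
one-sided p-value from a seeded permutation null (999 label shuffles by
default), declaring a pattern iff `r > 0` and `p < 0.05`. It is a single
pre-specified test per session, so no multiplicity correction applies;
degenerate sessions (no misses, no catches, constant challenge) carry no
evidence and score the point. Every point records its provenance
(`gameplay`, `observation`, or `automated`).

Criteria 5–8 come from the notes page: instructions followed, visual
focus maintained, no gross body adjustments, no verbal cues required.
Missing notes score 0 on criteria 4–8 and flag the card incomplete
rather than failing — a partially filled page still carries information.

## Dashboard metrics

Per session: catch counts and rate, serve cadence, the farthest crossing
distance of a returned ball, and misses binned over six equal-width
intervals of the playfield (bin attempts always re-aggregate to the
resolved-ball total). Across sessions: per-stage ordinary-least-squares
slope of the card total against session ordinal, defined only with at
least two sessions of a stage. All metrics are pure functions of their
inputs; plots are an optional matplotlib layer with no bit-exactness
claim.

## Wire format

JSON envelopes with an embedded schema name and semantic version; reads
validate every record invariant and reject unknown versions. Notes
schema 1.0 (without the distance-pattern item) migrates forward with the
field set to null. Score cards flatten to a comma-separated, UTF-8,
header-row CSV. Child identifiers are pseudonymous opaque strings;
timestamps are ISO-8601 UTC; no personal data enters the schema.

## Problem sizes used in the shipped checks

Population-level tests use 200 sessions per arm (and 200 replicates for
the permutation-test calibration); randomized property batteries use 500
instances of short (10–45 s) sessions; distribution checks of the spawn
rules use 10⁴ draws. These sizes make the binomial bounds in the
assertions comfortably tight while keeping the whole suite fast.

## Known limitations

- The player models are synthetic by necessity; see above.
- The criterion thresholds are fixed, not normed by age.
- One ball is in play at a time (serial serve loop); overlapping balls
  are out of scope.
- The dashboard computes and exports metrics; it is not a hosted,
  interactive view.
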