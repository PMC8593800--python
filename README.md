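# midline-game

A headless, testable implementation of a serious-game telehealth system
for screening and treating children who have difficulty crossing the
body's midline — the skill of spontaneously reaching a hand across to
the opposite side of the body, expected by around age five and
foundational for writing, reading and bilateral motor skills.

Children play a simple catch game at home: a hat slides along a
horizontal axis `x ∈ [−7.5, +7.5]` with the midline at `x = 0`, balls
fall from the top of the screen, and a point is scored only after a
caught ball is carried back to the hat's home side — which sits opposite
the child's dominant hand, so every scoring cycle crosses the midline.
An occupational therapist reviews the uploaded telemetry remotely. This
package provides everything around the graphics: the deterministic game
engine, synthetic child player models, the screening score card, the
JSON wire format, and the dashboard metrics.

## The model in brief

Each 120 s session runs one of four stages. With score `S` (balls caught
and returned), the spawn position and fall speed are

- stage 1 (assessment): `x = x0 + I·S`, constant speed — the ball creeps
  farther across the midline with every success;
- stage 2 (intervention): `x = x0 + Uniform(−DV, +DV)`, constant speed;
- stage 3 (intervention): `x = x0`, speed `Sp0 + Isp·S`;
- stage 4 (maintenance): `x = Uniform(−7.5, +7.5)`, constant speed.

The screening score card awards one point per criterion: balls caught
> 14, balls missed < 4, mean time between balls < 7.5 s, no pattern of
misses with increasing challenge, and four observational items from the
caretaker's notes page. A total of **≥ 4 of 8 points** is reported as
*no pathology indicated*; anything less flags the child for further
assessment.

Simulated children come in two families: unimpaired, and
midline-crossing impaired — the latter hesitate before contralateral
reaches and refuse to cross with probability growing with how far past
the midline the ball lies, reproducing the avoidance behaviours
therapists screen for. See `docs/methods.md` for the full account and
`docs/caretaker_guidance.md` for the observation script that accompanies
the notes page.

## Worked example

Simulate one session of the assessment stage for an unimpaired child and
score it:

```sh
midline-game simulate --stage 1 --profile unimpaired --n-sessions 1 \
    --seed 7 --child-id demo --out run/
```

```python
from midline_game import read_session, extract_stats, score_gameplay_criteria

s = read_session("run/sessions/demo-stage1-0000.json")
st = extract_stats(s)
print(s.final_score, st.balls_caught, st.balls_missed,
      round(st.mean_inter_ball_time_s, 3), score_gameplay_criteria(st))
```

prints

```
16 16 1 7.026 (1, 1, 1)
```

— 16 balls caught and returned, one lapse, a 7.03 s serve cadence, and
all three gameplay criteria earned. The same pipeline for a severely
impaired profile (`--profile impaired-severe`, seeds 7–9, then
`midline-game score` with the synthesized notes) produces cards like

```
session_id,stage_id,...,total,classification,...
demo-child-stage1-0000,1,...,0,further_assessment_needed,...
demo-child-stage1-0001,1,...,2,further_assessment_needed,...
demo-child-stage1-0002,1,...,0,further_assessment_needed,...
```

every session correctly flagged for follow-up. `midline-game dashboard`
then exports the per-session summary CSV and a progress JSON with
per-stage trend slopes; `midline-game schema` prints the JSON schemas of
the wire-format records.

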