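# Caretaker guidance script

Key points of reference for the adult supervising a session at home.
Read this before the child plays; fill in the notes page immediately
after each stage.

## Before the session

- Seat the child squarely facing the screen, hips and shoulders forward,
  with the input device centred in front of them.
- Explain the goal once, simply: "catch the ball in the hat, then bring
  the hat all the way back to its side of the screen to get your point."
- Confirm the configured handedness matches the child's dominant hand —
  the hat must start on the *opposite* side.
- Do not practise beforehand; the first stage is an assessment.

## During the session (observe, do not steer)

Watch for, and remember for the notes page:

- **Instructions** — did the child follow them without re-explanation?
- **Eyes** — did the child keep visual focus on the ball across the
  whole screen, or blink/refocus when it crossed the middle?
- **Body** — did the child rotate the trunk, lean, swap hands, or shift
  in the seat to avoid reaching across the body?
- **Prompts** — did you need to give verbal cues ("go get it", "bring it
  back") to keep play going?
- **Distance** — did misses become more frequent as balls landed farther
  across the screen?

Only intervene if the child releases the device or disengages entirely;
note any intervention in the free-text field.

## After the stage

Complete every item of the notes page while the session is fresh. An
honest "no" is more useful to the therapist than a hopeful "yes"; the
notes and the gameplay data are read together.
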