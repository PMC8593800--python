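"""One-shot calibration report for the synthetic player profiles.

Runs the default stage configurations against the unimpaired profile and
the impaired profile on a severity grid, and prints the rates at which
each population meets the gameplay criteria and the screening
classification.  The shipped profile defaults were frozen after a single
run of this script; re-run it to audit them:

    python scripts/tune_profiles.py [--n 200] [--seed 100]
"""

from __future__ import annotations

import argparse

import numpy as np

from midline_game import (
    Handedness,
    default_config,
    extract_stats,
    run_session,
    score_card,
    score_gameplay_criteria,
)
from midline_game.players import make_profile, synthesize_notes


def population_report(kind: str, severity: float, n: int, seed: int) -> dict:
    cfg = default_config(1)
    player = make_profile(kind, severity)
    all_pass = all_fail = no_path = 0
    scores = []
    for i in range(n):
        rec = run_session(cfg, Handedness.right, player, seed + i)
        stats = extract_stats(rec)
        pts = score_gameplay_criteria(stats)
        all_pass += pts == (1, 1, 1)
        all_fail += pts == (0, 0, 0)
        notes = synthesize_notes(rec, severity, np.random.default_rng([seed + i, 97]))
        card = score_card(stats, notes, 1, session_id=rec.session_id)
        no_path += card.classification.value == "no_pathology_indicated"
        scores.append(rec.final_score)
    return {
        "profile": f"{kind} (severity {severity:.2f})",
        "mean_score": float(np.mean(scores)),
        "criteria_1_3_all_pass": all_pass / n,
        "criteria_1_3_all_fail": all_fail / n,
        "no_pathology_rate": no_path / n,
    }


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=200)
    ap.add_argument("--seed", type=int, default=100)
    args = ap.parse_args()

    grid = [("unimpaired", 0.0)] + [("impaired", s) for s in (0.25, 0.5, 0.75, 1.0)]
    header = f"{'profile':28s} {'mean_score':>10s} {'all-pass':>9s} {'all-fail':>9s} {'no-path':>8s}"
    print(header)
    print("-" * len(header))
    for kind, sev in grid:
        r = population_report(kind, sev, args.n, args.seed)
        print(
            f"{r['profile']:28s} {r['mean_score']:10.2f} "
            f"{r['criteria_1_3_all_pass']:9.3f} {r['criteria_1_3_all_fail']:9.3f} "
            f"{r['no_pathology_rate']:8.3f}"
        )


if __name__ == "__main__":
    main()
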