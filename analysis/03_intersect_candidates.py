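#!/usr/bin/env python
"""Intersect the two screens and check direction concordance.

A gene is a candidate only if it passes the |r| > 0.55 screen in BOTH
cohorts. The union identity (union = passing_1 + passing_2 - intersection)
is asserted, per-candidate correlation signs are compared across cohorts,
and the ranked candidate table (weaker-|r| summary) goes to
results/03_candidates.tsv.
"""

import json
from pathlib import Path

from coexnet.ingest import read_annotation, read_expression_tsv
from coexnet.meta import concordance_report, intersect_screens, write_candidate_table
from coexnet.screen import ScreenConfig, run_screen

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "synthetic_bundle"
RESULTS = ROOT / "results"


def run() -> None:
    if not (BUNDLE / "expression_1.tsv").is_file():
        raise SystemExit("synthetic bundle missing; run analysis/01_simulate_cohorts.py first")
    ann = read_annotation(BUNDLE / "annotation.tsv")
    config = ScreenConfig(seed="GSK3B")
    screens = [
        run_screen(
            read_expression_tsv(BUNDLE / f"expression_{i}.tsv", dataset_id=f"ds{i}"),
            ann,
            config,
        )
        for i in (1, 2)
    ]
    cs = intersect_screens(screens[0], screens[1], ann, ann, level="feature")
    counts = cs.counts()
    assert counts["union"] == counts["passing_1"] + counts["passing_2"] - counts["intersection"]
    frac, discordant = concordance_report(cs)

    write_candidate_table(cs, RESULTS / "03_candidates.tsv")
    with open(RESULTS / "03_intersection_counts.json", "w") as fh:
        json.dump({**counts, "discordant_keys": discordant}, fh, indent=2, sort_keys=True)
    print(
        f"{counts['intersection']} candidates common to both cohorts out of "
        f"{counts['union']} total correlates "
        f"({counts['passing_1']} + {counts['passing_2']} passing per cohort); "
        f"direction concordance {frac:.3f} "
        f"({len(discordant)} discordant)"
    )


if __name__ == "__main__":
    run()
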