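#!/usr/bin/env python
"""Synthetic-cohort checks of the scoring rules.

Finding: a 500-trial cohort whose mixture-cure plateaus are engineered to
satisfy the durable-survival rule earns the tail bonus in 100% of trials,
while a null cohort (hazard ratio centred at 1, no plateau, no benefit
flags, exchangeable toxicity) has a median NHB near 0 - the engine awards
nothing when there is nothing to award.
"""

import json
import sys
from pathlib import Path

import numpy as np

from oncovalue import score_cohort, summarize
from oncovalue.synthetic_data import generate, null_config, tail_qualifying_config

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main(seed: int = 0) -> None:
    doc = {}

    scored = score_cohort(generate(tail_qualifying_config(500, seed=seed)))
    rate = sum(1 for a in scored if a.asco.tail_bonus > 0) / len(scored)
    doc["engineered_tail_bonus_rate"] = rate
    print(f"engineered-plateau cohort (n=500, seed={seed}): "
          f"tail-bonus rate {rate:.1%}")

    scored = score_cohort(generate(null_config(500, seed=seed)))
    median_nhb = float(np.median([a.asco.nhb for a in scored]))
    summary = summarize(scored, level="arm")
    doc["null_median_nhb"] = median_nhb
    doc["null_tail_indications"] = summary.n_tail_indications
    print(f"null cohort (n=500, seed={seed}): median NHB {median_nhb:.2f}; "
          f"tail bonus in {summary.n_tail_indications} trials")

    (OUT / "synthetic_checks.json").write_text(json.dumps(doc, indent=1) + "\n")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
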