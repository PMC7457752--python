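#!/usr/bin/env python
"""Initial-versus-updated comparison at the best-arm-per-indication level.

Finding: 12 of the 14 re-assessed indications improved, with a median NHB
gain of 10 (range 2-20), largely from newly reported quality-of-life and
symptom-palliation bonuses; the consolidation-NSCLC indication is the sole
decrease (47.7 -> 41.8, re-evaluated on mature OS instead of PFS), and two
indications upgraded from ESMO grade 4 to 5.
"""

import json
from pathlib import Path

from oncovalue import compare_phases, load_fixtures, score_fixture_cohort, summarize

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    summaries = {
        phase: summarize(score_fixture_cohort(load_fixtures(phase)),
                         level="indication")
        for phase in ("initial", "updated")
    }
    comparison = compare_phases(summaries["initial"], summaries["updated"])
    (OUT / "phase_comparison.json").write_text(
        json.dumps(comparison.to_dict(), indent=1) + "\n")

    print(f"shared indications: {len(comparison.deltas)}; "
          f"improved: {len(comparison.improved)}; "
          f"unchanged: {comparison.unchanged}; "
          f"decreased: {list(comparison.decreased)}")
    print(f"median NHB improvement {comparison.median_improvement:.1f} "
          f"(range {comparison.improvement_min:.1f}-{comparison.improvement_max:.1f})")
    print(f"grade changes: {comparison.grade_changes}")
    print(f"long-term criterion changes: {comparison.long_term_changes}")
    print(f"excluded (initial phase only): {comparison.excluded}")


if __name__ == "__main__":
    main()
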