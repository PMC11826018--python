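"""Apply the exclusion chain to the generated trial table.

Removes heavy omitters at study level, then per-block warm-up trials,
omissions, fast guesses (< 250 ms) and slow outliers (pooled mean + 3 SD),
then participants left with fewer than half their trials.
"""

import argparse
import json
from pathlib import Path

from faeddm.generate import read_trials, write_trials
from faeddm.preprocess import apply_exclusions


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    trials = read_trials(args.out / "trials.csv")
    kept, report = apply_exclusions(trials)
    write_trials(kept, args.out / "trials_clean.csv")
    (args.out / "exclusion_report.json").write_text(json.dumps(report.to_dict(), indent=1))

    print(f"{len(trials)} trials in, {len(kept)} retained")
    print(f"removed per rule: {report.counts}")
    print(f"slow-RT threshold: {report.slow_threshold_ms:.0f} ms")
    if report.participants_removed_study or report.participants_removed_hddm:
        print(f"participants removed: study {report.participants_removed_study}, "
              f"model {report.participants_removed_hddm}")


if __name__ == "__main__":
    main()
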