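"""Posterior contrast tests on the fitted drift rates.

Iteration-wise posterior differences for the 16-member drift family
(8 group differences, 8 adaptor effects), BH-FDR-corrected at q = 0.05;
a contrast is credible when zero falls outside its adjusted central
credible interval.
"""

import argparse
from pathlib import Path

import pandas as pd

from faeddm.contrasts import default_drift_family, run_contrast_family
from faeddm.hddm import PosteriorSamples


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--q", type=float, default=0.05)
    args = ap.parse_args()

    samples = PosteriorSamples.load(args.out)
    results = run_contrast_family(samples, default_drift_family(samples), q=args.q)

    df = pd.DataFrame(
        {
            "contrast": [r.name for r in results],
            "median": [r.median for r in results],
            "p": [r.p for r in results],
            "ci_lo": [r.interval[0] for r in results],
            "ci_hi": [r.interval[1] for r in results],
            "coverage": [r.coverage for r in results],
            "credible": [r.credible for r in results],
        }
    )
    df.to_csv(args.out / "contrasts.csv", index=False)

    cov = results[0].coverage
    print(f"{len(results)} contrasts, adjusted interval coverage {cov:.1%}")
    credible = df[df["credible"]]
    if credible.empty:
        print("no credible contrasts")
    else:
        print("credible contrasts:")
        print(credible[["contrast", "median", "ci_lo", "ci_hi"]].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
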