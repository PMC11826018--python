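"""Model-free analysis: male-response proportions, FAE curve, mixed ANOVA.

The 2 (Group) x 2 (Adaptor) x 4 (Morph) mixed ANOVA on per-cell male
response proportions, with Mauchly's sphericity test, Greenhouse–Geisser
correction and Levene's homogeneity test.  The FAE is the difference in
male-response probability between the androgynous- and male-adaptor
conditions.
"""

import argparse
from pathlib import Path

import pandas as pd

from faeddm.generate import read_trials
from faeddm.model_free import fae_curve, group_cell_summary, mixed_anova, response_proportions
from faeddm.preprocess import exclude_participants_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    trials = read_trials(args.out / "trials.csv")
    study_trials, _ = exclude_participants_study(trials)
    table = response_proportions(study_trials)
    table.to_csv(args.out / "proportions.csv", index=False)
    group_cell_summary(table).to_csv(args.out / "cell_summary.csv", index=False)
    curve = fae_curve(table)
    curve.to_csv(args.out / "fae_curve.csv", index=False)

    res = mixed_anova(table)
    res.effects.to_csv(args.out / "anova.csv")
    res.mauchly.to_csv(args.out / "mauchly.csv")

    pd.set_option("display.width", 140)
    print(res.effects[["F", "df1", "df2", "p", "eps", "p_corr"]].round(4))
    print(f"\nLevene: F = {res.levene[0]:.3f}, p = {res.levene[1]:.3f}")
    fae_by_morph = curve.groupby("morph_pct")["fae"].mean()
    print("\nmean FAE by morph level (androgynous - male adaptor):")
    print(fae_by_morph.round(3).to_string())


if __name__ == "__main__":
    main()
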