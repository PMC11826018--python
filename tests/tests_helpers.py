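"""Small builders shared across test modules."""

import numpy as np
import pandas as pd

ADAPTORS = ["androgynous", "male"]
MORPHS = [20, 40, 60, 80]


def proportion_table(values: dict, group_of: dict) -> pd.DataFrame:
    """Build a proportion table from {(pid, adaptor, morph): prop}."""
    rows = [
        {"participant_id": pid, "group": group_of[pid], "adaptor": ad, "morph_pct": m,
         "prop_male": p, "n_responded": 10, "missing": False}
        for (pid, ad, m), p in values.items()
    ]
    return pd.DataFrame(rows)


def random_proportion_table(rng, n_aut, n_nt, sd=0.05) -> pd.DataFrame:
    """A full 2x4 within-design proportion table with mild random noise."""
    values, group_of = {}, {}
    for g, n in (("AUT", n_aut), ("NT", n_nt)):
        for i in range(n):
            pid = f"{g}{i:02d}"
            group_of[pid] = g
            base = rng.uniform(0.2, 0.4)
            for a_i, ad in enumerate(ADAPTORS):
                for m_i, m in enumerate(MORPHS):
                    p = base + 0.15 * m_i - 0.1 * a_i + sd * rng.standard_normal()
                    values[(pid, ad, m)] = float(np.clip(p, 0, 1))
    return proportion_table(values, group_of)
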