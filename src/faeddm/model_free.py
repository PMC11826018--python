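"""Model-free (frequentist) analysis of the face-aftereffect experiment.

Per-cell male-response proportions, the FAE difference curve
(androgynous minus male adaptor), and a 2 (Group, between) x 2 (Adaptor,
within) x 4 (Morph, within) mixed ANOVA on the proportions.

The ANOVA uses the multivariate/contrast formulation of univariate
repeated measures: the eight within-subject cell proportions of every
participant are projected onto orthonormal contrast sets (one per within
effect), hypothesis and error sums of squares are traces of the
corresponding SSCP matrices, and Type III (unweighted-means) hypotheses
accommodate unequal group sizes.  Sphericity is assessed with Mauchly's
test on the pooled within-group covariance of the contrast scores, and
the Greenhouse–Geisser epsilon deflates the degrees of freedom of every
within effect involving the four-level Morph factor.  Homogeneity of the
between factor is checked with Levene's test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from faeddm.conventions import (
    ADAPTOR_ANDRO,
    ADAPTOR_MALE,
    RESPONSE_MALE,
    RESPONSE_OMITTED,
)

__all__ = [
    "response_proportions",
    "group_cell_summary",
    "fae_curve",
    "mixed_anova",
    "AnovaResult",
]


def response_proportions(trials: pd.DataFrame) -> pd.DataFrame:
    """Male-response proportion per participant x adaptor x morph cell.

    Computed over responded (non-omitted) trials only.  Cells with zero
    responded trials carry ``NaN`` proportions and ``missing=True``.
    """
    responded = trials[trials["response"] != RESPONSE_OMITTED]
    grp = responded.groupby(["participant_id", "group", "adaptor", "morph_pct"])
    tab = grp.agg(
        n_responded=("response", "size"),
        n_male=("response", lambda s: int((s == RESPONSE_MALE).sum())),
    ).reset_index()
    tab["prop_male"] = tab["n_male"] / tab["n_responded"]

    # reinstate cells that lost every trial to omission
    cells = (
        trials.groupby(["participant_id", "group", "adaptor", "morph_pct"])
        .size()
        .reset_index()[["participant_id", "group", "adaptor", "morph_pct"]]
    )
    tab = cells.merge(tab, how="left", on=["participant_id", "group", "adaptor", "morph_pct"])
    tab["n_responded"] = tab["n_responded"].fillna(0).astype(int)
    tab["missing"] = tab["n_responded"] == 0
    return tab


def _mean_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    x = np.asarray(x, dtype=float)
    m = x.mean()
    if x.size < 2:
        return m, np.nan, np.nan
    half = stats.t.ppf(0.5 + level / 2, x.size - 1) * x.std(ddof=1) / np.sqrt(x.size)
    return m, m - half, m + half


def group_cell_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Group mean male-response proportion and 95% CI per cell."""
    rows = []
    for (g, ad, m), sub in table.dropna(subset=["prop_male"]).groupby(
        ["group", "adaptor", "morph_pct"]
    ):
        mean, lo, hi = _mean_ci(sub["prop_male"].to_numpy())
        rows.append((g, ad, m, sub.shape[0], mean, lo, hi))
    return pd.DataFrame(
        rows, columns=["group", "adaptor", "morph_pct", "n", "mean", "ci_lo", "ci_hi"]
    )


def fae_curve(table: pd.DataFrame) -> pd.DataFrame:
    """The FAE: P(male | androgynous adaptor) - P(male | male adaptor).

    Computed per participant and morph level, then averaged per group with
    a 95% CI.  Missing cells propagate as missing participants for that
    morph level.
    """
    wide = table.pivot_table(
        index=["participant_id", "group", "morph_pct"],
        columns="adaptor",
        values="prop_male",
    ).reset_index()
    if ADAPTOR_ANDRO not in wide.columns or ADAPTOR_MALE not in wide.columns:
        raise ValueError("both adaptor conditions are required for the FAE curve")
    wide["fae"] = wide[ADAPTOR_ANDRO] - wide[ADAPTOR_MALE]
    rows = []
    for (g, m), sub in wide.dropna(subset=["fae"]).groupby(["group", "morph_pct"]):
        mean, lo, hi = _mean_ci(sub["fae"].to_numpy())
        rows.append((g, m, sub.shape[0], mean, lo, hi))
    per_group = pd.DataFrame(
        rows, columns=["group", "morph_pct", "n", "mean", "ci_lo", "ci_hi"]
    )
    per_participant = wide[["participant_id", "group", "morph_pct", "fae"]]
    return per_participant.merge(per_group, on=["group", "morph_pct"], suffixes=("", "_group"))


# ---------------------------------------------------------------------------
# mixed ANOVA


@dataclass
class AnovaResult:
    """Mixed-ANOVA decomposition with sphericity/homogeneity diagnostics."""

    effects: pd.DataFrame  # one row per effect
    mauchly: pd.DataFrame  # one row per within effect with >= 2 df
    levene: tuple  # (statistic, p)
    dropped_participants: list  # incomplete cases removed
    n_per_group: dict


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """A (k, k-1) matrix of orthonormal contrasts (zero-sum columns)."""
    basis = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(basis)
    q = q[:, : k - 1]
    # QR of a centered matrix: columns are zero-sum and orthonormal
    return q


def _unit_mean(k: int) -> np.ndarray:
    return np.ones((k, 1)) / np.sqrt(k)


def _type3_ss(Z: np.ndarray, gi: np.ndarray, n_g: np.ndarray, term: str) -> float:
    """Trace of the Type III hypothesis SSCP for ``term`` over columns of Z.

    Cell-means parameterisation: the hypothesis is L @ group_means = 0,
    with L the unweighted grand mean (``intercept``) or all pairwise-to-last
    group differences (``group``).
    """
    g = n_g.size
    means = np.vstack([Z[gi == j].mean(axis=0) for j in range(g)])  # (g, q)
    if term == "intercept":
        L = np.full((1, g), 1.0 / g)
    elif term == "group":
        L = np.hstack([np.eye(g - 1), -np.ones((g - 1, 1))])
    else:  # pragma: no cover
        raise ValueError(term)
    xtx_inv = np.diag(1.0 / n_g)
    mid = np.linalg.inv(L @ xtx_inv @ L.T)
    lb = L @ means  # (rows, q)
    return float(np.trace(lb.T @ mid @ lb))


def _resid_sscp(Z: np.ndarray, gi: np.ndarray, g: int) -> np.ndarray:
    E = np.zeros((Z.shape[1], Z.shape[1]))
    for j in range(g):
        Zi = Z[gi == j]
        D = Zi - Zi.mean(axis=0)
        E += D.T @ D
    return E


def _gg_epsilon(S: np.ndarray) -> float:
    q = S.shape[0]
    if q <= 1:
        return 1.0
    tr = np.trace(S)
    return float(tr**2 / (q * np.trace(S @ S)))


def _mauchly(S: np.ndarray, df: int) -> tuple[float, float, float]:
    """Mauchly's W on a pooled covariance with ``df`` error df.

    Returns (W, chi2, p).  Vacuous (W=1, p=1) for one-dimensional scores.
    """
    q = S.shape[0]
    if q <= 1:
        return 1.0, 0.0, 1.0
    W = float(np.linalg.det(S) / (np.trace(S) / q) ** q)
    W = min(max(W, np.finfo(float).tiny), 1.0)
    # Box's chi-square approximation with the second-order correction term
    d1 = 1.0 - (2.0 * q**2 + q + 2.0) / (6.0 * q * df)
    chi2 = -df * d1 * np.log(W)
    ddf = q * (q + 1) // 2 - 1
    w2 = (
        (q + 2.0)
        * (q - 1.0)
        * (q - 2.0)
        * (2.0 * q**3 + 6.0 * q**2 + 3.0 * q + 2.0)
        / (288.0 * q**2 * df**2 * d1**2)
    )
    p = float(
        stats.chi2.sf(chi2, ddf)
        + w2 * (stats.chi2.sf(chi2, ddf + 4) - stats.chi2.sf(chi2, ddf))
    )
    return W, chi2, min(max(p, 0.0), 1.0)


def mixed_anova(
    table: pd.DataFrame,
    gg_policy: str = "always",
) -> AnovaResult:
    """2 (Group) x 2 (Adaptor) x 4 (Morph) mixed ANOVA on proportions.

    ``gg_policy`` controls when Greenhouse–Geisser-corrected dfs/p-values
    are reported for within effects involving the multi-level factor:
    ``"always"`` (unconditional; conservative) or ``"if-significant"``
    (only when Mauchly's test rejects at 0.05, as is traditional).
    Participants with any missing cell are dropped (listed in the result).
    """
    if gg_policy not in ("always", "if-significant"):
        raise ValueError(f"unknown gg_policy {gg_policy!r}")

    adaptors = sorted(table["adaptor"].unique())
    morphs = sorted(table["morph_pct"].unique())
    J, K = len(adaptors), len(morphs)

    wide = table.pivot_table(
        index=["participant_id", "group"],
        columns=["adaptor", "morph_pct"],
        values="prop_male",
        dropna=False,
    )
    wide = wide.reindex(columns=pd.MultiIndex.from_product([adaptors, morphs]))
    complete = wide.dropna()
    dropped = sorted(set(wide.index.get_level_values(0)) - set(complete.index.get_level_values(0)))

    groups = sorted(complete.index.get_level_values("group").unique())
    g = len(groups)
    gi = np.array([groups.index(x) for x in complete.index.get_level_values("group")])
    n_g = np.bincount(gi, minlength=g).astype(float)
    if np.any(n_g < 2):
        raise ValueError("need at least two participants per group")
    N = int(n_g.sum())
    Y = complete.to_numpy()  # (N, J*K), adaptor-major ordering

    cJ = _orthonormal_contrasts(J)
    cK = _orthonormal_contrasts(K)
    uJ, uK = _unit_mean(J), _unit_mean(K)

    within_effects = {
        "Adaptor": np.kron(cJ, uK),
        "Morph": np.kron(uJ, cK),
        "Adaptor x Morph": np.kron(cJ, cK),
    }
    morph_involved = {"Adaptor": False, "Morph": True, "Adaptor x Morph": True}

    rows = []
    mauchly_rows = []

    # between-subject part: scores on the unit-mean contrast
    Z0 = Y @ _unit_mean(J * K)
    ss_group = _type3_ss(Z0, gi, n_g, "group")
    ss_err_b = float(np.trace(_resid_sscp(Z0, gi, g)))
    df_err_b = N - g
    ms_err_b = ss_err_b / df_err_b
    F = (ss_group / (g - 1)) / ms_err_b
    rows.append(
        {
            "effect": "Group",
            "ss": ss_group,
            "df1": g - 1,
            "df2": df_err_b,
            "ss_error": ss_err_b,
            "F": F,
            "p": float(stats.f.sf(F, g - 1, df_err_b)),
            "eps": np.nan,
            "df1_corr": g - 1.0,
            "df2_corr": float(df_err_b),
            "p_corr": float(stats.f.sf(F, g - 1, df_err_b)),
        }
    )

    for name, M in within_effects.items():
        q = M.shape[1]
        Z = Y @ M
        E = _resid_sscp(Z, gi, g)
        df_err = q * (N - g)
        ms_err = np.trace(E) / df_err
        S = E / (N - g)  # pooled covariance of contrast scores
        eps = _gg_epsilon(S)
        W, chi2, p_m = _mauchly(S, N - g)
        if q >= 2:
            mauchly_rows.append(
                {"effect": name, "W": W, "chi2": chi2, "df": q * (q + 1) // 2 - 1, "p": p_m}
            )
        correct = morph_involved[name] and q >= 2 and (
            gg_policy == "always" or p_m < 0.05
        )
        for hyp, label in (("intercept", name), ("group", f"{name} x Group")):
            ss = _type3_ss(Z, gi, n_g, hyp)
            df1 = q if hyp == "intercept" else q * (g - 1)
            F = (ss / df1) / ms_err
            p = float(stats.f.sf(F, df1, df_err))
            use_eps = eps if correct else 1.0
            rows.append(
                {
                    "effect": label,
                    "ss": ss,
                    "df1": df1,
                    "df2": df_err,
                    "ss_error": float(np.trace(E)),
                    "F": F,
                    "p": p,
                    "eps": eps if q >= 2 else np.nan,
                    "df1_corr": df1 * use_eps,
                    "df2_corr": df_err * use_eps,
                    "p_corr": float(stats.f.sf(F, df1 * use_eps, df_err * use_eps)),
                }
            )

    effects = pd.DataFrame(rows).set_index("effect")
    mauchly = pd.DataFrame(
        mauchly_rows, columns=["effect", "W", "chi2", "df", "p"]
    ).set_index("effect")

    # Levene on participant-mean proportions (absolute deviations from the
    # group mean)
    pm = Y.mean(axis=1)
    lev = stats.levene(*[pm[gi == j] for j in range(g)], center="mean")
    return AnovaResult(
        effects=effects,
        mauchly=mauchly,
        levene=(float(lev.statistic), float(lev.pvalue)),
        dropped_participants=dropped,
        n_per_group={groups[j]: int(n_g[j]) for j in range(g)},
    )
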