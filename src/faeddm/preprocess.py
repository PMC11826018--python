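"""Trial- and participant-level exclusion rules.

The exclusion chain mirrors standard practice for choice/RT experiments:

1. *Study level*: participants who failed to respond in more than a third
   of all trials are removed entirely.
2. *Trial level* (for the diffusion model): per participant and condition
   block, the first three trials are dropped (the adaptation context is
   still building up); then response omissions; then extremely fast
   (< 250 ms) responses; then extremely slow responses (more than 3 SD
   above the pooled mean RT, the threshold being computed from the data
   that survived the earlier rules).
3. *Model level*: participants retaining fewer than 50% of their trials
   after step 2 are removed from the diffusion-model fit.

Each removed trial is attributed to exactly one rule, in the fixed order
first-three -> omission -> fast -> slow, so the report is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from faeddm.conventions import RESPONSE_OMITTED

__all__ = [
    "ExclusionReport",
    "FAST_RT_MS",
    "exclude_participants_study",
    "exclude_trials_hddm",
    "exclude_participants_hddm",
    "apply_exclusions",
]

#: Fast-response cutoff (milliseconds).
FAST_RT_MS = 250.0

#: Omission fraction above which a participant is excluded at study level.
STUDY_OMISSION_LIMIT = 1.0 / 3.0

#: Minimum fraction of valid trials to stay in the diffusion-model fit.
HDDM_VALID_MINIMUM = 0.5

#: Trials dropped at the start of every condition block.
N_WARMUP_TRIALS = 3


@dataclass
class ExclusionReport:
    """Book-keeping of what the exclusion chain removed, and why."""

    counts: dict = field(default_factory=dict)  # rule -> trials removed
    slow_threshold_ms: float = float("nan")
    participants_removed_study: list = field(default_factory=list)
    participants_removed_hddm: list = field(default_factory=list)
    trials_in: dict = field(default_factory=dict)  # participant -> input trials
    trials_remaining: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "slow_threshold_ms": self.slow_threshold_ms,
            "participants_removed_study": list(self.participants_removed_study),
            "participants_removed_hddm": list(self.participants_removed_hddm),
            "trials_in": dict(self.trials_in),
            "trials_remaining": dict(self.trials_remaining),
        }


def _check_nonempty(trials: pd.DataFrame) -> None:
    if trials.empty:
        raise ValueError("empty trial table")


def exclude_participants_study(
    trials: pd.DataFrame, report: ExclusionReport | None = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove participants whose omission fraction exceeds one third."""
    _check_nonempty(trials)
    report = report or ExclusionReport()
    omitted = trials["response"].eq(RESPONSE_OMITTED)
    frac = omitted.groupby(trials["participant_id"]).mean()
    removed = frac.index[frac > STUDY_OMISSION_LIMIT].tolist()
    report.participants_removed_study = removed
    retained = trials[~trials["participant_id"].isin(removed)].copy()
    return retained, report


def exclude_trials_hddm(
    trials: pd.DataFrame,
    report: ExclusionReport | None = None,
    n_sd: float = 3.0,
    slow_threshold_ms: float | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the trial-level rules, attributing each trial to one rule.

    The slow threshold is pooled mean + ``n_sd`` SD of the RTs that
    survived the first-three, omission and fast rules; it is recomputed
    from the data on every call and recorded in the report.  Passing
    ``slow_threshold_ms`` pins the threshold instead (one global cutoff,
    e.g. when re-applying a previously computed chain), which makes the
    chain idempotent.
    """
    _check_nonempty(trials)
    report = report or ExclusionReport()
    block_sizes = trials.groupby(["participant_id", "adaptor"]).size()
    if (block_sizes <= N_WARMUP_TRIALS).any():
        raise ValueError("each condition block needs more than three trials")

    report.trials_in = trials.groupby("participant_id").size().to_dict()

    first3 = trials["trial_index"] < N_WARMUP_TRIALS
    omitted = ~first3 & trials["response"].eq(RESPONSE_OMITTED)
    fast = ~first3 & ~omitted & (trials["rt_ms"] < FAST_RT_MS)

    surviving = ~(first3 | omitted | fast)
    rts = trials.loc[surviving, "rt_ms"]
    if slow_threshold_ms is not None:
        threshold = float(slow_threshold_ms)
    else:
        threshold = float(rts.mean() + n_sd * rts.std(ddof=1)) if len(rts) > 1 else float("inf")
    slow = surviving & (trials["rt_ms"] > threshold)

    report.counts = {
        "first_trials": int(first3.sum()),
        "omission": int(omitted.sum()),
        "fast": int(fast.sum()),
        "slow": int(slow.sum()),
    }
    report.slow_threshold_ms = threshold
    retained = trials[surviving & ~slow].copy()
    report.trials_remaining = retained.groupby("participant_id").size().to_dict()
    return retained, report


def exclude_participants_hddm(
    trials: pd.DataFrame, report: ExclusionReport
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove participants retaining less than 50% of their input trials.

    Exactly 50% retained is kept (the rule is *less than* half).
    ``report`` must come from :func:`exclude_trials_hddm` so the
    pre-exclusion totals are known.
    """
    removed = []
    for pid, n_in in report.trials_in.items():
        n_kept = report.trials_remaining.get(pid, 0)
        if n_kept / n_in < HDDM_VALID_MINIMUM:
            removed.append(pid)
    report.participants_removed_hddm = removed
    retained = trials[~trials["participant_id"].isin(removed)].copy()
    report.trials_remaining = retained.groupby("participant_id").size().to_dict()
    return retained, report


def apply_exclusions(trials: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Run the full chain: study-level, trial-level, then model-level."""
    retained, report = exclude_participants_study(trials)
    retained, report = exclude_trials_hddm(retained, report)
    retained, report = exclude_participants_hddm(retained, report)
    return retained, report
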