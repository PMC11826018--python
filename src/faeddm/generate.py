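"""Synthetic gender face-aftereffect experiments with a known generative truth.

The generator emulates the design of the FAE choice experiment: two groups
of adolescent participants (autistic, AUT, and neurotypical, NT), two
adaptation blocks (androgynous vs. male adaptor, order counterbalanced),
four test-face morph levels (20/40/60/80% male) with 32 repetitions each,
i.e. 128 trials per condition.  Each subject's behaviour is governed by a
drift-diffusion parameter set drawn from group-level normal distributions
(mean mu, precision tau) per parameter cell: one boundary ``a`` and
non-decision time ``t`` per subject, a start point ``b`` per adaptor, and a
drift rate ``v`` per adaptor x morph cell.  Contaminant processes —
response omissions, fast guesses (< 250 ms) and slow outliers — are
injected on top of the diffusion trials, and any RT beyond the response
window is recorded as an omission.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from faeddm.conventions import (
    ADAPTOR_ANDRO,
    ADAPTOR_MALE,
    ADAPTORS,
    ConfigError,
    GROUP_AUT,
    GROUP_NT,
    GROUPS,
    MORPH_LEVELS,
    RESPONSE_FEMALE,
    RESPONSE_MALE,
    RESPONSE_OMITTED,
    TRIAL_COLUMNS,
)
from faeddm.ddm import DDMParameters, simulate_trials

logger = logging.getLogger(__name__)

__all__ = [
    "GroupTruth",
    "GeneratorConfig",
    "SubjectTruth",
    "sample_subject_truth",
    "generate_experiment",
    "preset_paper_like",
    "write_trials",
    "read_trials",
]

#: Clip bounds applied to out-of-domain subject-parameter draws.  Clipping
#: (rather than resampling) keeps the random stream aligned across
#: configurations; clip events are counted and logged.
CLIP_BOUNDS = {"a": (0.05, np.inf), "t": (0.0, 0.6), "b": (0.02, 0.98), "v": (-np.inf, np.inf)}


@dataclass(frozen=True)
class GroupTruth:
    """Group-level generative truth: mean and precision per parameter cell."""

    mu_a: float
    tau_a: float
    mu_t: float
    tau_t: float
    mu_b: dict  # adaptor -> mean
    tau_b: dict
    mu_v: dict  # (adaptor, morph) -> mean
    tau_v: dict

    def __post_init__(self) -> None:
        for name, taus in (
            ("tau_a", [self.tau_a]),
            ("tau_t", [self.tau_t]),
            ("tau_b", list(self.tau_b.values())),
            ("tau_v", list(self.tau_v.values())),
        ):
            if any(tau <= 0 for tau in taus):
                raise ConfigError(f"{name} must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic experiment."""

    group_level_truth: dict  # group label -> GroupTruth
    n_per_group: dict = field(
        default_factory=lambda: {GROUP_AUT: 29, GROUP_NT: 39}
    )
    trials_per_morph: int = 32
    morph_levels: tuple = MORPH_LEVELS
    adaptors: tuple = ADAPTORS
    omission_rate: float = 0.02
    fast_guess_rate: float = 0.02
    slow_outlier_rate: float = 0.02
    response_window_ms: float = 2200.0
    resolution: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.morph_levels or self.trials_per_morph <= 0:
            raise ConfigError("need at least one morph level and positive trials_per_morph")
        if not self.adaptors:
            raise ConfigError("need at least one adaptor condition")
        for r in (self.omission_rate, self.fast_guess_rate, self.slow_outlier_rate):
            if not 0 <= r <= 1:
                raise ConfigError("contamination rates must lie in [0, 1]")
        if self.omission_rate + self.fast_guess_rate + self.slow_outlier_rate > 1:
            raise ConfigError("contamination rates must sum to at most 1")
        if self.response_window_ms <= 250:
            raise ConfigError("response window must exceed the 250 ms fast-guess bound")
        missing = set(self.n_per_group) - set(self.group_level_truth)
        if missing:
            raise ConfigError(f"no generative truth for groups {sorted(missing)}")

    @property
    def trials_per_condition(self) -> int:
        return self.trials_per_morph * len(self.morph_levels)


@dataclass(frozen=True)
class SubjectTruth:
    """One subject's true diffusion parameters across all cells."""

    participant_id: str
    group: str
    a: float
    t: float
    b: dict  # adaptor -> start point
    v: dict  # (adaptor, morph) -> drift

    def params_for(self, adaptor: str, morph: int) -> DDMParameters:
        return DDMParameters(
            a=self.a, t=self.t, b=self.b[adaptor], v=self.v[(adaptor, morph)]
        )


def _sd(tau: float) -> float:
    return 1.0 / np.sqrt(tau)


def _clip_logged(x: np.ndarray, name: str, counter: dict) -> np.ndarray:
    lo, hi = CLIP_BOUNDS[name]
    clipped = np.clip(x, lo, hi)
    counter[name] = counter.get(name, 0) + int(np.sum(clipped != x))
    return clipped


def sample_subject_truth(
    config: GeneratorConfig, rng: np.random.Generator
) -> list[SubjectTruth]:
    """Draw each subject's parameters from their group's cell distributions.

    Draws are iid normal with the configured mean and precision; draws
    outside a parameter's domain are clipped to :data:`CLIP_BOUNDS` and
    the clip count is logged.
    """
    subjects = []
    clip_counts: dict = {}
    for group in sorted(config.n_per_group, key=_group_order):
        truth = config.group_level_truth[group]
        n = config.n_per_group[group]
        a = _clip_logged(rng.normal(truth.mu_a, _sd(truth.tau_a), n), "a", clip_counts)
        t = _clip_logged(rng.normal(truth.mu_t, _sd(truth.tau_t), n), "t", clip_counts)
        b = {
            ad: _clip_logged(
                rng.normal(truth.mu_b[ad], _sd(truth.tau_b[ad]), n), "b", clip_counts
            )
            for ad in config.adaptors
        }
        v = {
            (ad, m): rng.normal(
                truth.mu_v[(ad, m)], _sd(truth.tau_v[(ad, m)]), n
            )
            for ad in config.adaptors
            for m in config.morph_levels
        }
        for i in range(n):
            subjects.append(
                SubjectTruth(
                    participant_id=f"{group}{i + 1:02d}",
                    group=group,
                    a=float(a[i]),
                    t=float(t[i]),
                    b={ad: float(b[ad][i]) for ad in config.adaptors},
                    v={k: float(v[k][i]) for k in v},
                )
            )
    total_clipped = sum(clip_counts.values())
    if total_clipped:
        logger.info("clipped %d out-of-domain subject draws: %s", total_clipped, clip_counts)
    return subjects


def _group_order(g: str):
    return (GROUPS.index(g), g) if g in GROUPS else (len(GROUPS), g)


def generate_experiment(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, list[SubjectTruth]]:
    """Generate a complete synthetic experiment.

    Each participant completes one block per adaptor condition (block order
    counterbalanced by participant parity), with ``trials_per_morph``
    repetitions of every morph level per block in randomised order.  Trial
    choices and RTs are simulated from the subject's cell parameters;
    contaminants are then injected, and RTs beyond the response window
    become omissions.

    Returns the long-format trial table and the list of subject truths.
    """
    rng = np.random.default_rng(config.seed)
    subjects = sample_subject_truth(config, rng)

    rows = []
    for idx, subj in enumerate(subjects):
        block_order = (
            config.adaptors if idx % 2 == 0 else tuple(reversed(config.adaptors))
        )
        for adaptor in block_order:
            morphs = np.repeat(config.morph_levels, config.trials_per_morph)
            rng.shuffle(morphs)
            n_tr = morphs.size
            v = np.array([subj.v[(adaptor, int(m))] for m in morphs])
            ch, rt = simulate_trials(
                n_tr,
                subj.a,
                subj.t,
                subj.b[adaptor],
                v,
                rng,
                resolution=config.resolution,
            )
            rt_ms = rt * 1000.0
            resp = np.where(ch > 0, RESPONSE_MALE, RESPONSE_FEMALE).astype(object)

            # contaminant injection: each trial belongs to at most one process
            u = rng.uniform(size=n_tr)
            p_om, p_fast = config.omission_rate, config.fast_guess_rate
            p_slow = config.slow_outlier_rate
            omit = u < p_om
            fast = (~omit) & (u < p_om + p_fast)
            slow = (~omit) & (~fast) & (u < p_om + p_fast + p_slow)
            if fast.any():
                rt_ms[fast] = rng.uniform(0.0, 250.0, fast.sum())
                resp[fast] = np.where(
                    rng.uniform(size=fast.sum()) < 0.5, RESPONSE_MALE, RESPONSE_FEMALE
                )
            if slow.any():
                rt_ms[slow] = rt_ms[slow] + rng.uniform(600.0, 2000.0, slow.sum())
            late = rt_ms > config.response_window_ms
            omit = omit | late
            rt_ms = np.where(omit, np.nan, rt_ms)
            resp[omit] = RESPONSE_OMITTED

            for j in range(n_tr):
                rows.append(
                    (
                        subj.participant_id,
                        subj.group,
                        adaptor,
                        int(morphs[j]),
                        j,
                        resp[j],
                        rt_ms[j],
                    )
                )

    trials = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    return trials, subjects


# ---------------------------------------------------------------------------
# presets


def _base_truth(v_shift: float, b_shift: float, v_reduction: dict | None = None) -> GroupTruth:
    """Build a GroupTruth from the default cell layout.

    ``v_shift`` is the male-adaptor drift shift (subtracted from every
    male-adaptor drift mean, pushing decisions toward "female" after male
    adaptation — the face aftereffect).  ``b_shift`` shifts the
    male-adaptor start point downward.  ``v_reduction`` maps (adaptor,
    morph) cells to an additional drift decrement.
    """
    v_reduction = v_reduction or {}
    base_v = {20: -1.8, 40: -0.6, 60: 0.6, 80: 1.8}
    mu_v = {}
    for ad in ADAPTORS:
        for m, mu in base_v.items():
            val = mu - (v_shift if ad == ADAPTOR_MALE else 0.0)
            val -= v_reduction.get((ad, m), 0.0)
            mu_v[(ad, m)] = val
    mu_b = {
        ADAPTOR_ANDRO: 0.5,
        ADAPTOR_MALE: 0.5 - b_shift,
    }
    sd_v, sd_b = 0.45, 0.06
    return GroupTruth(
        mu_a=1.5,
        tau_a=1 / 0.25**2,
        mu_t=0.30,
        tau_t=1 / 0.05**2,
        mu_b=mu_b,
        tau_b={ad: 1 / sd_b**2 for ad in ADAPTORS},
        mu_v=mu_v,
        tau_v={k: 1 / sd_v**2 for k in mu_v},
    )


#: Size of the AUT drift reduction injected at the 60/80% (male) morphs in
#: the ``male_drift_reduction`` scenario (evidence units per second).
MALE_DRIFT_REDUCTION = 0.45

SCENARIOS = ("null", "adaptor_shift_only", "male_drift_reduction")


def preset_paper_like(effect: str = "male_drift_reduction", **overrides) -> GeneratorConfig:
    """A documented generator configuration for one of three scenarios.

    * ``null`` — identical groups, no adaptor effect anywhere: drift means
      ordered negative to positive across morph levels, start point 0.5.
    * ``adaptor_shift_only`` — identical groups; the male adaptor shifts
      every drift mean downward (toward "female") and the start point
      slightly toward the female boundary.
    * ``male_drift_reduction`` — as ``adaptor_shift_only``, plus a drift
      reduction of :data:`MALE_DRIFT_REDUCTION` for the AUT group at the
      predominantly male (60/80%) morph levels only.

    Keyword overrides are applied to the returned config (e.g.
    ``n_per_group``, ``trials_per_morph``, ``seed``).
    """
    if effect not in SCENARIOS:
        raise ConfigError(f"unknown scenario {effect!r}; choose from {SCENARIOS}")
    if effect == "null":
        nt = _base_truth(v_shift=0.0, b_shift=0.0)
        aut = nt
    elif effect == "adaptor_shift_only":
        nt = _base_truth(v_shift=0.8, b_shift=0.04)
        aut = nt
    else:
        nt = _base_truth(v_shift=0.8, b_shift=0.04)
        aut = _base_truth(
            v_shift=0.8,
            b_shift=0.04,
            v_reduction={
                (ad, m): MALE_DRIFT_REDUCTION for ad in ADAPTORS for m in (60, 80)
            },
        )
    config = GeneratorConfig(group_level_truth={GROUP_AUT: aut, GROUP_NT: nt})
    if overrides:
        config = replace(config, **overrides)
    return config


# ---------------------------------------------------------------------------
# trial-table I/O


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table to CSV with the canonical column order."""
    trials[list(TRIAL_COLUMNS)].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials` (round-trips exactly)."""
    df = pd.read_csv(
        path,
        dtype={
            "participant_id": str,
            "group": str,
            "adaptor": str,
            "morph_pct": np.int64,
            "trial_index": np.int64,
            "response": str,
            "rt_ms": float,
        },
    )
    return df[list(TRIAL_COLUMNS)]
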