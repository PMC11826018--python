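"""Hierarchical Bayesian drift-diffusion model and its MCMC sampler.

Model
-----
Every trial's signed reaction time is distributed as a Wiener
first-passage time: ``rt_{o,i} ~ wfpt(t_p, a_p, b_{p,adaptor},
v_{p,adaptor,morph})`` — upper boundary for male, lower for female
responses.  Subject-level parameters are exchangeable within their group
cell, ``theta_p ~ Normal(mu_cell, tau_cell)`` (tau = precision), with one
cell per group for ``a`` and ``t``, per group x adaptor for ``b``, and per
group x adaptor x morph for ``v``.  With 2 groups, 2 adaptors and 4 morph
levels that gives 2 + 2 + 4 + 16 = 24 group-level parameter cells.

Sampler
-------
Metropolis-within-Gibbs: adaptive random-walk Metropolis for the subject
parameters (vectorised across subjects, which are conditionally
independent given the cell parameters), exact conjugate Gibbs draws for
the cell means (normal, truncated to the parameter domain) and cell
precisions (gamma).  Chains are independent given distinct sub-seeds and
bit-reproducible.  Convergence is assessed with the split-chain
Gelman–Rubin statistic (R-hat); any parameter at or above the threshold
triggers a recoverable :class:`ConvergenceWarning` that still carries the
samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from faeddm.conventions import (
    ADAPTORS,
    CHOICE_UPPER,
    ConfigError,
    GROUPS,
    RESPONSE_MALE,
    RESPONSE_OMITTED,
)
from faeddm.ddm import wfpt_logpdf

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "Hyperpriors",
    "SamplerConfig",
    "PosteriorSamples",
    "ConvergenceWarning",
    "build_model",
    "log_joint",
    "sample_posterior",
    "rhat",
    "RHAT_THRESHOLD",
]

#: Convergence threshold on the split-chain R-hat.
RHAT_THRESHOLD = 1.01


class ConvergenceWarning(UserWarning):
    """MCMC diagnostics indicate possible non-convergence."""


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """Cell layout and trial-to-cell mapping for one dataset."""

    groups: tuple
    adaptors: tuple
    morphs: tuple
    participants: tuple
    participant_group: np.ndarray  # (n_subj,) group index
    trial_subj: np.ndarray  # (T,) subject index
    trial_b_idx: np.ndarray  # (T,) adaptor index
    trial_v_idx: np.ndarray  # (T,) adaptor*M + morph index
    rt: np.ndarray  # (T,) seconds
    choice: np.ndarray  # (T,) +1 male / -1 female

    @property
    def n_subjects(self) -> int:
        return len(self.participants)

    @property
    def n_trials(self) -> int:
        return self.rt.size

    @property
    def n_group_cells(self) -> int:
        """g + g + g*A + g*A*M group-level mean cells (same count for tau)."""
        g, A, M = len(self.groups), len(self.adaptors), len(self.morphs)
        return g + g + g * A + g * A * M

    def mu_names(self) -> list[str]:
        names = [f"mu_a[{g}]" for g in self.groups]
        names += [f"mu_t[{g}]" for g in self.groups]
        names += [f"mu_b[{g},{a}]" for g in self.groups for a in self.adaptors]
        names += [
            f"mu_v[{g},{a},{m}]"
            for g in self.groups
            for a in self.adaptors
            for m in self.morphs
        ]
        return names


def _ordered(values, reference) -> tuple:
    """Order factor levels by the package convention, unknown levels last."""
    ref = [x for x in reference if x in values]
    extra = sorted(set(values) - set(reference))
    return tuple(ref + extra)


def build_model(trials: pd.DataFrame) -> ModelSpec:
    """Enumerate parameter cells and map every trial onto them.

    Expects the hDDM exclusion chain to have been applied (no omissions,
    no out-of-range RTs).  Raises if any group x adaptor x morph cell has
    no trials at all.
    """
    if trials.empty:
        raise ValueError("empty trial table")
    if trials["response"].eq(RESPONSE_OMITTED).any():
        raise ValueError("omitted trials must be excluded before model building")

    groups = _ordered(trials["group"].unique(), GROUPS)
    adaptors = _ordered(trials["adaptor"].unique(), ADAPTORS)
    morphs = tuple(int(m) for m in sorted(trials["morph_pct"].unique()))

    counts = trials.groupby(["group", "adaptor", "morph_pct"]).size()
    for g in groups:
        for a in adaptors:
            for m in morphs:
                if (g, a, m) not in counts.index:
                    raise ValueError(f"no trials in cell {(g, a, m)}")

    participants = tuple(sorted(trials["participant_id"].unique()))
    p_index = {p: i for i, p in enumerate(participants)}
    p_group = np.empty(len(participants), dtype=np.int64)
    for pid, sub in trials.groupby("participant_id"):
        p_group[p_index[pid]] = groups.index(sub["group"].iloc[0])

    a_index = {a: i for i, a in enumerate(adaptors)}
    m_index = {m: i for i, m in enumerate(morphs)}
    M = len(morphs)

    subj = trials["participant_id"].map(p_index).to_numpy()
    b_idx = trials["adaptor"].map(a_index).to_numpy()
    v_idx = b_idx * M + trials["morph_pct"].map(m_index).to_numpy()
    rt = trials["rt_ms"].to_numpy(dtype=float) / 1000.0
    choice = np.where(trials["response"].eq(RESPONSE_MALE), 1, -1)

    return ModelSpec(
        groups=groups,
        adaptors=adaptors,
        morphs=morphs,
        participants=participants,
        participant_group=p_group,
        trial_subj=subj,
        trial_b_idx=b_idx,
        trial_v_idx=v_idx,
        rt=rt,
        choice=choice,
    )


# ---------------------------------------------------------------------------
# priors and sampler configuration


@dataclass(frozen=True)
class PriorSpec:
    """A (possibly truncated) normal prior: Normal(loc, scale) on (lo, hi)."""

    loc: float
    scale: float
    lo: float = -np.inf
    hi: float = np.inf


@dataclass(frozen=True)
class Hyperpriors:
    """Weakly-informative hyperpriors for the 24 cell means and precisions.

    Cell-mean priors are broad normals truncated to each parameter's
    domain; cell-precision priors are Gamma(shape, rate) with mean 1 and
    variance 10 by default.  All values are plain configuration.
    """

    mu_a: PriorSpec = PriorSpec(1.5, 5.0, 0.0, np.inf)
    mu_t: PriorSpec = PriorSpec(0.3, 1.0, 0.0, np.inf)
    mu_b: PriorSpec = PriorSpec(0.5, 1.0, 0.0, 1.0)
    mu_v: PriorSpec = PriorSpec(0.0, 5.0)
    tau_shape: float = 0.1
    tau_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.tau_shape <= 0 or self.tau_rate <= 0:
            raise ConfigError("tau prior shape and rate must be positive")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings; retained draws per chain = n_iterations - n_burn_in."""

    n_chains: int = 2
    n_iterations: int = 20_000
    n_burn_in: int = 15_000
    seed: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.44
    tau_init: float = 1.0
    sample_tau: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ConfigError("need at least one chain")
        if not (0 <= self.n_burn_in < self.n_iterations):
            raise ConfigError("burn-in must be shorter than the chain")

    @property
    def n_retained(self) -> int:
        return self.n_iterations - self.n_burn_in


# subject-level parameter domains (walls enforced in the MH step)
_DOMAINS = {"a": (0.0, np.inf), "t": (0.0, np.inf), "b": (0.0, 1.0), "v": (-np.inf, np.inf)}


def _default_loglik(rt, choice, a, t, b, v):
    return wfpt_logpdf(rt, choice, a, t, b, v)


# ---------------------------------------------------------------------------
# log joint density


def log_joint(spec: ModelSpec, hyper: Hyperpriors, state: dict, loglik=None) -> float:
    """Unnormalised log joint of all parameters and the trials.

    ``state`` holds subject arrays ``a (n,), t (n,), b (n, A), v (n, A*M)``
    and cell arrays ``mu_a (G,), tau_a (G,), mu_t, tau_t, mu_b (G, A),
    tau_b, mu_v (G, A, M), tau_v``.  Returns ``-inf`` whenever any
    parameter sits outside its domain, so rejection-style samplers can use
    it directly.  (Truncation constants of the hyperpriors are omitted;
    they do not depend on the parameters.)
    """
    loglik = loglik or _default_loglik
    G = len(spec.groups)
    M = len(spec.morphs)
    a, t, b, v = state["a"], state["t"], state["b"], state["v"]

    if not (np.all(a > 0) and np.all((b > 0) & (b < 1)) and np.all(t >= 0)):
        return -np.inf
    for fam in ("a", "t", "b", "v"):
        pr: PriorSpec = getattr(hyper, f"mu_{fam}")
        mu = np.asarray(state[f"mu_{fam}"], dtype=float)
        tau = np.asarray(state[f"tau_{fam}"], dtype=float)
        if np.any(tau <= 0):
            return -np.inf
        if not np.all((mu > pr.lo) & (mu < pr.hi)):
            return -np.inf

    from scipy.special import gammaln

    total = 0.0
    # hyperpriors
    for fam in ("a", "t", "b", "v"):
        pr = getattr(hyper, f"mu_{fam}")
        mu = np.asarray(state[f"mu_{fam}"], dtype=float)
        tau = np.asarray(state[f"tau_{fam}"], dtype=float)
        total += float(
            np.sum(-0.5 * np.log(2 * np.pi * pr.scale**2) - (mu - pr.loc) ** 2 / (2 * pr.scale**2))
        )
        total += float(
            np.sum(
                hyper.tau_shape * np.log(hyper.tau_rate)
                - gammaln(hyper.tau_shape)
                + (hyper.tau_shape - 1) * np.log(tau)
                - hyper.tau_rate * tau
            )
        )

    # subject-level priors
    gi = spec.participant_group
    for fam, arr in (("a", a), ("t", t)):
        mu = np.asarray(state[f"mu_{fam}"])[gi]
        tau = np.asarray(state[f"tau_{fam}"])[gi]
        total += float(np.sum(0.5 * np.log(tau / (2 * np.pi)) - 0.5 * tau * (arr - mu) ** 2))
    mu_b = np.asarray(state["mu_b"])[gi]  # (n, A)
    tau_b = np.asarray(state["tau_b"])[gi]
    total += float(np.sum(0.5 * np.log(tau_b / (2 * np.pi)) - 0.5 * tau_b * (b - mu_b) ** 2))
    mu_v = np.asarray(state["mu_v"]).reshape(G, -1)[gi]  # (n, A*M)
    tau_v = np.asarray(state["tau_v"]).reshape(G, -1)[gi]
    total += float(np.sum(0.5 * np.log(tau_v / (2 * np.pi)) - 0.5 * tau_v * (v - mu_v) ** 2))

    # trial likelihood
    s = spec.trial_subj
    ll = loglik(
        spec.rt,
        spec.choice,
        a[s],
        t[s],
        b[s, spec.trial_b_idx],
        v[s, spec.trial_v_idx],
    )
    total += float(np.sum(ll))
    return total


# ---------------------------------------------------------------------------
# posterior samples container


@dataclass
class PosteriorSamples:
    """Chains x retained draws for every parameter, with diagnostics."""

    draws: dict  # name -> (n_chains, n_retained)
    rhat: dict  # name -> float
    config: SamplerConfig
    meta: dict  # groups/adaptors/morphs/participants
    converged: bool = True

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated for one parameter."""
        return self.draws[name].reshape(-1)

    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def names(self) -> list[str]:
        return list(self.draws)

    def to_frame(self) -> pd.DataFrame:
        """Columnar layout: one column per parameter, chain-ordered rows."""
        return pd.DataFrame({k: self.pooled(k) for k in self.draws})

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(d / "posterior.csv", index=False)
        sidecar = {
            "rhat": self.rhat,
            "converged": self.converged,
            "config": {
                "n_chains": self.config.n_chains,
                "n_iterations": self.config.n_iterations,
                "n_burn_in": self.config.n_burn_in,
                "seed": self.config.seed,
            },
            "meta": {
                k: list(v) if isinstance(v, (tuple, list)) else v
                for k, v in self.meta.items()
            },
        }
        (d / "posterior_meta.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, directory) -> "PosteriorSamples":
        from pathlib import Path

        d = Path(directory)
        frame = pd.read_csv(d / "posterior.csv")
        sidecar = json.loads((d / "posterior_meta.json").read_text())
        cfg = sidecar["config"]
        config = SamplerConfig(
            n_chains=cfg["n_chains"],
            n_iterations=cfg["n_iterations"],
            n_burn_in=cfg["n_burn_in"],
            seed=cfg["seed"],
        )
        n_c = config.n_chains
        draws = {
            k: frame[k].to_numpy().reshape(n_c, -1) for k in frame.columns
        }
        return cls(
            draws=draws,
            rhat=sidecar["rhat"],
            config=config,
            meta=sidecar["meta"],
            converged=sidecar["converged"],
        )


# ---------------------------------------------------------------------------
# R-hat


def rhat(chains, split: bool = True) -> float:
    """Gelman–Rubin potential scale reduction factor.

    ``chains`` is an (m, n) array of m chains with n draws each.  With
    ``split=True`` (default) each chain is halved first, the more
    stringent modern variant.  Requires at least two chains of at least
    two draws.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("rhat needs >= 2 chains with >= 2 draws each")
    if split:
        n = x.shape[1] // 2
        if n < 2:
            raise ValueError("chains too short to split")
        x = np.vstack([x[:, :n], x[:, x.shape[1] - n :]])
    m, n = x.shape
    means = x.mean(axis=1)
    W = float(np.mean(x.var(axis=1, ddof=1)))
    B = n * float(np.var(means, ddof=1))
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


# ---------------------------------------------------------------------------
# the sampler


def _trunc_normal(rng, m, sd, lo, hi):
    """Vectorised truncated-normal draws via inverse-CDF."""
    a = ndtr((lo - m) / sd)
    b_ = ndtr((hi - m) / sd)
    u = rng.uniform(a, b_)
    u = np.clip(u, 1e-15, 1 - 1e-15)
    return m + sd * ndtri(u)


def _gibbs_mu_tau(rng, values, gi, G, prior: PriorSpec, hyper, cfg, mu, tau):
    """Conjugate updates for one parameter family.

    ``values`` is (n_subj,) or (n_subj, C); mu/tau are (G,) or (G, C).
    Returns updated (mu, tau).
    """
    vals = values if values.ndim == 2 else values[:, None]
    C = vals.shape[1]
    mu2 = mu.reshape(G, C).copy()
    tau2 = tau.reshape(G, C).copy()
    prior_prec = 1.0 / prior.scale**2
    for g in range(G):
        sel = vals[gi == g]  # (n_g, C)
        n_g = sel.shape[0]
        post_prec = prior_prec + n_g * tau2[g]
        post_mean = (prior_prec * prior.loc + tau2[g] * sel.sum(axis=0)) / post_prec
        mu2[g] = _trunc_normal(rng, post_mean, 1.0 / np.sqrt(post_prec), prior.lo, prior.hi)
        if cfg.sample_tau:
            shape = hyper.tau_shape + n_g / 2.0
            rate = hyper.tau_rate + 0.5 * ((sel - mu2[g]) ** 2).sum(axis=0)
            tau2[g] = rng.gamma(shape, 1.0 / rate)
    return mu2.reshape(mu.shape), tau2.reshape(tau.shape)


def _run_chain(spec: ModelSpec, hyper: Hyperpriors, cfg: SamplerConfig, seed, loglik):
    rng = np.random.default_rng(seed)
    n_s = spec.n_subjects
    G, A, M = len(spec.groups), len(spec.adaptors), len(spec.morphs)
    gi = spec.participant_group
    s_of_trial = spec.trial_subj

    # --- initial state: prior centers with chain-specific jitter
    min_rt = np.full(n_s, np.inf)
    np.minimum.at(min_rt, s_of_trial, spec.rt)
    min_rt[~np.isfinite(min_rt)] = 1.0
    a = np.clip(hyper.mu_a.loc + 0.15 * rng.standard_normal(n_s), 0.3, None)
    t = np.clip(0.5 * min_rt * (1 + 0.1 * rng.standard_normal(n_s)), 0.0, None)
    b = np.clip(hyper.mu_b.loc + 0.03 * rng.standard_normal((n_s, A)), 0.05, 0.95)
    v = hyper.mu_v.loc + 0.3 * rng.standard_normal((n_s, A * M))

    mu_a = np.array([a[gi == g].mean() for g in range(G)])
    mu_t = np.array([t[gi == g].mean() for g in range(G)])
    mu_b = np.vstack([b[gi == g].mean(axis=0) for g in range(G)])
    mu_v = np.vstack([v[gi == g].mean(axis=0) for g in range(G)]).reshape(G, A, M)
    tau_a = np.full(G, cfg.tau_init)
    tau_t = np.full(G, cfg.tau_init)
    tau_b = np.full((G, A), cfg.tau_init)
    tau_v = np.full((G, A, M), cfg.tau_init)

    # --- per-slot bookkeeping
    # slots: ("a", None), ("t", None), a joint ("at", None) move to cut the
    # boundary/non-decision-time posterior correlation, ("b", j) x A,
    # ("v", k) x A*M
    slots = [("a", None), ("t", None), ("at", None)]
    slots += [("b", j) for j in range(A)]
    slots += [("v", k) for k in range(A * M)]
    slot_trials = {}
    for fam, j in slots:
        if fam in ("a", "t", "at"):
            slot_trials[(fam, j)] = np.arange(spec.n_trials)
        elif fam == "b":
            slot_trials[(fam, j)] = np.nonzero(spec.trial_b_idx == j)[0]
        else:
            slot_trials[(fam, j)] = np.nonzero(spec.trial_v_idx == j)[0]

    init_scale = {"a": 0.15, "t": 0.03, "at": 0.08, "b": 0.04, "v": 0.3}
    scales = {sl: np.full(n_s, init_scale[sl[0]]) for sl in slots}
    acc_count = {sl: np.zeros(n_s) for sl in slots}
    adapt_round = 0

    def trial_ll(idx, a_, t_, b_, v_):
        s = s_of_trial[idx]
        return loglik(
            spec.rt[idx],
            spec.choice[idx],
            a_[s],
            t_[s],
            b_[s, spec.trial_b_idx[idx]],
            v_[s, spec.trial_v_idx[idx]],
        )

    cur_ll = trial_ll(np.arange(spec.n_trials), a, t, b, v)

    n_keep = cfg.n_retained
    out_mu = np.empty((n_keep, G * 2 + G * A + G * A * M))
    out_tau = np.empty_like(out_mu)
    out_subj = np.empty((n_keep, n_s * (2 + A + A * M)))

    for it in range(cfg.n_iterations):
        for sl in slots:
            fam, j = sl
            idx = slot_trials[sl]
            if fam == "at":
                # joint move: shift a and t together (anti-correlated
                # posterior direction), full-trial likelihood
                z = scales[sl] * rng.standard_normal(n_s)
                a_prop = a + z
                t_prop = t - 0.5 * z
                valid = (a_prop > 0) & (t_prop >= 0)
                a_safe = np.where(valid, a_prop, a)
                t_safe = np.where(valid, t_prop, t)
                new_ll = trial_ll(idx, a_safe, t_safe, b, v)
                dll = np.bincount(
                    s_of_trial[idx], weights=new_ll - cur_ll[idx], minlength=n_s
                )
                dprior = -0.5 * tau_a[gi] * ((a_safe - mu_a[gi]) ** 2 - (a - mu_a[gi]) ** 2)
                dprior += -0.5 * tau_t[gi] * ((t_safe - mu_t[gi]) ** 2 - (t - mu_t[gi]) ** 2)
                log_alpha = np.where(valid, dll + dprior, -np.inf)
                accept = np.log(rng.uniform(size=n_s)) < log_alpha
                a = np.where(accept, a_safe, a)
                t = np.where(accept, t_safe, t)
                tr_acc = accept[s_of_trial[idx]]
                cur_ll[idx] = np.where(tr_acc, new_ll, cur_ll[idx])
                acc_count[sl] += accept
                continue
            if fam == "a":
                cur_vals, lo, hi = a, *_DOMAINS["a"]
                mu_c, tau_c = mu_a[gi], tau_a[gi]
            elif fam == "t":
                cur_vals, lo, hi = t, *_DOMAINS["t"]
                mu_c, tau_c = mu_t[gi], tau_t[gi]
            elif fam == "b":
                cur_vals, lo, hi = b[:, j], *_DOMAINS["b"]
                mu_c, tau_c = mu_b[gi, j], tau_b[gi, j]
            else:
                cur_vals, lo, hi = v[:, j], *_DOMAINS["v"]
                mu_c = mu_v.reshape(G, -1)[gi, j]
                tau_c = tau_v.reshape(G, -1)[gi, j]

            prop = cur_vals + scales[sl] * rng.standard_normal(n_s)
            valid = (prop > lo) & (prop < hi)
            safe = np.where(valid, prop, cur_vals)

            if fam == "a":
                new_ll = trial_ll(idx, safe, t, b, v)
            elif fam == "t":
                new_ll = trial_ll(idx, a, safe, b, v)
            elif fam == "b":
                b_try = b.copy()
                b_try[:, j] = safe
                new_ll = trial_ll(idx, a, t, b_try, v)
            else:
                v_try = v.copy()
                v_try[:, j] = safe
                new_ll = trial_ll(idx, a, t, b, v_try)

            dll = np.bincount(
                s_of_trial[idx], weights=new_ll - cur_ll[idx], minlength=n_s
            )
            dprior = -0.5 * tau_c * ((safe - mu_c) ** 2 - (cur_vals - mu_c) ** 2)
            log_alpha = np.where(valid, dll + dprior, -np.inf)
            accept = np.log(rng.uniform(size=n_s)) < log_alpha

            if np.any(accept):
                if fam == "a":
                    a = np.where(accept, safe, a)
                elif fam == "t":
                    t = np.where(accept, safe, t)
                elif fam == "b":
                    b[:, j] = np.where(accept, safe, b[:, j])
                else:
                    v[:, j] = np.where(accept, safe, v[:, j])
                tr_acc = accept[s_of_trial[idx]]
                cur_ll[idx] = np.where(tr_acc, new_ll, cur_ll[idx])
                if fam in ("a", "t"):
                    # a/t changed for accepted subjects: cur_ll already
                    # refreshed on all trials (idx covers everything)
                    pass
            acc_count[sl] += accept

        # --- conjugate Gibbs for cell means and precisions
        mu_a, tau_a = _gibbs_mu_tau(rng, a, gi, G, hyper.mu_a, hyper, cfg, mu_a, tau_a)
        mu_t, tau_t = _gibbs_mu_tau(rng, t, gi, G, hyper.mu_t, hyper, cfg, mu_t, tau_t)
        mu_b, tau_b = _gibbs_mu_tau(rng, b, gi, G, hyper.mu_b, hyper, cfg, mu_b, tau_b)
        mu_v2, tau_v2 = _gibbs_mu_tau(
            rng, v, gi, G, hyper.mu_v, hyper, cfg, mu_v.reshape(G, -1), tau_v.reshape(G, -1)
        )
        mu_v, tau_v = mu_v2.reshape(G, A, M), tau_v2.reshape(G, A, M)

        # --- proposal-scale adaptation (burn-in only, diminishing)
        if it < cfg.n_burn_in and (it + 1) % cfg.adapt_interval == 0:
            adapt_round += 1
            step = 1.0 / np.sqrt(adapt_round)
            for sl in slots:
                rate = acc_count[sl] / cfg.adapt_interval
                scales[sl] *= np.exp(step * (rate - cfg.target_accept))
                acc_count[sl][:] = 0.0

        if it >= cfg.n_burn_in:
            k = it - cfg.n_burn_in
            out_mu[k] = np.concatenate(
                [mu_a, mu_t, mu_b.ravel(), mu_v.ravel()]
            )
            out_tau[k] = np.concatenate(
                [tau_a, tau_t, tau_b.ravel(), tau_v.ravel()]
            )
            out_subj[k] = np.concatenate([a, t, b.ravel(), v.ravel()])

    return out_mu, out_tau, out_subj


def _subject_names(spec: ModelSpec) -> list[str]:
    A, M = len(spec.adaptors), len(spec.morphs)
    names = [f"a[{p}]" for p in spec.participants]
    names += [f"t[{p}]" for p in spec.participants]
    names += [f"b[{p},{ad}]" for p in spec.participants for ad in spec.adaptors]
    names += [
        f"v[{p},{ad},{m}]"
        for p in spec.participants
        for ad in spec.adaptors
        for m in spec.morphs
    ]
    return names


def sample_posterior(
    spec: ModelSpec,
    hyper: Hyperpriors | None = None,
    config: SamplerConfig | None = None,
    loglik=None,
) -> PosteriorSamples:
    """Draw posterior samples for all group- and subject-level parameters.

    Runs ``config.n_chains`` independent chains (distinct sub-seeds of
    ``config.seed``), discards the burn-in, computes split-chain R-hat for
    every stored parameter, and warns (recoverably) if any exceeds
    :data:`RHAT_THRESHOLD`.  ``loglik`` may override the per-trial
    log-likelihood (signature ``(rt, choice, a, t, b, v)``) — used by
    validation tests with tractable likelihoods.
    """
    hyper = hyper or Hyperpriors()
    config = config or SamplerConfig()
    loglik = loglik or _default_loglik

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains_mu, chains_tau, chains_subj = [], [], []
    for cs in seeds:
        out_mu, out_tau, out_subj = _run_chain(spec, hyper, config, cs, loglik)
        chains_mu.append(out_mu)
        chains_tau.append(out_tau)
        chains_subj.append(out_subj)

    mu_names = spec.mu_names()
    tau_names = [n.replace("mu_", "tau_", 1) for n in mu_names]
    subj_names = _subject_names(spec)

    draws: dict = {}
    for i, name in enumerate(mu_names):
        draws[name] = np.stack([c[:, i] for c in chains_mu])
    for i, name in enumerate(tau_names):
        draws[name] = np.stack([c[:, i] for c in chains_tau])
    for i, name in enumerate(subj_names):
        draws[name] = np.stack([c[:, i] for c in chains_subj])

    rhats = {}
    for name, arr in draws.items():
        if config.n_chains >= 2 and arr.shape[1] >= 4:
            rhats[name] = rhat(arr, split=True)
        else:
            rhats[name] = float("nan")

    finite = [r for r in rhats.values() if np.isfinite(r)]
    converged = bool(finite) and max(finite) < RHAT_THRESHOLD
    samples = PosteriorSamples(
        draws=draws,
        rhat=rhats,
        config=config,
        meta={
            "groups": spec.groups,
            "adaptors": spec.adaptors,
            "morphs": spec.morphs,
            "participants": spec.participants,
        },
        converged=converged,
    )
    if not converged:
        if finite:
            worst = max((r, n) for n, r in rhats.items() if np.isfinite(r))
            msg = f"possible non-convergence: max split R-hat {worst[0]:.4f} ({worst[1]})"
        else:
            msg = "convergence not assessable (fewer than two chains)"
        warnings.warn(msg, ConvergenceWarning, stacklevel=2)
    return samples
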