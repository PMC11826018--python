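"""Hierarchical DDM: model building, log joint, R-hat, sampler correctness."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from faeddm.conventions import ConfigError
from faeddm.ddm import wfpt_density, SignedResponse, DDMParameters
from faeddm.hddm import (
    ConvergenceWarning,
    Hyperpriors,
    ModelSpec,
    SamplerConfig,
    build_model,
    log_joint,
    rhat,
    sample_posterior,
)


def trials_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["participant_id", "group", "adaptor", "morph_pct", "trial_index", "response", "rt_ms"],
    )


def dense_trials(groups, adaptors, morphs, n_subj=2, n_per_cell=3, rt=600.0):
    rows = []
    for g in groups:
        for i in range(n_subj):
            pid = f"{g}{i:02d}"
            for ad in adaptors:
                for k, m in enumerate(morphs):
                    for r in range(n_per_cell):
                        rows.append((pid, g, ad, m, k * n_per_cell + r, "male", rt + 10 * r))
    return trials_frame(rows)


class TestBuildModel:
    @pytest.mark.parametrize(
        "groups,adaptors,morphs,expected",
        [
            (("AUT", "NT"), ("androgynous", "male"), (20, 40, 60, 80), 24),
            (("NT",), ("androgynous",), (50,), 4),
            (("AUT", "NT", "X"), ("androgynous", "male"), (20, 40, 60, 80), 36),
        ],
    )
    def test_cell_counting_formula(self, groups, adaptors, morphs, expected):
        spec = build_model(dense_trials(groups, adaptors, morphs))
        assert spec.n_group_cells == expected
        assert len(spec.mu_names()) == expected

    def test_empty_cell_errors(self):
        trials = dense_trials(("NT",), ("androgynous", "male"), (20, 40))
        missing = trials[~((trials["adaptor"] == "male") & (trials["morph_pct"] == 40))]
        with pytest.raises(ValueError):
            build_model(missing)

    def test_omissions_rejected(self):
        trials = dense_trials(("NT",), ("androgynous",), (50,))
        trials.loc[0, "response"] = "omitted"
        with pytest.raises(ValueError):
            build_model(trials)

    def test_trial_mapping(self, tiny_cohort):
        from faeddm.preprocess import apply_exclusions

        _, trials, _ = tiny_cohort
        kept, _ = apply_exclusions(trials)
        spec = build_model(kept)
        assert spec.n_trials == len(kept)
        assert spec.groups == ("AUT", "NT")
        # every trial's v cell index is consistent with its adaptor index
        M = len(spec.morphs)
        assert np.all(spec.trial_v_idx // M == spec.trial_b_idx)


def naive_log_joint(spec, hyper, state):
    """Independent slow recomputation: plain loops and scipy distributions."""
    total = 0.0
    G = len(spec.groups)
    M = len(spec.morphs)
    for fam in ("a", "t", "b", "v"):
        pr = getattr(hyper, f"mu_{fam}")
        mu = np.atleast_1d(np.asarray(state[f"mu_{fam}"], dtype=float)).ravel()
        tau = np.atleast_1d(np.asarray(state[f"tau_{fam}"], dtype=float)).ravel()
        for x in mu:
            total += norm.logpdf(x, pr.loc, pr.scale)
        for x in tau:
            total += gamma_dist.logpdf(x, hyper.tau_shape, scale=1 / hyper.tau_rate)
    for s in range(spec.n_subjects):
        g = spec.participant_group[s]
        total += norm.logpdf(state["a"][s], state["mu_a"][g], 1 / np.sqrt(state["tau_a"][g]))
        total += norm.logpdf(state["t"][s], state["mu_t"][g], 1 / np.sqrt(state["tau_t"][g]))
        for j in range(len(spec.adaptors)):
            total += norm.logpdf(
                state["b"][s, j], state["mu_b"][g, j], 1 / np.sqrt(state["tau_b"][g, j])
            )
            for k in range(M):
                total += norm.logpdf(
                    state["v"][s, j * M + k],
                    state["mu_v"][g, j, k],
                    1 / np.sqrt(state["tau_v"][g, j, k]),
                )
    for i in range(spec.n_trials):
        s = spec.trial_subj[i]
        params = DDMParameters(
            a=state["a"][s],
            t=state["t"][s],
            b=state["b"][s, spec.trial_b_idx[i]],
            v=state["v"][s, spec.trial_v_idx[i]],
        )
        dens = wfpt_density(SignedResponse(int(spec.choice[i]), float(spec.rt[i])), params)
        total += np.log(dens) if dens > 0 else -np.inf
    return total


def random_state_for(spec, rng):
    G, A, M = len(spec.groups), len(spec.adaptors), len(spec.morphs)
    n = spec.n_subjects
    return {
        "a": rng.uniform(1.0, 2.0, n),
        "t": rng.uniform(0.1, 0.3, n),
        "b": rng.uniform(0.3, 0.7, (n, A)),
        "v": rng.normal(0, 1, (n, A * M)),
        "mu_a": rng.uniform(1.0, 2.0, G),
        "tau_a": rng.uniform(0.5, 2.0, G),
        "mu_t": rng.uniform(0.1, 0.3, G),
        "tau_t": rng.uniform(0.5, 2.0, G),
        "mu_b": rng.uniform(0.3, 0.7, (G, A)),
        "tau_b": rng.uniform(0.5, 2.0, (G, A)),
        "mu_v": rng.normal(0, 1, (G, A, M)),
        "tau_v": rng.uniform(0.5, 2.0, (G, A, M)),
    }


class TestLogJoint:
    def _small_spec(self):
        rows = [
            ("NT00", "NT", "androgynous", 50, i, resp, rt)
            for i, (resp, rt) in enumerate(
                [("male", 600.0), ("female", 700.0), ("male", 800.0), ("male", 550.0), ("female", 900.0)]
            )
        ]
        return build_model(trials_frame(rows))

    def test_matches_naive_recomputation(self, rng):
        spec = self._small_spec()
        hyper = Hyperpriors()
        state = random_state_for(spec, rng)
        assert log_joint(spec, hyper, state) == pytest.approx(
            naive_log_joint(spec, hyper, state), abs=1e-10
        )

    def test_single_trial_additivity(self, rng):
        spec = self._small_spec()
        hyper = Hyperpriors()
        state = random_state_for(spec, rng)
        empty = ModelSpec(
            groups=spec.groups,
            adaptors=spec.adaptors,
            morphs=spec.morphs,
            participants=spec.participants,
            participant_group=spec.participant_group,
            trial_subj=np.empty(0, dtype=int),
            trial_b_idx=np.empty(0, dtype=int),
            trial_v_idx=np.empty(0, dtype=int),
            rt=np.empty(0),
            choice=np.empty(0, dtype=int),
        )
        prior_only = log_joint(empty, hyper, state)
        one = ModelSpec(
            groups=spec.groups,
            adaptors=spec.adaptors,
            morphs=spec.morphs,
            participants=spec.participants,
            participant_group=spec.participant_group,
            trial_subj=spec.trial_subj[:1],
            trial_b_idx=spec.trial_b_idx[:1],
            trial_v_idx=spec.trial_v_idx[:1],
            rt=spec.rt[:1],
            choice=spec.choice[:1],
        )
        lik = log_joint(one, hyper, state) - prior_only
        params = DDMParameters(
            a=state["a"][0], t=state["t"][0], b=state["b"][0, 0], v=state["v"][0, 0]
        )
        dens = wfpt_density(SignedResponse(int(spec.choice[0]), float(spec.rt[0])), params)
        assert lik == pytest.approx(np.log(dens), abs=1e-10)

    def test_out_of_domain_is_minus_inf(self, rng):
        spec = self._small_spec()
        state = random_state_for(spec, rng)
        state["a"] = np.array([-1.0])
        assert log_joint(spec, Hyperpriors(), state) == -np.inf


class TestRhat:
    def test_hand_oracle_unsplit(self):
        # chains [1,2,3] and [2,3,4]: W = 1, B = 1.5, var+ = 7/6
        val = rhat(np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]]), split=False)
        assert val == pytest.approx(np.sqrt(7 / 6), abs=1e-12)

    def test_identical_distributions_near_one(self, rng):
        chains = rng.standard_normal((2, 5000))
        assert abs(rhat(chains) - 1.0) < 0.01

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.standard_normal(500), rng.standard_normal(500) + 10])
        assert rhat(chains) > 1.5

    def test_single_chain_errors(self):
        with pytest.raises(ValueError):
            rhat(np.ones((1, 100)))

    def test_matches_arviz_split_variant(self, rng):
        az = pytest.importorskip("arviz")
        chains = rng.standard_normal((4, 1000)) + rng.standard_normal((4, 1))
        ours = rhat(chains, split=True)
        theirs = float(az.rhat(chains, method="split"))
        assert ours == pytest.approx(theirs, rel=1e-6)


class TestSampler:
    def test_config_validation(self):
        with pytest.raises(ConfigError):
            SamplerConfig(n_iterations=100, n_burn_in=100)
        with pytest.raises(ConfigError):
            SamplerConfig(n_chains=0)
        assert SamplerConfig(n_iterations=20_000, n_burn_in=15_000).n_retained == 5000

    def test_determinism_and_draw_counts(self):
        spec = build_model(dense_trials(("NT",), ("androgynous",), (50,), n_subj=3, n_per_cell=4))
        cfg = SamplerConfig(n_chains=2, n_iterations=120, n_burn_in=60, seed=4)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            s1 = sample_posterior(spec, config=cfg)
            s2 = sample_posterior(spec, config=cfg)
        for name in s1.names():
            assert s1.draws[name].shape == (2, 60)
            np.testing.assert_array_equal(s1.draws[name], s2.draws[name])

    def test_short_run_warns_but_returns(self):
        spec = build_model(dense_trials(("NT",), ("androgynous",), (50,), n_subj=3))
        cfg = SamplerConfig(n_chains=2, n_iterations=40, n_burn_in=10, seed=1)
        with pytest.warns(ConvergenceWarning):
            samples = sample_posterior(spec, config=cfg)
        assert not samples.converged
        assert samples.max_rhat() > 1.0

    def test_conjugate_reduction_matches_closed_form(self):
        """Normal-likelihood hook: posterior means match the Gaussian linear model.

        Data y_si ~ N(theta_s, 1), theta_s ~ N(mu, 1) (tau frozen at 1),
        mu ~ N(1.5, 25).  The exact posterior is jointly Gaussian and
        computable by a precision-matrix solve.
        """
        rng = np.random.default_rng(12)
        n_subj, n_tr = 6, 20
        theta_true = rng.normal(3.0, 1.0, n_subj)
        rows = []
        ys = np.empty((n_subj, n_tr))
        for s in range(n_subj):
            ys[s] = rng.normal(theta_true[s], 1.0, n_tr)
            for i in range(n_tr):
                rows.append((f"NT{s:02d}", "NT", "androgynous", 50, i, "male", 1000.0 * ys[s, i]))
        spec = build_model(trials_frame(rows))

        def normal_loglik(rt, choice, a, t, b, v):
            return norm.logpdf(rt, a, 1.0)

        cfg = SamplerConfig(
            n_chains=2, n_iterations=4000, n_burn_in=1000, seed=9, sample_tau=False, tau_init=1.0
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            samples = sample_posterior(spec, config=cfg, loglik=normal_loglik)

        # exact posterior: precision matrix over (mu, theta_1..theta_6)
        prior = Hyperpriors().mu_a  # N(1.5, 5) truncated at 0 (negligible here)
        P = np.zeros((n_subj + 1, n_subj + 1))
        rhs = np.zeros(n_subj + 1)
        P[0, 0] = 1 / prior.scale**2 + n_subj * 1.0
        rhs[0] = prior.loc / prior.scale**2
        for s in range(n_subj):
            P[0, s + 1] = P[s + 1, 0] = -1.0
            P[s + 1, s + 1] = 1.0 + n_tr
            rhs[s + 1] = ys[s].sum()
        exact = np.linalg.solve(P, rhs)

        assert np.mean(samples.pooled("mu_a[NT]")) == pytest.approx(exact[0], abs=0.1)
        for s in range(n_subj):
            est = np.mean(samples.pooled(f"a[NT{s:02d}]"))
            assert est == pytest.approx(exact[s + 1], abs=0.1)
        # frozen precision stayed frozen
        assert np.all(samples.pooled("tau_a[NT]") == 1.0)
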