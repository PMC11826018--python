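"""Shared fixtures: small generated cohorts and one reusable MCMC fit."""

import warnings

import numpy as np
import pytest

from faeddm.generate import generate_experiment, preset_paper_like
from faeddm.hddm import ConvergenceWarning, SamplerConfig, build_model, sample_posterior
from faeddm.preprocess import apply_exclusions


@pytest.fixture(scope="session")
def tiny_cohort():
    """4+4 participants, 8 trials/morph, with contaminants; deterministic."""
    config = preset_paper_like(
        "male_drift_reduction",
        n_per_group={"AUT": 4, "NT": 4},
        trials_per_morph=8,
        seed=101,
        resolution=4e-4,
    )
    trials, subjects = generate_experiment(config)
    return config, trials, subjects


@pytest.fixture(scope="session")
def small_fit(tiny_cohort):
    """A quick hierarchical fit on the tiny cohort (not convergence-grade)."""
    _, trials, _ = tiny_cohort
    kept, _ = apply_exclusions(trials)
    spec = build_model(kept)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        samples = sample_posterior(
            spec, config=SamplerConfig(n_chains=2, n_iterations=1200, n_burn_in=600, seed=7)
        )
    return spec, samples


@pytest.fixture(scope="session")
def acceptance_fit():
    """The scaled-down convergence-grade fit: 8 subjects/group, 16 trials/morph."""
    config = preset_paper_like(
        "male_drift_reduction",
        n_per_group={"AUT": 8, "NT": 8},
        trials_per_morph=16,
        seed=11,
    )
    trials, _ = generate_experiment(config)
    kept, _ = apply_exclusions(trials)
    spec = build_model(kept)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        samples = sample_posterior(
            spec,
            config=SamplerConfig(n_chains=2, n_iterations=12_000, n_burn_in=6_000, seed=5),
        )
    return config, spec, samples


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
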