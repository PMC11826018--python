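"""End-to-end orchestration: one config, one reproducible output bundle.

A :class:`PipelineConfig` fully determines every output byte: the
synthetic cohort (or an input trial CSV), the exclusion chain, the
model-free ANOVA, the hierarchical fit, the contrast family and the
posterior predictive checks.  Every stage writes its artifact under the
output directory, and a manifest records the config, seed, package
version and a config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from faeddm.contrasts import default_drift_family, run_contrast_family
from faeddm.generate import (
    generate_experiment,
    preset_paper_like,
    read_trials,
    write_trials,
)
from faeddm.hddm import SamplerConfig, build_model, sample_posterior
from faeddm.model_free import (
    fae_curve,
    group_cell_summary,
    mixed_anova,
    response_proportions,
)
from faeddm.ppc import posterior_predict, ppc_summary
from faeddm.preprocess import apply_exclusions, exclude_participants_study

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "SCALES"]

#: Named problem scales: the full published design and a desk-scale one.
SCALES = {
    "paper": {
        "n_per_group": {"AUT": 29, "NT": 39},
        "trials_per_morph": 32,
        "n_iterations": 20_000,
        "n_burn_in": 15_000,
    },
    "test": {
        "n_per_group": {"AUT": 8, "NT": 8},
        "trials_per_morph": 16,
        "n_iterations": 12_000,
        "n_burn_in": 6_000,
    },
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable record."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause

    def record(self) -> dict:
        return {"stage": self.stage, "error": str(self.cause), "type": type(self.cause).__name__}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one full analysis run."""

    scenario: str = "male_drift_reduction"
    input_trials: str | None = None  # CSV path; set to skip generation
    n_per_group: dict = field(default_factory=lambda: dict(SCALES["test"]["n_per_group"]))
    trials_per_morph: int = 16
    seed: int = 0
    n_chains: int = 2
    n_iterations: int = 12_000
    n_burn_in: int = 6_000
    q: float = 0.05
    ppc_replicates: int = 50
    gg_policy: str = "always"
    out_dir: str = "results/pipeline"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def with_scale(self, scale: str) -> "PipelineConfig":
        if scale not in SCALES:
            raise ValueError(f"unknown scale {scale!r}; choose from {sorted(SCALES)}")
        return replace(self, **SCALES[scale])

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


#: Stage order for partial runs.
STAGES = ("generate", "preprocess", "model_free", "fit", "contrasts", "ppc")


def run_pipeline(config: PipelineConfig, until: str = "ppc") -> dict:
    """Execute the stages up to ``until`` and write the output bundle.

    Returns a dict of artifact paths plus headline numbers (max R-hat,
    credible contrasts, PPC coverage).  Any stage error aborts with a
    :class:`PipelineError` naming the stage.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; choose from {STAGES}")
    last = STAGES.index(until)
    from faeddm import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    def _stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            err = PipelineError(name, exc)
            (out / "error.json").write_text(json.dumps(err.record(), indent=1))
            raise err from exc

    # --- data
    def load_or_generate():
        if config.input_trials:
            return read_trials(config.input_trials), None
        gen = preset_paper_like(
            config.scenario,
            n_per_group=dict(config.n_per_group),
            trials_per_morph=config.trials_per_morph,
            seed=config.seed,
        )
        return generate_experiment(gen)

    trials, truths = _stage("generate", load_or_generate)
    write_trials(trials, out / "trials.csv")
    artifacts["trials"] = str(out / "trials.csv")
    if truths is not None:
        truth_rows = [
            {
                "participant_id": s.participant_id,
                "group": s.group,
                "a": s.a,
                "t": s.t,
                **{f"b[{ad}]": val for ad, val in s.b.items()},
                **{f"v[{ad},{m}]": val for (ad, m), val in s.v.items()},
            }
            for s in truths
        ]
        (out / "subject_truth.json").write_text(json.dumps(truth_rows, indent=1))
        artifacts["subject_truth"] = str(out / "subject_truth.json")

    # --- exclusions
    def run_exclusions():
        return apply_exclusions(trials)

    if last < STAGES.index("preprocess"):
        return artifacts

    kept, report = _stage("preprocess", run_exclusions)
    (out / "exclusion_report.json").write_text(json.dumps(report.to_dict(), indent=1))
    artifacts["exclusion_report"] = str(out / "exclusion_report.json")
    if last == STAGES.index("preprocess"):
        return artifacts

    # --- model-free analysis (study-level exclusions only)
    def run_model_free():
        study_trials, _ = exclude_participants_study(trials)
        table = response_proportions(study_trials)
        summary = group_cell_summary(table)
        curve = fae_curve(table)
        anova = mixed_anova(table, gg_policy=config.gg_policy)
        return table, summary, curve, anova

    table, summary, curve, anova = _stage("model_free", run_model_free)
    table.to_csv(out / "proportions.csv", index=False)
    summary.to_csv(out / "cell_summary.csv", index=False)
    curve.to_csv(out / "fae_curve.csv", index=False)
    anova.effects.to_csv(out / "anova.csv")
    anova.mauchly.to_csv(out / "mauchly.csv")
    artifacts.update(
        anova=str(out / "anova.csv"),
        proportions=str(out / "proportions.csv"),
        fae_curve=str(out / "fae_curve.csv"),
    )
    if last == STAGES.index("model_free"):
        return artifacts

    # --- hierarchical fit
    def run_fit():
        spec = build_model(kept)
        sampler = SamplerConfig(
            n_chains=config.n_chains,
            n_iterations=config.n_iterations,
            n_burn_in=config.n_burn_in,
            seed=config.seed,
        )
        return spec, sample_posterior(spec, config=sampler)

    spec, samples = _stage("fit", run_fit)
    samples.save(out)
    artifacts["posterior"] = str(out / "posterior.csv")
    artifacts["max_rhat"] = samples.max_rhat()
    if last == STAGES.index("fit"):
        return artifacts

    # --- contrasts
    def run_contrasts():
        fam = default_drift_family(samples)
        return run_contrast_family(samples, fam, q=config.q)

    results = _stage("contrasts", run_contrasts)
    import pandas as pd

    contrast_df = pd.DataFrame(
        [
            {
                "contrast": r.name,
                "median": r.median,
                "p": r.p,
                "ci_lo": r.interval[0],
                "ci_hi": r.interval[1],
                "coverage": r.coverage,
                "credible": r.credible,
            }
            for r in results
        ]
    )
    contrast_df.to_csv(out / "contrasts.csv", index=False)
    artifacts["contrasts"] = str(out / "contrasts.csv")
    if last == STAGES.index("contrasts"):
        return artifacts

    # --- PPC
    def run_ppc():
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]).generate_state(1)[0] >> 1)
        choices, rts = posterior_predict(samples, spec, config.ppc_replicates, rng)
        return ppc_summary(spec, choices, rts, out_dir=out)

    ppc_res = _stage("ppc", run_ppc)
    ppc_res.cell_table.to_csv(out / "ppc_cells.csv", index=False)
    ppc_res.rt_table.to_csv(out / "ppc_rt.csv", index=False)
    artifacts["ppc_cells"] = str(out / "ppc_cells.csv")

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "max_rhat": samples.max_rhat(),
        "converged": samples.converged,
        "n_credible_contrasts": int(contrast_df["credible"].sum()),
        "ppc_coverage": ppc_res.coverage,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    artifacts["manifest"] = str(out / "manifest.json")
    return {**artifacts, **{k: manifest[k] for k in ("max_rhat", "converged", "n_credible_contrasts", "ppc_coverage")}}
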