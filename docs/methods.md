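# Methods

## The diffusion kernel

A trial is modelled as Brownian motion with drift *v* and unit diffusion
coefficient between absorbing boundaries at 0 (female response) and *a*
(male response), started at *b·a*; the first-passage time plus the
non-decision time *t* is the RT. Fixing the diffusion coefficient at 1 is
the scaling convention of the Wiener-likelihood parameterisation this
model family standardly uses; all parameters are interpreted on that
scale. The start point is stored only as the relative fraction
*b* ∈ (0, 1).

The defective density over (choice, rt) is evaluated with the two
complementary series expansions of the standardised first-passage density
— small-time and large-time — switching automatically to whichever needs
fewer terms for a truncation error below 10⁻¹⁰ per evaluation. The upper
boundary is obtained from the lower-boundary formula by the reflection
(v, b) → (−v, 1−b); the reflection identity and the normalisation of the
two defective densities to 1 are property-tested. The closed-form upper
absorption probability `expm1(−2vab)/expm1(−2va)` (limit *b* as v → 0) is
used both by the generator tests and as an independent check on the
density's rt-integral.

The simulator is Euler–Maruyama with step `resolution` (default 10⁻⁴ s).
Discretely monitored boundaries underestimate absorption; the boundaries
are therefore pulled inward by 0.5826·√dt (the Broadie–Glasserman
continuity correction), reducing the first-passage bias from O(√dt) to
O(dt). With this correction simulated RT distributions pass
Kolmogorov–Smirnov tests against the numerically integrated density at
n = 2·10⁴ per parameter set, α = 0.01, across a grid of eight parameter
sets. Trials not absorbed by 60 s (vanishing probability for sane
parameters) are assigned the nearer boundary.

## The synthetic experiment

The generator emulates the published design: two groups (29 AUT / 39 NT
participants by default), two adaptation blocks with order
counterbalanced by participant parity, 32 repetitions of each of four
morph levels per block (128 trials/condition), binary responses with RTs.
Responses beyond the 2200 ms response window (200 ms test face + 2000 ms
response screen) become omissions, since late key presses cannot be
recorded.

Subject parameters are drawn from group-level normal distributions
(mean μ, precision τ) per cell; out-of-domain draws are *clipped* to the
domain (a ≥ 0.05, b ∈ [0.02, 0.98], t ∈ [0, 0.6] s) rather than
resampled, so the random stream stays aligned across configurations; clip
counts are logged.

Default generative truth (the study conditions; chosen once from the
field's typical parameter ranges and the qualitative effect pattern the
experiment is designed around):

| quantity | value | note |
|---|---|---|
| μ_a | 1.5 (SD 0.25) | moderate response caution |
| μ_t | 0.30 s (SD 0.05) | encoding + motor time |
| μ_b | 0.50 androgynous; 0.46 male adaptor (SD 0.06) | small start-point aftereffect |
| μ_v (androgynous) | −1.8, −0.6, +0.6, +1.8 across morphs 20→80 (SD 0.45) | drift ordered with morph level |
| adaptor drift shift | −0.8 for every male-adaptor cell | the FAE proper |
| AUT reduction | −0.45 at 60/80% morphs (scenario `male_drift_reduction`) | sized at the midpoint of the published credible cell differences |
| contamination | 2% omissions, 2% fast guesses U(0, 250) ms, 2% slow outliers (+U(600, 2000) ms) | injected after diffusion simulation |

Scenarios: `null` (identical groups, no adaptor effect),
`adaptor_shift_only`, and `male_drift_reduction` (the default). A constant
drift shift produces the inverted-U FAE proportion curve without any
morph-specific tuning, because proportion changes are largest where
choices are most uncertain.

What the generator does *not* emulate: sequence effects (adaptation
build-up/decay within a block beyond the warm-up trials), RT drifts from
fatigue, inter-trial parameter variability (the model has none), and any
demographic structure. Passing recovery tests therefore shows the
estimation chain is correct and adequately powered under the model's own
assumptions — not that the model fits arbitrary real data.

## Exclusion rules

Study level: participants with omission fraction > 1/3. Trial level, in a
fixed attribution order (first-three → omission → fast → slow): the first
three trials of every condition block (each block is a fresh adaptation
context; the alternative per-session reading is available by passing data
with session-level trial indices), omissions, RTs < 250 ms, and RTs above
the pooled mean + 3 SD of the surviving responded trials (pooled across
groups, matching the single global cutoff the design reports; `n_sd` and a
pinned threshold are parameters). Model level: participants retaining
< 50% of their trials. Re-applying the chain with the recorded slow
threshold is a no-op; recomputing the threshold on truncated data would
drift it downward, which is why the report carries the global number.

## Model-free analysis

Male-response proportions per participant × adaptor × morph cell over
responded trials; the FAE is the androgynous-minus-male-adaptor difference
per participant, summarised per group with 95% t-intervals. The
2 × 2 × 4 mixed ANOVA uses the contrast formulation of univariate repeated
measures: per within effect, an orthonormal contrast set transforms the
eight cell proportions, hypothesis/error sums of squares are traces of the
Type III (unweighted-means) SSCP matrices — which handles the unequal
group sizes the way SPSS does — and the between effect is the one-way
ANOVA on the unit-mean scores. Greenhouse–Geisser ε is computed from the
pooled within-group covariance of each effect's contrast scores and
applied, by default unconditionally, to every within effect involving the
four-level Morph factor (`gg_policy="if-significant"` restores the
traditional conditional rule). Mauchly's W uses Box's chi-square
approximation with the published second-order term (R's implementation
carries a variant constant; W agrees exactly, p to ~10⁻⁴). Levene's test
uses absolute deviations from the group mean of participant-mean
proportions. Participants with a missing cell are dropped and listed.
The implementation is frozen-value-tested against `car::Anova` (type III,
contr.sum) and `stats::mauchly.test` outputs and against a textbook
balanced-design oracle at 10⁻¹⁰.

## Hierarchical model and sampler

Cells: a, t per group; b per group × adaptor; v per group × adaptor ×
morph (24 μ cells and 24 τ cells for the full design; the count formula
g + g + gA + gAM is exposed and tested). Hyperpriors are configuration,
not dogma: μ priors are broad normals truncated to each domain
(centres a 1.5, t 0.3 s, b 0.5, v 0; scales 5, 1, 1, 5), τ priors
Gamma(0.1, 0.1) (mean 1, variance 10). The exact hyperpriors of the
original JAGS Wiener-module analysis are not published; these defaults are
deliberately weak and all exposed.

The sampler is Metropolis-within-Gibbs. Subject parameters get adaptive
random-walk Metropolis moves, vectorised across subjects (conditionally
independent given the cell parameters): single-site moves per parameter
plus one joint (a, +a/−t) move that cuts the strong boundary/non-decision
posterior correlation. Proposal scales adapt per subject and move type
toward 0.44 acceptance during burn-in only, with Robbins–Monro-style
diminishing steps, so the post-burn-in kernel is fixed and valid. Cell
means are exact conjugate truncated-normal Gibbs draws; cell precisions
exact gamma Gibbs draws (`sample_tau=False` freezes them — the hook used
by the conjugate-reduction correctness test, which matches a closed-form
Gaussian linear model). Out-of-domain proposals are rejected via the
−∞-outside-domain log joint; `log_joint` is the single source of truth and
is tested against a naive loop-based recomputation at 10⁻¹⁰.

Chains are independent (sub-seeds of one seed) and bit-reproducible.
Convergence: split-chain Gelman–Rubin R̂ per parameter, threshold 1.01;
non-convergence raises a recoverable warning that still carries the
samples and diagnostics. The full-design default is 2 chains × 20,000
iterations with 15,000 burn-in (5,000 retained per chain). The scaled
desk-size study (8 subjects/group, 16 trials/morph) uses 12,000/6,000 in
the test suite and 24,000/12,000 in the acceptance script; this
random-walk sampler needs more iterations per effective sample than a
specialised Gibbs sampler would, and these counts were chosen to reach
max R̂ < 1.01 with margin in a few minutes on one CPU.

## Contrasts and FDR

Contrasts are iteration-wise differences of aligned posterior draws
(chains pooled afterwards); interactions are nested subtractions
(A1−A2)−(B1−B2). Cell arguments may be lists, averaged iteration-wise,
for e.g. "all male-morph cells". The two-sided posterior tail probability
p = 2·min(P(d ≤ 0), P(d ≥ 0)), floored at 1/n_draws, enters a
Benjamini–Hochberg step-up over the family (default: the 16 drift
contrasts of one run — 8 group differences and 8 adaptor effects; family
membership is explicit configuration). The BH threshold p\* sets the
central credible interval coverage (1 − p\*); credible ⇔ zero outside ⇔
p ≤ p\* up to draw resolution. When nothing survives BH, intervals are
reported at the most conservative rung q/m and nothing is credible.
"HDI" is implemented as the equal-tailed central interval because the
percentile-symmetric bounds (1.35%/98.65% at 97.3%) only exist for a
central interval; a true highest-density variant is behind
`method="hdi"`. Quantiles use linear interpolation.

## Posterior predictive checks and recovery

Each PPC replicate draws one posterior iteration and simulates the entire
observed trial design with that draw's subject parameters (no mixing of
draws within a replicate). Summaries: per-cell male-choice proportions
and 10/50/90% RT quantiles against their central predictive bands, plus
signed-RT histogram overlays (negative = female). The PPC simulator uses
a 10⁻³ s step — millisecond-scale bias, immaterial for band checks.

The recovery harness loops generate → exclude → fit → contrast over
replicates, reporting per-cell bias, RMSE, 95%-interval coverage of the
true group-level means, the sign-recovery rate of the injected AUT
male-morph drift reduction, and the rate of any credible contrast (the
FDR-control figure under the null scenario). Desk-scale settings — 20
replicates at 8 subjects/group with single shortened chains for recovery,
40 replicates at 4 subjects/group for FDR control — keep the suites in
minutes; they are problem-size choices of this package, with the
thresholds (≥ 90% coverage, ≥ 80% sign recovery, binomial band around
q = 0.05) taken as stated.

## Numerical choices and limitations

* Density evaluations clamp at 10⁻³⁰⁰ before the log; genuinely zero
  density (rt ≤ t, impossible parameters) is −∞.
* Truncated-normal draws use inverse-CDF sampling (`ndtr`/`ndtri`), exact
  and reproducible.
* Degenerate contrast draws (all equal) give zero-width intervals without
  error.
* The Type III ANOVA requires ≥ 2 participants per group and complete
  cells after dropping incomplete participants.
* The sampler's hyperprior truncation constants are omitted from
  `log_joint` (they are parameter-independent for fixed hyperpriors).
* Known limitations: no inter-trial variability parameters (sv, st, sz);
  no model comparison (DIC/WAIC); single-subject datasets cannot inform
  τ meaningfully; with very few trials per v-cell the cell posteriors
  lean on the hierarchy, which is the point of the hierarchical design
  but means extreme subjects shrink toward their group mean.
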