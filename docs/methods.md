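# Methods

## The scientific question

The low prevalence effect (LPE) is the tendency to miss targets that occur
rarely: an observer who detects a hazard reliably when half the trials
contain one will miss the same hazard far more often when only 4% of trials
do. `hazardlpe` analyses two-session road-hazard detection experiments in
which each participant judges brief road videos ("hazard" / "no hazard")
once under high and once under low hazard prevalence, and in which an
independent panel has rated every video's hazardousness on a continuous
[0, 1] scale. The pipeline asks whether perceived hazardousness modulates
the LPE — in particular whether the most dangerous-looking hazards escape
it — and whether the prevalence manipulation shifts the decision criterion
conservatively (LPE) or liberally (prevalence-induced concept change, PICC).

## The observer model behind the synthetic data

Every stage of the pipeline is exercisable without any real data via a
signal-detection generator whose ground truth is known in closed form. A
simulated observer responds "hazard present" to a movie with median rating
*m* with probability

    p_yes = lambda/2 + (1 - lambda) * logistic(beta * m - c),

with sensitivity `beta` (logit units per unit rating), lapse rate `lambda`,
and criterion `c = c_high` in the high-prevalence session and
`c_high + delta` in the low-prevalence session. The emitted response is
then inverted with probability `mu` (a motor slip). Useful closed forms:

* the 50% point of the emitted-response curve is exactly `c / beta`
  (lapses and motor slips are symmetric around 0.5 and do not move it);
* the threshold-shift LPE is exactly `delta / beta`;
* `delta = 0` is an exact null generator: the expected miss-rate LPE is 0
  in every quartile, which calibrates the permutation tests' type-I error;
* `delta > 0` yields a positive expected miss-rate LPE in every quartile.

### Generator defaults (the simulated study conditions)

| parameter | default | why |
|---|---|---|
| movies | 432 hazard-present + 944 hazard-absent | the real stimulus set has 1376 clips, 432 hazard-present |
| present-movie latent law | Beta(5, 2) | broad mid-to-high support, so rating quartiles of present movies are non-degenerate |
| absent-movie latent law | Beta(1.6, 6) | absent movies concentrate at the safe end while still spanning the scale |
| raters | 48, additive N(0, 0.1) noise, clamped to [0, 1] | matches the real panel size; only the median enters the analysis, so a simple symmetric noise law suffices |
| designs | 50%/4% prevalence, 440/500 trials, 16 participants (x4 feedback regimes); 10%/1%, 480/580 trials, 32 participants | the five-experiment design; hazard-present trials per session are `round(prevalence x n_trials)`, drawn without replacement |
| `beta` | 8.7 | 0.87 logit per 0.1 rating, the sensitivity scale the detection data exhibit |
| `c_high` | 2.61 | puts the high-prevalence threshold at 0.30, mid-scale |
| `delta` presets | full 2.61, response-correction 2.44, partial 2.00, none 1.13, lower-prevalence 2.78 | `beta` x the per-experiment threshold shifts the five feedback regimes produce (0.30 / 0.28 / 0.23 / 0.13 / 0.32); feedback has no mechanistic role beyond selecting these presets |
| `lambda`, `mu` | 0.02, 0.02 | small stimulus-independent error floors typical of online psychophysics |
| response-correction factor | 0.25 | letting participants correct a response suppresses most, not all, motor slips |

Seeding: one master seed; per-participant and per-session generators are
spawned from it (`numpy.random.SeedSequence`), so every table is a pure
function of its arguments.

What the generator deliberately does **not** emulate: between-participant
sensitivity or criterion differences (the random-intercept variance of the
simulated data is therefore 0 — mixed-model variance recovery is tested on
directly simulated GLMM data instead), learning or sequential effects
within a session, reaction times, and any feature of the videos themselves.
Passing tests on synthetic data therefore validate the *statistical
machinery*, not claims about real drivers.

## Ingest and merging

Delimited text (comma default, tab accepted), UTF-8, header required; a
user-supplied column map decouples the pipeline from any one export
dialect. Rows with missing/unparseable condition, truth, or response
fields, and ratings outside [0, 1], are dropped and itemised in a JSON load
report; fully duplicated rows are kept with a warning (no deduplication
rule is defensible without provenance). Movie ids are compared
case-sensitively after whitespace trimming. Per-movie medians use the
ordinary sample median (mean of the two middle order statistics for an even
panel). The merge is an inner join on movie id; `rows_out + rows_dropped =
rows_in` always, and zero overlap raises an explicit id-format error. A
pre-aggregated export (counts per participant x movie x condition) can be
expanded to trial level with `expand_aggregated_trials`; trial level is the
canonical path.

## Psychometric models

**Per-condition logistic.** `fit_logistic` is an independent-observations
binomial logit fit (statsmodels GLM/IRLS) of yes-counts against median
rating. Complete separation and IRLS non-convergence are flagged, never
silently returned; constant ratings raise a rank error. The 50% threshold
is the closed form `-intercept/slope`, defined only for positive slopes;
values outside [0, 1] are kept and flagged, not discarded.

**Binomial GLMM.** The full model is fitted across all experiments with
fixed effects median rating, prevalence, experiment, and all interactions
involving the rating, plus a Gaussian random intercept per participant.
Coding is treatment contrasts with reference = high prevalence and the
first experiment label; the rating stays on its native [0, 1] scale
(centering would break the threshold interpretation), with a companion
"per 0.1 rating" column in the coefficient table. The marginal likelihood
is maximised by adaptive Gauss–Hermite quadrature: per participant the
conditional mode of the random intercept is found by Newton steps, the
10-node Hermite rule (configurable; 1 node = Laplace) is recentred and
rescaled there, and L-BFGS-B optimises (coefficients, log sigma) from a GLM
warm start. Standard errors come from the inverted central-difference
Hessian at the optimum; a non-positive-definite Hessian falls back to the
pseudo-inverse and clears the convergence flag. With sigma fixed at 0 the
model reproduces the plain GLM to < 1e-4, and on heterogeneous data the
fit matches lme4's `glmer(..., nAGQ=10)` to ~1e-3 in coefficients, SEs,
sigma and log-likelihood (cross-checked in the test suite).

**Type III Wald tests.** The treatment-coded fit is re-expressed under
sum-to-zero contrasts by an exact linear reparametrisation (solve
`X_treatment A = X_sum`), and each term's chi-square is `c' V^{-1} c` over
its sum-coded coefficient block — the standard Type III construction. A
singular block falls back to the pseudo-inverse with a reduced-rank df and
a warning.

**Threshold provenance.** Per-experiment thresholds default to fixed-effect
slices of the single full GLMM (population level, random intercept at 0),
matching the one-model description of the analysis; an independent
per-condition logistic mode is provided for sensitivity analysis, and the
two agree closely on simulated data. The threshold-shift LPE is
`threshold_low - threshold_high`: positive = conservative shift (LPE),
negative = liberal shift (PICC).

## Miss-rate LPE and permutation inference

Only hazard-present trials enter the miss-rate analyses. Present movies
are split into quartiles of median hazardousness at the 25/50/75% empirical
quantiles (linear interpolation; ties go to the lower quartile; Q1 =
least hazardous — 432 distinct medians force 108 movies per quartile).
Cells with zero hazard trials are undefined, never 0. The miss-rate LPE
is the across-participant mean of within-participant
`miss_low - miss_high` differences (not a pooled-rate difference, because
the permutation schemes are within-participant); participants lacking
either cell are excluded pairwise and counted in a coverage report, and the
same exclusion rule is applied inside every permutation iteration. The
proportional LPE is the ratio of participant-mean miss rates, low over
high, flagged undefined at a zero denominator.

Two permutation schemes, both within-participant, both reported with the
`(count + 1)/(B + 1)` convention (so p is never exactly 0; the floor at
B = 1000 is 1/1001) and two-sided (`|null| >= |observed|`) by default with
a one-sided option:

* **condition swap** — each iteration exchanges each participant's two
  condition labels with a fair coin and recomputes the statistic; used for
  the threshold shift (refitting the two per-condition logistic curves per
  iteration — refitting the full GLMM per iteration is orders of magnitude
  costlier for no change in the tested hypothesis) and for per-quartile
  miss-rate LPEs. For <= 10 participants the Monte-Carlo p converges to
  exhaustive enumeration over all 2^n swap patterns.
* **quartile shuffle** — each iteration permutes quartile labels across a
  participant's hazard-present movies (movies carry their trials with them,
  preserving per-quartile movie counts) and recomputes a focal quartile's
  LPE or a Q-vs-Q difference; used to compare the top quartile against the
  others.

Multiple comparisons follow two Bonferroni families: the 20 quartile-level
tests (5 experiments x 4 quartiles, critical alpha 0.05/20 = 0.0025) and
the quartile-vs-quartile comparisons as their own family. Family
membership is recorded in the output rather than silently assumed.

## Pipeline, outputs, reproducibility

`run_pipeline` executes simulate-or-ingest → merge → fit → LPE →
permutations → report from a YAML config in which exactly one of
`simulate` / `inputs` is active. Outputs are tidy delimited text and JSON:
a one-row-per-experiment summary table (threshold LPE + p, per-quartile
LPE + p), per-quartile miss-rate means with percentile-bootstrap 95% CIs
(resampling participants, 10,000 resamples, seeded), proportional-LPE and
fitted-curve tables, every permutation result with its seed and B, and a
run log with versions, seeds, config hash and exclusion counts. Identical
configs produce byte-identical statistical outputs. The CLI maps failures
to exit codes 2 (config), 3 (data), 4 (convergence).

`scripts/acceptance.py` recomputes the headline quantities from scratch at
the full five-experiment design sizes (about 94,000 trials, a 17-parameter
GLMM, B = 1000 permutations; a few minutes on one CPU).

## Numerical choices and degenerate inputs

* GLMM: L-BFGS-B with `ftol 1e-13`, gradient tolerance 1e-7, inner Newton
  mode tolerance 1e-11 (warm-started across objective evaluations),
  log-sigma bounded in [log 1e-6, log 50]; Hessian steps 1e-3 relative.
* Logistic separation heuristic: statsmodels' separation error/warning or
  a diverging slope (> 1e3) clears the convergence flag with a diagnostic.
* Thresholds: exact ratio, verified against Brent root-finding to 1e-9.
* Quartile ties: movie at a cut point goes to the lower quartile,
  matching an enumerate-and-assign oracle in the tests.
* Empty permutation cells: participants missing a condition are excluded
  with a warning; if all are excluded the test errors rather than
  reporting a vacuous p.
* Point-mass latent distributions (zero-width) are valid generator inputs;
  distributions supported outside [0, 1] are rejected.

## Known limitations

* The generator omits participant heterogeneity, so simulated studies do
  not exercise large random-intercept variances end-to-end (the mixed
  model itself is validated on directly simulated heterogeneous data).
* The per-condition logistic curves have no lapse parameter; a lapsing
  observer attenuates fitted slopes (the reported rating coefficient is
  therefore slightly below the generating sensitivity), though the 50%
  threshold — the quantity of interest — is essentially unaffected.
* Thresholds are population-level fixed-effect slices; no random slopes
  are modelled, and no Bayesian estimation is offered.
* The quartile-shuffle null assumes exchangeability of quartile labels
  within participant; it is calibrated under a rating-independent observer
  in the tests, but real data could violate exchangeability in ways the
  synthetic checks do not probe.
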