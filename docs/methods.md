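# Methods

## Study design and trial enumeration

The reference design is a 24-participant, 4-session study with three
bisection tasks per session. Stimuli are lines or rods of 100/200/300 mm
presented at lateral offsets of 0/±20 mm relative to the body midline.
Landmark stimuli carry a signed colour-reversal asymmetry of 0, ±2, ±4,
±6, ±8 or ±10 mm, with 15 trials per nonzero level and 30 at zero
(180 trials/session; the zero level is doubled because it is the most
informative about the 50% crossing). Line bisection runs 90
trials/session (30 per length, 30 per offset, 45 per hand); rod
bisection 54 (18 per length/offset, 27 per hand and per start side),
blocked by rod length. The response timeout is 5 s.

`enumerate_trials` reproduces every *marginal* count exactly. Joint
assignments beyond the stated margins (e.g. which offset a particular
asymmetry trial gets when 15 does not divide over 9 length × offset
cells) are balanced-as-possible random draws controlled by a seed; the
exact within-session orderings of the original protocol are not
reconstructed, since no downstream statistic depends on them.

## Generative observer model

The simulator encodes exactly the hierarchy the analysis assumes, which
is what makes the full pipeline testable end to end:

* participant bias per task: $b \sim N(\mu_\text{task}, \sigma_\text{between}^2)$ —
  the trait that reliability measures try to detect;
* session jitter: one draw $N(0, \sigma_\text{session}^2)$ shared by all
  trials of a participant × task × session — the mechanism that degrades
  cross-session consistency. The population consistency over $k$
  sessions is therefore the closed form
  $\alpha = \sigma_b^2 / (\sigma_b^2 + \sigma_e^2/k)$, which
  `population_for_consistency` inverts;
* manual trials: perceived midpoint = true midpoint + b + jitter +
  $N(0, \sigma_\text{trial}^2)$. Rod responses are recorded from the left
  end of the rod (a 100 mm rod bisected 5 mm left of centre reads
  45 mm); line responses are screen coordinates that also carry the
  participant's stylus calibration offset, which the error module
  subtracts back out;
* landmark trials: Bernoulli draws from
  $p(x) = \lambda + (1-2\lambda)\Phi((x - \text{pse})/\sigma_\text{psy})$
  with $\text{pse} = -(b + \text{jitter})$, i.e. the exact inverse of the
  fitted model. Lapses are symmetric (guess = lapse), matching the
  fitting constraint;
* a configurable fraction (default 2%) of line trials exceed the 5 s
  timeout, exercising the filtering stage.

Default population values (units mm) were calibrated once against
published healthy-young-adult summary statistics for these tasks and
then frozen: task means −0.20 (landmark), −1.92 (line), −0.84 (rod);
landmark $\sigma_b = \sigma_s = 1.2$ (implying population consistency
$1.44/(1.44 + 1.44/4) = 0.8$); line $\sigma_b = 0.5$, $\sigma_s = 5.2$,
$\sigma_\text{trial} = 10$ (consistency ≈ 0.03 — line bisection carries
large session-to-session variance and essentially no stable trait
signal); rod $\sigma_b = 2.6$, $\sigma_s = 3.9$,
$\sigma_\text{trial} = 8$ (consistency ≈ 0.63); $\sigma_\text{psy} = 2.5$,
$\lambda = 0.02$, calibration-offset SD 0.5.

What the generator deliberately does *not* emulate: reaction-time
structure beyond the timeout flag, learning or order effects across
sessions, any effect of stimulus length/offset/hand on bias (the
analysis averages over them; optional per-task modifiers exist only for
robustness testing), and non-Gaussian individual-difference
distributions. Passing tests therefore show that the estimators recover
the truth *under the model's own assumptions* — they do not validate
those assumptions against real behaviour.

## Psychometric fitting

Fitting is always on counts (binomial likelihood), never least squares
on proportions. The lapse rate is a free parameter estimated jointly
with threshold and slope over all stimulus levels, bounded by
$\lambda_\text{max} = 0.10$ (configurable); the guess rate is tied equal
to the lapse rate. Optimisation is L-BFGS-B from a deterministic
multistart grid — thresholds {−6, 0, +6} mm × slopes {1, 3, 9} mm ×
lapse {0.01, 0.05} — plus one moment-based start at the interpolated
50% crossing. Bounds: |threshold| ≤ 50 mm, slope ∈ [0.05, 100] mm.

A fit is flagged non-converged (honestly, with no silent fallback) when
the optimiser fails, when the responses never vary (threshold
unidentifiable), or when the slope lands on its boundary (degenerate
step-like data). Goodness of fit is the deviance against the saturated
binomial model; its reference distribution is obtained by parametric
simulation from the fitted curve with refitting, and a fit is flagged
when the Monte-Carlo p-value drops below 0.01 (configurable). Bootstrap
SEs/CIs come from resampling each level's count from
Binomial(n, observed proportion) and refitting warm-started from the
point estimate; replicates that fail are dropped and counted, and the
result is flagged if more than 20% drop.

Per-session fits provide the session-level bisection errors
($-\mathrm{PSE}$) used for reliability; pooled all-session fits are
available separately (equal-trial pooling across sessions).

## Error matrices and screening

Bisection error is perceived minus physical midpoint, leftward negative,
with the line-bisection calibration offset subtracted; the rod
left-end-to-signed-error conversion happens in exactly one place.
Session cells are unweighted trial means over lengths, offsets and
hands (after timeout removal); task cells are means of the four session
values. Missing cells propagate as exclusions — never imputation — and
reliability requires complete rows.

Outlier screening flags a participant whose task-level mean lies more
than k (default 5) group SDs from the group mean, with the SD computed
including the candidate. Note an arithmetic consequence: such a z-score
cannot exceed $(n-1)/\sqrt{n}$, so a 5-SD rule can only ever fire for
n > 26. The removal policy is configurable (`any-task`, `all-tasks`,
`listed-tasks`, default `any-task`) because verbal descriptions of such
rules are often ambiguous between "flagged anywhere" and "flagged
everywhere"; the screening report records the policy with every
decision. Participants with non-converged or quality-flagged
psychometric fits are likewise excluded, and listed in the report.

## Reliability

Cronbach's alpha is computed both as the variance-of-sums form and as
ICC(3,k) from the two-way mean squares; the two are asserted equal at
run time. Negative values are reported as computed (they indicate score
reversals), never truncated. The significance test is the two-way-ANOVA
F test of between-participant variance on $(n-1, (n-1)(k-1))$ df — the
standard companion test printed by common statistics packages; no
distribution-free alternative is attempted. The absolute-agreement
average-measures ICC(2,k) is emitted alongside so the
consistency-vs-agreement contrast (sensitivity to measurement-level
offsets) is auditable. Pairwise Pearson correlations cover the two-task
comparisons.

Two fine points verified in the test suite rather than assumed: the
Spearman–Brown identity $\alpha = 2r/(1+r)$ at k = 2 is exact only under
equal column variances, and agreement ≤ consistency only when the
measurement variance-component estimate is nonnegative and consistency
is nonnegative.

## Group inference

One-sample t-tests (two-sided, $d = \bar{x}/s$, $d = t/\sqrt{n}$) are
run per session on participant means over tasks, per task on
participant means over sessions, and overall; session tests use the
Bonferroni level 0.05/4 (displayed 0.013) and task tests 0.05/3
(0.017). The ANOVA is the classical fully-within two-way decomposition
with effect-specific error strata; a 3-level task factor with n = 24
correctly has df (2, 46) and the 4-level session factor (3, 69).
Partial $\eta^2$ is reported as the headline effect size (the default of
common ANOVA software), with plain $\eta^2$ emitted alongside. No
sphericity correction is applied by default; Greenhouse–Geisser
corrected p-values are available behind `gg_correction=True`.

## Power

`power_cronbach` interprets "power to detect a consistency of $\alpha_0$"
as the power of the alpha-significance F test when the population
consistency truly equals $\alpha_0$, with the variance components set by
the closed-form inversion above; this interpretation is recorded in the
result metadata. `power_ttest` simulates Normal(d, 1) samples and
cross-checks against the noncentral-t analytic power. Both default to
1,000 replicates (overridable) and report the binomial Monte-Carlo SE.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` substreams (simulation, per-cell bootstrap,
deviance Monte-Carlo, power), so pipeline outputs are byte-identical
across runs with the same seed. Participant-id-derived keys use stable
byte encodings, never Python's salted `hash`. Problem sizes in the test
suite were chosen to keep the full run in the low minutes on one CPU:
e.g. parameter-recovery loops use an 8-participant study, bootstrap
coverage uses 200 simulated observers at 100 replicates each, and the
null-calibration sweeps use 600–2,000 replicates; these are stated in
each test.

## Known limitations

* The deviance reference distribution is simulated with refitting but at
  modest replicate counts in pipeline defaults; very marginal misfits
  may pass.
* The poor-fit exclusion criterion is a configurable diagnostic
  (deviance p, PSE SE, convergence); published studies rarely quantify
  theirs, so exact exclusion counts from any particular dataset are not
  reproducible by construction.
* Percentile bootstrap CIs at 100–400 replicates under-cover slightly;
  the coverage test asserts a deliberately loose ≥80% bound at nominal
  95%.
* No alternative sigmoids (logistic, Weibull), no Bayesian fitting, no
  mixed-effects alternatives to the ANOVA, and no reaction-time
  modelling.
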