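# Methods

## The problem

In-hospital death after pediatric congenital heart surgery is rare
(~2.4% overall) but varies over two orders of magnitude across
procedure types, and most procedures are performed too rarely for their
raw death rate to be a usable risk estimate (a 3/4 = 75% observed rate
carries almost no information about true risk). The package implements
the standard empirical answer in two stages: stabilise the per-procedure
rates with a hierarchical model, segment them into ordinal risk
categories, then combine the category with patient-level preoperative
covariates in a boosted classifier.

## Stage 1a — binomial random-effects shrinkage

Model: `d_j ~ Binomial(n_j, p_j)`, `logit(p_j) = mu + b_j`,
`b_j ~ Normal(0, tau^2)`, with priors `mu ~ Normal(0, 5^2)` and
`tau ~ HalfNormal(1)` — weakly informative on the logit scale, where a
unit is a substantial odds multiplier. Procedure tables must pass the
inclusion rule `cases >= 3` (procedures performed in fewer than three
patients are excluded from the cohort).

Inference integrates the random effects out by **adaptive Gauss–Hermite
quadrature** (default 20 nodes): for each procedure the integrand is
re-centred at the conditional mode of `b_j` — found by a
bisection-safeguarded Newton iteration on a bracket that provably
contains the root; plain capped Newton can limit-cycle when `tau` is
large and the likelihood sharp — and re-scaled by the conditional
curvature. This leaves a two-dimensional marginal posterior over
`(mu, log tau)` that is evaluated in vectorised batches.

Two inference paths share that marginal:

* **`method="eb"`** (default): empirical Bayes. The marginal posterior
  is maximised (Nelder–Mead) and per-procedure posteriors are computed
  by deterministic quadrature at the plug-in `(mu_hat, tau_hat)`;
  hyperparameter intervals are Wald intervals from a finite-difference
  Hessian. Bit-for-bit reproducible, sub-second on 100 procedures;
  ignores hyperparameter uncertainty (anti-conservative intervals for
  `p_j`, identical point estimates to within Monte-Carlo error of the
  full posterior in all checks).
* **`method="mcmc"`**: fully Bayesian. Four *independent* ensembles of
  affine-invariant walkers (emcee; default 32 walkers, 150 burn-in +
  350 retained steps each) sample `(mu, log tau)`; convergence is gated
  on the maximum cross-ensemble split-R-hat (< 1.01 by default, raising
  a `ConvergenceError` carrying the diagnostics otherwise). For each of
  the retained, thinned hyperparameter draws (default 400), `b_j` is
  drawn *exactly* from its conditional posterior by inverse-CDF sampling
  on a 401-point grid spanning the conditional mode ± 8 conditional
  standard deviations. Point estimate and equal-tailed 95% credible
  interval are the mean and 2.5/97.5 percentiles of the resulting
  `p_j` draws.

The point estimate is the **posterior mean of `p_j`** (not the median,
not the inverse-logit of the mean logit): the published "model-based"
column is a rate, and the mean is the rate-scale summary. A consequence
worth noting: the shrinkage target on the rate scale is the logit-normal
population *mean* `E[expit(mu + tau Z)]`, which exceeds `expit(mu)` (the
population *median*) markedly at `tau ~ 1`. Zero-death low-volume
procedures therefore shrink *upward past* `expit(mu)`; on the reference
cohort they land near 1–2%, matching the published model-based values
for such rows. The exact published model-based column is not
reproducible — it depends on prior choices its source does not publish —
so tests assert direction and ordering, not those printed values.

The posterior predictive check reports, per procedure, `P(d_rep >=
d_obs | data)` with the binomial tail computed exactly per posterior
draw and averaged (no replication noise). By default the replicated
rate is a fresh draw from the fitted *population* law `expit(mu + tau
Z)`: the classical same-data conditional check is also available but is
nearly powerless for rows whose own data dominate their posterior (a
corrupted high-volume row simply drags its own estimate along).
Marginal p-values are approximately uniform under the model and retain
power against planted outliers; they are still bounded below by the
population tail — a corrupted rate that is plausible for *some*
procedure of the population cannot be flagged.

## Stage 1b — optimal segmentation and BIC

Procedures are ordered by shrunk rate (ties: larger case count first,
then name — stable and deterministic) and partitioned into K contiguous
categories. The homogeneity criterion is the **case-weighted
within-category sum of squares** of the rates; its exact minimiser over
all contiguous K-partitions is found by dynamic programming with
prefix-sum segment costs, O(K J^2), ties resolved to the smallest left
boundary. Segmenting *shrunk* rather than raw rates matters: raw
ordering is unstable for tiny n (a 1/3 procedure would outrank every
high-volume procedure with rate < 33%).

K is selected over 2–20 by BIC with a per-category common binomial
death rate applied to the *observed* counts: `-2 sum_j log Bin(d_j |
n_j, phat_cat(j)) + K log(sum_j n_j)`, ties to the smaller K; the full
K-vs-BIC trace is retained. K = 1 is allowed internally as a baseline.

On the reference cohort the BIC curve is nearly flat between K = 5 and
K = 7 (differences of ~5 against a 2 log N tolerance of ~20): EB rates
select K = 6, full-MCMC rates K = 7, and the published five-category
solution is within a few BIC points of either optimum. The acceptance
output reports the selected K together with the BIC gap at K = 5 rather
than forcing agreement. Pooled category mortality must increase
strictly with the category index on any accepted result.

## Stage 2 — the patient-level classifier

Encoding: ordered clinical ladders (regurgitation/insufficiency
severity, dimension-vs-critical-value categories) are encoded ordinally;
unordered categoricals (shunt directions) one-hot with indicators set to
NaN where the source is missing; missing values stay NaN end-to-end and
are routed by the boosted trees' native default-direction rule.
Features missing in strictly more than 30% of rows are dropped first.

Split 75:25, stratified on the outcome. RFE ranks features by the
booster's **gain** importance, eliminates one feature per round, and
records stratified 5-fold CV AUC per subset size; the selected subset
maximises CV AUC (ties to the smaller subset). Cross-validation rather
than a held-out slice keeps the test set untouched during selection.
Grid search (exhaustive, same CV) tunes depth, learning rate and
`scale_pos_weight` by default — the class-imbalance weight is exposed
because a ~40:1 negative:positive ratio is the regime this endpoint
lives in — then refits on the full training split. The reported feature
importances are gain importances normalised to sum to 1.

## Evaluation

AUC is the Mann–Whitney pair-counting probability (ties ½). The
operating threshold maximises the Youden index `J = sens + spec - 1`
over the distinct observed scores plus +inf (rule: `score >= threshold`
is positive; ties take the lowest threshold). Confidence intervals are
percentile bootstrap (default 1000 resamples) over *patients* — rows
resampled jointly, not scores and labels separately; single-class
resamples are skipped and counted, >50% skips is an error; stratified
resampling is available but off by default. Ordinal risk scores
(RACHS-1, STS-EACTS-style categories, or the fitted stratification) are
evaluated by the same machinery with the category as the score.

## Synthetic registries

`RegistrySpec` declares the study conditions; defaults emulate the
reference cohort: 105 procedure types, case volumes discretised
log-uniform on [3, 8000] (reproducing the 4-to-7910 span simply),
logit-normal mortality heterogeneity with `tau = 0.9`, and ~2.4%
overall mortality. The location `mu` is solved so the logit-normal
*mean* rate equals the 2.4% target (setting `mu = logit(0.024)` would
put the mean near 3.4%). Patients draw a procedure volume-weighted;
the outcome is Bernoulli with log-odds `beta0 + sum(effects) +
procedure random effect`, where `beta0` is solved at generation time so
the mean simulated risk hits the target mortality. The ten default
covariates mirror the cohort's strongest preoperative risk factors with
marginals taken from its descriptive table (e.g. pulse-oximetry <= 90%
in 26% of patients) and effect signs from its death/non-death contrasts.
Missingness is applied completely at random per covariate, *after*
outcome generation, at realistic per-covariate fractions (3–8%).

What the generator does **not** emulate: correlation between echo
measurements and labs, longitudinal records, informative missingness,
and procedure-covariate dependence (cyanotic lesions co-occurring with
low saturation). Passing tests therefore demonstrate that the machinery
recovers planted structure under the model's own assumptions — not that
the fitted AUCs transfer to any real registry. Per-seed pooled death
rates of a 105-procedure table have an sd of ~0.6 percentage points
purely from volume-weighted sampling, so calibration checks compare
across-seed means.

## Numerical and design notes

* Delimiter auto-detection on input tables is restricted to comma and
  tab; percentages print with two decimals.
* Rows of the packaged cohort whose source lists two RACHS grades
  (e.g. "1/2") store the higher grade, with the original recorded in a
  `note` column; the grades are given inputs, not computed.
* The last-record-within-a-month rule for repeated surgeries is an
  input contract; `deduplicate_patient_records` implements it for
  tables carrying a surgery date, and the generator never emits
  duplicates.
* The source report's own counts disagree slightly (an abstract total
  of 595 deaths vs 591 = 442 + 149 in its tables); the packaged table
  follows the tables (591/24,685 = 2.4%). Similarly its printed 75:25
  split (18,552/6,133) is not an exact 75% of 24,685; the package
  splits exactly.
* Problem sizes in the test suite and acceptance script (J = 100–200
  registries, 20 replicates, n = 8,000–20,000 patients, lighter MCMC
  geometry for replicated fits) were chosen to make the full analysis
  reproducible on a single CPU in minutes while leaving every check's
  statistical resolution intact; the defaults on the estimators are the
  production settings.

## Known limitations

* Empirical-Bayes credible intervals for `p_j` ignore hyperparameter
  uncertainty; use `method="mcmc"` when interval coverage matters.
* The BIC likelihood treats procedures within a category as sharing one
  binomial rate; alternatives (e.g. scoring on posterior draws rather
  than point estimates) are plausible and would move the selected K
  within the flat region of the trace.
* No covariate-adjusted (patient-mix) shrinkage, no morbidity endpoint,
  no calibration modelling or decision-curve analysis.
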