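# Methods

## The task and its scores

The child Attention Network Test (ANT) is a cued flanker task. A trial
begins with a fixation cross jittered uniformly between 400 and 1,400 ms,
followed by one of four warning cues shown for 100 ms (no cue, a central
asterisk, a double asterisk above and below fixation, or a spatially valid
asterisk at the target location). After a fixed 400 ms stimulus-onset
asynchrony the target fish appears above or below fixation — alone
(neutral) or flanked by four fish swimming the same (congruent) or opposite
(incongruent) direction — and stays until a response or a 1,700 ms
deadline. A session is 24 practice trials with feedback, then 288 test
trials in three blocks of 96 with 5 s breaks. Within every test block each
cue x flanker x location x direction cell appears equally often (the
counterbalancing scheme is not uniquely determined by the task description;
exact per-block balance was chosen because it guarantees estimable
condition medians, with a seeded shuffle per block).

Performance is summarised per participant and condition margin by the
median reaction time over retained correct trials and the proportion of
errors (PE) over retained trials. Trials are excluded when the RT is
strictly below 200 ms or strictly above 1,700 ms, when no response occurred
(timeout, scored as an error), or when the trial was practice. The default
reads "excluded" as excluded from both the RT and the PE computations; a
`rt_only` switch keeps extreme-RT trials in the error counts.

Three network scores are Donders subtractions on the margins:

* alerting = no-cue − double-cue (both margins collapse flankers),
* orienting = central-cue − spatial-cue,
* executive control = incongruent − congruent (collapsing cues),

each computed for median RT (ms) and PE (percentage points). The composite
per network is the average of the z-scored RT and PE differences — a
balanced-integration-type score in which higher means worse.

**Standardisation scope.** z-scoring each network separately over
participants would force every network's cohort mean to zero, which
destroys the between-network ordering the composite is meant to carry (the
conflict cost of ~85–95 ms sits far above, and the cue benefits below, a
pooled mean of ~50 ms). The default therefore pools the moments over the
full stack of participants x three networks, separately for the RT and the
PE measure, always over the combined sample (never per group). A
`per_network` switch provides the alternative. Under pooled scope the grand
mean of all composites is exactly zero and each z component has pooled unit
variance; these identities are tested.

The arcsin transform used for overall PE is arcsin(sqrt(p)), without the
factor 2: at an overall error proportion near 2.6% this maps to ~0.16,
which is the magnitude scale the transformed-error descriptives are meant
to live on (the 2x variant would double it). Overall RT per participant is
the median over all retained correct test trials, not the mean of condition
medians; both are computable from the condition-summary table.

## Synthetic cohorts

The generator exists so that every stage is testable without external
data. Each simulated child is an ex-Gaussian responder: on a trial the RT
is a condition location term

    mu − alert_benefit·1[cue ≠ none] − orient_benefit·1[cue = spatial]
       + flanker_cost·1[incongruent] + N(0, sigma) + Exp(tau),

with the neutral flanker at the congruent baseline (neutral trials enter no
subtraction score, so this choice is inert for the headline outputs).
Errors are Bernoulli with log-odds `error_logit_base +
error_logit_incong·1[incongruent]`; RTs and errors are conditionally
independent — there is no speed–accuracy trade-off term, a documented
limitation. Contamination: with probability 0.005 a trial becomes an
anticipation (RT uniform on 80–199 ms, always excluded as too fast); with
probability 0.002 a lapse produces no response before the deadline
(timeout, scored incorrect), as does any RT draw beyond 1,700 ms. Together
these give ~0.7% out-of-range trials, so the exclusion rules have realistic
work.

Participant parameters are drawn from group-level normals. Defaults (54
children per group, 288 test trials):

| parameter | mean (gifted) | between-SD | units |
|---|---|---|---|
| mu | 557 | 78 | ms |
| sigma | 70 | 15 | ms |
| tau | 100 | 25 | ms |
| alert_benefit | 30 | 14.5 | ms |
| orient_benefit | 43 | 6 | ms |
| flanker_cost | 83.7 | 25 | ms |
| error_logit_base | −4.48 | 0.55 | log-odds |
| error_logit_incong | 1.41 | 0.30 | log-odds |

The average group adds +10.5 ms to the flanker cost and +0.55 to the base
error log-odds. These anchors were set once so that cohort-level outputs
land where school-age child-ANT samples land: overall median RT near
633–642 ms per group, alerting ~30 ms, orienting ~43 ms, conflict cost
~84 ms (gifted) vs ~94 ms (average), overall PE ~2.6% vs ~4.4% per group.
Two derivations behind the less obvious values: the base error logit is the
target logit minus sigma²/2 of its between-SD, because exp-convexity
inflates the mean error rate under logit-normal variation; and the
between-SDs of the cue benefits and the conflict cost were chosen from the
variance decomposition of a median-difference score — observed score
variance = true between-child variance + median-estimation noise
(~(1.253·sd_RT)²·(1/n₁+1/n₂) per margin) — so that the split-half
reliabilities come out high for executive control and near zero for
orienting, the ordering these network scores show empirically.

What the generator does *not* emulate: sequential effects (post-error
slowing, block fatigue), speed–accuracy coupling, cue-dependent error
rates, age or IQ covariates, and any network intercorrelation beyond the
shared `mu`. Passing tests therefore show that the pipeline's estimators
and tests behave correctly under a realistic-magnitude, well-specified
generative model — not that real children satisfy that model.

## Reliability

Permutation split-half: each participant's retained trials are split into
two random halves, each half is scored by the full preprocessing + scoring
path, the across-participant Pearson correlation of half-scores is
corrected to full length by Spearman–Brown 2r/(1+r), and the estimate is
the mean over 1,000 splits. The default split is stratified within each
cue x flanker cell (an odd cell sends its extra trial to a random half), so
both halves always contain every condition; an unrestricted
within-participant split is available, since the splitting granularity of
the original procedure is not recoverable from its description. The 95%
interval is mean ± 1.96·SD/√n over the permutation values — a
standard-error-of-the-mean interval, which is the only construction narrow
enough to match intervals like [.644, .657] around 0.650; a percentile
interval is available by flag. Pearson (not rank) correlation is used
between halves because the Spearman–Brown step-up presupposes it.

Note one subtlety the simulation exposed: for rare-event PE difference
scores, split-half values do not converge to zero even when the true score
variance is zero, because the two halves share each participant's fixed,
finite error trials; the chance allocation of those errors across cells
acts as a persistent pseudo-true-score. PE reliabilities of low-error
networks are therefore cohort-realisation-dependent and should be read
with caution; the RT-score reliabilities are the stable ones.

## Group inference

All statistics are computed from first principles, with scipy supplying
only distribution functions.

* **Descriptives**: SD with n−1; skewness g1 = m₃/m₂^1.5 and *excess*
  kurtosis g2 = m₄/m₂² − 3 (moment estimators, no small-sample bias
  correction — the bias-corrected forms are a flag away in scipy if
  wanted); variance ratio max/min for homogeneity screening.
* **Welch's t** with Welch–Satterthwaite df; Cohen's d always uses the
  pooled SD. Tests are two-sided by default with a one-sided option (a
  reported pair like p = .302 / p = .002 under Holm is reproduced by
  one-sided tests Holm-adjusted over the two outcomes).
* **Holm**: step-down, adjusted p in input order, applied within a declared
  family only (the RT+PE pair; the three post hoc contrasts) — never
  globally.
* **Pearson chi-square** on 2x2 tables without continuity correction;
  phi = sqrt(chi²/N).
* **Mixed ANOVA** (2 between x k within): the textbook SS partition with
  subjects-within-groups as the error for the between effect and the
  network x subjects-within-groups stratum for the within effects. Mauchly's
  W and the Greenhouse–Geisser epsilon are computed on the pooled
  within-group covariance of orthonormalised within-subject contrasts
  (groups centered separately, df = N − g) — the standard treatment for
  mixed designs; chi² ≈ −(N−g − (2p²+p+2)/(6p))·ln W with p = k−1. The GG
  correction rescales both dfs by epsilon and leaves F unchanged. Effect
  sizes are generalized eta squared, SS_effect /(SS_effect + SS_subjects +
  SS_within-error), whose denominator carries all subject-related variance.
  The whole machinery reproduces R's `car::Anova` (sum contrasts) to every
  printed digit on a frozen cross-check dataset, and the SS partition
  matches a nested least-squares projection oracle at 1e-10.
* **Post hocs**: the overall group contrast on subject-average composites
  (identical to Tukey's HSD with two groups, df = N − g); per-network group
  contrasts with a cell-mean variance mixing both error strata,
  (MS_subj + (k−1)·MS_error)/k, Satterthwaite df on the combination
  (landing between N−g and the total within df, ~315 at N = 108), Holm over
  the three contrasts. True studentized-range Tukey is deliberately not the
  default: with two groups it adds nothing, and "HSD plus Holm" is really a
  pooled-error pairwise family.
* **Cook's D** from leverages of the least-squares fit (intercept
  prepended; k counts predictors), flagged against the median of
  F(k+1, n−k−1) — for one predictor and 108 observations a cutoff of
  ≈ 0.70. A leave-one-out refit oracle checks the algebra in the tests.
* The testing convention follows the reported procedure: the GG-corrected
  p is used when Mauchly rejects at .05, the uncorrected p otherwise
  (`recommended_p`).

## Numerical and design choices

* All randomness descends from one seed through named `SeedSequence`
  substreams (participants, schedules, responses, splits, replicates), so
  each stage is independently reproducible and replicate seeds stay below
  2³¹.
* Medians of even counts are midpoints of the central order statistics
  (numpy convention). Exclusion boundaries are strict; the boundary values
  200 and 1,700 ms are retained.
* Degenerate inputs fail loudly: zero pooled SD in standardisation,
  constant ANOVA response (F undefined, flagged NaN), zero chi-square
  margins, rank-deficient Cook designs.
* Split-half estimates are invariant to the row order of the trial table
  (the engine canonicalises order before splitting).
* Monte-Carlo scale: 200 replicate cohorts for sign recovery; the
  null-size check uses 500-cohort batches (the reporting script runs one,
  the test suite pools four independent ones, since a single batch leaves
  ~1 percentage point of Monte-Carlo noise on a 5% rejection rate).

## Known limitations

* The generator's independence assumptions (errors vs RTs, networks vs
  each other) make the composite's behaviour cleaner than real data, where
  speed–accuracy trade-offs can move both components jointly.
* The per-network post hoc df construction is one defensible pooled-error
  recipe; other software may combine the strata differently and print
  slightly different dfs for the same data.
* PE-based reliability of low-error difference scores is intrinsically
  unstable (see above); no amount of permutation averaging fixes that.
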