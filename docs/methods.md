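# Methods

`seqswap` analyzes a context-cued serial-order task for rhesus macaques:
on each trial six objects appear and five must be touched in a fixed order
(A-B-C-D-E on the context-1 background); when the background switches to
context 2 the same objects must be touched as A-D-C-B-E, i.e. the objects
at ordinal positions 2 and 4 swap. How a subject fills position 2 after
correctly choosing A separates two representations of serial order:
*position coding* (re-indexing objects to absolute positions of a learned
structure, predicting D) and *serial chaining* (item-to-item associations,
predicting the next-in-chain C). The package contains a generative
simulator of the task, the behavioral metrics, the swap statistics, and a
Bayesian multinomial model of second-position choices.

No animal data are distributed with the task; every analysis here is
exercised on synthetic logs, so what the tests establish is the internal
correctness and calibration of the pipeline, not any claim about animals.

## Task structure and data model

A *block* is one sequence pair: up to 15 trials in context 1 followed by up
to 15 trials in context 2 with the same objects. Within a trial a subject
has at most 15 touches and at most 10 errors to reach position 5; after
any error it must re-touch the last correctly chosen object (the retouch
rule) before searching again. Trials and touches are 1-based. Objects are
labelled by their context-1 serial role A-E, plus the distractor X;
context-2 correctness is evaluated against the re-ordered required
sequence, so all results are reported in context-1 labels. A *session* is
~10 blocks with 120 delayed match-to-sample (DMTS) trials interleaved
half-way; late blocks are a mix of new sequences and repeats of early ones
(`<id>.r` block ids pair a repeat with its source). The canonical file
format is a tab-delimited log, one row per touch, with DMTS trials
co-stored under a `record_type` column; reading validates every structural
invariant and names the offending row.

## The generative agent

The agent learns a value matrix V over (object, ordinal position) pairs:
a correct touch moves V toward 1 by `learning_rate`, an error decays it by
the same rate. Search choices are a softmax (temperature
`softmax_temperature`) over the objects not yet secured in the trial, with
a `lapse_rate` chance of a uniform pick. Retouches are correct with
probability 1 − `lapse_rate`. The distractor X adds
`distractor_confusability` times B's current effective value to its own,
because X shares features with B; this reproduces distractor choices
peaking at position 2 in context 1 and position 4 in context 2.

In context 2 the agent keeps a fresh value matrix and, per trial, draws a
read-out strategy: *position* (probability `w_position`; the context-1
values are read with B and D exchanged, which is correct for the whole
swapped sequence), *serial* (`w_serial`; from position 2 on it reads the
serially next context-1 position, favoring C at position 2), or
*exploration* (the remainder). Two mechanisms beyond the bare mixture
proved necessary for the generator to exhibit the behavior the analyses
measure:

1. **Prior fading.** The context-1 read-out is scaled by
   1 − max(context-2 value at the position), so once feedback has taught
   the context-2 association the old read-out stops competing. Without
   this, serial-strategy trials keep failing indefinitely and context-2
   performance never stabilizes.
2. **Error-cued re-indexing.** After an error in context 2 the agent, with
   probability `error_reindex_rate`, abandons the read-out that just
   failed and re-draws among the others; an error on the *old-order*
   object (choosing B at position 2) is direct evidence for the swap and
   cues the position strategy outright. Without this the retro-active
   swap index (D versus C after an erroneous B) is ~0 or negative; with it
   the generator shows the positive retro-active re-indexing the analyses
   are designed to detect.

DMTS accuracy is `chance + (ceiling − chance) · wm_ability · f(similarity)`
with chance 1/3 (three test objects), ceiling 0.944, f(low) = 1 and
f(high) = 0.373; at `wm_ability` 0.6 this places low/high-similarity
accuracy at 0.70/0.47, the calibration points reported for the task, with
no delay dependence. `agent_from_wm` couples `w_position` linearly to
`wm_ability`; the coupling strength in real animals is unknown, and the
linear form is a modeling choice.

Defaults (`w_position` 0.45, `w_serial` 0.2, `learning_rate` 0.15,
`softmax_temperature` 0.2, `lapse_rate` 0.08, `distractor_confusability`
0.5, `error_reindex_rate` 0.3) were chosen so that pooled synthetic
behavior sits near the reported operating point of trained macaques:
criterion at roughly trial 6 in context 1 versus 2-3 in context 2, a
pro-active index near +0.3, a retro-active index near +0.1, and D chosen
more often than C after an erroneous B. Repeats reuse the source block's
final context-1 values scaled by `retention_factor` (0.8), further reduced
by `background_bonus` (0.2) when the repeat appears on a different
background.

What the generator does *not* emulate: reaction-time structure beyond
optional log-normal noise, motivational drift within sessions, spatial
biases (object locations are not modelled at all), and any within-subject
evolution of the strategy mixture during a block. Passing tests therefore
say nothing about those aspects of real data.

## Learning metrics

The completion curve is the per-trial proportion of blocks whose trial was
completed (position 5 reached within the touch budget). The learning
criterion is the first trial with completion ≥ 80% sustained for three
further consecutive trials, computed on the raw curve; the bounded
four-parameter logistic fit (three starts, asymptotes clamped to [0, 1])
is descriptive only. Ordinal-position accuracy uses the first search
attempt per (trial, position); its chance reference is the forward-looking
level 1/(7 − p), which assumes secured objects are never re-chosen and
equals the absolute 1/6 only at position 1. Errors are classified into
exploration, rule-breaking, distractor and perseverative types with a
fixed precedence (rule_breaking > perseverative > distractor >
exploration) because the definitions overlap; "not yet learned" for
exploration errors means not yet correctly chosen in the current trial.
Error-type proportions per trial are fitted with a·exp(−b·x) + c, with b
reported even when non-positive. Proficiency terciles cut mean errors per
trial at 5.33 and 6.6 (the study's thresholds) or at empirical terciles
with a deterministic tie-break on block id.

## Swap statistics

Transition tables condition on three events in context 2 — a correct A at
position 1, an erroneous B at position 2, a correct D at position 2 — and
count the *next free search choice*; forced retouches are skipped, which
is why P(A) after an erroneous B is near zero rather than near one. The
default scope is trials strictly before the block's own criterion; blocks
that never reach criterion contribute all 15 trials. Binomial confidence
intervals use the normal approximation with a Wilson fallback below 5
counts. The pro-active index is P(D|A) − P(B|A), the retro-active index
P(D|B) − P(C|B), the serial contrast P(D|A) − P(C|A).

Per-block and per-session indices used in regressions (proficiency,
across-session trends, DMTS coupling, context effects) are computed on a
fixed early window, context-2 trials 1-3, instead of the pre-criterion
filter. The reason is a selection artifact: a block that re-indexes
immediately reaches criterion on trial 1 and has *no* pre-criterion
trials, so the pre-criterion filter silently drops the strongest swappers
and can invert block-level couplings. The same effect is worth remembering
when reading pooled pre-criterion tables: they over-represent trials from
serial- and exploration-dominated stretches.

First-choice analyses condition on trials whose first touch was a correct
A and read the second touch, comparing the first context-2 trial with the
last context-1 trial (Welch tests per label, Benjamini-Hochberg adjusted);
the trial-by-trial version tracks D−B, C−B and D−C across context-2 trials
and reports the first trial whose D−C interval excludes zero. Welch's t
(with Welch-Satterthwaite df), the two-proportion Z with pooled variance,
Bonferroni and BH step-up adjustments, and OLS with Cohen's
f² = R²/(1 − R²) are thin wrappers over scipy/statsmodels; fixed label
contrasts default to Bonferroni, first-choice contrasts to BH, matching
the analyses' stated usage.

## Bayesian strategy model

Counts of second-position choices over {B, C, D, E, X} are multinomial
with probability vector θ. Each raw component carries an independent
Beta(2, 5) prior on (0, 1) and the likelihood is evaluated at θ/Σθ; the
prior breaks the likelihood's scale invariance, making the posterior over
raw components proper, and all summaries (means, 95% credible intervals,
ordering probabilities, R̂) are computed from the normalized draws.

Sampling is a Metropolis-Hastings Gaussian random walk with fixed step
0.05, 200,000 iterations, 100,000 burn-in, no thinning, four chains (the
first started at the floored empirical-proportion MLE, the rest drawn
from the prior). Components are updated **one at a time in a systematic
scan** rather than jointly: a joint perturbation of all components at this
step size has acceptance ~10⁻³ once counts reach a thousand and freezes
the chains entirely at ten thousand (measured max R̂ ≈ 2.2), while the
component-wise walk keeps acceptance between roughly 0.1 and 0.6 across
count totals of 100-10,000 and R̂ below 1.01. Proposals leaving (0, 1)
are rejected. Acceptance rates are logged and a warning is emitted
outside (0.05, 0.8).

A consequence of this prior geometry worth stating plainly: with flat
Beta(1, 1) priors the normalized posterior is **not** Dirichlet(counts+1).
Marginalizing the free scale of the raw components leaves a tilt factor
(∝ max(p)^−(n+K) for flat priors), producing an O(1/n) deviation from the
Dirichlet mean — about 0.017 on the largest component at n = 100. The
sampler itself is validated against exact Gauss-Legendre quadrature of
the true posterior at K = 2 and K = 3, and against closed-form ordering
probabilities computed the same way.

Strategy calls use posterior ordering mass: position coding is
P(θ_D > θ_B and θ_D > θ_C), serial inference is
P(θ_C > θ_B and θ_C > θ_D), the rest is "other"; the label is the argmax
(ties → other). Aggregation sums counts per group for the pooled
posterior and classifies each session separately; sessions with fewer
than 5 conditioning events are excluded and logged. Per-session
classification uses reduced settings (20,000 iterations, 10,000 burn-in,
2 chains) — at 50-1,000 events the component-wise walk equilibrates well
within that budget, and classification depends only on ordering
probabilities.

## Session-level analyses

Condition comparisons (new-early / new-late / repeat) report mean
criterion trials (censored blocks counted separately) and mean swap
indices with Bonferroni-adjusted pairwise Welch tests. The completion
gain of a repeat is its context-1 completion rate minus its paired source
block's. One-sample tests of an index against zero use Student's t. The
DMTS correlation reports per-subject and pooled OLS plus the slope and p
of a random-intercept mixed model delegated to statsmodels (`MixedLM`);
that fit is the only statistic not computed by this package's own code.
The consolidated report (JSON + markdown) contains provenance (seed,
config, library versions, no timestamps) and is byte-identical across
runs with the same seed and inputs.

## Numerical choices and problem sizes

Simulations in the test suite run at the session skeleton's natural scale
(10 blocks of 2 × 15 trials); pooled statistics use a few hundred blocks,
sign-test effect-recovery checks use 200 replicates of small paired
experiments, and strategy-recovery checks use 200 sessions of 60 events —
sizes at which every targeted effect is decided with wide margin while
the full suite stays in the minutes range. Sigmoid and decay fits use
bounded `curve_fit` with three starts and report non-convergence through
a flag rather than an exception; degenerate inputs (constant samples,
zero denominators, missing reaction times, censored criteria) are flagged
values or logged skips, never silent zeros.

## Known limitations

* The agent is a stand-in, not a fitted model of any animal; its strategy
  mixture is the *definition* of ground truth in recovery tests, which is
  what makes them interpretable but also circular with respect to real
  behavioral mechanisms.
* The retro-active index at single-session scale rests on few conditioning
  events (B-errors at position 2 are rare by design) and is accordingly
  noisy; pooled analyses are the intended scale.
* The Bayesian model treats sessions as exchangeable within a group and
  pools by summing counts; there is no hierarchical shrinkage, and no
  hyperparameters are estimated.
* The "valid session" minimum-event rule (≥ 5 conditioning events) is this
  package's operationalization; no external definition exists.
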