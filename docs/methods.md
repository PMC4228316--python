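# Methods

## The problem the package models

Computer-tailored print interventions generate individualised health
communication by passing a participant's survey responses through
deterministic selection algorithms and a library of pre-written messages.
tailorkit implements the full loop for a multi-wave physical-activity
program aimed at post-treatment breast cancer survivors: a baseline
tailoring assessment drives the first newsletter, two interim "update
cards" (dispatched 4 and 8 weeks post-baseline) refresh the activity data
for newsletters two and three, and a post-program evaluation survey is
summarised and modelled.

## Variable algebra and rule-chain semantics

Tailoring logic is expressed in three tiers:

- **Raw variables** are direct survey responses.  Domains are numeric
  (finite bounds), coded categories (1-based integer codes, as printed on
  the survey), or free text.  The empty cell is the missing sentinel.
- **Intermediate variables** derive values from raw responses — either
  through a first-match rule chain or, where the formula involves
  arithmetic over several items, a named builtin (currently only the
  aerobic guideline classifier).
- **Feedback variables** are first-match chains over raw and intermediate
  values whose output codes are message identifiers.

A rule chain is an ordered if/else-if/else cascade of conjunctions of
atomic comparisons (`<`, `<=`, `==`, `>=`, `>`, set membership) against
constants, closed by a mandatory default code.  Evaluation semantics:

- the *first* clause whose conjunction holds determines the result;
- any comparison touching a missing value is false, so a fully unanswered
  assessment falls through every clause to the default — this implements
  the default-message rule for non-response and makes missing data
  *monotone*: deleting answers can only move a result to the default code,
  never to a different message;
- evaluation is pure and independent of binding insertion order.

A defaultless builtin intermediate that cannot be resolved (incomplete
activity profile) is recorded under the reserved assignment code `0`
(`UNRESOLVED`) and treated as missing by downstream chains, so the
assignment map stays total while non-response still routes to the default
feedback message.

Aliases map alternative spellings of a variable name (the kind of drift
that accumulates between assessment and algorithm tables) onto one declared
variable; lookups are alias-transparent on both the rule side and the data
side.

## Aerobic guideline classification

The guideline is >= 150 weighted minutes of aerobic activity per week
across >= 5 sessions, with vigorous (strenuous) minutes counted double.
The assessment items record sessions/week and average minutes *per
session* for strenuous and moderate activity separately, which leaves two
readings of the published decision table:

- **weekly-total** (default): `weighted = 2·st_sess·st_min +
  mo_sess·mo_min`, meeting iff `st_sess + mo_sess >= 5` and
  `weighted >= 150`.  This is dimensionally consistent (the 150 threshold
  is a weekly quantity) and matches the cohort-table row label
  "aerobic exercise > 150 min/wk + 5 or more sessions".
- **literal**: the two published branches applied verbatim to per-session
  minutes (`2·st_min + mo_min`).  The two branches do not cover mixed
  cases (e.g. >= 5 sessions but minutes below threshold); such profiles
  are conservatively classified *not meeting*, with a logged warning —
  erring toward offering support.

Both thresholds are closed (>=).  Missing minutes are tolerated only when
the matching session count is zero; otherwise the profile is unresolved.
The "disability < 3" branch cut is strict, complementary to the ">= 3"
branches.  The published feedback table is truncated ("Etc.") after five
lines; the shipped catalog completes the pattern symmetrically across both
guideline codes — 2 (guideline) × 2 (disability split) × 3 (post-diagnosis
change) = 12 codes plus default code 13 — which is a documented
reconstruction, not a transcription.

## Newsletter assembly

Every newsletter has five slots in fixed order: welcome, expert advice
(non-tailored), behaviour feedback, persuasive message (content-matched on
Social Cognitive Theory constructs: self-efficacy, environment,
behavioural capability, expectations, self-control, observational
learning), and an action-planning task.  Merge fields use `{{name}}`
syntax against a closed declared set; a missing first name renders the
configured fallback salutation ("Dear participant").  The feedback chart
is emitted as data (per-wave weighted weekly minutes plus the 150 min/wk
reference); a matplotlib helper can rasterise it but the canonical payload
is the series itself.  Assembly is a pure function of (template, library,
assignments, record, chart) and serialises canonically (sorted keys, fixed
separators), so identical inputs are byte-identical — verified against a
frozen fixture document.

Coverage validation enumerates the reachable code set of each bound chain
by brute force over the (finite) domains of its referenced variables,
including the missing value, and reports unmapped codes, orphan messages
and missing defaults.  If coverage passes, assembly cannot fail for any
record valid against the catalog.

## Program schedule and the two-week fallback

The calendar is relative (day offsets), since nothing in the logic depends
on absolute dates: three waves 42 days apart, update cards at 28 and 56
days post-baseline, and a 14-day fallback window.  A card informs wave
`w ∈ {2, 3}` iff its return delay (measured from card dispatch; the
operationalisation from a print date is not distinguishable from the
published description) is <= 14 days; otherwise that wave is generated from
baseline data alone and flagged non-iterative.  This makes iterativeness
monotone in the window length.  Delivery logs capture the assignment map
and message ids per participant-wave; `message_heterogeneity` reports
per-slot variant counts and Shannon entropy in bits (0 = everyone received
the same message; log2 of the variant count = uniform spread), the audit
the tailoring literature asks for when judging whether an algorithm
actually differentiates its audience.

## Synthetic cohort generator

The generator exists so that calibration and property tests can run
without participant data.  Defaults encode the published summary figures
of the evaluated cohort and are treated as fixed study conditions:

| Quantity | Default | Source of the value |
|---|---|---|
| age | truncated normal, mean 56, range 34–74 | published mean/range; SD 10 chosen (not reported) |
| BMI | normal(26.60, 5.11) | published mean/SD |
| married/de facto | 0.796 | published |
| P(meet aerobic guideline) | 0.235 | published |
| P(> 6 resistance exercises/wk) | 0.1531 | published (strict `>` per the row label) |
| update-card cells (both, only-1, only-2, neither) | 0.49, 0.21, 0.11, 0.19 | see below |
| rating triples (mean, SD, P>=3) | attention 3.6/0.88/0.74; relevance 3.7/0.96/0.73; usefulness 3.2/1.11/0.632 | published |
| relevance→usefulness OR | 4.8 | published |
| evaluation response rate | 0.84 | published |

Activity is generated *label-first*: the meeting label is drawn Bernoulli
at the configured prevalence, then sessions and per-session minutes are
drawn from label-conditional distributions (meeting: 5–7 sessions, 150–600
weighted weekly minutes, ceiling-rounded; not meeting: either < 5 sessions,
or 5–7 sessions with < 150 weighted minutes, floor-rounded).  The
weekly-total classifier therefore recovers the label with certainty and
the configured prevalence is exact in expectation — no rejection sampling.
Disability and post-diagnosis-change category distributions are not
reported and were fixed once at plausible values (most survivors little
limited; half doing less than before diagnosis); they shape message
routing, not any calibration target.

**Update-card returns.**  The four published figures (card 1: 70%, card 2:
60%, both: 49%, none: 15%) are jointly inconsistent (the implied cells sum
to 0.96).  The model fixes both = 0.49, only-1 = 0.21, only-2 = 0.11 and
lets neither = 0.19 absorb the inconsistency, preserving the three rates
used as calibration targets.  Return delays are truncated-normal(8, 3) on
[1, 14] days: the published rates count returns *within the specified
two-week timeframe*, so in-window delays are the faithful reading; late
returns are folded into non-return.  Returned cards carry fresh last-month
activity drawn by the same label-first mechanism (at the baseline
prevalence — no intervention effect is published, so none is assumed).

**Ratings.**  Each printed triple (mean, SD, P>=3) is inverted into an
actual 5-point distribution by a constrained solver: four linear equality
constraints in five probabilities, maximum entropy among exact solutions.
The attention and relevance triples are *jointly infeasible* on a 1–5
scale — with the printed mean and tail mass the minimum attainable SD is
1.000 (attention) and 1.109 (relevance), above the printed 0.88 and 0.96.
This is unsurprising for rounded sample statistics from ~90 respondents,
but it means no generator can match all three figures at once.  The
non-strict solver therefore matches the mean and the tail mass exactly
(these are the figures the calibration checks target) and minimises the
variance gap; `strict=True` raises `InfeasibleMomentsError` instead.  Any
distribution the strict solver returns reproduces its targets to 1e-6.

The relevance→usefulness association is generated structurally: usefulness
is drawn from a two-group cumulative-logit model with binary exposure
"rated relevant" (relevance >= 3) and log-odds shift ln(4.8).  The four
cutpoints are solved (bisection on the monotone mixture CDF) so that the
*marginal* usefulness distribution still equals its moment-matched target
exactly.  Because a two-group cumulative-logit mixture *is* a
proportional-odds model in that binary predictor, the fitted odds ratio is
a consistent estimate of 4.8 — making parameter recovery a genuine
end-to-end check of generator plus fitter rather than a tautology.
Non-response to the evaluation survey is missing completely at random at
rate 0.16, consistent with the reported absence of responder/non-responder
differences.

## Process evaluation

`summarize_likert` reports completer n, mean, sample SD (ddof = 1) and
P(>= 3) ("somewhat" to "very much").  `fit_proportional_odds` is a
maximum-likelihood cumulative-logit fit (statsmodels `OrderedModel`,
logit link, BFGS) with Wald 95% intervals exponentiated to the OR scale,
parameterised so that OR > 1 means higher odds of a *higher* rating.
Constant outcomes, singular designs and (quasi-)complete separation
(|log-odds| > 15 or non-finite standard errors) raise errors; plain
non-convergence is flagged on the result and warned, never silently
ignored.  Predictors may be entered jointly (default) or as univariable
screens — the published analysis does not say which was used, so both are
available and neither is asserted.  P-values are unadjusted and flagged as
such.  Two identities anchor the fitter independently of the generator:
on a binary outcome the model coincides with binary logistic regression
(checked to 1e-4 relative), and with a single binary predictor the ML
estimate equals the 2×2 cross-product ratio.

`compare_responders` reports standardised mean differences (pooled-SD
denominator) with Welch t-tests for continuous variables and proportion
differences with chi-squared tests for binary ones.  `build_report`
assembles summaries, fits and heterogeneity tables into a deterministic
JSON/HTML report embedding seed and config hashes.

## Problem sizes and numerical choices

Calibration checks use 20,000 records for cohort prevalences (binomial SE
≈ 0.3 pp against ±1 pp tolerances), 10,000 for return cells (SE ≈ 0.5 pp
against ±1.5 pp), 5,000 respondents for rating marginals (SE on the mean
≈ 0.015 against ±0.05), and 200 replicates of n = 5,000 for odds-ratio
recovery — sizes at which Monte-Carlo error is a small fraction of each
tolerance while the full suite completes in about a minute on one core.
Chain enumeration in coverage validation caps the product space at 20,000
combinations and falls back to the syntactic code set beyond that.  The
marginal solver accepts constraint residuals up to 1e-9 and verifies
feasibility by linear programming before polishing with SLSQP.

## Known limitations

- Demographics are drawn as independent marginals; covariances between
  age, BMI, activity and ratings are not reported and not modelled, so
  analyses that depend on realistic cross-correlations (e.g. the published
  multi-predictor regression coefficients) are out of reach by design.
- The shipped message library is a demonstration: it covers every code of
  the shipped catalog with placeholder prose, since the original
  newsletters' text is not published.
- The published per-predictor regression table from the trial cannot be
  reproduced without participant-level data; the module reproduces the
  analysis *structure* and is validated by parameter recovery on synthetic
  data instead.
- Passing calibration shows the pipeline is self-consistent under the
  generator's assumptions (label-first activity, MCAR non-response,
  in-window return delays), not that it would reproduce any particular
  real cohort.
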