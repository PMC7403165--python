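# Methods

## The mixture model

A reading-aloud trial presents a pseudoword whose critical grapheme sits in
one of four orthographic conditions, formed by crossing two context-sensitive
rules against the context-free ("simple") correspondence. The model assumes a
reader resolves each trial by relying on one of three rule types — the simple
GPC and the two context-sensitive rules (onset-context `CS_O` and
body-context `CS_B` in the English-style design; the vowel-length super-rule
`SR` and `CS_B` in the German-style design) — with probabilities
β = (β₁, β₂, β₃). Conditional on the chosen rule *j* and the condition *c*,
the response category is drawn from the corpus conditional distribution
P(category | rule_j, c). The observable consequence is

P(category | c) = Σ_j β_j · P(category | rule_j, c),

so the modeled response proportions are linear in β and the weights are
interpretable as reliance probabilities.

**Estimation.** For each participant we collect the observed proportion of
every modeled category in every condition (non-error trials only; conditions
with no usable trials are dropped, and at least two conditions are required)
and minimise the equally weighted sum of squared residuals over all
(condition, category) cells, subject to β_j ∈ [0, 1] and Σ β_j = 1. The
objective is a convex quadratic and the feasible set is the probability
simplex; we solve with SLSQP from ten starting points (the three vertices,
the barycentre, and six seeded random interior points) and keep the best
solution, with a loss tolerance of 1e-12 per solve. Multi-start is cheap
insurance against solver stalls near the boundary; for this convex problem
every start should reach the same optimum, and the test suite verifies
global optimality against a 0.01-step brute-force grid over the simplex.

**Relaxed variant.** Dropping *all* constraints (the sum-to-one equality and
both box bounds) turns the problem into ordinary linear least squares, solved
in closed form. The relaxed fit can return negative weights; it exists as a
diagnostic — if the three modeled rules suffice, relaxing the constraints
should barely move the weights.

**Identifiability.** The fit is flagged non-identifiable when the stacked
rule-prediction matrix has rank < 3 (tolerance 1e-10), e.g. when all rules
make identical predictions; such fits are excluded from grade-level
aggregation (with a logged count) because their β is one of many equal-loss
optima.

**Observed-proportion denominators.** English-style transcriptions include
vowel responses outside the modeled set ("other vowel"). By default these
stay in the denominator — the modeled proportions are proportions of *all*
valid responses, matching the residual probability mass the corpus tables
leave unassigned — and a `renormalize_modeled` switch restricts denominators
to modeled categories for sensitivity analysis. Proportions and percentages
give identical weights (the objective only scales).

**Model fit.** Per grade, the observed and predicted percentages of every
participant × condition × category cell are pooled and summarised by one
Pearson r. Zero variance in either pooled vector leaves r undefined; it is
reported as NaN, never coerced to 0.

## Entropy statistics

Response variability is measured by the plug-in Shannon entropy
H = −Σ p_i log₂ p_i (bits), with 0·log 0 ≡ 0 and no small-sample correction.
Item-level entropy is computed over the response distribution of each item;
participant-level entropy over each reader's responses, overall and per
condition. Inclusion follows the design's scoring: English-style entropies
use consonant-correct trials and treat every distinct transcribed vowel label
(including an "other_vowel" code, if the table collapses them) as a category;
German-style entropies use correct trials only, so they are bounded by 1 bit.

## Lexicon statistics

For an orthographic cluster in a pronounced wordlist: frequency is the
number of words containing it; consistency is the modal pronunciation's
share of those words (ties broken lexicographically and flagged); entropy is
the Shannon entropy of the pronunciation distribution, in a type-based form
(each word once) and a token-weighted form (words weighted by token
frequency) — the two differ whenever token frequencies are non-uniform, and
the type/token choice is left to the caller because published consistency
norms vary in this respect. The same counting yields corpus tables
P(category | rule, condition) from any wordlist, given predicates selecting
the words that exemplify each rule's context in each condition.

The package bundles a nine-row reference table of critical *a*-context
clusters (frequency, consistency, entropy, and membership in one or both of
two developmental reading studies). Group averages over this table are pure
arithmetic on its printed values; the entropy column's exact weighting
scheme is not recoverable from those values alone (e.g. a row with
consistency 0.89 carries entropy 0.15 where a binary type entropy would give
0.50), so only the group means — not re-derived row entropies — are treated
as checkable quantities.

## Test–retest overlap

For a reader responding to the same items in two sessions, each item is coded
1 when both sessions produced the same vowel category or both were scored
incorrect (consonant error / non-response), 0 otherwise, with incorrect
responses included in the denominator. The per-reader overlap is the mean
code; summaries report mean, sample SD, min, max and per-grade breakdowns.
Items present in only one session are excluded with a logged count. Coding is
symmetric in session order, and a session compared with itself scores exactly
1.

## The synthetic-data generator

The simulator implements the generative mechanism the model assumes, plus
two noise processes: per trial, (1) with probability `consonant_error_rate`
the trial is an error (consonant error / non-response); otherwise (2) a rule
type is sampled from the participant's β and a response from that rule's
conditional distribution, English residual mass going to "other_vowel";
(3) with probability `lapse_rate` the response is overwritten by a uniform
draw over the plausible categories (modeled plus "other_vowel" for English,
short/long for German) — an unsystematic error term. Optional per-participant
heterogeneity draws individual β from a Dirichlet centred on the grade-level
vector; it defaults off so recovery studies have a well-defined estimand.
Sessions are independent conditional on the profile.

Randomness uses one root seed with per-participant `SeedSequence([seed,
grade, index])` streams, so enlarging a cohort never perturbs existing
participants and every table is bit-reproducible.

**What the simulator does and does not emulate.** It reproduces the
statistical structure the analyses assume — mixture-of-rules responding,
condition-specific conditional distributions, unsystematic lapses,
session-independent repetition — so passing recovery tests shows the
estimator and statistics are correct *under that mechanism*. It does not
emulate lexical-neighbour interference, additional untracked regularities
(e.g. final-*e* effects), orthographic learning between sessions, or
transcription ambiguity; real data may violate the mechanism in exactly the
ways that depressed model fits motivate the entropy analyses.

## Preset designs and fixture tables

Two presets ship with the package: the English-style four-condition design
(`CS_O±CS_B±`, modeled categories /æ/, /ɔ/, /o:/) and the German-style design
(`SR±CS_B±`, short/long). Their probability tables are synthetic fixtures
with the qualitative structure of corpus statistics — each context rule
points strongly to its favoured vowel in its marked conditions and leaves a
few percent of residual mass — not values derived from any corpus. The
default condition sizes are 16 items (configurable); study-scale validation
uses 50 items per condition and 100 readers.

## Study conditions used by the validation runs

Parameter-recovery and degradation studies simulate 100 participants with
β = (0.2, 0.7, 0.1), 50 items per condition, lapse rates {0, 0.1, 0.2, 0.3},
averaged over 10 seeds; test-retest runs use 20 two-session participants with
16 items per condition. The recovery estimand is the cohort-averaged weight
vector — the quantity the grade-level tables report — whose absolute error
stays below 0.01 per component without noise; per-participant weights carry
sampling noise of a few hundredths at these trial counts. The degradation
runs show model-fit r strictly decreasing and mean item entropy strictly
increasing in the lapse rate: unsystematic noise masquerades as poor model
fit and inflated entropy, which is the package's diagnostic rationale for
computing both.

## Multiple-comparison note

Participant-level entropy measures (overall plus four conditions) are
intended to be correlated with reading-ability scores; for the standard
15-test correlation family the report prints the Bonferroni-adjusted alpha
0.05/15 = 0.003 (displayed at three decimals). Inferential statistics
themselves (ANOVAs, t tests, correlation significance) are out of scope: the
emitted tables are tidy inputs for any statistics package.

## Numerical choices and degenerate inputs

- Filter thresholds are strict inequalities; both error rates are computed on
  the unfiltered table, making participant-then-item removal
  order-independent.
- Sample SDs (n−1) throughout; a single observation reports SD as NaN.
- Entropy of an empty or negative distribution is an error, not 0.
- Constrained fits are renormalised onto the simplex after solving (clipping
  at 1e-6-level solver slack).
- `-0.0` entropies are normalised to `0.0`.
- Dialects: CSV/TSV chosen by file extension, UTF-8, decimal point.
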