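# Methods

This note documents the models and procedures implemented in `mhpulse`,
the defaults that matter, what the synthetic-data generator does and does
not emulate, and the design choices made where the design was genuinely
open. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Filter cascade

Records pass five predicates in a fixed order: language (`lang == "en"`
exactly), retweet flag, URL presence, mental-health lexicon match, and a
spam-user rule. Each record is removed at exactly one stage (the first
failing one), which gives a telescoping per-stage report. Design points:

* URL detection trusts the metadata entity list; a regex fallback
  (`https?://…`, `t.co/…`) applies only to records without an `entities`
  object, since upstream annotation is more reliable than text scraping.
* The spam rule counts a user's *matching* tweets within the analysis
  window and removes users with strictly more than the threshold
  (default 1000): a user at exactly the threshold is kept.
* Duplicate tweet ids keep the first occurrence; more than 10% malformed
  lines in a stream aborts ingestion as a probable schema mismatch.
* Total kept count is invariant to permuting the record-local stages
  (language/retweet/URL); only the per-stage attribution depends on order.

## Lexicons and matching

Matching is case-insensitive after NFKC normalization, at word boundaries
(a term matches only when flanked by non-word characters or string edges),
with multi-word phrases matched as contiguous token sequences and `#`
treated as a boundary so `#anxiety` matches `anxiety`. Word-boundary
rather than substring matching prevents, e.g., "mad" firing inside
"nomad". A tweet may match terms from several subgroups and then counts
once in *each* subgroup's numerator — subgroup shares may legitimately sum
above 100%.

The packaged mental-health lexicon (85 terms over anxiety / depression /
insomnia / addiction) is a representative working list, not a clinically
curated instrument; every classifier takes the lexicon as an argument so a
curated list can be dropped in. The 47-term health-care-worker dictionary
spans occupations, degrees and association titles. Short degree acronyms
(`MD`, `DO`, `RN`, …) match only as exact-case standalone tokens, and a
co-occurrence guard suppresses an acronym that doubles as a state
abbreviation whenever another state alias appears in the description
("Road trip through MD and VA" is geography, not a degree).

Geography: the GPS-derived `place` field is primary evidence; the
free-text `location` is the fallback. Full state names match
case-insensitively; two-letter USPS abbreviations only as exact-uppercase
tokens (otherwise "or", "in", "me" would geocode). On conflicts between
full names the longest alias wins ("Kansas City, Missouri" → Missouri).
Users whose tweets resolve to two or more states are excluded from all
geographic analyses; users with no resolution stay in non-geographic ones.
City-to-state inference is deliberately not attempted.

## Proportions and intervals

Proportions are matched-tweet counts over all-stream counts per period and
stratum. Weeks are ISO weeks (Monday start), months calendar months, all
UTC, half-open `[start, end)`. Intervals are 95% Wilson score by default —
robust for the small numerators of low-volume state-months — with the Wald
interval available for comparison. The denominator is the
language/retweet/URL-filtered stream (the population from which matches
are drawn); this is configurable since the alternative (pre-URL-filter)
is equally defensible.

For cohort topic usage, the average number of tweets per user on a topic
divides by all distinct users in the cohort, including users with zero
tweets on that topic. The HCW/general log-ratio uses Haldane-style
smoothing (add 0.5 tweets to both cohorts' totals) when either average is
zero, flagged in the output, so all topics plot finitely.

## Topic model

LDA with symmetric priors, fitted by collapsed Gibbs sampling — chosen
over variational inference because the sampler is correct by construction
and its count statistics are invariant-checkable after every sweep
(Σ_w n_kw[k,w] = n_k[k]; Σ_k n_dk[d,k] = doc length; counts consistent
with the assignment vector). Defaults α = 50/K, β = 0.01. The inner loop
is numba-jitted with an inline xorshift64* generator threaded through the
kernels, so runs are bit-reproducible for a fixed seed independent of
library RNG state; a pure-Python reference sampler in the test suite
checks distributional agreement on a toy corpus.

Preprocessing lower-cases (NFKC), keeps letter-initial tokens (numbers
and symbol runs drop), removes a packaged snapshot of a standard English
stopword list (pinned for reproducibility over upstream drift), and
adjoins bigrams of adjacent surviving tokens occurring at least
`bigram_min_count` (default 5) times. Documents empty after cleaning are
dropped with a logged count.

Held-out perplexity is exp(−mean per-token log-likelihood) under
posterior-mean topic-word estimates, with held-out document mixtures
estimated by 30 fold-in Gibbs sweeps (topic-word counts frozen);
out-of-vocabulary tokens are dropped and counted. Coherence is UMass
(intrinsic, needs no external corpus): per topic the mean over ordered
top-10 term pairs of log[(D(w_i,w_j)+1)/D(w_j)] with document frequencies
from the training corpus, a top term absent from the corpus contributing
with its document frequency floored at 1 (so absence never raises).

Model-size selection fits each K in a grid (averaged over seeds) on an
80/20 train/held-out split and returns the K maximizing coherence among
those whose held-out perplexity is within 5% (relative) of the grid
minimum; the full diagnostic table is returned so any other rule can be
applied. The reference configuration for real corpora of this kind is
K = 16. Note the rule's behaviour depends on corpus richness: with very
small vocabularies, split near-duplicate topics can cohere as well as the
planted ones and the rule may prefer a larger K; the planted-recovery
guarantees quoted by the tests are for the documented generator
conditions (K_true = 5, V = 200, 1000 documents of mean length 60).

Topic-share series use each document's modal topic (argmax of smoothed
doc-topic counts), so shares are mutually exclusive and sum to 1 per
period.

## Interrupted time series

Segmented OLS of the daily matched proportion on [1, t, P, t·P] over a
±`window` (default 15-day) span. Encoding decisions that change the
meaning of coefficients, recorded prominently:

* t = 1 on the first pre-policy day and runs to 2·window — so the
  intercept is the level one day before the window, not at the policy
  date;
* the policy day itself is the first post-policy day (P = 1 on that day);
* re-fitting at a narrower window re-bases t, which leaves the two slope
  coefficients unchanged and shifts intercept and step by the exact
  affine map β₀ → β₀ + β₁·offset, β₂ → β₂ + β₃·offset (offset = window
  difference in days). The sensitivity table reports sign stability of
  the step and slope-change terms across windows.

Inference is classical OLS (matching standard ITS practice), with
Newey–West (HAC) standard errors by flag and the Durbin–Watson statistic
reported so users can judge residual autocorrelation. Significance is
two-sided at .05 with no multiplicity correction across states (noted in
output metadata). Missing days inside the window are linearly
interpolated with a logged warning; more than 20% missing refuses to fit.
Degenerate inputs (constant y, exact fit) fall back to the
sums-of-squares definition of the overall F (0 when the centered total
sum of squares vanishes, +∞ when only the residual does).

## Cohort comparison

Pairing unit is the ISO week (months by configuration); the two cohorts'
series are inner-joined on period, and unpaired periods are dropped with a
logged count. Zero differences are removed (Wilcoxon's convention), tied
absolute differences get midranks, and W is the sum of ranks of positive
differences. For n_eff ≤ 25 the two-sided p is exact, computed from the
full sign-flip distribution of W via the characteristic polynomial
∏(1 + x^{2r_i}) on doubled midranks — integer arithmetic, mathematically
identical to enumerating all 2^n sign assignments, and symmetric about
S/2 even under ties, so p = P(W′ ≤ min(w, S−w)) + P(W′ ≥ max(w, S−w)).
Beyond 25 pairs a normal approximation with tie correction
(Σ(t³−t)/48) and continuity correction is used; the two agree within 0.01
by n ≈ 20. Fewer than 6 effective pairs returns a low-power flag rather
than refusing. Summaries are medians with 25th/75th percentiles by linear
interpolation between order statistics, reported in percent (the test is
scale-invariant).

## Synthetic-data generator

The generator emulates exactly the features the pipeline estimates:
multi-label keyword occurrence at cohort-specific per-tweet rates, an HCW
subpopulation identifiable from profile descriptions, state-resolvable
geography with a multi-state-user fraction, spam users, mutually
exclusive URL/retweet/non-English nuisance categories, tweet text drawn
from an LDA generative process with planted lexicon terms inserted, and a
state-specific step and slope change in the daily matched proportion
inside the policy window. One global seed drives independent per-component
substreams, so adding a component never perturbs another's draws and
regeneration is byte-identical.

Reference defaults (chosen once as the study conditions): 1000 users, 1%
HCW, five states with fixed weights, a Feb–May 2020 window containing the
four planted policy dates with the published step/slope pairs, per-tweet
subgroup rates near the published cohort medians (≈1% anxiety/depression,
≈0.1% insomnia/addiction, HCW higher), nuisance fractions 0.30/0.20/0.10
(URL/retweet/non-English), 5% multi-state users, 19% geotagged, daily
proportion noise SD 0.003, and topic structure K_true = 5, V = 200,
Dirichlet concentrations α = 0.1, β = 0.01 (the standard sparse-topic
choice for synthetic LDA evaluation). Spam users emit exactly
threshold + 100 matching tweets so the spam filter's effect is
deterministic. Per-day volume is a Poisson knob
(`tweets_per_user_mean`), not a fixed schedule, since real streams vary.

What it does *not* emulate — hence what passing tests do not show about
real data: natural language (text is planted tokens, so lexicon recall on
real tweets, sarcasm, negation are untested), follower/reply structure,
platform sampling bias, population-share drift, and the joint scale of
the real corpus (10⁴ tweets versus 10⁸). The ITS effects are planted on
the daily proportion scale by rescaling subgroup rates, which is a
first-order approximation valid for small rates.

## Problem sizes

The test suite and acceptance script run at deliberately chosen sizes:
corpora of 300–1000 users (≈2,500–10,000 tweets), LDA at 1000 documents ×
60 tokens with 2000 sweeps for recovery and 150-sweep fits for model-size
search, 2000 replicates for the ITS type-I and coverage simulations
(the coverage band [0.93, 0.97] is ~4 Monte-Carlo standard errors wide at
that size, so the verdict is reliable), and 10,000 random samples for the
Wilcoxon oracle equivalence. These sizes give stable Monte-Carlo verdicts
while keeping a full run in minutes on one CPU.

## Known limitations

* Lexicon-based case ascertainment cannot distinguish self-report from
  commentary; the URL filter mitigates but does not remove this.
* The exact Wilcoxon path is O(n · S) in the rank total and is capped at
  25 pairs; beyond that the corrected normal approximation is used.
* The Gibbs sampler is single-chain; multi-seed refits are the supported
  way to assess stability (the selection routine does this).
* State resolution uses state names/abbreviations only; city-only
  locations do not resolve.
* ITS assumes i.i.d. Gaussian errors for its classical inference;
  Durbin–Watson and HAC errors are provided for checking, not an
  autocorrelation-robust default.
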