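# Methods

This note documents the statistical procedures implemented in `phv`, the
assumptions behind them, the tunable parameters and their defaults, what the
synthetic generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Data model

The unit of input is the *annotation line*: one row of a CSV table recording,
for one forum post, a drug annotation, an adverse-drug-event (ADE)
annotation, or both. When both appear on the same row the annotator has
asserted a causality relationship and the row is a *couple*; a couple is
*normalized* only when the drug carries an ATC level-5 code (pattern
`L DD LL DD`, e.g. `H03AA01`) and the ADE a MedDRA preferred-term (PT) code
(8 digits). Couples are never inferred by joining separate rows of a post:
the annotation process emits co-annotated rows, and the statistics respect
that boundary. Optional cells are empty on write; on read, empty cells and
the em-dash placeholder of printed tables both map to absent values. Dates
are canonically ISO 8601, with a locale fallback ("October 8, 2018") for
data pasted from publications. Rows that violate the schema are rejected
individually and reported with row numbers rather than aborting the load, so
accepted + rejected always equals the raw row count.

The bundled MedDRA/ATC tables (`phv/data/*.csv`) are a small synthetic
subset — 50 PTs with HLT/HLGT/SOC assignments and 40 ATC codes — sufficient
for tests and simulations. The licensed MedDRA and WHO ATC dictionaries are
not distributed; any production use should load real tables through the same
`Vocabulary` interface.

## Descriptive statistics

Percentages are reported to two decimals, rounded half-up, matching the
convention of printed cumulative-frequency tables; ranked distributions sort
by count descending with lexicographic tie-break so output is deterministic,
and cumulative percentages are always computed on the full total before any
top-n truncation. "Posts mentioning X" counts distinct post identifiers,
never lines. The F1 helper returns the exact harmonic mean 2PR/(P+R) of the
given precision/recall pair; published F1 values that were rounded before
printing may differ in the third decimal, and the helper makes no attempt to
reproduce such artifacts.

## Disproportionality (PRR / ROR)

Couple events are classified into the 2×2 table (a, b, c, d) =
(drug-of-interest × ADE-of-interest, drug × other ADE, other drug × ADE,
other × other). Counting is **event-level**: a pair annotated k times —
including repeats within one post — contributes k events. This is the
analysis mode; a post-level mode (each post counted once, classified by
presence) exists behind the `by="posts"` flag for sensitivity analyses only.
Multi-code selectors are pooled into a single entity of interest.

PRR = [a/(a+b)]/[c/(c+d)] and ROR = ad/bc. Confidence intervals are the
standard 95% Wald intervals on the log scale:

- ln PRR ± 1.96·sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d))
- ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d)

A **signal** is declared when the lower bound of the 95% CI of the log
measure exceeds 0 — a one-sided use of a two-sided interval, so the nominal
false-flag rate under independence is 2.5%.

Zero cells: the default policy is *strict* — when a required cell is zero
the estimate is returned as an explicit not-computable marker (NaN fields,
`computable=False`), never a silent infinity. The Haldane–Anscombe
continuity correction (+0.5 to every cell) is selectable with
`zero_cell="haldane"` for users who prefer a finite shrunken estimate.

The cumulative monthly series evaluates the chosen measure on all data up to
the end of each month, from the first month containing an event of the
selected pair to the last month with any couple event. Cumulative-from-start
windows are the default reading of "monthly cumulated" trends; a rolling
window would answer a different (local) question and is not implemented.

## Class-imbalanced subsampling lasso

The detector asks, for one ADE of interest, which drugs raise its per-post
odds after adjusting for all co-mentioned drugs. The design matrix is built
at post level: outcome 1 iff the post has at least one annotation of the
ADE; predictor i equal to 1 iff drug i (ATC level-5 identity) is annotated
at least once — presence, never multiplicity, on the assumption that an
annotated drug was taken by the author. All-zero predictor columns are
dropped with a report. Designs where every post, or no post, has the outcome
are refused as degenerate.

Because non-case posts vastly outnumber cases, each of B = 250 draws
resamples n₁ cases with replacement from S₁ and R = max(4·n₁, 4·N_m)
non-cases with replacement from S₀ — the 4·n₁ term mirrors case-control
matching ratios, the 4·N_m term guarantees observations against the
predictor count. Each draw fits an L1-penalized logistic regression
(liblinear; intercept unpenalized; binary indicators left unstandardized
since they share a scale) under a model-size cap of 50 predictors.

Penalty choice per draw: the path runs geometrically over 15 values from the
entry penalty λ_max (the sup-norm of the null-model score, where the first
predictor would enter) down to 0.1·λ_max, and the selected model is the one
at the smallest penalty whose active set respects the cap. The floor ratio
0.1 keeps the penalty within an order of magnitude of the entry point —
weaker floors approach the unpenalized fit and defeat the purpose of a
selection procedure, as in stability-selection practice where the informative
part of the path is its early region. When the candidate drug count is at
most the cap (the common case) the floor model itself is the selection, and
it is fitted directly. A cross-validated alternative
(`lambda_mode="cv"`) is available. A draw whose fit fails to converge is
re-drawn once with a derived seed, then recorded as all-zero with a warning
counter.

Retention: each drug accumulates one coefficient per draw (0 when absent
from the model); a drug is retained when the q-th percentile (q ∈ {5, 10,
15}; linear interpolation between order statistics) of its coefficient
collection is strictly positive. Lower q is stricter — q = 5 demands ~95% of
draws positive — so retained(5) ⊆ retained(10) ⊆ retained(15). A
selection-count mode (`retention="selection_counts"`, retain when selected
with a positive coefficient in at least (100−q)% of draws) is exposed as an
option; the two rules coincide except when coefficient ties at exactly zero
straddle the percentile.

Reproducibility: one master seed; per-draw generators are spawned
deterministically from it, so identical (design, config) give identical
results bitwise (liblinear's internal shuffling is pinned).

The adjusted factors are concomitant medications only; patient covariates
(age, sex) are typically absent from forum posts and are out of scope.

## Change-point analysis

For a segment x₁..xₙ with mean m, the CUSUM path S₀ = 0, Sᵢ = Sᵢ₋₁ + (xᵢ −
m) ends at zero and drifts when the mean shifts. The drift magnitude
s_diff = max S − min S is referred to its permutation distribution: the
segment values are randomly reordered n_bootstrap = 1000 times and the
confidence is the fraction of reorderings with smaller s_diff. When
confidence ≥ 0.95 a breakpoint is placed at the largest |Sᵢ| (earliest index
on ties) — the index equals the number of pre-shift observations — and the
procedure recurses on both sub-segments until no confident shift remains.

Numerical and structural choices: candidate breakpoints are constrained to
lie at least `min_segment_length` (default 6 months) from each segment
boundary, which both prevents spurious micro-segments and guarantees that
reported breakpoints are pairwise separated by at least that distance;
segments shorter than twice the minimum are never tested; the statistic is
the raw monthly count, unsmoothed; permutation (sampling without
replacement) is used rather than an i.i.d. bootstrap because the null
hypothesis is exchangeability of the segment. Recursion performs multiple
tests, so the family-wise false-alarm rate exceeds the per-segment 5%; the
acceptance study measures the per-series false-detection rate on i.i.d.
series at ~4–7%.

## Synthetic corpus generator

The generator emulates the *structure* of an annotated multi-forum corpus,
not its language. Per post: a forum is drawn from the configured mixture; a
month from a uniform distribution over the period, optionally volume-shifted
by a step multiplier from a configured month onward (the ground-truth
changepoint); each drug i is mentioned independently with probability pᵢ;
each ADE j is then present with log-odds logit(qⱼ) + Σ_{i mentioned} ln ρᵢⱼ.
This ADE stage is exactly the logistic model the lasso assumes, so the
configured odds multipliers ρ are the true coefficients (e^β) a correct
detector should recover, and ρ > 1 inflates the couple rate that
disproportionality should flag; ρ = 1 everywhere gives exact independence
for calibration studies.

Mentions materialize as annotation rows: every co-present (drug, ADE) pair
becomes a couple row with a pairing probability calibrated so that the mean
number of couple rows per post equals `couples_per_post` at independence
(default 0.2, the approximate couple-to-post ratio of large annotated forum
corpora); mentions left unpaired become drug-only or ADE-only rows, so
partial annotations — the majority of real rows — are represented. Verbatim
fields are lowercase label variants: schema-complete, linguistically empty.
Dates are uniform within the month and times uniform within the day; both
are schema requirements with no statistical role.

What passing tests on this generator do **not** show: robustness to NLP
annotation errors (miscoded drugs/ADEs), duplicate or fraudulent posts,
correlated drug co-mention structure (mentions are independent given the
post), forum-specific reporting styles, or seasonal patterns. Results on
real corpora depend on those features; the generator establishes correctness
of the statistics, not field performance.

The packaged surge scenario (`scenario_levothyrox`) is a 50-month corpus
with one dominant community forum (82% weight), a levothyroxine-class drug
mentioned in 35% of posts with ρ = 8 toward the "Tiredness" PT, and a
three-fold volume surge at month 24. Its parameters were calibrated once so
that the designed properties (dominant-forum share 75–90%, a breakpoint at
the surge month ±1, cumulative-PRR lower bound above 0 from the surge
onward) hold across seeds; it is used by the documentation and integration
tests.

## Study sizes used in the acceptance script

Simulation studies are sized to run in about a minute on one CPU while
keeping binomial noise well below the margins being tested: lasso recovery
uses 20 replicates of 2000 posts × 30 drugs (causal ρ = 5), the lasso null
100 replicates of a single-drug independent corpus, change-point recovery 50
replicates of a Poisson 10→40 step at month 24 of 48, false-alarm control
200 i.i.d. series, and disproportionality calibration 3 corpora of 20,000
posts (48 drug–ADE pairs each, all ρ = 1).

## Known limitations

- Wald intervals are first-order; for very sparse tables (cells of 1–3
  events) their coverage is approximate, and the strict zero-cell policy
  refuses rather than extrapolates.
- The lasso retention rule is one-sided by construction (positive
  coefficients only); protective associations are not reported.
- The percentile retention rule's intrinsic one-sided error under a
  selection-free null is roughly q%; corpora assembled from annotated posts
  only (the tool's actual input) are markedly more conservative because
  annotation acts as a selection filter.
- CUSUM recursion controls error per segment, not family-wise.
- The generator draws post months independently of content except through
  the configured shift; it cannot emulate autocorrelated posting dynamics.
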