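# Methods

## The screening model

`termscreen` operationalises a two-step expert-driven triage of bibliographic
records. Step 1 eliminates clearly irrelevant records by their titles: the
default rule removes a record whose title matches at least one negative
keyword and no positive keyword; decisions are exported for manual review
rather than silently applied. Step 2 scores every remaining record over its
title-plus-abstract tokens:

    TS = Σ_p w_p·m_p − penalty · Σ_n w_n·m_n
    w = weight/10,   m = (match count × keyword word count) / document word count

with integer expert weights in 1–10 and a default `penalty` of 1.2. Both
steps consume one shared keyword registry, which versions every committed
change (add, revise, remove) so the exact keyword state behind a screening
pass is auditable and reusable for review updates.

Key modelling assumptions:

* **Inclusive integer weights.** "Between 1 and 10" is read as inclusive
  integers, so `weight/10` gives clean decimal multipliers; fractional
  weights are rejected.
* **Tokenization.** Unicode NFKC, lowercase, punctuation stripped, split on
  whitespace; no stemming by default (an optional per-token stemmer hook
  exists but is off for all reference numbers). Keyword phrases pass through
  the same pipeline at registry-insertion time, so document and registry
  tokens match by construction.
* **Match counting** is non-overlapping greedy left-to-right: in
  `[a, a, a]` the phrase `[a, a]` matches once. The policy is named in
  `ScoringConfig` so alternatives would be explicit, recorded choices.
* **Ranking direction.** Higher TS ⇒ smaller rank number ⇒ screened
  earlier. Ties in TS break by record id, for reproducibility. Hard-excluded
  records are appended after all included records in stable input order,
  whatever their scores.
* **Exclusion rules** (applied before scoring): no DOI, no abstract,
  abstract under 200 *characters* (of the whitespace-trimmed raw abstract —
  not a token count), or an ineligible article type. The default ineligible
  set {review, editorial, erratum, letter} is a configurable convention; an
  all-whitespace abstract counts as absent.
* **Quartile boundary.** The top quartile is ranks 1..⌈n/4⌉.
* **Spearman's ρ** uses average ranks for ties (delegated to
  `scipy.stats.spearmanr`; the test suite cross-checks tie handling against
  a brute-force average-rank + Pearson implementation). ρ is undefined for
  n < 3 or constant input and raises rather than returning NaN.
* **Workload estimator** uses the ceiling of `n / daily_rate`: 60,000
  records at 470 per day is ⌈127.66⌉ = 128 whole reviewer-days.
* **Seed/test splits** are simple random with seed size
  round-half-up(fraction·n), reproducible under an explicit RNG seed.

### A boundary property of greedy matching

TS is exactly invariant under self-concatenation of a document's token list
*provided no keyword occurrence spans the junction between the two copies*
(then every match count and the word count double, so every `m` is
unchanged). A phrase can, however, straddle the junction — doc `[b, a]`
contains no `[a, b]`, while `[b, a, b, a]` contains one — in which case
counts need not exactly double. This is inherent to any contiguous
match-counting, not an artefact of the greedy policy. The property tests
therefore fuzz documents whose final token is not keyword material
(junction-clean by construction), which isolates the length-normalisation
invariance, and a dedicated unit test pins the junction counterexample.

## Screening simulation

The simulator emulates how semi-automated screening tools are driven,
without depending on any external tool:

* **rank-once**: a stratified seed sample (n relevant, n irrelevant, drawn
  reproducibly by seed) trains the ranker once; all unscreened records are
  ranked a single time.
* **active learning**: from a minimal seed, the top-ranked record's gold
  label is revealed (the gold label plays the reviewer, standard practice in
  screening simulations), the ranker refits, and the loop continues for a
  fixed budget or until k consecutive irrelevant decisions (the stopping
  rule, off by default).

The ranker is a deliberately transparent **nearest-centroid bag-of-words**
model: documents are term-count vectors; a candidate scores cosine
similarity to the relevant centroid minus cosine similarity to the
irrelevant centroid. It is deterministic given the screened sets, cheap
enough to refit every step, and sits behind a small interface so an adapter
to a real tool could replace it. It is *not* a re-implementation of any
particular tool's learner, so simulation results characterise the workflow,
not any specific product.

**Recall at 25% effort** for configuration comparisons is computed on the
ranking of the *unscreened* records each configuration produces (effort =
fraction of the unscreened pool screened in ranked order). Configurations
differ in seed size, so this measures what the remaining screening effort
buys after each configuration's seed investment.

## Synthetic corpora

Real screening corpora cannot ship with the package; the generator builds
token-level stand-ins carrying exactly the structure the method consumes:

* class label Bernoulli(prevalence), default 8% eligible — a minority class,
  as in real broad-topic reviews;
* background tokens uniform over a synthetic vocabulary (`w00042`-style
  words, default 2,000 types); titles 5–15 tokens;
* abstract lengths negative-binomial (gamma–Poisson, default mean 120
  tokens, dispersion 8), giving realistic variance including a small tail
  under the 200-character exclusion threshold;
* planted phrases inserted at a random position with class-conditional
  Bernoulli rates — the separation between eligible and ineligible rates is
  what makes keywords informative;
* independent missingness: absent DOI, absent abstract, truncated abstract.

Every corpus embeds a manifest (parameters + seed) sufficient to regenerate
it bit-identically.

The fixed **benchmark corpus** uses n = 5,000, prevalence 0.08, 12 positive
and 12 negative planted phrases (a mixture of 1- and 2-word phrases) with
eligible-class positive rates 5–10× the ineligible rates (mirrored for
negatives), missingness rates 0.02/0.02/0.01 (≈5% of records flagged by the
default exclusion rules), and seed 13, paired with a reference registry
whose weights span 1–10. The 5,000-record size keeps every experiment
single-CPU friendly while leaving ~400 eligible records, enough for stable
recall and quartile statistics; replicate draws reuse the structure under
child seeds.

What the generator does **not** emulate: natural language (synonymy,
polysemy, phrasal variation), correlated keyword co-occurrence, topic
drift, duplicate records across databases, or citation structure. Passing
benchmarks therefore demonstrate that the pipeline's mechanics behave as
designed under the assumed keyword-separation structure — not that any
particular keyword list would achieve these numbers on a real corpus, where
keyword quality is the binding constraint.

## Numerical and degenerate-input choices

* Scores are IEEE doubles; the per-record `TermScore` keeps its per-keyword
  components so TS can be re-derived and audited exactly.
* A tokenless record (empty title, no abstract) has an undefined score and
  raises; such records should be flagged by the exclusion rules upstream.
* `flag_exclusions` is total and idempotent; relaxing the exclusion
  configuration can only un-exclude records (monotonicity, property-tested).
* Empty registry ⇒ TS = 0 for every record; title screening retains all.
* Active-learning top-pick ties break by record id (via the score/id sort),
  making trajectories bit-reproducible under a fixed seed.

## Experiment sizes

The replicated configuration comparison uses 20 replicate corpus draws of
the 5,000-record benchmark; each replicate shares one document vectorisation
across the four configurations. Monte Carlo null checks (random rankings ≈
0.25 top-quartile fraction, ≈ 0.5 recall at half effort) use 500
permutations at n = 100–200. The rate-convergence check for the generator
runs one 50,000-record corpus against a 3-standard-error band.

## Known limitations

* Keyword lists and weights are domain-specific and expert-supplied; the
  package gives one expert's weighting an explicit, auditable form but does
  not reconcile multiple experts or suggest keywords.
* The 1.2 penalty is surfaced as configuration for sensitivity analysis but
  defaults to the reference value; nothing here tunes it.
* The reference ranker is a stand-in with the right qualitative behaviour;
  absolute simulated recall numbers should not be read as predictions for
  any specific screening tool.
* Evaluation covers title/abstract triage only; full-text screening and
  deduplication are out of scope.
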