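# Methods

## The question the package operationalizes

When two syntactically related words are non-adjacent, what exactly is
costly about the material between them?  The classic *dependency length
minimization* (DLM) account counts intervening **words**: the dependency
length (DL) of an edge head→dependent is the number of words strictly
between the two.  The *intervener complexity minimization* (ICM) account
counts intervening **heads**: the intervener complexity (IC) of an edge is
the number of intervening words that themselves govern at least one
dependent, anywhere in the sentence.  Terminal dependents (leaves) between
the two words do not add to IC, so `0 ≤ IC ≤ DL` for every edge.  The same
DL can therefore hide very different structures: four intervening leaves
(IC 0) versus a four-word chain of heads (IC 3).

The package asks, corpus-level, whether each quantity grows more slowly
with sentence length in real trees than in random baseline trees matched on
nuisance statistics — and crucially whether each minimization survives when
the *other* quantity's distribution is clamped to the real tree's.

## Complexity metrics

Trees are single-rooted dependency trees over linearly ordered words
(CoNLL-U; the artificial root is position 0 and is not a word; the root
attachment edge is excluded from all DL/IC aggregates).

* `DL(h,d) = |h − d| − 1` (intervening-word count, not the positional
  difference convention; the two differ by 1).
* `IC(h,d)` = number of positions strictly between `h` and `d` whose word
  has ≥ 1 dependent.  Head status is **global**: a word whose only
  dependent lies outside the span still counts.  This makes IC a
  leaf/non-leaf distinction, which is the natural reading of "intervening
  heads vs. terminal dependents".
* Crossings: the default count is edge-level — edge `h→d` is non-projective
  iff some intervening word is not reflexively-transitively dominated by
  `h`.  A pairwise count (strictly interleaving spans) is also provided; in
  the pairwise view the root attachment participates as an edge from
  position 0, which is what makes "zero crossings" coincide exactly between
  the two formalizations (an edge covering the root word is non-projective
  in the dominance view even though no two word–word spans interleave).
* Arity = number of dependents of a node; per-tree summaries report both
  the max and the mean, since different analyses care about different
  aggregates.  Depth counts words along the longest root-to-leaf path
  (root word = 1).

## Random baselines

Six families, each generated per reference tree by uniform proposal plus
rejection, and all matched on sentence length and crossing count:

| kind | proposal | extra constraint | topology preserved |
|---|---|---|---|
| random_structures | uniform rooted tree | — | no |
| rla | uniform word-order permutation | — | yes |
| dl_matched_random_structures | uniform rooted tree | DL multiset | no |
| dl_matched_rla | uniform permutation | DL multiset | yes |
| ic_matched_random_structures | uniform rooted tree | IC multiset | no |
| ic_matched_rla | uniform permutation | IC multiset | yes |

Uniform rooted trees are drawn by decoding a uniform Prüfer sequence and
choosing the root uniformly, giving equal mass to each of the `n^(n−1)`
rooted labeled trees; tree labels *are* linear positions.  RLAs permute the
word order while keeping the dependency relation on word identities, so
shape, arity multiset and depth carry over by construction.

Because accepted draws are untouched proposals, the sampler is exactly
uniform over the constraint-satisfying set — the test suite verifies this
against full enumeration at n = 5.

Design choices worth knowing:

* **Multiset matching.** "Matching the sequence of dependency lengths" is
  implemented as multiset equality of per-edge values.  Random-structure
  candidates have no edge-to-edge correspondence with the reference, so an
  ordered reading is ill-defined there; the multiset reading is applied to
  both families for consistency.
* **Budgets and pairing.** Default budget is 100,000 attempts per tree.
  When a budget is exhausted the *pair* is dropped — the real tree is also
  excluded from that comparison — keeping the design matched.  Budgets,
  failures and per-length acceptance rates are reported.
* **Determinism.** Per-tree RNG streams derive from (spec seed, corpus
  index), so corpora regenerate byte-identically regardless of execution
  order.
* **Cost.** Rejection against projectivity is the expensive case: a uniform
  rooted tree on 11 nodes is projective with probability ≈ 1.5 × 10⁻⁴, and
  an RLA of an 11-word tree lands on a crossing-matched order at a rate set
  by the shape's linearization count over 11!.  This is why the analysis is
  confined to short sentences (≤ 11 words by default).

## Statistical model

Per sentence i of language j, with S the sentence length, R ∈ {0, 1} the
real-vs-baseline indicator and y the per-sentence mean IC or mean DL:

    y_ij = (β0 + u0j) + (β1 + u1j) S_ij + (β2 + u2j) R_ij
           + (β3 + u3j) S_ij·R_ij + ε_ij

β3 < 0 means the response grows more slowly with length in real trees than
in the baseline.  Verdicts are driven by β3 (|t| > 2), with the main effect
β2 reported alongside because the two can disagree and mean different
things (an aggregate offset vs. a growth-rate difference).

Estimation: REML via statsmodels MixedLM.  S enters raw (uncentered) by
default; a centering flag exists.  Random effects default to uncorrelated
(diagonal) intercept + S, R, S·R slopes per language; the fully correlated
structure is available behind a flag.  On non-convergence the structure is
reduced along a fixed ladder (drop the S·R slope, then R, then S, then
intercept-only, finally pooled OLS), and the structure that converged is
recorded on the fit.  Numerically, L-BFGS is tried first and Powell second:
the former is fast but reports failure when a variance component sits on
the zero boundary, where Powell converges cleanly.  Per-language analyses
drop the random effects and fit OLS per language.  t-values are
estimate/SE with a conventional |t| > 2 star; no degrees-of-freedom
approximation is attempted.

## Synthetic treebanks

No external treebank is needed to exercise the pipeline.  The generator
emulates the short-sentence slice of a natural corpus:

* sentence lengths 3–11, geometrically short-skewed (decay 0.82 per added
  word — 3-word sentences ≈ 5× as frequent as 11-word ones);
* tree shapes grown by iterated dependent attachment with a
  truncated-geometric arity distribution (default mean ≈ 1, max 5),
  matching the observation that heads rarely take many arguments.  The
  growth rule truncates the final draw to land on exactly n nodes, and if
  the frontier dies out early it re-enters a random existing node with a
  forced minimum of one dependent;
* a word order policy: `uniform_random` (uniform over recursive
  head+child-block arrangements — projective, no ordering pressure),
  `dlm_greedy` (dependents alternately left/right of the head in
  increasing subtree-size order — the classic DL-minimizing heuristic), or
  `icm_biased` (leaf dependents hug the head, head-bearing subtrees pushed
  outward — low IC by construction);
* occasional non-projectivity: with probability `crossing_rate` (default
  0.05) a tree receives one adjacent transposition that creates ≥ 1
  crossing.  Some orders (a perfectly linearized chain) admit no such
  swap; proposals are capped at n² and the tree then stays projective, so
  `crossing_rate` is a target rate, not an exact one.

What this deliberately does **not** emulate: lexical content, morphology,
dependency relation labels, head-direction typology, or any correlation
between arity and word identity.  Passing tests on synthetic corpora
therefore demonstrate that the *pipeline* detects ordering pressures of
known direction and calibrates correctly under a null — not that any
natural language behaves one way or the other.

### Controls of known direction

A `dlm_greedy` corpus compared against its `random_structures` baseline
must yield β3 < 0 with |t| > 2 for both responses (the planted signal).
The null control compares a `uniform_random` corpus against its **RLA**
baseline: a uniformly ordered tree and a crossing-matched uniform
re-ordering of the same tree are exchangeable by construction, so β3 has
no signal to find.  (Random structures would *not* be a null here: the
generator's arity model differs from the uniform-tree distribution, and
that shape difference alone moves IC/DL growth.)

## Problem sizes used in the checks

Uniformity checks: all 16 Prüfer sequences at n = 4; 64,000 rooted-tree
draws over the 64 rooted labeled trees; 24,000 RLAs over the 24 orders of a
4-word chain; 50,000 accepted crossing-matched RLAs at n = 5 against full
enumeration (χ², α = 0.001).  Constraint fidelity: 500 synthetic trees for
the unconstrained families; the multiset-matched families are checked on
the ≤ 7-word slice (60 trees), where rejection is cheap and successes are
plentiful.  Parameter recovery: one headline fit at 40 languages × 200
sentences, then 200 replications at 10 × 30 for the recovery average,
interval coverage, and the null false-positive rate.  End-to-end controls:
4 languages × 120 sentences.

## Known limitations

* Rejection sampling is the only generation mechanism (by design); the
  multiset-matched families become impractical for long sentences.
  Budget-exhausted pairs are excluded, which at small budgets biases the
  surviving sample toward easily-matched (shorter, flatter) trees — the
  report makes this visible per length.
* MixedLM t-values carry no df correction; with few languages the |t| > 2
  rule is only approximate (the suite's null calibration stays within
  Monte-Carlo range of 5% at 10 languages).
* `exclude_punct` drops trees in which punctuation heads a real word
  rather than re-attaching grandchildren, which can discard a small number
  of sentences in annotation styles that allow such heads.
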