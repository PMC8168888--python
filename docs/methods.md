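# Methods

## The measurement model

Let each vocabulary word carry a vector *w* ∈ ℝᵈ from a pre-trained embedding
table (the intended production input is the GloVe 6B release: 400,000 uncased
words, *d* = 300, file-ordered by descending corpus frequency). A *concept*
is defined by a word list *L* (a LIWC-style category such as the masculine
and feminine pronoun lists, or the positive/negative-emotion lists) resolved
against the vocabulary, and represented by the arithmetic mean of the raw
vectors of its resolved words:

    μ = (1 / |L|) Σᵢ wordᵢ

Words are scored against a concept by cosine similarity, ⟨ŵ, μ̂⟩ ∈ [−1, 1].
Averaging happens on raw vectors and normalisation afterwards
(average-then-normalise); the order matters because frequent function words
have larger norms, and the mean of raw vectors is what defines the concept
direction here.

Two opposed concepts form a *bias axis*; a word's bias on the axis is the
difference of its two cosines, F(w, μ₁, μ₂) = ⟨ŵ, μ̂₁⟩ − ⟨ŵ, μ̂₂⟩ ∈ [−2, 2]:

* gender = male − female, positive ⇒ masculine;
* valence = posemo − negemo, positive ⇒ positive.

Raw similarity and bias values are small and unit-free, so they are
interpreted *normatively*: every score is ranked within the distribution of
the same score over the k most frequent words (default k = 100,000; file
order proxies frequency rank, since the format carries no frequency column).
The percentile rank of x is the percentage of the population *strictly*
below x — no interpolation, no midranking of ties, which are measure-zero in
a large continuous population. A score is called extreme when its percentile
is strictly below 5 or strictly above 95 (both thresholds configurable); a
percentile of exactly 5 or 95 is not extreme.

Similarity to a single pole and bias on an axis are deliberately distinct
readouts: pole similarities are positively correlated across the population
(both pronoun lists share "person-ness"), so a word can be extreme toward
*both* poles while its bias is unremarkable.

## Lexicon semantics

Lexicon files are plain text, one pattern per line, `#` comments, with an
optional single trailing `*` stem wildcard. Two resolution modes exist:

* `expand` (default): a wildcard contributes every vocabulary word with the
  stem as a prefix — faithful to how LIWC categories are applied to text;
* `literal`: a wildcard contributes only its bare stem — provided for
  sensitivity analysis.

The divisor |L| in the mean is the count of *resolved* vocabulary words, not
of raw patterns: out-of-vocabulary patterns are skipped with a warning (an
entirely unresolved lexicon is an error, since the concept mean would be
undefined). Queries and vocabulary are lowercased by default, matching the
uncased GloVe 6B release; `--no-case-fold` disables this. The proprietary
LIWC 2015 categories are not shipped; small openly authored stand-in lists
are bundled, and a licensee can drop in the real category files unchanged.

## The synthetic generator

The generator builds embedding spaces in which the quantities the analysis
estimates exist by construction, so recovery is measurable. Five orthonormal
directions are drawn (seeded) in ℝᵈ:

| direction | role | loading |
|---|---|---|
| u | common mean direction shared by all words | `common_loading` = 3 |
| g | latent gender axis | per-word |
| v | latent valence axis | per-word |
| p_g | shared by *both* gender pole lexicons ("person-ness") | `pole_shared_loading` = 1.5 on pole words; N(0, 0.45²) background |
| p_v | shared by both valence pole lexicons ("affect-ness") | same scheme |

Each word vector is the loading-weighted sum of these directions plus
isotropic Gaussian noise ε with per-coordinate sd `noise_sd`/√d, i.e.
E‖ε‖ ≈ `noise_sd`, putting the noise norm on the same scale as loadings of
order one. Pole words carry ±`pole_loading` (default 1) on their own axis;
background words draw axis loadings from N(0, `background_loading_sd`² =
0.3²); targets use configured loadings in [−1, 1] and no shared loading.

The common and pole-shared components cancel exactly in every bias
difference, which yields three properties the analysis relies on:

1. at `noise_sd` = 0 the recovered bias ordering over targets equals the
   planted loading ordering exactly, per axis (without the dominant common
   component, cosine's norm denominator would reorder targets whose other-axis
   loadings differ);
2. pole similarities are positively correlated across the population, and
   background words rich in a pole-shared direction are extreme toward both
   poles without an extreme bias — the pattern real corpora show for
   frequent concrete words;
3. with the default noise (0.5), Spearman correlation between planted
   loadings and recovered biases stays ≥ 0.95 per axis over 30 targets.

Default study conditions: d = 50, 2,000 background words, four 20-word pole
lexicons, 30 recovery targets with loadings evenly spaced in [−1, 1]
(valence order decoupled from gender by a seeded shuffle), seed 42. The
demonstration study swaps in the 11 basic colour terms and 4 anchor words
with planted loadings (one colour strongly feminine at −0.9, a block of
clearly positive colours at +0.75…0.85, anchors at ±1).

What the generator does *not* emulate: Zipfian frequency structure,
embedding anisotropy beyond a single mean direction, polysemy, and the
correlation structure of real LIWC categories. Passing recovery tests
therefore shows the estimator is sound under its own assumptions — cosine
geometry separating pole lexicons — not that any particular real corpus is
unbiased or biased.

## Numerical and design choices

* Cosine values may exceed [−1, 1] by ≤ 1e−12 through rounding; raw values
  are kept internally, and each reported bias equals the difference of its
  pole similarities bit-for-bit.
* Concept vectors are computed once per run; scoring the normative
  population is one matrix–vector pass per concept.
* Embedding files are written with 8 significant digits: one round trip is
  exact to well under 1e−6 and a second is byte-identical. Malformed lines
  abort with the line number rather than being skipped, so a damaged file
  cannot silently shift the frequency ranking.
* The scored target is not excluded from the normative population when it
  ranks inside the top k; with k = 100,000 a single membership shifts a
  percentile by at most 0.001.
* Reports print similarities and biases to 4 decimals and percentiles to 2,
  the precision of the published reference table; the JSON report keeps full
  precision and reproduces the TSV exactly on re-rendering.
* The published reference table bundled in `colorbias.reference` contains
  one internal inconsistency: the white/valence bias is printed as 0.1130
  while its printed pole similarities differ by 0.1113. That row is excluded
  from exact arithmetic checks. Because the printed percentile columns are
  rounded to 2 decimals, count checks over them use an inclusive ≥ 95
  boundary (brown's valence-bias percentile prints as exactly 95.00 yet is
  flagged extreme in the source); the runtime classifier itself is strictly
  `>`.

## Problem sizes

The test suite and the acceptance script run everything on the synthetic
fixtures above (≈ 2,100-word vocabularies at d = 50, plus one d = 300 run at
the production interface); the whole suite completes in well under a minute
on one CPU. The pipeline itself streams the 400,000 × 300 production table
comfortably: the full-scale run needs only the GloVe 6B download and LIWC
category files, via `colorbias analyze`.

## Known limitations

* Frequency rank is file order; for embedding files that are not
  frequency-sorted the normative population is simply "the first k records".
* Only trailing-asterisk wildcards are supported (the LIWC convention);
  general globbing is out of scope.
* Percentile reproduction against the published table is qualitative
  (extreme / not extreme): digit-level percentiles depend on the exact
  embedding release and licensed category files.
* The bias score is the plain cosine difference; permutation-test effect
  sizes (WEAT-style) are deliberately not implemented.
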