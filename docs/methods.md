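# Methods

## Problem and scope

The package models a binary judgment — is a single German word beautiful
or ugly? — as a function of eight features computable from a frequency
corpus and a lexical-semantic taxonomy, without any human rating norms
among the predictors. Three stages: feature extraction, an
extremely-randomized-trees (ERT) classification study with its evaluation
battery, and per-feature statistical follow-ups. A synthetic-study
generator supplies all inputs, so the pipeline is exercised end to end
without the license-restricted originals.

## Features

**Syllables.** Counted as vowel groups, with the German
diphthongs/digraphs *ei, ai, au, eu, äu, ie* merged greedily from the
left inside a vowel run (so *aue* → au‑e → 2 nuclei). This is a
transparent rule-based default; a hyphenation-dictionary backend can be
passed as a callable where finer syllabification matters. Known
limitation: morpheme boundaries are ignored (*beachten* would merge
*ea*… only if adjacent — it is not — but compounds like *Seeufer* with
three adjacent vowels are split greedily, not morphologically).

**Sonority.** Each letter is assigned a class (plosive 1, fricative 2,
nasal 3, liquid 4, glide 4.5, vowel 5) by a fixed German grapheme table;
the word score is the mean rank. Grapheme-level scoring is a deliberate
simplification — no grapheme-to-phoneme conversion — chosen because it
is deterministic, testable, and yields word means in the empirically
reported ~3 range. The scale and the letter table are both replaceable.

**Surprisal.** −log₂ of *relative* frequency (count / total tokens).
Using relative rather than raw frequency makes the value invariant to
corpus size; a word carrying probability 1 has 0 bits.

**Orthographic neighborhood (Coltheart's N).** Same-length lexicon
entries at Hamming distance exactly 1 (substitutions only; no
insertions/deletions), the word itself excluded.

**Relatedness, similarity, valence, aesthetic potential.** Relatedness
between two lemmas is 1 − d/(2·D) (clipped at 0), where d is the
shortest undirected path between their closest attachment nodes in the
is-a taxonomy and D is the taxonomy depth — a linearized
Leacock–Chodorow measure; 1/(1+d) is available as an alternative. Word
similarity is the mean relatedness of a word to all *other* targets,
deliberately label-blind so it can serve as a classifier input; the
within-group similarity question is answered post hoc by the ANOVA
module. Valence and aesthetic potential are signed contrasts — mean
relatedness to a positive label list minus mean relatedness to a
negative one — with 18+18 labels for valence and 62+62 for the
aesthetic potential. The shipped German label lists are editable
configuration anchored around words like *Anmut* and *Freude*; they are
plausible defaults, not a validated norm set.

## Classification study

The ERT ensemble (scikit-learn `ExtraTreesClassifier`, no bootstrap)
uses random split thresholds and per-split feature subsets. Two named
parameter sets are provided: `set1` = 100 trees with √8 ≈ 3 features per
split, `set2` = 1000 trees with all 8; both unbounded depth. Trees are
scale-invariant, so classification runs on raw features; the z-scored
view (column mean 0, sample SD 1, denominator n−1) is reserved for the
statistics.

Evaluation:

- **Train-on-all confusion matrix.** With unbounded depth and distinct
  feature rows this is exactly diagonal — a consistency check on the
  plumbing, not a performance estimate.
- **Stratified k-fold ROC/AUC**, default k = 5; folds preserve the
  75/55 class ratio within one item. Scores are the fraction of trees
  voting "beautiful"; ROC by threshold sweep with trapezoidal AUC,
  which equals the Mann-Whitney concordant-pair statistic (verified
  against a hand-written oracle in the tests).
- **Permutation null.** Labels are randomly permuted (identity
  permutations redrawn) and the CV repeated; default 5 runs. The
  per-run mean AUC is expected at 0.5. On the default 130-word study
  the 5-run average has a seed-to-seed SD of about 0.03 — chance-level
  checks at this n are noisy by nature, which is why the acceptance
  band is [0.45, 0.55] rather than a point.
- **Importances.** Mean impurity decrease, normalized to sum 1,
  reported as a descriptive ranking only.

One master seed fans out via `numpy.random.SeedSequence` to fold
assignment, tree construction and permutation draws; every stage is
bit-reproducible given the seed, and all reports embed the full
parameterization.

## Statistics

One-way ANOVA by direct sums-of-squares decomposition, p from the F
distribution; for two groups F = t² (pooled t), which the tests verify
on random fixtures. Effect sizes R² = SSB/SST and
R²adj = 1 − (1−R²)(n−1)/(n−k). A useful algebraic anchor: on a pooled
z-scored variable with groups 75/55 and beautiful-group mean 0.25, the
zero-mean constraint forces the ugly-group mean to −0.25·75/55 ≈ −0.341
and the unit variance forces SSW, giving F(1,128) ≈ 12.0 and
R²adj ≈ 0.08 with no free quantities. Group differences tested by
"linear regression on a binary predictor" are the same computation and
share this code path. No multiple-testing correction is applied across
the eight features; every report flags the p-values as raw.

## Synthetic study generator

The generator's defaults are the study conditions: 75 beautiful and 55
ugly target words inside a 1000-word lexicon, mean length 12 letters
(SD 3), group sonority means 3.12 / 2.9, aesthetic-potential z-mean
separation 0.58 (z-means 0.25 / −0.33), Zipf exponent 1.0, taxonomy
depth 6.

**Word forms** are consonant/vowel cluster strings. The vowel share is
fixed at 0.37 for *both* groups; each group's consonant-class mixture is
solved analytically from its target mean sonority (word mean =
5p + c̄(1−p)), so a sonority contrast never leaks into the vowel-driven
syllable count. The per-word vowel count is deterministic given a
jittered per-word vowel share (SD 0.10); the jitter is what keeps the
length–syllable squared correlation at a corpus-like ~0.5 instead of
~1. Letters are interleaved following the sonority sequencing principle
(onsets rise toward the nucleus, the final coda falls). About 30% of
distractor words are single-letter substitutions of dataset words so
the neighborhood feature has non-degenerate variance.

**Frequencies** follow a deterministic Zipf law (rank r gets
⌊10⁶/rᶳ⌉ tokens, minimum 1) with ranks assigned to words at random,
independent of the grouping.

**Taxonomy.** A rooted tree with four affective hub subtrees (positive/
negative aesthetic, positive/negative valence — separate hubs keep
valence and AP uncorrelated) plus a neutral region. Label lemmas attach
inside their hub subtree. Each dataset word attaches inside its own
group's aesthetic hub with probability 1−q and uniformly anywhere with
probability q. The noise q is the single effect dial: q = 0 separates
the groups perfectly, q = 1 is the no-signal control (chosen exactly,
not approximated, when the configured effect is 0). Otherwise q is
calibrated by bisection against the *measured* z-scored AP separation,
using common pre-drawn attachment randomness so the measured separation
is monotone in q.

**Ground truth** records the configured targets (AP z-separation,
sonority means, zero length effect) plus the calibrated q, enabling
parameter-recovery tests: over 20 seeds the full
generate → featurize → summarize pipeline recovers the injected AP
separation within ±0.15 z-units and the sonority means within ±0.1.

**What the generator does not emulate.** Real German morphology and
orthotactics; frequency–length and frequency–neighborhood correlations
(frequency is independent of everything by construction); polysemy
(one attachment node per generated word); rating noise in the labels.
Passing tests therefore demonstrate that the pipeline measures what was
injected under clean conditions — not that the features capture real
aesthetic judgments, for which the original resources would be needed.
The published real-data results (cross-validated AUC 0.94–1.0, the
importance ranking led by length and aesthetic potential) depend on
those resources and serve here as documentation anchors only; the
default synthetic study injects just the two documented small effects,
so its CV AUC of ~0.6–0.7 is the expected outcome, not a defect.

## Numerical choices and degenerate inputs

- z-scoring uses sample SD (ddof = 1) and rejects constant columns by
  name; ANOVA rejects zero within-group variance rather than returning
  an infinite F.
- ROC tie handling: trapezoidal interpolation (equivalent to the 0.5
  credit per tied pair of the Mann-Whitney count).
- Bisection runs 20 iterations on q ∈ [0, 1]; if even q = 0 cannot
  reach the requested separation the generator returns the q = 0
  taxonomy (maximal achievable effect) rather than failing.
- Problem sizes throughout (130-word default study, 1000-word lexicon,
  20-seed recovery averages, 5 permutation runs) are the study's own
  defaults and keep any single check in the seconds-to-a-minute range.
- Stratified CV requires k ≤ the minority class count; k = 5 against
  55 ugly words leaves ~11 per fold.

## Known limitations

- Grapheme-level sonority and rule-based syllables approximate
  phonology; both are pluggable.
- The relatedness measure ignores edge direction and node specificity
  (no information-content weighting); alternative measures can be added
  behind the same interface.
- The label lists are illustrative configuration; substantive use on
  real data should substitute curated lists.
- Hamming-distance neighborhoods exclude insertion/deletion neighbors.
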