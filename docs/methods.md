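# Methods

This note documents the models, parameters and design choices behind
`speechlex`, in the order the pipeline runs them.

## Transcript dialect and parsing

Transcripts are UTF-8 text with header lines (`#id`, `#group`, `#picture`,
`#duration_s`) and a body in a small markup dialect: excluded ("false
speech") spans are `{code words…}` with codes `fs` (false start), `gram`
(grammatical error), `fill` (filler), `pause`, `rep` (repetition), `unint`
(unintelligible), `neo` (neologism); `//` is a clause boundary and `%` a
prosodic break. Exclusion spans and both segmentation marks split the
retained words into *runs*; n-grams are counted within runs only, so no
bigram or trigram bridges removed material — counting across a removed
disfluency would manufacture word combinations the speaker never produced.

Tokens are lower-cased and stripped of edge punctuation; internal
apostrophes and hyphens are kept, so contractions and hyphenated compounds
are single tokens. Parsing is deterministic and idempotent
(`parse(serialize(parse(x))) == parse(x)`), and malformed markup (unbalanced
or nested braces, unknown codes) raises an error naming the byte offset.

Transcriber agreement divides the number of matching words by the total
words of the designated reference transcript. "Matching" is operationalized
as a longest-common-subsequence positional alignment: it tolerates
insertions/deletions between the two versions while never matching words out
of order. The measure is deliberately asymmetric (the denominator is the
reference), and can be restricted to a word list (e.g. checklist targets).

`duration_s` is taken as given metadata (speaking time including pauses);
the package computes no acoustic measures.

## Fluency measures

Thirteen measures per participant × picture: word/bigram/trigram token and
type counts, the three TTRs, total time (s), words per minute, the ratio of
function to content tokens, and the combination ratio (trigram tokens / word
tokens, in [0, 1], an index of connected multi-word output). Word token
counts include function words; the function/content proportion captures
their balance separately. The bundled closed-class list (~170 entries:
articles, demonstratives, prepositions, pronouns, auxiliaries, conjunctions,
particles, common contractions) can be overridden wherever a function list
is accepted. Undefined ratios (TTR of an empty transcript, function/content
with zero content tokens) are flagged as missing, not silently zeroed.

## Norms lexicon

Eight properties per word: length (letters), log frequency, semantic
diversity, semantic neighbourhood density, concreteness, age of acquisition
(years), OLD20 and PLD20. Ratings are inputs (CSV schema
`word,length,…,pld`; empty cell = missing); the package never derives them
from corpora. Familiarity and imageability are excluded from the pipeline.
Lookup prefers an exact entry and falls back to the singular form for
plural suffixes (-s, -es, -ies→-y), flagged as a fallback. Annotation is
token-level — a participant's property averages weight words by how often
they were used. Tokens without norms are dropped listwise and accounted for
in a coverage report (dropped + annotated + function = total).

## PCA stage

Both PCAs are correlation-matrix PCAs (features z-scored) because the
inputs mix scales (counts, ratios, seconds). Rows are participant × picture
observations for the fluency PCA and unique corpus words for the word PCA;
per-participant word scores are the token-weighted mean of their words'
scores, per picture.

*Component selection.* The scree elbow is operationalized as the index of
the maximum second difference (acceleration) of the descending eigenvalue
curve. Because elbow criteria are inherently visual, the pipeline defaults
to an explicit override of k = 3 (`n_components: 3` in the run config) while
logging the elbow choice; passing `n_components: null` uses the pure elbow.
A flat spectrum raises an explicit ambiguity error rather than guessing.

*Rotation.* Varimax with Kaiser row normalization, computed by classic
pairwise Jacobi sweeps (closed-form planar angle per column pair;
convergence when the largest angle in a sweep is below 1e-8; at most 1000
sweeps). Scores are the standardized data projected on the rotated
orthonormal eigenvector basis, so scores have exactly zero column means on
the fitted data and total variance explained is invariant under rotation.
Each rotated component is sign-normalized (largest-|loading| feature loads
positively) and components are ordered by explained variance, making refits
bit-reproducible. Component labels ("speech quanta", "semantic richness",
…) are attached metadata, never inferred from loadings.

*Sampling adequacy.* KMO = Σr²/(Σr² + Σpartial-r²) over off-diagonal
entries, with partial correlations from the inverse correlation matrix.
Degenerate inputs (singular or identity correlation) raise; the pipeline
stage reports KMO as unavailable in that case instead of aborting, since it
is diagnostic rather than load-bearing.

*Group tests.* One-way ANOVA with Tukey HSD on fluency PC scores; two-way
(group × picture) ANOVA on averaged word PC scores. Both delegate to
statsmodels OLS/anova_lm. The ANOVA is standard fixed-effects; no attempt
is made to reproduce any particular historical degrees-of-freedom
bookkeeping.

## Distribution analysis

The "quartiles" are fixed score ranges with edges −4, −2, 0, 2, 4 — not
data quantiles. The lowest bin is closed on both sides, the rest
right-closed; scores outside ±4 are clipped into the end bins and logged
(they are rare because word scores on the rotated basis have SD ≈ 1.6).
Bivariate 4×4 proportion maps are computed per participant and averaged
unweighted within groups; difference maps subtract the control mean map.
Cellwise tests are Welch (unequal-variance) two-tailed t-tests on
participant-level proportions, reported uncorrected — they annotate the
maps descriptively, and the serialized report carries a multiplicity note.
The inferential test is the group × quartile mixed ANOVA
(pingouin.mixed_anova; quartile within-subject, group between-subject) with
Tukey HSD on the quartile factor. A fully degenerate count table (every
participant identical) short-circuits to F = 0, p = 1. Any contour plots
are a visualization layer only; statistics are always computed on the 4×4
grid.

## Checklist derivation and validation

*Equivalence classes.* A target word plus explicit dialect variants; a
token scores 1 if it is a listed variant or if its inflectional root
matches the target's (suffixes -s/-es/-ies/-ing/-ed/-en stripped with
consonant-doubling undo and silent-e tolerance, so digging→dig and
overflowing→overflow). Explicit variant lists take precedence over
stemming. For the screening step, every unique content word becomes its
own class, with observed inflections folded onto the most frequent form.

*Penalized regression.* L1 (LASSO) logistic regression on the binary
indicators. Binary predictors are *not* standardized — they share the 0/1
scale, which keeps |β| comparable across words for the ranking criterion;
appended cognitive columns are z-scored. The penalty path is glmnet-style:
λ_max = max_j |x_jᵀ(y − ȳ)|/n (the smallest λ with all coefficients zero)
down to λ_max/100 over 30 log-spaced values; the floor of 0.01·λ_max is the
usual convention when predictors outnumber observations, and deeper paths
only re-admit noise words. λ is chosen to minimize mean 4-fold
cross-validated binomial deviance, ties resolved toward the larger λ
(parsimony); the model is then refit on all rows. The solver is coordinate
descent (liblinear) with the intercept carried as a scaled pseudo-feature
(`intercept_scaling = 1e6`), so its residual penalty is O(λ/10⁶): at λ → ∞
all β are zero and the intercept equals logit of the base rate to ~1e-5,
and at λ → 0 on non-separable data the fit matches the unpenalized MLE to
~1e-7. Complete separation is handled by the penalty itself (finite β for
λ > 0). Constant columns are dropped and recorded; classes smaller than the
fold count reduce the folds with a warning.

*Selection, ranking, truncation.* LASSO screening runs over all 15
pairwise contrasts for 6 groups (5 control-vs-patient, 10
patient-vs-patient); contrasts where the penalty keeps no word are recorded
— empirically these are the within-cluster pairs, which is what motivates
the hierarchical classifier. Survivors are pooled, the regressions re-run
on the pooled columns, and words ordered lexicographically by (i) number of
pairwise models with a nonzero β, (ii) max |β| across contrasts (absolute
value: the sign only encodes contrast direction), (iii) maximum
between-group difference in production proportion, (iv) alphabetically, for
determinism. The top 15 form the checklist.

*Validation.* Hierarchical: stage 1 patients vs controls on everyone;
stage 2 motor (nfvPPA/PSP/CBS) vs lexico-semantic (svPPA/lvPPA) on
patients; stage 3 pairs within clusters, with PSP and CBS merged into one
class by default (small samples). K-fold validation is stratified 4-fold
with a fixed seed and decision threshold 0.5 on predicted probability
(class priors not adjusted). When the predictor matrix passed in is the
full unique-word indicator, word selection happens inside each training
fold (the LASSO is part of model fitting), so selection cannot leak into
held-out folds — the null-cohort control in the test suite verifies mean
accuracy ≈ 0.5 on identically generated groups. When it is a fixed
checklist, only coefficients are re-estimated per fold, mirroring how a
published scoresheet would be used; both usages are available because
either convention is defensible, and a strict `nested_kfold_validate` mode
re-runs the entire derivation (screening, pooling, ranking, truncation)
inside each training fold. Out-of-sample validation refits on the
full training cohort and predicts a participant-disjoint test cohort.
Supplementation appends z-scored ACE-R/MLSE sub-score columns (all-missing
or constant columns dropped, incomplete rows dropped listwise).

## Synthetic cohorts

The generator encodes the conditions the analysis is designed for, with
ground truth attached for recovery tests. Defaults (the study conditions):

- **Group sizes** 24 controls / 9 svPPA / 9 lvPPA / 9 nfvPPA / 10 PSP /
  13 CBS, both pictures per participant; vocabulary of 500 words (the
  pooled corpora reach ~500 unique words per picture).
- **Output volume**: content tokens ~ negative binomial per group
  (control mean 110, svPPA 105, lvPPA 92, nfvPPA 45, PSP 52, CBS 56;
  dispersion 8–14), overdispersion reflecting patient heterogeneity.
  Durations ~ Normal (65–80 s by group, truncated at 20 s): descriptions
  often run past the one-minute mark.
- **Lexical choice**: words sampled with probability ∝ softmax of weighted
  z-scored properties — svPPA tilts +1.0 log frequency, +0.8 semantic
  diversity, −0.6 length (lvPPA slightly weaker); nfvPPA −0.8 and CBS −0.7
  on age of acquisition, PSP −0.3. Controls are untilted.
- **Planted checklist words**: 20 scene words per picture with slot-wise
  production probabilities (e.g. 0.90 in controls vs 0.25 in patients for
  the control-discriminative slots; 0.80 lexico-semantic vs 0.15 motor for
  verb-like slots; svPPA dips to 0.15 on two low-frequency nouns),
  occasionally realized as plurals to exercise the equivalence machinery.
  nfvPPA/PSP/CBS share production probabilities, so those contrasts are
  word-null by construction — as observed clinically.
- **Norms lexicon**: an 8-dimensional Gaussian with a three-cluster
  correlation target — length/OLD/PLD pairwise r = 0.80;
  frequency/SemD/SND pairwise r = 0.77 with concreteness at −0.77; age of
  acquisition correlated ≤ 0.3 with either cluster; small cross-cluster
  terms. Realized correlations are within ±0.1 of target at n ≥ 500, the
  population scree elbow is 3, and the third component (age of acquisition)
  stands clear of the ≈0.2–0.3 noise floor, so elbow selection recovers
  k = 3 in essentially all lexica of 1000 words. Marginals are set to
  plausible rating scales (e.g. length ≈ 5.5 ± 1.8 letters, AoA ≈ 7.5 ± 2.2
  years), and synthetic word strings match their length property while
  avoiding inflection-like endings so the stemmer never merges them.
- **Phrase retracing**: with probability 0.05 per token the speaker repeats
  the last two or three words. Connected speech reuses word combinations;
  without this the bigram/trigram TTRs would be degenerate (constant 1)
  because independent word sampling almost never repeats an n-gram.
- **Disfluencies**: per-token injection rates by code (e.g. nfvPPA: 5%
  false starts, 4% grammatical errors, 6% fillers, 5% pauses, 4%
  repetitions; controls: 2% fillers) realized as markup spans.
- **Cognitive scores**: Gaussian sub-scores with group means placed so the
  word-null pairs become separable — svPPA low MLSE semantics, lvPPA low
  phonology/working memory, nfvPPA low motor speech and syntax, PSP/CBS
  moderate motor speech with distinct fluency/visuospatial profiles.

What the generator does **not** emulate: syntax or discourse coherence
(token order is exchangeable within clause chunks), acoustic properties,
realistic norms for specific English words (properties are draws from the
cluster model), item-level correlations between output volume and lexical
tilt, or longitudinal change. Passing recovery tests therefore shows the
*pipeline* is correct and unbiased under the assumed generative structure —
not that the clinical effect sizes are as planted.

## Problem sizes and numerical choices

Tests and the acceptance script use deliberately scaled problem sizes
chosen to exercise every code path at comfortable statistical power: the
full-cohort pipeline at the study Ns with a 500-word vocabulary; recovery
simulations with 3 groups × 25 participants and a 120-word vocabulary over
50 seeds; null-leakage controls at 2 × 20 participants over 100 seeds;
structure-recovery over 100 lexica of 1000 words. Varimax tolerance 1e-8;
lambda grids of 12–30 points (smaller grids in smoke tests); liblinear
tolerance 1e-10. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`, and a full `run-all` is byte-identical across
reruns with the same config and seed.

## Known limitations

- The stemmer is a small heuristic (suffix stripping + doubling/silent-e
  rules), adequate for checklist scoring where explicit variant lists
  dominate; it is not a general morphological analyzer.
- Cellwise difference-map p-values are uncorrected by design; treat them as
  map annotations, not inferences.
- The mixed ANOVA assumes sphericity as implemented in pingouin's
  univariate table; with four within-levels this is mild but real.
- KMO on the synthetic word lexicon is low (~0.5): tight planted clusters
  produce high partial correlations. This is a property of the synthetic
  correlation structure, not of the KMO implementation.
- `percent_agreement` matches exact token strings; near-miss spellings
  count as disagreements.
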