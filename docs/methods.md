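# Methods

This note documents the models and procedures `witsem` implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Semantic space

The space is classic count-based LSA. Word frequencies are token
occurrences summed over grams weighted by gram counts; the top-R words
index rows and the top-C columns of the co-occurrence matrix, with
lexicographic tie-breaks so vocabularies are deterministic. Tokens are
compared after Unicode NFC normalisation and (by default) lower-casing;
lower-casing is a corpus-level switch because published n-gram corpora
differ in case policy. Punctuation is stripped except intra-word
apostrophes/hyphens, and transcription pauses ("...", "…") are kept as a
filler token because the keyword analysis treats fillers as words.

**Co-occurrence convention.** "Co-occurs within a gram" is ambiguous. The
default counts *ordered pairs of distinct positions*: cell (r, c) sums
gram count × #{(i, j) : i ≠ j, token_i = r, token_j = c}. This makes
cell(a, b) = cell(b, a) for distinct words and gives a word repeated
within a gram a self co-occurrence. Unordered pairs and a maximum
positional distance are available as options (`pairs`, `max_distance`).

**SVD geometry.** Cells are transformed x ↦ ln(1 + x) and the matrix
decomposed as U S Vᵀ. Word vectors are rows of U_d S_d by default — the
classic LSA term geometry, where dot products approximate the
log-co-occurrence inner products — with U-only rows as an option. Each
singular vector's sign is fixed so its largest-magnitude component is
positive, making serialised spaces byte-stable; all downstream statistics
are invariant to these flips (asserted by test). Vectors are then
unit-normalised; rows that are all-zero before compression carry no
information and are dropped with a warning.

## Statement and construct representations

A statement's vector is the unit-normalised sum of its in-vocabulary word
vectors. Repeated words contribute repeatedly (straight sum); no stop
words are removed. Out-of-vocabulary tokens are skipped and counted, and
a statement with no in-vocabulary token is flagged invalid — the pipeline
drops it with a logged warning rather than failing. Construct word lists
are embedded the same way. Both representations are unit-norm, so every
similarity score is a cosine bounded by ±1.

## Accuracy model

- **Theme folds.** One fold per topical theme (11 in the full design).
  Theme-blocked folds prevent the regression from exploiting topic
  overlap between train and test. A theme with fewer than two statements
  or a single accuracy class is an error (exit code 3 in the CLI): the
  within-fold z-transform is undefined there.
- **Per-fold z-transform.** Binary labels are standardised within each
  fold with the sample sd (ddof = 1), giving each fold mean 0 and sd 1.
  This removes between-theme base-rate information from the target, so a
  model can only score above chance by separating statements *within*
  themes. The problem becomes regression, not classification.
- **Dimension selection.** The embedding matrix of all valid statements
  is SVD-decomposed once (scores = U S, decreasing singular values). For
  each outer fold, an inner leave-one-theme-out loop over the remaining
  K − 1 folds computes the out-of-fold MSE for each candidate k in the
  grid (1, 2, 3, 5, 7, 10, 14, 19, 26, 35, 46, 61, 80, 105, 137, 179,
  234, 305, 397, 488, 768, truncated at the available dimensionality and
  capped at n_train − 2); the selected k minimises inner MSE, and a
  larger k must beat the incumbent by more than numerical noise
  (relative 1e-9, absolute 1e-12) so exact-fit ties resolve to the most
  parsimonious model. The fold's final model is OLS with intercept on
  the first k score columns, fit on all non-test data. Every statement
  receives exactly one out-of-fold prediction; folds may select
  different k. Test labels are never touched during selection or
  fitting (asserted by mutation test).
- **Inner criterion.** MSE was chosen as the inner selection criterion:
  it matches the regression framing and the MSE metric reported
  alongside the group comparison. Correlation-based selection would be a
  one-line change.
- **Group comparison.** Pooled two-sample Student t with df = N − 2;
  Cohen's d = (mean_incorrect − mean_correct)/pooled sd, so d < 0 means
  correct statements received higher predicted scores. The 95% CI for d
  uses the large-sample normal approximation
  se(d) = √(N/(n_I·n_C) + d²/(2·df)). Note that summary tables in this
  literature sometimes print t(N − 1) for what is structurally a
  two-sample comparison; this package reports the two-sample df = N − 2.

## Rating models

Rated constructs (dominance on 1–9, valence on −3…+3, abstractness) are
predicted from word embeddings by the same dimension-selection
regression, with two differences: the target is the raw rating (no
z-transform), and folds are ten random partitions under a seed — word
lists carry no theme structure. The reported `cv_r` is the Pearson
correlation between out-of-fold predictions and ratings from the nested
procedure. The deployable model then selects k by plain ten-fold CV over
the same folds on all rated words and refits on all of them; nesting
matters for the *estimate* of predictive validity, not for the final
coefficients. Applied to a statement vector, the model projects it into
the word-SVD basis and evaluates the linear model; outputs are raw
regression predictions and are **not clipped** to the rating scale — a
statement vector is not a word vector, and its projection can sit far
from the rated words' region, so predicted "dominance" values need not
resemble the 1–9 scale numerically. Comparisons between groups are still
meaningful; absolute values are not anchored to the scale.

Out-of-fold correlations carry a small negative finite-sample bias under
the null (fold means shift opposite to the held-out points); at a few
hundred rated words it is ≈ −0.05 to −0.1 and shrinks with list size.

## Keyword analysis

For each word, a 2×2 contingency table contrasts its frequency in
incorrect vs correct statements; Pearson chi-square without continuity
correction, Bonferroni threshold α/m with m = the number of words
actually tested. Two codings:

- `tokens` (default): occurrences of the word vs occurrences of all
  other words, split by class. This follows the "frequency of each
  unique word" framing, but treats tokens as independent; repeated use
  of a word within one statement violates that, so token-coded p-values
  run **anticonservative** for bursty words.
- `presence`: statements containing the word vs statements not
  containing it. Statement-level independence holds, making this the
  calibrated variant; the Type-I control test uses it.

Words below a minimum count on the tested margin (default 5) are
excluded: the chi-square approximation needs adequate expected counts,
and at Bonferroni-corrected significance levels sparse tables' tail
probabilities are badly approximated. For strict familywise control at
small samples a higher floor (15–25) is advisable.

## Synthetic data

The generator is a topic-style cluster mixture — the only linguistic
structure LSA can see is co-occurrence, so richer structure (syntax,
discourse) would be untestable anyway. Defaults emulate the study shape
the pipeline targets: 800 short cued-recall statements
(truncated-geometric lengths, mean ~12 tokens, range 4–40), 11 themes
with base accuracy rates spread evenly over 78% ± 10 points, a 240-word
vocabulary in 13 Zipf-weighted clusters (one per theme, one
high-frequency function-word cluster drawn three times as often, one
target "communion" cluster), 5-grams, 30,000 sampled grams, and a small
cross-cluster leakage (0.15) so clusters overlap weakly.

Statement token composition mixes the function cluster (0.30), global
noise (0.08), a per-statement target-cluster share, and — for the
topical remainder — a Dirichlet-weighted soft mixture over all theme
clusters concentrated on the statement's own theme. Soft themes matter:
with hard one-cluster themes, a held-out theme's vocabulary is entirely
absent from training, the corresponding SVD component is degenerate in
the training set, and leave-one-theme-out regression must extrapolate —
the inner CV then correctly refuses every dimension. Real testimony
themes share most of their vocabulary; the soft mixture reproduces that.

**Planted effect.** The target-cluster share is
p₀ + u (u ~ N(0, 0.05²)), plus, for incorrect statements, δ × s, where
s = √(Var(u) + p₀(1 − p₀)·E[1/L]) is the analytic null sd of the
per-statement target-token *rate* (expectation over the length
distribution). δ therefore approximates the standardised rate difference
between classes; the cosine similarity to the construct representation
tracks the rate closely, so the recovered Cohen's d is mildly attenuated
(≈ 0.45 recovered for δ = 0.5). With δ = 0 the classes are exchangeable
given theme, and the construct-score t-test rejects at the nominal α.

Ratings are each cluster's level (evenly spaced across the declared
scale) plus Gaussian noise, clipped to the scale; construct lists are
the most frequent words of a designated cluster. All generators are pure
functions of (config, seed).

**What passing tests show — and don't.** The synthetic corpus has no
morphology, no syntax, no pragmatics, no transcription artifacts, and
its themes are exchangeable by construction. Tests on it establish that
the pipeline's machinery is correct (normalisations, fold separation,
selection, calibration, effect recovery) — not that real testimony
carries a semantic accuracy signal of any particular size. The
real-data effect sizes in this literature require the original corpus
and transcripts, which cannot be redistributed.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale — 240-word
vocabularies, spaces of 60–100 dimensions, 300–800 statements — chosen
so the full suite exercises every stage end to end in about a minute.
The implementation assembles the co-occurrence matrix densely; nothing
in the interfaces precludes a sparse assembly for full-scale
vocabularies, but out-of-core scaling is explicitly out of scope.
Degenerate inputs fail loudly: empty corpora warn, all-OOV statements
are dropped with a warning, single-class themes / constant ratings /
zero-variance groups raise typed errors that the CLI maps to exit
code 3. SVD rank deficiencies are truncated at the numerical rank with
a warning.

## Known limitations

- Token-coded keyword chi-square is anticonservative under burstiness
  (see above); presence coding is the calibrated route.
- The d confidence interval is the large-sample approximation, not a
  noncentral-t interval; at small n it is slightly narrow.
- Statements scored against a construct built in a different-language
  space must be supplied already translated; translation is upstream
  and out of scope.
- Contextual (transformer) embeddings are out of scope; the embedding
  step is a module boundary behind which such a backend could be added.
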