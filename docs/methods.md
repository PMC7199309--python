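# Methods

## Model and procedure

The package compares miRNA–miRNA similarity measurements by how well each
supports guilt-by-association prediction of miRNA–disease associations on
a bipartite network. The scorer (MBSI) treats the known incidence matrix
as training labels: the score of a candidate pair (m_i, d_j) is the
similarity-weighted mean of the other miRNAs' binary association
indicators for d_j, with the l = i term excluded from both numerator and
denominator. The weighted-mean form makes scores scale-free in each
similarity row (multiplying row i's off-diagonal similarities by any
c > 0 leaves row i's scores unchanged) and bounded in [0, 1].

Evaluation is leave-one-out cross-validation over miRNAs: each test
miRNA's associations are masked, every disease in the universe is
re-scored, its known diseases are labelled positive and all others
negative, and the ranking is summarized by ROC-AUC, PR-AUC and top-k
precision/recall. The negative universe is always the full disease set of
the association table. miRNAs with zero positives or zero negatives are
skipped (and counted), not scored as NaN.

## Similarity construction

**Sequence.** True global (end-to-end, end gaps penalized)
Needleman–Wunsch alignment with affine gap penalties, computed with
Biopython's `PairwiseAligner`. Scoring uses the EDNAFULL values for
unambiguous nucleotides (match +5, mismatch −4) with gap open 10 and
extension 0.5 under the EMBOSS convention: a gap run of length L costs
`open + (L−1)·extend`. U is silently mapped to T; any other character is
an error rather than a wildcard, since mature miRNA sequences are
unambiguous. Raw scores are mapped to (0,1) by
`S_ij = max(0, raw_ij) / sqrt(raw_ii · raw_jj)` — symmetric, unit
self-similarity, with negative raw scores (possible for dissimilar short
sequences under this score family) clipped to 0. The normalization
formula is a design choice of this package: several symmetric
normalizations satisfy the same (0,1) contract, and nothing downstream
depends on which is used beyond monotonicity.

**Expression.** Duplicate-ID rows are merged by element-wise mean
("merging" could also mean summing or keeping the first profile; the mean
is used because replicate profiles of one miRNA are repeated measurements
of the same quantity). All-zero rows are removed. Similarity is the
absolute Pearson correlation; at least 3 conditions are required.
Zero-variance rows have undefined correlation and are assigned similarity
0 to all other rows, with a logged warning, so the matrix stays valid.

**Raw external matrices** (e.g. GO-semantic or MeSH-term-based outputs)
are normalized by dividing each row by its diagonal element, then
symmetrized as (N + Nᵀ)/2 with the diagonal forced to 1 and entries
clipped to [0, 1]. The averaging symmetrization is a package choice: a
row-wise diagonal division of an asymmetric matrix does not determine a
symmetric result by itself.

Every constructed matrix is validated on construction: symmetry to within
1e-12, unit diagonal, entries in [0, 1].

## Metrics

ROC and PR curves sweep the threshold through the distinct score values;
tied candidates enter the positive-prediction set together. ROC AUC uses
the trapezoidal rule, which on these step curves equals the tie-corrected
Mann–Whitney concordance probability (an invariant checked in the test
suite against an independent rank-based computation). PR AUC uses the
average-precision step rule — precision times recall-increment summed
over thresholds — and the PR curve is anchored at recall 0 with the first
threshold's precision, with no interpolated (0,1) point. Top-k ranking
breaks score ties by candidate identifier (lexicographic), so runs are
reproducible; AUCs are tie-corrected and hence order-independent.

Of the four confusion-matrix rates, FPR is FP/(FP+TN), the standard
definition; TPR = REC = TP/(TP+FN), PRE = TP/(TP+FP).

## Distribution summaries and tests

Similarity distributions are summarized from the strict upper triangle
(n(n−1)/2 values): mean, sample SD (n−1 denominator), and
skewness/kurtosis from population central moments (n denominators), with
kurtosis in the non-excess (Pearson) convention where a normal
distribution has kurtosis 3 — chosen because similarity distributions in
this setting are heavy-tailed and the non-excess convention keeps the
values positive and comparable across measurements. Skewness and kurtosis
are computed whenever the sample has at least 2 points and positive
variance; `skewness_defined`/`kurtosis_defined` flags additionally
require n ≥ 3 and n ≥ 4 respectively, so tiny samples carry an explicit
caveat instead of being silently dropped.

Measurements are compared by paired t-tests on per-miRNA ROC-AUC (or
PR-AUC) values, paired on the intersection of evaluated miRNA IDs,
one-sided ("is the reference higher?") by default. Identical inputs
produce zero-variance differences and a surfaced error rather than a
silent p-value. Raw p-values are reported with no multiple-testing
correction, and the output table says so.

## Synthetic benchmark

The generator emulates the three study inputs with the statistical
structure the analysis assumes, and nothing more:

- **Sequences** — each family draws one ancestor uniformly over
  {A,C,G,U}; each member substitutes every position independently with
  probability `mutation_rate` (default 0.1), drawing uniformly from the
  three alternative bases. Defaults: 6 families × 10 members, 22 nt.
- **Expression** — each family shares a standard-normal latent profile
  over `n_conditions` (default 24, the cell-line count typical of public
  miRNA expression compendia); member rows are
  `sqrt(ρ)·latent + sqrt(1−ρ)·noise_sd·ε` with ρ = `within_block_corr`
  (default 0.6), so at the default `noise_sd = 1` the expected
  within-family Pearson correlation is ρ and `noise_sd = 0` gives exactly
  correlated rows. The matrix is shifted to be nonnegative
  (abundance-like); a common shift changes no correlation.
- **Associations** — each of 20 diseases is seeded on one uniformly drawn
  (family, member); co-members join with `p_within = 0.8`, all miRNAs
  outside the family with `p_background = 0.05`. These defaults plant a
  strong but noisy family signal: roughly 80% of each disease's carriers
  sit in one family against a 5% background.
- **Null** — miRNA labels are randomly permuted, conserving per-disease
  association counts and the total pair count while destroying the
  similarity–association coupling.

One global seed expands into fixed per-component substreams
(`SeedSequence(seed, spawn_key=(component,))`), so adding a generator
never perturbs another's output.

What the generator does *not* emulate: miRNA secondary structure, genomic
context, read-count noise, disease-ontology structure, or the incomplete
and biased feature coverage of real databases. Passing tests on planted
data therefore show the pipeline is correct and sensitive to a known
signal — not that any particular measurement is superior on real data.

## Pipeline

`run_comparison` builds each configured measurement, summarizes its
distribution, runs LOOCV on (a) each measurement's own miRNA set
intersected with the association table and (b) the common miRNA subset
shared by all measurements, runs the paired comparisons on both, and
extracts top-10 novel (non-interacting) predictions using the measurement
with the highest full-set mean ROC-AUC (ties: higher mean PR-AUC, then
lexicographic name). miRNAs present in a similarity matrix but absent
from the association table are retained as neighbors — they contribute
similarity mass with a_lj = 0, which affects denominators — but are not
test cases. All randomness flows from the run seed; outputs are
byte-reproducible, and a failed run leaves an `INCOMPLETE` marker in its
output directory.

## Problem sizes

The default benchmark (60 miRNAs, 20 diseases, 24 conditions) makes every
stage — 1 770 pairwise alignments, 60 leave-one-out folds — run in
seconds while leaving enough planted signal for stable separation of
benchmark (mean ROC-AUC ≈ 0.89) from null (≈ 0.5). The acceptance script
averages the null over 10 permutation replicates to tighten its estimate.

## Known limitations

- The (0,1) normalization of raw alignment scores is not canonical;
  different choices change similarity values (though not their ordering).
- PR AUC by the step rule differs from trapezoidal PR integration by
  O(1/n) on small candidate sets.
- The scorer inherits the cold-start problem: a miRNA whose neighbors
  have no associations for a disease scores 0 regardless of its
  similarity structure.
- Disease-side similarity is deliberately out of scope; the scorer uses
  miRNA-side similarity only.
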