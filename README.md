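# mirsimbench

Benchmarking miRNA–miRNA similarity measurements for miRNA–disease
association prediction.

## The problem

Computational predictors of miRNA–disease associations rest on one
hypothesis: miRNAs that are similar — in sequence, in expression across
cell lines or tissues, in the GO annotations of their targets, or in the
MeSH terms of their known diseases — tend to be implicated in the same
diseases. How much the *choice of similarity measurement* matters is an
empirical question. This package provides the machinery to answer it: it
builds symmetric, (0,1)-normalized miRNA similarity matrices from several
feature spaces, scores candidate miRNA–disease pairs by similarity-weighted
guilt-by-association, evaluates each measurement by leave-one-out
cross-validation (LOOCV) with ROC/PR and top-k metrics, compares
measurements statistically, and extracts ranked novel predictions. A
seeded synthetic-data module generates planted benchmarks (miRNA families
that preferentially share diseases) and permutation nulls, so the entire
pipeline is testable without external downloads.

## The scorer

For a similarity matrix Sim over n miRNAs and a binary incidence matrix
a (a_lj = 1 iff miRNA m_l is known to be associated with disease d_j),
the inference score of a candidate pair (m_i, d_j) is the
similarity-weighted mean of the other miRNAs' association indicators
(miRNA-based similarity inference, MBSI):

    score(m_i, d_j) = Σ_{l≠i} Sim(m_i, m_l) · a_lj  /  Σ_{l≠i} Sim(m_i, m_l)

Scores lie in [0, 1]; a miRNA with zero similarity to every other miRNA
scores 0 (no evidence). In LOOCV each miRNA's associations are masked in
turn, all diseases are re-scored, and the ranking of its true diseases is
summarized by ROC-AUC, PR-AUC and precision/recall in the top 5/10/20.

Similarity routes:

- **sequence** — global (end-to-end) Needleman–Wunsch alignment with
  affine gaps (EDNAFULL scores: match +5, mismatch −4; gap open 10,
  extend 0.5, a gap run of length L costing `open + (L−1)·extend`),
  normalized by S_ij = max(0, raw_ij)/√(raw_ii·raw_jj);
- **expression** — absolute Pearson correlation between expression
  profiles, after merging duplicate-ID rows and dropping all-zero rows;
- **raw** — externally computed matrices (e.g. GO- or MeSH-based),
  normalized by their diagonal and symmetrized.

## Worked example

```python
from mirsimbench import (SyntheticConfig, gen_sequences, gen_associations,
                         sequence_similarity, loocv, permute_associations)

cfg = SyntheticConfig(seed=1)     # 6 families x 10 miRNAs, 20 diseases
sim = sequence_similarity(gen_sequences(cfg))
assoc = gen_associations(cfg)

planted = loocv(sim, assoc)
null = loocv(sim, permute_associations(assoc, seed=1))
print(f"planted mean ROC-AUC {planted.mean_roc_auc:.4f}, "
      f"null {null.mean_roc_auc:.4f}")
```

prints

```
planted mean ROC-AUC 0.8876, null 0.5083
```

The planted benchmark — families of similar sequences whose members share
diseases — is recovered well above chance (0.89), while permuting miRNA
labels destroys the similarity–association coupling and drops performance
to chance (0.51).

The same study is available from the shell:

```sh
mirsimbench simulate --out data/ --seed 1
mirsimbench similarity --method sequence --in data/sequences.fasta --out seqsim.tsv
mirsimbench evaluate --sim seqsim.tsv --assoc data/associations.tsv --k 5,10,20
mirsimbench predict --sim seqsim.tsv --assoc data/associations.tsv --top-n 10 --out novel.csv
mirsimbench compare --config run.yaml   # full multi-measurement comparison
```

## Documentation

See `docs/methods.md` for the model assumptions, parameter choices,
normalization and tie-breaking conventions, and known limitations.
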