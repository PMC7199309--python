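"""Construction of symmetric, (0,1)-normalized miRNA-miRNA similarity matrices.

Three routes produce a :class:`SimilarityMatrix`:

* :func:`sequence_similarity` — global (end-to-end) Needleman-Wunsch
  alignment with affine gap penalties (EDNAFULL scores: match +5,
  mismatch -4; gap open 10, gap extend 0.5 in the EMBOSS convention where
  a gap run of length L costs ``open + (L-1)*extend``), normalized by the
  geometric mean of the two self-alignment scores.
* :func:`expression_similarity` — absolute Pearson correlation between
  expression profiles across conditions.
* :func:`diagonal_normalize` — rescaling of an externally computed raw
  similarity matrix (e.g. GO-semantic or MeSH-based output) by its
  diagonal, then symmetrization.

All three enforce the same contract: symmetric values in [0, 1] with a
unit diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ComputationError, InputError

logger = logging.getLogger(__name__)

#: Absolute tolerance for symmetry and range checks on similarity matrices.
SYMMETRY_TOL = 1e-12

_ALPHABET = "ACGT"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceSet:
    """An ordered collection of nucleotide sequences with unique IDs.

    Sequences are over {A, C, G, U, T}; U and T are interchangeable
    (mature miRNA sequences are RNA, alignment scoring is DNA-alphabet).
    """

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise InputError("ids and sequences must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise InputError("sequence IDs must be unique")
        for sid, seq in zip(self.ids, self.sequences):
            if not seq:
                raise InputError(f"empty sequence for {sid!r}")
            bad = set(seq.upper()) - set("ACGUT")
            if bad:
                raise InputError(
                    f"sequence {sid!r} contains characters outside "
                    f"{{A,C,G,U,T}}: {sorted(bad)!r}"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceSet":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise InputError(f"no sequences in {path}")
        return cls(
            ids=tuple(r.id for r in records),
            sequences=tuple(str(r.seq).upper() for r in records),
        )

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=sid, description="")
            for sid, seq in zip(self.ids, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for global alignment with affine gaps.

    Defaults are the EDNAFULL values for unambiguous nucleotides
    (match +5, mismatch -4) with gap opening 10 and extension 0.5:
    a gap run of length L costs ``gap_open + (L - 1) * gap_extend``.
    End gaps are penalized (true end-to-end alignment).
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise InputError("require gap_open >= gap_extend >= 0")

    def substitution_matrix(self) -> substitution_matrices.Array:
        m = substitution_matrices.Array(_ALPHABET, dims=2)
        for a in _ALPHABET:
            for b in _ALPHABET:
                m[a, b] = self.match if a == b else self.mismatch
        return m


@dataclass(frozen=True)
class ExpressionMatrix:
    """miRNA expression profiles: rows are miRNAs, columns conditions."""

    ids: tuple[str, ...]
    condition_labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.ids), len(self.condition_labels)):
            raise InputError("values shape inconsistent with labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.ids), columns=list(self.condition_labels)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            ids=tuple(str(i) for i in df.index),
            condition_labels=tuple(str(c) for c in df.columns),
            values=df.to_numpy(dtype=float),
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric n x n miRNA similarity matrix with values in [0, 1].

    Invariants (checked on construction): symmetry to within
    ``SYMMETRY_TOL``, unit diagonal, all entries in [0, 1].
    """

    ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise InputError("similarity matrix IDs must be unique")
        if values.shape != (n, n):
            raise InputError(f"expected {n}x{n} matrix, got {values.shape}")
        if not np.allclose(values, values.T, atol=SYMMETRY_TOL, rtol=0):
            raise ComputationError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(values), 1.0, atol=SYMMETRY_TOL, rtol=0):
            raise ComputationError("similarity matrix diagonal must be 1")
        if values.min() < -SYMMETRY_TOL or values.max() > 1 + SYMMETRY_TOL:
            raise ComputationError("similarity values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, mirna_id: str) -> int:
        try:
            return self.ids.index(mirna_id)
        except ValueError:
            raise InputError(f"unknown miRNA {mirna_id!r}") from None

    def restrict(self, keep_ids: Sequence[str]) -> "SimilarityMatrix":
        """View of the matrix restricted to ``keep_ids`` in the given order."""
        idx = [self.index_of(i) for i in keep_ids]
        return SimilarityMatrix(
            ids=tuple(keep_ids), values=self.values[np.ix_(idx, idx)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise InputError("similarity TSV row and column IDs must match")
        return cls(ids=tuple(str(i) for i in df.index), values=df.to_numpy(float))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f")


def _finalize_similarity(ids: Sequence[str], values: np.ndarray) -> SimilarityMatrix:
    """Force exact symmetry / unit diagonal / clipping before validation."""
    values = np.asarray(values, dtype=float)
    values = (values + values.T) / 2.0
    values = np.clip(values, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=tuple(ids), values=values)


# ---------------------------------------------------------------------------
# Sequence similarity
# ---------------------------------------------------------------------------

def _make_aligner(params: AlignmentParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = params.substitution_matrix()
    # Biopython charges open_gap_score for the first gap position and
    # extend_gap_score for each further one: a run of length L scores
    # -(open + (L-1)*extend), the EMBOSS needle convention.
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _prepare_sequence(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set(_ALPHABET)
    if bad:
        raise InputError(
            f"sequence contains characters outside the alphabet: {sorted(bad)!r}"
        )
    if not seq:
        raise InputError("empty sequence")
    return seq


def align_score(
    a: str, b: str, params: AlignmentParams | None = None
) -> float:
    """Optimal global alignment score of two sequences under affine gaps.

    End gaps are penalized; the score is symmetric in its arguments.
    """
    params = params or AlignmentParams()
    aligner = _make_aligner(params)
    return float(aligner.score(_prepare_sequence(a), _prepare_sequence(b)))


def sequence_similarity(
    seqs: SequenceSet, params: AlignmentParams | None = None
) -> SimilarityMatrix:
    """Pairwise alignment-score similarity, self-score normalized.

    S_ij = max(0, raw_ij) / sqrt(raw_ii * raw_jj) where raw is the global
    affine-gap alignment score; the diagonal is 1 by construction.
    """
    if len(seqs) < 2:
        raise InputError("need at least 2 sequences")
    params = params or AlignmentParams()
    aligner = _make_aligner(params)
    prepared = [_prepare_sequence(s) for s in seqs.sequences]
    n = len(prepared)
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            raw[i, j] = raw[j, i] = aligner.score(prepared[i], prepared[j])
    self_scores = np.diag(raw).copy()
    if np.any(self_scores <= 0):
        bad = [seqs.ids[i] for i in np.nonzero(self_scores <= 0)[0]]
        raise ComputationError(f"nonpositive self-alignment score for {bad!r}")
    norm = np.sqrt(np.outer(self_scores, self_scores))
    return _finalize_similarity(seqs.ids, np.maximum(raw, 0.0) / norm)


# ---------------------------------------------------------------------------
# Expression similarity
# ---------------------------------------------------------------------------

def preprocess_expression(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Merge duplicate-ID rows (element-wise mean) and drop all-zero rows.

    Order of first appearance is preserved.
    """
    if len(raw.ids) == 0:
        raise InputError("empty expression matrix")
    df = raw.to_frame()
    merged = df.groupby(level=0, sort=False).mean()
    nonzero = merged.loc[(merged != 0).any(axis=1)]
    n_dup = len(df) - len(merged)
    n_zero = len(merged) - len(nonzero)
    if n_dup or n_zero:
        logger.info(
            "preprocess_expression: merged %d duplicate rows, dropped %d all-zero rows",
            n_dup, n_zero,
        )
    if nonzero.empty:
        raise InputError("no rows left after preprocessing")
    return ExpressionMatrix.from_frame(nonzero)


def expression_similarity(expr: ExpressionMatrix) -> SimilarityMatrix:
    """Absolute Pearson correlation between expression profiles.

    Rows with zero variance have undefined correlation; their similarity
    to every other row is set to 0 (diagonal stays 1) and a warning is
    logged, so the output matrix remains valid.
    """
    if len(expr.condition_labels) < 3:
        raise InputError("need at least 3 conditions for Pearson correlation")
    x = expr.values
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "expression_similarity: %d zero-variance rows get similarity 0 (%s)",
            int(constant.sum()),
            [expr.ids[i] for i in np.nonzero(constant)[0]],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    sim = np.abs(corr)
    sim[constant, :] = 0.0
    sim[:, constant] = 0.0
    return _finalize_similarity(expr.ids, sim)


# ---------------------------------------------------------------------------
# Raw (externally computed) similarity
# ---------------------------------------------------------------------------

def diagonal_normalize(
    ids: Sequence[str], raw: np.ndarray
) -> SimilarityMatrix:
    """Normalize a raw square similarity matrix by its diagonal.

    Each row is divided by its diagonal element (N_ij = raw_ij / raw_ii);
    the result is symmetrized as (N + N^T)/2 with the diagonal forced to 1
    and entries clipped to [0, 1].
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise InputError(f"raw similarity matrix must be square, got {raw.shape}")
    if raw.shape[0] != len(ids):
        raise InputError("ID list length does not match matrix size")
    diag = np.diag(raw)
    if np.any(diag <= 0):
        bad = [ids[i] for i in np.nonzero(diag <= 0)[0]]
        raise InputError(f"nonpositive diagonal entries for {bad!r}")
    return _finalize_similarity(ids, raw / diag[:, None])


def load_raw_similarity_tsv(path: str | Path) -> SimilarityMatrix:
    """Read an externally computed raw matrix and diagonal-normalize it."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise InputError("raw similarity TSV row and column IDs must match")
    return diagonal_normalize(
        [str(i) for i in df.index], df.to_numpy(float)
    )


# ---------------------------------------------------------------------------
# Common-subset alignment across measurements
# ---------------------------------------------------------------------------

def align_matrices(
    matrices: Iterable[SimilarityMatrix],
    tables: Iterable = (),
) -> tuple[list[SimilarityMatrix], list]:
    """Restrict matrices (and association tables) to their common miRNA set.

    The shared order is the first matrix's ID order filtered to the
    intersection. Association tables constrain the intersection only
    through their miRNA ID lists.
    """
    matrices = list(matrices)
    tables = list(tables)
    if not matrices:
        raise InputError("need at least one similarity matrix")
    common = set(matrices[0].ids)
    for m in matrices[1:]:
        common &= set(m.ids)
    for t in tables:
        common &= set(t.mirna_ids)
    if not common:
        raise InputError("empty miRNA intersection across inputs")
    order = [i for i in matrices[0].ids if i in common]
    out_matrices = [m.restrict(order) for m in matrices]
    out_tables = [t.restrict_mirnas(order) for t in tables]
    return out_matrices, out_tables
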