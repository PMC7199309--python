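"""miRNA-based similarity inference (MBSI).

The scorer encodes guilt-by-association on a bipartite miRNA-disease
network: the score of pair (m_i, d_j) is the similarity-weighted mean of
the other miRNAs' known association indicators for disease d_j,

    score(m_i, d_j) = sum_{l != i} Sim(m_i, m_l) * a_lj
                      ----------------------------------
                      sum_{l != i} Sim(m_i, m_l)

with a_lj = 1 iff (m_l, d_j) is a known association. The l = i term is
excluded from both sums, so a miRNA's own associations never feed its own
scores. A miRNA with zero similarity to every other miRNA has an undefined
ratio; its score is defined as 0 (no evidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .similarity import SimilarityMatrix

__all__ = ["AssociationTable", "ScoreMatrix", "mbsi_score", "mbsi_score_matrix"]


@dataclass(frozen=True)
class AssociationTable:
    """Known miRNA-disease associations and their binary incidence matrix."""

    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise InputError("duplicate miRNA IDs")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise InputError("duplicate disease IDs")
        mset, dset = set(self.mirna_ids), set(self.disease_ids)
        for m, d in self.pairs:
            if m not in mset:
                raise InputError(f"pair references unknown miRNA {m!r}")
            if d not in dset:
                raise InputError(f"pair references unknown disease {d!r}")

    @property
    def incidence(self) -> np.ndarray:
        """Binary matrix a with a[l, j] = 1 iff (mirna l, disease j) known."""
        m_index = {m: i for i, m in enumerate(self.mirna_ids)}
        d_index = {d: j for j, d in enumerate(self.disease_ids)}
        a = np.zeros((len(self.mirna_ids), len(self.disease_ids)))
        for m, d in self.pairs:
            a[m_index[m], d_index[d]] = 1.0
        return a

    def __len__(self) -> int:
        return len(self.pairs)

    def restrict_mirnas(self, keep_ids: Sequence[str]) -> "AssociationTable":
        keep = set(keep_ids)
        unknown = keep - set(self.mirna_ids)
        if unknown:
            raise InputError(f"unknown miRNAs {sorted(unknown)!r}")
        return AssociationTable(
            mirna_ids=tuple(keep_ids),
            disease_ids=self.disease_ids,
            pairs=frozenset((m, d) for m, d in self.pairs if m in keep),
        )

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        mirna_ids: Sequence[str] | None = None,
        disease_ids: Sequence[str] | None = None,
    ) -> "AssociationTable":
        """Build a table from (miRNA, disease) pairs.

        ID universes default to the IDs appearing in the pairs, in order
        of first appearance.
        """
        pairs = list(pairs)
        if mirna_ids is None:
            mirna_ids = list(dict.fromkeys(m for m, _ in pairs))
        if disease_ids is None:
            disease_ids = list(dict.fromkeys(d for _, d in pairs))
        return cls(
            mirna_ids=tuple(mirna_ids),
            disease_ids=tuple(disease_ids),
            pairs=frozenset(pairs),
        )

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        mirna_ids: Sequence[str] | None = None,
        disease_ids: Sequence[str] | None = None,
    ) -> "AssociationTable":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["mirna_id", "disease_id"],
            dtype=str, comment="#",
        )
        return cls.from_pairs(
            [(m, d) for m, d in zip(df["mirna_id"], df["disease_id"])],
            mirna_ids=mirna_ids, disease_ids=disease_ids,
        )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for m, d in sorted(self.pairs):
                fh.write(f"{m}\t{d}\n")


@dataclass(frozen=True)
class ScoreMatrix:
    """MBSI inference scores for every miRNA-disease pair, all in [0, 1]."""

    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise InputError("score matrix shape inconsistent with ID lists")
        if scores.min() < 0 or scores.max() > 1:
            raise InputError("scores must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=list(self.mirna_ids), columns=list(self.disease_ids)
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f")

    def write_long_csv(self, path: str | Path) -> None:
        """Long-format `mirna,disease,score`, best scores first."""
        long = (
            self.to_frame()
            .rename_axis("mirna")
            .reset_index()
            .melt(id_vars="mirna", var_name="disease", value_name="score")
            .sort_values(["score", "mirna", "disease"], ascending=[False, True, True])
        )
        long.to_csv(path, index=False, float_format="%.6f")


def _check_aligned(sim: SimilarityMatrix, assoc: AssociationTable) -> None:
    if sim.ids != assoc.mirna_ids:
        raise InputError(
            "similarity matrix and association table must share the same "
            "miRNA ID order"
        )


def mbsi_score(
    sim: SimilarityMatrix, assoc: AssociationTable, i: int, j: int
) -> float:
    """Score of the single pair (miRNA i, disease j) under MBSI."""
    _check_aligned(sim, assoc)
    n = sim.n
    if not (0 <= i < n) or not (0 <= j < len(assoc.disease_ids)):
        raise InputError("index out of range")
    weights = np.delete(sim.values[i], i)
    labels = np.delete(assoc.incidence[:, j], i)
    denom = weights.sum()
    if denom == 0:
        return 0.0
    return float(weights @ labels / denom)


def mbsi_score_matrix(
    sim: SimilarityMatrix,
    assoc: AssociationTable,
    exclude: int | None = None,
) -> ScoreMatrix:
    """All MBSI scores at once; equals the scalar scorer entrywise.

    With ``exclude`` set, that miRNA's incidence row is treated as all
    zeros before scoring — the leave-one-out masking in which the test
    miRNA's association information is removed from the training data.
    """
    _check_aligned(sim, assoc)
    n = sim.n
    if exclude is not None and not (0 <= exclude < n):
        raise InputError(f"exclude index {exclude} out of range")
    a = assoc.incidence
    if exclude is not None:
        a = a.copy()
        a[exclude, :] = 0.0
    # Zero the diagonal of a working copy so every row sum runs over l != i.
    w = sim.values.copy()
    np.fill_diagonal(w, 0.0)
    # Numerator and denominator go through the identical matrix product so
    # the saturated case (all neighbors associated) is exactly 1 and
    # rounding can never push the ratio outside [0, 1] by more than an ulp.
    numer = w @ a
    denom = w @ np.ones_like(a)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    scores = np.clip(scores, 0.0, 1.0)
    return ScoreMatrix(
        mirna_ids=sim.ids, disease_ids=assoc.disease_ids, scores=scores
    )
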