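"""Leave-one-out cross-validation and ranking metrics for MBSI.

Each miRNA is left out in turn: its known associations are masked, every
disease in the universe is re-scored by MBSI, and the ranking of its true
diseases against the rest is summarized by ROC/PR curves, their areas,
and precision/recall in the top-k candidates.

Curve conventions
-----------------
The threshold sweeps through the distinct score values from high to low;
candidates tied at a threshold enter the positive-prediction set
together. TPR = TP/(TP+FN), FPR = FP/(FP+TN), PRE = TP/(TP+FP),
REC = TP/(TP+FN). ROC AUC is the trapezoidal area (equal to the
tie-corrected pairwise concordance probability); PR AUC is the
average-precision step rule, sum of precision times recall increment at
each threshold, with the PR curve anchored at recall 0 with the first
threshold's precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EvaluationError, InputError
from .mbsi import AssociationTable, mbsi_score_matrix
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Curve + metric primitives
# ---------------------------------------------------------------------------

def roc_pr_from_scores(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[list[tuple[float, float]], list[tuple[float, float]], float, float]:
    """ROC and PR curves (and AUCs) from scores and binary labels.

    Returns ``(roc_points, pr_points, roc_auc, pr_auc)`` where roc_points
    are (FPR, TPR) pairs from (0,0) to (1,1) and pr_points are
    (REC, PRE) pairs starting at recall 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise InputError("scores and labels must be equal-length 1-D")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos + n_neg != len(labels):
        raise InputError("labels must be binary 0/1")
    if n_pos == 0 or n_neg == 0:
        raise InputError("need at least one positive and one negative label")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # indices where a new (lower) distinct score starts; tied scores are
    # swallowed into the same threshold step
    distinct_ends = np.nonzero(np.diff(s_sorted))[0]
    cut = np.r_[distinct_ends, len(s_sorted) - 1]
    tp = np.cumsum(l_sorted == 1)[cut].astype(float)
    fp = np.cumsum(l_sorted == 0)[cut].astype(float)

    tpr = tp / n_pos
    fpr = fp / n_neg
    pre = tp / (tp + fp)
    rec = tpr

    roc_points = [(0.0, 0.0)] + list(zip(fpr, tpr))
    roc_auc = float(np.trapezoid(np.r_[0.0, tpr], np.r_[0.0, fpr]))
    pr_points = [(0.0, float(pre[0]))] + list(zip(rec, pre))
    pr_auc = float(np.sum(np.diff(np.r_[0.0, rec]) * pre))
    return roc_points, pr_points, roc_auc, pr_auc


def topk_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    k: int,
    candidate_ids: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Precision and recall restricted to the top-k ranked candidates.

    PRE@k = TP_k / k and REC@k = TP_k / (total positives). Ties at the
    k-th score are broken by candidate identifier (lexicographic) when
    IDs are supplied, by original position otherwise, so results are
    reproducible.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not (1 <= k <= len(scores)):
        raise InputError(f"k={k} outside 1..{len(scores)}")
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise InputError("need at least one positive label")
    order = rank_order(scores, candidate_ids)
    tp_k = int((labels[order[:k]] == 1).sum())
    return tp_k / k, tp_k / n_pos


def rank_order(
    scores: Sequence[float], candidate_ids: Sequence[str] | None = None
) -> np.ndarray:
    """Indices sorted by descending score, ties by ascending identifier."""
    scores = np.asarray(scores, dtype=float)
    if candidate_ids is None:
        return np.argsort(-scores, kind="stable")
    ids = np.asarray(candidate_ids, dtype=object)
    return np.lexsort((ids, -scores))


# ---------------------------------------------------------------------------
# Per-miRNA evaluation containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerMiRNAEvaluation:
    """One left-out miRNA's curves, AUCs and top-k metrics."""

    mirna_id: str
    roc_points: tuple[tuple[float, float], ...]
    pr_points: tuple[tuple[float, float], ...]
    roc_auc: float
    pr_auc: float
    topk: dict[int, tuple[float, float]]
    n_positives: int
    n_negatives: int
    thresholds: tuple[float, ...] = ()

    def curve_rows(self) -> list[dict]:
        """Per-threshold confusion counts for CSV export."""
        rows = []
        thresholds = self.thresholds or (float("nan"),) * (len(self.roc_points) - 1)
        for thr, (fpr, tpr) in zip(thresholds, self.roc_points[1:]):
            tp = tpr * self.n_positives
            fp = fpr * self.n_negatives
            rows.append(
                {
                    "mirna": self.mirna_id,
                    "threshold": thr,
                    "tp": tp,
                    "fp": fp,
                    "fn": self.n_positives - tp,
                    "tn": self.n_negatives - fp,
                    "tpr": tpr,
                    "fpr": fpr,
                    "pre": tp / (tp + fp) if tp + fp else float("nan"),
                    "rec": tpr,
                }
            )
        return rows


@dataclass(frozen=True)
class EvaluationSummary:
    """Aggregate of per-miRNA LOOCV results."""

    per_mirna: tuple[PerMiRNAEvaluation, ...]
    mean_roc_auc: float
    mean_pr_auc: float
    mean_topk: dict[int, tuple[float, float]]
    skipped: tuple[str, ...] = ()

    @property
    def evaluated_ids(self) -> tuple[str, ...]:
        return tuple(e.mirna_id for e in self.per_mirna)

    def metric_by_mirna(self, metric: str) -> dict[str, float]:
        if metric not in ("roc_auc", "pr_auc"):
            raise InputError(f"unknown metric {metric!r}")
        return {e.mirna_id: getattr(e, metric) for e in self.per_mirna}

    def to_dict(self) -> dict:
        return {
            "n_evaluated": len(self.per_mirna),
            "n_skipped": len(self.skipped),
            "skipped": list(self.skipped),
            "mean_roc_auc": self.mean_roc_auc,
            "mean_pr_auc": self.mean_pr_auc,
            "mean_topk": {
                str(k): {"precision": p, "recall": r}
                for k, (p, r) in self.mean_topk.items()
            },
            "per_mirna": {
                e.mirna_id: {
                    "roc_auc": e.roc_auc,
                    "pr_auc": e.pr_auc,
                    "n_positives": e.n_positives,
                    "n_negatives": e.n_negatives,
                    "topk": {
                        str(k): {"precision": p, "recall": r}
                        for k, (p, r) in e.topk.items()
                    },
                }
                for e in self.per_mirna
            },
        }


@dataclass(frozen=True)
class RankedPrediction:
    """One ranked miRNA-disease candidate (rank 1 = best)."""

    mirna_id: str
    disease_id: str
    score: float
    rank: int


# ---------------------------------------------------------------------------
# LOOCV harness
# ---------------------------------------------------------------------------

def loocv(
    sim: SimilarityMatrix,
    assoc: AssociationTable,
    k_list: Sequence[int] = (5, 10, 20),
) -> EvaluationSummary:
    """Leave-one-out cross-validation of MBSI over all evaluable miRNAs.

    A miRNA is evaluable when it has at least one known association and
    at least one non-associated disease in the universe; others are
    skipped and recorded. For each test miRNA its associations are
    masked, all diseases are scored, and ranking metrics are computed
    against the full disease set.
    """
    if not k_list:
        raise InputError("k_list must be nonempty")
    n_diseases = len(assoc.disease_ids)
    for k in k_list:
        if not (1 <= k <= n_diseases):
            raise InputError(f"k={k} outside 1..{n_diseases}")
    incidence = assoc.incidence
    per: list[PerMiRNAEvaluation] = []
    skipped: list[str] = []
    disease_ids = list(assoc.disease_ids)
    for i, mirna in enumerate(sim.ids):
        labels = incidence[i].astype(int)
        n_pos = int(labels.sum())
        n_neg = n_diseases - n_pos
        if n_pos == 0 or n_neg == 0:
            skipped.append(mirna)
            logger.info("loocv: skipping %s (positives=%d, negatives=%d)",
                        mirna, n_pos, n_neg)
            continue
        scores = mbsi_score_matrix(sim, assoc, exclude=i).scores[i]
        roc_pts, pr_pts, roc_auc, pr_auc = roc_pr_from_scores(scores, labels)
        topk = {
            k: topk_metrics(scores, labels, k, candidate_ids=disease_ids)
            for k in k_list
        }
        per.append(
            PerMiRNAEvaluation(
                mirna_id=mirna,
                roc_points=tuple(roc_pts),
                pr_points=tuple(pr_pts),
                roc_auc=roc_auc,
                pr_auc=pr_auc,
                topk=topk,
                n_positives=n_pos,
                n_negatives=n_neg,
                thresholds=tuple(np.unique(scores)[::-1]),
            )
        )
    if not per:
        raise EvaluationError("no evaluable miRNA (all skipped)")
    mean_topk = {
        k: (
            float(np.mean([e.topk[k][0] for e in per])),
            float(np.mean([e.topk[k][1] for e in per])),
        )
        for k in k_list
    }
    return EvaluationSummary(
        per_mirna=tuple(per),
        mean_roc_auc=float(np.mean([e.roc_auc for e in per])),
        mean_pr_auc=float(np.mean([e.pr_auc for e in per])),
        mean_topk=mean_topk,
        skipped=tuple(skipped),
    )


# ---------------------------------------------------------------------------
# Prediction extraction
# ---------------------------------------------------------------------------

def predict_novel(
    sim: SimilarityMatrix, assoc: AssociationTable, top_n: int = 10
) -> list[RankedPrediction]:
    """Top-n highest-scoring non-interacting diseases per miRNA.

    Scores are computed with all known associations in place (no
    masking); known pairs are excluded from the candidate ranking. A
    miRNA with fewer than ``top_n`` non-interacting diseases yields all
    it has, with a logged warning.
    """
    if top_n < 1:
        raise InputError("top_n must be >= 1")
    score_matrix = mbsi_score_matrix(sim, assoc)
    incidence = assoc.incidence
    disease_ids = np.asarray(assoc.disease_ids, dtype=object)
    out: list[RankedPrediction] = []
    for i, mirna in enumerate(sim.ids):
        candidates = np.nonzero(incidence[i] == 0)[0]
        if len(candidates) < top_n:
            logger.warning(
                "predict_novel: %s has only %d non-interacting diseases (< %d)",
                mirna, len(candidates), top_n,
            )
        scores = score_matrix.scores[i, candidates]
        order = rank_order(scores, disease_ids[candidates])
        for rank, pos in enumerate(order[:top_n], start=1):
            j = candidates[pos]
            out.append(
                RankedPrediction(
                    mirna_id=mirna,
                    disease_id=str(disease_ids[j]),
                    score=float(score_matrix.scores[i, j]),
                    rank=rank,
                )
            )
    return out


def rank_diseases_for_mirna(
    sim: SimilarityMatrix, assoc: AssociationTable, mirna_id: str
) -> list[RankedPrediction]:
    """Rank the whole disease universe for one miRNA (case-study protocol).

    The miRNA's own associations are masked before scoring, and all
    diseases — including its known positives — are ranked.
    """
    i = sim.index_of(mirna_id)
    scores = mbsi_score_matrix(sim, assoc, exclude=i).scores[i]
    disease_ids = np.asarray(assoc.disease_ids, dtype=object)
    order = rank_order(scores, disease_ids)
    return [
        RankedPrediction(
            mirna_id=mirna_id,
            disease_id=str(disease_ids[j]),
            score=float(scores[j]),
            rank=rank,
        )
        for rank, j in enumerate(order, start=1)
    ]
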