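"""Distributional summaries of similarity values and paired significance tests.

Conventions: the standard deviation is the n-1 sample form; skewness and
kurtosis use population central moments (n denominators), with kurtosis
in the non-excess (Pearson) convention where a normal distribution has
kurtosis 3. Paired t-tests default to the one-sided "greater"
alternative, asking whether a reference measurement scores higher than a
competitor on shared test miRNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ComputationError, InputError
from .evaluation import EvaluationSummary
from .similarity import SimilarityMatrix

__all__ = [
    "MomentSummary",
    "PairedTestResult",
    "similarity_sample",
    "moments",
    "paired_t_test",
    "compare_measurements",
]


@dataclass(frozen=True)
class MomentSummary:
    """Mean, SD, skewness and kurtosis of a similarity-value sample.

    ``skewness``/``kurtosis`` are NaN when undefined (constant sample or
    too few observations); the ``defined`` flags record which fields are
    meaningful.
    """

    mean: float
    std: float
    skewness: float
    kurtosis: float
    n: int

    @property
    def std_defined(self) -> bool:
        return self.n >= 2

    @property
    def skewness_defined(self) -> bool:
        return self.n >= 3 and not math.isnan(self.skewness)

    @property
    def kurtosis_defined(self) -> bool:
        return self.n >= 4 and not math.isnan(self.kurtosis)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "std": self.std,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "n": self.n,
        }


@dataclass(frozen=True)
class PairedTestResult:
    """Paired Student t-test between two matched metric samples."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    alternative: str
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
            "alternative": self.alternative,
            "n_pairs": self.n_pairs,
        }


def similarity_sample(sim: SimilarityMatrix) -> np.ndarray:
    """The n(n-1)/2 strict upper-triangle similarity values."""
    if sim.n < 2:
        raise InputError("need at least a 2x2 similarity matrix")
    iu = np.triu_indices(sim.n, k=1)
    return sim.values[iu]


def moments(x: Sequence[float]) -> MomentSummary:
    """Four-moment summary of a sample.

    Degenerate cases (too few points, zero variance) leave the affected
    fields NaN rather than raising.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InputError("empty sample")
    n = int(x.size)
    mean = float(x.mean())
    std = float(x.std(ddof=1)) if n >= 2 else float("nan")
    m2 = float(((x - mean) ** 2).mean())
    if n >= 2 and m2 > 0:
        skewness = float(sps.skew(x, bias=True))
        kurtosis = float(sps.kurtosis(x, fisher=False, bias=True))
    else:
        skewness = float("nan")
        kurtosis = float("nan")
    return MomentSummary(mean=mean, std=std, skewness=skewness,
                         kurtosis=kurtosis, n=n)


def paired_t_test(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "greater",
) -> PairedTestResult:
    """Paired Student t-test on matched samples a and b (d = a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("a and b must be equal-length 1-D samples")
    if a.size < 2:
        raise InputError("need at least 2 pairs")
    if alternative not in ("greater", "two-sided", "less"):
        raise InputError(f"unknown alternative {alternative!r}")
    d = a - b
    if d.std(ddof=1) == 0:
        raise ComputationError(
            "zero-variance differences: paired t statistic undefined"
        )
    res = sps.ttest_rel(a, b, alternative=alternative)
    return PairedTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=int(a.size - 1),
        p_value=float(res.pvalue),
        alternative=alternative,
        n_pairs=int(a.size),
    )


def histogram_data(x: Sequence[float], bins: int = 50) -> "np.ndarray | tuple":
    """Binned counts over [0, 1] for external plotting of Fig.-1-style panels."""
    x = np.asarray(x, dtype=float)
    counts, edges = np.histogram(x, bins=bins, range=(0.0, 1.0))
    return counts, edges


def boxplot_data(x: Sequence[float]) -> dict[str, float]:
    """Quartiles and Tukey whiskers for external boxplot rendering."""
    x = np.asarray(x, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo = x[x >= q1 - 1.5 * iqr].min()
    hi = x[x <= q3 + 1.5 * iqr].max()
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(lo),
        "whisker_high": float(hi),
        "n": int(x.size),
    }


def compare_measurements(
    evals: Mapping[str, EvaluationSummary],
    metric: str = "roc_auc",
    reference: str | None = None,
    alternative: str = "greater",
) -> dict[str, PairedTestResult]:
    """Paired tests of a reference measurement against each competitor.

    Per-miRNA metric values are paired on the intersection of evaluated
    miRNA IDs between the reference and each other measurement; the test
    asks whether the reference is higher (one-sided by default).
    """
    if len(evals) < 2:
        raise InputError("need at least 2 named evaluations")
    if reference is None or reference not in evals:
        raise InputError(f"reference {reference!r} not among measurements")
    ref_vals = evals[reference].metric_by_mirna(metric)
    out: dict[str, PairedTestResult] = {}
    for name, summary in evals.items():
        if name == reference:
            continue
        other_vals = summary.metric_by_mirna(metric)
        shared = sorted(set(ref_vals) & set(other_vals))
        if len(shared) < 2:
            raise InputError(
                f"fewer than 2 shared evaluated miRNAs between "
                f"{reference!r} and {name!r}"
            )
        out[name] = paired_t_test(
            [ref_vals[m] for m in shared],
            [other_vals[m] for m in shared],
            alternative=alternative,
        )
    return out
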