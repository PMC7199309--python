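"""End-to-end orchestration of the similarity-measurement comparison study.

A run loads or generates the inputs, builds one similarity matrix per
named measurement, summarizes each matrix's value distribution, runs
leave-one-out cross-validation both on each measurement's own miRNA set
(intersected with the association table) and on the common miRNA subset
shared by all measurements, compares measurements with paired t-tests,
extracts novel predictions with the best-performing measurement, and
writes all artifacts plus a JSON manifest.

All randomness flows from ``RunConfig.seed``; two runs with the same
config produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, InputError, MirSimBenchError
from .evaluation import EvaluationSummary, loocv, predict_novel
from .mbsi import AssociationTable
from .similarity import (
    AlignmentParams,
    ExpressionMatrix,
    SequenceSet,
    SimilarityMatrix,
    align_matrices,
    expression_similarity,
    load_raw_similarity_tsv,
    preprocess_expression,
    sequence_similarity,
)
from .stats import (
    boxplot_data,
    compare_measurements,
    histogram_data,
    moments,
    similarity_sample,
)
from .synthetic import SyntheticConfig, gen_associations, gen_expression, gen_sequences

logger = logging.getLogger(__name__)

_METHODS = ("sequence", "expression", "raw")


@dataclass(frozen=True)
class MeasurementSpec:
    """One similarity measurement: how to build it and from what.

    ``path`` may be omitted for sequence/expression methods when a
    synthetic config is present in the run — the measurement is then
    built from generated data.
    """

    method: str
    path: str | None = None

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ConfigurationError(
                f"method must be one of {_METHODS}, got {self.method!r}"
            )
        if self.method == "raw" and self.path is None:
            raise ConfigurationError("raw measurements require a path")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full comparison run."""

    measurements: Mapping[str, MeasurementSpec]
    output_dir: str
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    associations_path: str | None = None
    k_list: tuple[int, ...] = (5, 10, 20)
    top_n: int = 10
    reference: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ConfigurationError("need at least one measurement")
        if any(k < 1 for k in self.k_list):
            raise ConfigurationError("k_list values must be positive")
        if self.reference is not None and self.reference not in self.measurements:
            raise ConfigurationError(
                f"reference {self.reference!r} not among measurements"
            )
        if self.associations_path is None and self.synthetic is None:
            raise ConfigurationError(
                "need either an associations path or a synthetic config"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        measurements = {
            name: MeasurementSpec(**spec) if isinstance(spec, dict)
            else MeasurementSpec(method=str(spec))
            for name, spec in d.pop("measurements").items()
        }
        synthetic = d.pop("synthetic", None)
        if synthetic is not None and not isinstance(synthetic, SyntheticConfig):
            synthetic = SyntheticConfig(**{**synthetic, "seed": d.get("seed", 0)})
        if "k_list" in d:
            d["k_list"] = tuple(int(k) for k in d["k_list"])
        return cls(measurements=measurements, synthetic=synthetic, **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "measurements": {
                name: dataclasses.asdict(spec)
                for name, spec in self.measurements.items()
            },
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "synthetic": None if self.synthetic is None else self.synthetic.to_dict(),
            "associations_path": self.associations_path,
            "k_list": list(self.k_list),
            "top_n": self.top_n,
            "reference": self.reference,
            "log_level": self.log_level,
        }


@dataclass
class RunReport:
    """In-memory results of a comparison run."""

    config: RunConfig
    matrices: dict[str, SimilarityMatrix]
    moment_summaries: dict[str, dict]
    full_evals: dict[str, EvaluationSummary]
    common_evals: dict[str, EvaluationSummary]
    full_tests: dict[str, dict[str, dict]]
    common_tests: dict[str, dict[str, dict]]
    best_measurement: str
    novel_predictions: list
    manifest: dict = dc_field(default_factory=dict)


def _build_measurement(
    name: str, spec: MeasurementSpec, cfg: RunConfig
) -> SimilarityMatrix:
    if spec.method == "sequence":
        if spec.path is not None:
            seqs = SequenceSet.from_fasta(spec.path)
        elif cfg.synthetic is not None:
            seqs = gen_sequences(cfg.synthetic)
        else:
            raise ConfigurationError(
                f"measurement {name!r}: no path and no synthetic config"
            )
        return sequence_similarity(seqs, AlignmentParams())
    if spec.method == "expression":
        if spec.path is not None:
            expr = ExpressionMatrix.read_tsv(spec.path)
        elif cfg.synthetic is not None:
            expr = gen_expression(cfg.synthetic)
        else:
            raise ConfigurationError(
                f"measurement {name!r}: no path and no synthetic config"
            )
        return expression_similarity(preprocess_expression(expr))
    return load_raw_similarity_tsv(spec.path)


def _select_best(evals: Mapping[str, EvaluationSummary]) -> str:
    """Highest mean ROC-AUC; ties to higher mean PR-AUC, then name."""
    return min(
        evals,
        key=lambda n: (-evals[n].mean_roc_auc, -evals[n].mean_pr_auc, n),
    )


def run_comparison(cfg: RunConfig) -> RunReport:
    """Execute the full study and write all artifacts to the output dir.

    Any stage failure aborts with a stage-named error; an ``INCOMPLETE``
    marker flags partial output directories and is removed on success.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "INCOMPLETE"
    marker.write_text("run in progress or failed\n")
    try:
        report = _run_stages(cfg, outdir)
    except MirSimBenchError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise MirSimBenchError(f"run failed: {exc}") from exc
    marker.unlink()
    return report


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        logger.info("stage %s: start", name)
        try:
            return fn(*args, **kwargs)
        except MirSimBenchError as exc:
            raise type(exc)(f"stage {name!r}: {exc}") from exc

    return wrap


def _run_stages(cfg: RunConfig, outdir: Path) -> RunReport:
    # --- load / generate associations
    if cfg.associations_path is not None:
        assoc = _stage("load_associations")(
            AssociationTable.read_tsv, cfg.associations_path
        )
    else:
        assoc = _stage("generate_associations")(gen_associations, cfg.synthetic)

    # --- build similarity matrices
    matrices: dict[str, SimilarityMatrix] = {}
    for name, spec in cfg.measurements.items():
        matrices[name] = _stage(f"similarity[{name}]")(
            _build_measurement, name, spec, cfg
        )
        matrices[name].write_tsv(outdir / f"similarity_{name}.tsv")

    # --- distribution summaries
    moment_summaries: dict[str, dict] = {}
    hist_rows, box_rows = [], []
    for name, m in matrices.items():
        sample = similarity_sample(m)
        moment_summaries[name] = moments(sample).to_dict()
        counts, edges = histogram_data(sample)
        hist_rows.extend(
            {"measurement": name, "bin_left": float(edges[b]),
             "bin_right": float(edges[b + 1]), "count": int(counts[b])}
            for b in range(len(counts))
        )
        box_rows.append({"measurement": name, **boxplot_data(sample)})
    pd.DataFrame(moment_summaries).T.rename_axis("measurement").to_csv(
        outdir / "moments.tsv", sep="\t", float_format="%.6f"
    )
    pd.DataFrame(hist_rows).to_csv(outdir / "histograms.csv", index=False)
    pd.DataFrame(box_rows).to_csv(
        outdir / "boxplots.csv", index=False, float_format="%.6f"
    )

    # --- LOOCV on each measurement's own miRNA set (∩ association miRNAs)
    full_evals: dict[str, EvaluationSummary] = {}
    for name, m in matrices.items():
        (m_aligned,), (a_aligned,) = align_matrices([m], [assoc])
        full_evals[name] = _stage(f"loocv_full[{name}]")(
            loocv, m_aligned, a_aligned, cfg.k_list
        )

    # --- LOOCV on the common miRNA subset across all measurements
    common_matrices, (common_assoc,) = _stage("common_subset")(
        align_matrices, list(matrices.values()), [assoc]
    )
    common_evals = {
        name: _stage(f"loocv_common[{name}]")(loocv, cm, common_assoc, cfg.k_list)
        for name, cm in zip(matrices, common_matrices)
    }

    # --- paired significance tests
    reference = cfg.reference or _select_best(full_evals)
    full_tests: dict[str, dict[str, dict]] = {}
    common_tests: dict[str, dict[str, dict]] = {}
    if len(matrices) >= 2:
        for metric in ("roc_auc", "pr_auc"):
            full_tests[metric] = _pairwise_tests(full_evals, metric, reference)
            common_tests[metric] = _pairwise_tests(common_evals, metric, reference)
        _write_pvalue_table(full_tests, reference, outdir / "paired_tests_full.tsv")
        _write_pvalue_table(
            common_tests, reference, outdir / "paired_tests_common.tsv"
        )

    # --- novel predictions with the best measurement
    best = _select_best(full_evals)
    (best_m,), (best_a,) = align_matrices([matrices[best]], [assoc])
    novel = _stage("predict_novel")(predict_novel, best_m, best_a, cfg.top_n)
    pd.DataFrame(
        [
            {"mirna": p.mirna_id, "disease": p.disease_id,
             "score": p.score, "rank": p.rank}
            for p in novel
        ]
    ).to_csv(outdir / "novel_predictions.csv", index=False, float_format="%.6f")

    # --- per-miRNA curves and summaries
    for name, ev in full_evals.items():
        rows = [row for e in ev.per_mirna for row in e.curve_rows()]
        pd.DataFrame(rows).to_csv(
            outdir / f"curves_{name}.csv", index=False, float_format="%.6f"
        )
        (outdir / f"evaluation_{name}.json").write_text(
            json.dumps(ev.to_dict(), indent=2, sort_keys=True) + "\n"
        )

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "reference": reference,
        "best_measurement": best,
        "n_mirnas": {name: m.n for name, m in matrices.items()},
        "n_common_mirnas": common_matrices[0].n,
        "n_associations": len(assoc),
        "n_diseases": len(assoc.disease_ids),
        "skipped_mirnas": {
            name: list(ev.skipped) for name, ev in full_evals.items()
        },
        "mean_roc_auc": {
            name: ev.mean_roc_auc for name, ev in full_evals.items()
        },
        "mean_pr_auc": {name: ev.mean_pr_auc for name, ev in full_evals.items()},
        "mean_roc_auc_common": {
            name: ev.mean_roc_auc for name, ev in common_evals.items()
        },
        "mean_pr_auc_common": {
            name: ev.mean_pr_auc for name, ev in common_evals.items()
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return RunReport(
        config=cfg,
        matrices=matrices,
        moment_summaries=moment_summaries,
        full_evals=full_evals,
        common_evals=common_evals,
        full_tests=full_tests,
        common_tests=common_tests,
        best_measurement=best,
        novel_predictions=novel,
        manifest=manifest,
    )


def _pairwise_tests(
    evals: Mapping[str, EvaluationSummary], metric: str, reference: str
) -> dict[str, dict]:
    """Reference-vs-other paired tests; degenerate pairs are recorded,
    not fatal (identical measurements have zero-variance differences)."""
    from .errors import ComputationError

    out: dict[str, dict] = {}
    for name in evals:
        if name == reference:
            continue
        try:
            res = compare_measurements(
                {reference: evals[reference], name: evals[name]},
                metric=metric, reference=reference,
            )
            out[name] = res[name].to_dict()
        except ComputationError as exc:
            logger.warning("paired test %s vs %s (%s): %s",
                           reference, name, metric, exc)
            out[name] = {"degenerate": str(exc), "p_value": float("nan")}
    return out


def _write_pvalue_table(
    tests: dict[str, dict[str, dict]], reference: str, path: Path
) -> None:
    rows = []
    for metric, per_name in tests.items():
        row = {"metric": metric, "reference": reference}
        for name, res in per_name.items():
            row[name] = res["p_value"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    with open(path, "a") as fh:
        fh.write("# one-sided paired t-tests; raw p-values, no "
                "multiple-testing correction\n")
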