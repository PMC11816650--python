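"""End-to-end evaluation: load, preprocess, measure, score, aggregate, report.

One :func:`evaluate` call takes a multi-omics dataset, a clinical table and
two or more cluster assignments (one per subtyping method), and produces an
:class:`EvaluationReport` with the raw metrics, the harmonized 0-10
scoreboard, AWA values and the ranking. Score harmonization is per dataset:
methods are compared within one cohort; :func:`compare_reports` aggregates
across cohorts by averaging AWA, never raw metrics.

Reports serialize to JSON (losslessly, including +inf sentinels) and to a TSV
scoreboard. Re-running with identical inputs and config yields byte-identical
report content; only the embedded timestamp differs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import clinical_metrics as cm
from . import internal_metrics as im
from .data_io import (
    ClinicalTable,
    ClusterAssignment,
    DataValidationError,
    OmicsDataset,
    OmicsKind,
    align_and_validate,
    read_clinical_table,
    read_cluster_assignment,
    read_omics_matrix,
    read_yaml,
)
from .preprocess import PreprocessConfig, preprocess_dataset
from .scoring import AWAConfig, METRICS, AWAResult, ScoreBoard, build_scoreboard, rank_and_sweep

logger = logging.getLogger("subtype_awa")


@dataclass
class EvalConfig:
    """One evaluation run's knobs: AWA weights, enrichment level alpha, the
    internal-metric representation strategy, preprocessing thresholds and an
    optional weight sweep."""

    w1: float = 0.5
    w2: float = 0.5
    alpha: float = 0.05
    representation: str = im.CONCATENATE
    adjust: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sweep_weights: list[tuple[float, float]] | None = None
    skip_preprocess: bool = False

    @classmethod
    def from_dict(cls, d: Mapping) -> "EvalConfig":
        d = dict(d)
        pp = PreprocessConfig(**d.pop("preprocess", {}))
        sweep = d.pop("sweep_weights", None)
        if sweep is not None:
            sweep = [tuple(map(float, w)) for w in sweep]
        return cls(preprocess=pp, sweep_weights=sweep, **d)

    def to_dict(self) -> dict:
        out = asdict(self)
        if out["sweep_weights"] is not None:
            out["sweep_weights"] = [list(w) for w in out["sweep_weights"]]
        return out


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


@dataclass
class EvaluationReport:
    dataset_name: str
    config: dict
    raw_metrics: dict[str, dict[str, float]]
    per_covariate_p: dict[str, dict[str, float]]
    scores: dict[str, dict[str, float]]
    internal_avg: dict[str, float]
    clinical_avg: dict[str, float]
    awa: dict[str, float]
    ranking: list[str]
    runtime_s: dict[str, float | None]
    sweep: list[dict] | None
    dropped_samples: dict[str, list[str]]
    warnings: list[str]
    timestamp: str = ""

    def content_dict(self) -> dict:
        """Report content with the timestamp excluded (determinism checks)."""
        d = asdict(self)
        d.pop("timestamp")
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EvaluationReport":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            source = Path(source).read_text(encoding="utf-8")
        return cls(**json.loads(source))

    def scoreboard_frame(self) -> pd.DataFrame:
        """Methods x metrics TSV-ready table: raw values, scores, AWA, rank."""
        rows = []
        for m in self.ranking:
            row: dict[str, object] = {"method": m}
            row.update({f"raw_{k}": self.raw_metrics[m][k] for k in METRICS})
            row.update({f"score_{k}": self.scores[m][k] for k in METRICS})
            row["internal_avg"] = self.internal_avg[m]
            row["clinical_avg"] = self.clinical_avg[m]
            row["AWA"] = self.awa[m]
            row["runtime_s"] = self.runtime_s.get(m)
            rows.append(row)
        return pd.DataFrame(rows).set_index("method")


def evaluate(
    dataset: OmicsDataset,
    clinical: ClinicalTable,
    assignments: Sequence[ClusterAssignment],
    config: EvalConfig | None = None,
) -> EvaluationReport:
    """Run the full evaluation for >= 2 methods on one dataset."""
    config = config or EvalConfig()
    if len(assignments) < 2:
        raise DataValidationError(
            "evaluation needs assignments from at least 2 methods: "
            "score harmonization is a cross-method min-max rescale"
        )
    names = [a.method_name for a in assignments]
    if len(set(names)) != len(names):
        raise DataValidationError(f"duplicate method names: {names}")

    collector = _WarningCollector()
    logger.addHandler(collector)
    try:
        t0 = time.perf_counter()
        aligned = align_and_validate(dataset, clinical, assignments)
        logger.info("stage align_and_validate: %.3fs", time.perf_counter() - t0)

        t0 = time.perf_counter()
        data = aligned.dataset if config.skip_preprocess else preprocess_dataset(
            aligned.dataset, config.preprocess
        )
        logger.info("stage preprocess: %.3fs", time.perf_counter() - t0)

        raw_rows: dict[str, dict[str, float]] = {}
        per_cov: dict[str, dict[str, float]] = {}
        runtimes: dict[str, float | None] = {}
        for assign in aligned.assignments:
            t0 = time.perf_counter()
            try:
                internal = im.compute_internal_metrics(data, assign, config.representation)
                clin = cm.evaluate_clinical(aligned.clinical, assign, config.alpha, config.adjust)
            except DataValidationError as exc:
                raise DataValidationError(
                    f"metric stage failed for method {assign.method_name!r}: {exc}"
                ) from exc
            raw_rows[assign.method_name] = {
                "S": internal.S, "CH": internal.CH, "D": internal.D,
                "LRT": clin.lrt_p, "ECP": float(clin.ecp),
            }
            per_cov[assign.method_name] = clin.per_covariate_p
            runtimes[assign.method_name] = assign.runtime_s
            logger.info("stage metrics[%s]: %.3fs", assign.method_name, time.perf_counter() - t0)

        raw = pd.DataFrame.from_dict(raw_rows, orient="index").loc[names]
        board = build_scoreboard(raw, runtimes)
        result = rank_and_sweep(board, AWAConfig(config.w1, config.w2), config.sweep_weights)
    finally:
        logger.removeHandler(collector)

    sweep_rows = None
    if result.sweep is not None:
        sweep_rows = [
            {"w1": w1, "w2": w2, **{m: float(v) for m, v in row.items()}}
            for (w1, w2), row in result.sweep.iterrows()
        ]
    return EvaluationReport(
        dataset_name=dataset.name,
        config=config.to_dict(),
        raw_metrics={m: {k: float(v) for k, v in r.items()} for m, r in raw_rows.items()},
        per_covariate_p={m: {k: float(v) for k, v in d.items()} for m, d in per_cov.items()},
        scores={m: {k: float(board.scores.loc[m, k]) for k in METRICS} for m in names},
        internal_avg={m: float(board.internal_avg[m]) for m in names},
        clinical_avg={m: float(board.clinical_avg[m]) for m in names},
        awa={m: float(v) for m, v in result.awa.items()},
        ranking=result.ranking,
        runtime_s=result.runtime_s,
        sweep=sweep_rows,
        dropped_samples=aligned.dropped,
        warnings=collector.messages,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )


def load_dataset_config(path: str | Path) -> tuple[OmicsDataset, ClinicalTable]:
    """Read a dataset YAML: name, mapping of omics kind -> TSV path, clinical path."""
    path = Path(path)
    cfg = read_yaml(path)
    base = path.parent
    matrices = {}
    for kind, rel in cfg["omics"].items():
        k = OmicsKind(kind)
        matrices[k] = read_omics_matrix(base / rel, k)
    dataset = OmicsDataset(cfg.get("name", path.stem), matrices)
    clinical = read_clinical_table(base / cfg["clinical"])
    return dataset, clinical


def evaluate_paths(
    dataset_yaml: str | Path,
    assignment_paths: Sequence[str | Path],
    config: EvalConfig | None = None,
) -> EvaluationReport:
    dataset, clinical = load_dataset_config(dataset_yaml)
    assignments = [read_cluster_assignment(p) for p in assignment_paths]
    return evaluate(dataset, clinical, assignments, config)


def compare_reports(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Per-method mean AWA across datasets, with the overall ranking.

    All reports must cover the same method set; the result is invariant to
    the order of the reports.
    """
    if not reports:
        raise DataValidationError("compare_reports needs at least one report")
    methods = set(reports[0].awa)
    for r in reports[1:]:
        if set(r.awa) != methods:
            missing = methods.symmetric_difference(r.awa)
            raise DataValidationError(
                f"method sets differ between reports (dataset {r.dataset_name!r}): {sorted(missing)}"
            )
    cols = {r.dataset_name: pd.Series(r.awa) for r in sorted(reports, key=lambda r: r.dataset_name)}
    table = pd.DataFrame(cols)
    table["mean_AWA"] = table.mean(axis=1)
    order = sorted(table.index, key=lambda m: (-table.loc[m, "mean_AWA"], m))
    table = table.loc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    return table
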