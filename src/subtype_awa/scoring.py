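"""Cross-method score harmonization and the accuracy-weighted average (AWA).

Raw metric values are not comparable across metrics (a Calinski-Harabasz
index of 200 and a log-rank p of 0.008 live on different scales), so each
metric is first *oriented* so that larger is better and then min-max rescaled
across the evaluated methods onto a common 0-10 score scale. The five
harmonized scores S_S, S_CH, S_D, S_LRT, S_ECP are then combined as

    AWA = ((S_S + S_CH + S_D) * w1 + (S_LRT + S_ECP) * w2) / (3*w1 + 2*w2)

with w1 weighting the three internal scores and w2 the two clinical ones
(default w1 = w2 = 0.5, i.e. internal and clinical evidence count equally).
AWA is a weighted mean, so it always lies between the smallest and largest of
the five scores, and at equal weights reduces to (3*I + 2*C)/5 where I and C
are the internal and clinical score averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import DataValidationError

logger = logging.getLogger("subtype_awa")

#: Metric identifiers in fixed column order. "LRT" is carried as the raw
#: log-rank p-value and oriented via -log10 before scoring.
METRICS: tuple[str, ...] = ("S", "CH", "D", "LRT", "ECP")
INTERNAL_METRICS: tuple[str, ...] = ("S", "CH", "D")
CLINICAL_METRICS: tuple[str, ...] = ("LRT", "ECP")

P_FLOOR = 1e-300  # guards -log10 against numerically underflowed p-values


@dataclass
class AWAConfig:
    """Weights of the internal (w1) and clinical (w2) score blocks."""

    w1: float = 0.5
    w2: float = 0.5

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise DataValidationError("weights must be nonnegative")
        if self.w1 + self.w2 == 0:
            raise DataValidationError("w1 + w2 must be positive")


@dataclass
class ScoreBoard:
    """Raw metric values and harmonized 0-10 scores for a set of methods."""

    methods: list[str]
    raw: pd.DataFrame      # methods x (S, CH, D, LRT [p-value], ECP)
    scores: pd.DataFrame   # methods x metrics, each in [0, 10]
    runtimes: dict[str, float | None] = field(default_factory=dict)

    @property
    def internal_avg(self) -> pd.Series:
        return self.scores[list(INTERNAL_METRICS)].mean(axis=1)

    @property
    def clinical_avg(self) -> pd.Series:
        return self.scores[list(CLINICAL_METRICS)].mean(axis=1)


@dataclass
class AWAResult:
    awa: dict[str, float]
    ranking: list[str]
    runtime_s: dict[str, float | None]
    sweep: pd.DataFrame | None = None


def orient_metric(values: Sequence[float], metric: str) -> np.ndarray:
    """Orient raw metric values so larger = better.

    S, CH, D and ECP have optimum "maximum" and pass through. LRT's optimum
    is a minimal p-value, so p is mapped to -log10(p) with p floored at
    1e-300. +inf sentinels (degenerate geometry) are replaced by the largest
    finite value plus one step, keeping them the best without breaking the
    min-max rescale.
    """
    if metric not in METRICS:
        raise DataValidationError(f"unknown metric {metric!r}")
    vals = np.asarray(values, dtype=float)
    if metric == "LRT":
        vals = -np.log10(np.maximum(vals, P_FLOOR))
    if np.isposinf(vals).any():
        finite = vals[np.isfinite(vals)]
        top = float(finite.max()) + 1.0 if finite.size else 1.0
        vals = np.where(np.isposinf(vals), top, vals)
    return vals


def normalize_to_scores(oriented: Sequence[float]) -> np.ndarray:
    """Min-max rescale oriented values across methods onto [0, 10].

    With at least two distinct values the best method scores 10 and the worst
    0; when all methods tie, every method receives the neutral score 5.
    """
    vals = np.asarray(oriented, dtype=float)
    if vals.size < 2:
        raise DataValidationError("score normalization needs at least 2 methods")
    if not np.isfinite(vals).all():
        raise DataValidationError("non-finite value after metric orientation")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return np.full(vals.shape, 5.0)
    return np.clip(10.0 * (vals - lo) / (hi - lo), 0.0, 10.0)


def build_scoreboard(
    raw: pd.DataFrame,
    runtimes: Mapping[str, float | None] | None = None,
) -> ScoreBoard:
    """Harmonize a methods x metrics table of raw values into 0-10 scores.

    ``raw`` must have one row per method and the columns S, CH, D, LRT (the
    log-rank p-value) and ECP.
    """
    missing = [m for m in METRICS if m not in raw.columns]
    if missing:
        raise DataValidationError(f"raw metric table missing columns {missing}")
    raw = raw[list(METRICS)].astype(float)
    scores = pd.DataFrame(
        {m: normalize_to_scores(orient_metric(raw[m].to_numpy(), m)) for m in METRICS},
        index=raw.index,
    )
    methods = [str(m) for m in raw.index]
    rt = {m: (runtimes or {}).get(m) for m in methods}
    return ScoreBoard(methods, raw, scores, rt)


def compute_awa(scores: Sequence[float] | Mapping[str, float], cfg: AWAConfig | None = None) -> float:
    """AWA for one method from its five harmonized scores.

    ``scores`` is either the 5-vector (S_S, S_CH, S_D, S_LRT, S_ECP) or a
    mapping keyed by metric id. All scores must lie in [0, 10].
    """
    cfg = cfg or AWAConfig()
    if isinstance(scores, Mapping):
        vec = [float(scores[m]) for m in METRICS]
    else:
        vec = [float(v) for v in scores]
    if len(vec) != 5:
        raise DataValidationError(f"AWA needs exactly 5 scores, got {len(vec)}")
    if any(not 0 <= v <= 10 for v in vec):
        raise DataValidationError(f"scores must lie in [0,10], got {vec}")
    s_s, s_ch, s_d, s_lrt, s_ecp = vec
    return ((s_s + s_ch + s_d) * cfg.w1 + (s_lrt + s_ecp) * cfg.w2) / (3 * cfg.w1 + 2 * cfg.w2)


def rank_and_sweep(
    board: ScoreBoard,
    cfg: AWAConfig | None = None,
    sweep_weights: Sequence[tuple[float, float]] | None = None,
) -> AWAResult:
    """AWA per method at the configured weights, a deterministic ranking, and
    an optional weight-sweep table.

    Ranking is by descending AWA; ties are broken by descending internal
    score average, then by method name, so output files are reproducible.
    """
    cfg = cfg or AWAConfig()
    if not board.methods:
        raise DataValidationError("scoreboard has no methods")
    awa = {
        m: compute_awa(board.scores.loc[m, list(METRICS)].to_numpy(), cfg)
        for m in board.methods
    }
    internal = board.internal_avg
    ranking = sorted(board.methods, key=lambda m: (-awa[m], -internal[m], m))
    sweep = None
    if sweep_weights:
        rows = {}
        for (w1, w2) in sweep_weights:
            c = AWAConfig(w1, w2)
            rows[(w1, w2)] = {
                m: compute_awa(board.scores.loc[m, list(METRICS)].to_numpy(), c)
                for m in board.methods
            }
        sweep = pd.DataFrame.from_dict(rows, orient="index")
        sweep.index.names = ["w1", "w2"]
    return AWAResult(awa, ranking, dict(board.runtimes), sweep)
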