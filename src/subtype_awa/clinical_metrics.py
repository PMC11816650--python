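"""Clinical relevance of a subtyping: survival separation and covariate enrichment.

Two metrics:

* LRT — the k-sample (unstratified) log-rank test comparing overall survival
  across subtypes; reported as the chi-square statistic (k - 1 df) and its
  p-value. Smaller p = stronger clinical separation.
* ECP — the number of clinical covariates significantly associated with the
  subtype labels: Pearson chi-square (no continuity correction) for discrete
  covariates, Kruskal-Wallis for numeric ones, counted at level alpha
  (default 0.05, uncorrected; Benjamini-Hochberg optionally).

Missing data are dropped per test (pairwise deletion): samples without
survival are excluded from LRT only, samples missing a covariate are excluded
from that covariate's test only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .data_io import DISCRETE, NUMERIC, ClinicalTable, ClusterAssignment, Covariate, DataValidationError

logger = logging.getLogger("subtype_awa")


@dataclass
class ClinicalMetricResult:
    lrt_statistic: float
    lrt_p: float
    per_covariate_p: dict[str, float]
    ecp: int
    alpha: float


def logrank_groups(times: np.ndarray, events: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """k-sample log-rank test on raw arrays; returns (chi2 statistic, p-value).

    Standard risk-set observed-minus-expected construction with simultaneous
    accounting of tied event times; k - 1 degrees of freedom.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if len(set(groups.tolist())) < 2:
        raise DataValidationError("log-rank test needs at least 2 groups with survival data")
    if events.sum() == 0:
        logger.warning("logrank: no observed events in any group, returning p = 1")
        return 0.0, 1.0
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def logrank_test(clinical: ClinicalTable, assign: ClusterAssignment) -> tuple[float, float]:
    """Log-rank comparison of survival across the assignment's subtypes.

    Samples with missing survival time or event indicator are dropped with a
    warning; it is an error if fewer than two subtypes remain.
    """
    order = [s for s in clinical.sample_ids if s in assign.labels]
    if not order:
        raise DataValidationError("no overlap between clinical table and assignment")
    idx = [clinical.sample_ids.index(s) for s in order]
    times = clinical.survival_time[idx]
    events = clinical.event[idx]
    labels = assign.labels_for(order)
    ok = ~np.isnan(times) & ~np.isnan(events)
    if not ok.all():
        logger.warning(
            "logrank_test(%s): dropping %d sample(s) with missing survival",
            assign.method_name, int((~ok).sum()),
        )
    return logrank_groups(times[ok], events[ok].astype(int), labels[ok])


def covariate_enrichment(values, kind: str, labels) -> float:
    """Association p-value between one clinical covariate and the subtype labels.

    Discrete covariates: Pearson chi-square test of independence on the
    clusters x categories contingency table, no continuity correction (a
    warning is logged when any expected count falls below 5). Numeric
    covariates: Kruskal-Wallis rank test across clusters. Missing covariate
    values are dropped pairwise. A covariate with a single observed category
    (or constant values) gives p = 1; an all-missing covariate gives NaN and
    is excluded from the ECP denominator.
    """
    labels = np.asarray(labels)
    if kind == NUMERIC:
        vals = np.asarray(values, dtype=float)
        ok = ~np.isnan(vals)
    elif kind == DISCRETE:
        vals = np.asarray(list(values), dtype=object)
        ok = np.asarray([v is not None and not (isinstance(v, float) and np.isnan(v)) for v in vals])
    else:
        raise DataValidationError(f"unknown covariate kind {kind!r}")
    if not ok.any():
        logger.warning("covariate_enrichment: covariate entirely missing, excluded from ECP")
        return float("nan")
    if not ok.all():
        logger.warning("covariate_enrichment: dropping %d missing value(s)", int((~ok).sum()))
    vals, labels = vals[ok], labels[ok]

    if kind == DISCRETE:
        table = pd.crosstab(labels, vals.astype(str))
        if table.shape[0] < 2 or table.shape[1] < 2:
            logger.warning("covariate_enrichment: single observed category/cluster, p = 1")
            return 1.0
        chi2, p, _, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
        if (expected < 5).any():
            logger.warning("covariate_enrichment: chi-square expected count < 5 in some cell")
        return float(p)

    groups = [vals[labels == g] for g in sorted(set(labels.tolist()))]
    if len(groups) < 2 or np.ptp(vals) == 0:
        logger.warning("covariate_enrichment: constant numeric covariate, p = 1")
        return 1.0
    try:
        _, p = stats.kruskal(*groups)
    except ValueError:  # all numbers identical
        return 1.0
    return float(p)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def evaluate_clinical(
    clinical: ClinicalTable,
    assign: ClusterAssignment,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> ClinicalMetricResult:
    """LRT and ECP for one assignment.

    ``adjust="bh"`` applies Benjamini-Hochberg across the covariates before
    counting (off by default). Raw per-covariate p-values are always retained.
    """
    if not 0 < alpha < 1:
        raise DataValidationError(f"alpha must be in (0,1), got {alpha}")
    stat, p = logrank_test(clinical, assign)
    order = [s for s in clinical.sample_ids if s in assign.labels]
    idx = [clinical.sample_ids.index(s) for s in order]
    labels = assign.labels_for(order)
    per_cov: dict[str, float] = {}
    for name, cov in clinical.covariates.items():
        per_cov[name] = covariate_enrichment(cov.values[idx], cov.kind, labels)
    names = [n for n, pv in per_cov.items() if not np.isnan(pv)]
    pvals = np.asarray([per_cov[n] for n in names])
    if adjust == "bh" and len(pvals):
        counted = _bh_adjust(pvals)
    elif adjust in (None, "none"):
        counted = pvals
    else:
        raise DataValidationError(f"unknown adjustment {adjust!r}")
    ecp = int((counted < alpha).sum())
    return ClinicalMetricResult(stat, p, per_cov, ecp, alpha)


def ecp_count(
    clinical: ClinicalTable,
    assign: ClusterAssignment,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> int:
    """Number of clinical covariates enriched across subtypes at level alpha."""
    return evaluate_clinical(clinical, assign, alpha, adjust).ecp
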