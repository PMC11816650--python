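"""Internal cluster-validity indices: silhouette, Calinski-Harabasz, Dunn.

These measure a subtyping purely from intra-cluster compactness and
inter-cluster separation, with Euclidean distances on a standardized sample
representation. The representation is either the horizontal concatenation of
all preprocessed omics layers (default) or a per-omics computation whose
metric values are averaged.

Degenerate geometries yield +inf sentinels (with a warning) instead of
errors, so the downstream scoring layer can still rank methods:
Calinski-Harabasz when every cluster is a point mass, Dunn when every cluster
is a singleton.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data_io import ClusterAssignment, DataValidationError, OmicsDataset

logger = logging.getLogger("subtype_awa")

CONCATENATE = "concatenate"
PER_OMICS_MEAN = "per_omics_mean"


@dataclass
class InternalMetricResult:
    S: float
    CH: float
    D: float


def build_representation(dataset: OmicsDataset, strategy: str = CONCATENATE):
    """Sample representation for internal metrics.

    ``concatenate`` returns one samples x (sum of widths) matrix with omics
    stacked in a fixed kind order; ``per_omics_mean`` returns the list of
    per-omics matrices (metrics are computed per omics and averaged).
    """
    mats = [dataset.matrices[k].values for k in dataset.kinds_in_order()]
    if strategy == CONCATENATE:
        return np.hstack(mats)
    if strategy == PER_OMICS_MEAN:
        return mats
    raise DataValidationError(f"unknown representation strategy {strategy!r}")


def _as_labels(assign, rep_n: int, sample_ids: Sequence[str] | None) -> np.ndarray:
    if isinstance(assign, ClusterAssignment):
        if sample_ids is None:
            raise DataValidationError(
                "passing a ClusterAssignment requires sample_ids giving the row order"
            )
        labels = assign.labels_for(sample_ids)
    else:
        labels = np.asarray(assign, dtype=int)
    if labels.shape != (rep_n,):
        raise DataValidationError(
            f"labels length {labels.shape} does not match {rep_n} representation rows"
        )
    return labels


def _check_k(labels: np.ndarray, need_n_gt_k: bool) -> list[int]:
    ks = sorted(set(labels.tolist()))
    if len(ks) < 2:
        raise DataValidationError("internal metrics undefined for a single cluster")
    if need_n_gt_k and len(labels) <= len(ks):
        raise DataValidationError("internal metrics need more samples than clusters")
    return ks


def silhouette(rep: np.ndarray, assign, sample_ids: Sequence[str] | None = None) -> float:
    """Mean silhouette coefficient, in [-1, 1].

    Per sample, a = mean distance to the other members of its own cluster and
    b = mean distance to the nearest other cluster; the sample's width is
    (b - a) / max(a, b). Samples in singleton clusters contribute 0, as do
    samples with a = b = 0 (duplicate points).
    """
    rep = np.asarray(rep, dtype=float)
    labels = _as_labels(assign, rep.shape[0], sample_ids)
    ks = _check_k(labels, need_n_gt_k=True)
    dist = squareform(pdist(rep))
    n = rep.shape[0]
    members = {k: np.nonzero(labels == k)[0] for k in ks}
    widths = np.zeros(n)
    for i in range(n):
        own = members[labels[i]]
        if own.size < 2:
            continue  # singleton convention: s_i = 0
        a = dist[i, own].sum() / (own.size - 1)
        b = min(dist[i, members[k]].mean() for k in ks if k != labels[i])
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(widths.mean())


def calinski_harabasz(rep: np.ndarray, assign, sample_ids: Sequence[str] | None = None) -> float:
    """Calinski-Harabasz index: (tr(B_k) * (n - k)) / (tr(W_k) * (k - 1)).

    tr(B_k) = sum_c n_c * ||mean_c - mean||^2 (between-cluster scatter trace),
    tr(W_k) = sum_c sum_{i in c} ||x_i - mean_c||^2 (within-cluster scatter
    trace). Returns +inf with a warning when every cluster is a point mass.
    """
    rep = np.asarray(rep, dtype=float)
    labels = _as_labels(assign, rep.shape[0], sample_ids)
    ks = _check_k(labels, need_n_gt_k=True)
    n, k = rep.shape[0], len(ks)
    overall = rep.mean(axis=0)
    tr_b = 0.0
    tr_w = 0.0
    for c in ks:
        pts = rep[labels == c]
        mean_c = pts.mean(axis=0)
        tr_b += pts.shape[0] * float(np.sum((mean_c - overall) ** 2))
        tr_w += float(np.sum((pts - mean_c) ** 2))
    if tr_w == 0.0:
        logger.warning("calinski_harabasz: zero within-cluster scatter, returning +inf")
        return float("inf")
    return (tr_b * (n - k)) / (tr_w * (k - 1))


def dunn_index(rep: np.ndarray, assign, sample_ids: Sequence[str] | None = None) -> float:
    """Dunn's index: min inter-cluster single-linkage distance / max cluster diameter.

    The inter-cluster distance d(C_i, C_j) is the minimum pairwise distance
    between members (single linkage); the diameter is the maximum intra-
    cluster pairwise distance. Returns +inf with a warning when all clusters
    are singletons (maximum diameter 0).
    """
    rep = np.asarray(rep, dtype=float)
    labels = _as_labels(assign, rep.shape[0], sample_ids)
    ks = _check_k(labels, need_n_gt_k=False)
    dist = squareform(pdist(rep))
    members = {k: np.nonzero(labels == k)[0] for k in ks}
    max_diam = 0.0
    for idx in members.values():
        if idx.size > 1:
            max_diam = max(max_diam, float(dist[np.ix_(idx, idx)].max()))
    min_inter = min(
        float(dist[np.ix_(members[a], members[b])].min())
        for i, a in enumerate(ks)
        for b in ks[i + 1:]
    )
    if max_diam == 0.0:
        logger.warning("dunn_index: all clusters are singletons, returning +inf")
        return float("inf")
    return min_inter / max_diam


def compute_internal_metrics(
    dataset: OmicsDataset,
    assign: ClusterAssignment,
    strategy: str = CONCATENATE,
) -> InternalMetricResult:
    """All three indices on a preprocessed dataset for one assignment."""
    labels = assign.labels_for(dataset.sample_ids)
    rep = build_representation(dataset, strategy)
    reps = [rep] if strategy == CONCATENATE else rep
    vals = np.asarray(
        [
            [silhouette(r, labels), calinski_harabasz(r, labels), dunn_index(r, labels)]
            for r in reps
        ]
    )
    s, ch, d = vals.mean(axis=0)
    return InternalMetricResult(float(s), float(ch), float(d))
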