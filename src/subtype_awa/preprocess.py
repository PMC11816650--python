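"""Per-omics preprocessing: deduplication, filtering, imputation, normalization.

Each omics kind gets its own pipeline, applied feature-wise so the sample set
and its order never change:

* copy number      — drop duplicate regions (identical value vectors);
* DNA methylation  — keep probes whose mean beta >= a threshold (default 0.3);
* mRNA / miRNA     — log2(x + 1), then drop the lowest-MAD fraction of
                     features, then drop features at or below a variance
                     threshold (the step order is part of the contract);
* (phospho)proteomics — drop features with > 50% missing values, impute the
                     rest with the feature mean, keep the top-MAD features,
                     and median-center each sample.

All kinds finish with :func:`impute_and_standardize`: remaining missing
entries are imputed with the sample (row) mean within the omics, then each
feature is centered and scaled to unit (population) variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import DataValidationError, OmicsDataset, OmicsKind, OmicsMatrix

logger = logging.getLogger("subtype_awa")

SAMPLE_MEAN = "sample_mean"
FEATURE_MEAN = "feature_mean"


@dataclass
class PreprocessConfig:
    """Tunable preprocessing thresholds.

    beta_threshold        minimum mean beta for a methylation probe to be kept
    mad_quantile          fraction of lowest-MAD features removed (0.5 = half)
    variance_threshold    features with variance <= this are removed
    missing_fraction_max  proteomics features with a larger missing fraction
                          are dropped (strictly greater)
    log_offset            pseudo-count in log2(x + offset)
    imputation            "sample_mean" (row mean, default) or "feature_mean"
    """

    beta_threshold: float = 0.3
    mad_quantile: float = 0.5
    variance_threshold: float = 0.0
    missing_fraction_max: float = 0.5
    log_offset: float = 1.0
    imputation: str = SAMPLE_MEAN

    def __post_init__(self) -> None:
        if not 0.0 <= self.mad_quantile <= 1.0:
            raise DataValidationError(f"mad_quantile must be in [0,1], got {self.mad_quantile}")
        if self.variance_threshold < 0:
            raise DataValidationError("variance_threshold must be nonnegative")
        if not 0.0 <= self.missing_fraction_max <= 1.0:
            raise DataValidationError("missing_fraction_max must be in [0,1]")
        if self.log_offset <= 0:
            raise DataValidationError("log_offset must be positive")
        if self.imputation not in (SAMPLE_MEAN, FEATURE_MEAN):
            raise DataValidationError(f"unknown imputation strategy {self.imputation!r}")


def dedup_copy_number(m: OmicsMatrix) -> OmicsMatrix:
    """Drop duplicate copy-number regions, keeping the first of each group.

    Two features are duplicates when their value vectors are identical across
    all samples (missing entries compare equal to missing).
    """
    if m.omics_kind is not OmicsKind.COPY_NUMBER:
        raise DataValidationError("dedup_copy_number expects a copy_number matrix")
    seen: dict[bytes, int] = {}
    keep: list[int] = []
    canon = np.nan_to_num(m.values, nan=np.inf)  # one fixed bit pattern for NaN
    for j in range(m.n_features):
        key = canon[:, j].tobytes() + m.missing_mask[:, j].tobytes()
        if key not in seen:
            seen[key] = j
            keep.append(j)
    removed = m.n_features - len(keep)
    if removed:
        logger.info("dedup_copy_number: removed %d duplicate features", removed)
    return m.select_features(keep)


def filter_methylation(m: OmicsMatrix, cfg: PreprocessConfig | None = None) -> OmicsMatrix:
    """Keep methylation probes whose mean beta (over non-missing samples) >= threshold.

    The boundary is inclusive. Probes with no observed values are dropped with
    a warning.
    """
    cfg = cfg or PreprocessConfig()
    if m.omics_kind is not OmicsKind.METHYLATION:
        raise DataValidationError("filter_methylation expects a methylation matrix")
    obs = ~m.missing_mask
    counts = obs.sum(axis=0)
    sums = np.where(obs, m.values, 0.0).sum(axis=0)
    means = np.divide(sums, counts, out=np.full(m.n_features, np.nan), where=counts > 0)
    all_missing = np.isnan(means)
    if all_missing.any():
        names = [m.feature_ids[j] for j in np.nonzero(all_missing)[0]]
        logger.warning("filter_methylation: dropping all-missing probes %s", names)
    keep = [j for j in range(m.n_features) if not all_missing[j] and means[j] >= cfg.beta_threshold]
    logger.info("filter_methylation: kept %d of %d probes", len(keep), m.n_features)
    return m.select_features(keep)


def _feature_mad(values: np.ndarray) -> np.ndarray:
    """Per-feature median absolute deviation, ignoring missing entries."""
    with np.errstate(invalid="ignore"):
        med = np.nanmedian(values, axis=0)
        return np.nanmedian(np.abs(values - med), axis=0)


def _feature_variance(values: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.nanvar(values, axis=0)  # population (1/n) variance


def _drop_lowest_mad(m: OmicsMatrix, mad_quantile: float) -> OmicsMatrix:
    """Remove the floor(mad_quantile * p) lowest-MAD features, ties broken by input order."""
    n_remove = int(np.floor(mad_quantile * m.n_features))
    if n_remove == 0:
        return m
    mad = _feature_mad(m.values)
    order = np.argsort(mad, kind="stable")
    removed = set(order[:n_remove].tolist())
    keep = [j for j in range(m.n_features) if j not in removed]
    logger.info("MAD filter: removed %d of %d features", n_remove, m.n_features)
    return m.select_features(keep)


def preprocess_expression(m: OmicsMatrix, cfg: PreprocessConfig | None = None) -> OmicsMatrix:
    """mRNA/miRNA pipeline: log2 transform, MAD filter, variance filter — in that order."""
    cfg = cfg or PreprocessConfig()
    if m.omics_kind not in (OmicsKind.MRNA, OmicsKind.MIRNA):
        raise DataValidationError("preprocess_expression expects an mrna or mirna matrix")
    neg = np.nonzero(~m.missing_mask & (m.values < 0))
    if neg[0].size:
        r, c = int(neg[0][0]), int(neg[1][0])
        raise DataValidationError(
            f"negative expression value at (sample {m.sample_ids[r]!r}, "
            f"feature {m.feature_ids[c]!r}): {m.values[r, c]}"
        )
    with np.errstate(invalid="ignore"):
        logged = m.with_values(np.log2(m.values + cfg.log_offset))
    filtered = _drop_lowest_mad(logged, cfg.mad_quantile)
    var = _feature_variance(filtered.values)
    keep = [j for j in range(filtered.n_features) if var[j] > cfg.variance_threshold]
    if len(keep) < filtered.n_features:
        logger.info(
            "variance filter: removed %d of %d features",
            filtered.n_features - len(keep), filtered.n_features,
        )
    return filtered.select_features(keep)


def preprocess_proteomics(m: OmicsMatrix, cfg: PreprocessConfig | None = None) -> OmicsMatrix:
    """(Phospho)proteomics pipeline: missingness filter, mean imputation, MAD
    selection, per-sample median normalization."""
    cfg = cfg or PreprocessConfig()
    if m.omics_kind not in (OmicsKind.PROTEOMICS, OmicsKind.PHOSPHOPROTEOMICS):
        raise DataValidationError("preprocess_proteomics expects a (phospho)proteomics matrix")
    frac = m.missing_mask.mean(axis=0)
    keep = [j for j in range(m.n_features) if frac[j] <= cfg.missing_fraction_max]
    if len(keep) < m.n_features:
        logger.info(
            "missingness filter: removed %d of %d features",
            m.n_features - len(keep), m.n_features,
        )
    m = m.select_features(keep)
    vals = m.values.copy()
    mask = np.isnan(vals)
    if mask.any():
        with np.errstate(invalid="ignore"):
            col_means = np.nanmean(vals, axis=0)
        vals[mask] = np.take(col_means, np.nonzero(mask)[1])
    m = m.with_values(vals)
    m = _drop_lowest_mad(m, cfg.mad_quantile)
    med = np.median(m.values, axis=1, keepdims=True)
    return m.with_values(m.values - med)


def impute_and_standardize(m: OmicsMatrix, strategy: str = SAMPLE_MEAN) -> OmicsMatrix:
    """Impute missing entries, then z-score each feature (population variance).

    The default imputation replaces a missing entry with the mean of that
    sample's observed values within the omics; ``feature_mean`` uses the
    feature's mean instead. Constant features become all-zero columns with a
    warning rather than being dropped.
    """
    if m.n_samples < 2:
        raise DataValidationError("impute_and_standardize needs at least 2 samples")
    vals = m.values.astype(float).copy()
    mask = np.isnan(vals)
    if mask.any():
        if strategy == SAMPLE_MEAN:
            bad = np.nonzero(mask.all(axis=1))[0]
            if bad.size:
                raise DataValidationError(
                    f"sample {m.sample_ids[int(bad[0])]!r} has no observed values "
                    f"in omics {m.omics_kind.value}"
                )
            row_means = np.nanmean(vals, axis=1)
            vals[mask] = np.take(row_means, np.nonzero(mask)[0])
        elif strategy == FEATURE_MEAN:
            with np.errstate(invalid="ignore"):
                col_means = np.nanmean(vals, axis=0)
            col_means = np.nan_to_num(col_means, nan=0.0)
            vals[mask] = np.take(col_means, np.nonzero(mask)[1])
        else:
            raise DataValidationError(f"unknown imputation strategy {strategy!r}")
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0)  # ddof=0
    constant = sd == 0
    if constant.any():
        logger.warning(
            "impute_and_standardize: %d constant feature(s) set to zero in omics %s",
            int(constant.sum()), m.omics_kind.value,
        )
    sd_safe = np.where(constant, 1.0, sd)
    out = (vals - mean) / sd_safe
    out[:, constant] = 0.0
    return m.with_values(out, beta_scale=False)


_EXPRESSION = (OmicsKind.MRNA, OmicsKind.MIRNA)
_PROTEO = (OmicsKind.PROTEOMICS, OmicsKind.PHOSPHOPROTEOMICS)


def preprocess_matrix(m: OmicsMatrix, cfg: PreprocessConfig | None = None) -> OmicsMatrix:
    """Apply the kind-appropriate pipeline, ending with impute + z-scoring."""
    cfg = cfg or PreprocessConfig()
    if m.omics_kind is OmicsKind.COPY_NUMBER:
        m = dedup_copy_number(m)
    elif m.omics_kind is OmicsKind.METHYLATION:
        m = filter_methylation(m, cfg)
    elif m.omics_kind in _EXPRESSION:
        m = preprocess_expression(m, cfg)
    elif m.omics_kind in _PROTEO:
        m = preprocess_proteomics(m, cfg)
    if m.n_features == 0:
        raise DataValidationError(f"omics {m.omics_kind.value}: no features survive preprocessing")
    return impute_and_standardize(m, cfg.imputation)


def preprocess_dataset(dataset: OmicsDataset, cfg: PreprocessConfig | None = None) -> OmicsDataset:
    """Preprocess every omics layer of a dataset."""
    cfg = cfg or PreprocessConfig()
    return OmicsDataset(
        dataset.name,
        {kind: preprocess_matrix(m, cfg) for kind, m in dataset.matrices.items()},
    )
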