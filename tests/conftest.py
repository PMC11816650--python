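import numpy as np
import pytest

from subtype_awa import (
    ClinicalTable,
    ClusterAssignment,
    Covariate,
    DISCRETE,
    NUMERIC,
    OmicsDataset,
    OmicsKind,
    OmicsMatrix,
)


def mk_matrix(kind, values, sample_ids=None, feature_ids=None) -> OmicsMatrix:
    """Build an OmicsMatrix from a nested list, auto-naming ids."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return OmicsMatrix(
        OmicsKind(kind),
        sample_ids or [f"s{i + 1}" for i in range(n)],
        feature_ids or [f"f{j + 1}" for j in range(p)],
        values,
    )


def mk_assignment(labels, method="m", K=None, sample_ids=None) -> ClusterAssignment:
    labels = list(labels)
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(len(labels))]
    return ClusterAssignment(method, dict(zip(sample_ids, labels)), K or max(labels))


def mk_clinical(times, events, covariates=None, sample_ids=None) -> ClinicalTable:
    times = np.asarray(times, dtype=float)
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(len(times))]
    covs = {}
    for name, (kind, vals) in (covariates or {}).items():
        covs[name] = Covariate(kind, np.asarray(vals, dtype=float if kind == NUMERIC else object))
    return ClinicalTable(sample_ids, times, np.asarray(events, dtype=float), covs)


@pytest.fixture
def two_omics_dataset() -> OmicsDataset:
    """Tiny 4-sample dataset with two separated groups in both omics layers."""
    rng = np.random.default_rng(7)
    base = np.array([[0.0], [0.5], [10.0], [10.5]])
    m1 = mk_matrix(OmicsKind.MRNA, np.hstack([base, base + 1]) + 1.0)
    m2 = mk_matrix(OmicsKind.COPY_NUMBER, base - 5.0)
    return OmicsDataset("tiny", {OmicsKind.MRNA: m1, OmicsKind.COPY_NUMBER: m2})
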