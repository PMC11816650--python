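"""Reading, writing and validation of the three evaluation inputs.

The evaluation harness consumes three kinds of artifact, all plain TSV:

* per-omics feature matrices (samples as rows, features as columns),
* a clinical table (overall survival plus a typed covariate set),
* one cluster-assignment file per evaluated subtyping method.

Everything downstream assumes the three share one canonical sample order;
:func:`align_and_validate` establishes it by sample-set intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("subtype_awa")


class DataValidationError(ValueError):
    """An input artifact violates one of its structural invariants."""


class OmicsKind(str, Enum):
    COPY_NUMBER = "copy_number"
    METHYLATION = "methylation"
    MRNA = "mrna"
    MIRNA = "mirna"
    PROTEOMICS = "proteomics"
    PHOSPHOPROTEOMICS = "phosphoproteomics"


#: Fixed order used when omics matrices are concatenated into one representation.
OMICS_ORDER: tuple[OmicsKind, ...] = tuple(OmicsKind)

#: Cell contents (lower-cased, stripped) that denote a missing value in TSV.
MISSING_TOKENS = frozenset({"", "na"})

DISCRETE = "discrete"
NUMERIC = "numeric"

#: The default clinical covariate schema: gender, age at diagnosis and the
#: pathologic T/M/N/stage annotations shared by TCGA-style clinical tables.
DEFAULT_COVARIATE_SCHEMA: dict[str, str] = {
    "gender": DISCRETE,
    "age_at_diagnosis": NUMERIC,
    "pathologic_t": DISCRETE,
    "pathologic_m": DISCRETE,
    "pathologic_n": DISCRETE,
    "pathologic_stage": DISCRETE,
}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DataValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# Omics matrices
# ---------------------------------------------------------------------------


@dataclass
class OmicsMatrix:
    """One omics layer: a real-valued samples x features matrix.

    ``values`` is float64 with NaN marking missing entries. Methylation
    matrices carry beta values and every non-missing entry must lie in [0, 1].
    """

    omics_kind: OmicsKind
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    #: methylation matrices carry beta values until standardization rescales
    #: them; the [0,1] range check applies only while this flag is set
    beta_scale: bool = True

    def __post_init__(self) -> None:
        self.omics_kind = OmicsKind(self.omics_kind)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise DataValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if self.omics_kind is OmicsKind.METHYLATION and self.beta_scale:
            bad = np.nonzero(~np.isnan(self.values) & ((self.values < 0) | (self.values > 1)))
            if bad[0].size:
                r, c = int(bad[0][0]), int(bad[1][0])
                raise DataValidationError(
                    "methylation beta value outside [0,1] at "
                    f"(sample {self.sample_ids[r]!r}, feature {self.feature_ids[c]!r}): "
                    f"{self.values[r, c]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def select_features(self, keep: Sequence[int]) -> "OmicsMatrix":
        """New matrix keeping feature columns ``keep`` (indices, input order)."""
        keep = list(keep)
        return OmicsMatrix(
            self.omics_kind,
            list(self.sample_ids),
            [self.feature_ids[j] for j in keep],
            self.values[:, keep].copy(),
            self.beta_scale,
        )

    def reorder_samples(self, order: Sequence[str]) -> "OmicsMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in order]
        return OmicsMatrix(
            self.omics_kind, list(order), list(self.feature_ids), self.values[idx], self.beta_scale
        )

    def with_values(self, values: np.ndarray, beta_scale: bool | None = None) -> "OmicsMatrix":
        return OmicsMatrix(
            self.omics_kind,
            list(self.sample_ids),
            list(self.feature_ids),
            values,
            self.beta_scale if beta_scale is None else beta_scale,
        )


@dataclass
class OmicsDataset:
    """A named collection of omics matrices sharing one ordered sample set."""

    name: str
    matrices: dict[OmicsKind, OmicsMatrix]

    def __post_init__(self) -> None:
        if not self.matrices:
            raise DataValidationError("an OmicsDataset needs at least one omics matrix")
        self.matrices = {OmicsKind(k): m for k, m in self.matrices.items()}
        ref = None
        for kind, m in self.matrices.items():
            if m.omics_kind is not kind:
                raise DataValidationError(
                    f"matrix registered under {kind.value} declares kind {m.omics_kind.value}"
                )
            if ref is None:
                ref = m.sample_ids
            elif m.sample_ids != ref:
                raise DataValidationError(
                    f"omics {kind.value} sample list differs from the dataset's sample list"
                )

    @property
    def sample_ids(self) -> list[str]:
        return next(iter(self.matrices.values())).sample_ids

    def kinds_in_order(self) -> list[OmicsKind]:
        return [k for k in OMICS_ORDER if k in self.matrices]

    def reorder_samples(self, order: Sequence[str]) -> "OmicsDataset":
        return OmicsDataset(self.name, {k: m.reorder_samples(order) for k, m in self.matrices.items()})


def read_omics_matrix(path: str | Path, omics_kind: OmicsKind | str) -> OmicsMatrix:
    """Read a samples x features TSV (header = feature ids, first column = sample ids).

    Empty cells and "NA" (case-insensitive) are treated as missing. Rejects
    duplicate ids, non-numeric cells (naming the coordinates) and, for
    methylation, beta values outside [0, 1].
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    sample_ids = [str(s) for s in df.index]
    feature_ids = [str(f) for f in df.columns]
    _check_unique(sample_ids, "sample")
    _check_unique(feature_ids, "feature")
    raw = df.to_numpy(dtype=str)
    stripped = np.char.strip(raw)
    missing = np.isin(np.char.lower(stripped), list(MISSING_TOKENS))
    values = np.full(raw.shape, np.nan)
    if (~missing).any():
        try:
            values[~missing] = stripped[~missing].astype(float)
        except ValueError:
            for (r, c) in zip(*np.nonzero(~missing)):
                try:
                    values[r, c] = float(stripped[r, c])
                except ValueError:
                    raise DataValidationError(
                        f"non-numeric cell at (sample {sample_ids[r]!r}, "
                        f"feature {feature_ids[c]!r}) in {path.name}: {raw[r, c]!r}"
                    ) from None
    return OmicsMatrix(OmicsKind(omics_kind), sample_ids, feature_ids, values)


def write_omics_matrix(m: OmicsMatrix, path: str | Path) -> None:
    """Write the matrix as TSV; missing entries become "NA". Round-trip exact."""
    m.to_frame().to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------


@dataclass
class Covariate:
    """One typed clinical covariate.

    Discrete covariates are stored as an object array of category strings with
    ``None`` marking missing; numeric covariates as float64 with NaN missing.
    """

    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in (DISCRETE, NUMERIC):
            raise DataValidationError(f"covariate kind must be discrete or numeric, got {self.kind!r}")
        if self.kind == NUMERIC:
            self.values = np.asarray(self.values, dtype=float)
        else:
            self.values = np.asarray(
                [None if v is None or (isinstance(v, float) and np.isnan(v)) else str(v) for v in self.values],
                dtype=object,
            )

    @property
    def missing_mask(self) -> np.ndarray:
        if self.kind == NUMERIC:
            return np.isnan(self.values)
        return np.asarray([v is None for v in self.values])


@dataclass
class ClinicalTable:
    """Survival outcome plus typed clinical covariates for one sample set.

    ``survival_time`` is overall survival in days (NaN = unknown); ``event``
    is 1 for an observed death, 0 for censoring, NaN for unknown.
    """

    sample_ids: list[str]
    survival_time: np.ndarray
    event: np.ndarray
    covariates: dict[str, Covariate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        self.survival_time = np.asarray(self.survival_time, dtype=float)
        self.event = np.asarray(self.event, dtype=float)
        if self.survival_time.shape != (n,) or self.event.shape != (n,):
            raise DataValidationError("survival_time/event length does not match sample count")
        neg = np.nonzero(self.survival_time < 0)[0]
        if neg.size:
            raise DataValidationError(
                f"negative survival time for sample {self.sample_ids[int(neg[0])]!r}"
            )
        ok = np.isnan(self.event) | (self.event == 0) | (self.event == 1)
        bad = np.nonzero(~ok)[0]
        if bad.size:
            raise DataValidationError(
                f"event indicator must be 0 or 1; sample {self.sample_ids[int(bad[0])]!r} "
                f"has {self.event[int(bad[0])]}"
            )
        for name, cov in self.covariates.items():
            if len(cov.values) != n:
                raise DataValidationError(f"covariate {name!r} length does not match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def reorder_samples(self, order: Sequence[str]) -> "ClinicalTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in order]
        return ClinicalTable(
            list(order),
            self.survival_time[idx],
            self.event[idx],
            {n: Covariate(c.kind, c.values[idx]) for n, c in self.covariates.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {
            "os_time": self.survival_time,
            "os_event": self.event,
        }
        for name, cov in self.covariates.items():
            data[name] = cov.values
        df = pd.DataFrame(data, index=pd.Index(self.sample_ids, name="sample_id"))
        return df


def read_clinical_table(
    path: str | Path,
    covariate_schema: Mapping[str, str] | None = None,
) -> ClinicalTable:
    """Read a clinical TSV with required columns sample_id, os_time, os_event.

    Covariate columns are typed per ``covariate_schema`` (default: the
    six-covariate TCGA-style schema). Schema columns absent from the file are
    skipped with a warning; file columns outside the schema are ignored with a
    warning.
    """
    path = Path(path)
    schema = dict(DEFAULT_COVARIATE_SCHEMA if covariate_schema is None else covariate_schema)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("sample_id", "os_time", "os_event")
    for col in required:
        if col not in df.columns:
            raise DataValidationError(f"clinical table missing required column {col!r}")
    sample_ids = [str(s) for s in df["sample_id"]]

    def parse_numeric(col: str) -> np.ndarray:
        out = np.full(len(df), np.nan)
        for i, cell in enumerate(df[col]):
            cell = str(cell).strip()
            if cell.lower() in MISSING_TOKENS:
                continue
            try:
                out[i] = float(cell)
            except ValueError:
                raise DataValidationError(
                    f"non-numeric value {cell!r} in column {col!r} for sample {sample_ids[i]!r}"
                ) from None
        return out

    times = parse_numeric("os_time")
    events = parse_numeric("os_event")
    covariates: dict[str, Covariate] = {}
    for name, kind in schema.items():
        if name not in df.columns:
            logger.warning("clinical table %s: covariate column %r absent, skipped", path.name, name)
            continue
        if kind == NUMERIC:
            covariates[name] = Covariate(NUMERIC, parse_numeric(name))
        else:
            vals = [
                None if str(v).strip().lower() in MISSING_TOKENS else str(v).strip()
                for v in df[name]
            ]
            covariates[name] = Covariate(DISCRETE, np.asarray(vals, dtype=object))
    unknown = [c for c in df.columns if c not in required and c not in schema]
    if unknown:
        logger.warning("clinical table %s: ignoring columns outside the schema: %s", path.name, unknown)
    return ClinicalTable(sample_ids, times, events, covariates)


def write_clinical_table(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.to_frame().to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# Cluster assignments
# ---------------------------------------------------------------------------


@dataclass
class ClusterAssignment:
    """One method's sample -> subtype mapping with configured cluster count K.

    Labels are 1-based integers in {1..K}. ``runtime_s`` optionally carries
    the method's own clustering wall-clock time (the RT efficiency metric);
    None means "not measured".
    """

    method_name: str
    labels: dict[str, int]
    K: int
    runtime_s: float | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise DataValidationError(f"K must be >= 1, got {self.K}")
        clean: dict[str, int] = {}
        for s, lab in self.labels.items():
            lab = int(lab)
            if not 1 <= lab <= self.K:
                raise DataValidationError(
                    f"method {self.method_name!r}: label {lab} for sample {s!r} "
                    f"outside 1..{self.K}"
                )
            clean[str(s)] = lab
        self.labels = clean

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels)

    def labels_for(self, order: Sequence[str]) -> np.ndarray:
        """Integer label vector aligned to ``order``."""
        return np.asarray([self.labels[s] for s in order], dtype=int)

    def cluster_sizes(self) -> dict[int, int]:
        sizes = {k: 0 for k in range(1, self.K + 1)}
        for lab in self.labels.values():
            sizes[lab] += 1
        return sizes

    def check_clusters_nonempty(self) -> None:
        for k, n in self.cluster_sizes().items():
            if n == 0:
                raise DataValidationError(
                    f"method {self.method_name!r}: cluster {k} is empty"
                )

    def restrict(self, samples: Iterable[str]) -> "ClusterAssignment":
        keep = set(samples)
        return ClusterAssignment(
            self.method_name,
            {s: l for s, l in self.labels.items() if s in keep},
            self.K,
            self.runtime_s,
        )


def read_cluster_assignment(
    path: str | Path,
    method_name: str | None = None,
) -> ClusterAssignment:
    """Read an assignment TSV (columns sample_id, label; 1-based integer labels).

    Leading ``# key=value`` comment lines may set ``method``, ``K`` and
    ``runtime_s``. K defaults to the maximum observed label; the method name
    defaults to the file stem. Every cluster in 1..K must be non-empty.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("#").strip().partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if line.strip():
                rows.append(line.rstrip("\n"))
    if not rows:
        raise DataValidationError(f"assignment file {path.name} is empty")
    header = rows[0].split("\t")
    if header[:2] != ["sample_id", "label"]:
        raise DataValidationError(
            f"assignment file {path.name} must have header 'sample_id\\tlabel', got {header[:2]}"
        )
    labels: dict[str, int] = {}
    for line in rows[1:]:
        parts = line.split("\t")
        sid, lab = parts[0], parts[1]
        if sid in labels:
            raise DataValidationError(f"duplicate sample {sid!r} in {path.name}")
        try:
            labels[sid] = int(lab)
        except ValueError:
            raise DataValidationError(
                f"non-integer label {lab!r} for sample {sid!r} in {path.name}"
            ) from None
    name = method_name or meta.get("method") or path.stem
    K = int(meta["K"]) if "K" in meta else max(labels.values())
    runtime = float(meta["runtime_s"]) if "runtime_s" in meta else None
    assign = ClusterAssignment(name, labels, K, runtime)
    assign.check_clusters_nonempty()
    return assign


def write_cluster_assignment(assign: ClusterAssignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# method={assign.method_name}\n")
        fh.write(f"# K={assign.K}\n")
        if assign.runtime_s is not None:
            fh.write(f"# runtime_s={assign.runtime_s!r}\n")
        fh.write("sample_id\tlabel\n")
        for s, lab in assign.labels.items():
            fh.write(f"{s}\t{lab}\n")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignedInputs:
    dataset: OmicsDataset
    clinical: ClinicalTable
    assignments: list[ClusterAssignment]
    dropped: dict[str, list[str]]

    def __iter__(self):
        return iter((self.dataset, self.clinical, self.assignments))


def align_and_validate(
    dataset: OmicsDataset,
    clinical: ClinicalTable,
    assignments: Sequence[ClusterAssignment],
) -> AlignedInputs:
    """Intersect the sample sets of all inputs and reorder to one canonical order.

    The canonical order is the dataset's sample order restricted to the
    intersection. Samples dropped from each input are reported. After the
    intersection every cluster of every assignment must still be non-empty.
    Idempotent: realigning aligned inputs is the identity.
    """
    common = set(dataset.sample_ids) & set(clinical.sample_ids)
    for assign in assignments:
        common &= set(assign.labels)
    if not common:
        raise DataValidationError("sample-set intersection across inputs is empty")
    order = [s for s in dataset.sample_ids if s in common]
    dropped: dict[str, list[str]] = {}
    d = [s for s in dataset.sample_ids if s not in common]
    if d:
        dropped["omics"] = d
    d = [s for s in clinical.sample_ids if s not in common]
    if d:
        dropped["clinical"] = d
    aligned_assignments = []
    for assign in assignments:
        d = [s for s in assign.labels if s not in common]
        if d:
            dropped[f"assignment:{assign.method_name}"] = d
        restricted = assign.restrict(order)
        try:
            restricted.check_clusters_nonempty()
        except DataValidationError as exc:
            raise DataValidationError(f"after sample intersection: {exc}") from None
        aligned_assignments.append(restricted)
    if dropped:
        logger.warning(
            "align_and_validate dropped samples outside the common set: %s",
            {k: len(v) for k, v in dropped.items()},
        )
    return AlignedInputs(
        dataset.reorder_samples(order),
        clinical.reorder_samples(order),
        aligned_assignments,
        dropped,
    )


def read_yaml(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise DataValidationError(f"config {path} must be a YAML mapping")
    return out
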