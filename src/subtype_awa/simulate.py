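"""Synthetic multi-omics datasets with known subtype structure.

The generator emulates what a K-subtype cancer cohort looks like to the
evaluation harness: per-omics feature matrices whose cluster centroids are
separated by a controllable effect size, exponential survival with
multiplicative per-subtype hazards, and clinical covariates whose
distributions are tilted toward the subtype labels with a controllable
association strength. Ground-truth labels are returned alongside, so every
stage of the harness — preprocessing, internal metrics, clinical metrics,
scoring — can be tested against a known answer without any external download.

All randomness flows through a single ``numpy.random.default_rng(seed)``
generator with a fixed draw order (labels are deterministic blocks; then per
omics: affected-feature subset, offset signs, noise, missing mask; then
survival; then covariates in declaration order), so one seed yields
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .data_io import (
    DISCRETE,
    NUMERIC,
    ClinicalTable,
    ClusterAssignment,
    Covariate,
    DataValidationError,
    OmicsDataset,
    OmicsKind,
    OmicsMatrix,
    write_clinical_table,
    write_cluster_assignment,
    write_omics_matrix,
)

#: Category sets for the default discrete covariates.
DISCRETE_CATEGORIES: dict[str, list[str]] = {
    "gender": ["female", "male"],
    "pathologic_t": ["T1", "T2", "T3", "T4"],
    "pathologic_m": ["M0", "M1"],
    "pathologic_n": ["N0", "N1", "N2"],
    "pathologic_stage": ["Stage I", "Stage II", "Stage III", "Stage IV"],
}


@dataclass
class OmicsSpec:
    """One omics layer: feature count, centroid effect size delta (offset
    magnitude on the affected half of the features), Gaussian noise SD sigma,
    and the fraction of entries masked as missing."""

    kind: OmicsKind
    n_features: int = 100
    effect_size: float = 1.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        self.kind = OmicsKind(self.kind)
        if self.n_features < 1:
            raise DataValidationError("omics_spec: n_features must be >= 1")
        if self.effect_size < 0:
            raise DataValidationError("omics_spec: effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise DataValidationError("omics_spec: noise_sd must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise DataValidationError("omics_spec: missing_rate must be in [0,1)")


@dataclass
class SurvivalSpec:
    """Exponential survival: per-sample event rate = baseline_rate *
    hazard_multipliers[cluster]; independent exponential censoring tuned so the
    expected censored fraction equals censoring_rate."""

    baseline_rate: float = 0.001  # per day: mean survival 1000 days at hazard 1
    hazard_multipliers: tuple[float, ...] = (1.0, 2.0, 3.0)
    censoring_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise DataValidationError("survival_spec: baseline_rate must be > 0")
        if any(h <= 0 for h in self.hazard_multipliers):
            raise DataValidationError("survival_spec: hazard multipliers must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise DataValidationError("survival_spec: censoring_rate must be in [0,1)")


@dataclass
class CovariateSpec:
    """One clinical covariate: kind plus the strength (in [0,1]) with which
    its distribution is tilted toward the subtype labels; 0 = no association."""

    kind: str
    association_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in (DISCRETE, NUMERIC):
            raise DataValidationError(f"covariate kind must be discrete or numeric, got {self.kind!r}")
        if not 0 <= self.association_strength <= 1:
            raise DataValidationError("association_strength must be in [0,1]")


def default_clinical_spec(associated_strength: float = 0.8) -> dict[str, CovariateSpec]:
    """The six-covariate TCGA-style schema with three covariates associated
    with the subtypes (age at diagnosis, pathologic T, pathologic stage) and
    three null ones (gender, pathologic M, pathologic N)."""
    return {
        "gender": CovariateSpec(DISCRETE, 0.0),
        "age_at_diagnosis": CovariateSpec(NUMERIC, associated_strength),
        "pathologic_t": CovariateSpec(DISCRETE, associated_strength),
        "pathologic_m": CovariateSpec(DISCRETE, 0.0),
        "pathologic_n": CovariateSpec(DISCRETE, 0.0),
        "pathologic_stage": CovariateSpec(DISCRETE, associated_strength),
    }


@dataclass
class SimConfig:
    K: int = 3
    n_per_cluster: tuple[int, ...] = (50, 50, 50)
    omics_specs: list[OmicsSpec] = field(
        default_factory=lambda: [
            OmicsSpec(OmicsKind.COPY_NUMBER, 60, 1.0, 1.0, 0.02),
            OmicsSpec(OmicsKind.METHYLATION, 80, 1.0, 1.0, 0.02),
            OmicsSpec(OmicsKind.MRNA, 100, 1.0, 1.0, 0.02),
            OmicsSpec(OmicsKind.MIRNA, 40, 1.0, 1.0, 0.02),
        ]
    )
    survival_spec: SurvivalSpec = field(default_factory=SurvivalSpec)
    clinical_spec: dict[str, CovariateSpec] = field(default_factory=default_clinical_spec)
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise DataValidationError("sim_config: K must be >= 1")
        if len(self.n_per_cluster) != self.K:
            raise DataValidationError("sim_config: n_per_cluster must have K entries")
        if any(n < 1 for n in self.n_per_cluster):
            raise DataValidationError("sim_config: cluster sizes must be >= 1")
        if len(self.survival_spec.hazard_multipliers) != self.K:
            raise DataValidationError("sim_config: hazard_multipliers must have K entries")
        if not self.omics_specs:
            raise DataValidationError("sim_config: at least one omics spec required")
        kinds = [s.kind for s in self.omics_specs]
        if len(set(kinds)) != len(kinds):
            raise DataValidationError("sim_config: duplicate omics kinds")


@dataclass
class SyntheticTruth:
    labels: ClusterAssignment
    associated_covariates: set[str]


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _censoring_rate_for(c: float, rates: np.ndarray) -> float:
    # P(censoring exponential(c) precedes event exponential(r)) = c / (c + r)
    return float(np.mean(c / (c + rates)))


def _solve_censoring_rate(target: float, rates: np.ndarray) -> float:
    """Censoring hazard c with mean_i c/(c + r_i) = target, by bisection."""
    lo, hi = 1e-12, float(rates.max())
    while _censoring_rate_for(hi, rates) < target:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _censoring_rate_for(mid, rates) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _simulate_omics(spec: OmicsSpec, labels0: np.ndarray, K: int, rng: np.random.Generator) -> OmicsMatrix:
    n = labels0.size
    p = spec.n_features
    centroids = np.zeros((K, p))
    n_affected = max(1, p // 2)
    for c in range(K):
        affected = rng.choice(p, size=n_affected, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_affected)
        centroids[c, affected] = signs * spec.effect_size
    latent = centroids[labels0] + rng.normal(0.0, spec.noise_sd, size=(n, p))
    if spec.kind in (OmicsKind.MRNA, OmicsKind.MIRNA):
        # abundance scale: log2(values) ~ latent around a base expression of 5
        values = np.exp2(latent + 5.0)
    elif spec.kind is OmicsKind.METHYLATION:
        # latent lives in logit space; squash to beta values in [0,1]
        values = _logistic(latent)
    else:
        values = latent
    if spec.missing_rate > 0:
        mask = rng.random((n, p)) < spec.missing_rate
        # never blank out a whole sample: keep each row's first observed entry
        full_rows = np.nonzero(mask.all(axis=1))[0]
        mask[full_rows, 0] = False
        values = values.copy()
        values[mask] = np.nan
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    feature_ids = [f"{spec.kind.value}_f{j + 1:04d}" for j in range(p)]
    return OmicsMatrix(spec.kind, sample_ids, feature_ids, values)


def simulate_dataset(cfg: SimConfig) -> tuple[OmicsDataset, ClinicalTable, SyntheticTruth]:
    """Draw one multi-omics cohort with known subtype structure.

    Returns the omics dataset, the clinical table (survival in days plus the
    configured covariates) and the ground truth (labels and the set of
    covariates generated with a nonzero association).
    """
    rng = np.random.default_rng(cfg.seed)
    labels0 = np.repeat(np.arange(cfg.K), cfg.n_per_cluster)  # 0-based, block order
    n = labels0.size
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    matrices = {spec.kind: _simulate_omics(spec, labels0, cfg.K, rng) for spec in cfg.omics_specs}
    dataset = OmicsDataset(cfg.name, matrices)

    sv = cfg.survival_spec
    rates = sv.baseline_rate * np.asarray(sv.hazard_multipliers)[labels0]
    event_times = rng.exponential(1.0 / rates)
    if sv.censoring_rate > 0:
        c = _solve_censoring_rate(sv.censoring_rate, rates)
        censor_times = rng.exponential(1.0 / c, size=n)
        events = (event_times <= censor_times).astype(float)
        times = np.minimum(event_times, censor_times)
    else:
        events = np.ones(n)
        times = event_times

    covariates: dict[str, Covariate] = {}
    for name, spec in cfg.clinical_spec.items():
        s = spec.association_strength
        if spec.kind == DISCRETE:
            cats = DISCRETE_CATEGORIES.get(name, [f"cat{j + 1}" for j in range(3)])
            m = len(cats)
            probs = np.full((cfg.K, m), (1.0 - s) / m)
            for c in range(cfg.K):
                probs[c, c % m] += s  # each cluster prefers one category
            draws = np.array(
                [cats[rng.choice(m, p=probs[lab])] for lab in labels0], dtype=object
            )
            covariates[name] = Covariate(DISCRETE, draws)
        else:
            # cluster-shifted ages: shift of s * 10 years per cluster step
            means = 60.0 + s * 10.0 * labels0
            covariates[name] = Covariate(NUMERIC, rng.normal(means, 10.0))
    clinical = ClinicalTable(sample_ids, times, events, covariates)

    truth = SyntheticTruth(
        ClusterAssignment(
            "ground_truth", dict(zip(sample_ids, (labels0 + 1).tolist())), cfg.K
        ),
        {name for name, spec in cfg.clinical_spec.items() if spec.association_strength > 0},
    )
    return dataset, clinical, truth


def perturb_labels(truth: ClusterAssignment, flip_fraction: float, seed: int) -> ClusterAssignment:
    """Degrade an assignment by relabeling a random flip_fraction of samples.

    Exactly round(flip_fraction * n) samples are chosen without replacement
    and each is given a label drawn uniformly over all K clusters, so a
    perturbed sample carries no label information (it may land back in its
    own cluster by chance: the expected fraction of labels that actually
    change is flip_fraction * (K-1)/K). flip_fraction = 0 is the identity;
    flip_fraction = 1 yields chance-level labels, destroying all association
    with the input.
    """
    if not 0 <= flip_fraction <= 1:
        raise DataValidationError("flip_fraction must be in [0,1]")
    name = f"{truth.method_name}_flip{flip_fraction:g}"
    samples = list(truth.labels)
    labels = dict(truth.labels)
    if flip_fraction == 0 or truth.K < 2:
        return ClusterAssignment(name, labels, truth.K, truth.runtime_s)
    rng = np.random.default_rng(seed)
    n_flip = int(round(flip_fraction * len(samples)))
    flip_idx = rng.choice(len(samples), size=n_flip, replace=False)
    new_labels = rng.integers(1, truth.K + 1, size=n_flip)
    for i, lab in zip(flip_idx, new_labels):
        labels[samples[int(i)]] = int(lab)
    return ClusterAssignment(name, labels, truth.K, truth.runtime_s)


def write_simulation(
    outdir: str | Path,
    dataset: OmicsDataset,
    clinical: ClinicalTable,
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write the simulated cohort as the TSV artifacts the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for kind, m in dataset.matrices.items():
        p = outdir / f"omics_{kind.value}.tsv"
        write_omics_matrix(m, p)
        paths[f"omics_{kind.value}"] = p
    p = outdir / "clinical.tsv"
    write_clinical_table(clinical, p)
    paths["clinical"] = p
    p = outdir / "truth_assignment.tsv"
    write_cluster_assignment(truth.labels, p)
    paths["truth"] = p
    p = outdir / "dataset.yaml"
    with open(p, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "name": dataset.name,
                "omics": {k.value: f"omics_{k.value}.tsv" for k in dataset.matrices},
                "clinical": "clinical.tsv",
            },
            fh,
        )
    paths["dataset_yaml"] = p
    return paths
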