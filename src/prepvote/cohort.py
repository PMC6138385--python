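"""Synthetic cohorts with hypoxia-driven survival and pipeline distortions.

The generator produces (a) a latent log2-scale abundance matrix in which a
subset of signature genes load on a per-patient hypoxia activity factor,
(b) exponential event times whose hazard scales with that factor plus
independent exponential censoring, and (c) one distorted abundance matrix
per preprocessing variant — a strictly monotone transform plus noise, with
per-dataset batch offsets only for separately-handled variants and gene
dropout emulating the alternative annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import stage_seed
from .pipelines import Annotation, Handling, PipelineSpec

logger = logging.getLogger(__name__)

_NONLINEARITIES = {
    None: lambda x: x,
    "identity": lambda x: x,
    "asinh": lambda x: 4.0 * np.arcsinh(x / 4.0),
    "cube": lambda x: x + (x / 12.0) ** 3,
}


@dataclass
class DistortionSpec:
    """How one pipeline variant distorts the latent abundances."""

    slope: float = 1.0
    intercept: float = 0.0
    nonlinearity: str | None = None
    noise_sd: float = 0.0
    batch_sd: float = 0.0  # applied only under separate handling
    dropout: float = 0.0  # fraction of genes removed

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive to keep the transform monotone")
        if self.noise_sd < 0 or self.batch_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout fraction must be in [0, 1)")
        if self.nonlinearity not in _NONLINEARITIES:
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")


@dataclass
class LatentCohort:
    true_abundance: pd.DataFrame  # genes x patients, log2 scale
    hypoxia_activity: pd.Series  # per patient
    signature_genes: tuple[str, ...]
    survival: pd.DataFrame  # patient-indexed clinical table
    dataset_assignment: pd.Series = field(repr=False)


def generate_survival(
    hypoxia_activity: pd.Series,
    log_hr_per_unit: float = np.log(2),
    baseline_rate: float = 0.1,
    censoring_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times with hazard ``baseline * exp(log_hr * h)``.

    Censoring times are independent exponentials; the observed time is the
    minimum, with event = 1 when the event precedes censoring.
    """
    h = np.asarray(hypoxia_activity, dtype=float)
    if not np.isfinite(h).all():
        raise ValueError("hypoxia activities must be finite")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if censoring_rate < 0:
        raise ValueError("censoring_rate must be non-negative")
    rng = np.random.default_rng(seed)
    rates = baseline_rate * np.exp(log_hr_per_unit * h)
    event_times = rng.exponential(1.0 / rates)
    if censoring_rate > 0:
        censor_times = rng.exponential(1.0 / censoring_rate, size=h.size)
    else:
        censor_times = np.full(h.size, np.inf)
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    return pd.DataFrame(
        {"time_years": time, "event": event},
        index=pd.Index(hypoxia_activity.index, name="patient_id"),
    )


def generate_latent_cohort(
    n_patients: int,
    n_genes: int,
    n_signature_genes: int,
    n_datasets: int = 1,
    loading_strength: float = 1.0,
    seed: int = 0,
    log_hr_per_unit: float = np.log(2),
    baseline_rate: float = 0.1,
    censoring_rate: float = 0.05,
    subtype_labels: int = 4,
    subtype_missing_fraction: float = 0.2,
) -> LatentCohort:
    """Latent cohort: Gaussian background genes plus a hypoxia gene module.

    Signature genes are ``loading_strength * h_j`` plus unit Gaussian noise
    around the common baseline; hypoxia activity h_j is standard normal.
    Subtype labels (used only for accuracy stratification) are quartiles of
    h with a seeded fraction left unlabeled.  Fully deterministic per seed.
    """
    if min(n_patients, n_genes, n_signature_genes, n_datasets) < 1:
        raise ValueError("all counts must be >= 1")
    if n_signature_genes > n_genes:
        raise ValueError("n_signature_genes cannot exceed n_genes")
    rng = np.random.default_rng(stage_seed(seed, "latent"))
    genes = [f"g{i:05d}" for i in range(n_genes)]
    patients = [f"p{i:05d}" for i in range(n_patients)]
    h = rng.standard_normal(n_patients)
    baseline = 8.0
    X = baseline + rng.standard_normal((n_genes, n_patients))
    sig_idx = rng.choice(n_genes, size=n_signature_genes, replace=False)
    X[sig_idx] += loading_strength * h[None, :]
    signature_genes = tuple(genes[i] for i in sorted(sig_idx))

    datasets = pd.Series(
        [f"d{rng.integers(n_datasets) + 1}" for _ in patients],
        index=patients,
        name="dataset_id",
    )
    hypoxia = pd.Series(h, index=patients, name="hypoxia_activity")
    surv = generate_survival(
        hypoxia,
        log_hr_per_unit=log_hr_per_unit,
        baseline_rate=baseline_rate,
        censoring_rate=censoring_rate,
        seed=stage_seed(seed, "survival"),
    )
    quartile = pd.qcut(hypoxia, subtype_labels, labels=[f"s{i+1}" for i in range(subtype_labels)])
    subtype = quartile.astype("string")
    if subtype_missing_fraction > 0:
        mask = rng.random(n_patients) < subtype_missing_fraction
        subtype[mask] = pd.NA
    survival = pd.DataFrame(
        {
            "dataset_id": datasets,
            "time_years": surv["time_years"],
            "event": surv["event"],
            "subtype": subtype,
        },
        index=pd.Index(patients, name="patient_id"),
    )
    logger.info(
        "generated latent cohort: %d genes x %d patients, %d signature genes, %d events",
        n_genes, n_patients, n_signature_genes, int(survival["event"].sum()),
    )
    return LatentCohort(
        true_abundance=pd.DataFrame(X, index=genes, columns=patients),
        hypoxia_activity=hypoxia,
        signature_genes=signature_genes,
        survival=survival,
        dataset_assignment=datasets,
    )


def default_distortion_specs(
    pipeline_specs: list[PipelineSpec],
    noise_sd: float = 0.5,
    batch_sd: float = 0.5,
    dropout_alternative: float = 0.1,
    seed: int = 0,
) -> dict[str, DistortionSpec]:
    """A plausible distortion per pipeline: per-variant affine + nonlinearity,
    batch offsets for separate handling, dropout for alternative annotation."""
    nonlin_cycle = [None, "asinh", "cube"]
    out = {}
    for i, spec in enumerate(pipeline_specs):
        rng = np.random.default_rng(stage_seed(seed, "distortion", spec.id))
        out[spec.id] = DistortionSpec(
            slope=float(rng.uniform(0.8, 1.25)),
            intercept=float(rng.uniform(-1.0, 1.0)),
            nonlinearity=nonlin_cycle[i % len(nonlin_cycle)],
            noise_sd=noise_sd,
            batch_sd=batch_sd if spec.handling is Handling.SEPARATE else 0.0,
            dropout=dropout_alternative if spec.annotation is Annotation.ALTERNATIVE else 0.0,
        )
    return out


def apply_pipeline_variants(
    latent: LatentCohort,
    distortion_specs: dict[str, DistortionSpec],
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """One distorted abundance matrix per pipeline variant.

    Each output is ``nonlinearity(slope * X + intercept)`` plus Gaussian
    noise, plus a per-(dataset, gene-independent) batch offset when the
    variant's batch sd is positive; dropped genes are removed entirely.
    """
    X = latent.true_abundance
    out: dict[str, pd.DataFrame] = {}
    for pid, dist in distortion_specs.items():
        rng = np.random.default_rng(stage_seed(seed, "variant", pid))
        transform = _NONLINEARITIES[dist.nonlinearity]
        values = transform(dist.slope * X.to_numpy() + dist.intercept)
        if dist.noise_sd > 0:
            values = values + rng.normal(0.0, dist.noise_sd, size=values.shape)
        if dist.batch_sd > 0:
            levels = latent.dataset_assignment.unique()
            offsets = dict(zip(levels, rng.normal(0.0, dist.batch_sd, size=len(levels))))
            values = values + latent.dataset_assignment.map(offsets).to_numpy()[None, :]
        matrix = pd.DataFrame(values, index=X.index, columns=X.columns)
        if dist.dropout > 0:
            n_drop = int(np.floor(dist.dropout * matrix.shape[0]))
            if n_drop:
                drop = rng.choice(matrix.index.to_numpy(), size=n_drop, replace=False)
                matrix = matrix.drop(index=drop)
        out[pid] = matrix
    logger.info("applied %d pipeline distortions", len(out))
    return out
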