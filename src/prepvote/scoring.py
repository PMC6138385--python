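"""Per-patient risk calls from a gene signature and one abundance matrix.

Scoring follows the median-vote scheme: each signature gene is median
dichotomized across patients, the per-gene votes are summed into a score,
and patients whose score exceeds the cohort (or dataset-stratum) median
score are called high risk.  Ties at the median always go to the low/0
side, which bounds the high-risk fraction at one half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipelines import Handling, PipelineSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature gene list must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")


def median_dichotomize(values) -> np.ndarray:
    """1 where strictly above the median of ``values``, else 0.

    Even-length medians are the mean of the two central order statistics;
    values equal to the median go to 0.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("median dichotomization requires at least 2 values")
    if not np.isfinite(arr).all():
        raise ValueError("values must be finite")
    return (arr > np.median(arr)).astype(np.int8)


def score_signature(
    matrix: pd.DataFrame,
    signature: GeneSignature,
    survival: pd.DataFrame,
    handling: Handling | str = Handling.MERGED,
) -> pd.DataFrame:
    """Score one signature on one abundance matrix.

    Returns a DataFrame indexed by patient with columns ``score`` (sum of
    per-gene votes) and ``high_risk`` (0/1).  With merged handling all
    medians pool every patient; with separate handling both the per-gene
    and the score dichotomizations are computed within each dataset_id.
    Signature genes missing from the matrix are dropped with a warning;
    if none are present this is an error.
    """
    handling = Handling(handling)
    patients = [p for p in matrix.columns if p in survival.index]
    if not patients:
        raise ValueError("no overlap between matrix patients and clinical table")
    if len(patients) < len(matrix.columns):
        logger.warning(
            "dropping %d matrix patients absent from clinical table",
            len(matrix.columns) - len(patients),
        )
    present = [g for g in signature.genes if g in matrix.index]
    missing = [g for g in signature.genes if g not in matrix.index]
    if not present:
        raise ValueError(
            f"none of signature {signature.name!r} genes found in matrix; missing: {missing}"
        )
    if missing:
        logger.warning(
            "signature %s: %d/%d genes missing from matrix, scoring with the rest",
            signature.name,
            len(missing),
            len(signature.genes),
        )
    sub = matrix.loc[present, patients]

    if handling is Handling.MERGED:
        strata = {"__all__": patients}
    else:
        ds = survival.loc[patients, "dataset_id"]
        strata = {k: list(v.index) for k, v in ds.groupby(ds)}

    score = pd.Series(0, index=patients, dtype=int)
    high = pd.Series(0, index=patients, dtype=np.int8)
    for _, stratum_patients in strata.items():
        block = sub[stratum_patients].to_numpy()
        votes = (block > np.median(block, axis=1, keepdims=True)).astype(int)
        s = votes.sum(axis=0)
        score.loc[stratum_patients] = s
        high.loc[stratum_patients] = (s > np.median(s)).astype(np.int8)
    return pd.DataFrame({"score": score, "high_risk": high})


def score_all_pipelines(
    matrices_by_pipeline: dict[str, pd.DataFrame],
    signature: GeneSignature,
    survival: pd.DataFrame,
) -> pd.DataFrame:
    """Score the signature on every pipeline variant, producing the vote matrix.

    ``matrices_by_pipeline`` maps pipeline id -> abundance matrix, in
    enumeration order; the handling mode is parsed from each id.  Patients
    are restricted to the intersection across all matrices (dropped counts
    are logged); an empty intersection is an error.  Output is patients x
    pipelines with 1 = high risk / poor prognosis.
    """
    if not matrices_by_pipeline:
        raise ValueError("no pipeline matrices supplied")
    common: list[str] | None = None
    for pid, matrix in matrices_by_pipeline.items():
        cols = set(matrix.columns)
        if common is None:
            common = [p for p in matrix.columns if p in survival.index]
        else:
            common = [p for p in common if p in cols]
    assert common is not None
    n_all = max(len(m.columns) for m in matrices_by_pipeline.values())
    if not common:
        raise ValueError("empty patient intersection across pipeline matrices")
    if len(common) < n_all:
        logger.warning("restricting to %d common patients (max per-matrix %d)", len(common), n_all)

    votes = {}
    for pid, matrix in matrices_by_pipeline.items():
        spec = PipelineSpec.from_id(pid)
        scored = score_signature(matrix[common], signature, survival, spec.handling)
        votes[pid] = scored["high_risk"]
    out = pd.DataFrame(votes, index=pd.Index(common, name="patient_id"))
    return out.astype(np.int8)
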