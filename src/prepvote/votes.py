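"""Vote-summary engineered features and the unanimous-vote classifier."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .pipelines import Algorithm, Annotation, Handling, PipelineSpec

logger = logging.getLogger(__name__)

ENGINEERED_COLUMNS = (
    "votes_total",
    "votes_separate",
    "votes_merged",
    "votes_RMA",
    "votes_GCRMA",
    "votes_MBEI",
    "votes_MAS5",
    "votes_MBEI_log2",
    "votes_MAS5_log2",
    "votes_RMA_and_MAS5",
    "votes_default_annotation",
    "votes_alternative_annotation",
)

#: algorithms pooled by the combined RMA-and-MAS5 count; overridable because
#: the published definition of this one feature is ambiguous.
RMA_AND_MAS5_ALGORITHMS = frozenset({Algorithm.RMA, Algorithm.MAS5})


def engineer_vote_features(
    vote_matrix: pd.DataFrame,
    pipeline_specs: list[PipelineSpec] | None = None,
    rma_and_mas5: frozenset = RMA_AND_MAS5_ALGORITHMS,
) -> pd.DataFrame:
    """Summarize each patient's poor-prognosis votes by pipeline characteristics.

    Produces the 12 integer count features in :data:`ENGINEERED_COLUMNS`.
    Every vote-matrix column must resolve to a pipeline spec (by default the
    id string is parsed directly).
    """
    if pipeline_specs is None:
        specs = {pid: PipelineSpec.from_id(pid) for pid in vote_matrix.columns}
    else:
        by_id = {s.id: s for s in pipeline_specs}
        unmapped = [c for c in vote_matrix.columns if c not in by_id]
        if unmapped:
            raise ValueError(f"vote columns without a pipeline spec: {unmapped}")
        specs = {pid: by_id[pid] for pid in vote_matrix.columns}

    def count(predicate) -> pd.Series:
        cols = [pid for pid, s in specs.items() if predicate(s)]
        return vote_matrix[cols].sum(axis=1) if cols else pd.Series(0, index=vote_matrix.index)

    features = pd.DataFrame(
        {
            "votes_total": vote_matrix.sum(axis=1),
            "votes_separate": count(lambda s: s.handling is Handling.SEPARATE),
            "votes_merged": count(lambda s: s.handling is Handling.MERGED),
            "votes_RMA": count(lambda s: s.algorithm is Algorithm.RMA),
            "votes_GCRMA": count(lambda s: s.algorithm is Algorithm.GCRMA),
            "votes_MBEI": count(lambda s: s.algorithm is Algorithm.MBEI),
            "votes_MAS5": count(lambda s: s.algorithm is Algorithm.MAS5),
            "votes_MBEI_log2": count(lambda s: s.algorithm is Algorithm.MBEI_LOG2),
            "votes_MAS5_log2": count(lambda s: s.algorithm is Algorithm.MAS5_LOG2),
            "votes_RMA_and_MAS5": count(lambda s: s.algorithm in rma_and_mas5),
            "votes_default_annotation": count(lambda s: s.annotation is Annotation.DEFAULT),
            "votes_alternative_annotation": count(
                lambda s: s.annotation is Annotation.ALTERNATIVE
            ),
        },
        index=vote_matrix.index,
    )
    return features.astype(int)


def unanimous_classify(vote_matrix: pd.DataFrame) -> tuple[pd.Series, float]:
    """Label patients on which every pipeline agrees; others stay unclassified.

    Returns (labels, coverage) where labels take values in
    {'poor', 'good', 'unclassified'} and coverage is the classified fraction.
    """
    if vote_matrix.shape[1] == 0:
        raise ValueError("vote matrix has no pipeline columns")
    total = vote_matrix.sum(axis=1)
    k = vote_matrix.shape[1]
    labels = pd.Series("unclassified", index=vote_matrix.index, dtype=object)
    labels[total == k] = "poor"
    labels[total == 0] = "good"
    coverage = float((labels != "unclassified").mean())
    logger.info(
        "unanimous classifier: %d poor, %d good, %d unclassified (coverage %.1f%%)",
        int((labels == "poor").sum()),
        int((labels == "good").sum()),
        int((labels == "unclassified").sum()),
        100 * coverage,
    )
    return labels, coverage
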