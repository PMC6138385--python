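"""Enumeration of preprocessing pipeline configurations.

A pipeline variant is the triple (normalization algorithm, probe annotation,
dataset handling).  The default configuration space is six algorithms x two
annotations x two handling modes = 24 variants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum


class Algorithm(str, Enum):
    RMA = "RMA"
    MAS5 = "MAS5"
    MBEI = "MBEI"
    GCRMA = "GCRMA"
    MAS5_LOG2 = "MAS5_log2"
    MBEI_LOG2 = "MBEI_log2"


class Annotation(str, Enum):
    DEFAULT = "default"
    ALTERNATIVE = "alternative"


class Handling(str, Enum):
    SEPARATE = "separate"
    MERGED = "merged"


#: canonical ordering used for deterministic enumeration
DEFAULT_ALGORITHMS = (
    Algorithm.RMA,
    Algorithm.MAS5,
    Algorithm.MBEI,
    Algorithm.GCRMA,
    Algorithm.MAS5_LOG2,
    Algorithm.MBEI_LOG2,
)
DEFAULT_ANNOTATIONS = (Annotation.DEFAULT, Annotation.ALTERNATIVE)
DEFAULT_HANDLINGS = (Handling.SEPARATE, Handling.MERGED)


@dataclass(frozen=True)
class PipelineSpec:
    """One preprocessing configuration, identified by ``algorithm_annotation_handling``."""

    algorithm: Algorithm
    annotation: Annotation
    handling: Handling

    @property
    def id(self) -> str:
        return f"{self.algorithm.value}_{self.annotation.value}_{self.handling.value}"

    @classmethod
    def from_id(cls, pipeline_id: str) -> "PipelineSpec":
        """Parse an id string back into a spec.

        The algorithm token may itself contain underscores (``MAS5_log2``),
        so the annotation and handling are taken from the right.
        """
        parts = pipeline_id.rsplit("_", 2)
        if len(parts) != 3:
            raise ValueError(f"malformed pipeline id: {pipeline_id!r}")
        algo, annot, hand = parts
        try:
            return cls(Algorithm(algo), Annotation(annot), Handling(hand))
        except ValueError as exc:
            raise ValueError(f"malformed pipeline id: {pipeline_id!r}") from exc

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.id


def enumerate_pipelines(
    algorithms=DEFAULT_ALGORITHMS,
    annotations=DEFAULT_ANNOTATIONS,
    handlings=DEFAULT_HANDLINGS,
) -> list[PipelineSpec]:
    """Cross the three configuration factors into the full list of variants.

    The output order is deterministic: factors vary slowest-to-fastest in the
    order given (algorithm, then annotation, then handling).  Factor lists
    must be non-empty and free of duplicates.
    """
    factors = {
        "algorithms": [Algorithm(a) for a in algorithms],
        "annotations": [Annotation(a) for a in annotations],
        "handlings": [Handling(h) for h in handlings],
    }
    for name, values in factors.items():
        if not values:
            raise ValueError(f"{name} must be non-empty")
        if len(set(values)) != len(values):
            raise ValueError(f"duplicate entries in {name}: {values}")
    return [
        PipelineSpec(algo, annot, hand)
        for algo, annot, hand in itertools.product(
            factors["algorithms"], factors["annotations"], factors["handlings"]
        )
    ]
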