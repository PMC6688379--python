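"""Additive per-entity scoring of one patient against a knowledge base.

The score of an entity is the sum, over every symptom the patient presently
has, of that symptom's linkage weight for the entity. Absent and untested
symptoms contribute nothing: a "No" never subtracts — negative evidence
enters only through negatively weighted symptoms that ARE present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

from .knowledge_base import EntityKind, KnowledgeBase
from .patient_io import PatientRecord, Response

__all__ = ["ScoreVector", "score_patient"]


@dataclass(frozen=True)
class ScoreVector:
    """Integer score for every entity of a catalog, for one patient."""

    entity_kind: EntityKind
    scores: Mapping[str, int]
    entity_order: tuple[str, ...]

    def ranked(self) -> list[tuple[str, int]]:
        """Entities sorted by score descending, ties in catalog order."""
        order = {e: i for i, e in enumerate(self.entity_order)}
        return sorted(
            self.scores.items(), key=lambda kv: (-kv[1], order[kv[0]])
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "entity_kind": self.entity_kind.value,
                "scores": {e: s for e, s in self.ranked()},
            },
            indent=1,
        )


def score_patient(patient: PatientRecord, kb: KnowledgeBase) -> ScoreVector:
    """Score one entry mask: score(e) = sum of weight(e, s) over PRESENT s."""
    unknown = [s for s in patient.responses if s not in kb.symptom_catalog]
    if unknown:
        raise KeyError(
            f"patient {patient.patient_id!r} has symptoms outside the "
            f"knowledge base catalog: {unknown}"
        )
    present = [
        s for s, r in patient.responses.items() if r is Response.PRESENT
    ]
    scores = {
        e: sum(kb.weight(e, s) for s in present)
        for e in kb.entity_catalog.entities
    }
    return ScoreVector(
        entity_kind=kb.entity_kind,
        scores=scores,
        entity_order=kb.entity_catalog.entities,
    )
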