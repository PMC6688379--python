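"""Shortlist interpretation of a score vector.

Diseases (three rules):

1. The result is every disease scoring at least as high as the
   second-ranked score — nominally the top two, expanded by ties.
2. A shortlist of more than five diseases is "not helpful".
3. If one disease scores at least three points above every other, it is
   the sole result ("dominant"); this overrides the other rules.

Brain zones (three rules, similar but not identical):

1. The result is every zone scoring at least the second-ranked score
   among surviving zones.
2. Scores of one point or less are ignored — unless one point is the
   highest existing score, in which case the one-point zones survive.
3. A shortlist of more than four zones is "not helpful". A vector whose
   maximum is zero or negative leaves no survivor and is likewise not
   helpful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .knowledge_base import EntityKind
from .scoring import ScoreVector

__all__ = [
    "InterpretationResult",
    "interpret_disease_scores",
    "interpret_zone_scores",
    "interpret_scores",
    "MAX_DISEASE_SHORTLIST",
    "MAX_ZONE_SHORTLIST",
    "DOMINANCE_MARGIN",
    "ZONE_MIN_SCORE",
]

MAX_DISEASE_SHORTLIST = 5
MAX_ZONE_SHORTLIST = 4
DOMINANCE_MARGIN = 3
ZONE_MIN_SCORE = 2  # zone scores below this are ignored (with the max==1 exception)


@dataclass(frozen=True)
class InterpretationResult:
    entity_kind: EntityKind
    shortlist: tuple[str, ...]  # catalog order; empty iff not_helpful
    not_helpful: bool
    dominant: bool = False

    def __post_init__(self) -> None:
        if self.not_helpful and self.shortlist:
            raise ValueError("a not-helpful result has an empty shortlist")
        if self.dominant and len(self.shortlist) != 1:
            raise ValueError("a dominant result names exactly one entity")

    def to_json(self, scores: ScoreVector | None = None) -> str:
        payload: dict = {
            "entity_kind": self.entity_kind.value,
            "shortlist": list(self.shortlist),
            "not_helpful": self.not_helpful,
            "dominant": self.dominant,
        }
        if scores is not None:
            payload["scores"] = {e: s for e, s in scores.ranked()}
        return json.dumps(payload, indent=1)


def _top_two_with_ties(ranked: list[tuple[str, int]]) -> list[str]:
    """Entities scoring >= the second-ranked score (all of them, if only one)."""
    if len(ranked) == 1:
        return [ranked[0][0]]
    cutoff = ranked[1][1]
    return [e for e, s in ranked if s >= cutoff]


def interpret_disease_scores(scores: ScoreVector) -> InterpretationResult:
    if scores.entity_kind is not EntityKind.DISEASE:
        raise ValueError("disease rules applied to a non-disease score vector")
    ranked = scores.ranked()

    # rule 3 first: dominance overrides the shortlist and the size cap
    top_entity, top_score = ranked[0]
    if all(top_score >= s + DOMINANCE_MARGIN for _, s in ranked[1:]):
        return InterpretationResult(
            entity_kind=scores.entity_kind,
            shortlist=(top_entity,),
            not_helpful=False,
            dominant=True,
        )

    shortlist = _top_two_with_ties(ranked)
    if len(shortlist) > MAX_DISEASE_SHORTLIST:
        return InterpretationResult(scores.entity_kind, (), not_helpful=True)
    in_catalog_order = tuple(e for e in scores.entity_order if e in set(shortlist))
    return InterpretationResult(scores.entity_kind, in_catalog_order, not_helpful=False)


def interpret_zone_scores(scores: ScoreVector) -> InterpretationResult:
    if scores.entity_kind is not EntityKind.BRAIN_ZONE:
        raise ValueError("zone rules applied to a non-zone score vector")
    ranked = scores.ranked()
    top_score = ranked[0][1]

    if top_score == 1:
        survivors = [(e, s) for e, s in ranked if s == 1]
    else:
        survivors = [(e, s) for e, s in ranked if s >= ZONE_MIN_SCORE]
    if not survivors:  # max score <= 0: nothing localizes
        return InterpretationResult(scores.entity_kind, (), not_helpful=True)

    shortlist = _top_two_with_ties(survivors)
    if len(shortlist) > MAX_ZONE_SHORTLIST:
        return InterpretationResult(scores.entity_kind, (), not_helpful=True)
    in_catalog_order = tuple(e for e in scores.entity_order if e in set(shortlist))
    return InterpretationResult(scores.entity_kind, in_catalog_order, not_helpful=False)


def interpret_scores(scores: ScoreVector) -> InterpretationResult:
    """Dispatch to the disease or zone rules by the vector's entity kind."""
    if scores.entity_kind is EntityKind.DISEASE:
        return interpret_disease_scores(scores)
    return interpret_zone_scores(scores)
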