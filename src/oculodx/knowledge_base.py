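"""Entity x symptom linkage matrices: the medical content of the scoring algorithm.

A knowledge base (KB) is a table of diseases (or brain zones) against clinical
signs and symptoms. Each cell holds a small integer weight expressing how
strongly the symptom argues for (positive) or against (negative) the entity.
Weights are usually written as symbolic linkage codes:

====== ====== =================================================
code   weight meaning
====== ====== =================================================
NEV    -3     (almost) never occurs with the entity
OTTD   -2     occurs, but points to a different diagnosis
UL     -1     unlikely to occur with the entity
N       0     no linkage
Y      +1     occurs with the entity (diseases only)
R      +1     related to the entity (brain zones only)
HR     +2     highly related -- very typical of the entity
====== ====== =================================================

Bare integers in [-3, +4] are accepted alongside the codes; brain-zone
matrices must be non-negative (a lesion site is never argued against).
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

__all__ = [
    "EntityKind",
    "SymptomGroup",
    "SymptomCatalog",
    "EntityCatalog",
    "KnowledgeBase",
    "KnowledgeBaseError",
    "CODE_TO_WEIGHT",
    "WEIGHT_MIN",
    "WEIGHT_MAX",
    "code_weight",
    "weight_code",
    "load_knowledge_base",
    "write_knowledge_base",
    "validate_knowledge_base",
]

WEIGHT_MIN = -3
WEIGHT_MAX = 4

CODE_TO_WEIGHT: dict[str, int] = {
    "NEV": -3,
    "OTTD": -2,
    "UL": -1,
    "N": 0,
    "Y": 1,
    "R": 1,
    "HR": 2,
}

#: codes legal only in disease matrices / only in zone matrices
_DISEASE_ONLY = frozenset({"NEV", "OTTD", "UL", "Y"})
_ZONE_ONLY = frozenset({"R"})


class EntityKind(str, enum.Enum):
    DISEASE = "DISEASE"
    BRAIN_ZONE = "BRAIN_ZONE"


class SymptomGroup(str, enum.Enum):
    GENERAL = "GENERAL"
    OCULOMOTOR = "OCULOMOTOR"


class KnowledgeBaseError(ValueError):
    """Raised on malformed or invalid knowledge-base input."""


def code_weight(code: str, entity_kind: EntityKind) -> int:
    """Translate a linkage code to its integer weight, enforcing kind rules."""
    token = code.strip()
    if token not in CODE_TO_WEIGHT:
        raise KnowledgeBaseError(f"unknown linkage code {token!r}")
    if entity_kind is EntityKind.DISEASE and token in _ZONE_ONLY:
        raise KnowledgeBaseError(
            f"code {token!r} is only valid in a brain-zone matrix"
        )
    if entity_kind is EntityKind.BRAIN_ZONE and token in _DISEASE_ONLY:
        raise KnowledgeBaseError(
            f"code {token!r} is only valid in a disease matrix"
        )
    return CODE_TO_WEIGHT[token]


def weight_code(weight: int, entity_kind: EntityKind) -> str:
    """Canonical textual cell for a weight: a code where one exists, else digits."""
    if weight == 0:
        return "N"
    if weight == 1:
        return "Y" if entity_kind is EntityKind.DISEASE else "R"
    if weight == 2:
        return "HR"
    if entity_kind is EntityKind.DISEASE:
        for code, w in CODE_TO_WEIGHT.items():
            if w == weight and code in _DISEASE_ONLY:
                return code
    return str(weight)


@dataclass(frozen=True)
class SymptomCatalog:
    """Ordered catalog of symptom identifiers with their group labels.

    The reference catalog of the diagnostic tool has 60 symptoms split into
    general-neurological and ocular motor groups, but any non-empty unique
    list is accepted.
    """

    symptoms: tuple[str, ...]
    groups: Mapping[str, SymptomGroup] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.symptoms:
            raise KnowledgeBaseError("symptom catalog must be non-empty")
        if len(set(self.symptoms)) != len(self.symptoms):
            dupes = _duplicates(self.symptoms)
            raise KnowledgeBaseError(f"duplicate symptom identifiers: {dupes}")
        if any(not s for s in self.symptoms):
            raise KnowledgeBaseError("empty symptom identifier")

    def __contains__(self, symptom: str) -> bool:
        return symptom in set(self.symptoms)

    def __len__(self) -> int:
        return len(self.symptoms)

    def group_of(self, symptom: str) -> SymptomGroup:
        return self.groups.get(symptom, SymptomGroup.GENERAL)


@dataclass(frozen=True)
class EntityCatalog:
    """Ordered catalog of diseases or brain zones."""

    entities: tuple[str, ...]
    entity_kind: EntityKind

    def __post_init__(self) -> None:
        if not self.entities:
            raise KnowledgeBaseError("entity catalog must be non-empty")
        if len(set(self.entities)) != len(self.entities):
            dupes = _duplicates(self.entities)
            raise KnowledgeBaseError(f"duplicate entity identifiers: {dupes}")

    def __contains__(self, entity: str) -> bool:
        return entity in set(self.entities)

    def __len__(self) -> int:
        return len(self.entities)


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


@dataclass(frozen=True)
class KnowledgeBase:
    """A validated entity x symptom weight matrix.

    ``weights`` maps ``(entity, symptom)`` to an integer; pairs absent from
    the mapping carry weight 0 ("N", no linkage).
    """

    symptom_catalog: SymptomCatalog
    entity_catalog: EntityCatalog
    weights: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        # canonical form: zero weights are implicit, so weight-map equality
        # is exact across a serialization round-trip
        object.__setattr__(
            self, "weights", {k: w for k, w in dict(self.weights).items() if w != 0}
        )

    @property
    def entity_kind(self) -> EntityKind:
        return self.entity_catalog.entity_kind

    def weight(self, entity: str, symptom: str) -> int:
        return self.weights.get((entity, symptom), 0)

    def positive_symptoms(self, entity: str) -> tuple[str, ...]:
        """Symptoms with weight >= +1 for ``entity``, in catalog order."""
        return tuple(
            s for s in self.symptom_catalog.symptoms if self.weight(entity, s) >= 1
        )

    def to_frame(self) -> pd.DataFrame:
        """Dense weight matrix as a DataFrame (symptoms x entities)."""
        return pd.DataFrame(
            [
                [self.weight(e, s) for e in self.entity_catalog.entities]
                for s in self.symptom_catalog.symptoms
            ],
            index=list(self.symptom_catalog.symptoms),
            columns=list(self.entity_catalog.entities),
            dtype=int,
        )


# ---------------------------------------------------------------------------
# validation

def validate_knowledge_base(kb: KnowledgeBase) -> list[str]:
    """Check every type invariant; return one finding string per violation.

    An empty list means the knowledge base is valid. Findings name the
    offending cell so a curator can fix the source table.
    """
    findings: list[str] = []
    for (entity, symptom), w in kb.weights.items():
        if entity not in kb.entity_catalog:
            findings.append(f"weight references unknown entity {entity!r}")
            continue
        if symptom not in kb.symptom_catalog:
            findings.append(f"weight references unknown symptom {symptom!r}")
            continue
        if not isinstance(w, (int,)) or isinstance(w, bool):
            findings.append(f"non-integer weight at ({entity!r}, {symptom!r}): {w!r}")
            continue
        if not (WEIGHT_MIN <= w <= WEIGHT_MAX):
            findings.append(
                f"weight {w} at ({entity!r}, {symptom!r}) outside "
                f"[{WEIGHT_MIN}, {WEIGHT_MAX}]"
            )
        elif kb.entity_kind is EntityKind.BRAIN_ZONE and w < 0:
            findings.append(
                f"negative weight {w} at ({entity!r}, {symptom!r}) "
                "in a brain-zone matrix"
            )
    return findings


# ---------------------------------------------------------------------------
# I/O

_KIND_HEADER = "# entity_kind:"


def load_knowledge_base(
    source: TextIO | str,
    entity_kind: EntityKind | str | None = None,
    *,
    delimiter: str | None = None,
) -> KnowledgeBase:
    """Load a KB from delimited text (TSV by default, CSV autodetected).

    Layout: optional ``# entity_kind: DISEASE|BRAIN_ZONE`` comment line, then
    a header row ``symptom<TAB>Entity1<TAB>...``; cells are linkage codes,
    bare integers, or empty (== N). ``entity_kind`` overrides the comment
    line; one of the two must supply the kind.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    text = source.read()
    lines = text.splitlines()
    declared_kind: EntityKind | None = None
    body_start = 0
    for i, line in enumerate(lines):
        stripped = line.strip()
        if stripped.startswith(_KIND_HEADER):
            declared_kind = EntityKind(stripped[len(_KIND_HEADER):].strip())
            continue
        if stripped.startswith("#") or not stripped:
            continue
        body_start = i
        break
    if entity_kind is None:
        entity_kind = declared_kind
    if entity_kind is None:
        raise KnowledgeBaseError(
            "entity_kind not given and no '# entity_kind:' header present"
        )
    entity_kind = EntityKind(entity_kind)

    body = "\n".join(lines[body_start:])
    header = lines[body_start]
    if delimiter is None:
        delimiter = "\t" if "\t" in header else ","
    raw_entities = [c.strip() for c in header.split(delimiter)[1:]]
    if len(set(raw_entities)) != len(raw_entities):
        raise KnowledgeBaseError(
            f"duplicate entity identifiers: {_duplicates(raw_entities)}"
        )
    df = pd.read_csv(
        io.StringIO(body), sep=delimiter, dtype=str, keep_default_na=False
    )
    if df.shape[1] < 2:
        raise KnowledgeBaseError("table needs a symptom column plus >=1 entity column")

    symptom_col = df.columns[0]
    entities = tuple(c.strip() for c in df.columns[1:])
    symptoms = tuple(s.strip() for s in df[symptom_col].tolist())

    entity_catalog = EntityCatalog(entities=entities, entity_kind=entity_kind)
    symptom_catalog = SymptomCatalog(symptoms=symptoms)

    weights: dict[tuple[str, str], int] = {}
    for row_idx, symptom in enumerate(symptoms):
        for col_idx, entity in enumerate(entities):
            raw = str(df.iat[row_idx, col_idx + 1]).strip()
            where = f"row {row_idx + 2} ({symptom!r}), column {entity!r}"
            if raw == "" or raw.lower() == "nan":
                continue
            try:
                w = int(raw)
            except ValueError:
                try:
                    w = code_weight(raw, entity_kind)
                except KnowledgeBaseError as exc:
                    raise KnowledgeBaseError(f"{exc} at {where}") from None
            else:
                if not (WEIGHT_MIN <= w <= WEIGHT_MAX):
                    raise KnowledgeBaseError(
                        f"integer weight {w} outside [{WEIGHT_MIN}, {WEIGHT_MAX}] "
                        f"at {where}"
                    )
                if entity_kind is EntityKind.BRAIN_ZONE and w < 0:
                    raise KnowledgeBaseError(
                        f"negative weight {w} in brain-zone matrix at {where}"
                    )
            if w != 0:
                weights[(entity, symptom)] = w

    kb = KnowledgeBase(
        symptom_catalog=symptom_catalog,
        entity_catalog=entity_catalog,
        weights=weights,
    )
    findings = validate_knowledge_base(kb)
    if findings:
        raise KnowledgeBaseError("; ".join(findings))
    return kb


def write_knowledge_base(
    kb: KnowledgeBase, sink: TextIO | None = None, *, delimiter: str = "\t"
) -> str:
    """Serialize a KB to delimited text; ``load(write(kb))`` is the identity.

    Cells are emitted as canonical codes where one exists for the weight
    (N, Y/R, HR, UL, OTTD, NEV) and as bare integers otherwise (+3, +4).
    """
    rows = [f"{_KIND_HEADER} {kb.entity_kind.value}"]
    rows.append(delimiter.join(["symptom", *kb.entity_catalog.entities]))
    for s in kb.symptom_catalog.symptoms:
        cells = [
            weight_code(kb.weight(e, s), kb.entity_kind)
            for e in kb.entity_catalog.entities
        ]
        rows.append(delimiter.join([s, *cells]))
    text = "\n".join(rows) + "\n"
    if sink is not None:
        sink.write(text)
    return text
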