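"""Tri-state patient entry masks and labeled cohorts.

Every symptom of the catalog is answered "Yes" (present), "No" (absent) or
"0" (not tested / not testable); an empty field also means not tested. The
distinction between absent and untested is preserved end to end — the
scoring engine treats them identically, but downstream consumers (and the
round-trip serialization) must not conflate them.
"""

from __future__ import annotations

import enum
import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .knowledge_base import EntityCatalog, SymptomCatalog

__all__ = [
    "Response",
    "PatientRecord",
    "LabeledPatient",
    "PatientIOError",
    "read_patients",
    "write_patients",
    "read_labels",
    "write_labels",
]

_ZONE_SEP = ";"


class PatientIOError(ValueError):
    """Raised on malformed entry masks or label files."""


class Response(enum.Enum):
    PRESENT = "Yes"
    ABSENT = "No"
    UNTESTED = "0"


# read tokens case-insensitively; always write the canonical token
_TOKEN_TO_RESPONSE = {
    "yes": Response.PRESENT,
    "no": Response.ABSENT,
    "0": Response.UNTESTED,
    "": Response.UNTESTED,
}


def parse_token(token: str) -> Response:
    key = token.strip().lower()
    if key not in _TOKEN_TO_RESPONSE:
        raise PatientIOError(f"unknown response token {token!r}")
    return _TOKEN_TO_RESPONSE[key]


@dataclass(frozen=True)
class PatientRecord:
    """One patient's entry mask: symptom -> tri-state response.

    Symptoms absent from ``responses`` are UNTESTED. Construction validates
    symptom names against the governing catalog.
    """

    patient_id: str
    responses: Mapping[str, Response]
    catalog: SymptomCatalog

    def __post_init__(self) -> None:
        unknown = [s for s in self.responses if s not in self.catalog]
        if unknown:
            raise PatientIOError(
                f"patient {self.patient_id!r}: symptoms not in catalog: {unknown}"
            )
        # drop explicit UNTESTED entries: absent-from-mapping is the same state
        object.__setattr__(
            self,
            "responses",
            {
                s: r
                for s, r in dict(self.responses).items()
                if r is not Response.UNTESTED
            },
        )

    def response(self, symptom: str) -> Response:
        return self.responses.get(symptom, Response.UNTESTED)

    def present_symptoms(self) -> tuple[str, ...]:
        return tuple(
            s for s in self.catalog.symptoms
            if self.responses.get(s) is Response.PRESENT
        )


@dataclass(frozen=True)
class LabeledPatient:
    """Entry mask plus ground truth: exactly one disease, 0..n brain zones.

    ``zones_evaluable`` lets a cohort exclude a patient from the brain-zone
    accuracy tables while keeping it in the disease tables.
    """

    record: PatientRecord
    true_disease: str
    true_zones: frozenset[str] = frozenset()
    zones_evaluable: bool = True

    def validate(
        self, disease_catalog: EntityCatalog, zone_catalog: EntityCatalog
    ) -> None:
        if self.true_disease not in disease_catalog:
            raise PatientIOError(
                f"patient {self.record.patient_id!r}: unknown disease "
                f"{self.true_disease!r}"
            )
        unknown = sorted(set(self.true_zones) - set(zone_catalog.entities))
        if unknown:
            raise PatientIOError(
                f"patient {self.record.patient_id!r}: unknown zones {unknown}"
            )


# ---------------------------------------------------------------------------
# entry-mask I/O

def read_patients(
    source: TextIO | str, catalog: SymptomCatalog, *, fmt: str | None = None
) -> list[PatientRecord]:
    """Read entry masks from wide CSV/TSV or JSON.

    Tabular layout: one row per patient, first column ``patient_id``, one
    column per symptom, tokens in {Yes, No, 0, empty}. JSON layout:
    ``{patient_id: {symptom: token}}``.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    text = source.read()
    if fmt is None:
        fmt = "json" if text.lstrip().startswith("{") else "table"

    if fmt == "json":
        payload = json.loads(text)
        records = []
        for pid, answers in payload.items():
            responses = {}
            for symptom, token in answers.items():
                try:
                    responses[symptom] = parse_token(str(token))
                except PatientIOError as exc:
                    raise PatientIOError(
                        f"patient {pid!r}, symptom {symptom!r}: {exc}"
                    ) from None
            records.append(PatientRecord(pid, responses, catalog))
        return records

    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)
    id_col = df.columns[0]
    symptom_cols = [c.strip() for c in df.columns[1:]]
    records = []
    for row_idx, row in df.iterrows():
        pid = str(row[id_col]).strip()
        responses = {}
        for col_pos, symptom in enumerate(symptom_cols):
            token = str(row.iloc[col_pos + 1])
            try:
                responses[symptom] = parse_token(token)
            except PatientIOError:
                raise PatientIOError(
                    f"unknown response token {token!r} at row {row_idx + 2}, "
                    f"column {symptom!r}"
                ) from None
        records.append(PatientRecord(pid, responses, catalog))
    return records


def write_patients(
    patients: Sequence[PatientRecord],
    sink: TextIO | None = None,
    *,
    fmt: str = "table",
    delimiter: str = ",",
) -> str:
    """Serialize entry masks; inverse of :func:`read_patients`."""
    if fmt == "json":
        payload = {
            p.patient_id: {
                s: p.response(s).value for s in p.catalog.symptoms
            }
            for p in patients
        }
        text = json.dumps(payload, indent=1)
    else:
        if patients:
            catalog = patients[0].catalog
        else:
            raise PatientIOError("cannot infer symptom columns from empty patient list")
        header = delimiter.join(["patient_id", *catalog.symptoms])
        lines = [header]
        for p in patients:
            cells = [p.response(s).value for s in catalog.symptoms]
            lines.append(delimiter.join([p.patient_id, *cells]))
        text = "\n".join(lines) + "\n"
    if sink is not None:
        sink.write(text)
    return text


# ---------------------------------------------------------------------------
# cohort label I/O

def read_labels(
    source: TextIO | str,
    patients: Sequence[PatientRecord],
    disease_catalog: EntityCatalog,
    zone_catalog: EntityCatalog,
) -> list[LabeledPatient]:
    """Attach ground-truth labels (CSV: patient_id, true_disease, true_zones
    [, zones_evaluable]) to entry masks; zones are a semicolon-separated set."""
    if isinstance(source, str):
        source = io.StringIO(source)
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    required = {"patient_id", "true_disease", "true_zones"}
    missing = required - set(df.columns)
    if missing:
        raise PatientIOError(f"label file missing columns: {sorted(missing)}")
    by_id = {p.patient_id: p for p in patients}
    labeled = []
    for _, row in df.iterrows():
        pid = str(row["patient_id"]).strip()
        if pid not in by_id:
            raise PatientIOError(f"label for unknown patient {pid!r}")
        zones = frozenset(
            z.strip() for z in str(row["true_zones"]).split(_ZONE_SEP) if z.strip()
        )
        evaluable = True
        if "zones_evaluable" in df.columns:
            evaluable = str(row["zones_evaluable"]).strip().lower() not in {
                "false", "0", "no",
            }
        lp = LabeledPatient(
            record=by_id[pid],
            true_disease=str(row["true_disease"]).strip(),
            true_zones=zones,
            zones_evaluable=evaluable,
        )
        lp.validate(disease_catalog, zone_catalog)
        labeled.append(lp)
    return labeled


def write_labels(
    cohort: Sequence[LabeledPatient], sink: TextIO | None = None
) -> str:
    lines = ["patient_id,true_disease,true_zones,zones_evaluable"]
    for lp in cohort:
        zones = _ZONE_SEP.join(sorted(lp.true_zones))
        lines.append(
            f"{lp.record.patient_id},{lp.true_disease},{zones},"
            f"{str(lp.zones_evaluable).lower()}"
        )
    text = "\n".join(lines) + "\n"
    if sink is not None:
        sink.write(text)
    return text
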