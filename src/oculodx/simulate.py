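"""Synthetic labeled cohorts drawn from a knowledge base.

Real entry-mask data for this class of tool is not publicly deposited, so
the pipeline is exercised on simulated patients instead. A patient with
disease ``d`` is generated symptom by symptom with independent Bernoulli
draws conditioned on the knowledge-base linkage:

* weight >= +2 (highly related): present with ``p_typical + p_hr_boost``
* weight == +1: present with ``p_typical`` (incomplete penetrance)
* weight == 0: present with ``p_spurious`` (comorbidity / exam noise)
* weight <= -1: never present — a negative linkage encodes a symptom
  unlikely to occur with the disease, and the generator honours that.

Each response is then independently masked to UNTESTED with ``p_untested``,
emulating incomplete clinical examinations. True brain zones come from a
disease -> zones map. Everything is reproducible: one global seed, one
per-patient substream derived as ``SeedSequence([seed, patient_index])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .accuracy import evaluate_cohort
from .knowledge_base import EntityKind, KnowledgeBase
from .patient_io import LabeledPatient, PatientRecord, Response

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "noise_sweep"]


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings.

    counts
        patients per disease (catalog ids -> n >= 0).
    p_typical
        probability a positively linked (weight >= +1) symptom is present.
    p_hr_boost
        additive bump for highly related (weight >= +2) symptoms;
        ``p_typical + p_hr_boost <= 1``.
    p_spurious
        probability an unlinked (weight 0) symptom is present anyway.
    p_untested
        probability any response is masked to "not tested" afterwards.
    seed
        global integer seed; identical config + seed => identical cohort.
    """

    counts: Mapping[str, int]
    p_typical: float = 0.8
    p_hr_boost: float = 0.15
    p_spurious: float = 0.05
    p_untested: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_typical", "p_hr_boost", "p_spurious", "p_untested"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_typical + self.p_hr_boost > 1.0 + 1e-12:
            raise ValueError("p_typical + p_hr_boost must be <= 1")
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("per-disease counts must be >= 0")


@dataclass(frozen=True)
class SyntheticCohort:
    patients: tuple[LabeledPatient, ...]
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.patients)


def _symptom_probability(weight: int, config: CohortConfig) -> float:
    if weight >= 2:
        return config.p_typical + config.p_hr_boost
    if weight == 1:
        return config.p_typical
    if weight <= -1:
        return 0.0
    return config.p_spurious


def generate_cohort(
    disease_kb: KnowledgeBase,
    zone_map: Mapping[str, frozenset[str] | set[str]],
    config: CohortConfig,
) -> SyntheticCohort:
    """Draw a labeled cohort of ``sum(config.counts.values())`` patients.

    Patients are generated disease by disease in knowledge-base catalog
    order, so the cohort layout is deterministic; the patient index feeds
    the per-patient RNG substream.
    """
    if disease_kb.entity_kind is not EntityKind.DISEASE:
        raise ValueError("generate_cohort needs a disease knowledge base")
    unknown = set(config.counts) - set(disease_kb.entity_catalog.entities)
    if unknown:
        raise ValueError(f"counts name unknown diseases: {sorted(unknown)}")

    catalog = disease_kb.symptom_catalog
    patients: list[LabeledPatient] = []
    patient_index = 0
    for disease in disease_kb.entity_catalog.entities:
        n = int(config.counts.get(disease, 0))
        zones = frozenset(zone_map.get(disease, frozenset()))
        for _ in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(config.seed), patient_index])
            )
            present_draw = rng.random(len(catalog.symptoms))
            untested_draw = rng.random(len(catalog.symptoms))
            responses: dict[str, Response] = {}
            for j, symptom in enumerate(catalog.symptoms):
                p = _symptom_probability(disease_kb.weight(disease, symptom), config)
                r = Response.PRESENT if present_draw[j] < p else Response.ABSENT
                if untested_draw[j] < config.p_untested:
                    r = Response.UNTESTED
                responses[symptom] = r
            record = PatientRecord(
                patient_id=f"sim{patient_index:04d}",
                responses=responses,
                catalog=catalog,
            )
            patients.append(
                LabeledPatient(
                    record=record, true_disease=disease, true_zones=zones
                )
            )
            patient_index += 1
    return SyntheticCohort(patients=tuple(patients), config=config)


def noise_sweep(
    disease_kb: KnowledgeBase,
    zone_kb: KnowledgeBase,
    zone_map: Mapping[str, frozenset[str] | set[str]],
    base_config: CohortConfig,
    p_spurious_grid: Sequence[float],
    replicates: int,
) -> pd.DataFrame:
    """Mean per-disease sensitivity/specificity across replicate cohorts at
    each spurious-symptom noise level.

    Replicate ``r`` at grid position ``g`` uses seed
    ``base_config.seed + 100_000 * g + r`` so every cell of the sweep is an
    independent but reproducible cohort. Returns a tidy DataFrame with
    columns p_spurious, disease, mean_sensitivity_pct, mean_specificity_pct.
    """
    records: list[dict] = []
    for g, p_spurious in enumerate(p_spurious_grid):
        per_disease_sens: dict[str, list[float]] = {}
        per_disease_spec: dict[str, list[float]] = {}
        for r in range(replicates):
            config = replace(
                base_config,
                p_spurious=float(p_spurious),
                seed=base_config.seed + 100_000 * g + r,
            )
            cohort = generate_cohort(disease_kb, zone_map, config)
            disease_rows, _ = evaluate_cohort(
                list(cohort.patients), disease_kb, zone_kb
            )
            for row in disease_rows:
                if row.sensitivity_pct is not None:
                    per_disease_sens.setdefault(row.entity, []).append(
                        row.sensitivity_pct
                    )
                if row.specificity_pct is not None:
                    per_disease_spec.setdefault(row.entity, []).append(
                        row.specificity_pct
                    )
        for disease in disease_kb.entity_catalog.entities:
            if disease not in per_disease_sens and disease not in per_disease_spec:
                continue
            records.append(
                {
                    "p_spurious": float(p_spurious),
                    "disease": disease,
                    "mean_sensitivity_pct": float(
                        np.mean(per_disease_sens.get(disease, [np.nan]))
                    ),
                    "mean_specificity_pct": float(
                        np.mean(per_disease_spec.get(disease, [np.nan]))
                    ),
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["p_spurious", "disease", "mean_sensitivity_pct", "mean_specificity_pct"],
    )
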