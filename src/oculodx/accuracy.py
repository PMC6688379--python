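"""Shortlist confusion accounting and diagnostic-accuracy tables.

Because the result of the algorithm is a shortlist (usually two entities)
rather than a single call, the confusion bookkeeping is per entity and per
patient: the true entity appearing in the shortlist is a true positive,
every incorrect shortlist member a false positive, every entity in neither
the truth nor the shortlist a true negative. A "not helpful" result counts
as a false negative for the true entity and a false positive for every
other entity. Brain-zone truth is a set, so each true zone is scored
present/missing independently (multi-label extension of the same rules).

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), with 95% confidence
intervals from the Wald (asymptotic-normal) binomial construction,
truncated to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import norm

from .interpretation import (
    InterpretationResult,
    interpret_disease_scores,
    interpret_zone_scores,
)
from .knowledge_base import EntityCatalog, EntityKind, KnowledgeBase
from .patient_io import LabeledPatient
from .scoring import score_patient

__all__ = [
    "ConfusionTally",
    "AccuracyRow",
    "Z_95",
    "wald_ci",
    "tally_disease_result",
    "tally_zone_result",
    "accuracy_table",
    "accuracy_frame",
    "evaluate_cohort",
]

#: exact two-sided 95% normal quantile (1.959964 to the precision that matters)
Z_95: float = float(norm.ppf(0.975))


@dataclass
class ConfusionTally:
    """Per-entity TP/FP/TN/FN counts; only ever incremented."""

    entity: str
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _round_half_up(x: float, ndigits: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{ndigits}"), ROUND_HALF_UP))


def wald_ci(k: int, n: int, *, z: float = Z_95) -> tuple[float, float] | None:
    """95% Wald interval for a binomial proportion, truncated to [0, 1].

    Returns ``None`` for n == 0 (undefined interval). Bounds are raw floats;
    presentation rounding (3 decimals, half-up) happens in the table layer.
    """
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n == 0:
        return None
    p = k / n
    half = z * (p * (1.0 - p) / n) ** 0.5
    return (max(0.0, p - half), min(1.0, p + half))


@dataclass(frozen=True)
class AccuracyRow:
    """One line of an accuracy table: raw fractions, percents, CI bounds.

    Percents are rounded half-up to 1 decimal, CI bounds to 3 decimals; the
    raw numerators/denominators are always carried alongside. A zero
    denominator leaves the percent and interval ``None``.
    """

    entity: str
    sens_num: int
    sens_den: int
    spec_num: int
    spec_den: int
    sensitivity_pct: float | None
    specificity_pct: float | None
    sens_ci: tuple[float, float] | None
    spec_ci: tuple[float, float] | None


def tally_disease_result(
    truth: str,
    result: InterpretationResult,
    catalog: EntityCatalog,
    tallies: Mapping[str, ConfusionTally],
) -> None:
    """Apply one patient's disease result to the running tallies in place."""
    if truth not in catalog:
        raise KeyError(f"true disease {truth!r} not in catalog")
    if result.not_helpful:
        for e in catalog.entities:
            if e == truth:
                tallies[e].fn += 1
            else:
                tallies[e].fp += 1
        return
    shortlist = set(result.shortlist)
    for e in catalog.entities:
        if e == truth:
            if e in shortlist:
                tallies[e].tp += 1
            else:
                tallies[e].fn += 1
        elif e in shortlist:
            tallies[e].fp += 1
        else:
            tallies[e].tn += 1


def tally_zone_result(
    truth_zones: Iterable[str],
    result: InterpretationResult,
    catalog: EntityCatalog,
    tallies: Mapping[str, ConfusionTally],
) -> None:
    """Multi-label tally: each true zone is a positive, every other a negative."""
    truth = set(truth_zones)
    unknown = truth - set(catalog.entities)
    if unknown:
        raise KeyError(f"true zones not in catalog: {sorted(unknown)}")
    if result.not_helpful:
        for e in catalog.entities:
            if e in truth:
                tallies[e].fn += 1
            else:
                tallies[e].fp += 1
        return
    shortlist = set(result.shortlist)
    for e in catalog.entities:
        if e in truth:
            if e in shortlist:
                tallies[e].tp += 1
            else:
                tallies[e].fn += 1
        elif e in shortlist:
            tallies[e].fp += 1
        else:
            tallies[e].tn += 1


def accuracy_table(
    tallies: Sequence[ConfusionTally], *, z: float = Z_95
) -> list[AccuracyRow]:
    """Derive sensitivity/specificity rows (with Wald CIs) from raw tallies."""
    rows = []
    for t in tallies:
        sens_den = t.tp + t.fn
        spec_den = t.tn + t.fp
        sens_pct = (
            _round_half_up(100.0 * t.tp / sens_den, 1) if sens_den else None
        )
        spec_pct = (
            _round_half_up(100.0 * t.tn / spec_den, 1) if spec_den else None
        )
        sens_ci = wald_ci(t.tp, sens_den, z=z) if sens_den else None
        spec_ci = wald_ci(t.tn, spec_den, z=z) if spec_den else None
        round3 = lambda ci: (  # noqa: E731
            (_round_half_up(ci[0], 3), _round_half_up(ci[1], 3)) if ci else None
        )
        rows.append(
            AccuracyRow(
                entity=t.entity,
                sens_num=t.tp,
                sens_den=sens_den,
                spec_num=t.tn,
                spec_den=spec_den,
                sensitivity_pct=sens_pct,
                specificity_pct=spec_pct,
                sens_ci=round3(sens_ci),
                spec_ci=round3(spec_ci),
            )
        )
    return rows


def accuracy_frame(rows: Sequence[AccuracyRow]) -> pd.DataFrame:
    """Accuracy rows as a DataFrame mirroring the published table layout."""
    return pd.DataFrame(
        {
            "entity": [r.entity for r in rows],
            "sens_num": [r.sens_num for r in rows],
            "sens_den": [r.sens_den for r in rows],
            "sensitivity_pct": [r.sensitivity_pct for r in rows],
            "sens_ci_low": [r.sens_ci[0] if r.sens_ci else None for r in rows],
            "sens_ci_high": [r.sens_ci[1] if r.sens_ci else None for r in rows],
            "spec_num": [r.spec_num for r in rows],
            "spec_den": [r.spec_den for r in rows],
            "specificity_pct": [r.specificity_pct for r in rows],
            "spec_ci_low": [r.spec_ci[0] if r.spec_ci else None for r in rows],
            "spec_ci_high": [r.spec_ci[1] if r.spec_ci else None for r in rows],
        }
    )


def evaluate_cohort(
    cohort: Sequence[LabeledPatient],
    disease_kb: KnowledgeBase,
    zone_kb: KnowledgeBase,
) -> tuple[list[AccuracyRow], list[AccuracyRow]]:
    """Run the full pipeline (score -> interpret -> tally -> table) on a
    labeled cohort; returns (disease rows, zone rows).

    Patients flagged ``zones_evaluable=False`` contribute to no zone tally.
    """
    if disease_kb.entity_kind is not EntityKind.DISEASE:
        raise ValueError("disease_kb must have entity_kind DISEASE")
    if zone_kb.entity_kind is not EntityKind.BRAIN_ZONE:
        raise ValueError("zone_kb must have entity_kind BRAIN_ZONE")
    d_cat, z_cat = disease_kb.entity_catalog, zone_kb.entity_catalog
    d_tallies = {e: ConfusionTally(e) for e in d_cat.entities}
    z_tallies = {e: ConfusionTally(e) for e in z_cat.entities}
    for lp in cohort:
        lp.validate(d_cat, z_cat)
        d_result = interpret_disease_scores(score_patient(lp.record, disease_kb))
        tally_disease_result(lp.true_disease, d_result, d_cat, d_tallies)
        if lp.zones_evaluable:
            z_result = interpret_zone_scores(score_patient(lp.record, zone_kb))
            tally_zone_result(lp.true_zones, z_result, z_cat, z_tallies)
    return (
        accuracy_table([d_tallies[e] for e in d_cat.entities]),
        accuracy_table([z_tallies[e] for e in z_cat.entities]),
    )
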