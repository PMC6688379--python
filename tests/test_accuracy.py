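"""Confusion accounting, sensitivity/specificity tables and Wald intervals."""

import math
import random

import pytest

from oculodx.accuracy import (
    ConfusionTally,
    Z_95,
    accuracy_frame,
    accuracy_table,
    evaluate_cohort,
    tally_disease_result,
    tally_zone_result,
    wald_ci,
)
from oculodx.interpretation import InterpretationResult
from oculodx.knowledge_base import EntityCatalog, EntityKind
from oculodx.patient_io import LabeledPatient, PatientRecord, Response

DISEASES = EntityCatalog(
    entities=tuple(f"D{i}" for i in range(14)), entity_kind=EntityKind.DISEASE
)
ZONES = EntityCatalog(
    entities=tuple(f"Z{i}" for i in range(8)), entity_kind=EntityKind.BRAIN_ZONE
)


def _result(kind, shortlist=(), not_helpful=False, dominant=False):
    return InterpretationResult(
        entity_kind=kind,
        shortlist=tuple(shortlist),
        not_helpful=not_helpful,
        dominant=dominant,
    )


def _fresh(catalog):
    return {e: ConfusionTally(e) for e in catalog.entities}


# ---------------------------------------------------------------------------
# disease tallies

def test_shortlist_hit_is_tp_plus_fp_plus_tn_split():
    t = _fresh(DISEASES)
    tally_disease_result(
        "D0", _result(EntityKind.DISEASE, ["D0", "D1"]), DISEASES, t
    )
    assert (t["D0"].tp, t["D0"].fn) == (1, 0)
    assert (t["D1"].fp, t["D1"].tn) == (1, 0)
    assert sum(x.tn for x in t.values()) == 12


def test_not_helpful_is_fn_for_truth_fp_for_other_thirteen():
    t = _fresh(DISEASES)
    tally_disease_result(
        "D0", _result(EntityKind.DISEASE, not_helpful=True), DISEASES, t
    )
    assert t["D0"].fn == 1
    assert sum(x.fp for x in t.values()) == 13


def test_dominant_single_hit_yields_zero_fp():
    t = _fresh(DISEASES)
    tally_disease_result(
        "D3", _result(EntityKind.DISEASE, ["D3"], dominant=True), DISEASES, t
    )
    assert t["D3"].tp == 1
    assert sum(x.fp for x in t.values()) == 0
    assert sum(x.tn for x in t.values()) == 13


def test_random_tallies_match_case_oracle_and_sum_to_catalog_size():
    """1,000 random (truth, shortlist/not-helpful) pairs: each pair's
    increments total |catalog| and agree with a literal case analysis."""
    rng = random.Random(2024)
    for _ in range(1000):
        truth = rng.choice(DISEASES.entities)
        if rng.random() < 0.15:
            result = _result(EntityKind.DISEASE, not_helpful=True)
            shortlist = set()
            nh = True
        else:
            shortlist = set(
                rng.sample(DISEASES.entities, rng.randint(1, 5))
            )
            result = _result(EntityKind.DISEASE, sorted(shortlist))
            nh = False
        t = _fresh(DISEASES)
        tally_disease_result(truth, result, DISEASES, t)
        assert sum(x.total for x in t.values()) == len(DISEASES)
        for e in DISEASES.entities:  # independent case-by-case oracle
            if nh:
                expected = ("fn" if e == truth else "fp")
            elif e == truth:
                expected = "tp" if e in shortlist else "fn"
            elif e in shortlist:
                expected = "fp"
            else:
                expected = "tn"
            assert getattr(t[e], expected) == 1 and t[e].total == 1


# ---------------------------------------------------------------------------
# zone tallies (multi-label truth)

def test_multilabel_zone_split():
    t = _fresh(ZONES)
    tally_zone_result(
        {"Z0", "Z1"}, _result(EntityKind.BRAIN_ZONE, ["Z0", "Z7"]), ZONES, t
    )
    assert t["Z0"].tp == 1
    assert t["Z1"].fn == 1
    assert t["Z7"].fp == 1
    assert sum(x.tn for x in t.values()) == 5


def test_zone_not_helpful_fn_for_true_fp_for_rest():
    t = _fresh(ZONES)
    tally_zone_result(
        {"Z2"}, _result(EntityKind.BRAIN_ZONE, not_helpful=True), ZONES, t
    )
    assert t["Z2"].fn == 1
    assert sum(x.fp for x in t.values()) == 7


def test_empty_truth_shortlist_members_are_fp_rest_tn():
    t = _fresh(ZONES)
    tally_zone_result(
        set(), _result(EntityKind.BRAIN_ZONE, ["Z1"]), ZONES, t
    )
    assert t["Z1"].fp == 1
    assert sum(x.tn for x in t.values()) == 7


def test_conservation_over_random_cohorts():
    """TP+FN equals the entity's prevalence and FP+TN its complement, for
    every entity, on randomly generated result streams."""
    rng = random.Random(77)
    for _ in range(20):
        n = rng.randint(1, 60)
        t = _fresh(DISEASES)
        prevalence = {e: 0 for e in DISEASES.entities}
        for _ in range(n):
            truth = rng.choice(DISEASES.entities)
            prevalence[truth] += 1
            if rng.random() < 0.2:
                result = _result(EntityKind.DISEASE, not_helpful=True)
            else:
                result = _result(
                    EntityKind.DISEASE,
                    sorted(rng.sample(DISEASES.entities, rng.randint(1, 5))),
                )
            tally_disease_result(truth, result, DISEASES, t)
        for e in DISEASES.entities:
            assert t[e].tp + t[e].fn == prevalence[e]
            assert t[e].fp + t[e].tn == n - prevalence[e]


# ---------------------------------------------------------------------------
# Wald intervals and table derivation

@pytest.mark.parametrize(
    "k, n, low, high",
    [
        (30, 39, 0.637, 0.901),   # truncation-free interval
        (3, 5, 0.171, 1.000),     # upper bound truncated from > 1
        (86, 94, 0.858, 0.971),
        (10, 10, 1.000, 1.000),   # degenerate p = 1
        (0, 54, 0.000, 0.000),    # degenerate p = 0
    ],
)
def test_wald_ci_reproduces_reference_values(k, n, low, high):
    got = wald_ci(k, n)
    assert round(got[0], 3) == low
    assert round(got[1], 3) == high


def test_wald_ci_symmetric_before_truncation_and_truncated_to_unit():
    rng = random.Random(31)
    for _ in range(500):
        n = rng.randint(1, 200)
        k = rng.randint(0, n)
        low, high = wald_ci(k, n)
        assert 0.0 <= low <= k / n <= high <= 1.0
        p = k / n
        half = Z_95 * math.sqrt(p * (1 - p) / n)
        if 0 <= p - half and p + half <= 1:  # untruncated: symmetric about p
            assert math.isclose(high - p, p - low, abs_tol=1e-12)


def test_wald_z_constant_vs_1_96_agree_on_reference_fractions():
    """The exact 97.5% quantile and the rounded 1.96 give the same interval
    to 3 decimals for every numerator/denominator pair in the published
    accuracy tables."""
    pairs = [
        (10, 10), (5, 5), (3, 4), (11, 11), (8, 10), (4, 5), (3, 5), (4, 4),
        (71, 94), (65, 99), (82, 100), (82, 93), (63, 94), (89, 94), (83, 94),
        (89, 99), (86, 99), (78, 100), (86, 94), (94, 99), (79, 94), (78, 99),
        (30, 39), (28, 34), (34, 54), (14, 54), (0, 54), (22, 28), (5, 11),
        (30, 58), (34, 63), (78, 93), (25, 43), (34, 43), (42, 43), (57, 69),
        (85, 86),
    ]
    for k, n in pairs:
        exact = wald_ci(k, n)
        approx = wald_ci(k, n, z=1.96)
        assert round(exact[0], 3) == round(approx[0], 3), (k, n)
        assert round(exact[1], 3) == round(approx[1], 3), (k, n)


def test_wald_ci_edge_inputs():
    assert wald_ci(0, 0) is None
    with pytest.raises(ValueError):
        wald_ci(5, 4)


@pytest.mark.parametrize(
    "tally, sens_pct, spec_pct",
    [
        (ConfusionTally("e", tp=30, fn=9), 76.9, None),
        (ConfusionTally("e", tn=86, fp=8), None, 91.5),
        (ConfusionTally("e", tp=4, fn=0), 100.0, None),
        (ConfusionTally("e", tn=65, fp=34), None, 65.7),
    ],
)
def test_accuracy_table_percentages(tally, sens_pct, spec_pct):
    (row,) = accuracy_table([tally])
    assert row.sensitivity_pct == sens_pct
    assert row.specificity_pct == spec_pct


def test_zero_denominator_rows_are_emitted_as_undefined():
    (row,) = accuracy_table([ConfusionTally("e")])
    assert row.sensitivity_pct is None and row.sens_ci is None
    assert row.specificity_pct is None and row.spec_ci is None
    frame = accuracy_frame([row])
    assert list(frame["entity"]) == ["e"]


def test_percent_rounding_is_half_up():
    # 55/88 = 62.5% exactly at the .05 boundary after the first decimal:
    # 62.5 stays; 5/8 = 62.5; use 0.625 -> 62.5; and 67/96 = 69.79 -> 69.8
    (row,) = accuracy_table([ConfusionTally("e", tp=67, fn=29)])
    assert row.sensitivity_pct == 69.8
    (row,) = accuracy_table([ConfusionTally("e", tp=1, fn=7)])
    assert row.sensitivity_pct == 12.5


# ---------------------------------------------------------------------------
# cohort evaluation

def test_single_dominant_correct_patient_gives_all_perfect_rows(
    disease_kb, zone_kb, zone_map
):
    catalog = disease_kb.symptom_catalog
    responses = {
        s: Response.PRESENT for s in disease_kb.positive_symptoms("NPC")
    }
    lp = LabeledPatient(
        record=PatientRecord("p1", responses, catalog),
        true_disease="NPC",
        true_zones=zone_map["NPC"],
    )
    disease_rows, _ = evaluate_cohort([lp], disease_kb, zone_kb)
    by_entity = {r.entity: r for r in disease_rows}
    assert by_entity["NPC"].sensitivity_pct == 100.0
    assert by_entity["NPC"].sens_ci == (1.0, 1.0)
    for e, row in by_entity.items():
        if e != "NPC":
            assert (row.spec_num, row.spec_den) == (1, 1)
            assert row.specificity_pct == 100.0


def test_evaluation_is_invariant_to_patient_order(disease_kb, zone_kb, zone_map):
    from oculodx.simulate import CohortConfig, generate_cohort

    cfg = CohortConfig(
        counts={d: 2 for d in disease_kb.entity_catalog.entities}, seed=5
    )
    cohort = list(generate_cohort(disease_kb, zone_map, cfg).patients)
    fwd = evaluate_cohort(cohort, disease_kb, zone_kb)
    rev = evaluate_cohort(list(reversed(cohort)), disease_kb, zone_kb)
    assert fwd == rev


def test_zones_evaluable_flag_excludes_patient_from_zone_tables(
    disease_kb, zone_kb, zone_map
):
    catalog = disease_kb.symptom_catalog
    responses = {
        s: Response.PRESENT for s in disease_kb.positive_symptoms("MS")
    }
    make = lambda flag: LabeledPatient(  # noqa: E731
        record=PatientRecord("p", responses, catalog),
        true_disease="MS",
        true_zones=zone_map["MS"],
        zones_evaluable=flag,
    )
    _, zones_in = evaluate_cohort([make(True)], disease_kb, zone_kb)
    _, zones_out = evaluate_cohort([make(False)], disease_kb, zone_kb)
    assert sum(r.sens_den + r.spec_den for r in zones_in) == len(zone_kb.entity_catalog)
    assert sum(r.sens_den + r.spec_den for r in zones_out) == 0
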