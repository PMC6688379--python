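# oculodx

Rule-based differential diagnosis of central ocular motor disorders.

Central ocular motor disorders — supranuclear gaze palsies, internuclear
ophthalmoplegia, pathological nystagmus — are produced by a short list of
diseases (many of them rare and treatable, such as Niemann-Pick type C or
Gaucher disease type 3) and localize to a small set of brain zones. A
careful bedside examination therefore carries a lot of diagnostic
information, but exploiting it requires specialist pattern knowledge.
`oculodx` implements that pattern knowledge as a transparent, auditable
scoring engine for neurologists and for methodologists studying rule-based
clinical decision support.

## The algorithm

The medical content lives entirely in a **knowledge base**: a table of
entities (14 diseases, or 8 brain zones) against 60 signs and symptoms,
each cell holding an integer linkage weight, usually written as a code —
NEV = −3, OTTD = −2, UL = −1, N = 0, Y/R = +1, HR = +2 ("highly related"
adds two points instead of one; negative weights encode symptoms unlikely
to occur with a disease).

A patient is an **entry mask**: for each symptom, `Yes` (present), `No`
(absent) or `0` (not tested). The score of entity *e* is

&nbsp;&nbsp;&nbsp;&nbsp;score(e) = Σ<sub>s present</sub> w(e, s)

— absent and untested symptoms contribute nothing. Scores are condensed
into a **shortlist** by fixed rules. Diseases: the top two scores with
ties expanded; a disease leading by ≥ 3 points is the sole ("dominant")
result; more than five diseases is "not helpful". Zones: scores ≤ 1 are
ignored (unless 1 is the maximum), then top two with ties; more than four
zones is "not helpful".

On a labeled cohort the shortlist confusion is tallied per entity (truth
in shortlist → TP; each wrong shortlist member → FP; "not helpful" → FN
for the truth and FP for every other entity) and reported as sensitivity
and specificity with 95% Wald (asymptotic-normal) confidence intervals,
p ± z·√(p(1−p)/n) truncated to [0, 1].

The package ships an **illustrative, non-clinical** 60 × 14 / 60 × 8
knowledge base so everything runs out of the box, and a seeded synthetic
cohort generator (disease-conditional Bernoulli symptom draws with
penetrance, spurious-symptom noise and an untested rate) so the whole
pipeline is testable without patient data.

## Worked example

Score a partially examined patient with a vertical supranuclear gaze
palsy, vertical saccade palsy, ataxia, dysarthria and splenomegaly
(mask built over the bundled knowledge base):

```sh
oculodx score --mask mask.csv --format tsv
```

```text
patient_id  kind     shortlist                           not_helpful  dominant
p1          disease  NPC                                 False        True
p1          zone     Midbrain; Vermis/fastigial nucleus  False        False
```

NPC scores 7 (vertical saccade palsy and vertical supranuclear gaze palsy
are HR, +2 each; ataxia, dysarthria, splenomegaly +1 each); the runners-up
(PSP, cerebellar syndromes) reach 3, so NPC leads by ≥ 3 points and is
flagged `dominant` — the sole suggested diagnosis. The zone scores put the
midbrain first (4) with the vermis/fastigial nucleus second (3); the pons
(1) falls below the zone filter, leaving a two-zone localization.

Other commands: `oculodx simulate --seed 7 --out-dir cohort/` writes a
synthetic mask + label file; `oculodx evaluate --mask … --labels …`
produces the per-entity sensitivity/specificity tables;
`oculodx validate-kb --kb my_kb.tsv` checks a custom knowledge base.

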