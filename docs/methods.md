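# Methods

## Model

`oculodx` is a deterministic, additive rule-based classifier. All medical
knowledge is data: an entity × symptom matrix of integer linkage weights
in [−3, +4] (brain-zone matrices are non-negative — a finding can argue
*for* a lesion site but the model never argues against one). The symbolic
codes NEV/OTTD/UL/N/Y/R/HR map to −3/−2/−1/0/+1/+1/+2; weights +3 and +4
have no code and are written as digits.

Scoring is a plain sum over the symptoms marked present. Two modelling
commitments follow from the scoring rule's "whenever a symptom occurs"
semantics:

* a `No` answer never changes a score — negative evidence enters only
  through negatively weighted symptoms that are present, so `No` and
  `0` (not tested) are score-equivalent, although the tri-state
  distinction is preserved in I/O;
* scores are unnormalized integers: a sparsely examined patient simply
  has smaller scores, which the shortlist rules (rank-based for
  diseases) largely absorb.

### Shortlist rules

Diseases: (1) dominance — a unique top scorer at least 3 points above
every other score is the sole result (checked first; a dominant result
cannot be "more than five"); (2) otherwise every disease scoring at
least the second-ranked score (the "top two", with ties expanded at
either rank — {5,5,4} yields the two 5s, {5,4,4} all three); (3) a
shortlist longer than five is "not helpful". The disease shortlist is
deliberately not score-thresholded: a top score of 0 still forms a
result unless the size cap fires — only the zone rules state a filter.

Zones: scores ≤ 1 are discarded unless the maximum is exactly 1 (then
the 1-point zones survive); the top-two-with-ties rule is applied to
the survivors; more than four zones is "not helpful", and so is a
vector with no survivor (max ≤ 0) — the only defined failure mode.

### Accuracy accounting

Shortlists make the confusion bookkeeping per entity and per patient:
truth in the shortlist → TP for the truth and FP for every other
shortlist member, TN elsewhere; truth missing → FN; "not helpful" → FN
for the truth and FP for all remaining entities. Zone truth is a *set*
(a lesion can span zones): each true zone is scored independently as
TP/FN, each false shortlist zone as FP, the rest TN. A per-patient
`zones_evaluable` flag can exclude a patient from the zone tables
without touching the disease tables, supporting cohorts where the
anatomical ground truth is unavailable for some patients.

Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) are reported with 95%
Wald intervals, z = Φ⁻¹(0.975) ≈ 1.959964 (the rounded 1.96 gives the
same bounds at 3 decimals for every count pair we regression-test).
Percents are rounded half-up to 1 decimal, CI bounds to 3 decimals; raw
fractions are always carried alongside, and zero-denominator rows are
emitted with the percent and interval marked undefined.

## The bundled knowledge base

The shipped 60 × 14 disease and 60 × 8 zone matrices are an
**illustrative fixture**, not clinically curated content. They encode the
hallmark linkages the method is built around (e.g. internuclear
ophthalmoplegia under 60 → MS:HR, vertical saccade palsy → NPC:HR,
resting tremor → Parkinsonian syndromes:HR, paresis → NPC:OTTD and
GD3:OTTD to separate them from Tay-Sachs), fill the remaining cells with
plausible placeholder codes, and were constructed so that every
disease's positive-weight profile is unique and *self-dominant*: a
patient presenting exactly that profile scores the disease at least 3
points above all competitors. That construction is what makes the
noiseless end-to-end property ("100% sensitivity on a clean cohort")
exact rather than statistical. Do not use the fixture for patient care.

## Synthetic cohorts

The generator emulates the structure of a diagnostic validation cohort:
patients with exactly one true disease, multi-zone anatomical truth via
a disease → zones map, and an incompletely examined entry mask. For a
patient with disease *d*, each symptom is an independent Bernoulli draw:

| linkage weight | P(present) | default |
|---|---|---|
| ≥ +2 | p_typical + p_hr_boost | 0.95 |
| +1 | p_typical | 0.80 |
| 0 | p_spurious | 0.05 |
| ≤ −1 | 0 | — |

then every response is independently masked to "not tested" with
p_untested (default 0.3, reflecting that bedside batteries are rarely
complete). Negatively linked symptoms are never generated for their
disease, matching the knowledge-base semantics (a negative link means
"unlikely to occur with this disease"). Defaults were chosen as
plausible penetrance/noise/coverage figures for this setting and are
deliberately not tuned.

Reproducibility: one global integer seed; patient *i* draws from
`numpy` `default_rng(SeedSequence([seed, i]))`, so cohorts are
byte-identical across runs and platforms and independent of container
iteration order. The `noise_sweep` harness derives the cohort seed at
grid position *g*, replicate *r* as `seed + 100000·g + r`.

What the generator does **not** model: symptom–symptom correlation,
age/onset structure, disease progression, examiner bias, or multiple
concurrent conditions. Passing pipeline tests on synthetic cohorts
therefore demonstrates the correctness of the machinery (scoring, rules,
accounting, CIs), not clinical performance on real patients — the
published cohort results cannot be reproduced here because neither the
patient data nor the authors' full weight matrices are public.

## Numerical and design choices

* Identifier matching is exact and case-sensitive after whitespace
  trimming; mask tokens are read case-insensitively but always written
  canonically (`Yes`/`No`/`0`).
* Missing knowledge-base cells are weight 0; zero weights are kept
  implicit internally so a write→load round trip is exact map equality.
* Ranking ties break by catalog order; shortlist outputs are reported
  in catalog order (set semantics — ordering never affects the rules).
* Rounding is decimal half-up, applied only at the presentation layer.
* Problem sizes in the test suite (toy-catalog enumerations over
  {0..6}⁴ and {0..4}⁵, 1,000-case randomized oracles, 104-patient
  synthetic cohorts with 20 replicates for the noise-degradation check)
  were chosen to make each property either exhaustive or statistically
  comfortable while keeping the suite in the seconds range.

## Known limitations

* The fixture knowledge base is illustrative; all quantitative claims
  about real diagnostic accuracy rest on the published count pairs, not
  on anything recomputed from patient data.
* The Wald interval degenerates at p = 0 or 1 (zero-width) and is known
  to undercover for small n; it is used because it is the method the
  accuracy tables were computed with. Wilson or Clopper–Pearson
  intervals are an easy extension but intentionally not offered.
* The top-two tie-expansion reading ({5,5,4} → the two 5s) and the
  unthresholded disease shortlist are interpretive choices on points
  the rules leave open; both are isolated in `interpretation.py` and
  covered by exhaustive oracle tests, so changing the reading is a
  one-line edit with immediate test feedback.
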