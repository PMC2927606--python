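# aismarshall

Translate Abbreviated Injury Scale (AIS) head-injury codes from trauma
registries into the **Marshall CT Classification** of traumatic brain
injury.

Trauma registries code brain injuries anatomically with the AIS dictionary:
each injury gets a 6-digit code plus a post-decimal severity score 1–6
(e.g. `140666.5`), and one patient may carry several codes. Clinicians and
prognostic models (e.g. the IMPACT family) instead use the Marshall system,
a mutually exclusive CT-based grading: I (no visible pathology), II
(diffuse injury), III (swelling — compressed or absent basal cisterns), IV
(midline shift > 5 mm), V (evacuated mass lesion), VI (non-evacuated mass
lesion > 25 cc). This package implements the published expert-consensus
crosswalk between the two systems, so registry datasets can feed
Marshall-based analyses. It is written for registry analysts and TBI
epidemiologists.

## The method

**Stage 1 — cross-tabulation.** Every head-region AIS code is looked up in
an embedded consensus table (AIS dictionary updates 1998 and 2005) and
assigned an *Equivalent to Marshall Class*: one of I, II, III, IV, V/VI,
brain-stem/cerebellar, or penetrating. The volume cut-offs that separate
these groups (25 cc in the Marshall system; 30/50 cc in the AIS dictionary)
are pre-compiled into the table, never recomputed. The code `116002`
(superficial penetrating scalp wound) means *no brain injury* and maps to a
NON_TBI sentinel; codes absent from the tables (e.g. cranial-nerve or
unconsciousness codes) are UNMAPPED.

**Stage 2 — priority selection.** The patient's set of equivalent classes,
plus the surgical-evacuation flag, is resolved to a single class by an
ordinal priority algorithm:

```
penetrating            → VIII  (stop: Marshall covers blunt injury only)
mass lesion (V/VI)     → VI if evacuated else V   (crush 113000 forces VI)
shift                  → IV
swelling               → III
brain stem/cerebellar  → VII
diffuse injury         → II
no visible pathology   → I
nothing mappable       → NO_TBI sentinel
```

Classes VII and VIII are the published extensions for brain-stem/cerebellar
and penetrating injuries. Three documented variant points are configurable
(`SelectorConfig`): the slot of the VII step, the V-vs-VI evacuation
convention, and whether VII/VIII are reported split, split by anatomy, or
merged as "unclassified". An independent priority-order oracle
(`oracle_select`) recomputes every answer by a different route and is used
throughout the tests.

## Worked example

```python
from aismarshall import DictionaryVersion, PatientRecord, classify_record, parse_ais_code

version = DictionaryVersion.AIS98
patient = PatientRecord(
    patient_id="TARN-0001",
    codes=(parse_ais_code("140204.5", version),   # brain-stem contusion
           parse_ais_code("140608.4", version)),  # large mass lesion
    evacuated=True,
)
a = classify_record(patient)
print(a.label, a.fired_step)
```

prints

```
VI mass_lesion_evacuated
```

The patient attracts two equivalent classes (brain-stem/cerebellar and
V/VI); the mass-lesion step outranks the brain-stem step, and surgical
evacuation selects class VI. See `examples/` for more: cohort
classification (`classify_cohort.py` prints `agreement with oracle ground
truth: 500/500`), the algorithm variants, the table audit, and an
agreement report with Cohen's kappa.

## Command line

```
aismarshall map cohort.csv out.csv --dict 1998        # classify a registry extract
aismarshall check                                     # audit the embedded tables
aismarshall tables crosswalk.csv --dict 2005          # export the crosswalk
aismarshall simulate sim.csv --n 100 --truth truth.csv
aismarshall compare out.csv truth.csv                 # contingency table + kappa
```

Input is a CSV with columns `patient_id`, `ais_codes`
(semicolon-separated), `evacuated` (0/1/true/false/yes/no) and optionally
`dict_version` (1998 or 2005).

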