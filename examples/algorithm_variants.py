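"""Show how the documented algorithm variants change an assignment.

Two switches genuinely matter: where the brain-stem/cerebellar (VII) step
sits in the priority order, and which of classes V/VI an evacuated mass
lesion receives (the method's prose and the classic class-definition
table contradict each other on this point).
"""

from aismarshall import (
    DictionaryVersion,
    EvacuationSemantics,
    PatientRecord,
    SelectorConfig,
    ViiPosition,
    classify_record,
    parse_ais_code,
)

version = DictionaryVersion.AIS98
# brain-stem contusion + small cerebral haemorrhage (diffuse injury II)
patient = PatientRecord(
    "P1",
    tuple(parse_ais_code(r, version) for r in ("140204.5", "140602.3")),
    evacuated=False,
)
print("brain-stem + diffuse-injury codes, by VII-step position:")
for pos in ViiPosition:
    cfg = SelectorConfig(vii_position=pos)
    a = classify_record(patient, config=cfg)
    print(f"  {pos.value:>20}: class {a.label}")

# evacuated mass lesion under the two evacuation conventions
lesion = PatientRecord("P2", (parse_ais_code("140608.4", version),), evacuated=True)
print("evacuated mass lesion, by evacuation semantics:")
for sem in EvacuationSemantics:
    a = classify_record(lesion, config=SelectorConfig(evacuation_semantics=sem))
    print(f"  {sem.value:>20}: class {a.label}")
# Default semantics follow the prose (evacuated -> VI); marshall_table1
# follows the classic table (evacuated -> V).
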