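"""Classify one trauma-registry patient and inspect the audit trail.

A patient carrying a brain-stem contusion code and a large subdural
haematoma code, surgically evacuated: the mass-lesion step fires before
the brain-stem step, and evacuation selects class VI.
"""

from aismarshall import DictionaryVersion, PatientRecord, classify_record, parse_ais_code

version = DictionaryVersion.AIS98
patient = PatientRecord(
    patient_id="TARN-0001",
    codes=(
        parse_ais_code("140204.5", version),  # brain-stem contusion
        parse_ais_code("140608.4", version),  # mass lesion (equivalent to V/VI)
    ),
    evacuated=True,
)

assignment = classify_record(patient)
print(f"patient          : {patient.patient_id}")
print(f"codes            : {', '.join(str(c) for c in patient.codes)}")
print(f"equivalent classes: {sorted(c.value for c in assignment.equivalent_classes)}")
print(f"final Marshall class: {assignment.label} (step: {assignment.fired_step})")
# The final class is the single, mutually exclusive Marshall grade; the
# fired step names the branch of the priority algorithm that decided it.
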