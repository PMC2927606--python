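import pytest
from hypothesis import settings

from aismarshall import AISCode, DictionaryVersion, PatientRecord, parse_ais_code

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")

AIS98 = DictionaryVersion.AIS98
AIS2005 = DictionaryVersion.AIS2005


def code(raw: str, version: DictionaryVersion = AIS98) -> AISCode:
    return parse_ais_code(raw, version)


def record(
    *raws: str,
    evacuated: bool = False,
    version: DictionaryVersion = AIS98,
    patient_id: str = "P1",
) -> PatientRecord:
    return PatientRecord(
        patient_id=patient_id,
        codes=tuple(code(r, version) for r in raws),
        evacuated=evacuated,
        version=version,
    )


@pytest.fixture
def registry_csv(tmp_path):
    """Write a small registry extract and return its path."""

    def _write(rows, header="patient_id,ais_codes,evacuated,dict_version"):
        path = tmp_path / "cohort.csv"
        path.write_text("\n".join([header, *rows]) + "\n", encoding="utf-8")
        return path

    return _write
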