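"""Audit the embedded crosswalk tables and export them as plain text.

The per-code cross-tabulation and the grouped equivalent-class view were
transcribed independently; the consistency check compares them set for
set so a transcription slip in either cannot pass silently.
"""

from aismarshall import (
    DictionaryVersion,
    builtin_table,
    check_table_consistency,
    export_table,
)

problems = check_table_consistency()
print(f"consistency audit: {len(problems)} discrepancy(ies)")

for version in DictionaryVersion:
    table = builtin_table(version)
    groups = table.grouped()
    print(f"AIS {version.value} crosswalk: {len(table.entries)} codes in {len(groups)} classes")
    for eq, predots in sorted(groups.items(), key=lambda kv: kv[0].value):
        print(f"  {eq.value:>22}: {len(predots)} codes")

export_table(builtin_table(DictionaryVersion.AIS2005), "crosswalk_2005.csv")
print("wrote crosswalk_2005.csv (predot, severity, class, subtag, provenance)")
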