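"""Embedded AIS -> Marshall cross-tabulation data.

Two independent transcriptions of the published consensus mapping live here:

``TABLE2_ROWS`` / ``TABLE3_ROWS`` / ``APPENDIX_ROWS``
    The per-code cross-tabulation: (code-as-printed, allocation-as-printed).
    Table 2 covers the AIS dictionary update 1998 (86 rows, dotted codes with
    canonical severity digits); Table 3 the codes added for the 2005 update
    (printed without severity digits); the appendix row adds the cerebral
    NFS code 140999, which the published per-code table omits.

``TABLE4_GROUPS``
    The grouped "Equivalent to Marshall Class" view, transcribed separately
    from its own printed table. It exists solely so the consistency audit in
    :func:`aismarshall.crosswalk.check_table_consistency` can compare the two
    transcriptions set-for-set; the runtime lookup never reads it.

Do not edit one transcription to match the other: their independence is the
point of the audit.
"""

from __future__ import annotations

# (printed code, printed allocation) -- AIS dictionary update 1998.
TABLE2_ROWS: tuple[tuple[str, str], ...] = (
    ("113000.6", "V/VI"),
    ("116004.5", "Penetrating injury"),
    ("140299.5", "Brain stem injury"),
    ("140202.5", "III"),
    ("140204.5", "Brain stem injury"),
    ("140206.5", "Brain stem injury"),
    ("140208.5", "Brain stem injury"),
    ("140210.5", "Brain stem injury"),
    ("140212.6", "Brain stem injury"),
    ("140214.6", "Brain stem injury"),
    ("140216.6", "Penetrating injury"),
    ("140218.6", "Brain stem injury"),
    ("140499.3", "Cerebellar injury"),
    ("140402.3", "Cerebellar injury"),
    ("140403.3", "Cerebellar injury"),
    ("140404.4", "Cerebellar injury"),
    ("140405.5", "Cerebellar injury"),
    ("140406.5", "Cerebellar injury"),
    ("140410.4", "Cerebellar injury"),
    ("140414.4", "Cerebellar injury"),
    ("140418.4", "Cerebellar injury"),
    ("140422.5", "Cerebellar injury"),
    ("140426.4", "Cerebellar injury"),
    ("140430.4", "Cerebellar injury"),
    ("140434.5", "Cerebellar injury"),
    ("140438.4", "Cerebellar injury"),
    ("140442.4", "Cerebellar injury"),
    ("140446.5", "Cerebellar injury"),
    ("140450.3", "Cerebellar injury"),
    ("140458.3", "Cerebellar injury"),
    ("140462.3", "Cerebellar injury"),
    ("140466.3", "Cerebellar injury"),
    ("140470.3", "Cerebellar injury"),
    ("140474.4", "Cerebellar injury"),
    ("140478.5", "Penetrating injury"),
    ("140699.3", "II"),
    ("140602.3", "II"),
    ("140604.3", "II"),
    ("140606.3", "II"),
    ("140608.4", "V/VI"),
    ("140610.5", "V/VI"),
    ("140612.3", "II"),
    ("140614.3", "II"),
    ("140616.4", "V/VI"),
    ("140618.5", "V/VI"),
    ("140611.3", "II"),
    ("140620.3", "II"),
    ("140622.3", "II"),
    ("140624.4", "V/VI"),
    ("140626.5", "V/VI"),
    ("140628.5", "II"),
    ("140629.4", "II"),
    ("140630.4", "II"),
    ("140632.4", "II"),
    ("140634.5", "II"),
    ("140636.5", "V/VI"),
    ("140638.4", "II"),
    ("140640.4", "II"),
    ("140642.4", "II"),
    ("140644.4", "II"),
    ("140646.5", "II"),
    ("140648.5", "V/VI"),
    ("140650.4", "II"),
    ("140652.4", "II"),
    ("140654.5", "II"),
    ("140656.5", "V/VI"),
    ("140660.3", "III"),
    ("140662.3", "III"),
    ("140664.4", "III"),
    ("140666.5", "IV"),
    ("140676.3", "II"),
    ("140678.4", "II"),
    ("140680.3", "II"),
    ("140682.3", "II"),
    ("140684.3", "II"),
    ("140686.3", "II"),
    ("140688.4", "II"),
    ("140690.5", "Penetrating injury"),
    ("140799.3", "II"),
    ("150200.3", "I"),
    ("150202.3", "I"),
    ("150204.3", "I"),
    ("150206.4", "I"),
    ("150404.3", "I"),
    ("150406.4", "I"),
    ("150408.4", "I"),
)

# Codes added by the AIS dictionary update 2005; printed without severity
# digits. 140686 also appears in the 1998 table with the same class (II);
# the 1998 entry (which carries a canonical severity) takes precedence.
TABLE3_ROWS: tuple[tuple[str, str], ...] = (
    ("140605", "II"),
    ("140613", "II"),
    ("140621", "II"),
    ("140625", "II"),
    ("140627", "II"),
    ("140631", "II"),
    ("140639", "II"),
    ("140643", "II"),
    ("140645", "II"),
    ("140647", "II"),
    ("140649", "II"),
    ("140641", "V/VI"),
    ("140651", "II"),
    ("140655", "V/VI"),
    ("140687", "II"),
    ("140686", "II"),
    ("140691", "Penetrating injury"),
    ("140692", "Penetrating injury"),
    ("140689", "II"),
    ("140701", "I"),
    ("140702", "I"),
    ("140703", "I"),
    ("140675", "II"),
    ("140677", "II"),
    ("140681", "II"),
    ("140683", "II"),
    ("140694", "II"),
    ("140695", "II"),
    ("140697", "II"),
    ("140698", "II"),
    ("150000", "I"),
)

# Cerebral NFS: allocated Class II in the appendix text but absent from the
# printed per-code table. Applies to both dictionary versions.
APPENDIX_ROWS: tuple[tuple[str, str], ...] = (("140999", "II"),)

# Independent transcription of the grouped "Equivalent to Marshall Class"
# view (1998 dictionary). Keys are the printed row headings.
TABLE4_GROUPS: dict[str, frozenset[str]] = {
    "Equivalent to Marshall Class I": frozenset(
        {"150200", "150202", "150204", "150206", "150404", "150406", "150408"}
    ),
    "Equivalent to Marshall Class II": frozenset(
        {
            "140602", "140604", "140606", "140612", "140614", "140611",
            "140620", "140622", "140628", "140629", "140630", "140632",
            "140634", "140638", "140640", "140642", "140644", "140646",
            "140650", "140652", "140654", "140684", "140688", "140686",
            "140699", "140676", "140678", "140680", "140682", "140799",
        }
    ),
    "Equivalent to Marshall Class III": frozenset(
        {"140202", "140660", "140662", "140664"}
    ),
    "Equivalent to Marshall Class IV": frozenset({"140666"}),
    "Equivalent to Marshall Class V/VI": frozenset(
        {
            "140608", "140610", "140616", "140618", "140624",
            "140626", "140636", "140648", "140656", "113000",
        }
    ),
    "Cerebellar/brain stem injuries": frozenset(
        {
            "140204", "140206", "140208", "140210", "140212", "140214",
            "140218", "140299", "140402", "140403", "140404", "140405",
            "140406", "140410", "140414", "140418", "140422", "140426",
            "140430", "140434", "140438", "140442", "140446", "140450",
            "140458", "140462", "140466", "140470", "140474", "140499",
        }
    ),
    "Penetrating injury": frozenset({"140216", "140478", "140690", "116004"}),
}

# Superficial penetrating injury to the head: by definition not accompanied
# by brain injury, hence never allocated a Marshall class.
NON_TBI_PREDOT = "116002"

# Massive destruction of cranium and brain (crush): forces Class VI.
CRUSH_PREDOT = "113000"
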