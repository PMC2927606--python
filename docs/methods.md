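# Methods

## The translation problem

AIS coding and the Marshall CT Classification grade the same pathology for
different purposes. AIS codes are anatomical — location (brain stem,
cerebellum, cerebrum), lesion type (contusion, haemorrhage subtypes,
swelling, penetrating injury, crush, …) and extent — and a patient may
carry any number of them. The Marshall system is physiological in intent —
it stratifies the risk of raised intracranial pressure from CT features
(mass lesions with a 25 cc cut-off, basal cistern status, midline shift
with a 5 mm cut-off, surgical evacuation) — and is mutually exclusive: one
class per patient. The translation therefore needs (a) a per-code
allocation and (b) a resolution rule for multiply-coded patients. Both
stages here follow a published expert-consensus design; the fundamental
assumption is that AIS code descriptions can stand in for CT reports.

## Stage 1: the embedded crosswalk

`aismarshall._tables` holds two independent transcriptions of the
consensus mapping:

* the per-code table: 86 rows for the 1998 dictionary update (dotted codes
  with canonical severity digits) and 31 rows added for the 2005 update
  (printed without severities; one code, 140686, overlaps the 1998 table
  with the same class), plus the cerebral-NFS addition 140999 → II that the
  per-code table omits but the accompanying rationale states explicitly
  (provenance-tagged "Appendix");
* the grouped equivalent-class view, transcribed separately from its own
  printed form.

`check_table_consistency()` compares the two set-for-set (the brain-stem
and cerebellar columns jointly against the merged grouped row). Entries
with Appendix provenance are excluded from the set comparison — the
grouped view predates that addition — and are instead checked for
presence. The audit returns an empty discrepancy list on the shipped
tables; a transcription slip in either copy would surface here rather than
silently propagating.

Design points baked into the tables rather than computed at runtime:

* **NFS codes** (predot ending `99`) are treated as the least severe of
  their type purely through their printed allocations (e.g. 140699 → II);
  no severity inference happens at runtime.
* **Brain swelling** splits III vs IV by severity: mild/moderate swelling
  codes → III, the severe-swelling code 140666 → IV, because the AIS
  dictionary grades swelling by cistern status only and has no direct
  midline-shift equivalent.
* **Mass lesions**: small contusions/haemorrhages, SAH and subpial
  haemorrhage → II; large/massive/extensive lesions → the V/VI group. The
  differing size cut-offs (25 cc Marshall vs 30/50 cc AIS) are documented
  metadata only.
* **Skull fractures** (basal, non-simple vault) → I.
* **Hypoxic/ischaemic damage** (2005 codes 140701–140703) → I on the
  assumption of a clear CT; a patient who also develops swelling carries a
  swelling code, which outranks I in Stage 2.
* **116002** (superficial penetrating scalp wound) → NON_TBI sentinel, the
  only code so treated.

Stage-1 mapping is keyed on the 6-digit predot alone: the post-decimal
severity digit is advisory (a mismatch against the canonical severity
yields a warning via `validate_severity`, never a different class). Codes
are stored as digit strings to keep the 6-digit invariant visible and
leading digits safe. Duplicate codes collapse — the classes reflect
presence of pathology types, not counts. Non-head codes (leading digit ≠ 1)
are ignored at debug log level; unmapped head codes warn (lenient, default)
or raise (strict).

## Stage 2: the priority cascade

`select_marshall_class` screens the equivalent-class set in a fixed order
and stops at the first hit; `oracle_select` derives the same answer from a
total priority order plus a per-label outcome map. The duplication is
deliberate: the tests require exact agreement on every one of the 2⁷
subsets × evacuation states × 18 configuration variants, so a logic error
in either implementation is caught by the other.

Configurable variant points, all documented alternatives rather than free
parameters:

* **`vii_position`** — where the brain-stem/cerebellar step sits:
  `before_class_II` (default; VII outranks II but not III/IV),
  `after_penetrating` (VII screened immediately after penetrating codes),
  or `before_class_I`. These are the three orderings the method's
  description admits; no variant placing VII above III/IV is offered
  because none is described.
* **`evacuation_semantics`** — the method's prose (and its worked example)
  allocates VI to an *evacuated* mass lesion and V otherwise; the classic
  Marshall class-definition table says the opposite (V = evacuated,
  VI = non-evacuated > 25 cc). The contradiction is real and unresolved at
  source; the default follows the prose, `marshall_table1` implements the
  table. Crush (113000) forces VI under **both** conventions, since it is
  mapped to the most severe class outright, independent of surgery.
* **`unclassified_mode`** — VII/VIII reported as-is (`split`, default),
  with the brain-stem/cerebellar anatomy spelled out (`split_subtag`), or
  merged as a single `"unclassified"` label. Relabelling touches only the
  reported string; `MarshallAssignment.final` keeps the enum value so audit
  trails are stable across reporting modes.

A record with no mappable brain-injury code yields the `NO_TBI` sentinel,
deliberately distinct from class I: "no code" is not evidence of a normal
CT. The evacuation flag is ignored (with a warning) when no V/VI-equivalent
code is present. The selector contains no randomness; identical inputs and
config give byte-identical outputs.

## Registry I/O

No standard registry export schema exists for this task, so the package
defines its own: CSV with `patient_id`, `ais_codes` (semicolon-separated,
dotted or undotted), `evacuated` (0/1/true/false/yes/no, case-insensitive)
and optional per-row `dict_version`. Comma/semicolon delimiters avoid
quoting in the common case and are configurable. Lenient mode (default)
drops unparseable codes with a per-record warning but never drops rows;
strict mode raises. An unrecognised evacuation token is always an error —
a surgery flag is never guessed.

## Synthetic cohorts

`generate_cohort` emulates registry extracts: per patient it draws a code
count from a geometric distribution (success probability 0.5, mean 2,
clamped at 6 — real multiplicity distributions are not published, so this
is a configurable stand-in), samples equivalent classes by weight (uniform
over the seven substantive labels by default), then samples a concrete
code uniformly from that class's pool in the embedded table. The
evacuation flag is Bernoulli(0.5); with probability 0.05 a record gains a
contaminant code (an unmapped head-region code or a face-region code,
neither present in any table). Ground truth comes from `oracle_select`,
never the cascade under test. The default seed 20100806 is published so
documentation output reproduces verbatim.

What passing synthetic tests shows: the two algorithm implementations
agree, the pipeline is deterministic, order-invariant, and robust to
contaminants. What they cannot show: fidelity to real registries — the
generator models no clinical co-occurrence structure (e.g. brain-stem
injury accompanying severe swelling), no realistic class prevalences, and
no coding error modes beyond whole-code noise.

## Numerical and degenerate-case choices

* Cohen's kappa uses scikit-learn over the fixed 9-label class space; under
  perfect agreement the chance-correction denominator can vanish (single
  dominant class), and kappa is defined as 1.0 there.
* Empty class sets: `NO_TBI` sentinel in lenient mode, error in strict.
* Table lookups are immutable and cached; exporting and re-importing the
  crosswalk as CSV round-trips exactly, so the mapping is auditable without
  reading source.
* Problem sizes in the test suite and acceptance script — exhaustive
  enumeration of all 128 class subsets per variant, and a 1000-record
  synthetic cohort — were chosen because the input space is small enough to
  cover completely; nothing is sampled where enumeration is feasible.

## Known limitations

* The crosswalk covers only the codes printed in the consensus tables;
  2005-dictionary codes beyond those resolve to UNMAPPED, as do
  unconsciousness and cranial-nerve codes (excluded at source in favour of
  GCS-based measures).
* AIS codes aggregate information beyond the admission CT (MRI, surgery,
  post-mortem), so a Marshall class derived from them can overstate the
  admission-CT grade; this is inherent to the method, not to the
  implementation.
* Class II pools heterogeneous pathology (infarction alongside laceration),
  losing prognostic detail by construction.
* No prognostic modelling, ISS computation, or imaging interpretation is
  attempted.
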