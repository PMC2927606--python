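"""Seeded synthetic trauma-registry cohorts for end-to-end testing.

Real TBI registry extracts cannot be shipped, so every stage of the
pipeline is exercised on generated cohorts instead. A cohort draws, per
patient, a code count (truncated geometric — most patients carry one or
two head codes, a few carry several), a set of equivalent classes by
weight, and a concrete AIS code uniformly from each drawn class's code set
in the embedded crosswalk. Ground-truth Marshall classes come from the
independent priority-order oracle, never from the step cascade under test,
so the generator and the selector cross-validate each other.

The generator emulates code multiplicity, the evacuation flag and registry
noise (unmapped/non-head contaminant codes). It does not model clinically
realistic injury co-occurrence or outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .codes import AISCode, DictionaryVersion
from .crosswalk import SUBSTANTIVE_CLASSES, EquivalentClass, builtin_table
from ._tables import CRUSH_PREDOT
from .registry import PatientRecord
from .selector import DEFAULT_CONFIG, MarshallClass, SelectorConfig, oracle_select

__all__ = ["CohortSpec", "generate_cohort", "CONTAMINANT_PREDOTS"]

#: Codes injected as registry noise: a head-region code absent from the
#: crosswalk (resolves to UNMAPPED) and a face-region code (ignored).
CONTAMINANT_PREDOTS = ("130299", "210200")

#: Published default seed so documentation examples reproduce verbatim.
DEFAULT_SEED = 20100806


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``class_weights`` defaults to uniform over the seven substantive
    equivalent-class labels; ``codes_per_record`` is a truncated geometric
    draw (success probability 0.5, i.e. mean 2 before truncation) capped at
    ``max_codes``. ``evacuation_rate`` is the probability the surgical-
    evacuation flag is set, and ``contamination_rate`` the per-record
    probability of injecting one unmapped or non-head code.
    """

    n_records: int
    seed: int = DEFAULT_SEED
    class_weights: Optional[Mapping[EquivalentClass, float]] = None
    geometric_p: float = 0.5
    max_codes: int = 6
    evacuation_rate: float = 0.5
    contamination_rate: float = 0.05
    version: DictionaryVersion = DictionaryVersion.AIS98

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        if not 0 < self.geometric_p <= 1:
            raise ValueError("geometric_p must be in (0, 1]")
        if self.max_codes < 1:
            raise ValueError("max_codes must be at least 1")
        for name in ("evacuation_rate", "contamination_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.class_weights is not None:
            w = [self.class_weights.get(c, 0.0) for c in SUBSTANTIVE_CLASSES]
            if any(x < 0 for x in w):
                raise ValueError("class weights must be nonnegative")
            if not any(w):
                raise ValueError("class weights must not all be zero")

    def probabilities(self) -> np.ndarray:
        """Normalized sampling probabilities over the substantive labels."""
        if self.class_weights is None:
            return np.full(len(SUBSTANTIVE_CLASSES), 1 / len(SUBSTANTIVE_CLASSES))
        w = np.array(
            [float(self.class_weights.get(c, 0.0)) for c in SUBSTANTIVE_CLASSES]
        )
        return w / w.sum()


def generate_cohort(
    spec: CohortSpec,
    config: SelectorConfig = DEFAULT_CONFIG,
) -> tuple[list[PatientRecord], list[MarshallClass]]:
    """Generate a seeded cohort plus oracle-derived ground truth.

    Identical spec and seed reproduce the cohort bit-for-bit. The returned
    truth list is computed under *config* via :func:`oracle_select`; to
    test a different algorithm variant, regenerate with that config (the
    records themselves do not depend on it).
    """
    rng = np.random.default_rng(spec.seed)
    table = builtin_table(spec.version)
    # deterministic, sorted code pools per class
    pools = {
        eq: sorted(predots)
        for eq, predots in table.grouped().items()
        if eq in SUBSTANTIVE_CLASSES
    }
    probs = spec.probabilities()
    labels = list(SUBSTANTIVE_CLASSES)

    records: list[PatientRecord] = []
    truths: list[MarshallClass] = []
    width = len(str(spec.n_records))
    for i in range(spec.n_records):
        n_codes = min(int(rng.geometric(spec.geometric_p)), spec.max_codes)
        drawn = rng.choice(len(labels), size=n_codes, p=probs)
        codes: list[AISCode] = []
        classes: set[EquivalentClass] = set()
        crush = False
        for j in drawn:
            eq = labels[int(j)]
            pool = pools[eq]
            predot = pool[int(rng.integers(len(pool)))]
            entry = table.entries[predot]
            codes.append(
                AISCode(predot, entry.canonical_severity, spec.version)
            )
            classes.add(eq)
            if predot == CRUSH_PREDOT:
                crush = True
        if rng.random() < spec.contamination_rate:
            contaminant = CONTAMINANT_PREDOTS[int(rng.integers(len(CONTAMINANT_PREDOTS)))]
            codes.append(AISCode(contaminant, None, spec.version))
        evacuated = bool(rng.random() < spec.evacuation_rate)
        records.append(
            PatientRecord(
                patient_id=f"S{i + 1:0{width}d}",
                codes=tuple(codes),
                evacuated=evacuated,
                version=spec.version,
            )
        )
        truths.append(
            oracle_select(classes, evacuated, crush_present=crush, config=config)
        )
    return records, truths
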