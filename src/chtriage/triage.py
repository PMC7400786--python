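"""Origin triage of variants across matched tumor / PBC / plasma call sets.

The rule is compartment co-detection: any variant detected in peripheral
blood cells is labeled CH-related (blood precedence holds even when the
variant is also seen in tumor tissue); otherwise a variant in both tumor and
plasma is tumor-derived concordant; plasma-only variants have unknown
origin; tumor-only variants are labeled as such.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

from .umi_caller import VariantCall

COMPARTMENTS = ("tumor", "pbc", "plasma")

STAGE_GROUPS = {
    "I-II": ("I", "II"),
    "III-IV": ("III", "IV"),
}


class OriginLabel(enum.Enum):
    CH_RELATED = "CH_RELATED"
    TUMOR_DERIVED_CONCORDANT = "TUMOR_DERIVED_CONCORDANT"
    UNKNOWN_PLASMA_ONLY = "UNKNOWN_PLASMA_ONLY"
    TUMOR_ONLY = "TUMOR_ONLY"


@dataclass(frozen=True)
class VariantKey:
    """Cross-compartment identity of a variant: exact (chrom, pos, ref, alt).

    Gene and amino-acid labels are annotations and never part of equality.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = field(default="", compare=False)
    aa_change: str = field(default="", compare=False)

    @classmethod
    def from_call(cls, call: VariantCall) -> "VariantKey":
        return cls(chrom=call.chrom, pos=call.pos, ref=call.ref, alt=call.alt, gene=call.gene)


@dataclass
class CompartmentCallSet:
    """All calls for one patient in one compartment (and timepoint, for plasma)."""

    patient_id: str
    compartment: str
    calls: list[VariantCall] = field(default_factory=list)
    timepoint_label: str = ""
    months_from_surgery: float | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        seen: set[VariantKey] = set()
        for call in self.calls:
            key = VariantKey.from_call(call)
            if key in seen:
                raise ValueError(
                    f"{self.patient_id}/{self.compartment}: duplicate call for {key}"
                )
            seen.add(key)

    def keys(self) -> set[VariantKey]:
        return {VariantKey.from_call(c) for c in self.calls}

    def vaf_by_key(self) -> dict[VariantKey, float]:
        return {VariantKey.from_call(c): c.vaf_pct for c in self.calls}


@dataclass
class LabeledVariant:
    key: VariantKey
    origin: OriginLabel
    vafs: dict[str, float | None]  # compartment -> vaf_pct, None = not detected


@dataclass
class PatientTriage:
    patient_id: str
    variants: dict[VariantKey, LabeledVariant]
    stage: str | None = None
    age: float | None = None

    def keys_with_origin(self, origin: OriginLabel) -> set[VariantKey]:
        return {k for k, v in self.variants.items() if v.origin is origin}

    def plasma_keys(self) -> set[VariantKey]:
        return {k for k, v in self.variants.items() if v.vafs.get("plasma") is not None}

    def tumor_keys(self) -> set[VariantKey]:
        return {k for k, v in self.variants.items() if v.vafs.get("tumor") is not None}


@dataclass
class CohortSummary:
    n_patients: int
    tumor_total: int
    plasma_total: int
    concordant_count: int
    label_counts: dict[OriginLabel, int]
    ch_in_plasma: int
    ch_in_tumor: int
    plasma_exclusive: int

    @property
    def concordance_pct(self) -> float:
        """Tumor variants also found in plasma, as percent of tumor variants."""
        return 100.0 * self.concordant_count / self.tumor_total

    @property
    def ch_pct_of_plasma(self) -> float:
        return 100.0 * self.ch_in_plasma / self.plasma_total

    @property
    def tumor_derived_pct_of_plasma(self) -> float:
        return 100.0 * self.label_counts[OriginLabel.TUMOR_DERIVED_CONCORDANT] / self.plasma_total

    @property
    def unknown_pct_of_plasma(self) -> float:
        return 100.0 * self.label_counts[OriginLabel.UNKNOWN_PLASMA_ONLY] / self.plasma_total

    @property
    def plasma_exclusive_pct(self) -> float:
        return 100.0 * self.plasma_exclusive / self.plasma_total

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "tumor_total": self.tumor_total,
            "plasma_total": self.plasma_total,
            "concordant_count": self.concordant_count,
            "label_counts": {k.value: v for k, v in self.label_counts.items()},
            "ch_in_plasma": self.ch_in_plasma,
            "ch_in_tumor": self.ch_in_tumor,
            "plasma_exclusive": self.plasma_exclusive,
            "concordance_pct": self.concordance_pct,
            "ch_pct_of_plasma": self.ch_pct_of_plasma,
            "tumor_derived_pct_of_plasma": self.tumor_derived_pct_of_plasma,
            "unknown_pct_of_plasma": self.unknown_pct_of_plasma,
            "plasma_exclusive_pct": self.plasma_exclusive_pct,
        }


def classify_origin(in_tumor: bool, in_pbc: bool, in_plasma: bool) -> OriginLabel:
    """Label a variant from its per-compartment detection flags.

    PBC detection takes precedence over everything else.
    """
    if not (in_tumor or in_pbc or in_plasma):
        raise ValueError("variant not detected in any compartment")
    if in_pbc:
        return OriginLabel.CH_RELATED
    if in_tumor and in_plasma:
        return OriginLabel.TUMOR_DERIVED_CONCORDANT
    if in_plasma:
        return OriginLabel.UNKNOWN_PLASMA_ONLY
    return OriginLabel.TUMOR_ONLY


def triage_patient(
    tumor_set: CompartmentCallSet,
    pbc_set: CompartmentCallSet,
    plasma_set: CompartmentCallSet,
    stage: str | None = None,
    age: float | None = None,
) -> PatientTriage:
    """Label every variant seen in any compartment for one patient.

    ``plasma_set`` must be the preoperative (baseline) timepoint.
    """
    patient_ids = {tumor_set.patient_id, pbc_set.patient_id, plasma_set.patient_id}
    if len(patient_ids) != 1:
        raise ValueError(f"mismatched patient ids: {sorted(patient_ids)}")
    by_compartment = {"tumor": tumor_set, "pbc": pbc_set, "plasma": plasma_set}
    for name, cset in by_compartment.items():
        if cset.compartment != name:
            raise ValueError(f"expected a {name} call set, got {cset.compartment}")
    vafs = {name: cset.vaf_by_key() for name, cset in by_compartment.items()}
    all_keys = set().union(*(v.keys() for v in vafs.values()))
    variants = {}
    for key in sorted(all_keys, key=lambda k: (k.chrom, k.pos, k.ref, k.alt)):
        origin = classify_origin(
            in_tumor=key in vafs["tumor"],
            in_pbc=key in vafs["pbc"],
            in_plasma=key in vafs["plasma"],
        )
        variants[key] = LabeledVariant(
            key=key,
            origin=origin,
            vafs={name: vafs[name].get(key) for name in COMPARTMENTS},
        )
    return PatientTriage(
        patient_id=tumor_set.patient_id, variants=variants, stage=stage, age=age
    )


def concordance(cohort: Sequence[PatientTriage]) -> CohortSummary:
    """Cohort-level variant counts and the plasma-origin partition.

    ``concordant_count`` counts variants detected in both tumor and plasma of
    the same patient regardless of origin label, so it includes CH variants
    present in both compartments.
    """
    if not cohort:
        raise ValueError("empty cohort")
    tumor_total = plasma_total = concordant = 0
    label_counts = {label: 0 for label in OriginLabel}
    ch_in_plasma = ch_in_tumor = plasma_exclusive = 0
    for patient in cohort:
        for lv in patient.variants.values():
            in_tumor = lv.vafs.get("tumor") is not None
            in_plasma = lv.vafs.get("plasma") is not None
            tumor_total += in_tumor
            plasma_total += in_plasma
            concordant += in_tumor and in_plasma
            label_counts[lv.origin] += 1
            if lv.origin is OriginLabel.CH_RELATED:
                ch_in_plasma += in_plasma
                ch_in_tumor += in_tumor
            plasma_exclusive += in_plasma and not in_tumor
    return CohortSummary(
        n_patients=len(cohort),
        tumor_total=tumor_total,
        plasma_total=plasma_total,
        concordant_count=concordant,
        label_counts=label_counts,
        ch_in_plasma=ch_in_plasma,
        ch_in_tumor=ch_in_tumor,
        plasma_exclusive=plasma_exclusive,
    )


def _patient_has_plasma_variant(patient: PatientTriage, exclude_ch: bool) -> bool:
    for lv in patient.variants.values():
        if lv.vafs.get("plasma") is None:
            continue
        if exclude_ch and lv.origin is OriginLabel.CH_RELATED:
            continue
        return True
    return False


def detection_rate(
    cohort: Sequence[PatientTriage], stage_group: str, exclude_ch: bool
) -> float:
    """Percent of patients in a stage group with >= 1 preoperative plasma variant.

    ``stage_group`` is "I-II" or "III-IV".  With ``exclude_ch``, CH-related
    variants are ignored before the >= 1 test.  Full precision is returned;
    round for display.
    """
    stages = STAGE_GROUPS[stage_group]
    group = [p for p in cohort if p.stage in stages]
    if not group:
        raise ValueError(f"no patients in stage group {stage_group}")
    detected = sum(_patient_has_plasma_variant(p, exclude_ch) for p in group)
    return 100.0 * detected / len(group)


def monitorable_rate(cohort: Sequence[PatientTriage], exclude_ch: bool = True) -> float:
    """Percent of patients with >= 1 (non-CH, if exclude_ch) variant in tumor or plasma."""
    if not cohort:
        raise ValueError("empty cohort")
    n = 0
    for patient in cohort:
        for lv in patient.variants.values():
            if exclude_ch and lv.origin is OriginLabel.CH_RELATED:
                continue
            if lv.vafs.get("tumor") is not None or lv.vafs.get("plasma") is not None:
                n += 1
                break
    return 100.0 * n / len(cohort)
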