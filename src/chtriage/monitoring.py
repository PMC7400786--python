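"""Longitudinal tracking of baseline-triaged variants across postoperative plasma.

Separates two readings of serial plasma results: a naive one (any baseline
plasma variant still detected after surgery suggests residual disease) and a
CH-aware one (only tumor-derived markers count).  When the two disagree the
persistent signal comes from clonal hematopoiesis and a discordance warning
is raised — the misinterpretation scenario this package exists to prevent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .triage import CompartmentCallSet, OriginLabel, PatientTriage, VariantKey


@dataclass
class TimepointObservation:
    timepoint_label: str
    months_from_surgery: float
    vaf_pct: float | None  # None = not detected


@dataclass
class Trajectory:
    variant: VariantKey
    origin: OriginLabel
    baseline_vaf_pct: float | None
    series: list[TimepointObservation] = field(default_factory=list)
    emergent: bool = False

    def detected_postop(self) -> bool:
        return any(obs.vaf_pct is not None for obs in self.series)


@dataclass
class MonitoringReport:
    patient_id: str
    trajectories: list[Trajectory]
    residual_disease_naive: bool
    residual_disease_ch_aware: bool
    ch_persistence: bool

    @property
    def discordance_warning(self) -> bool:
        return self.residual_disease_naive != self.residual_disease_ch_aware

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "residual_disease_naive": self.residual_disease_naive,
            "residual_disease_ch_aware": self.residual_disease_ch_aware,
            "ch_persistence": self.ch_persistence,
            "discordance_warning": self.discordance_warning,
            "trajectories": [
                {
                    "chrom": t.variant.chrom,
                    "pos": t.variant.pos,
                    "ref": t.variant.ref,
                    "alt": t.variant.alt,
                    "gene": t.variant.gene,
                    "origin": t.origin.value,
                    "emergent": t.emergent,
                    "baseline_vaf_pct": t.baseline_vaf_pct,
                    "series": [
                        {
                            "timepoint": obs.timepoint_label,
                            "months_from_surgery": obs.months_from_surgery,
                            "vaf_pct": obs.vaf_pct,
                        }
                        for obs in t.series
                    ],
                }
                for t in self.trajectories
            ],
        }


def track_markers(
    baseline: PatientTriage, postop_sets: Sequence[CompartmentCallSet]
) -> list[Trajectory]:
    """Follow each baseline plasma variant through ordered postoperative plasma sets.

    Postop-only variants are appended as *emergent* trajectories with unknown
    origin.  Timepoints must be strictly increasing in months from surgery.
    """
    months = []
    for cset in postop_sets:
        if cset.compartment != "plasma":
            raise ValueError(f"postop set {cset.timepoint_label} is not plasma")
        if cset.patient_id != baseline.patient_id:
            raise ValueError(
                f"postop set patient {cset.patient_id} != baseline {baseline.patient_id}"
            )
        if cset.months_from_surgery is None:
            raise ValueError(f"postop set {cset.timepoint_label} lacks months_from_surgery")
        months.append(cset.months_from_surgery)
    if any(b <= a for a, b in zip(months, months[1:])):
        raise ValueError(f"postop timepoints not strictly increasing: {months}")

    postop_vafs = [cset.vaf_by_key() for cset in postop_sets]
    trajectories = []
    baseline_plasma = {
        key: lv
        for key, lv in baseline.variants.items()
        if lv.vafs.get("plasma") is not None
    }
    for key, lv in baseline_plasma.items():
        series = [
            TimepointObservation(
                timepoint_label=cset.timepoint_label,
                months_from_surgery=cset.months_from_surgery,
                vaf_pct=vafs.get(key),
            )
            for cset, vafs in zip(postop_sets, postop_vafs)
        ]
        trajectories.append(
            Trajectory(
                variant=key,
                origin=lv.origin,
                baseline_vaf_pct=lv.vafs["plasma"],
                series=series,
            )
        )
    emergent_keys: set[VariantKey] = set()
    for vafs in postop_vafs:
        emergent_keys |= set(vafs) - set(baseline_plasma)
    for key in sorted(emergent_keys, key=lambda k: (k.chrom, k.pos, k.ref, k.alt)):
        series = [
            TimepointObservation(
                timepoint_label=cset.timepoint_label,
                months_from_surgery=cset.months_from_surgery,
                vaf_pct=vafs.get(key),
            )
            for cset, vafs in zip(postop_sets, postop_vafs)
        ]
        trajectories.append(
            Trajectory(
                variant=key,
                origin=OriginLabel.UNKNOWN_PLASMA_ONLY,
                baseline_vaf_pct=None,
                series=series,
                emergent=True,
            )
        )
    return trajectories


def interpret(
    trajectories: Sequence[Trajectory],
    patient_id: str = "",
    count_unknown: bool = True,
    count_emergent: bool = False,
) -> MonitoringReport:
    """Derive residual-disease flags from a patient's trajectories.

    The naive flag fires when any baseline plasma variant is detected at any
    postop timepoint.  The CH-aware flag restricts to tumor-derived markers
    (plus unknown-origin baseline variants unless ``count_unknown`` is off;
    emergent postop-only variants only when ``count_emergent`` is set).
    """
    naive = False
    ch_aware = False
    ch_persist = False
    for traj in trajectories:
        detected = traj.detected_postop()
        if not detected:
            continue
        if traj.emergent:
            # counted on both sides so CH-aware stays a subset of naive
            if count_emergent:
                naive = True
                ch_aware = True
            continue
        naive = True
        if traj.origin is OriginLabel.CH_RELATED:
            ch_persist = True
        elif traj.origin is OriginLabel.TUMOR_DERIVED_CONCORDANT:
            ch_aware = True
        elif traj.origin is OriginLabel.UNKNOWN_PLASMA_ONLY and count_unknown:
            ch_aware = True
    return MonitoringReport(
        patient_id=patient_id,
        trajectories=list(trajectories),
        residual_disease_naive=naive,
        residual_disease_ch_aware=ch_aware,
        ch_persistence=ch_persist,
    )
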