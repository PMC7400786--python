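"""Glue running the simulator output through calling, triage, and monitoring."""

from __future__ import annotations

from dataclasses import dataclass, field

from ..monitoring import MonitoringReport, interpret, track_markers
from ..synthetic_data import PatientTruth, SimConfig, iter_samples, timepoint_label
from ..triage import CompartmentCallSet, PatientTriage, triage_patient
from ..umi_caller import call_sample


@dataclass
class PatientResult:
    truth: PatientTruth
    triage: PatientTriage
    postop_sets: list[CompartmentCallSet] = field(default_factory=list)
    monitoring: MonitoringReport | None = None


def run_simulated_cohort(
    config: SimConfig,
    min_family_reads: int = 3,
    min_alt_families: int = 2,
    monitor: bool = True,
) -> list[PatientResult]:
    """Simulate, call, triage, and (optionally) monitor every patient.

    Reads are processed sample by sample and discarded, so memory stays flat
    for large cohorts.
    """
    per_patient: dict[str, dict] = {}
    truths: dict[str, PatientTruth] = {}
    for truth, compartment, t, reads in iter_samples(config):
        calls, _ = call_sample(
            reads,
            config.panel,
            min_family_reads=min_family_reads,
            min_alt_families=min_alt_families,
            compartment=compartment,
            timepoint_label=timepoint_label(t),
            patient_id=truth.patient_id,
        )
        cset = CompartmentCallSet(
            patient_id=truth.patient_id,
            compartment=compartment,
            calls=calls,
            timepoint_label=timepoint_label(t),
            months_from_surgery=None if t == 0 else config.postop_months[t - 1],
        )
        entry = per_patient.setdefault(truth.patient_id, {"plasma_postop": []})
        truths[truth.patient_id] = truth
        if compartment == "plasma" and t > 0:
            entry["plasma_postop"].append(cset)
        else:
            entry[compartment] = cset

    results = []
    for patient_id, entry in per_patient.items():
        truth = truths[patient_id]
        triage = triage_patient(
            entry["tumor"], entry["pbc"], entry["plasma"],
            stage=truth.stage, age=truth.age,
        )
        result = PatientResult(truth=truth, triage=triage, postop_sets=entry["plasma_postop"])
        if monitor and result.postop_sets:
            trajectories = track_markers(triage, result.postop_sets)
            result.monitoring = interpret(trajectories, patient_id=patient_id)
        results.append(result)
    return results
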