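"""TSV readers and writers for panels, tagged reads, calls, and triage tables.

Human-readable tables use "N.D" for not-detected, matching the packaged
fixture table; parse errors name the offending line.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

from ..triage import CompartmentCallSet, PatientTriage
from ..umi_caller import Locus, TaggedRead, VariantCall

ND = "N.D"

CALLS_COLUMNS = [
    "patient", "compartment", "timepoint", "months_from_surgery",
    "chrom", "pos", "ref", "alt", "gene",
    "vaf_pct", "alt_families", "total_families", "read_depth",
]


def _open_reader(path, required: Sequence[str]) -> tuple[csv.DictReader, object]:
    fh = open(path, newline="")
    reader = csv.DictReader(fh, delimiter="\t")
    header = reader.fieldnames or []
    missing = [c for c in required if c not in header]
    if missing:
        fh.close()
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return reader, fh


def read_panel(path) -> dict[str, Locus]:
    """Panel TSV with columns locus_id, chrom, pos, ref, gene."""
    reader, fh = _open_reader(path, ["locus_id", "chrom", "pos", "ref", "gene"])
    panel: dict[str, Locus] = {}
    with fh:
        for lineno, rec in enumerate(reader, start=2):
            try:
                locus = Locus(
                    locus_id=rec["locus_id"],
                    chrom=rec["chrom"],
                    pos=int(rec["pos"]),
                    ref=rec["ref"],
                    gene=rec["gene"],
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if locus.locus_id in panel:
                raise ValueError(f"{path}:{lineno}: duplicate locus_id {locus.locus_id}")
            panel[locus.locus_id] = locus
    return panel


def write_panel(panel: dict[str, Locus], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tchrom\tpos\tref\tgene\n")
        for locus in sorted(panel.values(), key=lambda l: l.locus_id):
            fh.write(f"{locus.locus_id}\t{locus.chrom}\t{locus.pos}\t{locus.ref}\t{locus.gene}\n")


def read_tagged_reads(path) -> list[TaggedRead]:
    """Tagged-read TSV with columns locus_id, umi, allele; one row per read."""
    reader, fh = _open_reader(path, ["locus_id", "umi", "allele"])
    reads = []
    with fh:
        for lineno, rec in enumerate(reader, start=2):
            if not rec["umi"] or not rec["allele"]:
                raise ValueError(f"{path}:{lineno}: empty umi or allele")
            reads.append(TaggedRead(rec["locus_id"], rec["umi"], rec["allele"]))
    return reads


def write_tagged_reads(reads: Iterable[TaggedRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tumi\tallele\n")
        for read in reads:
            fh.write(f"{read.locus_id}\t{read.umi}\t{read.allele}\n")


def write_calls_tsv(calls: Iterable[VariantCall], path, months: dict | None = None) -> None:
    """Call table; ``months`` maps (patient, timepoint) -> months_from_surgery."""
    months = months or {}
    with open(path, "w") as fh:
        fh.write("\t".join(CALLS_COLUMNS) + "\n")
        for c in calls:
            m = months.get((c.patient_id, c.timepoint_label), "")
            fh.write(
                f"{c.patient_id}\t{c.compartment}\t{c.timepoint_label}\t{m}\t"
                f"{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.gene}\t"
                f"{c.vaf_pct:.2f}\t{c.alt_families}\t{c.total_functional_families}\t"
                f"{c.read_depth}\n"
            )


def read_calls_tsv(path) -> list[VariantCall]:
    required = [c for c in CALLS_COLUMNS if c not in ("months_from_surgery", "vaf_pct")]
    reader, fh = _open_reader(path, required)
    calls = []
    with fh:
        for lineno, rec in enumerate(reader, start=2):
            try:
                calls.append(
                    VariantCall(
                        locus_id=f"{rec['chrom']}:{rec['pos']}",
                        chrom=rec["chrom"],
                        pos=int(rec["pos"]),
                        ref=rec["ref"],
                        alt=rec["alt"],
                        gene=rec["gene"],
                        compartment=rec["compartment"],
                        timepoint_label=rec["timepoint"],
                        alt_families=int(rec["alt_families"]),
                        total_functional_families=int(rec["total_families"]),
                        read_depth=int(rec["read_depth"]),
                        patient_id=rec["patient"],
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return calls


def _months_from_calls_tsv(path) -> dict[tuple[str, str], float]:
    reader, fh = _open_reader(path, ["patient", "timepoint"])
    months: dict[tuple[str, str], float] = {}
    with fh:
        if "months_from_surgery" not in (reader.fieldnames or []):
            return months
        for lineno, rec in enumerate(reader, start=2):
            token = rec.get("months_from_surgery", "")
            if token:
                try:
                    months[(rec["patient"], rec["timepoint"])] = float(token)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return months


def read_call_sets(path) -> dict[str, dict]:
    """Group a call TSV into per-patient compartment call sets.

    Returns patient -> {"tumor": set, "pbc": set, "plasma": [ordered sets]};
    plasma sets are ordered preop first, then by months_from_surgery.
    """
    calls = read_calls_tsv(path)
    months = _months_from_calls_tsv(path)
    grouped: dict[tuple[str, str, str], list[VariantCall]] = defaultdict(list)
    for call in calls:
        grouped[(call.patient_id, call.compartment, call.timepoint_label)].append(call)
    out: dict[str, dict] = {}
    for (patient, compartment, timepoint), group in grouped.items():
        entry = out.setdefault(patient, {"tumor": None, "pbc": None, "plasma": []})
        cset = CompartmentCallSet(
            patient_id=patient,
            compartment=compartment,
            calls=group,
            timepoint_label=timepoint,
            months_from_surgery=months.get((patient, timepoint)),
        )
        if compartment == "plasma":
            entry["plasma"].append(cset)
        else:
            if entry[compartment] is not None:
                raise ValueError(f"{path}: multiple {compartment} call sets for {patient}")
            entry[compartment] = cset
    for patient, entry in out.items():
        for compartment in ("tumor", "pbc"):
            if entry[compartment] is None:
                entry[compartment] = CompartmentCallSet(patient_id=patient, compartment=compartment)
        entry["plasma"].sort(
            key=lambda s: (s.timepoint_label != "preop", s.months_from_surgery or 0.0)
        )
    return out


def write_triage_table(triages: Sequence[PatientTriage], path) -> None:
    """Per-patient labeled-variant table in the fixture-table layout."""
    with open(path, "w") as fh:
        fh.write(
            "patient\tlocus\tgenotype\tgene\taa_change\t"
            "vaf_pbc\tvaf_tumor\tvaf_plasma\torigin\n"
        )
        for patient in triages:
            for key, lv in patient.variants.items():
                vafs = [
                    ND if lv.vafs.get(c) is None else f"{lv.vafs[c]:.2f}"
                    for c in ("pbc", "tumor", "plasma")
                ]
                fh.write(
                    f"{patient.patient_id}\t{key.chrom}:{key.pos}\t{key.ref}/{key.alt}\t"
                    f"{key.gene}\t{key.aa_change}\t" + "\t".join(vafs) + f"\t{lv.origin.value}\n"
                )
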