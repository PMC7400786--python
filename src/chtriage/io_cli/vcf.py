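"""Minimal VCF 4.2 interchange for origin-annotated calls.

Writing is plain text (records sorted by chrom, pos); reading goes through
pysam so round-trips are validated against a real parser.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from ..triage import OriginLabel
from ..umi_caller import VariantCall

_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=ORIGIN,Number=1,Type=String,Description="Variant origin label">',
    '##INFO=<ID=VAF_PCT,Number=1,Type=Float,Description="Variant allele frequency, percent of functional families">',
    '##INFO=<ID=ALT_FAM,Number=1,Type=Integer,Description="Alternate-supporting functional families">',
    '##INFO=<ID=TOT_FAM,Number=1,Type=Integer,Description="Total functional families (molecular depth)">',
]


def write_vcf(
    calls_with_origins: Sequence[tuple[VariantCall, OriginLabel]], path
) -> None:
    records = sorted(calls_with_origins, key=lambda co: (co[0].chrom, co[0].pos))
    contigs = []
    for call, _ in records:
        if call.chrom not in contigs:
            contigs.append(call.chrom)
    with open(path, "w") as fh:
        for line in _HEADER_LINES:
            fh.write(line + "\n")
        for contig in sorted(contigs):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call, origin in records:
            info = (
                f"ORIGIN={origin.value};VAF_PCT={call.vaf_pct:.4f};"
                f"ALT_FAM={call.alt_families};TOT_FAM={call.total_functional_families}"
            )
            fh.write(
                f"{call.chrom}\t{call.pos}\t.\t{call.ref}\t{call.alt}\t.\tPASS\t{info}\n"
            )


def read_vcf(path) -> list[dict]:
    """Parse a VCF written by :func:`write_vcf` into plain record dicts."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            out.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else None,
                    "origin": rec.info.get("ORIGIN"),
                    "vaf_pct": float(rec.info.get("VAF_PCT")),
                    "alt_families": int(rec.info.get("ALT_FAM")),
                    "total_families": int(rec.info.get("TOT_FAM")),
                }
            )
    return out
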