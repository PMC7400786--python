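"""Molecular-family (UMI) consensus variant calling.

Reads tagged with the same molecular barcode at the same panel locus are
collapsed into a *molecular family*.  A family is *functional* when it holds
at least ``min_family_reads`` reads and a strict-majority consensus allele.
Variant calls are made per locus from functional-family consensus alleles:
an alternate allele needs at least ``min_alt_families`` supporting families,
and its VAF is the supporting-family fraction of all functional families at
the locus (molecular depth), reported in percent.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

DISCARDED = "discarded"

#: default thresholds used throughout the pipeline
MIN_FAMILY_READS = 3
MIN_ALT_FAMILIES = 2


@dataclass(frozen=True)
class Locus:
    """A panel position: chromosome, 1-based position, reference allele, gene."""

    locus_id: str
    chrom: str
    pos: int
    ref: str
    gene: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus {self.locus_id}: pos must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError(f"locus {self.locus_id}: empty reference allele")


class TaggedRead(NamedTuple):
    """One read's allele observation at a panel locus, with its molecular barcode."""

    locus_id: str
    umi: str
    allele: str


@dataclass
class MolecularFamily:
    """Reads sharing (locus_id, umi); the unit of error-corrected evidence."""

    locus_id: str
    umi: str
    read_count: int
    alleles: Counter = field(default_factory=Counter)
    consensus_allele: str | None = None
    functional: bool = False


@dataclass(frozen=True)
class VariantCall:
    locus_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    compartment: str
    timepoint_label: str
    alt_families: int
    total_functional_families: int
    read_depth: int
    patient_id: str = ""

    @property
    def vaf_pct(self) -> float:
        return 100.0 * self.alt_families / self.total_functional_families

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError(f"{self.locus_id}: alt equals ref ({self.alt})")
        if not 0 < self.alt_families <= self.total_functional_families:
            raise ValueError(
                f"{self.locus_id}: alt_families {self.alt_families} out of range "
                f"(total {self.total_functional_families})"
            )


@dataclass(frozen=True)
class DepthMetrics:
    locus_id: str
    sequencing_depth: int
    molecular_depth: int

    def __post_init__(self) -> None:
        if self.molecular_depth > self.sequencing_depth:
            raise ValueError(
                f"{self.locus_id}: molecular depth {self.molecular_depth} exceeds "
                f"sequencing depth {self.sequencing_depth}"
            )


Panel = Mapping[str, Locus]


def make_panel(loci: Iterable[Locus]) -> dict[str, Locus]:
    """Index loci by locus_id, rejecting duplicates."""
    panel: dict[str, Locus] = {}
    for locus in loci:
        if locus.locus_id in panel:
            raise ValueError(f"duplicate locus_id in panel: {locus.locus_id}")
        panel[locus.locus_id] = locus
    return panel


def group_families(
    reads: Iterable[TaggedRead], panel: Panel | None = None
) -> list[MolecularFamily]:
    """Group reads into one family per distinct (locus_id, umi) pair.

    Consensus and functional status are left unset; apply
    :func:`consensus_and_filter` next.  With a panel given, reads at unknown
    loci are rejected.
    """
    groups: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for read in reads:
        if panel is not None and read.locus_id not in panel:
            raise KeyError(f"read references unknown locus_id {read.locus_id!r}")
        if not read.umi:
            raise ValueError(f"read at {read.locus_id} has empty UMI")
        if not read.allele:
            raise ValueError(f"read at {read.locus_id} has empty allele")
        groups[(read.locus_id, read.umi)][read.allele] += 1
    return [
        MolecularFamily(
            locus_id=locus_id,
            umi=umi,
            read_count=sum(alleles.values()),
            alleles=alleles,
        )
        for (locus_id, umi), alleles in groups.items()
    ]


def consensus_and_filter(
    families: Iterable[MolecularFamily], min_family_reads: int = MIN_FAMILY_READS
) -> list[MolecularFamily]:
    """Assign each family a strict-majority consensus and a functional flag.

    The consensus allele must be held by more than half of the family's
    reads; ties (no strict majority) discard the family.  A family is
    functional iff it is not discarded and has at least ``min_family_reads``
    reads.
    """
    if min_family_reads < 1:
        raise ValueError("min_family_reads must be >= 1")
    out = []
    for fam in families:
        allele, count = fam.alleles.most_common(1)[0]
        if 2 * count > fam.read_count:
            consensus = allele
        else:
            consensus = DISCARDED
        fam.consensus_allele = consensus
        fam.functional = consensus != DISCARDED and fam.read_count >= min_family_reads
        out.append(fam)
    return out


def call_variants(
    functional_families: Sequence[MolecularFamily],
    locus: Locus,
    min_alt_families: int = MIN_ALT_FAMILIES,
    compartment: str = "plasma",
    timepoint_label: str = "preop",
    read_depth: int | None = None,
    patient_id: str = "",
) -> list[VariantCall]:
    """Call non-reference consensus alleles at one locus.

    Each alternate allele supported by at least ``min_alt_families``
    functional families yields one call; VAF is the supporting-family
    fraction of all functional families at the locus, in percent.  Zero
    functional families simply produce no calls.
    """
    for fam in functional_families:
        if not fam.functional:
            raise ValueError("call_variants expects functional families only")
        if fam.locus_id != locus.locus_id:
            raise ValueError(
                f"family at {fam.locus_id} passed to call_variants for {locus.locus_id}"
            )
    total = len(functional_families)
    if total == 0:
        return []
    support = Counter(fam.consensus_allele for fam in functional_families)
    if read_depth is None:
        read_depth = sum(fam.read_count for fam in functional_families)
    calls = []
    for alt, n_alt in sorted(support.items()):
        if alt == locus.ref or n_alt < min_alt_families:
            continue
        calls.append(
            VariantCall(
                locus_id=locus.locus_id,
                chrom=locus.chrom,
                pos=locus.pos,
                ref=locus.ref,
                alt=alt,
                gene=locus.gene,
                compartment=compartment,
                timepoint_label=timepoint_label,
                alt_families=n_alt,
                total_functional_families=total,
                read_depth=read_depth,
                patient_id=patient_id,
            )
        )
    return calls


def compute_depths(
    reads: Iterable[TaggedRead],
    families: Iterable[MolecularFamily],
    panel: Panel,
) -> dict[str, DepthMetrics]:
    """Per-locus sequencing depth (reads) and molecular depth (functional families).

    Every panel locus gets an entry; loci without coverage report (0, 0).
    """
    seq_depth: Counter = Counter()
    for read in reads:
        seq_depth[read.locus_id] += 1
    mol_depth: Counter = Counter()
    for fam in families:
        if fam.functional:
            mol_depth[fam.locus_id] += 1
    return {
        locus_id: DepthMetrics(
            locus_id=locus_id,
            sequencing_depth=seq_depth.get(locus_id, 0),
            molecular_depth=mol_depth.get(locus_id, 0),
        )
        for locus_id in panel
    }


def call_sample(
    reads: Iterable[TaggedRead],
    panel: Panel,
    min_family_reads: int = MIN_FAMILY_READS,
    min_alt_families: int = MIN_ALT_FAMILIES,
    compartment: str = "plasma",
    timepoint_label: str = "preop",
    patient_id: str = "",
) -> tuple[list[VariantCall], dict[str, DepthMetrics]]:
    """End-to-end calling for one sample: group, consensus-filter, call, depths."""
    reads = list(reads)
    families = consensus_and_filter(group_families(reads, panel), min_family_reads)
    depths = compute_depths(reads, families, panel)
    per_locus: dict[str, list[MolecularFamily]] = defaultdict(list)
    for fam in families:
        if fam.functional:
            per_locus[fam.locus_id].append(fam)
    calls: list[VariantCall] = []
    for locus_id in sorted(per_locus):
        calls.extend(
            call_variants(
                per_locus[locus_id],
                panel[locus_id],
                min_alt_families=min_alt_families,
                compartment=compartment,
                timepoint_label=timepoint_label,
                read_depth=depths[locus_id].sequencing_depth,
                patient_id=patient_id,
            )
        )
    return calls, depths
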