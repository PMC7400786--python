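import numpy as np
import pytest

from chtriage.umi_caller import Locus, TaggedRead, make_panel


@pytest.fixture
def small_panel():
    return make_panel(
        [
            Locus(locus_id="L1", chrom="chr1", pos=100, ref="A", gene="TP53"),
            Locus(locus_id="L2", chrom="chr1", pos=200, ref="C", gene="KRAS"),
            Locus(locus_id="L3", chrom="chr2", pos=300, ref="G", gene="GNAS"),
            Locus(locus_id="L4", chrom="chr2", pos=400, ref="T", gene="APC"),
            Locus(locus_id="L5", chrom="chr3", pos=500, ref="A", gene="PIK3CA"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)


def make_reads(locus_id, umi, alleles):
    return [TaggedRead(locus_id, umi, a) for a in alleles]


def oracle_call_table(reads, panel, min_family_reads=3, min_alt_families=2):
    """Independent brute-force reimplementation of grouping, strict-majority
    consensus, and thresholded calling.  Returns {(locus_id, alt): (n_alt, total)}.
    """
    groups = {}
    for r in reads:
        groups.setdefault((r.locus_id, r.umi), []).append(r.allele)
    consensi_per_locus = {lid: [] for lid in panel}
    for (lid, _umi), alleles in groups.items():
        best_allele, best_count = None, 0
        for a in set(alleles):
            c = alleles.count(a)
            if c > best_count:
                best_allele, best_count = a, c
        if 2 * best_count <= len(alleles):
            continue  # tie: discarded
        if len(alleles) < min_family_reads:
            continue
        consensi_per_locus[lid].append(best_allele)
    table = {}
    for lid, consensi in consensi_per_locus.items():
        total = len(consensi)
        for alt in set(consensi):
            n = consensi.count(alt)
            if alt != panel[lid].ref and n >= min_alt_families:
                table[(lid, alt)] = (n, total)
    return table


def random_read_set(rng, panel, max_reads=50):
    """Random small read set over <= 5 loci, with skewed UMI/allele reuse."""
    loci = list(panel)
    alleles = ["A", "C", "G", "T", "AT"]
    n = int(rng.integers(0, max_reads + 1))
    return [
        TaggedRead(
            loci[rng.integers(len(loci))],
            f"u{rng.integers(8)}",
            alleles[rng.integers(len(alleles))],
        )
        for _ in range(n)
    ]
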