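"""Synthetic matched tumor / PBC / plasma cohorts with UMI-tagged reads.

Generates ground-truth clones per patient (age-dependent blood clones at low
cell fraction, tumor clones drawn from per-gene mutation frequencies), maps
each clone to an expected alternate-molecule fraction per compartment and
timepoint, and realizes molecular families and reads with a per-read
substitution error model.  Everything is seed-deterministic.

Compartment mixing model (fractions, not percent):
  PBC     : blood clone cell fraction; tumor clones absent
  tumor   : tumor clone VAF; blood clones diluted by leukocyte infiltration
  plasma  : tumor clones scaled by the patient's circulating tumor fraction;
            blood clones scaled by the leukocyte share of cfDNA (~1, so
            plasma blood-clone VAFs overlap ctDNA VAFs)
Postoperative plasma zeroes, keeps, or restores tumor-clone fractions
according to the scenario; blood-clone fractions persist at all timepoints.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np

from .umi_caller import Locus, Panel, TaggedRead, make_panel

_BASES = ("A", "C", "G", "T")
_COMP_CODE = {"tumor": 1, "pbc": 2, "plasma": 3}

Scenario = Literal["cured", "residual", "relapse_at_t"]


def default_panel() -> dict[str, Locus]:
    """A compact hotspot panel covering the genes the simulator mutates."""
    rows = [
        ("chr17:7577568", "chr17", 7577568, "C", "TP53"),
        ("chr17:7577535", "chr17", 7577535, "C", "TP53"),
        ("chr17:7577120", "chr17", 7577120, "C", "TP53"),
        ("chr17:7577121", "chr17", 7577121, "G", "TP53"),
        ("chr17:7578536", "chr17", 7578536, "T", "TP53"),
        ("chr17:7577094", "chr17", 7577094, "G", "TP53"),
        ("chr17:7578457", "chr17", 7578457, "C", "TP53"),
        ("chr17:7578263", "chr17", 7578263, "G", "TP53"),
        ("chr17:7577570", "chr17", 7577570, "C", "TP53"),
        ("chr17:7578403", "chr17", 7578403, "C", "TP53"),
        ("chr17:7578190", "chr17", 7578190, "T", "TP53"),
        ("chr20:57484420", "chr20", 57484420, "C", "GNAS"),
        ("chr12:25398284", "chr12", 25398284, "C", "KRAS"),
        ("chr12:25398281", "chr12", 25398281, "C", "KRAS"),
        ("chr3:178952085", "chr3", 178952085, "A", "PIK3CA"),
        ("chr5:112175770", "chr5", 112175770, "G", "APC"),
    ]
    return make_panel(Locus(locus_id=r[0], chrom=r[1], pos=r[2], ref=r[3], gene=r[4]) for r in rows)


@dataclass
class SimConfig:
    seed: int = 0
    n_patients: int = 38
    age_range: tuple[float, float] = (42.0, 88.0)
    stage_probs: dict[str, float] = field(
        default_factory=lambda: {"I": 0.26, "II": 0.26, "III": 0.40, "IV": 0.08}
    )
    # logistic probability of carrying >=1 blood clone as a function of age
    ch_age_midpoint: float = 70.0
    ch_age_slope: float = 0.10
    ch_vaf_range_pct: tuple[float, float] = (0.05, 1.5)  # log-uniform
    ch_genes: tuple[str, ...] = ("TP53", "GNAS")
    tumor_gene_freqs: dict[str, float] = field(
        default_factory=lambda: {"TP53": 0.46, "KRAS": 0.19, "PIK3CA": 0.11, "APC": 0.10}
    )
    tumor_clone_vaf_range_pct: tuple[float, float] = (5.0, 60.0)  # log-uniform
    plasma_tumor_fraction_by_stage: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "I": (1e-3, 0.05),
            "II": (2e-3, 0.08),
            "III": (5e-3, 0.15),
            "IV": (2e-2, 0.30),
        }
    )
    tumor_leukocyte_infiltration: float = 0.05
    plasma_leukocyte_share: float = 1.0
    molecular_depth: dict[str, int] = field(
        default_factory=lambda: {"tumor": 2048, "pbc": 2581, "plasma": 4004}
    )
    mean_family_size: float = 4.0
    per_read_error_rate: float = 0.001
    postop_months: tuple[float, ...] = (7.5, 10.0, 12.5)
    postop_scenario: Scenario = "cured"
    relapse_timepoint: int = 1  # 1-based postop index, used by "relapse_at_t"
    panel: dict[str, Locus] = field(default_factory=default_panel)

    def __post_init__(self) -> None:
        if not 0 <= self.tumor_leukocyte_infiltration <= 1:
            raise ValueError("tumor_leukocyte_infiltration must be in [0, 1]")
        if not 0 <= self.plasma_leukocyte_share <= 1:
            raise ValueError("plasma_leukocyte_share must be in [0, 1]")
        if any(d < 1 for d in self.molecular_depth.values()):
            raise ValueError("molecular depths must be >= 1")
        if self.ch_vaf_range_pct[0] <= 0 or self.tumor_clone_vaf_range_pct[0] <= 0:
            raise ValueError("VAF ranges must be positive")
        if self.mean_family_size < 1:
            raise ValueError("mean_family_size must be >= 1")

    @property
    def functional_family_prob(self) -> float:
        """P(family size >= 3) under size = 1 + Poisson(mean - 1)."""
        lam = self.mean_family_size - 1.0
        return 1.0 - math.exp(-lam) * (1.0 + lam)

    def ch_probability(self, age: float) -> float:
        x = self.ch_age_slope * (age - self.ch_age_midpoint)
        return 1.0 / (1.0 + math.exp(-max(-700.0, min(700.0, x))))


@dataclass(frozen=True)
class Clone:
    locus_id: str
    alt: str
    vaf_pct: float  # cell fraction in the clone's native compartment
    kind: Literal["ch", "tumor"]


@dataclass
class PatientTruth:
    patient_id: str
    age: float
    stage: str
    ch_clones: list[Clone]
    tumor_clones: list[Clone]
    plasma_tumor_fraction: float

    def alt_fraction(
        self, clone: Clone, compartment: str, config: SimConfig, postop_index: int = 0
    ) -> float:
        """Expected alternate-molecule fraction for a clone in a compartment.

        ``postop_index`` 0 is the preoperative timepoint; >= 1 are the
        ordered postoperative plasma samples.
        """
        v = clone.vaf_pct / 100.0
        if clone.kind == "ch":
            if compartment == "pbc":
                return v
            if compartment == "tumor":
                return config.tumor_leukocyte_infiltration * v
            return config.plasma_leukocyte_share * v
        # tumor clone
        if compartment == "pbc":
            return 0.0
        if compartment == "tumor":
            return v
        frac = self.plasma_tumor_fraction * v
        if postop_index == 0:
            return frac
        if config.postop_scenario == "residual":
            return frac
        if config.postop_scenario == "relapse_at_t":
            return frac if postop_index >= config.relapse_timepoint else 0.0
        return 0.0  # cured

    def fractions_by_locus(
        self, compartment: str, config: SimConfig, postop_index: int = 0
    ) -> dict[str, tuple[str, float]]:
        """locus_id -> (alt allele, expected alt fraction) for nonzero clones."""
        out: dict[str, tuple[str, float]] = {}
        for clone in self.ch_clones + self.tumor_clones:
            f = self.alt_fraction(clone, compartment, config, postop_index)
            if f > 0:
                out[clone.locus_id] = (clone.alt, f)
        return out

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "age": self.age,
            "stage": self.stage,
            "plasma_tumor_fraction": self.plasma_tumor_fraction,
            "ch_clones": [vars(c) | {} for c in self.ch_clones],
            "tumor_clones": [vars(c) | {} for c in self.tumor_clones],
        }


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _random_alt(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in _BASES if b != ref]
    return choices[rng.integers(len(choices))]


def simulate_patient(
    config: SimConfig, rng: np.random.Generator, patient_id: str = "S01"
) -> PatientTruth:
    """Draw one patient's ground truth: age, stage, blood and tumor clones."""
    age = float(rng.uniform(*config.age_range))
    stages = list(config.stage_probs)
    probs = np.array([config.stage_probs[s] for s in stages], dtype=float)
    stage = stages[rng.choice(len(stages), p=probs / probs.sum())]

    loci = sorted(config.panel.values(), key=lambda l: l.locus_id)
    used: set[str] = set()

    ch_clones: list[Clone] = []
    if rng.random() < config.ch_probability(age):
        pool = [l for l in loci if l.gene in config.ch_genes]
        locus = pool[rng.integers(len(pool))]
        used.add(locus.locus_id)
        ch_clones.append(
            Clone(
                locus_id=locus.locus_id,
                alt=_random_alt(rng, locus.ref),
                vaf_pct=_log_uniform(rng, *config.ch_vaf_range_pct),
                kind="ch",
            )
        )

    tumor_clones: list[Clone] = []
    for gene, freq in config.tumor_gene_freqs.items():
        if rng.random() >= freq:
            continue
        pool = [l for l in loci if l.gene == gene and l.locus_id not in used]
        if not pool:
            continue
        locus = pool[rng.integers(len(pool))]
        used.add(locus.locus_id)
        tumor_clones.append(
            Clone(
                locus_id=locus.locus_id,
                alt=_random_alt(rng, locus.ref),
                vaf_pct=_log_uniform(rng, *config.tumor_clone_vaf_range_pct),
                kind="tumor",
            )
        )

    ptf_lo, ptf_hi = config.plasma_tumor_fraction_by_stage[stage]
    return PatientTruth(
        patient_id=patient_id,
        age=age,
        stage=stage,
        ch_clones=ch_clones,
        tumor_clones=tumor_clones,
        plasma_tumor_fraction=_log_uniform(rng, ptf_lo, ptf_hi),
    )


def emit_reads(
    truth: PatientTruth,
    compartment: str,
    config: SimConfig,
    rng: np.random.Generator,
    postop_index: int = 0,
) -> list[TaggedRead]:
    """Realize UMI-tagged reads for one sample.

    Family counts are Poisson around the target molecular depth inflated by
    the functional-family probability; each family's source molecule is
    alternate with the clone's compartment fraction; reads copy the molecule
    allele and are flipped to a random wrong base at the per-read error rate.
    UMIs are unique per family within a locus (no collisions).
    """
    if compartment not in _COMP_CODE:
        raise ValueError(f"unknown compartment {compartment!r}")
    if compartment != "plasma" and postop_index != 0:
        raise ValueError(f"{compartment} is only sampled at surgery (postop_index 0)")
    fractions = truth.fractions_by_locus(compartment, config, postop_index)
    target = config.molecular_depth[compartment] / config.functional_family_prob
    err = config.per_read_error_rate
    reads: list[TaggedRead] = []
    for locus_id in sorted(config.panel):
        locus = config.panel[locus_id]
        alt, f = fractions.get(locus_id, (None, 0.0))
        n_fam = int(rng.poisson(target))
        if n_fam == 0:
            continue
        sizes = 1 + rng.poisson(config.mean_family_size - 1.0, n_fam)
        is_alt = rng.random(n_fam) < f if f > 0 else np.zeros(n_fam, dtype=bool)
        fam_idx = np.repeat(np.arange(n_fam), sizes)
        total = fam_idx.size
        alleles = np.where(is_alt, alt if alt else locus.ref, locus.ref)[fam_idx]
        alleles = alleles.astype(object)
        if err > 0:
            flip = np.flatnonzero(rng.random(total) < err)
            for i in flip:
                alleles[i] = _random_alt(rng, alleles[i])
        umis = [f"{locus_id}:u{i}" for i in fam_idx]
        reads.extend(
            TaggedRead(locus_id, umi, allele) for umi, allele in zip(umis, alleles)
        )
    return reads


def _sample_rng(seed: int, patient_index: int, compartment: str, postop_index: int):
    return np.random.default_rng(
        [seed, 7919, patient_index, _COMP_CODE[compartment], postop_index]
    )


def _truth_rng(seed: int, patient_index: int) -> np.random.Generator:
    return np.random.default_rng([seed, 104729, patient_index])


def simulate_truths(config: SimConfig) -> list[PatientTruth]:
    """Ground truth for the whole cohort (no reads), seed-deterministic."""
    return [
        simulate_patient(config, _truth_rng(config.seed, i), patient_id=f"S{i + 1:02d}")
        for i in range(config.n_patients)
    ]


def iter_samples(
    config: SimConfig, truths: Sequence[PatientTruth] | None = None
) -> Iterator[tuple[PatientTruth, str, int, list[TaggedRead]]]:
    """Yield (truth, compartment, postop_index, reads) for every sample.

    Tumor and PBC are sampled at surgery only; plasma at the preoperative
    timepoint plus every configured postoperative month.
    """
    if truths is None:
        truths = simulate_truths(config)
    for i, truth in enumerate(truths):
        for compartment in ("tumor", "pbc"):
            rng = _sample_rng(config.seed, i, compartment, 0)
            yield truth, compartment, 0, emit_reads(truth, compartment, config, rng)
        for t in range(len(config.postop_months) + 1):
            rng = _sample_rng(config.seed, i, "plasma", t)
            yield truth, "plasma", t, emit_reads(truth, "plasma", config, rng, postop_index=t)


def timepoint_label(postop_index: int) -> str:
    return "preop" if postop_index == 0 else f"postop{postop_index}"


def simulate_cohort(
    config: SimConfig, out_dir: str | Path
) -> tuple[list[PatientTruth], Path]:
    """Write tagged-read TSVs, a truth JSON, and a manifest TSV to ``out_dir``.

    Returns the truths and the manifest path.  Refuses to overwrite an
    existing manifest.
    """
    from .io_cli.tables import write_tagged_reads

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.tsv"
    if manifest_path.exists():
        raise FileExistsError(f"{manifest_path} already exists")
    truths = simulate_truths(config)
    rows = []
    for truth, compartment, t, reads in iter_samples(config, truths):
        label = timepoint_label(t)
        fname = f"{truth.patient_id}_{compartment}_{label}.reads.tsv"
        write_tagged_reads(reads, out / fname)
        months = 0.0 if t == 0 else config.postop_months[t - 1]
        rows.append((truth.patient_id, compartment, label, f"{months:g}", fname))
    with open(out / "truth.json", "w") as fh:
        json.dump([t.to_dict() for t in truths], fh, indent=1)
    with open(manifest_path, "w") as fh:
        fh.write("patient\tcompartment\ttimepoint\tmonths_from_surgery\tfile\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return truths, manifest_path
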