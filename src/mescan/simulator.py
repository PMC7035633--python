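"""Synthetic cohorts of mobile-element insertions with truth labels.

The generator emulates the statistical structure of targeted
junction-fragment sequencing without simulating raw bases: for each
sample it emits the two evidence files the pipeline consumes — a
BLAST tabular file of ME-read bit scores and a SAM file of
flanking-read alignments — plus a manifest, truth tables and an
optional pedigree.

What is modelled: fixed reference loci (allele frequency 1) and
polymorphic loci with Hardy-Weinberg parental genotypes and Mendelian
transmission to children; per-locus read depth Poisson in the carried
allele dosage; a bimodal bit-score mixture (young target subfamily
vs. an older-subfamily mode below the cutoff); fragment-end geometry
placing flanking junctions within a read length of the insertion;
mapping-quality noise (MQ-0 multi-mappers, low-MQ tails, mismapping)
and genome-wide background reads; somatic events restricted to one
cell type at a configurable cellular fraction.

What is not modelled: base-level sequencing errors, PCR duplicates
beyond their UR-collapsing effect, 3' transductions, and reference
alignment artifacts around old repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .formats_io import PedigreeTrio
from .read_filtering import DEFAULT_BIT_CUTOFFS, MEFamily

__all__ = [
    "FamilySimParams",
    "NoiseParams",
    "SomaticEvent",
    "SimulationConfig",
    "TruthLocus",
    "TruthSet",
    "simulate_truth",
    "transmit",
    "simulate_reads",
    "simulate_cellset",
    "synthetic_consensus",
    "write_truth_bed",
]


@dataclass(frozen=True)
class FamilySimParams:
    """Bit-score emission model for one targeted family.

    ``target_bit_mean`` sits above the family cutoff (young subfamily),
    ``older_bit_mean`` below it (older subfamily reads pulled down by
    accumulated divergence); ``older_frac`` of reads draw from the
    older mode.
    """

    name: str
    bit_cutoff: float
    target_bit_mean: float
    older_bit_mean: float
    bit_sd: float = 5.0
    older_frac: float = 0.0

    @classmethod
    def for_family(cls, name: str, **overrides) -> "FamilySimParams":
        cutoff = DEFAULT_BIT_CUTOFFS.get(name, 50.0)
        defaults = dict(
            name=name,
            bit_cutoff=cutoff,
            target_bit_mean=cutoff + 15.0,
            older_bit_mean=max(cutoff - 20.0, 5.0),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class NoiseParams:
    """Rates of the mapping/scoring artifacts the filters must absorb."""

    me_score_noise_sd: float = 5.0
    mismap_rate: float = 0.0
    mapq0_rate: float = 0.0
    low_mq_rate: float = 0.0
    background_reads_per_sample: int = 0

    def __post_init__(self) -> None:
        for name in ("mismap_rate", "mapq0_rate", "low_mq_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SomaticEvent:
    """A planted somatic insertion in one cell type of one individual."""

    individual_id: str
    cell_type: str
    cellular_fraction: float = 1.0
    n_loci: int = 1


@dataclass
class SimulationConfig:
    seed: int
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    families: Sequence[FamilySimParams] = field(
        default_factory=lambda: [FamilySimParams.for_family("L1HS")]
    )
    n_fixed_loci: int = 100
    n_polymorphic_loci: int = 0
    allele_freq: float | tuple[float, float] | Sequence[float] = 0.2
    samples: Sequence[str] = field(default_factory=lambda: ["S1"])
    trios: Sequence[PedigreeTrio] = ()
    cell_types: Mapping[str, Sequence[str]] | None = None
    somatic_events: Sequence[SomaticEvent] = ()
    forced_parent_genotypes: tuple[int, int] | None = None
    depth_mean: float = 20.0
    read_length: int = 100
    window: int = 500
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def germline_samples(self) -> list[str]:
        if self.trios:
            out: list[str] = []
            for trio in self.trios:
                out.extend(trio.sample_ids)
            return out
        if self.cell_types is not None:
            return list(self.cell_types)
        return list(self.samples)

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass(frozen=True)
class TruthLocus:
    locus_id: str
    family: str
    chrom: str
    position: int
    strand: str
    cls: str  # fixed_reference | polymorphic | somatic
    allele_frequency: float


@dataclass
class TruthSet:
    """Planted loci, germline genotypes and somatic assignments.

    ``genotypes`` maps (sample_id, locus_id) -> insertion allele copies
    in {0, 1, 2}. For cell-type designs the sample_id is the individual;
    somatic loci carry genotype 0 everywhere and appear only in
    ``somatic`` as (individual, cell_type) -> locus ids.
    """

    loci: list[TruthLocus]
    genotypes: dict[tuple[str, str], int]
    somatic: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    samples: list[str] = field(default_factory=list)

    def loci_of_class(self, cls: str) -> list[TruthLocus]:
        return [locus for locus in self.loci if locus.cls == cls]

    def carrier_fraction(self, sample_id: str, cls: str = "polymorphic") -> float:
        loci = self.loci_of_class(cls)
        if not loci:
            raise ValueError(f"no loci of class {cls!r}")
        carried = sum(
            1 for locus in loci if self.genotypes[(sample_id, locus.locus_id)] > 0
        )
        return carried / len(loci)


def transmit(parent_copies: int, rng: np.random.Generator) -> int:
    """Mendelian transmission of one allele.

    A parent carrying ``copies`` insertion alleles transmits the
    insertion with probability copies/2 — hence the expected child
    inheritance rates of 50% (het parent) and 100% (hom parent).
    """
    if parent_copies not in (0, 1, 2):
        raise ValueError("parent copies must be 0, 1 or 2")
    if parent_copies == 0:
        return 0
    if parent_copies == 2:
        return 1
    return int(rng.integers(0, 2))


def _draw_frequencies(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.allele_freq
    n = config.n_polymorphic_loci
    if isinstance(spec, tuple):
        a, b = spec
        return rng.beta(a, b, size=n)
    if np.isscalar(spec):
        return np.full(n, float(spec))
    freqs = np.asarray(spec, dtype=float)
    if freqs.size != n:
        raise ValueError("per-locus allele_freq length != n_polymorphic_loci")
    return freqs


def _place_loci(
    config: SimulationConfig, n_total: int, rng: np.random.Generator
) -> list[tuple[str, int, str]]:
    """Uniform non-overlapping placement with min spacing 2x window.

    The chromosome is divided into slots of width 2x min-spacing; each
    locus takes a random offset within a randomly chosen slot, which
    guarantees pairwise distance >= min spacing.
    """
    min_spacing = 2 * config.window
    slot = 2 * min_spacing
    margin = 2 * config.read_length + config.window
    slots_per_chrom = max((config.chrom_length - 2 * margin) // slot, 0)
    total_slots = slots_per_chrom * config.n_chroms
    if n_total > total_slots:
        raise ValueError(
            f"genome too small: {n_total} loci requested but only "
            f"{total_slots} positions available at {min_spacing} bp spacing"
        )
    chosen = rng.choice(total_slots, size=n_total, replace=False)
    chosen.sort()
    placements: list[tuple[str, int, str]] = []
    for idx in chosen:
        chrom = config.chrom_names[idx // slots_per_chrom]
        slot_i = idx % slots_per_chrom
        offset = int(rng.integers(0, slot - min_spacing))
        position = margin + slot_i * slot + offset
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        placements.append((chrom, position, strand))
    return placements


def simulate_truth(config: SimulationConfig) -> TruthSet:
    """Plant loci and draw cohort genotypes.

    Fixed reference loci get frequency 1 and two copies in every
    germline sample. Polymorphic loci draw parental (or unrelated)
    genotypes from Hardy-Weinberg at the locus frequency; children
    receive one Mendelian allele per parent. ``forced_parent_genotypes``
    overrides the parental draw for every polymorphic locus, which is
    how transmission-rate experiments pin the parental state.
    """
    rng = np.random.default_rng(config.seed)
    n_somatic = sum(ev.n_loci for ev in config.somatic_events)
    n_total = config.n_fixed_loci + config.n_polymorphic_loci + n_somatic
    families = list(config.families)

    placements = _place_loci(config, n_total, rng)
    freqs = _draw_frequencies(config, rng)
    samples = config.germline_samples

    loci: list[TruthLocus] = []
    genotypes: dict[tuple[str, str], int] = {}
    somatic: dict[tuple[str, str], list[str]] = {}

    classes: list[tuple[str, float]] = (
        [("fixed_reference", 1.0)] * config.n_fixed_loci
        + [("polymorphic", float(f)) for f in freqs]
    )
    somatic_owner: list[SomaticEvent | None] = [None] * len(classes)
    for ev in config.somatic_events:
        classes.extend([("somatic", 0.0)] * ev.n_loci)
        somatic_owner.extend([ev] * ev.n_loci)

    for i, ((chrom, position, strand), (cls, freq)) in enumerate(
        zip(placements, classes)
    ):
        fam = families[i % len(families)]
        locus = TruthLocus(
            locus_id=f"truth_{i + 1:05d}",
            family=fam.name,
            chrom=chrom,
            position=position,
            strand=strand,
            cls=cls,
            allele_frequency=freq,
        )
        loci.append(locus)
        owner = somatic_owner[i]
        if owner is not None:
            somatic.setdefault(
                (owner.individual_id, owner.cell_type), []
            ).append(locus.locus_id)
            for s in samples:
                genotypes[(s, locus.locus_id)] = 0
            continue
        if cls == "fixed_reference":
            for s in samples:
                genotypes[(s, locus.locus_id)] = 2
            continue
        # polymorphic: parents / unrelated from Hardy-Weinberg
        if config.trios:
            for trio in config.trios:
                if config.forced_parent_genotypes is not None:
                    father_c, mother_c = config.forced_parent_genotypes
                else:
                    father_c = int(rng.binomial(2, freq))
                    mother_c = int(rng.binomial(2, freq))
                child_c = transmit(father_c, rng) + transmit(mother_c, rng)
                genotypes[(trio.father_id, locus.locus_id)] = father_c
                genotypes[(trio.mother_id, locus.locus_id)] = mother_c
                genotypes[(trio.child_id, locus.locus_id)] = child_c
        else:
            for s in samples:
                genotypes[(s, locus.locus_id)] = int(rng.binomial(2, freq))

    return TruthSet(
        loci=loci, genotypes=genotypes, somatic=somatic, samples=list(samples)
    )


def _sam_header(config: SimulationConfig) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": config.chrom_length}
                for name in config.chrom_names
            ],
        }
    )


def _emit_locus_reads(
    sam_out,
    blast_lines: list[str],
    config: SimulationConfig,
    fam: FamilySimParams,
    locus: TruthLocus,
    sample_label: str,
    n_reads: int,
    rng: np.random.Generator,
    read_tag: str,
) -> None:
    rl = config.read_length
    header_names = config.chrom_names
    for i in range(n_reads):
        read_id = f"{read_tag}:{locus.locus_id}:{i + 1}"
        # ME-read bit score: target mode or older-subfamily contaminant
        if fam.older_frac > 0 and rng.random() < fam.older_frac:
            bits = rng.normal(fam.older_bit_mean, fam.bit_sd)
        else:
            bits = rng.normal(
                fam.target_bit_mean, config.noise.me_score_noise_sd
            )
        bits = max(bits, 0.0)
        blast_lines.append(
            "\t".join(
                [
                    read_id,
                    fam.name,
                    "98.00",
                    str(rl),
                    "2",
                    "0",
                    "1",
                    str(rl),
                    "1",
                    str(rl),
                    "1e-20",
                    f"{bits:.1f}",
                ]
            )
        )
        # flanking-read geometry: junction within a read length of the locus
        offset = int(rng.integers(0, rl))
        chrom = locus.chrom
        if locus.strand == "+":
            # junction = alignment end = position - offset
            start = max(locus.position - offset - rl, 0)
            flag = 0
        else:
            # junction = alignment start = position + offset
            start = locus.position + offset
            flag = 16
        mapq = 60
        u = rng.random()
        if u < config.noise.mapq0_rate:
            mapq = 0
        elif u < config.noise.mapq0_rate + config.noise.low_mq_rate:
            mapq = int(rng.integers(1, 30))
        if config.noise.mismap_rate > 0 and rng.random() < config.noise.mismap_rate:
            chrom = header_names[int(rng.integers(0, len(header_names)))]
            start = int(
                rng.integers(rl, config.chrom_length - 2 * rl)
            )
        aln = pysam.AlignedSegment(sam_out.header)
        aln.query_name = read_id
        aln.flag = flag
        aln.reference_id = sam_out.header.get_tid(chrom)
        aln.reference_start = start
        aln.mapping_quality = mapq
        aln.cigarstring = f"{rl}M"
        aln.query_sequence = "A" * rl
        aln.query_qualities = pysam.qualitystring_to_array("I" * rl)
        sam_out.write(aln)


def _emit_background_reads(
    sam_out,
    blast_lines: list[str],
    config: SimulationConfig,
    fam: FamilySimParams,
    sample_label: str,
    rng: np.random.Generator,
) -> None:
    rl = config.read_length
    for i in range(config.noise.background_reads_per_sample):
        read_id = f"{sample_label}:bg:{i + 1}"
        bits = max(
            rng.normal(fam.target_bit_mean, config.noise.me_score_noise_sd), 0.0
        )
        blast_lines.append(
            "\t".join(
                [read_id, fam.name, "98.00", str(rl), "2", "0", "1",
                 str(rl), "1", str(rl), "1e-20", f"{bits:.1f}"]
            )
        )
        chrom = config.chrom_names[int(rng.integers(0, config.n_chroms))]
        start = int(rng.integers(rl, config.chrom_length - 2 * rl))
        aln = pysam.AlignedSegment(sam_out.header)
        aln.query_name = read_id
        aln.flag = 0 if rng.integers(0, 2) == 0 else 16
        aln.reference_id = sam_out.header.get_tid(chrom)
        aln.reference_start = start
        aln.mapping_quality = 60
        aln.cigarstring = f"{rl}M"
        aln.query_sequence = "A" * rl
        aln.query_qualities = pysam.qualitystring_to_array("I" * rl)
        sam_out.write(aln)


def simulate_reads(
    truth: TruthSet, config: SimulationConfig, outdir: str | Path
) -> Path:
    """Emit per-sample BLAST-6 + SAM evidence files and a manifest.

    For each (sample, locus) with copies > 0 the read count is
    Poisson(depth_mean x copies / 2) — depth scales with allele
    dosage. Returns the manifest path. Output is a deterministic
    function of the truth set and config seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    fam_by_name = {f.name: f for f in config.families}
    manifest_rows: list[str] = []

    for sample in truth.samples:
        for fam in config.families:
            blast_path = outdir / f"{sample}.{fam.name}.blast6.tsv"
            sam_path = outdir / f"{sample}.{fam.name}.sam"
            blast_lines: list[str] = []
            with pysam.AlignmentFile(
                str(sam_path), "wh", header=_sam_header(config)
            ) as sam_out:
                for locus in truth.loci:
                    if locus.family != fam.name or locus.cls == "somatic":
                        continue
                    copies = truth.genotypes[(sample, locus.locus_id)]
                    if copies == 0:
                        continue
                    n_reads = int(
                        rng.poisson(config.depth_mean * copies / 2)
                    )
                    _emit_locus_reads(
                        sam_out, blast_lines, config,
                        fam_by_name[locus.family], locus, sample,
                        n_reads, rng, read_tag=sample,
                    )
                _emit_background_reads(
                    sam_out, blast_lines, config, fam, sample, rng
                )
            blast_path.write_text(
                "".join(line + "\n" for line in blast_lines)
            )
            manifest_rows.append(
                f"{sample}\t{fam.name}\t{blast_path.name}\t{sam_path.name}\t\t"
            )

    manifest_path = outdir / "manifest.tsv"
    manifest_path.write_text(
        "sample_id\tfamily\tblast6\tsam\tcell_type\tindividual\n"
        + "".join(row + "\n" for row in manifest_rows)
    )
    if config.trios:
        ped_path = outdir / "pedigree.tsv"
        ped_path.write_text(
            "".join(
                f"{t.family_id}\t{t.father_id}\t{t.mother_id}\t{t.child_id}\n"
                for t in config.trios
            )
        )
    write_truth_bed(truth, outdir / "truth.bed")
    return manifest_path


def simulate_cellset(
    truth: TruthSet, config: SimulationConfig, outdir: str | Path
) -> Path:
    """Emit evidence per (individual, cell type).

    Germline loci produce reads in every cell type at the individual's
    dosage; somatic loci produce reads only in their assigned cell type
    with depth scaled by the event's cellular fraction (one new allele
    in a ``fraction`` of cells: Poisson(depth x fraction / 2)).
    """
    if config.cell_types is None:
        raise ValueError("config.cell_types must define the cell design")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 2)
    fam_by_name = {f.name: f for f in config.families}
    fractions = {
        (ev.individual_id, ev.cell_type): ev.cellular_fraction
        for ev in config.somatic_events
    }
    manifest_rows: list[str] = []
    for individual, cell_types in config.cell_types.items():
        for cell_type in cell_types:
            label = f"{individual}_{cell_type}"
            for fam in config.families:
                blast_path = outdir / f"{label}.{fam.name}.blast6.tsv"
                sam_path = outdir / f"{label}.{fam.name}.sam"
                blast_lines: list[str] = []
                with pysam.AlignmentFile(
                    str(sam_path), "wh", header=_sam_header(config)
                ) as sam_out:
                    for locus in truth.loci:
                        if locus.family != fam.name:
                            continue
                        if locus.cls == "somatic":
                            if locus.locus_id not in truth.somatic.get(
                                (individual, cell_type), []
                            ):
                                continue
                            frac = fractions.get((individual, cell_type), 1.0)
                            lam = config.depth_mean * frac / 2
                        else:
                            copies = truth.genotypes[
                                (individual, locus.locus_id)
                            ]
                            if copies == 0:
                                continue
                            lam = config.depth_mean * copies / 2
                        n_reads = int(rng.poisson(lam))
                        _emit_locus_reads(
                            sam_out, blast_lines, config, fam, locus,
                            label, n_reads, rng, read_tag=label,
                        )
                    _emit_background_reads(
                        sam_out, blast_lines, config, fam, label, rng
                    )
                blast_path.write_text(
                    "".join(line + "\n" for line in blast_lines)
                )
                manifest_rows.append(
                    f"{label}\t{fam.name}\t{blast_path.name}\t"
                    f"{sam_path.name}\t{cell_type}\t{individual}"
                )
    manifest_path = outdir / "cell_manifest.tsv"
    manifest_path.write_text(
        "sample_id\tfamily\tblast6\tsam\tcell_type\tindividual\n"
        + "".join(row + "\n" for row in manifest_rows)
    )
    write_truth_bed(truth, outdir / "truth.bed")
    return manifest_path


def write_truth_bed(truth: TruthSet, path: str | Path) -> None:
    """Truth loci as BED6 + class + allele-frequency columns."""
    with open(path, "w") as fh:
        for locus in truth.loci:
            fh.write(
                "\t".join(
                    [
                        locus.chrom,
                        str(locus.position),
                        str(locus.position + 1),
                        f"{locus.family}:{locus.locus_id}",
                        "0",
                        locus.strand,
                        locus.cls,
                        f"{locus.allele_frequency:.4f}",
                    ]
                )
                + "\n"
            )


def synthetic_consensus(
    name: str, length: int = 300, seed: int = 0
) -> MEFamily:
    """A random-sequence stand-in consensus for scoring tests.

    Real family consensus sequences are not bundled; alignment-level
    behavior only needs a fixed reference sequence of realistic length.
    """
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    cutoff = DEFAULT_BIT_CUTOFFS.get(name, 50.0)
    return MEFamily(name=name, consensus=seq, bit_cutoff=cutoff)
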