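"""Readers and writers for the standard formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals. The
converters in this module are the only places where the +/-1 adjustments
for SAM (1-based POS), GTF (1-based inclusive) and VCF (1-based POS)
appear; everything downstream can assume a single convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

__all__ = [
    "Blast6Record",
    "SamAlignment",
    "GenomicInterval",
    "PedigreeTrio",
    "ManifestEntry",
    "FormatError",
    "read_blast6",
    "read_sam",
    "write_bed",
    "write_vcf",
    "read_intervals",
    "read_pedigree",
    "read_manifest",
]


class FormatError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass(frozen=True)
class Blast6Record:
    """One line of BLAST tabular output (``-outfmt 6``, 12 columns)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float


@dataclass(frozen=True)
class SamAlignment:
    """A single alignment with 0-based half-open coordinates.

    ``start``/``end`` are only meaningful when ``is_unmapped`` is False.
    ``end`` is computed from the reference-consuming CIGAR operations.
    """

    read_id: str
    sample_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mapq: int
    flags: int
    is_secondary: bool = False
    is_supplementary: bool = False
    is_unmapped: bool = False


@dataclass(frozen=True)
class GenomicInterval:
    """Generic labelled interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = ""
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class PedigreeTrio:
    family_id: str
    father_id: str
    mother_id: str
    child_id: str

    def __post_init__(self) -> None:
        ids = {self.father_id, self.mother_id, self.child_id}
        if len(ids) != 3:
            raise ValueError(
                f"trio {self.family_id} must have three distinct samples"
            )

    @property
    def sample_ids(self) -> tuple[str, str, str]:
        return (self.father_id, self.mother_id, self.child_id)


@dataclass(frozen=True)
class ManifestEntry:
    """One row of the sample manifest: where a sample's evidence lives."""

    sample_id: str
    family: str
    blast6_path: str
    sam_path: str
    cell_type: str | None = None
    individual_id: str | None = None


def read_blast6(path: str | Path) -> list[Blast6Record]:
    """Parse BLAST ``-outfmt 6`` tabular output.

    Raises :class:`FormatError` naming the line number when a line does
    not have exactly 12 tab-separated columns.
    """
    records: list[Blast6Record] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 tab-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                records.append(
                    Blast6Record(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
    return records


def read_sam(
    path: str | Path,
    sample_id: str = "",
    skipped: list[int] | None = None,
) -> list[SamAlignment]:
    """Read SAM text into :class:`SamAlignment` records.

    1-based POS becomes a 0-based ``start``; ``end`` follows from the
    reference-consuming CIGAR operations (pysam's ``reference_end``).
    Records with an unparseable body line are skipped and counted in
    ``skipped`` (a single-element list used as an out-parameter) rather
    than aborting the whole file.
    """
    alignments: list[SamAlignment] = []
    n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        while True:
            try:
                rec = next(sam)
            except StopIteration:
                break
            except ValueError:
                n_skipped += 1
                continue
            if rec.is_unmapped:
                alignments.append(
                    SamAlignment(
                        read_id=rec.query_name or "",
                        sample_id=sample_id,
                        chrom="",
                        start=-1,
                        end=-1,
                        strand="+",
                        mapq=rec.mapping_quality,
                        flags=rec.flag,
                        is_unmapped=True,
                    )
                )
                continue
            alignments.append(
                SamAlignment(
                    read_id=rec.query_name or "",
                    sample_id=sample_id,
                    chrom=rec.reference_name or "",
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mapq=rec.mapping_quality,
                    flags=rec.flag,
                    is_secondary=rec.is_secondary,
                    is_supplementary=rec.is_supplementary,
                )
            )
    if skipped is not None:
        skipped.append(n_skipped)
    return alignments


def write_bed(loci: Sequence, path: str | Path) -> None:
    """Write candidate loci as BED6 single-base intervals.

    Each locus occupies ``[position, position + 1)``; the name column is
    ``family:locus_id`` and the score is the maximum per-sample UR,
    capped at 1000 per the BED score range.
    """
    with open(path, "w") as fh:
        for locus in loci:
            max_ur = max(
                (ev.ur for ev in locus.per_sample.values()), default=0
            )
            fh.write(
                "\t".join(
                    [
                        locus.chrom,
                        str(locus.position),
                        str(locus.position + 1),
                        f"{locus.family}:{locus.locus_id}",
                        str(min(int(max_ur), 1000)),
                        locus.strand,
                    ]
                )
                + "\n"
            )


def write_vcf(
    loci: Sequence,
    samples: Sequence[str],
    presence,
    path: str | Path,
    families: Iterable[str] | None = None,
    reference_name: str = "synthetic",
) -> None:
    """Write presence/absence calls as VCF 4.2 with symbolic ME ALT alleles.

    The assay detects presence of an insertion but cannot resolve
    zygosity, so carriers get genotype ``1/.`` and non-carriers ``0/0``.
    """
    if families is None:
        families = sorted({locus.family for locus in loci})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_name}\n")
        for fam in families:
            fh.write(
                f"##ALT=<ID=INS:ME:{fam.upper()},"
                f'Description="{fam} mobile element insertion">\n'
            )
        fh.write(
            '##INFO=<ID=MEFAM,Number=1,Type=String,'
            'Description="Mobile element family">\n'
        )
        fh.write(
            '##INFO=<ID=TPM,Number=.,Type=Float,'
            'Description="Tags-per-million per sample, sample order">\n'
        )
        fh.write(
            '##INFO=<ID=UR,Number=.,Type=Integer,'
            'Description="Unique supporting reads per sample">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for locus in loci:
            tpms = ",".join(
                f"{locus.per_sample[s].tpm:.4g}" if s in locus.per_sample else "0"
                for s in samples
            )
            urs = ",".join(
                str(locus.per_sample[s].ur) if s in locus.per_sample else "0"
                for s in samples
            )
            info = f"MEFAM={locus.family};TPM={tpms};UR={urs}"
            gts = "\t".join(
                "1/." if presence.is_present(locus.locus_id, s) else "0/0"
                for s in samples
            )
            fh.write(
                "\t".join(
                    [
                        locus.chrom,
                        str(locus.position + 1),
                        locus.locus_id,
                        "N",
                        f"<INS:ME:{locus.family.upper()}>",
                        ".",
                        "PASS",
                        info,
                        "GT",
                        gts,
                    ]
                )
                + "\n"
            )


def read_intervals(
    path: str | Path, format: str = "BED"
) -> list[GenomicInterval]:
    """Read BED or GTF features into unified 0-based half-open intervals.

    BED is already 0-based half-open and passes through. GTF is 1-based
    inclusive; start is decremented. For BED the label is the name
    column (4th) when present; for GTF it is the feature type (3rd
    column). Intervals that are empty after conversion are skipped.
    """
    fmt = format.upper()
    if fmt not in {"BED", "GTF", "GTF-FEATURE"}:
        raise ValueError(f"unknown interval format: {format}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if fmt == "BED":
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                label = fields[3] if len(fields) > 3 else ""
                strand = fields[5] if len(fields) > 5 else None
            else:
                chrom = fields[0]
                label = fields[2]
                start = int(fields[3]) - 1
                end = int(fields[4])
                strand = fields[6] if len(fields) > 6 else None
            if start >= end:
                continue
            out.append(
                GenomicInterval(
                    chrom=chrom, start=start, end=end, label=label,
                    strand=strand,
                )
            )
    return out


def read_pedigree(path: str | Path) -> list[PedigreeTrio]:
    """Read a tab-separated family/father/mother/child pedigree file.

    Duplicate family ids and repeated child ids are rejected: the
    de novo analysis assumes each child appears in exactly one trio.
    """
    trios: list[PedigreeTrio] = []
    seen_families: set[str] = set()
    seen_children: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected 4 columns "
                    f"(family, father, mother, child)"
                )
            family, father, mother, child = fields[:4]
            if family in seen_families:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate family id {family!r}"
                )
            if child in seen_children:
                raise FormatError(
                    f"{path}: line {lineno}: child {child!r} appears in "
                    f"more than one trio"
                )
            seen_families.add(family)
            seen_children.add(child)
            trios.append(PedigreeTrio(family, father, mother, child))
    return trios


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read the sample manifest TSV.

    Columns: sample_id, family, blast6, sam, and optionally cell_type
    and individual. A header line is required.
    """
    entries: list[ManifestEntry] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "family", "blast6", "sam"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(
                f"{path}: manifest needs columns {sorted(required)}"
            )
        for row in reader:
            entries.append(
                ManifestEntry(
                    sample_id=row["sample_id"],
                    family=row["family"],
                    blast6_path=row["blast6"],
                    sam_path=row["sam"],
                    cell_type=row.get("cell_type") or None,
                    individual_id=row.get("individual") or None,
                )
            )
    return entries
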