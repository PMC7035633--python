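"""Clustering of filtered Flanking Reads into candidate insertion loci.

Flanking reads whose junction-proximal ends fall within a 500-bp
sliding window on the same chromosome and strand are clustered into a
putative insertion locus (single linkage: a cluster breaks where the
gap between consecutive sorted junction positions exceeds the window).
Within a cluster the most ME-proximal coordinate becomes the insertion
position. Per-sample evidence at each locus is summarized as a raw
read count, TPM (tags per million — count normalized by the sample
library's total mapped reads, controlling inter-library depth
variation) and UR (unique reads — distinct alignment start positions,
collapsing PCR duplicates of the same pre-amplification fragment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .formats_io import SamAlignment
from .read_filtering import MEFamily, ReadPairEvidence

__all__ = [
    "EvidenceCluster",
    "SampleEvidence",
    "CandidateLocus",
    "SampleLibrary",
    "junction_position",
    "cluster_reads",
    "call_locus",
    "call_loci",
    "total_mapped",
]

DEFAULT_WINDOW = 500


@dataclass(frozen=True)
class SampleEvidence:
    """Evidence for one sample at one locus."""

    read_count: int
    tpm: float
    ur: int

    def __post_init__(self) -> None:
        if not (self.read_count >= self.ur >= 0):
            raise ValueError("require read_count >= ur >= 0")
        if self.tpm < 0:
            raise ValueError("tpm must be non-negative")


@dataclass
class EvidenceCluster:
    family: str
    chrom: str
    strand: str
    members: list[ReadPairEvidence]
    junction_positions: list[int]


@dataclass
class CandidateLocus:
    locus_id: str
    family: str
    chrom: str
    position: int
    strand: str
    per_sample: dict[str, SampleEvidence] = field(default_factory=dict)


@dataclass
class SampleLibrary:
    """Per-sample, per-family library totals and selected cutoffs."""

    sample_id: str
    family: str
    total_mapped_reads: int
    tpm_cutoff: float = 1.0
    ur_cutoff: int = 1


def junction_position(aln: SamAlignment, family: MEFamily | None = None) -> int:
    """Junction-proximal coordinate of a flanking alignment.

    The flanking read points toward the mobile element, so its 3'
    alignment boundary abuts the insertion: the alignment end for a
    plus-strand alignment, the alignment start for minus strand.
    """
    return aln.end if aln.strand == "+" else aln.start


def cluster_reads(
    evidence: Iterable[ReadPairEvidence],
    window: int = DEFAULT_WINDOW,
) -> list[EvidenceCluster]:
    """Single-linkage clustering of junction positions per (chrom, strand).

    Evidence is pooled across all samples before clustering so that a
    shared insertion gets one locus id across the cohort. A new cluster
    starts when the gap between consecutive sorted junction positions
    exceeds ``window``. Opposite strands never merge.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    keyed: dict[tuple[str, str, str], list[tuple[int, ReadPairEvidence]]] = {}
    for ev in evidence:
        key = (ev.family, ev.flank.chrom, ev.flank.strand)
        keyed.setdefault(key, []).append((junction_position(ev.flank), ev))

    clusters: list[EvidenceCluster] = []
    for (family, chrom, strand) in sorted(keyed):
        items = sorted(
            keyed[(family, chrom, strand)],
            key=lambda t: (t[0], t[1].sample_id, t[1].read_id),
        )
        current: list[tuple[int, ReadPairEvidence]] = []
        for pos, ev in items:
            if current and pos - current[-1][0] > window:
                clusters.append(
                    _make_cluster(family, chrom, strand, current)
                )
                current = []
            current.append((pos, ev))
        if current:
            clusters.append(_make_cluster(family, chrom, strand, current))
    return clusters


def _make_cluster(
    family: str, chrom: str, strand: str,
    items: list[tuple[int, ReadPairEvidence]],
) -> EvidenceCluster:
    return EvidenceCluster(
        family=family,
        chrom=chrom,
        strand=strand,
        members=[ev for _, ev in items],
        junction_positions=[pos for pos, _ in items],
    )


def call_locus(
    cluster: EvidenceCluster,
    libraries: Mapping[str, SampleLibrary],
    locus_id: str,
) -> CandidateLocus:
    """Summarize a cluster as a candidate locus with per-sample evidence.

    The insertion position is the cluster's most ME-proximal
    coordinate: maximum junction position for plus-strand clusters
    (flanking reads approach the element from the left), minimum for
    minus strand. UR counts distinct alignment start positions per
    sample; TPM is count / total_mapped_reads x 1e6.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    position = (
        max(cluster.junction_positions)
        if cluster.strand == "+"
        else min(cluster.junction_positions)
    )
    by_sample: dict[str, list[ReadPairEvidence]] = {}
    for ev in cluster.members:
        by_sample.setdefault(ev.sample_id, []).append(ev)
    per_sample: dict[str, SampleEvidence] = {}
    for sample_id, members in by_sample.items():
        if sample_id not in libraries:
            raise KeyError(
                f"sample {sample_id!r} has evidence but no library totals"
            )
        lib = libraries[sample_id]
        if lib.total_mapped_reads <= 0:
            raise ValueError(
                f"sample {sample_id!r}: total_mapped_reads must be > 0 "
                "before TPM computation (empty library?)"
            )
        count = len(members)
        ur = len({ev.flank.start for ev in members})
        tpm = count / lib.total_mapped_reads * 1e6
        per_sample[sample_id] = SampleEvidence(count, tpm, ur)
    return CandidateLocus(
        locus_id=locus_id,
        family=cluster.family,
        chrom=cluster.chrom,
        position=position,
        strand=cluster.strand,
        per_sample=per_sample,
    )


def call_loci(
    clusters: Sequence[EvidenceCluster],
    libraries: Mapping[str, SampleLibrary],
    prefix: str = "locus",
) -> list[CandidateLocus]:
    """Call every cluster, assigning stable sequential locus ids."""
    return [
        call_locus(cluster, libraries, f"{prefix}_{i:06d}")
        for i, cluster in enumerate(clusters, start=1)
    ]


def total_mapped(
    evidence: Iterable[ReadPairEvidence] | Iterable[SamAlignment],
    sample_id: str | None = None,
    family: str | None = None,
) -> int:
    """Count a sample's passing reads — the TPM denominator.

    By default counts reads that survived both the ME bit-score and
    flank MQ filters for one sample's family library, so the sum of a
    sample's per-locus read counts equals this total (every passing
    read lands in exactly one cluster).
    """
    n = 0
    for item in evidence:
        sid = getattr(item, "sample_id", None)
        fam = getattr(item, "family", None)
        if sample_id is not None and sid != sample_id:
            continue
        if family is not None and fam is not None and fam != family:
            continue
        n += 1
    return n
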