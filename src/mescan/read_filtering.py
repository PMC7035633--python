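"""ME-Read and Flanking-Read filtering.

A sequenced fragment spanning a mobile-element junction yields a read
pair: the ME Read sequences into the element body and identifies the
family, the Flanking Read lands in unique genomic sequence and
localizes the insertion. This module scores ME Reads against a family
consensus (Karlin-Altschul bit scale), derives family-specific
bit-score cutoffs that separate the young target subfamily from older
repeats, and reduces the Flanking-Read alignments to at most one
high-confidence position per read (best mapping quality, then a strict
MQ >= 30 filter that discards perfect multi-mappers, which carry MQ 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .formats_io import Blast6Record, SamAlignment

__all__ = [
    "MEFamily",
    "ScoringScheme",
    "ReadPairEvidence",
    "DEFAULT_BIT_CUTOFFS",
    "score_me_read",
    "derive_bit_cutoff",
    "filter_me_reads",
    "select_best_mapping",
    "filter_flank_mq",
    "join_pairs",
]

#: Family bit-score cutoffs used for the three targeted human families.
DEFAULT_BIT_CUTOFFS = {"AluYb": 67.0, "L1HS": 56.0, "SVA": 48.0}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MEFamily:
    """A targeted mobile-element family.

    ``junction_end`` records which end of the consensus the
    amplification primers face (5prime for AluYb/SVA, 3prime for L1HS);
    it is carried for provenance and does not change the coordinate
    logic, which is driven by the flanking-read strand.
    """

    name: str
    consensus: str = ""
    bit_cutoff: float = 0.0
    junction_end: str = "5prime"

    def __post_init__(self) -> None:
        if self.junction_end not in {"5prime", "3prime"}:
            raise ValueError("junction_end must be 5prime or 3prime")

    def with_default_cutoff(self) -> "MEFamily":
        if self.bit_cutoff > 0:
            return self
        cutoff = DEFAULT_BIT_CUTOFFS.get(self.name)
        if cutoff is None:
            raise ValueError(
                f"no bit-score cutoff configured for family {self.name!r}"
            )
        return MEFamily(self.name, self.consensus, cutoff, self.junction_end)


@dataclass(frozen=True)
class ScoringScheme:
    """Local-alignment scoring and its Karlin-Altschul parameters.

    Defaults mirror blastn-short: match +1, mismatch -3, gap open 5,
    gap extend 2 (a gap of length k costs open + k*extend). lambda_ and
    k convert a raw Smith-Waterman score S to bits as
    (lambda_*S - ln k) / ln 2.
    """

    match_reward: int = 1
    mismatch_penalty: int = 3
    gap_open: int = 5
    gap_extend: int = 2
    lambda_: float = 1.374
    k: float = 0.711

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.k <= 0:
            raise ValueError("lambda_ and k must be positive")
        if self.mismatch_penalty <= 0 or self.gap_extend <= 0:
            raise ValueError("penalties are given as positive magnitudes")

    def bits(self, raw_score: float) -> float:
        """Karlin-Altschul normalized score in bits; 0 for S <= 0."""
        if raw_score <= 0:
            return 0.0
        return (self.lambda_ * raw_score - math.log(self.k)) / math.log(2)


@dataclass(frozen=True)
class ReadPairEvidence:
    """One fragment surviving both filters: family call + flank position."""

    read_id: str
    sample_id: str
    family: str
    me_bit_score: float
    flank: SamAlignment


def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            if a == b and a != "N":
                matrix[a, b] = float(scheme.match_reward)
            else:
                matrix[a, b] = -float(scheme.mismatch_penalty)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # first gap base costs open+extend, each further base costs extend
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def score_me_read(
    read_seq: str,
    family: MEFamily,
    scheme: ScoringScheme = ScoringScheme(),
) -> float:
    """Bit score of the best local alignment of a read to the consensus.

    Both strands are scored and the maximum taken; library chemistry
    fixes the ME-read orientation, but simulated or contaminating reads
    may arrive flipped. Returns 0.0 when no positive-scoring local
    alignment exists (e.g. a read of Ns).
    """
    read_seq = read_seq.upper()
    if len(read_seq) < 10:
        raise ValueError("read too short to score (< 10 bp)")
    bad = set(read_seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN symbols in read: {sorted(bad)}")
    if not family.consensus:
        raise ValueError(f"family {family.name} has no consensus sequence")
    aligner = _aligner(scheme)
    consensus = family.consensus.upper()
    raw = max(
        aligner.score(consensus, read_seq),
        aligner.score(consensus, reverse_complement(read_seq)),
    )
    return scheme.bits(raw)


def derive_bit_cutoff(
    reference_scores: Sequence[float],
    target_subfamily_scores: Sequence[float],
    retain_frac: float = 0.95,
    contaminate_frac: float = 0.05,
) -> float:
    """Choose a bit-score threshold separating the target subfamily from
    older repeats.

    Scans candidate thresholds (every observed score and the value just
    above it) for the smallest t such that at least ``retain_frac`` of
    target-subfamily scores are >= t while at most ``contaminate_frac``
    of the older-family (reference background) scores are >= t. When the
    two distributions overlap too much for both constraints, returns
    the threshold minimizing contamination subject to the retention
    constraint, with a warning.
    """
    ref = np.asarray(reference_scores, dtype=float)
    tgt = np.asarray(target_subfamily_scores, dtype=float)
    if ref.size == 0 or tgt.size == 0:
        raise ValueError("both score sets must be non-empty")

    candidates = np.unique(np.concatenate([ref, tgt]))
    candidates = np.union1d(candidates, np.nextafter(candidates, np.inf))
    retain = (tgt[None, :] >= candidates[:, None]).mean(axis=1)
    contam = (ref[None, :] >= candidates[:, None]).mean(axis=1)

    feasible = (retain >= retain_frac) & (contam <= contaminate_frac)
    if feasible.any():
        return float(candidates[np.argmax(feasible)])

    warnings.warn(
        "target and background bit-score distributions overlap; no "
        "threshold satisfies both retention and contamination limits — "
        "returning the least-contaminating threshold that keeps "
        f"{retain_frac:.0%} of target scores",
        stacklevel=2,
    )
    ok = retain >= retain_frac
    idx = np.flatnonzero(ok)
    best = idx[np.argmin(contam[idx])]
    return float(candidates[best])


def filter_me_reads(
    records: Iterable[Blast6Record] | Mapping[str, float],
    family: MEFamily,
) -> set[str]:
    """Read ids whose best bit score against the family consensus passes
    the family cutoff (inclusive: score >= cutoff).

    A read with multiple HSPs contributes its maximum bit score. Input
    is either BLAST-6 records or a pre-scored {read_id: bits} mapping.
    """
    family = family.with_default_cutoff()
    best: dict[str, float] = {}
    if isinstance(records, Mapping):
        best = dict(records)
    else:
        for rec in records:
            prev = best.get(rec.query_id)
            if prev is None or rec.bit_score > prev:
                best[rec.query_id] = rec.bit_score
    return {rid for rid, score in best.items() if score >= family.bit_cutoff}


def select_best_mapping(
    alignments: Sequence[SamAlignment],
) -> SamAlignment:
    """Pick the single best position among a read's reported alignments.

    Highest MQ wins; ties break deterministically by (chrom, start) so
    the choice is invariant to input order. Secondary and supplementary
    records are candidate positions like any other.
    """
    if not alignments:
        raise ValueError("no alignments given")
    mapped = [a for a in alignments if not a.is_unmapped]
    if not mapped:
        return alignments[0]
    return min(mapped, key=lambda a: (-a.mapq, a.chrom, a.start))


def filter_flank_mq(
    alignments: Iterable[SamAlignment], min_mq: int = 30
) -> list[SamAlignment]:
    """Keep alignments with MQ >= min_mq (inclusive boundary).

    Perfect multi-mappers carry MQ 0 and are guaranteed to be removed.
    """
    return [
        a for a in alignments if not a.is_unmapped and a.mapq >= min_mq
    ]


def best_flank_alignments(
    alignments: Iterable[SamAlignment],
) -> list[SamAlignment]:
    """Group alignments by read id and keep one best position per read."""
    by_read: dict[str, list[SamAlignment]] = {}
    for aln in alignments:
        by_read.setdefault(aln.read_id, []).append(aln)
    return [select_best_mapping(alns) for alns in by_read.values()]


def join_pairs(
    me_read_ids: set[str],
    flank_alignments: Iterable[SamAlignment],
    family: MEFamily,
    me_scores: Mapping[str, float] | None = None,
    stage_counts: dict[str, int] | None = None,
) -> list[ReadPairEvidence]:
    """Pair up reads that pass both the ME-score and flank-MQ filters.

    Read ids are shared between the two mates of a pair; evidence is
    emitted only for ids present in both filtered sets, so every read
    id occurs at most once in the output.
    """
    flanks = {a.read_id: a for a in flank_alignments}
    kept = sorted(me_read_ids & set(flanks))
    if stage_counts is not None:
        stage_counts["me_pass"] = len(me_read_ids)
        stage_counts["flank_pass"] = len(flanks)
        stage_counts["joined"] = len(kept)
    return [
        ReadPairEvidence(
            read_id=rid,
            sample_id=flanks[rid].sample_id,
            family=family.name,
            me_bit_score=(me_scores or {}).get(rid, 0.0),
            flank=flanks[rid],
        )
        for rid in kept
    ]
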