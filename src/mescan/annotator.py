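"""Annotation of candidate loci against known insertions and functional context.

A called locus is classified as *reference* (matches a mobile element
already present in the reference genome), *known_polymorphic* (matches
a previously reported polymorphic insertion from a dbRIP/1000G/HuRef
style database) or *novel*. Gene context is assigned from GTF-derived
features with a fixed precedence ladder, and chromatin-state
enrichment is profiled against a ChromHMM-style segmentation.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .formats_io import GenomicInterval
from .locus_caller import CandidateLocus

__all__ = [
    "KnownLociDB",
    "AnnotatedLocus",
    "classify_status",
    "gene_context",
    "chromatin_profile",
    "annotate",
]

MATCH_TOL = 100

GENE_PRECEDENCE = ("CDS", "UTR", "exon_noncoding", "intron", "intergenic")


class _IntervalIndex:
    """Per-chromosome interval trees over labelled intervals."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            tree = self._trees.setdefault(iv.chrom, IntervalTree())
            tree.addi(iv.start, iv.end, iv)

    def within(
        self, chrom: str, position: int, tol: int
    ) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        # expanding the query by tol finds intervals within tol bases
        return [hit.data for hit in tree.overlap(position - tol, position + tol + 1)]

    def stab(self, chrom: str, position: int) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.at(position)]


class KnownLociDB:
    """Reference-genome MEIs plus known polymorphic insertion databases.

    Reference matching is family-aware (an AluYb locus should not match
    an L1 reference record; the interval label carries the family).
    Polymorphic databases use heterogeneous family labels, so matching
    there is family-agnostic by default.
    """

    def __init__(
        self,
        reference_meis: Iterable[GenomicInterval],
        polymorphic_meis: Iterable[GenomicInterval] = (),
        family_aware_reference: bool = True,
        family_aware_polymorphic: bool = False,
    ):
        self.reference_meis = list(reference_meis)
        self.polymorphic_meis = list(polymorphic_meis)
        self.family_aware_reference = family_aware_reference
        self.family_aware_polymorphic = family_aware_polymorphic
        self._ref_index = _IntervalIndex(self.reference_meis)
        self._poly_index = _IntervalIndex(self.polymorphic_meis)


@dataclass
class AnnotatedLocus:
    locus: CandidateLocus
    status: str
    gene_context: str
    chromatin_state: str | None = None


def classify_status(
    locus: CandidateLocus, db: KnownLociDB, tol: int = MATCH_TOL
) -> str:
    """reference > known_polymorphic > novel, matched within ``tol`` bases."""
    ref_hits = db._ref_index.within(locus.chrom, locus.position, tol)
    if db.family_aware_reference:
        ref_hits = [h for h in ref_hits if h.label == locus.family]
    if ref_hits:
        return "reference"
    poly_hits = db._poly_index.within(locus.chrom, locus.position, tol)
    if db.family_aware_polymorphic:
        poly_hits = [h for h in poly_hits if h.label == locus.family]
    if poly_hits:
        return "known_polymorphic"
    return "novel"


def gene_context(
    locus: CandidateLocus,
    gene_models: Sequence[GenomicInterval] | _IntervalIndex,
) -> str:
    """Gene-feature category of the insertion point.

    The single-base insertion position is tested for containment in
    GTF-derived features. Precedence: CDS > UTR > exon_noncoding >
    intron > intergenic. A position inside a gene/transcript span but
    outside any exon is intronic; feature labels 'gene' and
    'transcript' delimit that span.
    """
    index = (
        gene_models
        if isinstance(gene_models, _IntervalIndex)
        else _IntervalIndex(gene_models)
    )
    labels = {iv.label for iv in index.stab(locus.chrom, locus.position)}
    if "CDS" in labels:
        return "CDS"
    if labels & {"UTR", "five_prime_utr", "three_prime_utr"}:
        return "UTR"
    if "exon" in labels:
        return "exon_noncoding"
    if labels & {"gene", "transcript"}:
        return "intron"
    return "intergenic"


def chromatin_profile(
    loci: Sequence[CandidateLocus],
    segmentation: Sequence[GenomicInterval],
) -> dict[str, float]:
    """Insertion density per chromatin state.

    For each state label, the number of loci falling in segments of
    that state divided by the number of segments of that state. Loci on
    chromosomes absent from the segmentation are counted as unassigned
    with a warning. States with zero segments cannot occur in the
    output by construction.
    """
    index = _IntervalIndex(segmentation)
    segment_counts = Counter(iv.label for iv in segmentation)
    hits: Counter[str] = Counter()
    unassigned = 0
    covered_chroms = {iv.chrom for iv in segmentation}
    for locus in loci:
        if locus.chrom not in covered_chroms:
            unassigned += 1
            continue
        stabbed = index.stab(locus.chrom, locus.position)
        if not stabbed:
            unassigned += 1
            continue
        for iv in stabbed:
            hits[iv.label] += 1
    if unassigned:
        warnings.warn(
            f"{unassigned} loci fell outside the chromatin segmentation "
            "and were left unassigned",
            stacklevel=2,
        )
    return {
        state: hits[state] / segment_counts[state]
        for state in sorted(segment_counts)
        if state in hits or segment_counts[state] > 0
    }


def annotate(
    loci: Sequence[CandidateLocus],
    db: KnownLociDB,
    gene_models: Sequence[GenomicInterval] = (),
    segmentation: Sequence[GenomicInterval] = (),
    tol: int = MATCH_TOL,
) -> list[AnnotatedLocus]:
    """Full annotation pass: status, gene context, chromatin state."""
    gene_index = _IntervalIndex(gene_models)
    seg_index = _IntervalIndex(segmentation)
    out: list[AnnotatedLocus] = []
    for locus in loci:
        states = [
            iv.label for iv in seg_index.stab(locus.chrom, locus.position)
        ]
        out.append(
            AnnotatedLocus(
                locus=locus,
                status=classify_status(locus, db, tol),
                gene_context=gene_context(locus, gene_index),
                chromatin_state=states[0] if states else None,
            )
        )
    return out
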