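"""Trio-based validation and somatic candidate detection.

The trio analyses exploit Mendelian expectations to quantify call
quality without PCR validation: an insertion seen in a child but in
neither parent is either a genuine de novo event (rare: < 1 in 10
live births for Alu, < 1 in 100 for L1/SVA), a false positive in the
child, or false negatives in the parents. The observed inheritance
rate of parentally carried insertions has a closed-form expectation
(50% for a single heterozygous parent carrier, 100% for a homozygous
one; 75% when both parents are heterozygous), so shortfalls from the
best-performing trio estimate the false-negative rate.

The somatic screen looks for cell-type-specific insertions within an
individual: a candidate must be absent from known polymorphic
databases, private to one individual, and supported by reads in
exactly one cell type with zero reads in all others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotator import KnownLociDB, classify_status
from .cutoff_selector import PresenceMatrix
from .formats_io import PedigreeTrio
from .locus_caller import CandidateLocus

__all__ = [
    "TrioReport",
    "CellSampleSet",
    "denovo_candidates",
    "inheritance_error_rate",
    "observed_inheritance_rate",
    "false_negative_estimate",
    "somatic_candidates",
    "germline_shared_loci",
    "trio_report",
]


@dataclass
class TrioReport:
    family_id: str
    me_family: str
    child_locus_count: int
    mendelian_violations: int
    inheritance_error_rate: float
    single_parent_rate: float | None
    both_parent_rate: float | None
    fn_estimate_diff: float | None = None
    fn_estimate_ratio: float | None = None


@dataclass
class CellSampleSet:
    """Per-cell-type presence and read support for one individual.

    ``presence`` maps cell type -> PresenceMatrix sample id is not
    needed here; instead both frames are indexed by locus id with one
    column per cell type.
    """

    individual_id: str
    present: pd.DataFrame
    support_reads: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.present.columns) < 2:
            raise ValueError("need at least two cell types per individual")

    @property
    def cell_types(self) -> list[str]:
        return list(self.present.columns)


def denovo_candidates(
    matrix: PresenceMatrix,
    trios: Sequence[PedigreeTrio],
    strict_zero: bool = True,
) -> list[str]:
    """Loci present in exactly one child and absent in everyone else.

    With ``strict_zero`` (default) "absent" means zero supporting reads
    in every other cohort member — stricter than falling below the
    presence cutoffs, reflecting that sub-threshold reads in a parent
    already argue against a genuine de novo event.
    """
    children = {trio.child_id for trio in trios}
    candidates: list[str] = []
    present = matrix.present
    support = matrix.support_reads
    for locus_id in matrix.loci:
        carriers = set(present.columns[present.loc[locus_id]])
        if len(carriers) != 1:
            continue
        (carrier,) = carriers
        if carrier not in children:
            continue
        others = [s for s in matrix.samples if s != carrier]
        if strict_zero:
            if (support.loc[locus_id, others] > 0).any():
                continue
        candidates.append(locus_id)
    return candidates


def inheritance_error_rate(
    matrix: PresenceMatrix, trio: PedigreeTrio
) -> float:
    """Fraction of a child's loci absent from both parents.

    Zero when the child carries no loci at all.
    """
    child_loci = matrix.loci_present_in(trio.child_id)
    if not child_loci:
        return 0.0
    parental = matrix.loci_present_in(trio.father_id) | matrix.loci_present_in(
        trio.mother_id
    )
    violations = child_loci - parental
    return len(violations) / len(child_loci)


def observed_inheritance_rate(
    matrix: PresenceMatrix,
    trios: Sequence[PedigreeTrio],
    mode: str = "single_parent",
    min_parent_carriers: int = 2,
) -> tuple[dict[str, float], float]:
    """Per-trio and average child inheritance rate of parental loci.

    ``mode='single_parent'`` restricts to loci carried by exactly one
    parent of the trio, ``mode='both_parents'`` to loci carried by both.
    To damp parental false positives, loci are further restricted to
    those present in at least ``min_parent_carriers`` individuals among
    all cohort parents. Trios with no qualifying loci are excluded from
    the average with a warning.

    Returns ({family_id: rate}, cohort average over defined trios).
    """
    if mode not in {"single_parent", "both_parents"}:
        raise ValueError("mode must be single_parent or both_parents")
    all_parents = [
        s for trio in trios for s in (trio.father_id, trio.mother_id)
    ]
    parent_presence = matrix.present[all_parents]
    carrier_counts = parent_presence.sum(axis=1)
    widespread = set(
        carrier_counts.index[carrier_counts >= min_parent_carriers]
    )

    per_trio: dict[str, float] = {}
    for trio in trios:
        father = matrix.loci_present_in(trio.father_id)
        mother = matrix.loci_present_in(trio.mother_id)
        if mode == "single_parent":
            qualifying = (father ^ mother) & widespread
        else:
            qualifying = (father & mother) & widespread
        if not qualifying:
            warnings.warn(
                f"trio {trio.family_id}: no qualifying loci for "
                f"{mode} inheritance-rate analysis; excluded from average",
                stacklevel=2,
            )
            continue
        child = matrix.loci_present_in(trio.child_id)
        per_trio[trio.family_id] = len(qualifying & child) / len(qualifying)
    average = float(np.mean(list(per_trio.values()))) if per_trio else float("nan")
    return per_trio, average


def false_negative_estimate(
    per_trio_rates: Mapping[str, float],
) -> dict[str, dict[str, float]]:
    """Per-trio false-negative estimates against the best trio.

    Taking the highest observed inheritance rate r_max as the true
    rate, each trio's shortfall is reported under two conventions:
    ``diff`` = r_max - r_trio (percentage-point difference) and
    ``ratio`` = 1 - r_trio / r_max (fraction of calls missed). The two
    coincide only at r_max = 1.
    """
    if len(per_trio_rates) < 2:
        raise ValueError("need rates from at least two trios")
    r_max = max(per_trio_rates.values())
    out: dict[str, dict[str, float]] = {}
    for family_id, rate in per_trio_rates.items():
        out[family_id] = {
            "diff": r_max - rate,
            "ratio": 1.0 - rate / r_max if r_max > 0 else 0.0,
        }
    return out


def germline_shared_loci(cellsets: Iterable[CellSampleSet]) -> dict[str, list[str]]:
    """Loci present (by cutoffs) in every cell type of an individual.

    These behave as germline insertions: whatever tissue is assayed,
    the insertion is there.
    """
    out: dict[str, list[str]] = {}
    for cs in cellsets:
        all_present = cs.present.all(axis=1)
        out[cs.individual_id] = list(cs.present.index[all_present])
    return out


def somatic_candidates(
    cellsets: Sequence[CellSampleSet],
    known_db: KnownLociDB | None,
    loci: Mapping[str, CandidateLocus] | None = None,
    tol: int = 100,
) -> list[tuple[str, str, str]]:
    """Cell-type-specific insertion candidates.

    A locus qualifies when it (1) is not a known polymorphic insertion,
    (2) has reads in exactly one individual, and (3) within that
    individual is present in exactly one cell type with zero reads in
    every other cell type. Returns (individual, cell_type, locus_id)
    triples.
    """
    # individuals with any read support per locus
    individuals_with_reads: dict[str, set[str]] = {}
    for cs in cellsets:
        read_any = cs.support_reads.sum(axis=1) > 0
        for locus_id in cs.support_reads.index[read_any]:
            individuals_with_reads.setdefault(locus_id, set()).add(
                cs.individual_id
            )

    candidates: list[tuple[str, str, str]] = []
    for cs in cellsets:
        for locus_id in cs.present.index:
            if individuals_with_reads.get(locus_id, set()) != {
                cs.individual_id
            }:
                continue
            if known_db is not None and loci is not None and locus_id in loci:
                status = classify_status(loci[locus_id], known_db, tol)
                if status != "novel":
                    continue
            present_types = [
                ct for ct in cs.cell_types if cs.present.at[locus_id, ct]
            ]
            if len(present_types) != 1:
                continue
            (cell_type,) = present_types
            others = [ct for ct in cs.cell_types if ct != cell_type]
            if (cs.support_reads.loc[locus_id, others] > 0).any():
                continue
            candidates.append((cs.individual_id, cell_type, locus_id))
    return candidates


def trio_report(
    matrix: PresenceMatrix,
    trios: Sequence[PedigreeTrio],
    me_family: str,
    min_parent_carriers: int = 2,
) -> list[TrioReport]:
    """Assemble the full per-trio quality report for one ME family."""
    single_rates, _ = observed_inheritance_rate(
        matrix, trios, "single_parent", min_parent_carriers
    )
    both_rates, _ = observed_inheritance_rate(
        matrix, trios, "both_parents", min_parent_carriers
    )
    fn = (
        false_negative_estimate(single_rates)
        if len(single_rates) >= 2
        else {}
    )
    reports: list[TrioReport] = []
    for trio in trios:
        child_loci = matrix.loci_present_in(trio.child_id)
        err = inheritance_error_rate(matrix, trio)
        reports.append(
            TrioReport(
                family_id=trio.family_id,
                me_family=me_family,
                child_locus_count=len(child_loci),
                mendelian_violations=round(err * len(child_loci)),
                inheritance_error_rate=err,
                single_parent_rate=single_rates.get(trio.family_id),
                both_parent_rate=both_rates.get(trio.family_id),
                fn_estimate_diff=fn.get(trio.family_id, {}).get("diff"),
                fn_estimate_ratio=fn.get(trio.family_id, {}).get("ratio"),
            )
        )
    return reports
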