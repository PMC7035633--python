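"""Sensitivity-driven TPM/UR cutoff selection and presence calling.

Rather than calibrating against a false-discovery target (no ground
truth for novel insertions exists), each sample's evidence cutoffs are
tuned on presumably fixed reference insertions — elements present in
the reference genome and never reported polymorphic, which every
individual must carry. For each (TPM, UR) cutoff pair on a 1..10 grid
the fraction of fixed loci recovered is computed; the selected cutoffs
are the most stringent combination that still recovers more than 90%
of the fixed set. Presence/absence of each locus in each sample then
follows by thresholding at the selected cutoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import GenomicInterval
from .locus_caller import CandidateLocus, SampleLibrary

__all__ = [
    "SensitivityGrid",
    "PresenceMatrix",
    "sensitivity",
    "sensitivity_grid",
    "select_cutoffs",
    "overall_sensitivity",
    "call_presence",
]

GRID_MAX = 10
SENSITIVITY_TARGET = 0.90
MATCH_TOL = 100


@dataclass
class SensitivityGrid:
    """Per-sample sensitivity over the (TPM cutoff, UR cutoff) grid."""

    sample_id: str
    family: str
    grid: dict[tuple[int, int], float]

    def at(self, tpm_cut: int, ur_cut: int) -> float:
        return self.grid[(tpm_cut, ur_cut)]


@dataclass
class PresenceMatrix:
    """Presence calls and read support for loci x samples.

    ``present`` and ``support_reads`` are DataFrames indexed by locus id
    with one column per sample.
    """

    present: pd.DataFrame
    support_reads: pd.DataFrame

    @property
    def loci(self) -> list[str]:
        return list(self.present.index)

    @property
    def samples(self) -> list[str]:
        return list(self.present.columns)

    def is_present(self, locus_id: str, sample_id: str) -> bool:
        return bool(self.present.at[locus_id, sample_id])

    def loci_present_in(self, sample_id: str) -> set[str]:
        col = self.present[sample_id]
        return set(col.index[col])

    def __post_init__(self) -> None:
        if not self.present.index.equals(self.support_reads.index):
            raise ValueError("present/support_reads locus index mismatch")
        bad = self.present.to_numpy() & (self.support_reads.to_numpy() <= 0)
        if bad.any():
            raise ValueError("present calls require support_reads > 0")


def _matched_loci(
    loci: Sequence[CandidateLocus],
    fixed_truth: Sequence[GenomicInterval],
    match_tol: int,
) -> list[list[CandidateLocus]]:
    """For each truth interval, the loci within match_tol of it."""
    by_chrom: dict[str, list[CandidateLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    out: list[list[CandidateLocus]] = []
    for truth in fixed_truth:
        hits = [
            locus
            for locus in by_chrom.get(truth.chrom, [])
            # distance 0 when the position lies inside the interval
            if max(truth.start - locus.position,
                   locus.position - (truth.end - 1), 0) <= match_tol
        ]
        out.append(hits)
    return out


def sensitivity(
    loci: Sequence[CandidateLocus],
    fixed_truth: Sequence[GenomicInterval],
    sample_id: str,
    tpm_cut: float,
    ur_cut: int,
    match_tol: int = MATCH_TOL,
) -> float:
    """Fraction of fixed truth loci recovered in one sample at given cutoffs.

    A truth interval counts as recovered when at least one called locus
    lies within ``match_tol`` bases of it and that sample's evidence
    there meets tpm >= tpm_cut and ur >= ur_cut.
    """
    if not fixed_truth:
        raise ValueError("fixed-truth set is empty")
    hit = 0
    for matches in _matched_loci(loci, fixed_truth, match_tol):
        for locus in matches:
            ev = locus.per_sample.get(sample_id)
            if ev is not None and ev.tpm >= tpm_cut and ev.ur >= ur_cut:
                hit += 1
                break
    return hit / len(fixed_truth)


def sensitivity_grid(
    loci: Sequence[CandidateLocus],
    fixed_truth: Sequence[GenomicInterval],
    sample_id: str,
    family: str,
    grid_max: int = GRID_MAX,
    match_tol: int = MATCH_TOL,
) -> SensitivityGrid:
    """Sensitivity at every (tpm_cut, ur_cut) in 1..grid_max squared.

    Computed in one pass: for each truth interval the best matched
    evidence dominates the whole grid, so per-cell sensitivity is the
    fraction of truth loci whose best (tpm, ur) jointly clears the cell.
    """
    if not fixed_truth:
        raise ValueError("fixed-truth set is empty")
    matched = _matched_loci(loci, fixed_truth, match_tol)
    grid: dict[tuple[int, int], float] = {}
    n = len(fixed_truth)
    for t in range(1, grid_max + 1):
        for u in range(1, grid_max + 1):
            hit = 0
            for matches in matched:
                for locus in matches:
                    ev = locus.per_sample.get(sample_id)
                    if ev is not None and ev.tpm >= t and ev.ur >= u:
                        hit += 1
                        break
            grid[(t, u)] = hit / n
    return SensitivityGrid(sample_id=sample_id, family=family, grid=grid)


def select_cutoffs(
    grid: SensitivityGrid,
    target: float = SENSITIVITY_TARGET,
    max_cut: int = GRID_MAX,
) -> tuple[int, int]:
    """Most stringent (TPM, UR) cutoffs keeping sensitivity above target.

    Among grid points with sensitivity strictly greater than ``target``,
    the combination maximizing tpm_cut + ur_cut wins; ties break toward
    larger UR cutoff, then larger TPM cutoff. When no point exceeds the
    target the most permissive cutoffs (1, 1) are returned with a
    warning — the library is too shallow to tune.
    """
    qualifying = [
        (t, u)
        for (t, u), sens in grid.grid.items()
        if t <= max_cut and u <= max_cut and sens > target
    ]
    if not qualifying:
        warnings.warn(
            f"sample {grid.sample_id} ({grid.family}): no cutoff "
            f"combination reaches sensitivity > {target:.0%}; "
            "falling back to (1, 1)",
            stacklevel=2,
        )
        return (1, 1)
    return max(qualifying, key=lambda tu: (tu[0] + tu[1], tu[1], tu[0]))


def overall_sensitivity(
    per_sample_presence: Mapping[str, set[str]] | PresenceMatrix,
    fixed_truth_locus_ids: Iterable[str],
) -> float:
    """Fraction of fixed truth loci detected in at least one sample."""
    truth_ids = set(fixed_truth_locus_ids)
    if not truth_ids:
        raise ValueError("fixed-truth set is empty")
    if isinstance(per_sample_presence, PresenceMatrix):
        samples = per_sample_presence.samples
        if not samples:
            raise ValueError("no samples in presence matrix")
        detected: set[str] = set()
        for s in samples:
            detected |= per_sample_presence.loci_present_in(s)
    else:
        if not per_sample_presence:
            raise ValueError("no samples given")
        detected = set().union(*per_sample_presence.values())
    return len(truth_ids & detected) / len(truth_ids)


def call_presence(
    loci: Sequence[CandidateLocus],
    libraries: Mapping[str, SampleLibrary],
) -> PresenceMatrix:
    """Threshold per-sample evidence at each sample's selected cutoffs.

    present(locus, sample) iff tpm >= tpm_cutoff and ur >= ur_cutoff
    (inclusive boundaries).
    """
    samples = sorted(libraries)
    locus_ids = [locus.locus_id for locus in loci]
    present = pd.DataFrame(False, index=locus_ids, columns=samples)
    support = pd.DataFrame(0, index=locus_ids, columns=samples, dtype=int)
    for locus in loci:
        for sample_id, ev in locus.per_sample.items():
            lib = libraries[sample_id]
            support.at[locus.locus_id, sample_id] = ev.read_count
            if ev.tpm >= lib.tpm_cutoff and ev.ur >= lib.ur_cutoff:
                present.at[locus.locus_id, sample_id] = True
    return PresenceMatrix(present=present, support_reads=support)
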