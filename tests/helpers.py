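"""Independent oracles and small builders shared across the test suite.

The oracles here are deliberately naive (quadratic DP, exhaustive
graph clustering, linear scans) and independent of the library code
paths they check.
"""

from __future__ import annotations

import math

import numpy as np

from mescan.formats_io import SamAlignment
from mescan.read_filtering import ReadPairEvidence


def gotoh_local(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -3.0,
    gap_open: float = -7.0,
    gap_ext: float = -2.0,
) -> float:
    """Exhaustive Smith-Waterman/Gotoh local alignment score.

    Affine gaps: the first base of a gap costs ``gap_open`` (open +
    extend in BLAST terms), each further base ``gap_ext``. N matches
    nothing.
    """
    n, m = len(a), len(b)
    NEG = -1e18
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_ext, H[i][j - 1] + gap_open)
            F[i][j] = max(F[i - 1][j] + gap_ext, H[i - 1][j] + gap_open)
            s = (
                match
                if a[i - 1] == b[j - 1] and a[i - 1] != "N"
                else mismatch
            )
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def bits_oracle(raw: float, lam: float = 1.374, k: float = 0.711) -> float:
    if raw <= 0:
        return 0.0
    return (lam * raw - math.log(k)) / math.log(2)


def brute_force_clusters(
    positions_by_key: dict[tuple, list[int]], window: int
) -> list[list[int]]:
    """O(n^2) single-linkage clustering of junction positions.

    Two positions on the same (family, chrom, strand) key connect when
    their distance is <= window; clusters are the connected components.
    Returns sorted position lists, sorted for comparison.
    """
    clusters: list[list[int]] = []
    for key in sorted(positions_by_key):
        positions = positions_by_key[key]
        n = len(positions)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if abs(positions[i] - positions[j]) <= window:
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(positions[i])
        clusters.extend(sorted(group) for group in groups.values())
    return sorted(clusters)


def make_aln(
    read_id: str,
    chrom: str = "chr1",
    start: int = 100,
    end: int = 200,
    strand: str = "+",
    mapq: int = 60,
    sample_id: str = "S1",
    **kw,
) -> SamAlignment:
    return SamAlignment(
        read_id=read_id,
        sample_id=sample_id,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        mapq=mapq,
        flags=0 if strand == "+" else 16,
        **kw,
    )


def make_evidence(
    read_id: str,
    junction: int,
    strand: str = "+",
    chrom: str = "chr1",
    sample_id: str = "S1",
    family: str = "L1HS",
    read_length: int = 100,
    bit_score: float = 70.0,
) -> ReadPairEvidence:
    """Evidence whose flanking alignment has the given junction position."""
    if strand == "+":
        start, end = junction - read_length, junction
    else:
        start, end = junction, junction + read_length
    return ReadPairEvidence(
        read_id=read_id,
        sample_id=sample_id,
        family=family,
        me_bit_score=bit_score,
        flank=make_aln(
            read_id, chrom=chrom, start=start, end=end, strand=strand,
            sample_id=sample_id,
        ),
    )


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
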