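"""Mismatch-stratum profiling and per-position coverage tracks.

piRNAs identical (or nearly identical) to a TE consensus are read as
products of modern, potentially active copies; highly diverged reads
point to degraded ancestral insertions. For one feature the module
assigns each read its minimal achievable Hamming distance against the
consensus over all windows and both strands - stratum 0, 1, 2, 3 or
"unmapped_at_3" - splits the mass by orientation, and reports stratum
fractions. Coverage tracks accumulate alignment weights over every
aligned base, sense and antisense separately, scaled to per-million
retained mapped reads.

Stratum search is a direct sliding-window scan (vectorized), so it *is*
the brute-force definition; indels are not considered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ParameterError
from .io import ConsensusLibrary, SmallRNARead, reverse_complement
from .mapper import Alignment

__all__ = ["DivergenceProfile", "CoverageTrack", "mismatch_profile", "coverage_track",
           "STRATA", "min_mismatches"]

STRATA = (0, 1, 2, 3, "unmapped_at_3")
_ORD_N = ord("N")


@dataclass
class DivergenceProfile:
    """Mass per mismatch stratum for one feature and orientation."""

    feature: str
    orientation: str  # 'sense' or 'antisense'
    masses: dict  # stratum -> weighted mass

    @property
    def total(self) -> float:
        return float(sum(self.masses.values()))

    def fraction(self, stratum) -> float:
        t = self.total
        return self.masses[stratum] / t if t > 0 else float("nan")

    @property
    def fraction_perfect(self) -> float:
        """Mass fraction at stratum 0 (perfect match to the consensus)."""
        return self.fraction(0)

    def fraction_modern(self, max_stratum: int = 3) -> float:
        """Fraction mapped within ``max_stratum`` mismatches ("modern" copies)."""
        t = self.total
        if t == 0:
            return float("nan")
        return sum(self.masses[s] for s in range(max_stratum + 1)) / t


@dataclass
class CoverageTrack:
    """Per-position read-weighted depth on one consensus, per strand.

    Depths are scaled by 1e6 / denominator (reads per million).
    """

    feature: str
    sense: np.ndarray
    antisense: np.ndarray
    denominator: float

    def __post_init__(self) -> None:
        if len(self.sense) != len(self.antisense):
            raise ParameterError("sense/antisense tracks differ in length")


def _window_mins(query: str, ref_arr: np.ndarray) -> int:
    """Minimum Hamming distance of ``query`` over all windows of the reference.

    N anywhere counts as a mismatch. Returns a large sentinel when the
    query is longer than the reference.
    """
    L = len(query)
    if L > len(ref_arr):
        return L + 1
    qa = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
    mism = ((windows != qa) | (qa == _ORD_N)).sum(axis=1)
    return int(mism.min())


def min_mismatches(sequence: str, consensus: str) -> tuple[int, str]:
    """(minimal Hamming distance over both strands, achieving orientation).

    Orientation is 'sense' when the plus strand achieves the minimum
    (ties resolve to sense).
    """
    ref_arr = np.frombuffer(consensus.encode("ascii"), dtype=np.uint8)
    plus = _window_mins(sequence, ref_arr)
    minus = _window_mins(reverse_complement(sequence), ref_arr)
    if plus <= minus:
        return plus, "sense"
    return minus, "antisense"


def mismatch_profile(
    reads: Iterable,
    feature: str,
    library: ConsensusLibrary,
    weights: Optional[Mapping[str, float]] = None,
    max_stratum: int = 3,
) -> dict[str, DivergenceProfile]:
    """Stratum profile of a read set against one consensus, per orientation.

    ``reads`` are :class:`SmallRNARead` or ``(id, sequence)`` pairs,
    typically the piRNA-class reads attributed to the feature.
    ``weights`` (default 1 per read) lets multi-mapper fractions carry
    through. Returns ``{'sense': ..., 'antisense': ...}``.
    """
    if feature not in library:
        raise KeyError(f"feature '{feature}' not in library")
    consensus = library[feature]
    ref_arr = np.frombuffer(consensus.encode("ascii"), dtype=np.uint8)
    masses = {
        "sense": {s: 0.0 for s in STRATA},
        "antisense": {s: 0.0 for s in STRATA},
    }
    for read in reads:
        rid, seq = (read.id, read.sequence) if isinstance(read, SmallRNARead) else read
        w = 1.0 if weights is None else float(weights.get(rid, 1.0))
        plus = _window_mins(seq, ref_arr)
        minus = _window_mins(reverse_complement(seq), ref_arr)
        best, orient = (plus, "sense") if plus <= minus else (minus, "antisense")
        stratum = best if best <= max_stratum else "unmapped_at_3"
        masses[orient][stratum] += w
    return {
        orient: DivergenceProfile(feature, orient, m) for orient, m in masses.items()
    }


def coverage_track(
    alignments: Sequence[Alignment],
    feature: str,
    consensus_length: int,
    denominator: float,
) -> CoverageTrack:
    """Weighted per-base depth of one feature's alignments, per strand."""
    sense = np.zeros(consensus_length)
    antisense = np.zeros(consensus_length)
    for a in alignments:
        if a.feature != feature:
            continue
        if a.strand == "+":
            start, stop = a.five_prime_pos, a.five_prime_pos + a.length
            sense[start:stop] += a.weight
        else:
            start, stop = a.five_prime_pos - a.length + 1, a.five_prime_pos + 1
            antisense[start:stop] += a.weight
    scale = 1e6 / denominator
    return CoverageTrack(feature, sense * scale, antisense * scale, denominator)
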