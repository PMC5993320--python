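"""Ping-pong (secondary piRNA processing) signature.

Secondary piRNA biogenesis produces sense/antisense read pairs whose 5'
ends overlap by exactly 10 nt. For one feature's piRNA-class alignments
the module builds the 5'-5' overlap histogram over distances 1-20 nt
(pair mass = product of the two fractional alignment weights, so
multi-mappers contribute proportionally), counts distinct position
pairs at overlap 10, standardizes the 10-nt bin against the other 19
bins (the z-score used to call a ping-pong signal), and measures the
positional nucleotide biases of the amplification loop: 5'-U on
antisense piRNAs and A at position 10 of their sense partners.

Overlap convention: with both 5' ends in plus-strand coordinates,
``d = antisense_5p - sense_5p + 1``; d = 10 is the signal bin.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .mapper import Alignment

__all__ = ["PingPongStats", "overlap_histogram", "pingpong_stats", "OVERLAP_RANGE"]

OVERLAP_RANGE = range(1, 21)
SIGNAL_OVERLAP = 10


@dataclass
class PingPongStats:
    feature: str
    overlap_histogram: dict[int, float]
    distinct_pairs: int
    zscore_10: float  # NaN when flagged degenerate
    degenerate: bool
    u1_antisense: float  # weighted fraction of antisense mass with 5' U; NaN if no mass
    a10_sense: float  # weighted fraction of sense mass with A at position 10; NaN if no mass

    def to_row(self) -> dict:
        row = {"feature": self.feature}
        row.update({f"overlap_{d}": self.overlap_histogram[d] for d in OVERLAP_RANGE})
        row.update(
            distinct_pairs=self.distinct_pairs,
            zscore_10=self.zscore_10,
            degenerate=int(self.degenerate),
            u1_antisense=self.u1_antisense,
            a10_sense=self.a10_sense,
        )
        return row


def _position_weights(alignments: Iterable[Alignment]) -> tuple[dict, dict]:
    sense: dict[int, float] = defaultdict(float)
    antisense: dict[int, float] = defaultdict(float)
    for a in alignments:
        (sense if a.strand == "+" else antisense)[a.five_prime_pos] += a.weight
    return dict(sense), dict(antisense)


def overlap_histogram(alignments: Sequence[Alignment]) -> dict[int, float]:
    """Read-weighted 5'-5' overlap histogram over distances 1..20 nt.

    Aggregates weights by 5' position first, which equals the all-pairs
    sum of weight products exactly (it is the same bilinear form).
    """
    sense, antisense = _position_weights(alignments)
    hist = {d: 0.0 for d in OVERLAP_RANGE}
    for s, ws in sense.items():
        for d in OVERLAP_RANGE:
            wa = antisense.get(s + d - 1)
            if wa:
                hist[d] += ws * wa
    return hist


def pingpong_stats(
    feature: str,
    alignments: Sequence[Alignment],
    sequences: Optional[Mapping[str, str]] = None,
    background_excludes: tuple[int, ...] = (SIGNAL_OVERLAP,),
) -> PingPongStats:
    """Full ping-pong summary for one feature's piRNA alignments.

    ``sequences`` maps read ids to trimmed insert sequences (read
    orientation) and feeds the 1U/10A bias estimates; without it the
    biases are NaN. The z-score standardizes the 10-nt bin against the
    other bins (sample s.d.); a zero-spread background with a matching
    signal bin gives z = 0, otherwise the result is flagged degenerate
    and reported as NaN - never infinity.
    """
    hist = overlap_histogram(alignments)
    sense, antisense = _position_weights(alignments)

    distinct = sum(
        1 for s in sense if antisense.get(s + SIGNAL_OVERLAP - 1, 0.0) > 0.0
    )

    background = np.array(
        [hist[d] for d in OVERLAP_RANGE if d not in background_excludes], dtype=float
    )
    mean = float(background.mean())
    sd = float(background.std(ddof=1))
    signal = hist[SIGNAL_OVERLAP]
    if sd == 0.0:
        if signal == mean:
            z, degenerate = 0.0, False
        else:
            z, degenerate = float("nan"), True
    else:
        z, degenerate = (signal - mean) / sd, False

    u1 = a10 = float("nan")
    if sequences is not None:
        u1_num = u1_den = a10_num = a10_den = 0.0
        for a in alignments:
            seq = sequences.get(a.read_id)
            if seq is None:
                continue
            if a.strand == "-":
                u1_den += a.weight
                if seq[0] == "T":  # U in RNA space
                    u1_num += a.weight
            elif a.length >= 10:
                a10_den += a.weight
                if seq[9] == "A":
                    a10_num += a.weight
        u1 = u1_num / u1_den if u1_den > 0 else float("nan")
        a10 = a10_num / a10_den if a10_den > 0 else float("nan")

    return PingPongStats(feature, hist, distinct, z, degenerate, u1, a10)
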