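"""Strand-aware short-read alignment to consensus references.

Reads are placed on every reference, on both strands, at fixed Hamming
mismatch strata (0-3); only the best stratum is reported, with each
placement weighted 1/k over the k reported hits so multi-mapping reads
conserve unit mass. Coordinates are 0-based; the 5' end of an antisense
placement is reported in plus-strand coordinates, as required by the
ping-pong overlap convention. An N in either the read or the reference
always counts as a mismatch.

The search is exact, not heuristic: the query is split into
``max_mismatches + 1`` contiguous segments, each segment is located by
substring search over the concatenated reference (pigeonhole: any
placement within the mismatch budget contains at least one exact
segment), and candidates are verified by vectorized Hamming counting.
The result is identical to a brute-force sliding-window scan.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ParameterError
from .io import ConsensusLibrary, SmallRNARead, reverse_complement

__all__ = ["Alignment", "ReferenceIndex", "align_read", "map_reads", "MappingResult",
           "alignments_to_tsv", "alignments_from_tsv"]

_ALPHABET = frozenset("ACGTN")
_ORD_N = ord("N")
MIN_READ_LENGTH = 15


@dataclass(frozen=True)
class Alignment:
    """One placement of a read on a reference."""

    read_id: str
    feature: str
    strand: str  # '+' or '-'
    five_prime_pos: int  # 0-based plus-strand coordinate of the read's 5' end
    length: int
    mismatches: int
    weight: float


class ReferenceIndex:
    """Concatenated, boundary-aware view of a consensus library.

    Built once per library; alignment queries share it.
    """

    MAX_SEED = 8  # seed k-mers are segment prefixes capped at this length

    def __init__(self, library: ConsensusLibrary):
        self.library = library
        self.names = library.names()
        self._starts: list[int] = []
        self._lengths: list[int] = []
        parts = []
        offset = 0
        for name in self.names:
            seq = library[name]
            self._starts.append(offset)
            self._lengths.append(len(seq))
            parts.append(seq)
            offset += len(seq) + 1  # '#' separator
        self.concat = "#".join(parts)
        self._arr = np.frombuffer(self.concat.encode("ascii"), dtype=np.uint8)
        self._starts_np = np.asarray(self._starts, dtype=np.intp)
        self._lengths_np = np.asarray(self._lengths, dtype=np.intp)
        self._kmer_cache: dict[int, dict[str, np.ndarray]] = {}

    def kmer_positions(self, k: int) -> dict[str, np.ndarray]:
        """Positions of every k-mer in the concatenated reference (lazy)."""
        cached = self._kmer_cache.get(k)
        if cached is not None:
            return cached
        table: dict[str, list[int]] = {}
        concat = self.concat
        for i in range(len(concat) - k + 1):
            word = concat[i : i + k]
            if "#" in word:
                continue
            table.setdefault(word, []).append(i)
        out = {w: np.asarray(v, dtype=np.intp) for w, v in table.items()}
        self._kmer_cache[k] = out
        return out

    def locate(self, concat_pos: int, span: int):
        """Feature index whose body fully contains [concat_pos, concat_pos+span), or None."""
        i = bisect_right(self._starts, concat_pos) - 1
        if i < 0:
            return None
        start = self._starts[i]
        if concat_pos + span <= start + self._lengths[i]:
            return i
        return None

    def feature_length(self, name: str) -> int:
        return self._lengths[self.names.index(name)]


def _segments(length: int, parts: int) -> list[tuple[int, int]]:
    """Split [0, length) into ``parts`` near-equal contiguous intervals."""
    bounds = np.linspace(0, length, parts + 1).astype(int)
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(parts)
            if bounds[i + 1] > bounds[i]]


def align_read(
    read,
    reference: "ReferenceIndex | ConsensusLibrary",
    max_mismatches: int = 0,
) -> list[Alignment]:
    """All best-stratum placements of one read, both strands, all features.

    ``read`` may be a :class:`SmallRNARead` or an ``(id, sequence)`` pair.
    Returns the empty list when no placement has at most
    ``max_mismatches`` mismatches.
    """
    if isinstance(reference, ConsensusLibrary):
        reference = ReferenceIndex(reference)
    if max_mismatches not in (0, 1, 2, 3):
        raise ParameterError(f"max_mismatches must be in 0..3 (got {max_mismatches})")
    if isinstance(read, SmallRNARead):
        read_id, seq = read.id, read.sequence
    else:
        read_id, seq = read
    if len(seq) < MIN_READ_LENGTH:
        raise ParameterError(f"read '{read_id}' shorter than {MIN_READ_LENGTH} nt")
    if not set(seq) <= _ALPHABET:
        raise ParameterError(f"read '{read_id}' contains characters outside ACGTN")

    length = len(seq)
    arr = reference._arr
    concat_len = len(reference.concat)
    feat_starts = reference._starts_np
    feat_lengths = reference._lengths_np
    hits: dict[tuple[int, str, int], int] = {}  # (feature idx, strand, local start) -> mm

    for strand, query in (("+", seq), ("-", reverse_complement(seq))):
        qa = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
        q_is_n = qa == _ORD_N
        # Pigeonhole seeding: any placement within the budget contains a
        # mismatch-free segment; that segment's prefix k-mer must occur
        # exactly, so seed positions are a superset of the true candidates.
        chunks = []
        for off, end in _segments(length, max_mismatches + 1):
            k = min(end - off, ReferenceIndex.MAX_SEED)
            prefix = query[off : off + k]
            if "N" in prefix:
                continue  # a mismatch-free segment never contains N
            pos = reference.kmer_positions(k).get(prefix)
            if pos is not None:
                chunks.append(pos - off)
        if not chunks:
            continue
        starts = np.unique(np.concatenate(chunks))
        starts = starts[(starts >= 0) & (starts + length <= concat_len)]
        if starts.size == 0:
            continue
        fi = np.searchsorted(feat_starts, starts, side="right") - 1
        inside = starts + length <= feat_starts[fi] + feat_lengths[fi]
        starts, fi = starts[inside], fi[inside]
        if starts.size == 0:
            continue
        windows = arr[starts[:, None] + np.arange(length)]
        mism = ((windows != qa) | q_is_n).sum(axis=1)
        keep = mism <= max_mismatches
        for concat_start, f, mm in zip(starts[keep], fi[keep], mism[keep]):
            hits[(int(f), strand, int(concat_start - feat_starts[f]))] = int(mm)
    if not hits:
        return []

    best = min(hits.values())
    chosen = [(fi, strand, local, mm) for (fi, strand, local), mm in hits.items()
              if mm == best]
    weight = 1.0 / len(chosen)
    out = []
    for fi, strand, local, mm in chosen:
        five_prime = local if strand == "+" else local + length - 1
        out.append(Alignment(read_id, reference.names[fi], strand, five_prime,
                             length, mm, weight))
    out.sort(key=lambda a: (a.feature, a.five_prime_pos, a.strand))
    return out


@dataclass
class MappingResult:
    """Alignments for a read set plus per-read bookkeeping."""

    alignments: list[Alignment]
    mapped_reads: int
    total_reads: int
    read_lengths: dict[str, int]
    is_mapped: dict[str, bool]

    @property
    def mapped_fraction(self) -> float:
        return self.mapped_reads / self.total_reads if self.total_reads else 0.0


def map_reads(
    reads: Iterable,
    reference: "ReferenceIndex | ConsensusLibrary",
    max_mismatches: int = 0,
) -> MappingResult:
    """Apply :func:`align_read` to every read; deterministic output order.

    Alignments are ordered by (read_id, feature, five_prime_pos); a read
    counts as mapped when its hit list is non-empty.
    """
    if isinstance(reference, ConsensusLibrary):
        reference = ReferenceIndex(reference)
    alignments: list[Alignment] = []
    read_lengths: dict[str, int] = {}
    is_mapped: dict[str, bool] = {}
    total = 0
    for read in reads:
        total += 1
        rid = read.id if isinstance(read, SmallRNARead) else read[0]
        seq = read.sequence if isinstance(read, SmallRNARead) else read[1]
        read_lengths[rid] = len(seq)
        hits = align_read(read, reference, max_mismatches)
        is_mapped[rid] = bool(hits)
        alignments.extend(hits)
    alignments.sort(key=lambda a: (a.read_id, a.feature, a.five_prime_pos, a.strand))
    mapped = sum(1 for v in is_mapped.values() if v)
    return MappingResult(alignments, mapped, total, read_lengths, is_mapped)


_TSV_HEADER = "read_id\tfeature\tstrand\tfive_prime_pos\tlength\tmismatches\tweight\n"


def alignments_to_tsv(alignments: Sequence[Alignment], path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        for a in alignments:
            fh.write(f"{a.read_id}\t{a.feature}\t{a.strand}\t{a.five_prime_pos}\t"
                     f"{a.length}\t{a.mismatches}\t{a.weight:.6g}\n")


def alignments_from_tsv(path) -> list[Alignment]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, feat, strand, pos, length, mm, w = line.rstrip("\n").split("\t")
            out.append(Alignment(rid, feat, strand, int(pos), int(length),
                                 int(mm), float(w)))
    return out
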