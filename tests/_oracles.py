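"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package internals beyond the
data containers: alignment is a full sliding-window Hamming scan over
both strands, and the overlap histogram is an explicit all-pairs
enumeration.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ORD_N = ord("N")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def brute_force_align(seq: str, library, max_mm: int) -> set[tuple]:
    """Best-stratum hit set {(feature, strand, five_prime_pos, mismatches)}
    from a sliding-window Hamming scan over both strands of every reference."""
    hits = []
    for name, ref in library.items():
        ra = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            L = len(query)
            if L > len(ref):
                continue
            qa = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(ra, L)
            mism = ((windows != qa) | (qa == _ORD_N)).sum(axis=1)
            for i in np.nonzero(mism <= max_mm)[0]:
                five = int(i) if strand == "+" else int(i) + L - 1
                hits.append((name, strand, five, int(mism[i])))
    if not hits:
        return set()
    best = min(h[3] for h in hits)
    return {h for h in hits if h[3] == best}


def brute_force_align_many(seqs: list[str], library, max_mm: int) -> list[set[tuple]]:
    """Batched version of :func:`brute_force_align`: the same exhaustive
    sliding-window enumeration, vectorized over reads of equal length."""
    all_hits: list[list[tuple]] = [[] for _ in seqs]
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    for name, ref in library.items():
        ra = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
        for L, idxs in by_len.items():
            if L > len(ref):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ra, L)
            for strand in ("+", "-"):
                queries = np.frombuffer(
                    "".join(
                        (seqs[i] if strand == "+" else revcomp(seqs[i]))
                        for i in idxs
                    ).encode("ascii"),
                    dtype=np.uint8,
                ).reshape(len(idxs), L)
                for lo in range(0, len(idxs), 64):
                    Q = queries[lo : lo + 64]
                    diff = (Q[:, None, :] != windows[None, :, :]) | (Q[:, None, :] == _ORD_N)
                    mism = diff.sum(axis=2)
                    for qi, wi in zip(*np.nonzero(mism <= max_mm)):
                        read_idx = idxs[lo + qi]
                        five = int(wi) if strand == "+" else int(wi) + L - 1
                        all_hits[read_idx].append((name, strand, five, int(mism[qi, wi])))
    out = []
    for hits in all_hits:
        if not hits:
            out.append(set())
            continue
        best = min(h[3] for h in hits)
        out.append({h for h in hits if h[3] == best})
    return out


def fast_align_as_set(alignments) -> set[tuple]:
    return {(a.feature, a.strand, a.five_prime_pos, a.mismatches) for a in alignments}


def allpairs_histogram(alignments) -> dict[int, float]:
    """O(n^2) enumeration of every (sense, antisense) alignment pair."""
    sense = [(a.five_prime_pos, a.weight) for a in alignments if a.strand == "+"]
    anti = [(a.five_prime_pos, a.weight) for a in alignments if a.strand == "-"]
    hist = {d: 0.0 for d in range(1, 21)}
    for s, ws in sense:
        for a, wa in anti:
            d = a - s + 1
            if 1 <= d <= 20:
                hist[d] += ws * wa
    return hist


def spearman_by_definition(x, y) -> float:
    """Spearman r computed from the average-rank definition (Pearson on ranks)."""
    def average_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2.0 + 1.0
            i = j
        return ranks

    rx, ry = average_ranks(x), average_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
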