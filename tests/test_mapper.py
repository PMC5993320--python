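"""Alignment correctness against the brute-force sliding-window oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pirnatools import ConsensusLibrary, align_read, map_reads, reverse_complement
from pirnatools.errors import ParameterError
from conftest import random_seq
from _oracles import brute_force_align, fast_align_as_set


@pytest.fixture(scope="module")
def unique_library():
    """Two random consensuses (random sequence => placements are unique)."""
    rng = np.random.default_rng(21)
    lib = ConsensusLibrary()
    lib.add("consA", random_seq(rng, 500))
    lib.add("consB", random_seq(rng, 400))
    return lib


class TestCoordinateConvention:
    def test_plus_strand_window(self, unique_library):
        read = unique_library["consA"][10:35]
        hits = align_read(("r", read), unique_library, 0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.feature, h.strand, h.five_prime_pos, h.mismatches, h.weight) == (
            "consA", "+", 10, 0, 1.0)

    def test_minus_strand_five_prime_in_plus_coordinates(self, unique_library):
        read = reverse_complement(unique_library["consA"][0:25])
        hits = align_read(("r", read), unique_library, 0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.strand, h.five_prime_pos, h.length) == ("-", 24, 25)
        # 3' end plus-strand coordinate = five_prime - length + 1 >= 0
        assert h.five_prime_pos - h.length + 1 == 0

    def test_best_stratum_only(self, unique_library):
        window = unique_library["consB"][50:75]
        read = "T" + window[1:] if window[0] != "T" else "A" + window[1:]
        hits = align_read(("r", read), unique_library, 3)
        assert {h.mismatches for h in hits} == {1}

    def test_no_hit_returns_empty(self, unique_library):
        rng = np.random.default_rng(99)
        read = random_seq(rng, 25)
        # random 25-mers essentially never match within 0 mismatches
        assert align_read(("r", read), unique_library, 0) == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed,max_mm", [(0, 0), (1, 1), (2, 2), (3, 3)])
    def test_matches_brute_force_on_random_instances(self, seed, max_mm):
        rng = np.random.default_rng(seed)
        lib = ConsensusLibrary()
        for i in range(3):
            lib.add(f"c{i}", random_seq(rng, int(rng.integers(200, 500))))
        refs = [lib[n] for n in lib.names()]
        for _ in range(60):
            kind = rng.integers(3)
            length = int(rng.integers(16, 30))
            if kind == 0:  # planted window with mutations
                ref = refs[rng.integers(len(refs))]
                start = int(rng.integers(0, len(ref) - length + 1))
                seq = list(ref[start : start + length])
                for pos in rng.choice(length, size=int(rng.integers(0, 5)), replace=False):
                    seq[pos] = "ACGT"[rng.integers(4)]
                seq = "".join(seq)
                if rng.random() < 0.5:
                    seq = reverse_complement(seq)
            elif kind == 1:
                seq = random_seq(rng, length)
            else:  # N-containing read
                seq = list(random_seq(rng, length))
                for pos in rng.choice(length, size=int(rng.integers(1, 4)), replace=False):
                    seq[pos] = "N"
                seq = "".join(seq)
            fast = align_read(("r", seq), lib, max_mm)
            assert fast_align_as_set(fast) == brute_force_align(seq, lib, max_mm)

    def test_weight_conservation(self, unique_library):
        rng = np.random.default_rng(5)
        for _ in range(30):
            ref = unique_library["consA"]
            start = int(rng.integers(0, len(ref) - 25))
            hits = align_read(("r", ref[start : start + 25]), unique_library, 3)
            if hits:
                assert sum(h.weight for h in hits) == pytest.approx(1.0, abs=0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(data=st.data())
def test_strand_symmetry(data):
    """Reverse-complementing a read swaps strands and keeps mismatch counts;
    additionally reverse-complementing the whole library restores the
    original hits exactly."""
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    lib = ConsensusLibrary()
    lib.add("c", random_seq(rng, 300))
    start = int(rng.integers(0, 275))
    seq = list(lib["c"][start : start + 25])
    for pos in rng.choice(25, size=int(rng.integers(0, 3)), replace=False):
        seq[pos] = "ACGT"[rng.integers(4)]
    seq = "".join(seq)
    fwd = hits_sorted(seq, lib)
    rev = hits_sorted(reverse_complement(seq), lib)
    swap = {"+": "-", "-": "+"}
    assert sorted((swap[s], m) for _, s, _, m in fwd) == sorted(
        (s, m) for _, s, _, m in rev
    )
    rc_lib = ConsensusLibrary()
    rc_lib.add("c", reverse_complement(lib["c"]))
    both = hits_sorted(reverse_complement(seq), rc_lib)
    L, n = len(lib["c"]), len(seq)
    # window start maps s -> L - s - n; the 5' end sits at the window start
    # on '+' and at the window end on '-'
    def mapped(strand, p):
        start = p if strand == "+" else p - n + 1
        new_start = L - start - n
        return new_start if strand == "+" else new_start + n - 1

    assert sorted((s, mapped(s, p), m) for _, s, p, m in fwd) == sorted(
        (s, p, m) for _, s, p, m in both
    )


def hits_sorted(seq, lib):
    return sorted(fast_align_as_set(align_read(("r", seq), lib, 3)))


class TestMapReads:
    def test_empty_input(self, unique_library):
        result = map_reads([], unique_library)
        assert result.alignments == [] and result.mapped_reads == 0

    def test_deterministic_ordering(self, unique_library):
        rng = np.random.default_rng(17)
        reads = []
        ref = unique_library["consA"]
        for i in range(50):
            start = int(rng.integers(0, len(ref) - 25))
            reads.append((f"r{i:02d}", ref[start : start + 25]))
        a = map_reads(reads, unique_library, 3)
        b = map_reads(reads, unique_library, 3)
        assert a.alignments == b.alignments
        keys = [(x.read_id, x.feature, x.five_prime_pos) for x in a.alignments]
        assert keys == sorted(keys)

    def test_mapped_fraction_tracks_contaminants(self, tiny_library):
        from pirnatools import SimProfile, simulate_strain_reads, preprocess_reads

        names = tiny_library.names()
        prof = SimProfile(
            te_abundances={n: 1 / len(names) for n in names},
            n_reads=1500, seed=11, contaminant_fraction=0.2,
            divergence_mix={0: 1.0}, u1_bias=0.0, a10_bias=0.0,
        )
        reads, truth = simulate_strain_reads(tiny_library, prof)
        trimmed, _ = preprocess_reads(reads, prof.adapter, None)  # keep contaminants
        result = map_reads(trimmed, tiny_library, 0)
        expected = 1.0 - truth.contaminant.mean()
        assert abs(result.mapped_fraction - expected) <= 0.02

    def test_invalid_read_characters(self, unique_library):
        with pytest.raises(ParameterError, match="outside ACGTN"):
            align_read(("r", "ACGUACGUACGUACGUACGU"), unique_library, 0)
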