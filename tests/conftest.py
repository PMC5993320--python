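"""Shared fixtures: tiny consensus libraries and a hand-enumerated
pre-processing read set with a known stage ledger."""

from __future__ import annotations

import numpy as np
import pytest

from pirnatools import (
    ConsensusLibrary,
    SmallRNARead,
    generate_consensus_library,
    load_bundled_contaminants,
)
from pirnatools.simulate import TRUSEQ_SMALL_RNA_ADAPTER

ADAPTER = TRUSEQ_SMALL_RNA_ADAPTER


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def tiny_library() -> ConsensusLibrary:
    """Three random ~600-800 nt consensuses."""
    return generate_consensus_library(3, (600, 800), gc=0.45, seed=5)


@pytest.fixture(scope="session")
def contaminants() -> ConsensusLibrary:
    return load_bundled_contaminants()


def _read(rid: str, insert: str, insert_quals: list[int]) -> SmallRNARead:
    """Insert + full 3' adapter, adapter bases at Q40."""
    return SmallRNARead(rid, insert + ADAPTER,
                        insert_quals + [40] * len(ADAPTER))


@pytest.fixture(scope="session")
def preprocess_fixture(contaminants):
    """Ten adapter-bearing reads with a hand-enumerated fate.

    3 too short (16/17/18 nt, the 18-nt one exercising the strict
    > 18 rule), 2 low-quality (20 nt with 15/20 bases >= Q20), 1 exact
    ncRNA substring, 4 clean. Expected stage ledger:
    (10, 10, 7, 5, 4, 4); retained ids r01, r03, r07, r10 in order.
    """
    rng = np.random.default_rng(1234)
    trna = contaminants[contaminants.names()[6]]  # a bundled tRNA entry

    def clean(length):
        # avoid accidental ncRNA substring matches (checked below)
        while True:
            s = random_seq(rng, length)
            if s not in trna:
                return s

    reads = [
        _read("r01", clean(21), [40] * 21),
        _read("r02", clean(17), [40] * 17),
        _read("r03", clean(24), [40] * 24),
        _read("r04", clean(20), [40] * 15 + [2] * 5),
        _read("r05", clean(18), [40] * 18),
        _read("r06", trna[10:31], [40] * 21),
        _read("r07", clean(25), [40] * 25),
        _read("r08", clean(20), [10] * 5 + [40] * 15),
        _read("r09", clean(16), [40] * 16),
        _read("r10", clean(22), [40] * 22),
    ]
    expected = {
        "ledger": (10, 10, 7, 5, 4, 4),
        "retained_ids": ["r01", "r03", "r07", "r10"],
    }
    return reads, expected
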