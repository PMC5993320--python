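"""Seeded generator of consensus libraries and strain-level small-RNA reads.

The generator emulates the statistical structure an ovarian small-RNA
library is assumed to have when profiled against a transposon consensus
set: a mixture of 21-nt siRNAs and 23–29-nt piRNAs drawn sense or
antisense from TE consensuses, a tunable fraction of antisense piRNAs
paired with a sense partner whose 5' ends overlap by exactly 10 nt (the
ping-pong geometry), planted per-read divergence from the consensus
(0–3 substitutions or a heavily diverged class standing in for degraded
ancestral copies), 1U/10A nucleotide biases, ncRNA contaminants drawn
from a bundled synthetic reference set, a 3' sequencing adapter appended
to every insert, and Phred+33 qualities that keep genuine reads above an
80%-of-bases-at-Q20 filter.

Every emitted read is mirrored by one ground-truth record, so recovery
of planted proportions by the analysis modules can be tested exactly.
All randomness flows from a single :class:`numpy.random.Generator`
seeded from the profile, making output byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError
from .io import ConsensusLibrary, SmallRNARead, reverse_complement, write_fastq

__all__ = [
    "TRUSEQ_SMALL_RNA_ADAPTER",
    "SimProfile",
    "generate_consensus_library",
    "simulate_strain_reads",
    "load_bundled_contaminants",
    "write_truth",
    "TRUTH_COLUMNS",
]

#: 3' adapter of the Illumina TruSeq small RNA kit (default trimming target).
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: siRNAs are 21 nt; piRNAs span 23-29 nt.
SIRNA_LENGTH = 21
PIRNA_LENGTHS = tuple(range(23, 30))
_VALID_SIZES = frozenset((SIRNA_LENGTH,) + PIRNA_LENGTHS)

DEFAULT_SIZE_DISTRIBUTION: dict[int, float] = {
    21: 0.25,
    23: 0.05,
    24: 0.10,
    25: 0.20,
    26: 0.20,
    27: 0.10,
    28: 0.05,
    29: 0.05,
}

DEFAULT_DIVERGENCE_MIX: dict[object, float] = {0: 0.70, 1: 0.15, 2: 0.10, 3: 0.05}

TRUTH_COLUMNS = (
    "read_id",
    "feature",
    "strand",
    "five_prime_pos",
    "mismatches",
    "pingpong",
    "contaminant",
)

_BASES = "ACGT"


def _check_fraction_map(name: str, mapping: Mapping, tol: float = 1e-9) -> None:
    total = float(sum(mapping.values()))
    if not mapping or abs(total - 1.0) > tol:
        raise ParameterError(f"{name} must sum to 1 (got {total!r})")
    if any(v < 0 for v in mapping.values()):
        raise ParameterError(f"{name} contains negative fractions")


@dataclass
class SimProfile:
    """Describes one simulated strain library.

    ``te_abundances`` maps feature names to expected read fractions (the
    multinomial over features for non-contaminant reads). Size classes,
    strandedness, ping-pong pairing, the divergence mixture and the
    contaminant fraction are all tunable; defaults describe a library
    with a dominant piRNA population, a minor siRNA peak and mild
    background contamination.
    """

    te_abundances: dict[str, float]
    n_reads: int = 10_000
    seed: int = 0
    pingpong_fraction: float = 0.3
    sense_fraction: float = 0.5
    size_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_DISTRIBUTION)
    )
    divergence_mix: dict = field(default_factory=lambda: dict(DEFAULT_DIVERGENCE_MIX))
    contaminant_fraction: float = 0.05
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    # 5'-U bias of antisense piRNAs / position-10 A bias of their sense
    # partners; probability that the base is forced.
    u1_bias: float = 0.8
    a10_bias: float = 0.8
    # Fraction of reads emitted with uniformly low quality, to exercise
    # the quality filter. Zero by default.
    junk_fraction: float = 0.0

    def __post_init__(self) -> None:
        _check_fraction_map("te_abundances", self.te_abundances)
        _check_fraction_map("size_distribution", self.size_distribution)
        _check_fraction_map("divergence_mix", self.divergence_mix)
        if self.n_reads < 1:
            raise ParameterError(f"n_reads must be >= 1 (got {self.n_reads})")
        if len(self.adapter) < 8:
            raise ParameterError("adapter must be at least 8 nt")
        for frac_name in ("pingpong_fraction", "sense_fraction", "contaminant_fraction",
                          "u1_bias", "a10_bias", "junk_fraction"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{frac_name} must be in [0, 1] (got {v})")
        bad_sizes = set(self.size_distribution) - _VALID_SIZES
        if bad_sizes:
            raise ParameterError(f"size_distribution keys outside {{21, 23..29}}: {bad_sizes}")
        bad_div = set(self.divergence_mix) - {0, 1, 2, 3, "diverged"}
        if bad_div:
            raise ParameterError(f"divergence_mix keys outside {{0,1,2,3,'diverged'}}: {bad_div}")


def generate_consensus_library(
    n_te: int,
    length_range: tuple[int, int] = (800, 3000),
    gc: float = 0.42,
    seed: int = 0,
    prefix: str = "TE",
    category: str = "TE",
) -> ConsensusLibrary:
    """Generate ``n_te`` uniquely named random consensus sequences.

    Lengths are drawn uniformly from the inclusive ``length_range``;
    bases are i.i.d. with P(G) = P(C) = gc/2. Deterministic for a fixed
    seed.
    """
    if n_te < 1:
        raise ParameterError(f"n_te must be >= 1 (got {n_te})")
    lo, hi = length_range
    if lo > hi or lo < 100:
        raise ParameterError(f"invalid length range {length_range} (min length 100)")
    if not 0.0 < gc < 1.0:
        raise ParameterError(f"gc must be in (0, 1) (got {gc})")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    width = max(3, len(str(n_te)))
    lib = ConsensusLibrary()
    for i in range(n_te):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(np.array(list(_BASES))[rng.choice(4, size=length, p=p)])
        lib.add(f"{prefix}_{i + 1:0{width}d}", seq, category)
    return lib


def load_bundled_contaminants() -> ConsensusLibrary:
    """Bundled synthetic rRNA/tRNA/snRNA/miRNA contaminant references."""
    path = resources.files("pirnatools.data") / "synthetic_ncrna.fasta"
    with resources.as_file(path) as p:
        return ConsensusLibrary.from_fasta(p, category="ncRNA")


def _plant_mismatches(seq: str, count: int, rng: np.random.Generator) -> str:
    if count == 0:
        return seq
    chars = list(seq)
    positions = rng.choice(len(chars), size=min(count, len(chars)), replace=False)
    for pos in positions:
        options = [b for b in _BASES if b != chars[pos]]
        chars[pos] = options[int(rng.integers(3))]
    return "".join(chars)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _quality(length: int, junk: bool, rng: np.random.Generator) -> list[int]:
    """Q30 bases with ~5% Q10 (capped at 15% so reads pass the 80%>=Q20
    filter); junk reads are uniformly Q10 and always fail it."""
    if junk:
        return [10] * length
    qual = [30] * length
    n_low = min(int(rng.binomial(length, 0.05)), int(0.15 * length))
    if n_low:
        for pos in rng.choice(length, size=n_low, replace=False):
            qual[pos] = 10
    return qual


def simulate_strain_reads(
    library: ConsensusLibrary,
    profile: SimProfile,
    fastq_path=None,
    truth_path=None,
) -> tuple[list[SmallRNARead], pd.DataFrame]:
    """Emit ``profile.n_reads`` adapter-bearing reads plus a ground-truth table.

    Returns ``(reads, truth)``; optionally also writes the FASTQ and the
    truth TSV. Truth rows record, per read: source feature, strand, 5'
    position in plus-strand consensus coordinates, the *realized* mismatch
    count of the insert against its source window (planted substitutions
    plus any bias-forced base change), and ping-pong / contaminant flags.
    """
    for name in profile.te_abundances:
        if name not in library:
            raise ConfigurationError(f"profile feature '{name}' not in library")
    max_size = max(profile.size_distribution)
    for name in profile.te_abundances:
        if len(library[name]) < max_size:
            raise ConfigurationError(
                f"consensus '{name}' shorter than the longest read size {max_size}"
            )

    rng = np.random.default_rng(profile.seed)
    features = list(profile.te_abundances)
    feat_p = np.array([profile.te_abundances[f] for f in features], dtype=float)
    feat_p = feat_p / feat_p.sum()
    sizes = sorted(profile.size_distribution)
    size_p = np.array([profile.size_distribution[s] for s in sizes], dtype=float)
    size_p = size_p / size_p.sum()
    pi_sizes = [s for s in sizes if s in PIRNA_LENGTHS]
    pi_p = np.array([profile.size_distribution[s] for s in pi_sizes], dtype=float)
    if pi_p.sum() > 0:
        pi_p = pi_p / pi_p.sum()
    div_keys = list(profile.divergence_mix)
    div_p = np.array([profile.divergence_mix[k] for k in div_keys], dtype=float)
    div_p = div_p / div_p.sum()

    contaminants = load_bundled_contaminants()
    contam_names = contaminants.names()

    reads: list[SmallRNARead] = []
    truth_rows: list[tuple] = []
    n_digits = max(6, len(str(profile.n_reads)))

    def finish(insert: str, feature: str, strand: str, five_prime: int,
               mismatches: int, pingpong: bool, contaminant: bool) -> None:
        read_id = f"sim{len(reads):0{n_digits}d}"
        junk = profile.junk_fraction > 0 and rng.random() < profile.junk_fraction
        qual = _quality(len(insert), junk, rng)
        seq = insert + profile.adapter
        qual = qual + [30] * len(profile.adapter)
        reads.append(SmallRNARead(read_id, seq, qual))
        truth_rows.append(
            (read_id, feature, strand, five_prime, mismatches, pingpong, contaminant)
        )

    def planted_count(length: int) -> int:
        key = div_keys[int(rng.choice(len(div_keys), p=div_p))]
        if key == "diverged":
            return max(5, round(0.2 * length))
        return int(key)

    def make_te_read(feature: str, strand: str, start: int, length: int,
                     pingpong: bool, force_a10: bool) -> None:
        cons = library[feature]
        window = cons[start : start + length]
        insert = window if strand == "+" else reverse_complement(window)
        insert = _plant_mismatches(insert, planted_count(length), rng)
        if strand == "-" and rng.random() < profile.u1_bias:
            insert = "T" + insert[1:]
        if strand == "+" and force_a10 and length >= 10 and rng.random() < profile.a10_bias:
            insert = insert[:9] + "A" + insert[10:]
        back = insert if strand == "+" else reverse_complement(insert)
        realized = _hamming(back, window)
        five_prime = start if strand == "+" else start + length - 1
        finish(insert, feature, strand, five_prime, realized, pingpong, False)

    while len(reads) < profile.n_reads:
        if rng.random() < profile.contaminant_fraction:
            name = contam_names[int(rng.integers(len(contam_names)))]
            source = contaminants[name]
            length = sizes[int(rng.choice(len(sizes), p=size_p))]
            length = min(length, len(source))
            start = int(rng.integers(0, len(source) - length + 1))
            finish(source[start : start + length], name, "+", start, 0, False, True)
            continue

        feature = features[int(rng.choice(len(features), p=feat_p))]
        length = sizes[int(rng.choice(len(sizes), p=size_p))]
        cons_len = len(library[feature])
        sense = rng.random() < profile.sense_fraction

        pair = (
            not sense
            and length in PIRNA_LENGTHS
            and len(pi_sizes) > 0
            and len(reads) + 2 <= profile.n_reads
            and rng.random() < profile.pingpong_fraction
        )
        if pair:
            partner_len = pi_sizes[int(rng.choice(len(pi_sizes), p=pi_p))]
            # Sense partner 5' at s, antisense 5' (plus-strand) at s+9:
            # the canonical 10-nt 5'-5' overlap.
            s_lo = max(0, length - 10)
            s_hi = min(cons_len - partner_len, cons_len - 10)
            if s_hi >= s_lo:
                s = int(rng.integers(s_lo, s_hi + 1))
                a = s + 9
                make_te_read(feature, "-", a - length + 1, length, True, False)
                make_te_read(feature, "+", s, partner_len, True, True)
                continue
            # Consensus too short for the pair geometry; fall through.

        start = int(rng.integers(0, cons_len - length + 1))
        make_te_read(feature, "+" if sense else "-", start, length, False, False)

    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    if fastq_path is not None:
        write_fastq(reads, fastq_path)
    if truth_path is not None:
        write_truth(truth, truth_path)
    return reads, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the ground-truth table as TSV (booleans as 0/1)."""
    out = truth.copy()
    out["pingpong"] = out["pingpong"].astype(int)
    out["contaminant"] = out["contaminant"].astype(int)
    out.to_csv(path, sep="\t", index=False)
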