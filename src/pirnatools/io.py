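"""Readers and writers for the plain-text formats the pipeline touches.

FASTA holds reference sequences (transposon consensuses, transcripts,
ncRNA contaminants); FASTQ (Sanger/Phred+33, strict 4-line records) holds
sequenced small-RNA reads; tab-separated tables carry counts and reports.
Files ending in ``.gz`` are opened through gzip transparently.

Parsing of FASTA/FASTQ is delegated to Biopython; FASTQ reads are yielded
lazily so memory stays flat regardless of library size.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .errors import ParseError

__all__ = [
    "SmallRNARead",
    "ConsensusLibrary",
    "read_fastq",
    "write_fastq",
    "load_sequences",
    "write_count_table",
    "read_count_table",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SmallRNARead:
    """One sequenced small-RNA read with per-base Phred quality scores."""

    id: str
    sequence: str
    quality: list[int]

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("read with empty id")
        if len(self.sequence) != len(self.quality):
            raise ParseError(
                f"read '{self.id}': sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize(seq: str) -> str:
    """Uppercase and transliterate RNA 'U' to DNA 'T'."""
    return seq.upper().replace("U", "T")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


class ConsensusLibrary:
    """Ordered collection of named reference sequences.

    Each entry carries a category tag: ``TE``, ``repeat``, ``transcript``
    (for genic small-RNA profiling) or ``ncRNA`` (contaminants). Sequences
    are stored uppercase with U transliterated to T; names must be unique
    and sequences non-empty.
    """

    CATEGORIES = ("TE", "repeat", "transcript", "ncRNA")

    def __init__(self) -> None:
        self._seqs: dict[str, str] = {}
        self._cats: dict[str, str] = {}

    def add(self, name: str, sequence: str, category: str = "TE") -> None:
        if not name:
            raise ParseError("reference with empty name")
        if name in self._seqs:
            raise ParseError(f"duplicate reference name '{name}'")
        sequence = _normalize(sequence)
        if not sequence:
            raise ParseError(f"reference '{name}' has empty sequence")
        if category not in self.CATEGORIES:
            raise ParseError(f"unknown category '{category}' for '{name}'")
        self._seqs[name] = sequence
        self._cats[name] = category

    # Mapping-style access returns the sequence itself, which is what
    # nearly every caller wants.
    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def names(self) -> list[str]:
        return list(self._seqs)

    def category(self, name: str) -> str:
        return self._cats[name]

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._seqs.items())

    @classmethod
    def from_fasta(cls, path, category: str = "TE") -> "ConsensusLibrary":
        lib = cls()
        with _open_text(path) as fh:
            for i, rec in enumerate(SeqIO.parse(fh, "fasta"), start=1):
                try:
                    lib.add(rec.id, str(rec.seq), category)
                except ParseError as exc:
                    raise ParseError(f"{path}, record {i}: {exc}") from exc
        return lib

    def to_fasta(self, path, width: int = 60) -> None:
        with _open_text(path, "wt") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> Iterator[SmallRNARead]:
    """Lazily yield reads from a 4-line FASTQ file (Phred+33).

    Malformed records (quality/sequence length mismatch, truncated record)
    raise :class:`ParseError` naming the 1-based record index.
    """
    with _open_text(path) as fh:
        parser = SeqIO.parse(fh, "fastq")
        index = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise ParseError(
                    f"{path}: malformed FASTQ record {index + 1}: {exc}"
                ) from exc
            index += 1
            yield SmallRNARead(
                rec.id,
                _normalize(str(rec.seq)),
                list(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[SmallRNARead], path) -> None:
    """Write reads as 4-line FASTQ records, Phred+33."""
    with _open_text(path, "wt") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quality)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def load_sequences(path, format: str):
    """Load a FASTA file into a :class:`ConsensusLibrary`, or stream FASTQ reads.

    ``format`` is ``"FASTA"`` or ``"FASTQ"`` (case-insensitive).
    """
    fmt = format.upper()
    if fmt == "FASTA":
        return ConsensusLibrary.from_fasta(path)
    if fmt == "FASTQ":
        return read_fastq(path)
    raise ParseError(f"unsupported format '{format}'")


def write_count_table(matrix, path) -> None:
    """Serialize a :class:`~pirnatools.quantify.CountMatrix` as TSV.

    Layout: comment lines ``# denominator <sample> <value>``, then a header
    ``feature size_class strand raw:<s>... cpm:<s>...`` and one row per
    (feature, size-class, strand). Values carry 6 significant digits;
    floored-absent CPM cells are written as ``NA``.
    """
    matrix.to_tsv(path)


def read_count_table(path):
    """Inverse of :func:`write_count_table`."""
    from .quantify import CountMatrix

    return CountMatrix.from_tsv(path)
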