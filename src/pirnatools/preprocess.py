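"""Adapter trimming, length/quality filtering and ncRNA subtraction.

The pre-processing contract is: (1) trim the 3' adapter (leftmost
occurrence of an adapter prefix, minimum 5-nt overlap, at most one
mismatch); (2) keep reads strictly longer than 18 nt whose bases are at
least 80% at Phred >= 20; (3) subtract reads exactly matching any
rRNA/tRNA/snRNA/miRNA reference, on either strand, as a substring.
Boundary conventions are strict on length (an 18-nt read is removed)
and inclusive on quality (exactly 80% passes). All thresholds are
arguments with those defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .errors import ParameterError
from .io import ConsensusLibrary, SmallRNARead, reverse_complement

__all__ = ["PreprocessReport", "trim_adapter", "filter_and_subtract", "preprocess_reads"]

logger = logging.getLogger(__name__)

MIN_ADAPTER_OVERLAP = 5


@dataclass
class PreprocessReport:
    """Read counts surviving each pre-processing stage (monotone non-increasing)."""

    input: int = 0
    adapter_trimmed: int = 0
    length_pass: int = 0
    quality_pass: int = 0
    ncrna_subtracted: int = 0

    @property
    def retained(self) -> int:
        return self.ncrna_subtracted

    def stages(self) -> tuple[int, int, int, int, int, int]:
        return (
            self.input,
            self.adapter_trimmed,
            self.length_pass,
            self.quality_pass,
            self.ncrna_subtracted,
            self.retained,
        )

    def to_tsv(self, path) -> None:
        names = ("input", "adapter_trimmed", "length_pass", "quality_pass",
                 "ncrna_subtracted", "retained")
        with open(path, "w") as fh:
            fh.write("stage\treads\n")
            for name, count in zip(names, self.stages()):
                fh.write(f"{name}\t{count}\n")


def trim_adapter(
    read: SmallRNARead,
    adapter: str,
    min_overlap: int = MIN_ADAPTER_OVERLAP,
    max_mismatches: int = 1,
    keep_untrimmed: bool = False,
) -> Optional[SmallRNARead]:
    """Return the 5' insert of ``read``, or None for a discard.

    Scans 5'->3' for the leftmost position where a prefix of ``adapter``
    (overlap >= ``min_overlap``, <= ``max_mismatches`` mismatches) spans
    the rest of the read. Reads without an adapter hit are discarded
    unless ``keep_untrimmed``; an adapter at position 0 leaves an empty
    insert, which is always discarded.
    """
    if len(adapter) < min_overlap:
        raise ParameterError(
            f"adapter length {len(adapter)} below minimum overlap {min_overlap}"
        )
    seq = read.sequence
    n = len(seq)
    hit = None
    for start in range(0, n - min_overlap + 1):
        overlap = min(len(adapter), n - start)
        mism = 0
        for a, b in zip(seq[start : start + overlap], adapter[:overlap]):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            hit = start
            break
    if hit is None:
        if keep_untrimmed:
            return read
        return None
    if hit == 0:
        return None
    return SmallRNARead(read.id, seq[:hit], read.quality[:hit])


def _quality_ok(read: SmallRNARead, q_threshold: int, q_fraction: float) -> bool:
    good = sum(1 for q in read.quality if q >= q_threshold)
    return good >= q_fraction * len(read.quality)


def _ncrna_haystack(ncrna: ConsensusLibrary) -> str:
    # One joined string (both strands) so membership is a single C-level scan.
    parts = []
    for _, seq in ncrna.items():
        parts.append(seq)
        parts.append(reverse_complement(seq))
    return "#".join(parts)


def filter_and_subtract(
    reads: Iterable[SmallRNARead],
    ncrna: Optional[ConsensusLibrary],
    min_len: int = 18,
    q_threshold: int = 20,
    q_fraction: float = 0.8,
    report: Optional[PreprocessReport] = None,
) -> tuple[list[SmallRNARead], PreprocessReport]:
    """Length filter (strictly > ``min_len``), quality filter, ncRNA subtraction.

    Subtraction removes reads whose sequence is a perfect substring of
    any ncRNA reference on either strand. An empty or missing ncRNA
    library logs a warning and skips subtraction. Retained reads keep
    input order; the report tallies every stage.
    """
    if min_len < 1:
        raise ParameterError(f"min_len must be >= 1 (got {min_len})")
    if not 0.0 < q_fraction <= 1.0:
        raise ParameterError(f"q_fraction must be in (0, 1] (got {q_fraction})")
    if report is None:
        report = PreprocessReport()
        fill_input = True
    else:
        fill_input = False

    length_pass = []
    for read in reads:
        if fill_input:
            report.input += 1
            report.adapter_trimmed += 1
        if len(read) > min_len:
            length_pass.append(read)
    report.length_pass = len(length_pass)

    quality_pass = [r for r in length_pass if _quality_ok(r, q_threshold, q_fraction)]
    report.quality_pass = len(quality_pass)

    if ncrna is None or len(ncrna) == 0:
        logger.warning("empty ncRNA library: subtraction skipped")
        retained = quality_pass
    else:
        haystack = _ncrna_haystack(ncrna)
        retained = [r for r in quality_pass if r.sequence not in haystack]
    report.ncrna_subtracted = len(retained)
    return retained, report


def preprocess_reads(
    reads: Iterable[SmallRNARead],
    adapter: str,
    ncrna: Optional[ConsensusLibrary],
    min_len: int = 18,
    q_threshold: int = 20,
    q_fraction: float = 0.8,
    keep_untrimmed: bool = False,
) -> tuple[list[SmallRNARead], PreprocessReport]:
    """Full pre-processing: trim, length/quality filter, ncRNA subtraction."""
    report = PreprocessReport()
    trimmed = []
    for read in reads:
        report.input += 1
        out = trim_adapter(read, adapter, keep_untrimmed=keep_untrimmed)
        if out is not None:
            trimmed.append(out)
    report.adapter_trimmed = len(trimmed)
    retained, report = filter_and_subtract(
        trimmed, ncrna, min_len=min_len, q_threshold=q_threshold,
        q_fraction=q_fraction, report=report,
    )
    logger.info("preprocess stages: %s", report.stages())
    return retained, report
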