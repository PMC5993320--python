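"""Deterministic qPCR and ChIP-qPCR calculators.

Relative expression follows the comparative-Ct method with an assumed
amplification efficiency of 2: dCt = target Ct - reference Ct (the
reference being a ubiquitously expressed housekeeping gene such as
rp49), ddCt = dCt(sample) - dCt(calibrator), fold = 2^-ddCt. ChIP
recovery is expressed as percent of input: the input Ct is first
adjusted for the fraction of chromatin used as input
(Ct_adj = Ct_input - log2(1/fraction)), then
percent_input = 100 x 2^(Ct_adj - Ct_IP); enrichment is the ratio of
percent-input at the target locus to percent-input at the control
locus. Replicate summaries report mean and standard error of the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Optional, Sequence

from .errors import ParameterError

__all__ = ["CtRecord", "ChipRecord", "ddct", "ddct_replicates", "ReplicateSummary",
           "percent_input", "chip_enrichment", "ChipResult"]


@dataclass
class CtRecord:
    """One qPCR measurement: target and reference (housekeeping) Ct."""

    sample: str
    target_ct: float
    reference_ct: float
    replicate: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("target_ct", "reference_ct"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ParameterError(f"{self.sample}: {name} is not finite ({v!r})")

    @property
    def dct(self) -> float:
        return self.target_ct - self.reference_ct


@dataclass
class ChipRecord:
    """One ChIP-qPCR measurement at a locus (IP and input Ct)."""

    locus: str
    ip_ct: float
    input_ct: float
    input_fraction: float  # fraction of chromatin used as input, e.g. 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.input_fraction <= 1.0:
            raise ParameterError(
                f"{self.locus}: input_fraction must be in (0, 1] "
                f"(got {self.input_fraction!r})"
            )


def ddct(sample: CtRecord, calibrator: CtRecord) -> float:
    """Relative expression 2^-ddCt of ``sample`` versus ``calibrator``."""
    return 2.0 ** -(sample.dct - calibrator.dct)


@dataclass
class ReplicateSummary:
    folds: tuple[float, ...]
    mean: float
    sem: float  # NaN for a single replicate


def ddct_replicates(
    samples: Sequence[CtRecord], calibrators: Sequence[CtRecord]
) -> ReplicateSummary:
    """Per-replicate 2^-ddCt folds with mean and SEM.

    Replicates pair positionally; a single calibrator is broadcast
    against every sample replicate.
    """
    if len(calibrators) == 1:
        calibrators = list(calibrators) * len(samples)
    if len(samples) != len(calibrators):
        raise ParameterError(
            f"replicate count mismatch: {len(samples)} samples, "
            f"{len(calibrators)} calibrators"
        )
    if not samples:
        raise ParameterError("no replicates")
    folds = tuple(ddct(s, c) for s, c in zip(samples, calibrators))
    m = mean(folds)
    sem = stdev(folds) / math.sqrt(len(folds)) if len(folds) > 1 else float("nan")
    return ReplicateSummary(folds, m, sem)


def percent_input(record: ChipRecord) -> float:
    """ChIP recovery as percent of input chromatin.

    ``100 x 2^(input_ct - log2(1/input_fraction) - ip_ct)``.
    """
    adjusted_input = record.input_ct - math.log2(1.0 / record.input_fraction)
    return 100.0 * 2.0 ** (adjusted_input - record.ip_ct)


@dataclass
class ChipResult:
    percent_input_target: float
    percent_input_control: float
    enrichment: float


def chip_enrichment(target: ChipRecord, control: ChipRecord) -> ChipResult:
    """Percent-input at target and control loci plus their ratio.

    The control is typically an actively transcribed housekeeping locus
    (rp49); both records must use the same input-fraction convention.
    """
    pt = percent_input(target)
    pc = percent_input(control)
    return ChipResult(pt, pc, pt / pc)
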