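"""Cross-strain comparison: fold changes, 10-fold asymmetry calls,
Venn-style set intersections and Spearman profile correlation.

The central operation mirrors the pairwise scatter analysis of strain
small-RNA profiles: per feature, strand-summed class-restricted CPM in
two samples, fold change with a pseudocount on both terms, and a call
when the fold crosses the threshold (default 10-fold, the conventional
asymmetry line). Features floored to absent in both samples are
skipped; absent in one sample is treated as zero, so a family present
in only one strain is callable. Set intersections over multiple
comparisons expose shared asymmetric families, and Spearman's rank
correlation (average ranks for ties, via scipy) summarizes global
profile similarity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .quantify import CountMatrix

__all__ = ["AsymmetryReport", "fold_change_and_call", "intersect_sets",
           "VennRegion", "spearman", "SpearmanResult"]

DEFAULT_FOLD_THRESHOLD = 10.0
DEFAULT_EPSILON_CPM = 1.0


@dataclass
class SpearmanResult:
    r: float  # NaN when degenerate
    degenerate: bool


@dataclass
class AsymmetryReport:
    """Per-feature fold changes between two samples plus set summaries."""

    sample_a: str
    sample_b: str
    size_class: str
    threshold: float
    epsilon: float
    table: pd.DataFrame  # columns: cpm_a, cpm_b, fold, call; index: feature
    spearman: SpearmanResult

    @property
    def higher_in_a(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "higher_in_a"])

    @property
    def higher_in_b(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "higher_in_b"])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["log10_cpm_a"] = np.log10(out["cpm_a"] + self.epsilon)
        out["log10_cpm_b"] = np.log10(out["cpm_b"] + self.epsilon)
        out.to_csv(path, sep="\t", float_format="%.6g",
                   index_label="feature")


def spearman(values_a: Sequence[float], values_b: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    Vectors must have equal length >= 3; a constant vector yields a
    degenerate (NaN) result rather than an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ParameterError("need at least 3 paired values")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return SpearmanResult(float("nan"), True)
    r = float(stats.spearmanr(a, b).statistic)
    return SpearmanResult(r, not math.isfinite(r))


def fold_change_and_call(
    matrix: CountMatrix,
    sample_a: str,
    sample_b: str,
    size_class: str = "piRNA",
    threshold: float = DEFAULT_FOLD_THRESHOLD,
    epsilon: float = DEFAULT_EPSILON_CPM,
) -> AsymmetryReport:
    """Fold changes and asymmetry calls for one sample pair and size class.

    ``matrix`` should be floored (see
    :meth:`~pirnatools.quantify.CountMatrix.normalize_and_floor`); the
    fold is ``(cpm_a + eps) / (cpm_b + eps)`` with absent values as 0,
    and the call is ``higher_in_a`` iff fold >= threshold,
    ``higher_in_b`` iff fold <= 1/threshold, else ``none``.
    """
    if size_class not in ("siRNA", "piRNA"):
        raise ParameterError(f"size_class must be siRNA or piRNA (got {size_class!r})")
    if threshold <= 1:
        raise ParameterError(f"threshold must exceed 1 (got {threshold})")
    va = matrix.class_cpm(sample_a, size_class)
    vb = matrix.class_cpm(sample_b, size_class)
    keep = ~(va.isna() & vb.isna())  # absent in both -> skipped
    va = va[keep].fillna(0.0)
    vb = vb[keep].fillna(0.0)
    fold = (va + epsilon) / (vb + epsilon)
    call = pd.Series("none", index=fold.index, dtype=object)
    call[fold >= threshold] = "higher_in_a"
    call[fold <= 1.0 / threshold] = "higher_in_b"
    table = pd.DataFrame({"cpm_a": va, "cpm_b": vb, "fold": fold, "call": call})
    rho = (
        spearman(va.to_numpy(), vb.to_numpy())
        if len(table) >= 3
        else SpearmanResult(float("nan"), True)
    )
    return AsymmetryReport(sample_a, sample_b, size_class, threshold, epsilon,
                           table, rho)


@dataclass
class VennRegion:
    """One exclusive region of a Venn partition."""

    inside: tuple[str, ...]  # set names the region belongs to
    members: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.members)


def intersect_sets(named_sets: Mapping[str, Iterable[str]]) -> list[VennRegion]:
    """Exclusive Venn partition of k named sets into 2^k - 1 regions.

    Regions are ordered deterministically: by decreasing region size
    (number of participating sets), then by set order as given. Members
    are sorted.
    """
    names = list(named_sets)
    if len(names) < 2:
        raise ParameterError("need at least 2 sets")
    sets = {n: set(named_sets[n]) for n in names}
    regions = []
    subsets = []
    for k in range(len(names), 0, -1):
        subsets.extend(itertools.combinations(names, k))
    for inside in subsets:
        outside = [n for n in names if n not in inside]
        members = set.intersection(*(sets[n] for n in inside))
        for n in outside:
            members -= sets[n]
        regions.append(VennRegion(tuple(inside), tuple(sorted(members))))
    return regions


def region(regions: list[VennRegion], *inside: str) -> VennRegion:
    """Look up the exclusive region belonging to exactly ``inside``."""
    want = set(inside)
    for r in regions:
        if set(r.inside) == want:
            return r
    raise KeyError(f"no region for {inside!r}")
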