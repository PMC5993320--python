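"""Size-class calling, per-feature counting, CPM normalization and the
low-expression floor.

Size classes follow the field's *D. virilis* ovarian convention: 21 nt
reads are siRNAs, 23-29 nt reads are piRNAs, everything else is "other"
and excluded from both class totals. Counts accumulate alignment
weights per (feature, size class, strand); CPM is raw x 1e6 / per-sample
denominator (total retained mapped reads by default). A feature/class
whose strand-summed CPM falls below the floor (default 25 CPM) is marked
*absent* - represented as NaN, distinct from an expressed zero - and is
excluded from downstream comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import NormalizationError, ParameterError
from .mapper import Alignment

__all__ = ["SIZE_CLASSES", "size_class", "CountMatrix", "classify_and_count",
           "merge_samples", "normalize_and_floor"]

SIZE_CLASSES = ("siRNA", "piRNA", "other")
STRANDS = ("+", "-")

DEFAULT_FLOOR_CPM = 25.0


def size_class(length: int) -> str:
    """21 nt -> siRNA; 23-29 nt -> piRNA; anything else -> other."""
    if length == 21:
        return "siRNA"
    if 23 <= length <= 29:
        return "piRNA"
    return "other"


def _full_index(features: Sequence[str]) -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [list(features), list(SIZE_CLASSES), list(STRANDS)],
        names=["feature", "size_class", "strand"],
    )


@dataclass
class CountMatrix:
    """Raw weighted counts and CPM on (feature x size-class x strand) x sample.

    ``raw`` always holds the weighted counts. ``cpm`` is None until
    :meth:`normalize_and_floor` runs; afterwards floored-absent cells are
    NaN (distinct from an expressed 0.0).
    """

    raw: pd.DataFrame
    denominators: pd.Series
    cpm: Optional[pd.DataFrame] = None
    floor_cpm: Optional[float] = None

    @property
    def samples(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def features(self) -> list[str]:
        return list(self.raw.index.get_level_values("feature").unique())

    def compute_cpm(self) -> pd.DataFrame:
        """Pre-floor CPM: raw x 1e6 / denominator, cell-wise."""
        for s in self.samples:
            d = self.denominators.get(s, np.nan)
            if not (d and d > 0) or not math.isfinite(d):
                raise NormalizationError(f"sample '{s}' has denominator {d!r}")
        return self.raw * 1e6 / self.denominators

    def normalize_and_floor(self, floor_cpm: float = DEFAULT_FLOOR_CPM) -> "CountMatrix":
        """Return a copy with CPM filled and sub-floor feature/classes absent.

        The floor applies to strand-summed CPM per (sample, feature,
        size class): if the sum is below ``floor_cpm`` both strand cells
        become NaN for that sample.
        """
        cpm = self.compute_cpm()
        sums = cpm.groupby(level=["feature", "size_class"]).transform("sum")
        cpm = cpm.mask(sums < floor_cpm)
        return replace(self, cpm=cpm, floor_cpm=floor_cpm)

    def class_cpm(self, sample: str, size_cls: str) -> pd.Series:
        """Strand-summed CPM per feature for one sample and size class.

        NaN marks a floored-absent feature; requires a prior
        :meth:`normalize_and_floor` (falls back to pre-floor CPM).
        """
        frame = self.cpm if self.cpm is not None else self.compute_cpm()
        if sample not in frame.columns:
            raise KeyError(f"unknown sample '{sample}'")
        sub = frame[sample].xs(size_cls, level="size_class")
        return sub.groupby(level="feature").sum(min_count=1)

    # -- serialization ----------------------------------------------------

    def to_tsv(self, path) -> None:
        cpm = self.cpm if self.cpm is not None else self.compute_cpm()
        with open(path, "w") as fh:
            for s in self.samples:
                fh.write(f"# denominator\t{s}\t{self.denominators[s]:.10g}\n")
            if self.floor_cpm is not None:
                fh.write(f"# floor_cpm\t{self.floor_cpm:.6g}\n")
            cols = [f"raw:{s}" for s in self.samples] + [f"cpm:{s}" for s in self.samples]
            fh.write("feature\tsize_class\tstrand\t" + "\t".join(cols) + "\n")
            for idx in self.raw.index:
                feature, cls, strand = idx
                vals = [f"{self.raw.loc[idx, s]:.6g}" for s in self.samples]
                for s in self.samples:
                    v = cpm.loc[idx, s]
                    vals.append("NA" if pd.isna(v) else f"{v:.6g}")
                fh.write(f"{feature}\t{cls}\t{strand}\t" + "\t".join(vals) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        denoms: dict[str, float] = {}
        floor = None
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("# denominator"):
                    _, s, v = line.rstrip("\n").split("\t")
                    denoms[s] = float(v)
                elif line.startswith("# floor_cpm"):
                    floor = float(line.rstrip("\n").split("\t")[1])
                elif line.startswith("feature\t"):
                    header = line.rstrip("\n").split("\t")
                else:
                    rows.append(line.rstrip("\n").split("\t"))
        samples = [c[4:] for c in header if c.startswith("raw:")]
        index = pd.MultiIndex.from_tuples(
            [(r[0], r[1], r[2]) for r in rows],
            names=["feature", "size_class", "strand"],
        )
        n = len(samples)
        raw = pd.DataFrame(
            [[float(v) for v in r[3 : 3 + n]] for r in rows],
            index=index, columns=samples,
        )
        cpm_vals = [[np.nan if v == "NA" else float(v) for v in r[3 + n : 3 + 2 * n]]
                    for r in rows]
        cpm = pd.DataFrame(cpm_vals, index=index, columns=samples)
        return cls(raw=raw, denominators=pd.Series(denoms, dtype=float),
                   cpm=cpm if floor is not None else None, floor_cpm=floor)


def classify_and_count(
    alignments: Iterable[Alignment],
    sample: str,
    denominator: float,
    features: Optional[Sequence[str]] = None,
) -> CountMatrix:
    """Accumulate alignment weights into a single-sample count matrix.

    ``features`` fixes the row universe (recommended: the full library,
    so unexpressed features exist as zero rows and can be floored to
    absent); by default the features observed in the alignments are used.
    ``denominator`` is the per-sample normalization total, typically the
    number of retained reads that mapped anywhere.
    """
    alignments = list(alignments)
    if features is None:
        features = sorted({a.feature for a in alignments})
    acc: dict[tuple[str, str, str], float] = {}
    for a in alignments:
        key = (a.feature, size_class(a.length), a.strand)
        acc[key] = acc.get(key, 0.0) + a.weight
    index = _full_index(features)
    if acc:
        counts = pd.Series(acc, dtype=float).reindex(index, fill_value=0.0)
    else:
        counts = pd.Series(0.0, index=index)
    raw = counts.to_frame(name=sample)
    raw.index.names = ["feature", "size_class", "strand"]
    return CountMatrix(raw=raw, denominators=pd.Series({sample: float(denominator)}))


def merge_samples(matrices: Sequence[CountMatrix]) -> CountMatrix:
    """Combine single-sample matrices on the union of their row indexes."""
    if not matrices:
        raise ParameterError("no matrices to merge")
    raw = pd.concat([m.raw for m in matrices], axis=1).fillna(0.0)
    denoms = pd.concat([m.denominators for m in matrices])
    if denoms.index.duplicated().any():
        raise ParameterError("duplicate sample names in merge")
    return CountMatrix(raw=raw.sort_index(), denominators=denoms)


def normalize_and_floor(matrix: CountMatrix, floor_cpm: float = DEFAULT_FLOOR_CPM) -> CountMatrix:
    """Functional alias for :meth:`CountMatrix.normalize_and_floor`."""
    return matrix.normalize_and_floor(floor_cpm)
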