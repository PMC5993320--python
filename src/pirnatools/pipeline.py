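"""End-to-end orchestration: preprocess -> map -> quantify -> ping-pong ->
divergence -> compare, over one or more samples from a single config.

One :class:`RunConfig` names the sample FASTQ files, the consensus and
ncRNA references and every threshold (all defaulting to the standard
values: >18 nt length, 80% of bases at Q20, 25-CPM floor, 10-fold
asymmetry line). Reads are mapped once at the permissive 3-mismatch
stratum; counting keeps alignments within ``max_mismatches`` (default
0, i.e. perfect match - equivalent to mapping at that stratum because
only best-stratum hits are reported), while ping-pong signatures and
divergence profiles use the permissive alignments so that reads
carrying a biogenesis-derived base change are not lost. Re-running an
identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import AsymmetryReport, fold_change_and_call
from .divergence import coverage_track, mismatch_profile, STRATA
from .errors import PipelineStageError
from .io import ConsensusLibrary, read_fastq
from .mapper import ReferenceIndex, map_reads
from .pingpong import pingpong_stats
from .preprocess import preprocess_reads
from .quantify import CountMatrix, classify_and_count, merge_samples, size_class
from .simulate import TRUSEQ_SMALL_RNA_ADAPTER, load_bundled_contaminants

__all__ = ["RunConfig", "SampleResult", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)

PERMISSIVE_MISMATCHES = 3


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    samples: dict[str, str]  # sample name -> FASTQ path
    consensus_fasta: str
    ncrna_fasta: Optional[str] = None  # None -> bundled synthetic contaminant set
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    min_len: int = 18  # exclusive
    q_threshold: int = 20
    q_fraction: float = 0.8
    floor_cpm: float = 25.0
    fold_threshold: float = 10.0
    epsilon_cpm: float = 1.0
    max_mismatches: int = 0  # counting stratum; mapping itself is at 3
    denominator: str = "mapped"  # 'mapped' reads or all 'retained' reads
    compare_class: str = "piRNA"
    comparisons: Optional[list[tuple[str, str]]] = None  # default: all ordered pairs
    out_dir: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "comparisons" in data and data["comparisons"] is not None:
            data["comparisons"] = [tuple(p) for p in data["comparisons"]]
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["comparisons"] is not None:
            d["comparisons"] = [list(p) for p in d["comparisons"]]
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class SampleResult:
    name: str
    report: "PreprocessReport"
    mapping: "MappingResult"
    pingpong: dict[str, "PingPongStats"]
    divergence: dict[str, dict]
    coverage: dict[str, "CoverageTrack"]


@dataclass
class PipelineResult:
    config: RunConfig
    samples: dict[str, SampleResult]
    matrix: CountMatrix  # floored, multi-sample
    comparisons: dict[tuple[str, str], AsymmetryReport]
    manifest: dict


def _load_references(config: RunConfig):
    try:
        library = ConsensusLibrary.from_fasta(config.consensus_fasta)
    except OSError as exc:
        raise PipelineStageError("load_consensus", str(exc)) from exc
    if config.ncrna_fasta is None:
        ncrna = load_bundled_contaminants()
    else:
        try:
            ncrna = ConsensusLibrary.from_fasta(config.ncrna_fasta, category="ncRNA")
        except OSError as exc:
            raise PipelineStageError("preprocess", f"ncRNA library: {exc}") from exc
    return library, ncrna


def _process_sample(name: str, fastq: str, config: RunConfig,
                    library: ConsensusLibrary, index: ReferenceIndex,
                    ncrna: ConsensusLibrary):
    try:
        raw_reads = read_fastq(fastq)
        retained, report = preprocess_reads(
            raw_reads, config.adapter, ncrna,
            min_len=config.min_len, q_threshold=config.q_threshold,
            q_fraction=config.q_fraction,
        )
    except OSError as exc:
        raise PipelineStageError("preprocess", f"sample '{name}': {exc}") from exc

    mapping = map_reads(retained, index, max_mismatches=PERMISSIVE_MISMATCHES)
    sequences = {r.id: r.sequence for r in retained}

    # piRNA-class permissive alignments per feature, for ping-pong,
    # divergence and coverage.
    by_feature: dict[str, list] = {f: [] for f in library.names()}
    for a in mapping.alignments:
        if size_class(a.length) == "piRNA":
            by_feature[a.feature].append(a)

    pingpong = {}
    divergence = {}
    coverage = {}
    denominator = float(mapping.mapped_reads) if mapping.mapped_reads else 1.0
    for feature in library.names():
        alns = by_feature[feature]
        if not alns:
            continue
        pingpong[feature] = pingpong_stats(feature, alns, sequences)
        feature_read_ids = sorted({a.read_id for a in alns})
        weights = {}
        for a in alns:
            weights[a.read_id] = weights.get(a.read_id, 0.0) + a.weight
        divergence[feature] = mismatch_profile(
            [(rid, sequences[rid]) for rid in feature_read_ids],
            feature, library, weights=weights,
        )
        coverage[feature] = coverage_track(
            alns, feature, len(library[feature]), denominator
        )
    return SampleResult(name, report, mapping, pingpong, divergence, coverage)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage for every sample; optionally write a report bundle."""
    library, ncrna = _load_references(config)
    index = ReferenceIndex(library)

    sample_results: dict[str, SampleResult] = {}
    single_matrices = []
    for name, fastq in config.samples.items():
        logger.info("processing sample %s", name)
        res = _process_sample(name, fastq, config, library, index, ncrna)
        sample_results[name] = res
        counted = [a for a in res.mapping.alignments
                   if a.mismatches <= config.max_mismatches]
        counted_ids = {a.read_id for a in counted}
        if config.denominator == "retained":
            denominator = res.report.retained
        else:
            denominator = len(counted_ids)
        if denominator == 0:
            raise PipelineStageError("quantify", f"sample '{name}': no mapped reads")
        single_matrices.append(
            classify_and_count(counted, name, denominator, features=library.names())
        )

    matrix = merge_samples(single_matrices).normalize_and_floor(config.floor_cpm)

    pairs = config.comparisons
    if pairs is None:
        names = list(config.samples)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    comparisons = {}
    for a, b in pairs:
        comparisons[(a, b)] = fold_change_and_call(
            matrix, a, b, size_class=config.compare_class,
            threshold=config.fold_threshold, epsilon=config.epsilon_cpm,
        )

    manifest = {
        "pirnatools_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "stage_counts": {n: list(r.report.stages()) for n, r in sample_results.items()},
        "mapped_reads": {n: r.mapping.mapped_reads for n, r in sample_results.items()},
        "counted_denominators": {
            s: float(matrix.denominators[s]) for s in matrix.samples
        },
    }

    result = PipelineResult(config, sample_results, matrix, comparisons, manifest)
    if config.out_dir is not None:
        _write_bundle(result, Path(config.out_dir))
    return result


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, res in result.samples.items():
        res.report.to_tsv(out_dir / f"{name}.preprocess.tsv")
        _write_pingpong(res, out_dir / f"{name}.pingpong.tsv")
        _write_divergence(res, out_dir / f"{name}.divergence.tsv")
        _write_coverage(res, out_dir / f"{name}.coverage.tsv")
    result.matrix.to_tsv(out_dir / "counts.tsv")
    for (a, b), report in result.comparisons.items():
        report.to_tsv(out_dir / f"compare_{a}_vs_{b}.tsv")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_pingpong(res: SampleResult, path) -> None:
    rows = [res.pingpong[f].to_row() for f in sorted(res.pingpong)]
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_divergence(res: SampleResult, path) -> None:
    with open(path, "w") as fh:
        strata = [str(s) for s in STRATA]
        fh.write("feature\torientation\t" + "\t".join(strata) + "\n")
        for feature in sorted(res.divergence):
            for orient in ("sense", "antisense"):
                prof = res.divergence[feature][orient]
                vals = "\t".join(f"{prof.masses[s]:.6g}" for s in STRATA)
                fh.write(f"{feature}\t{orient}\t{vals}\n")


def _write_coverage(res: SampleResult, path) -> None:
    # BedGraph-style runs of equal depth, per strand.
    with open(path, "w") as fh:
        fh.write("feature\tstart\tend\tdepth\tstrand\n")
        for feature in sorted(res.coverage):
            track = res.coverage[feature]
            for strand, depths in (("+", track.sense), ("-", track.antisense)):
                start = 0
                for i in range(1, len(depths) + 1):
                    if i == len(depths) or depths[i] != depths[start]:
                        if depths[start] != 0.0:
                            fh.write(f"{feature}\t{start}\t{i}\t"
                                     f"{depths[start]:.6g}\t{strand}\n")
                        start = i
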