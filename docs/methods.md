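# Methods

This note documents the models, conventions and numerical choices behind
pirnatools: what each stage computes, which parameters matter and why
their defaults are what they are, what the synthetic-data generator does
and does not emulate, and the design decisions taken where more than one
reasonable convention exists.

## Scope and model

The package analyses small-RNA sequencing libraries against a library of
TE/repeat consensus sequences (optionally transcripts, for genic piRNA
profiling). Two size classes carry the biology: 21-nt siRNAs and
23–29-nt piRNAs; all other lengths are tallied as "other" and excluded
from class totals. All coordinates are 0-based; antisense placements
report their 5′ end in plus-strand consensus coordinates, which is the
convention the ping-pong overlap definition needs.

## Pre-processing

1. **Adapter trimming.** The leftmost position where a prefix of the 3′
   adapter (minimum overlap 5 nt, at most 1 mismatch) spans the rest of
   the read is the insert boundary. Reads with no adapter hit are
   discarded by default (configurable), as is an empty insert. The
   default adapter is the Illumina TruSeq small-RNA 3′ adapter; it is a
   plain argument, not an assumption.
2. **Length filter.** Strictly greater than 18 nt: an 18-nt insert is
   removed, a 19-nt insert kept. The strict reading is deliberate and
   tested at the boundary.
3. **Quality filter.** At least 80 % of bases at Phred ≥ 20, with ≥ on
   both comparisons, so a read at exactly 80 % passes.
4. **ncRNA subtraction.** A read is removed when its sequence is an
   exact substring of any rRNA/tRNA/snRNA/miRNA reference on either
   strand. Exact matching keeps the subtraction consistent with the
   perfect-match stringency used for counting. An empty contaminant
   library logs a warning and skips the stage rather than failing.

The stage ledger (input, adapter-trimmed, length-pass, quality-pass,
ncRNA-subtracted, retained) is monotone non-increasing by construction
and is written with every pipeline run.

## Mapping

Reads are placed on every consensus, both strands, by Hamming distance
only (no indels), and only the best stratum (minimal mismatch count
m\* ≤ max, with max ∈ 0…3) is reported. A read with k best-stratum
placements contributes weight 1/k to each, so multi-mapping families
conserve total read mass. An N in the read or the reference always
counts as a mismatch; a read whose minimal distance exceeds the cap is
unmapped.

The implementation seeds candidates by the pigeonhole principle — the
query is split into max+1 contiguous segments; any placement within the
budget contains at least one mismatch-free segment, whose prefix k-mer
(k ≤ 8) must occur exactly in the reference — and verifies candidates
with vectorized Hamming counting. This is exact, not heuristic: the
test suite asserts set equality against a brute-force sliding-window
scan on thousands of random instances, including N-containing reads.
Segments whose prefix contains an N are skipped as seeds; this is safe
because a mismatch-free segment can never contain an N.

## Quantification

Counts accumulate alignment weights per (feature, size class, strand).
CPM = raw × 10⁶ / denominator, where the per-sample denominator is by
default the number of retained reads that mapped at the counting
stratum (configurable to all retained reads). The low-expression floor
(default 25 CPM) applies to strand-summed CPM per feature and class:
floored entries become *absent* — serialized as NA, carried as NaN —
which is distinct from an expressed zero, so that downstream fold-change
logic can skip features absent in both samples but treat one-sided
absence as zero. Applying the floor per element rather than per strand
is a choice; the per-strand alternative would floor weakly expressed
antisense complements of strongly expressed features, which is not what
a per-element expression cutoff means.

The pipeline maps once at the permissive 3-mismatch stratum and filters
to the configured counting stratum (default 0, i.e. perfect match).
Because only best-stratum hits are ever reported, filtering an
mm ≤ 3 run to mm ≤ 0 yields exactly the hit set of an mm ≤ 0 run, so
the single mapping pass is a pure optimization. Ping-pong signatures,
divergence profiles and coverage tracks use the permissive alignments:
the 1U/10A biogenesis biases are real base changes on the read, and a
perfect-match requirement would silently discard a large fraction of
exactly the reads those statistics describe.

## Ping-pong signature

With both 5′ ends in plus-strand coordinates, the overlap of a sense
alignment at s and an antisense alignment at a is d = a − s + 1; d = 10
is the signal. Histogram mass at each d ∈ 1…20 is the sum of
weight products over qualifying pairs, computed by position-indexed
aggregation (Σ_s w⁺(s)·w⁻(s+d−1)), which is algebraically identical to
the all-pairs sum and is tested for exact equality against an explicit
O(n²) enumeration. Two pair counts are reported, because "number of
ping-pong pairs" is ambiguous: the read-weighted mass at d = 10 and the
number of distinct (sense 5′, antisense 5′) position pairs.

The z-score standardizes the d = 10 bin against the other 19 bins
(sample standard deviation, ddof = 1; the excluded-bin set is
configurable). Degenerate cases are explicit: a zero-spread background
with the signal equal to the background mean gives z = 0 (the uniform
histogram); a zero-spread background with a differing signal is
reported as NaN with a degenerate flag, never as infinity.

The 1U bias is the weighted fraction of antisense piRNA mass whose read
begins with T (U in RNA space); the 10A bias is the weighted fraction of
sense piRNA mass with A at read position 10. Both need the trimmed read
sequences and are NaN when those are not supplied.

## Divergence and coverage

Each read's stratum is its minimal Hamming distance over all windows
and both strands of the feature's consensus (0–3, else "unmapped at
3"), computed by a direct vectorized sliding-window scan — the
definition itself, so no separate oracle is possible beyond the
cross-check against the seeded aligner, which the tests perform.
Orientation is the strand achieving the minimum, ties resolving to
sense. The profile reports the full stratum distribution; "modern copy"
attribution is left to the report layer, with perfect match as the
default reading. Indels are not modeled anywhere, so a read from a copy
with an indel inflates its apparent stratum.

Coverage tracks add alignment weights over every aligned base, sense
and antisense separately, scaled to reads per million (denominator =
mapped retained reads). Pipeline output is a BedGraph-style run-length
TSV.

## Strain comparison

Fold change per feature: (CPM_a + ε)/(CPM_b + ε) with ε = 1 CPM on both
terms, making folds finite when one side is absent; features absent in
both samples are skipped, absent in one are treated as zero. A call is
made at fold ≥ threshold (default 10) — the ≥ is deliberate so a
boundary feature counts as exceeding. The pseudocount and threshold are
arguments; antisymmetry (swapping samples inverts folds and exchanges
call labels exactly) is a tested invariant.

Venn-style intersections return all 2^k − 1 exclusive regions with
member lists, in a deterministic order. Spearman correlation uses
average ranks for ties (scipy); a constant vector yields a flagged
degenerate result rather than an error or a fabricated value. For
scatter output, log10(CPM + ε) coordinates are written, but ranks make
the correlation itself ε-insensitive for positive data.

## Wet-lab calculators

Relative expression: fold = 2^−ΔΔCt with ΔCt = Ct_target − Ct_reference
and an assumed amplification efficiency of 2 (no efficiency
correction). Replicates pair positionally (a single calibrator
broadcasts) and report mean and SEM (sample s.d. / √n) over
per-replicate folds. ChIP recovery: percent input =
100 × 2^(Ct_input − log2(1/f) − Ct_IP) where f is the input chromatin
fraction — f has no default and must be supplied, since it is a
property of the experiment; enrichment is the ratio of percent-input at
the target locus to a control locus and is invariant to f when both
records share it.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with per-read ground truth, and is the basis of every recovery test.
Defaults describe one simulated ovarian library:

| parameter | default | meaning |
|---|---|---|
| size_distribution | 21 nt: 0.25; 23–29 nt peak at 25–26 | siRNA peak plus a piRNA hump |
| sense_fraction | 0.5 | strand of the source window |
| pingpong_fraction | 0.3 | antisense piRNAs emitted with a sense partner overlapping 10 nt |
| divergence_mix | 0: 0.70, 1: 0.15, 2: 0.10, 3: 0.05 | planted substitutions per read; a "diverged" class plants max(5, 0.2·len) |
| contaminant_fraction | 0.05 | reads drawn as exact substrings of the bundled synthetic ncRNA set |
| u1_bias / a10_bias | 0.8 | probability of forcing 5′ U (antisense) / position-10 A (sense partners) |
| junk_fraction | 0.0 | uniformly Q10 reads that must fail the quality filter |
| adapter | TruSeq small-RNA 3′ | appended to every insert |

Library sizes in tests and in the acceptance script are 5,000–30,000
reads per sample — the package's working scale for desk-size references;
real libraries are orders of magnitude deeper, which narrows all
sampling noise but changes no logic. Ping-pong partners are placed with
the sense 5′ at s and the antisense 5′ at s + 9, the exact 10-nt overlap
geometry. The truth table records the *realized* mismatch count of each
insert (planted substitutions plus any bias-forced base change), so
truth-based recovery checks remain exact even when a bias substitution
changes a read's stratum; recovery simulations that target the
divergence mix itself disable the 1U bias so the planted strata are the
realized strata. The strand ratio and size-distribution shape are free
parameters of the generator, not estimates of any particular real
library. Qualities are Phred+33: Q30 bases with ~5 % Q10 (capped at
15 % so genuine reads always clear the 80 %-at-Q20 filter).

What the generator does **not** emulate — and what passing recovery
tests therefore do not show about real data: positional sequencing-error
profiles (substitutions are uniform), indels, ligation and PCR biases,
genome-scale insertion context (reads come from consensuses, not from
copies embedded in a genome), and realistic ncRNA abundance structure
(the bundled contaminant set is 20 synthetic sequences, clearly labelled
synthetic, shipped so the subtraction stage is exercised without any
external database).

## Determinism and reproducibility

Every stochastic step flows from a single seeded NumPy generator;
identical profiles give byte-identical FASTQ and truth files, and
identical pipeline configs give byte-identical TSV bundles (tested).
The run manifest records package and library versions, a SHA-256 of the
config, and all stage counts.

## Known limitations

- Hamming-only alignment: indel-bearing copies inflate divergence
  strata and can lose alignments entirely.
- The 25-CPM floor, the 10-fold line and ε = 1 CPM are conventions, not
  estimates; all are configurable and logged.
- No between-sample normalization beyond CPM — comparisons assume
  library-level scaling is sufficient.
- Phasing signatures and protein-specific (Aub/Ago3) read attribution
  are out of scope; no IP data model exists here.
- The aligner is built for desk-scale references (≲ 1 Mb total); it is
  exact at any scale but not engineered for whole-genome use.
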