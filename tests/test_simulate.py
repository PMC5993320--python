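"""Generator properties: determinism, planted structure, ground-truth fidelity."""

import io

import numpy as np
import pandas as pd
import pytest

from pirnatools import (
    SimProfile,
    generate_consensus_library,
    reverse_complement,
    simulate_strain_reads,
)
from pirnatools.errors import ConfigurationError, ParameterError


def uniform_profile(library, **overrides):
    names = library.names()
    kwargs = dict(te_abundances={n: 1.0 / len(names) for n in names})
    kwargs.update(overrides)
    return SimProfile(**kwargs)


def fastq_bytes(reads) -> bytes:
    buf = io.StringIO()
    for r in reads:
        buf.write(f"@{r.id}\n{r.sequence}\n+\n"
                  + "".join(chr(q + 33) for q in r.quality) + "\n")
    return buf.getvalue().encode()


class TestConsensusLibrary:
    def test_exact_length_and_name_uniqueness(self):
        lib = generate_consensus_library(1, (749, 749), gc=0.5, seed=1)
        assert len(lib) == 1
        assert len(lib[lib.names()[0]]) == 749

    def test_deterministic_fasta(self, tmp_path):
        a = generate_consensus_library(5, (300, 600), seed=7)
        b = generate_consensus_library(5, (300, 600), seed=7)
        pa, pb = tmp_path / "a.fasta", tmp_path / "b.fasta"
        a.to_fasta(pa)
        b.to_fasta(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_gc_content_matches_request(self):
        lib = generate_consensus_library(3, (1000, 1000), gc=0.25, seed=3)
        gcs = [
            (lib[n].count("G") + lib[n].count("C")) / len(lib[n])
            for n in lib.names()
        ]
        assert 0.20 <= np.mean(gcs) <= 0.30

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_te=0), dict(n_te=2, gc=0.0), dict(n_te=2, gc=1.2),
         dict(n_te=2, length_range=(50, 40)), dict(n_te=2, length_range=(10, 20))],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            generate_consensus_library(**kwargs)


class TestStrainReads:
    def test_byte_identical_for_fixed_seed(self, tiny_library):
        prof = uniform_profile(tiny_library, n_reads=300, seed=9)
        ra, ta = simulate_strain_reads(tiny_library, prof)
        rb, tb = simulate_strain_reads(tiny_library, prof)
        assert fastq_bytes(ra) == fastq_bytes(rb)
        pd.testing.assert_frame_equal(ta, tb)

    def test_full_pairing_gives_exact_10nt_overlaps(self, tiny_library):
        prof = uniform_profile(
            tiny_library, n_reads=200, seed=11,
            pingpong_fraction=1.0, sense_fraction=0.5, contaminant_fraction=0.0,
        )
        _, truth = simulate_strain_reads(tiny_library, prof)
        anti = truth[(truth.strand == "-") & truth.pingpong]
        sense = truth[(truth.strand == "+") & truth.pingpong]
        # every flagged antisense read has a flagged sense partner with
        # 5'-5' distance exactly 10 on the same feature
        assert len(anti) > 0
        for _, row in anti.iterrows():
            partners = sense[(sense.feature == row.feature)
                             & (sense.five_prime_pos == row.five_prime_pos - 9)]
            assert len(partners) >= 1

    def test_zero_contaminant_fraction(self, tiny_library):
        prof = uniform_profile(tiny_library, n_reads=200, seed=2,
                               contaminant_fraction=0.0)
        _, truth = simulate_strain_reads(tiny_library, prof)
        assert not truth.contaminant.any()

    def test_divergence_mix_recovered_in_truth(self, tiny_library):
        prof = uniform_profile(
            tiny_library, n_reads=5000, seed=3,
            divergence_mix={0: 0.1, 3: 0.9},
            contaminant_fraction=0.0, u1_bias=0.0, a10_bias=0.0,
            pingpong_fraction=0.0,
        )
        _, truth = simulate_strain_reads(tiny_library, prof)
        frac0 = (truth.mismatches == 0).mean()
        assert abs(frac0 - 0.10) <= 0.02

    def test_truth_mirrors_reads_one_to_one(self, tiny_library):
        prof = uniform_profile(tiny_library, n_reads=150, seed=4)
        reads, truth = simulate_strain_reads(tiny_library, prof)
        assert list(truth.read_id) == [r.id for r in reads]
        # insert (sequence minus adapter) matches the recorded origin
        for read, (_, row) in zip(reads[:40], truth.iterrows()):
            insert = read.sequence[: len(read.sequence) - len(prof.adapter)]
            if row.contaminant:
                continue
            cons = tiny_library[row.feature]
            if row.strand == "+":
                window = cons[row.five_prime_pos : row.five_prime_pos + len(insert)]
                back = insert
            else:
                window = cons[row.five_prime_pos - len(insert) + 1 : row.five_prime_pos + 1]
                back = reverse_complement(insert)
            mism = sum(1 for a, b in zip(back, window) if a != b)
            assert mism == row.mismatches

    def test_feature_mass_conservation(self, tiny_library):
        abundances = dict(zip(tiny_library.names(), (0.5, 0.3, 0.2)))
        prof = SimProfile(te_abundances=abundances, n_reads=10_000, seed=6,
                          contaminant_fraction=0.0, pingpong_fraction=0.0)
        _, truth = simulate_strain_reads(tiny_library, prof)
        n = len(truth)
        for name, p in abundances.items():
            se = np.sqrt(p * (1 - p) / n)
            observed = (truth.feature == name).mean()
            assert abs(observed - p) <= 3 * se + 1e-12

    def test_nonjunk_reads_pass_quality_filter(self, tiny_library):
        prof = uniform_profile(tiny_library, n_reads=400, seed=8,
                               contaminant_fraction=0.0)
        reads, _ = simulate_strain_reads(tiny_library, prof)
        for r in reads:
            insert_q = r.quality[: len(r.quality) - len(prof.adapter)]
            good = sum(1 for q in insert_q if q >= 20)
            assert good >= 0.8 * len(insert_q)

    def test_unknown_feature_rejected(self, tiny_library):
        with pytest.raises(ConfigurationError):
            simulate_strain_reads(
                tiny_library,
                SimProfile(te_abundances={"nope": 1.0}, n_reads=10, seed=0),
            )

    @pytest.mark.parametrize(
        "overrides",
        [dict(n_reads=0), dict(adapter="ACGT"),
         dict(size_distribution={22: 1.0}),
         dict(divergence_mix={0: 0.5, 7: 0.5}),
         dict(te_abundances={"a": 0.4, "b": 0.4})],
    )
    def test_invalid_profiles_rejected(self, overrides):
        kwargs = dict(te_abundances={"a": 1.0}, n_reads=10, seed=0)
        kwargs.update(overrides)
        with pytest.raises(ParameterError):
            SimProfile(**kwargs)
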