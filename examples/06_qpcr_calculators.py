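"""qPCR relative expression (2^-ddCt) and ChIP-qPCR percent-input.

Deterministic calculators: relative expression of a transcript
normalized to a housekeeping gene (rp49), and heterochromatin-mark
enrichment at a repeat locus from IP and input Ct values.
"""

from pirnatools import (
    ChipRecord,
    CtRecord,
    chip_enrichment,
    ddct,
    ddct_replicates,
)

# A target amplifying 2 cycles earlier than in the calibrator, with the
# reference gene unchanged, is 4-fold over-expressed.
fold = ddct(CtRecord("M_strain", 20, 15), CtRecord("N_strain", 22, 15))
print(f"single-pair fold change: {fold}")

# Three biological replicates with per-replicate folds {2, 4, 8}.
summary = ddct_replicates(
    [CtRecord("M", 19, 15), CtRecord("M", 18, 15), CtRecord("M", 17, 15)],
    [CtRecord("N", 20, 15)],
)
print(f"replicate folds {summary.folds}: mean {summary.mean:.3f}, SEM {summary.sem:.3f}")

# H3K9me3 ChIP: 1% input; the repeat locus recovers more chromatin than
# the active control locus.
repeat = ChipRecord("repeat_315", ip_ct=24.0, input_ct=20.0, input_fraction=0.01)
control = ChipRecord("rp49", ip_ct=26.5, input_ct=20.0, input_fraction=0.01)
result = chip_enrichment(repeat, control)
print(f"percent input at repeat : {result.percent_input_target:.4f}%")
print(f"percent input at rp49   : {result.percent_input_control:.4f}%")
print(f"enrichment over control : {result.enrichment:.2f}")
# Enrichment > 2.5 at a repeat locus is the conventional mark of a
# heterochromatinized piRNA-producing region.
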