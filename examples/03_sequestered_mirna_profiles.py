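"""Sequence features of sequestered miRNAs vs the rest.

Simulates a genome, finds which miRNAs are sequestered by at least one
mimic, and compares their length distribution, 5' terminal composition
and 5'-anchored 15-nt positional profile (with per-position information
content in bits) against the non-sequestered control set.
"""
from mimicscan import SimConfig, generate, scan_transcriptome
from mimicscan.profiles import compare_sets, positional_profile, split_sequestered

sim = generate(SimConfig(seed=8, n_mirnas=30, n_transcripts=60, n_planted_mimics=15,
                         n_decoys=0, n_planted_targets=0, n_decoy_targets=0,
                         n_libraries=0))
table = scan_transcriptome(sim.mirnas, sim.transcripts)
sequestered_ids = sorted(set(table[table["accepted"]]["mirna_id"]))
sequestered, control = split_sequestered(sim.mirnas, sequestered_ids)
print(f"{len(sequestered)} sequestered vs {len(control)} control miRNAs\n")

tables = compare_sets(sequestered, control)
print(tables["length"].to_string(index=False), "\n")
print(tables["terminal_5p"].to_string(index=False), "\n")

profile = positional_profile(sequestered, "five_prime")
print(profile.to_frame().round(3).to_string(index=False))
# information_bits is R_p = 2 - H_p: 2 bits at a fully conserved position,
# 0 at a uniform one. Position 1 scores high here because the generator
# starts 70% of miRNAs with U, mirroring the 5'-U bias of plant miRNAs.
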