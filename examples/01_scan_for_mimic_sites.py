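"""Call a target-mimic site on a transcript.

Builds a 21-nt miRNA and a transcript carrying a perfect reverse-
complement site interrupted by a 3-nt bulge opposite miRNA positions
10-11 (the geometry of the canonical IPS1-miR399 interaction), scans the
transcript, and prints the accepted duplex with its rule diagnostics.
"""
import numpy as np

from mimicscan import MiRNA, Transcript, reverse_complement, scan_transcript

rng = np.random.default_rng(0)
random_rna = lambda n: "".join("ACGU"[i] for i in rng.integers(0, 4, size=n))

mirna = MiRNA("mir-demo", "U" + random_rna(20))
rc = reverse_complement(mirna.sequence)
site = rc[:11] + "CUA" + rc[11:]  # 3-nt target-side bulge between positions 10 and 11
transcript = Transcript("tr-demo", "gene-demo", random_rna(60) + site + random_rna(60))

for hit in scan_transcript(mirna, transcript):
    a, d = hit.alignment, hit.diagnostics
    print(
        f"site {a.site_start}-{a.site_end}  bulge {a.bulge_len} nt between "
        f"miRNA positions {a.bulge_insertion_point} and {a.bulge_insertion_point + 1}"
    )
    print(
        f"  non-middle mismatches {d.nonmiddle_mismatches} (longest run {d.max_run}), "
        f"middle mismatches {d.middle_mismatches}, G:U pairs {d.gu_pairs}"
    )
# The planted site is returned at positions 61-84: the transcript can bind
# (sequester) the miRNA, while the central bulge blocks cleavage there.
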