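from __future__ import annotations

import numpy as np
import pytest

from mimicscan.models import MiRNA, Transcript, TranscriptStructure, reverse_complement
from mimicscan.simulate import SimConfig, generate

BASES = "ACGU"


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def small_sim():
    """A compact synthetic genome shared by read-only tests."""
    return generate(
        SimConfig(
            seed=7,
            n_mirnas=8,
            n_transcripts=20,
            n_planted_mimics=6,
            n_decoys=6,
            n_planted_targets=4,
            n_decoy_targets=2,
        )
    )


@pytest.fixture()
def bulged_mimic_fixture():
    """A 21-nt miRNA and a transcript carrying its canonical mimic site.

    The site is a perfect reverse complement of the miRNA with a 3-nt
    bulge between the partners of positions 10 and 11 — the geometry that
    sequesters the miRNA without permitting cleavage.
    """
    rng = np.random.default_rng(42)
    mirna = MiRNA("mir-21mer", "U" + random_rna(rng, 20))
    rc = reverse_complement(mirna.sequence)
    site = rc[:11] + "CUU" + rc[11:]  # bulge between partners of 10 and 11
    upstream, downstream = random_rna(rng, 40), random_rna(rng, 40)
    transcript = Transcript("tmimic", "gmimic", upstream + site + downstream)
    site_start = len(upstream) + 1
    return mirna, transcript, site_start, len(site)


@pytest.fixture()
def structured_transcript():
    rng = np.random.default_rng(3)
    return Transcript(
        id="t1",
        gene_id="g1",
        sequence=random_rna(rng, 500),
        structure=TranscriptStructure(utr5=(1, 100), cds=(101, 400), utr3=(401, 500)),
    )
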