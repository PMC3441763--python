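from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mimicscan.annotate import (
    assign_region,
    dedup_sites,
    distribution_summary,
    per_gene_tally,
)
from mimicscan.models import Transcript, TranscriptStructure

from conftest import random_rna

STRUCT = TranscriptStructure(utr5=(1, 100), cds=(101, 400), utr3=(401, 500))


def _mimic_rows(rows):
    columns = ["mirna_id", "transcript_id", "site_start", "site_end", "accepted"]
    return pd.DataFrame(rows, columns=columns)


class TestAssignRegion:
    @pytest.mark.parametrize(
        "interval,expected",
        [
            ((10, 35), "5UTR"),
            ((150, 175), "CDS"),
            ((420, 445), "3UTR"),
            ((90, 115), "5UTR-CDS"),
            ((390, 415), "CDS-3UTR"),
            ((101, 400), "CDS"),
        ],
    )
    def test_containment_and_junctions(self, interval, expected):
        assert assign_region(interval, STRUCT) == expected

    def test_double_junction_takes_majority_with_cds_tiebreak(self):
        tiny_cds = TranscriptStructure(utr5=(1, 100), cds=(101, 120), utr3=(121, 500))
        # spans both junctions: 5 nt in 5'UTR, 20 in CDS, 5 in 3'UTR
        assert assign_region((96, 125), tiny_cds) == "CDS"
        # equal overlap everywhere -> tie broken toward CDS
        equal = TranscriptStructure(utr5=(1, 10), cds=(11, 20), utr3=(21, 500))
        assert assign_region((1, 30), equal) == "CDS"
        # spans both junctions with the majority in the 3'UTR
        assert assign_region((96, 145), tiny_cds) == "3UTR"

    def test_site_outside_transcript_errors(self):
        with pytest.raises(ValueError):
            assign_region((480, 520), STRUCT)


class TestDedup:
    def test_family_members_collapse_with_multiplicity(self):
        table = _mimic_rows(
            [
                ("miR395a", "t1", 50, 73, True),
                ("miR395b", "t1", 50, 73, True),
                ("miR395a", "t1", 200, 223, True),
            ]
        )
        unique = dedup_sites(table)
        assert len(unique) == 2
        first = unique[unique["site_start"] == 50].iloc[0]
        assert first["multiplicity"] == 2
        assert first["mirna_ids"] == "miR395a,miR395b"

    def test_non_identical_overlaps_stay_separate(self):
        table = _mimic_rows(
            [("a", "t1", 50, 73, True), ("a", "t1", 51, 74, True)]
        )
        assert len(dedup_sites(table)) == 2

    def test_idempotent_and_empty(self):
        table = _mimic_rows([("a", "t1", 50, 73, True)])
        once = dedup_sites(table)
        again = once.groupby(["transcript_id", "site_start", "site_end"]).size()
        assert (again == 1).all()
        assert dedup_sites(_mimic_rows([])).empty

    def test_rejected_rows_excluded(self):
        table = _mimic_rows([("a", "t1", 50, 73, False)])
        assert dedup_sites(table).empty


def _transcripts_with_lengths(n, u5, cds, u3, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        out.append(
            Transcript(
                id=f"t{k}",
                gene_id=f"g{k // 2}",  # two splice variants per gene
                sequence=random_rna(rng, u5 + cds + u3),
                structure=TranscriptStructure(
                    utr5=(1, u5), cds=(u5 + 1, u5 + cds), utr3=(u5 + cds + 1, u5 + cds + u3)
                ),
            )
        )
    return out


class TestDistribution:
    def test_hand_computed_percentages_and_densities(self):
        # 2 transcripts, 5'UTR 200 nt each, CDS 300, 3'UTR 100
        transcripts = _transcripts_with_lengths(2, 200, 300, 100)
        unique = pd.DataFrame(
            {
                "transcript_id": ["t0", "t0", "t1", "t1"],
                "site_start": [10, 190, 250, 550],
                "site_end": [33, 213, 273, 573],
                "multiplicity": [1, 1, 1, 1],
                "mirna_ids": ["a", "b", "c", "d"],
            }
        )
        # regions: [10,33] 5UTR; [190,213] 5UTR-CDS; [250,273] CDS; [550,573] 3UTR
        summary = distribution_summary(unique, transcripts)
        assert summary.n_unique_sites == 4
        assert summary.percentages["5UTR"] == pytest.approx(25.0)
        assert summary.percentages["5UTR-CDS"] == pytest.approx(25.0)
        assert sum(summary.percentages.values()) == pytest.approx(100.0, abs=1e-9)
        assert summary.densities["5UTR"] == pytest.approx(1 / 400 * 1000, abs=1e-9)
        assert summary.densities["CDS"] == pytest.approx(1 / 600 * 1000, abs=1e-9)
        assert summary.densities["3UTR"] == pytest.approx(1 / 200 * 1000, abs=1e-9)

    def test_doubling_region_lengths_halves_densities(self):
        unique = pd.DataFrame(
            {
                "transcript_id": ["t0"],
                "site_start": [10],
                "site_end": [33],
                "multiplicity": [1],
                "mirna_ids": ["a"],
            }
        )
        base = distribution_summary(unique, _transcripts_with_lengths(2, 100, 300, 100))
        doubled = distribution_summary(unique, _transcripts_with_lengths(2, 200, 600, 200))
        for region in ("5UTR", "CDS", "3UTR"):
            if base.densities[region]:
                assert doubled.densities[region] == pytest.approx(
                    base.densities[region] / 2
                )

    def test_all_cds_sites_give_full_cds_percentage(self):
        transcripts = _transcripts_with_lengths(1, 100, 300, 100)
        unique = pd.DataFrame(
            {
                "transcript_id": ["t0"] * 4,
                "site_start": [110, 150, 200, 250],
                "site_end": [133, 173, 223, 273],
                "multiplicity": [1] * 4,
                "mirna_ids": list("abcd"),
            }
        )
        summary = distribution_summary(unique, transcripts)
        assert summary.percentages["CDS"] == pytest.approx(100.0)
        assert summary.percentages["5UTR"] == 0.0

    def test_mimic_bearing_denominator_is_smaller(self):
        transcripts = _transcripts_with_lengths(4, 100, 300, 100)
        unique = pd.DataFrame(
            {
                "transcript_id": ["t0"],
                "site_start": [10],
                "site_end": [33],
                "multiplicity": [1],
                "mirna_ids": ["a"],
            }
        )
        all_t = distribution_summary(unique, transcripts, denominator="all")
        bearing = distribution_summary(unique, transcripts, denominator="mimic_bearing")
        assert bearing.densities["5UTR"] == pytest.approx(4 * all_t.densities["5UTR"])

    def test_per_gene_vs_per_transcript_tally(self):
        transcripts = _transcripts_with_lengths(4, 100, 300, 100)  # 2 genes
        unique = pd.DataFrame(
            {
                "transcript_id": ["t0", "t1"],
                "site_start": [10, 10],
                "site_end": [33, 33],
                "multiplicity": [1, 1],
                "mirna_ids": ["a", "a"],
            }
        )
        tally = per_gene_tally(unique, transcripts).set_index("level")
        assert tally.loc["transcript", "n_units_with_sites"] == 2
        assert tally.loc["gene", "n_units_with_sites"] == 1
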