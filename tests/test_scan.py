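from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mimicscan.models import (
    MimicRuleParams,
    MiRNA,
    Transcript,
    UnsupportedLengthError,
    reverse_complement,
)
from mimicscan.scan import (
    ScanParams,
    apply_mimic_rules,
    build_duplex,
    middle_region,
    scan_transcript,
    scan_transcriptome,
)

from conftest import random_rna
from oracle import oracle_accepted_intervals


class TestMiddleRegion:
    @pytest.mark.parametrize(
        "length,interval",
        [(19, (9, 11)), (20, (10, 11)), (21, (10, 12)),
         (22, (11, 12)), (23, (11, 13)), (24, (12, 13))],
    )
    def test_printed_table(self, length, interval):
        assert middle_region(length) == interval

    @pytest.mark.parametrize("length", [18, 25, 0])
    def test_out_of_table_lengths_error(self, length):
        with pytest.raises(UnsupportedLengthError):
            middle_region(length)


class TestBuildDuplex:
    def test_perfect_bulged_site_all_match(self, bulged_mimic_fixture):
        mirna, transcript, start, width = bulged_mimic_fixture
        a = build_duplex(mirna, transcript, start, 10, 3)
        assert set(a.pairing) == {"match"}
        assert a.site_interval == (start, start + width - 1)
        assert (a.bulge_insertion_point, a.bulge_len) == (10, 3)

    def test_insertion_outside_middle_rejected(self, bulged_mimic_fixture):
        mirna, transcript, start, _ = bulged_mimic_fixture
        with pytest.raises(ValueError, match="middle region"):
            build_duplex(mirna, transcript, start, 9, 3)

    def test_bulge_zero_rejected(self, bulged_mimic_fixture):
        mirna, transcript, start, _ = bulged_mimic_fixture
        with pytest.raises(ValueError, match="bulge"):
            build_duplex(mirna, transcript, start, 10, 0)

    def test_site_beyond_transcript_end_rejected(self, bulged_mimic_fixture):
        mirna, transcript, _, _ = bulged_mimic_fixture
        with pytest.raises(ValueError, match="beyond"):
            build_duplex(mirna, transcript, len(transcript) - 5, 10, 3)


def _mutate(site: str, width: int, L: int, i: int, positions, mirna_seq: str) -> str:
    """Force mismatches at given miRNA positions of a perfect bulged site."""
    anti = {"A": "C", "C": "A", "G": "A", "U": "C"}  # neither WC nor wobble
    chars = list(site)
    for p in positions:
        idx = width - p if p <= i else L - p
        chars[idx] = anti[mirna_seq[p - 1]]
    return "".join(chars)


class TestMimicRules:
    def _site(self, mirna, mutate_positions=()):
        rc = reverse_complement(mirna.sequence)
        site = rc[:11] + "GGG" + rc[11:]
        if mutate_positions:
            site = _mutate(site, 24, 21, 10, mutate_positions, mirna.sequence)
        t = Transcript("t", "g", "ACGU" * 5 + site + "ACGU" * 5)
        return build_duplex(mirna, t, 21, 10, 3)

    @pytest.fixture()
    def mirna(self):
        rng = np.random.default_rng(9)
        return MiRNA("m21", "U" + random_rna(rng, 20))

    def test_perfect_duplex_accepted(self, mirna):
        site = apply_mimic_rules(self._site(mirna))
        assert site.accepted and site.rejection_reasons == ()

    def test_five_scattered_mismatches_rejected_by_count(self, mirna):
        site = apply_mimic_rules(self._site(mirna, [1, 3, 5, 7, 15]))
        assert not site.accepted
        assert site.rejection_reasons == ("R2-count",)
        assert site.diagnostics.nonmiddle_mismatches == 5

    def test_run_of_three_rejected(self, mirna):
        site = apply_mimic_rules(self._site(mirna, [4, 5, 6]))
        assert site.rejection_reasons == ("R2-run",)
        assert site.diagnostics.max_run == 3

    def test_four_mismatches_in_two_runs_accepted(self, mirna):
        site = apply_mimic_rules(self._site(mirna, [4, 5, 8, 9]))
        assert site.accepted

    def test_two_nt_bulge_rejected(self, mirna):
        rc = reverse_complement(mirna.sequence)
        t = Transcript("t", "g", "ACGU" * 5 + rc[:11] + "GG" + rc[11:] + "ACGU" * 5)
        a = build_duplex(mirna, t, 21, 10, 2, enforce_geometry=False)
        assert apply_mimic_rules(a).rejection_reasons == ("R1-bulge",)

    def test_off_middle_insertion_rejected(self, mirna):
        rc = reverse_complement(mirna.sequence)
        t = Transcript("t", "g", "ACGU" * 5 + rc[:16] + "GGG" + rc[16:] + "ACGU" * 5)
        a = build_duplex(mirna, t, 21, 5, 3, enforce_geometry=False)
        assert "R1-position" in apply_mimic_rules(a).rejection_reasons

    def test_extra_indel_rejected(self, mirna):
        a = self._site(mirna)
        from dataclasses import replace

        assert apply_mimic_rules(replace(a, extra_indels=((4, 1),))).rejection_reasons == (
            "R3-indel",
        )

    def test_gu_mode_switch_changes_mismatch_count(self):
        # miRNA position 1 = G; put U opposite it: wobble pair
        mirna = MiRNA("mg", "G" + "A" * 20)
        rc = reverse_complement(mirna.sequence)
        site = rc[:11] + "GGG" + rc[11:]
        chars = list(site)
        chars[23] = "U"  # partner of position 1
        t = Transcript("t", "g", "ACGU" + "".join(chars) + "ACGU")
        a = build_duplex(mirna, t, 5, 10, 3)
        strict = apply_mimic_rules(a, MimicRuleParams(gu_counts_as_mismatch=True))
        lenient = apply_mimic_rules(a, MimicRuleParams(gu_counts_as_mismatch=False))
        assert strict.diagnostics.gu_pairs == lenient.diagnostics.gu_pairs == 1
        assert strict.diagnostics.nonmiddle_mismatches == 1
        assert lenient.diagnostics.nonmiddle_mismatches == 0

    def test_middle_mismatch_cap_optional(self, mirna):
        a = self._site(mirna, [11])  # middle position of a 21-mer
        assert apply_mimic_rules(a).accepted  # unlimited by default
        capped = apply_mimic_rules(a, MimicRuleParams(max_middle_mismatches=0))
        assert capped.rejection_reasons == ("middle-cap",)


class TestScanTranscript:
    def test_planted_site_recovered_and_matches_oracle(self, bulged_mimic_fixture):
        mirna, transcript, start, width = bulged_mimic_fixture
        sites = scan_transcript(mirna, transcript)
        intervals = {s.alignment.site_interval for s in sites}
        assert (start, start + width - 1) in intervals
        assert intervals == oracle_accepted_intervals(mirna.sequence, transcript.sequence)

    def test_transcript_too_short_yields_nothing(self):
        mirna = MiRNA("m", "U" * 21)
        assert scan_transcript(mirna, Transcript("t", "g", "ACGUACGUACGU")) == []

    def test_sense_copy_is_not_a_site(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            seq = random_rna(rng, 21)
            mirna = MiRNA("m", seq)
            t = Transcript("t", "g", random_rna(rng, 20) + seq + random_rna(rng, 20))
            got = {s.alignment.site_interval for s in scan_transcript(mirna, t)}
            assert got == oracle_accepted_intervals(seq, t.sequence)

    @pytest.mark.parametrize("gu_as_mismatch", [True, False])
    def test_oracle_equivalence_on_random_instances(self, gu_as_mismatch):
        rng = np.random.default_rng(17 if gu_as_mismatch else 18)
        params = ScanParams(rules=MimicRuleParams(gu_counts_as_mismatch=gu_as_mismatch))
        for _ in range(80):
            L = int(rng.integers(19, 25))
            mirna = MiRNA("m", random_rna(rng, L))
            t = Transcript("t", "g", random_rna(rng, int(rng.integers(L + 3, 61))))
            got = {s.alignment.site_interval for s in scan_transcript(mirna, t, params)}
            want = oracle_accepted_intervals(
                mirna.sequence, t.sequence, gu_is_mismatch=gu_as_mismatch
            )
            assert got == want

    def test_relaxing_mismatch_cap_is_monotone(self):
        rng = np.random.default_rng(23)
        mirna = MiRNA("m", random_rna(rng, 21))
        t = Transcript("t", "g", random_rna(rng, 400))
        previous: set = set()
        for cap in (0, 2, 4, 6, 8):
            params = ScanParams(rules=MimicRuleParams(max_nonmiddle_mismatches=cap))
            got = {s.alignment.site_interval for s in scan_transcript(mirna, t, params)}
            assert got >= previous
            previous = got


class TestScanTranscriptome:
    def test_deterministic_and_sorted(self, small_sim):
        t1 = scan_transcriptome(small_sim.mirnas, small_sim.transcripts)
        t2 = scan_transcriptome(small_sim.mirnas, small_sim.transcripts)
        pd.testing.assert_frame_equal(t1, t2)
        assert t1["mirna_id"].is_monotonic_increasing or len(t1) <= 1

    def test_family_members_keep_separate_rows(self, bulged_mimic_fixture):
        mirna, transcript, start, width = bulged_mimic_fixture
        twin = MiRNA("mir-21mer-b", mirna.sequence)
        table = scan_transcriptome([mirna, twin], [transcript])
        planted = table[
            (table["site_start"] == start) & (table["site_end"] == start + width - 1)
        ]
        assert set(planted["mirna_id"]) == {mirna.id, twin.id}

    def test_empty_mirna_set_gives_empty_table(self, bulged_mimic_fixture):
        _, transcript, _, _ = bulged_mimic_fixture
        table = scan_transcriptome([], [transcript])
        assert table.empty and "accepted" in table.columns

    def test_unsupported_length_skipped_with_warning(self, caplog):
        mirna = MiRNA("short", "U" * 16)
        t = Transcript("t", "g", "ACGU" * 30)
        with caplog.at_level("WARNING"):
            assert scan_transcript(mirna, t) == []
        assert "19-24" in caplog.text
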