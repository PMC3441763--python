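from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mimicscan.models import DegradomeLibrary, MiRNA, TargetPair, Transcript, reverse_complement
from mimicscan.validate import (
    TargetScoreParams,
    ValidationParams,
    first_filter,
    map_reads,
    normalize_library,
    pairs_to_frame,
    predict_target_sites,
    prominence_filter,
    tplot_data,
    validate_pairs,
)

from conftest import random_rna


@pytest.fixture()
def mirna():
    rng = np.random.default_rng(31)
    return MiRNA("m", "U" + random_rna(rng, 20))


def _embed(site, seed=32, flank=60):
    rng = np.random.default_rng(seed)
    upstream = random_rna(rng, flank)
    return Transcript("t", "g", upstream + site + random_rna(rng, flank)), len(upstream) + 1


class TestScorer:
    def test_perfect_site_scores_zero(self, mirna):
        t, start = _embed(reverse_complement(mirna.sequence))
        pairs = predict_target_sites(mirna, [t])
        exact = [p for p in pairs if (p.binding_start, p.binding_end) == (start, start + 20)]
        assert exact and exact[0].prediction_score == 0.0
        assert exact[0].expected_cleavage_position == exact[0].binding_end - 9

    def test_core_wobble_costs_doubled_gu_penalty(self):
        # G:U at miRNA position 5 (core): penalty 0.5 x 2 = 1.0
        mirna = MiRNA("mg", "UACGG" + "ACGUACGUACGUACGU")  # position 5 is G
        site = list(reverse_complement(mirna.sequence))
        idx = 21 - 5  # partner of miRNA position 5 in the ungapped site
        site[idx] = "U"  # wobble partner of G
        t, start = _embed("".join(site))
        pairs = predict_target_sites(mirna, [t])
        exact = [p for p in pairs if p.binding_start == start]
        assert exact and exact[0].prediction_score == pytest.approx(1.0)

    def test_mimic_geometry_rejected_as_cleavable_target(self, mirna):
        rc = reverse_complement(mirna.sequence)
        mimic_site = rc[:11] + "GGG" + rc[11:]
        t, start = _embed(mimic_site)
        pairs = predict_target_sites(mirna, [t])
        overlapping = [
            p for p in pairs if p.binding_start <= start + 23 and p.binding_end >= start
        ]
        assert overlapping == []

    def test_score_threshold_is_respected(self, mirna):
        t, _ = _embed(reverse_complement(mirna.sequence))
        strict = predict_target_sites(mirna, [t], TargetScoreParams(max_score=0.0))
        assert all(p.prediction_score == 0.0 for p in strict)


class TestNormalization:
    def test_worked_example(self):
        lib = DegradomeLibrary("l", (("A" * 20, 5), ("C" * 20, 1_999_995)))
        table = normalize_library(lib).set_index("sequence")
        assert table.loc["A" * 20, "rpm"] == pytest.approx(2.5)

    def test_rpm_sums_to_one_million(self, small_sim):
        for lib in small_sim.libraries:
            total_rpm = normalize_library(lib)["rpm"].sum()
            assert total_rpm == pytest.approx(1e6, rel=1e-9)

    def test_single_read_library(self):
        lib = DegradomeLibrary("l", (("ACGUACGUACGUACGUACGU", 7),))
        assert normalize_library(lib)["rpm"].iloc[0] == pytest.approx(1e6)


class TestMapping:
    def test_exact_occurrence_gets_full_rpm(self):
        t = Transcript("t", "g", "A" * 100 + "CGUCGUACGUACGAUCGAUC" + "A" * 100)
        lib = DegradomeLibrary("l", (("CGUCGUACGUACGAUCGAUC", 4),))
        signals = map_reads(lib, [t])
        assert len(signals) == 1
        row = signals.iloc[0]
        assert (row["position"], row["raw"]) == (101, 4)
        assert row["rpm"] == pytest.approx(1e6)

    def test_mismatched_read_yields_no_signal(self):
        t = Transcript("t", "g", "A" * 50 + "CGUCGUACGUACGAUCGAUC" + "A" * 50)
        lib = DegradomeLibrary("l", (("CGUCGUACGUACGAUCGAUG", 4),))
        assert map_reads(lib, [t]).empty

    def test_multi_occurrence_counted_at_each_locus(self):
        motif = "CGUCGUACGUACGAUCGAUC"
        t = Transcript("t", "g", motif + "A" * 30 + motif)
        lib = DegradomeLibrary("l", ((motif, 2),))
        signals = map_reads(lib, [t])
        assert list(signals["position"]) == [1, 51]
        np.testing.assert_allclose(signals["rpm"], 1e6)


def _pair(start=101, end=121):
    return TargetPair(
        mirna_id="m",
        transcript_id="t",
        binding_start=start,
        binding_end=end,
        expected_cleavage_position=end - 9,
        prediction_score=0.0,
    )


def _signals(rows):
    return pd.DataFrame(
        rows, columns=["library_id", "transcript_id", "position", "raw", "rpm", "n_species"]
    )


class TestFirstFilter:
    def test_summed_raw_three_at_one_position_passes(self):
        signals = _signals([("l", "t", 110, 3, 30.0, 2)])
        assert first_filter([_pair()], signals) == [_pair()] or len(
            first_filter([_pair()], signals)
        ) == 1

    def test_two_reads_insufficient(self):
        signals = _signals([("l", "t", 110, 2, 20.0, 1)])
        assert first_filter([_pair()], signals) == []

    def test_reads_outside_site_do_not_count(self):
        signals = _signals([("l", "t", 130, 5, 50.0, 1)])
        assert first_filter([_pair()], signals) == []

    def test_species_mode_counts_distinct_reads(self):
        signals = _signals([("l", "t", 110, 9, 90.0, 2)])
        lenient = ValidationParams(species_mode=False)
        strict = ValidationParams(species_mode=True)
        assert len(first_filter([_pair()], signals, lenient)) == 1
        assert first_filter([_pair()], signals, strict) == []

    def test_any_single_library_suffices(self):
        signals = _signals(
            [("libA", "t", 110, 1, 10.0, 1), ("libB", "t", 110, 4, 40.0, 1)]
        )
        assert len(first_filter([_pair()], signals)) == 1

    def test_raising_threshold_is_monotone(self):
        signals = _signals([("l", "t", 110, 4, 40.0, 1)])
        kept = {
            k: len(first_filter([_pair()], signals, ValidationParams(min_reads_same_5p=k)))
            for k in (1, 3, 5)
        }
        assert kept[1] >= kept[3] >= kept[5]


class TestTplot:
    def test_peak_position_and_window_clipping(self):
        t = Transcript("t", "g", "ACGU" * 40)  # 160 nt
        signals = _signals([("l", "t", 120, 10, 100.0, 1)])
        pair = TargetPair("m", "t", 110, 130, 120, 0.0)
        global_arr, local_arr = tplot_data(t, signals, pair)
        assert len(global_arr) == 160
        top = global_arr.loc[global_arr["rpm"].idxmax()]
        assert top["position"] == 120
        # window 110-50 .. 130+50 clipped at 160
        assert local_arr["position"].min() == 60
        assert local_arr["position"].max() == 160


class TestProminence:
    def test_canonical_peak_validates(self):
        signals = _signals(
            [("l", "t", 112, 50, 500.0, 1), ("l", "t", 10, 3, 30.0, 1)]
        )
        pair = prominence_filter(_pair(), signals)  # expected position 112
        assert pair.validated and pair.peak_rpm == pytest.approx(500.0)
        assert pair.supporting_library_ids == ("l",)

    def test_larger_offsite_peak_blocks_validation(self):
        signals = _signals(
            [("l", "t", 112, 50, 500.0, 1), ("l", "t", 300, 80, 800.0, 1)]
        )
        assert not prominence_filter(_pair(), signals).validated

    def test_peak_far_from_canonical_position_fails(self):
        # in-site peak 7 nt from the expected cleavage position
        signals = _signals([("l", "t", 105, 50, 500.0, 1)])
        assert not prominence_filter(_pair(), signals).validated

    def test_window_covers_positions_opposite_9_to_11(self):
        for pos, ok in [(111, True), (112, True), (113, True), (114, False), (110, False)]:
            signals = _signals([("l", "t", pos, 50, 500.0, 1)])
            assert prominence_filter(_pair(), signals).validated is ok

    def test_relaxed_prominence_fraction(self):
        signals = _signals(
            [("l", "t", 112, 40, 400.0, 1), ("l", "t", 300, 50, 500.0, 1)]
        )
        strict = prominence_filter(_pair(), signals, ValidationParams())
        assert not strict.validated
        relaxed = prominence_filter(
            _pair(), signals, ValidationParams(prominence_fraction=0.5)
        )
        assert relaxed.validated


class TestEndToEnd:
    def test_planted_targets_validate_and_decoys_do_not(self, small_sim):
        from mimicscan.simulate import score_pipeline_against_truth
        from mimicscan.validate import predict_all_targets

        pairs = predict_all_targets(small_sim.mirnas, small_sim.transcripts)
        pairs, _ = validate_pairs(pairs, small_sim.libraries, small_sim.transcripts)
        scores = score_pipeline_against_truth(
            small_sim.truth, validated_pairs=pairs_to_frame(pairs)
        ).set_index("stage")
        row = scores.loc["target_validation"]
        assert row["sensitivity"] == 1.0
        assert row["n_false_positive"] == 0

    def test_library_union_is_monotone(self, small_sim):
        from mimicscan.validate import map_all_libraries, predict_all_targets

        pairs = predict_all_targets(small_sim.mirnas, small_sim.transcripts)
        one = map_all_libraries(small_sim.libraries[:1], small_sim.transcripts)
        both = map_all_libraries(small_sim.libraries, small_sim.transcripts)
        kept_one = {
            (p.mirna_id, p.transcript_id, p.binding_start)
            for p in first_filter(pairs, one)
        }
        kept_both = {
            (p.mirna_id, p.transcript_id, p.binding_start)
            for p in first_filter(pairs, both)
        }
        assert kept_both >= kept_one
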