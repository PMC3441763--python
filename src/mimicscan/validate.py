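"""Target prediction and degradome-sequencing-based validation.

Prediction uses an explicit weighted penalty scorer over antiparallel
duplexes (mismatch 1.0, G:U wobble 0.5, indel 2.0, the core miRNA
positions 2-13 doubled; total <= 3.0 accepted). Validation normalizes
each degradome library to reads per million, maps reads to transcripts
by perfect match, requires >= 3 raw reads with identical 5' ends inside
the predicted binding site in at least one library, and then applies a
prominence filter: the in-site peak must reach the transcript-wide
maximum and sit in the canonical window opposite miRNA positions 9-11.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import DegradomeLibrary, MiRNA, TargetPair, Transcript
from .scan import _encode

SIGNAL_COLUMNS = ["library_id", "transcript_id", "position", "raw", "rpm", "n_species"]
PAIR_COLUMNS = [
    "mirna_id",
    "transcript_id",
    "binding_start",
    "binding_end",
    "expected_cleavage_position",
    "prediction_score",
    "validated",
    "peak_rpm",
    "supporting_library_ids",
]

_G, _U = 2, 3


@dataclass(frozen=True)
class TargetScoreParams:
    """Penalty weights for the duplex scorer (all configurable)."""

    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    indel_penalty: float = 2.0
    core_region: tuple[int, int] = (2, 13)
    core_multiplier: float = 2.0
    max_score: float = 3.0
    allow_single_indel: bool = True

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty, self.gu_penalty, self.indel_penalty) < 0:
            raise ValueError("penalties must be >= 0")


@dataclass(frozen=True)
class ValidationParams:
    """Degradome filtering thresholds.

    ``min_reads_same_5p`` is a raw-count sum at one 5'-end position per
    library by default; ``species_mode`` switches to counting distinct
    read species instead. ``cleavage_window`` is given in miRNA positions
    (the canonical slicing region 9-11) and translated to transcript
    coordinates around the expected cleavage position of each pair.
    """

    min_reads_same_5p: int = 3
    local_window: int = 50
    prominence_fraction: float = 1.0
    cleavage_window: tuple[int, int] = (9, 11)
    species_mode: bool = False

    def __post_init__(self) -> None:
        if self.min_reads_same_5p < 1:
            raise ValueError("min_reads_same_5p must be >= 1")
        if not 0 < self.prominence_fraction <= 1:
            raise ValueError("prominence_fraction must be in (0, 1]")

    def transcript_window(self, expected_position: int) -> tuple[int, int]:
        lo, hi = self.cleavage_window
        # miRNA position 10 pairs the expected cleavage nucleotide; larger
        # miRNA positions pair transcript positions further 5' (smaller).
        return (expected_position - (hi - 10), expected_position + (10 - lo))


def _pair_costs(window: np.ndarray, m_code: int, params: TargetScoreParams) -> np.ndarray:
    match = window == (3 - m_code)
    if m_code == _G:
        wobble = window == _U
    elif m_code == _U:
        wobble = window == _G
    else:
        wobble = np.zeros_like(match)
    return np.where(match, 0.0, np.where(wobble, params.gu_penalty, params.mismatch_penalty))


def predict_target_sites(
    mirna: MiRNA,
    transcripts: Sequence[Transcript],
    params: TargetScoreParams | None = None,
) -> list[TargetPair]:
    """Score ungapped (and optionally single 1-nt target-insertion) duplexes.

    Placements with total weighted penalty <= ``max_score`` become
    unvalidated :class:`TargetPair` objects; the expected cleavage
    position is the transcript nucleotide pairing miRNA position 10.
    """
    params = params or TargetScoreParams()
    L = len(mirna)
    if L < 19:
        raise ValueError(f"miRNA {mirna.id} shorter than 19 nt")
    core_lo, core_hi = params.core_region
    if core_hi > L:
        raise ValueError("core region extends beyond the miRNA")
    m_code = _encode(mirna.sequence)
    weights = np.array(
        [params.core_multiplier if core_lo <= p <= core_hi else 1.0 for p in range(1, L + 1)]
    )
    geometries: list[tuple[int, int, float]] = [(0, L, 0.0)]  # (bulge_len, gap_after, indel cost)
    if params.allow_single_indel:
        for g in range(1, L):
            core_gap = core_lo <= g and g + 1 <= core_hi
            cost = params.indel_penalty * (params.core_multiplier if core_gap else 1.0)
            if cost <= params.max_score:
                geometries.append((1, g, cost))

    best: dict[tuple[str, int, int], TargetPair] = {}
    for t in transcripts:
        t_code = _encode(t.sequence)
        for bulge_len, gap_after, indel_cost in geometries:
            W = L + bulge_len
            n = len(t_code) - W + 1
            if n <= 0:
                continue
            penalty = np.full(n, indel_cost)
            for p in range(1, L + 1):
                offset = W - p if p <= gap_after else L - p
                penalty += weights[p - 1] * _pair_costs(
                    t_code[offset : offset + n], int(m_code[p - 1]), params
                )
            for s0 in np.flatnonzero(penalty <= params.max_score):
                start = int(s0) + 1
                end = start + W - 1
                expected = end - 9 if gap_after >= 10 else end - bulge_len - 9
                pair = TargetPair(
                    mirna_id=mirna.id,
                    transcript_id=t.id,
                    binding_start=start,
                    binding_end=end,
                    expected_cleavage_position=expected,
                    prediction_score=float(penalty[s0]),
                )
                key = (t.id, start, end)
                if key not in best or pair.prediction_score < best[key].prediction_score:
                    best[key] = pair
    return [best[k] for k in sorted(best)]


def predict_all_targets(
    mirnas: Sequence[MiRNA],
    transcripts: Sequence[Transcript],
    params: TargetScoreParams | None = None,
) -> list[TargetPair]:
    pairs: list[TargetPair] = []
    for m in mirnas:
        pairs.extend(predict_target_sites(m, transcripts, params))
    return pairs


def normalize_library(library: DegradomeLibrary) -> pd.DataFrame:
    """Per-read RPM: raw / library total x 10^6; RPMs sum to 10^6."""
    total = library.total_count
    if total <= 0:
        raise ValueError(f"library {library.library_id} is empty")
    rows = [
        (library.library_id, seq, raw, raw / total * 1e6) for seq, raw in library.reads
    ]
    return pd.DataFrame(rows, columns=["library_id", "sequence", "raw", "rpm"])


def map_reads(
    library: DegradomeLibrary, transcripts: Sequence[Transcript]
) -> pd.DataFrame:
    """Map reads to transcripts by perfect match; 5'-end signals per position.

    Every exact occurrence contributes the read's full RPM at the
    occurrence's 5' end (no fractional allocation for multi-mappers);
    signals at the same (transcript, position) are summed and the number
    of distinct read species recorded.
    """
    total = library.total_count
    if total <= 0:
        raise ValueError(f"library {library.library_id} is empty")
    acc: dict[tuple[str, int], list] = {}
    for seq, raw in library.reads:
        rpm = raw / total * 1e6
        for t in transcripts:
            found = t.sequence.find(seq)
            while found != -1:
                key = (t.id, found + 1)
                entry = acc.setdefault(key, [0, 0.0, 0])
                entry[0] += raw
                entry[1] += rpm
                entry[2] += 1
                found = t.sequence.find(seq, found + 1)
    rows = [
        (library.library_id, tid, pos, raw, rpm, nsp)
        for (tid, pos), (raw, rpm, nsp) in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=SIGNAL_COLUMNS)


def map_all_libraries(
    libraries: Sequence[DegradomeLibrary], transcripts: Sequence[Transcript]
) -> pd.DataFrame:
    frames = [map_reads(lib, transcripts) for lib in libraries]
    if not frames:
        return pd.DataFrame(columns=SIGNAL_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def first_filter(
    pairs: Sequence[TargetPair],
    signals: pd.DataFrame,
    params: ValidationParams | None = None,
) -> list[TargetPair]:
    """Keep pairs with >= min_reads reads sharing a 5' end inside the site.

    All libraries are screened jointly; a single passing library
    suffices. ``species_mode`` counts distinct read species instead of
    the summed raw count.
    """
    params = params or ValidationParams()
    metric = "n_species" if params.species_mode else "raw"
    retained = []
    for pair in pairs:
        sub = signals[
            (signals["transcript_id"] == pair.transcript_id)
            & (signals["position"] >= pair.binding_start)
            & (signals["position"] <= pair.binding_end)
        ]
        if not sub.empty and (sub[metric] >= params.min_reads_same_5p).any():
            retained.append(pair)
    return retained


def tplot_data(
    transcript: Transcript,
    signals: pd.DataFrame,
    pair: TargetPair,
    params: ValidationParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Global and local target-plot arrays (RPM per position per library).

    The global frame covers the whole transcript; the local frame the
    window around the binding site, clipped at the transcript ends with
    coordinates preserved.
    """
    params = params or ValidationParams()
    sub = signals[signals["transcript_id"] == transcript.id]
    libraries = sorted(sub["library_id"].unique()) or ["(none)"]
    length = len(transcript)
    frames = []
    for lib in libraries:
        rpm = np.zeros(length)
        lib_sub = sub[sub["library_id"] == lib]
        rpm[lib_sub["position"].to_numpy() - 1] = lib_sub["rpm"].to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "library_id": lib,
                    "position": np.arange(1, length + 1),
                    "rpm": rpm,
                }
            )
        )
    global_frame = pd.concat(frames, ignore_index=True)
    lo = max(1, pair.binding_start - params.local_window)
    hi = min(length, pair.binding_end + params.local_window)
    local_frame = global_frame[
        (global_frame["position"] >= lo) & (global_frame["position"] <= hi)
    ].reset_index(drop=True)
    return global_frame, local_frame


def prominence_filter(
    pair: TargetPair,
    signals: pd.DataFrame,
    params: ValidationParams | None = None,
) -> TargetPair:
    """Decide validation: the in-site peak must dominate the transcript.

    Per library, the maximum RPM inside the binding site must reach
    ``prominence_fraction`` x the transcript-wide maximum, and the peak
    position must fall in the canonical cleavage window. Any single
    passing library validates the pair; ``peak_rpm`` records the largest
    passing in-site peak and ``supporting_library_ids`` the passing
    libraries.
    """
    params = params or ValidationParams()
    window_lo, window_hi = params.transcript_window(pair.expected_cleavage_position)
    sub = signals[signals["transcript_id"] == pair.transcript_id]
    supporting = []
    peak_rpm = 0.0
    for lib, lib_sub in sub.groupby("library_id"):
        transcript_max = lib_sub["rpm"].max()
        in_site = lib_sub[
            (lib_sub["position"] >= pair.binding_start)
            & (lib_sub["position"] <= pair.binding_end)
        ]
        if in_site.empty:
            continue
        peak_row = in_site.loc[in_site["rpm"].idxmax()]
        if (
            peak_row["rpm"] >= params.prominence_fraction * transcript_max
            and window_lo <= peak_row["position"] <= window_hi
        ):
            supporting.append(str(lib))
            peak_rpm = max(peak_rpm, float(peak_row["rpm"]))
    pair.validated = bool(supporting)
    pair.peak_rpm = peak_rpm
    pair.supporting_library_ids = tuple(supporting)
    return pair


def validate_pairs(
    pairs: Sequence[TargetPair],
    libraries: Sequence[DegradomeLibrary],
    transcripts: Sequence[Transcript],
    params: ValidationParams | None = None,
) -> tuple[list[TargetPair], pd.DataFrame]:
    """Run the full validation chain; returns all pairs plus the signal table.

    Pairs failing the first (>=3-read) filter keep ``validated=False``;
    survivors are classified by the prominence filter.
    """
    params = params or ValidationParams()
    signals = map_all_libraries(libraries, transcripts)
    retained = set(id(p) for p in first_filter(pairs, signals, params))
    out = []
    for pair in pairs:
        if id(pair) in retained:
            pair = prominence_filter(pair, signals, params)
        else:
            pair.validated = False
            pair.peak_rpm = 0.0
            pair.supporting_library_ids = ()
        out.append(pair)
    return out, signals


def pairs_to_frame(pairs: Sequence[TargetPair]) -> pd.DataFrame:
    rows = [
        (
            p.mirna_id,
            p.transcript_id,
            p.binding_start,
            p.binding_end,
            p.expected_cleavage_position,
            p.prediction_score,
            p.validated,
            p.peak_rpm,
            ",".join(p.supporting_library_ids),
        )
        for p in pairs
    ]
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    df = df.astype(
        {
            "binding_start": int,
            "binding_end": int,
            "expected_cleavage_position": int,
            "prediction_score": float,
            "validated": bool,
            "peak_rpm": float,
        }
    )
    return df.sort_values(
        ["mirna_id", "transcript_id", "binding_start"], kind="mergesort"
    ).reset_index(drop=True)
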