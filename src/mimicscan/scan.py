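"""Exhaustive enumeration and rule-based classification of mimic sites.

A target mimic site is a transcript locus that is reverse complementary
to a miRNA except for a 3-5 nt bulge on the transcript ("target") side
sitting opposite the middle of the miRNA — the geometry that blocks
slicing while preserving binding (the IPS1-miR399 configuration). The
scanner enumerates every (site start, bulge length, insertion point)
placement, so acceptance is decided purely by the rules with no aligner
ranking heuristic in the way.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    GU,
    MATCH,
    MIDDLE_REGION_TABLE,
    MISMATCH,
    DuplexAlignment,
    MimicRuleParams,
    MimicSite,
    MiRNA,
    RuleDiagnostics,
    Transcript,
    UnsupportedLengthError,
    pair_label,
)

logger = logging.getLogger(__name__)

MIMIC_TABLE_COLUMNS = [
    "mirna_id",
    "transcript_id",
    "site_start",
    "site_end",
    "bulge_len",
    "insertion_point",
    "nonmiddle_mismatches",
    "max_run",
    "middle_mismatches",
    "gu_pairs",
    "accepted",
    "rejection_reasons",
]

# base encoding for the vectorized prefilter: complement(code) == 3 - code
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGU"):
    _CODE[ord(_b)] = _i
_G, _U = 2, 3


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScanParams:
    """Scanner configuration: the mimic rules plus reporting knobs."""

    rules: MimicRuleParams = field(default_factory=MimicRuleParams)
    max_sites_per_mirna: Optional[int] = None
    report_rejected: bool = False

    def __post_init__(self) -> None:
        if self.max_sites_per_mirna is not None and self.max_sites_per_mirna < 1:
            raise ValueError("max_sites_per_mirna must be >= 1 when set")


def middle_region(mirna_length: int) -> tuple[int, int]:
    """Middle positions [m_start, m_end] for a 19-24 nt miRNA."""
    try:
        return MIDDLE_REGION_TABLE[mirna_length]
    except KeyError:
        raise UnsupportedLengthError(
            f"no middle-position entry for miRNA length {mirna_length} "
            f"(supported: 19-24 nt)"
        ) from None


def build_duplex(
    mirna: MiRNA,
    transcript: Transcript,
    site_start: int,
    bulge_insertion_point: int,
    bulge_len: int,
    *,
    enforce_geometry: bool = True,
) -> DuplexAlignment:
    """Construct the duplex for one placement and label every base pair.

    miRNA position 1 pairs the site's 3'-most transcript nucleotide
    (antiparallel); positions 1..i pair the 3' block, ``bulge_len``
    transcript nucleotides are skipped, then positions i+1..L pair the
    5' block. With ``enforce_geometry`` the insertion point must keep
    both flanking miRNA positions inside the middle region and the bulge
    within the accepted 3-5 nt range; pass ``False`` to build off-rule
    duplexes for diagnostic classification.
    """
    L = len(mirna)
    m_start, m_end = middle_region(L)
    i = bulge_insertion_point
    if bulge_len < 1:
        raise ValueError("bulge_len must be >= 1 (rule 1 requires a bulge)")
    if not 1 <= i < L:
        raise ValueError(f"insertion point {i} outside 1..{L - 1}")
    if enforce_geometry:
        if not (m_start <= i and i + 1 <= m_end):
            raise ValueError(
                f"insertion between positions {i} and {i + 1} lies outside "
                f"the middle region [{m_start},{m_end}] of a {L}-nt miRNA"
            )
        if not 3 <= bulge_len <= 5:
            raise ValueError(f"bulge_len {bulge_len} outside the accepted 3-5 nt range")
    site_end = site_start + L + bulge_len - 1
    if site_start < 1 or site_end > len(transcript):
        raise ValueError(
            f"site [{site_start},{site_end}] extends beyond transcript "
            f"{transcript.id} (length {len(transcript)})"
        )
    tseq = transcript.sequence
    labels = []
    for p in range(1, L + 1):
        if p <= i:
            tpos = site_end - (p - 1)
        else:
            tpos = site_end - bulge_len - (p - 1)
        labels.append(pair_label(mirna.sequence[p - 1], tseq[tpos - 1]))
    return DuplexAlignment(
        mirna_id=mirna.id,
        transcript_id=transcript.id,
        site_start=site_start,
        site_end=site_end,
        pairing=tuple(labels),
        bulge_insertion_point=i,
        bulge_len=bulge_len,
    )


def apply_mimic_rules(
    alignment: DuplexAlignment, params: MimicRuleParams | None = None
) -> MimicSite:
    """Classify a duplex against the three mimic rules.

    R1: 3-5 nt target-side bulge with both flanking miRNA positions in
    the middle region. R2: at most ``max_nonmiddle_mismatches`` non-middle
    mismatches and no run longer than ``max_consecutive_mismatches``
    (middle positions break a run). R3: no indel other than the single
    middle bulge. G:U wobbles count as mismatches when
    ``gu_counts_as_mismatch`` (the default).
    """
    params = params or MimicRuleParams()
    L = alignment.mirna_length
    m_start, m_end = middle_region(L)
    i = alignment.bulge_insertion_point

    def is_mismatch(label: str) -> bool:
        return label == MISMATCH or (label == GU and params.gu_counts_as_mismatch)

    nonmiddle_mm = 0
    middle_mm = 0
    gu_pairs = 0
    max_run = 0
    run = 0
    for p, label in enumerate(alignment.pairing, start=1):
        if label == GU:
            gu_pairs += 1
        in_middle = m_start <= p <= m_end
        if is_mismatch(label):
            if in_middle:
                middle_mm += 1
                run = 0
            else:
                nonmiddle_mm += 1
                run += 1
                max_run = max(max_run, run)
        else:
            run = 0

    reasons: list[str] = []
    if not params.bulge_min <= alignment.bulge_len <= params.bulge_max:
        reasons.append("R1-bulge")
    if not (m_start <= i and i + 1 <= m_end):
        reasons.append("R1-position")
    if nonmiddle_mm > params.max_nonmiddle_mismatches:
        reasons.append("R2-count")
    if max_run > params.max_consecutive_mismatches:
        reasons.append("R2-run")
    if alignment.extra_indels:
        reasons.append("R3-indel")
    if (
        params.max_middle_mismatches is not None
        and middle_mm > params.max_middle_mismatches
    ):
        reasons.append("middle-cap")

    diagnostics = RuleDiagnostics(
        bulge_len=alignment.bulge_len,
        nonmiddle_mismatches=nonmiddle_mm,
        max_run=max_run,
        middle_mismatches=middle_mm,
        gu_pairs=gu_pairs,
    )
    return MimicSite(
        alignment=alignment,
        diagnostics=diagnostics,
        accepted=not reasons,
        rejection_reasons=tuple(reasons),
    )


def _candidate_starts(
    t_code: np.ndarray,
    m_code: np.ndarray,
    bulge_len: int,
    insertion_point: int,
    m_start: int,
    m_end: int,
    params: MimicRuleParams,
) -> np.ndarray:
    """Vectorized prefilter: 0-based site starts whose non-middle mismatch
    count is within the cap (a necessary condition for acceptance; the run
    cap and diagnostics are rechecked exactly on the survivors)."""
    L = len(m_code)
    W = L + bulge_len
    n = len(t_code) - W + 1
    if n <= 0:
        return np.empty(0, dtype=np.intp)
    nonmiddle_mm = np.zeros(n, dtype=np.int16)
    middle_mm = np.zeros(n, dtype=np.int16)
    for p in range(1, L + 1):
        offset = W - p if p <= insertion_point else L - p
        window = t_code[offset : offset + n]
        ok = window == (3 - m_code[p - 1])
        if not params.gu_counts_as_mismatch:
            if m_code[p - 1] == _G:
                ok = ok | (window == _U)
            elif m_code[p - 1] == _U:
                ok = ok | (window == _G)
        if m_start <= p <= m_end:
            middle_mm += ~ok
        else:
            nonmiddle_mm += ~ok
    keep = nonmiddle_mm <= params.max_nonmiddle_mismatches
    if params.max_middle_mismatches is not None:
        keep &= middle_mm <= params.max_middle_mismatches
    return np.flatnonzero(keep)


def scan_transcript(
    mirna: MiRNA, transcript: Transcript, params: ScanParams | None = None
) -> list[MimicSite]:
    """Enumerate and classify every bulged placement of one miRNA.

    Returns accepted sites (plus rejected ones when
    ``params.report_rejected``). Accepted placements describing the same
    transcript interval are collapsed to the one with fewest mismatches
    (ties: smallest insertion point).
    """
    params = params or ScanParams()
    L = len(mirna)
    try:
        m_start, m_end = middle_region(L)
    except UnsupportedLengthError:
        logger.warning(
            "skipping miRNA %s: length %d outside the 19-24 nt table", mirna.id, L
        )
        return []
    t_code = _encode(transcript.sequence)
    m_code = _encode(mirna.sequence)
    best: dict[tuple[int, int], MimicSite] = {}
    rejected: list[MimicSite] = []
    for bulge_len in range(params.rules.bulge_min, params.rules.bulge_max + 1):
        for i in range(m_start, m_end):  # insertion between i and i+1
            if params.report_rejected:
                n = len(t_code) - (L + bulge_len) + 1
                starts = np.arange(max(n, 0))
            else:
                starts = _candidate_starts(
                    t_code, m_code, bulge_len, i, m_start, m_end, params.rules
                )
            for s0 in starts:
                alignment = build_duplex(
                    mirna, transcript, int(s0) + 1, i, bulge_len
                )
                site = apply_mimic_rules(alignment, params.rules)
                if not site.accepted:
                    if params.report_rejected:
                        rejected.append(site)
                    continue
                key = alignment.site_interval
                incumbent = best.get(key)
                if incumbent is None or _site_rank(site) < _site_rank(incumbent):
                    best[key] = site
    accepted = [best[k] for k in sorted(best)]
    return accepted + rejected


def _site_rank(site: MimicSite) -> tuple[int, int]:
    d = site.diagnostics
    return (
        d.nonmiddle_mismatches + d.middle_mismatches,
        site.alignment.bulge_insertion_point,
    )


def sites_to_frame(sites: Iterable[MimicSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        a, d = s.alignment, s.diagnostics
        rows.append(
            (
                a.mirna_id,
                a.transcript_id,
                a.site_start,
                a.site_end,
                a.bulge_len,
                a.bulge_insertion_point,
                d.nonmiddle_mismatches,
                d.max_run,
                d.middle_mismatches,
                d.gu_pairs,
                s.accepted,
                ";".join(s.rejection_reasons),
            )
        )
    df = pd.DataFrame(rows, columns=MIMIC_TABLE_COLUMNS)
    return df.astype(
        {c: int for c in MIMIC_TABLE_COLUMNS[2:10]} | {"accepted": bool}
    )


def scan_transcriptome(
    mirnas: Sequence[MiRNA],
    transcripts: Sequence[Transcript],
    params: ScanParams | None = None,
) -> pd.DataFrame:
    """Scan every miRNA against every transcript.

    One row per (miRNA, transcript, site interval), deterministically
    ordered by (mirna_id, transcript_id, site_start) with exact duplicate
    rows dropped. The same interval hit by two family members yields two
    rows — de-duplication across miRNAs happens only in the region
    statistics, not here.
    """
    params = params or ScanParams()
    frames = []
    for mirna in mirnas:
        mirna_sites: list[MimicSite] = []
        for transcript in transcripts:
            mirna_sites.extend(scan_transcript(mirna, transcript, params))
        if params.max_sites_per_mirna is not None:
            kept = [s for s in mirna_sites if s.accepted][: params.max_sites_per_mirna]
            kept += [s for s in mirna_sites if not s.accepted]
            mirna_sites = kept
        frames.append(sites_to_frame(mirna_sites))
    if not frames:
        return sites_to_frame([])
    table = pd.concat(frames, ignore_index=True)
    table = table.drop_duplicates().sort_values(
        ["mirna_id", "transcript_id", "site_start", "site_end"], kind="mergesort"
    )
    return table.reset_index(drop=True)
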