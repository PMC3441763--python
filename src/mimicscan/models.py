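"""Domain types shared across the target-mimicry pipeline.

Coordinates are 1-based inclusive everywhere in public types, files and
reports (position 10 of a miRNA is its tenth nucleotide counted from the
5' end). Sequence comparisons run in RNA space: input sequences are
uppercased and T is replaced by U at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

RNA_ALPHABET = frozenset("ACGU")
_RC_TABLE = str.maketrans("ACGU", "UGCA")

#: Length-dependent central ("middle") miRNA positions where the
#: target-side bulge of a mimic site must sit, keyed by miRNA length.
#: The canonical slicing site (between positions 10 and 11 of a 21-mer)
#: always falls inside the middle interval.
MIDDLE_REGION_TABLE: dict[int, tuple[int, int]] = {
    19: (9, 11),
    20: (10, 11),
    21: (10, 12),
    22: (11, 12),
    23: (11, 13),
    24: (12, 13),
}

# pairing labels for one miRNA position in a duplex
MATCH = "match"
MISMATCH = "mismatch"
GU = "GU"


class AlphabetError(ValueError):
    """A sequence contains characters outside the nucleotide alphabet."""


class StructureError(ValueError):
    """A transcript's UTR/CDS intervals violate the tiling invariant."""


class UnsupportedLengthError(ValueError):
    """miRNA length outside the 19-24 nt middle-position table."""


def normalize_rna(sequence: str, *, context: str = "sequence") -> str:
    """Uppercase and convert T to U; reject anything outside {A,C,G,U}."""
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"illegal character(s) {sorted(bad)} in {context}: {sequence[:40]!r}"
        )
    return seq


def reverse_complement(sequence: str) -> str:
    """Reverse complement in RNA space (A<->U, G<->C).

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    return normalize_rna(sequence).translate(_RC_TABLE)[::-1]


def is_watson_crick(a: str, b: str) -> bool:
    return {a, b} in ({"A", "U"}, {"G", "C"})


def is_wobble(a: str, b: str) -> bool:
    return {a, b} == {"G", "U"}


def pair_label(mirna_nt: str, transcript_nt: str) -> str:
    """Classify one antiparallel base pair as match / GU / mismatch."""
    if is_watson_crick(mirna_nt, transcript_nt):
        return MATCH
    if is_wobble(mirna_nt, transcript_nt):
        return GU
    return MISMATCH


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA; the query of every scan.

    ``is_star`` flags passenger-strand (miRNA*) species, derived from the
    id by the usual miRBase conventions ('*' suffix or a '.star' tag).
    """

    id: str
    sequence: str
    family: Optional[str] = None

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence, context=f"miRNA {self.id}")
        if not seq:
            raise ValueError(f"miRNA {self.id} has empty sequence")
        object.__setattr__(self, "sequence", seq)

    @property
    def is_star(self) -> bool:
        return self.id.endswith("*") or self.id.endswith(".star")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptStructure:
    """5'UTR / CDS / 3'UTR intervals, 1-based inclusive on the transcript.

    Either UTR may be absent (``None``); the CDS is mandatory. Present
    intervals must be non-overlapping, in order, and exactly tile
    ``[1, length]`` of the transcript they annotate.
    """

    utr5: Optional[tuple[int, int]]
    cds: tuple[int, int]
    utr3: Optional[tuple[int, int]]

    def validate(self, length: int, transcript_id: str = "?") -> None:
        segments = [
            ("5'UTR", self.utr5),
            ("CDS", self.cds),
            ("3'UTR", self.utr3),
        ]
        cursor = 1
        for name, iv in segments:
            if iv is None:
                if name == "CDS":
                    raise StructureError(f"{transcript_id}: CDS interval required")
                continue
            start, end = iv
            if start != cursor or end < start:
                raise StructureError(
                    f"{transcript_id}: {name} interval [{start},{end}] does not "
                    f"tile the transcript (expected to start at {cursor})"
                )
            cursor = end + 1
        if cursor != length + 1:
            raise StructureError(
                f"{transcript_id}: intervals cover [1,{cursor - 1}] "
                f"but transcript length is {length}"
            )

    def region_length(self, region: str) -> int:
        iv = {"5UTR": self.utr5, "CDS": self.cds, "3UTR": self.utr3}[region]
        return 0 if iv is None else iv[1] - iv[0] + 1


@dataclass(frozen=True)
class Transcript:
    """A cDNA sequence, optionally with 5'UTR-CDS-3'UTR structure.

    Transcripts without structure are scannable for mimic sites but are
    excluded from region-distribution statistics.
    """

    id: str
    gene_id: str
    sequence: str
    structure: Optional[TranscriptStructure] = None

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence, context=f"transcript {self.id}")
        if not seq:
            raise ValueError(f"transcript {self.id} has empty sequence")
        object.__setattr__(self, "sequence", seq)
        if self.structure is not None:
            self.structure.validate(len(seq), self.id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DuplexAlignment:
    """One antiparallel miRNA-transcript duplex with a single target-side bulge.

    miRNA position 1 pairs the 3'-most nucleotide of the transcript site;
    ``bulge_len`` unpaired transcript nucleotides lie between the partners
    of miRNA positions ``bulge_insertion_point`` and
    ``bulge_insertion_point + 1``. ``pairing[p-1]`` labels miRNA position p
    as match / GU / mismatch. ``extra_indels`` records any additional
    indels (none are ever produced by the scanner; the field exists so the
    rule checker can reject externally constructed multi-bulge duplexes).
    """

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    pairing: tuple[str, ...]
    bulge_insertion_point: int
    bulge_len: int
    extra_indels: tuple[tuple[int, int], ...] = ()

    @property
    def mirna_length(self) -> int:
        return len(self.pairing)

    @property
    def site_interval(self) -> tuple[int, int]:
        return (self.site_start, self.site_end)


@dataclass(frozen=True)
class MimicRuleParams:
    """Acceptance rules for a target-mimic duplex.

    A site is a mimic when a 3-5 nt target-side bulge sits in the middle
    of the miRNA, at most 4 non-middle mismatches occur with no run longer
    than 2 nt, and no other indel exists anywhere. G:U wobbles count as
    mismatches by default (the stringent reading; a switch is provided for
    sensitivity analyses). Middle-region mismatches are reported and only
    capped when ``max_middle_mismatches`` is set.
    """

    bulge_min: int = 3
    bulge_max: int = 5
    max_nonmiddle_mismatches: int = 4
    max_consecutive_mismatches: int = 2
    gu_counts_as_mismatch: bool = True
    max_middle_mismatches: Optional[int] = None

    def __post_init__(self) -> None:
        if self.bulge_min > self.bulge_max:
            raise ValueError("bulge_min must be <= bulge_max")
        if min(self.max_nonmiddle_mismatches, self.max_consecutive_mismatches) < 0:
            raise ValueError("mismatch caps must be >= 0")


@dataclass(frozen=True)
class RuleDiagnostics:
    bulge_len: int
    nonmiddle_mismatches: int
    max_run: int
    middle_mismatches: int
    gu_pairs: int


@dataclass(frozen=True)
class MimicSite:
    """A classified duplex: the pipeline's core call."""

    alignment: DuplexAlignment
    diagnostics: RuleDiagnostics
    accepted: bool
    rejection_reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.accepted == (not self.rejection_reasons)


@dataclass(frozen=True)
class DegradomeLibrary:
    """Collapsed degradome reads: (sequence, raw count) with library total."""

    library_id: str
    reads: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for seq, raw in self.reads:
            if not seq:
                raise ValueError(f"{self.library_id}: empty read sequence")
            if raw <= 0:
                raise ValueError(f"{self.library_id}: non-positive count {raw}")

    @property
    def total_count(self) -> int:
        return sum(raw for _, raw in self.reads)


@dataclass(frozen=True)
class CleavageSignal:
    """Normalized 5'-end signal of degradome reads at one transcript position."""

    transcript_id: str
    position: int
    raw: int
    rpm: float
    library_id: str
    n_species: int = 1


@dataclass
class TargetPair:
    """A predicted (and possibly degradome-validated) miRNA-target interaction."""

    mirna_id: str
    transcript_id: str
    binding_start: int
    binding_end: int
    expected_cleavage_position: int
    prediction_score: float
    validated: bool = False
    peak_rpm: float = 0.0
    supporting_library_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.binding_start <= self.expected_cleavage_position <= self.binding_end:
            raise ValueError(
                f"{self.mirna_id}->{self.transcript_id}: expected cleavage "
                f"position {self.expected_cleavage_position} outside binding "
                f"interval [{self.binding_start},{self.binding_end}]"
            )
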