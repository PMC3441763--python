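"""Synthetic miRNA/transcriptome/degradome generator with a truth ledger.

Emulates the statistical structure of plant miRNA and transcript inputs:
miRNA lengths peaked at 21 nt with tunable 5'-U enrichment, transcripts
with contiguous 5'UTR-CDS-3'UTR structure, planted mimic sites with
specified bulge/mismatch geometry, planted cleavable target sites, and
degradome reads concentrated at canonical cleavage positions over a
uniform low-count noise floor. Every planted feature is recorded in a
machine-readable truth ledger so each pipeline stage can be scored
without external data. Output is fully determined by the seed.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as msio
from .models import (
    DegradomeLibrary,
    MiRNA,
    Transcript,
    TranscriptStructure,
    reverse_complement,
)
from .scan import ScanParams, middle_region, scan_transcript, scan_transcriptome

BASES = "ACGU"
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {"G": "U", "U": "G"}

DECOY_KINDS = ("R1-small", "R1-large", "R2-count", "R2-run", "off-middle", "R3-extra")

TRUTH_COLUMNS = [
    "kind",
    "mirna_id",
    "transcript_id",
    "start",
    "end",
    "bulge_len",
    "insertion_point",
    "n_mismatches",
    "violation",
    "expected_verdict",
    "expected_cleavage_position",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic genome.

    Defaults encode a realistic desk-scale plant-like input: 21-nt-peaked
    miRNA lengths, 70% 5'-U starts, UTR/CDS length ranges of typical
    mRNAs, strong cleavage signals (raw 50) over a 1-3-count noise floor.
    """

    seed: int = 0
    n_mirnas: int = 20
    mirna_length_weights: dict[int, float] = field(
        default_factory=lambda: {19: 0.03, 20: 0.10, 21: 0.55, 22: 0.17, 23: 0.05, 24: 0.10}
    )
    p_5prime_U: float = 0.7
    n_transcripts: int = 60
    utr5_range: tuple[int, int] = (100, 300)
    cds_range: tuple[int, int] = (300, 1500)
    utr3_range: tuple[int, int] = (100, 500)
    n_planted_mimics: int = 20
    mimic_mismatch_range: tuple[int, int] = (0, 2)
    n_decoys: int = 20
    decoy_kinds: tuple[str, ...] = DECOY_KINDS
    n_planted_targets: int = 8
    n_decoy_targets: int = 4
    n_libraries: int = 2
    signal_raw_count: int = 50
    decoy_signal_raw_count: int = 2
    background_positions: int = 20
    background_count_range: tuple[int, int] = (1, 3)
    disjoint_cascades: bool = False

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_transcripts) < 1:
            raise ValueError("need at least one miRNA and one transcript")
        for name in ("n_planted_mimics", "n_decoys", "n_planted_targets",
                     "n_decoy_targets", "n_libraries", "background_positions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.disjoint_cascades:
            if not (self.n_planted_mimics == self.n_planted_targets == self.n_mirnas):
                raise ValueError(
                    "disjoint cascades require n_planted_mimics == "
                    "n_planted_targets == n_mirnas"
                )
            if self.n_transcripts < 2 * self.n_mirnas:
                raise ValueError("disjoint cascades require >= 2 transcripts per miRNA")


def cascade_config(n_cascades: int, seed: int = 0) -> SimConfig:
    """Config for K independent mimic -> miRNA -> target cascades.

    Each cascade uses its own miRNA, mimic transcript and target
    transcript, so the resulting regulatory network has exactly K
    connected components of three typed nodes each.
    """
    return SimConfig(
        seed=seed,
        n_mirnas=n_cascades,
        n_transcripts=2 * n_cascades,
        n_planted_mimics=n_cascades,
        n_planted_targets=n_cascades,
        n_decoys=0,
        n_decoy_targets=0,
        disjoint_cascades=True,
    )


@dataclass
class SimResult:
    """Generated inputs plus the ground-truth ledger."""

    config: SimConfig
    mirnas: list[MiRNA]
    transcripts: list[Transcript]
    libraries: list[DegradomeLibrary]
    truth: pd.DataFrame

    @property
    def structures(self) -> dict[str, TranscriptStructure]:
        return {t.id: t.structure for t in self.transcripts if t.structure is not None}

    def write(self, out_dir: str | os.PathLike) -> dict[str, str]:
        """Write every output file; returns logical name -> path."""
        out_dir = str(out_dir)
        os.makedirs(os.path.join(out_dir, "degradome"), exist_ok=True)
        paths = {
            "mirnas": os.path.join(out_dir, "mirnas.fasta"),
            "transcripts": os.path.join(out_dir, "transcripts.fasta"),
            "structures": os.path.join(out_dir, "structures.tsv"),
            "truth": os.path.join(out_dir, "truth.tsv"),
        }
        msio.write_fasta(paths["mirnas"], [(m.id, m.sequence) for m in self.mirnas])
        msio.write_fasta(
            paths["transcripts"], [(t.id, t.sequence) for t in self.transcripts]
        )
        msio.write_structure_table(paths["structures"], self.structures)
        msio.write_table(paths["truth"], self.truth)
        for lib in self.libraries:
            p = os.path.join(out_dir, "degradome", f"{lib.library_id}.tsv")
            msio.write_degradome_tsv(p, lib)
            paths[f"degradome/{lib.library_id}"] = p
        return paths


# ---------------------------------------------------------------------------
# sequence construction helpers

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _mismatch_base(rng: np.random.Generator, mirna_nt: str) -> str:
    """A transcript base that pairs the miRNA base neither WC nor wobble."""
    forbidden = {_WC[mirna_nt]}
    if mirna_nt in _WOBBLE:
        forbidden.add(_WOBBLE[mirna_nt])
    options = [b for b in BASES if b not in forbidden]
    return options[rng.integers(0, len(options))]


def _site_index(p: int, insertion_point: int, site_len: int, mirna_len: int) -> int:
    """0-based index within the site pairing miRNA position p (single bulge)."""
    if p <= insertion_point:
        return site_len - p
    return mirna_len - p


def build_mimic_site_seq(
    rng: np.random.Generator,
    mirna_seq: str,
    bulge_len: int,
    insertion_point: int,
    mismatch_positions: Sequence[int] = (),
    extra_indel_after: Optional[int] = None,
) -> str:
    """Construct the transcript-side site for a bulged duplex, 5'->3'.

    The site is the reverse complement of the miRNA with ``bulge_len``
    random nucleotides inserted between the partners of positions
    ``insertion_point`` and ``insertion_point + 1``; listed miRNA
    positions are turned into mismatches (never wobbles). An optional
    extra 1-nt insertion after ``extra_indel_after`` builds rule-3
    violations.
    """
    L = len(mirna_seq)
    i = insertion_point
    rc = reverse_complement(mirna_seq)
    site = rc[: L - i] + _random_seq(rng, bulge_len) + rc[L - i :]
    chars = list(site)
    for p in mismatch_positions:
        idx = _site_index(p, i, len(chars), L)
        chars[idx] = _mismatch_base(rng, mirna_seq[p - 1])
    if extra_indel_after is not None:
        g = extra_indel_after
        if g <= i:
            idx = _site_index(g, i, len(chars), L)  # partner of position g
        else:
            idx = _site_index(g + 1, i, len(chars), L) + 1
        chars.insert(idx, _random_seq(rng, 1))
    return "".join(chars)


def _sample_mismatch_positions(
    rng: np.random.Generator,
    n: int,
    nonmiddle: Sequence[int],
    max_run: int = 2,
) -> list[int]:
    """Choose n non-middle positions whose longest consecutive run <= max_run."""
    positions = list(nonmiddle)
    for _ in range(200):
        chosen = sorted(rng.choice(positions, size=n, replace=False).tolist())
        run = best = 1
        for a, b in zip(chosen, chosen[1:]):
            run = run + 1 if b == a + 1 else 1
            best = max(best, run)
        if n <= 1 or best <= max_run:
            return chosen
    raise RuntimeError("could not sample mismatch positions under the run cap")


def _run_of(rng: np.random.Generator, length: int, nonmiddle: Sequence[int]) -> list[int]:
    """A run of `length` consecutive non-middle positions."""
    runs = [
        list(range(s, s + length))
        for s in nonmiddle
        if all(s + k in nonmiddle for k in range(length))
    ]
    if not runs:
        raise RuntimeError(f"no run of {length} consecutive non-middle positions")
    return runs[rng.integers(0, len(runs))]


# ---------------------------------------------------------------------------
# the generator

class _Genome:
    """Mutable transcript pool with overlap-free planting."""

    def __init__(self, transcripts: list[Transcript]):
        self.seqs = {t.id: t.sequence for t in transcripts}
        self.meta = {t.id: t for t in transcripts}
        self.occupied: dict[str, list[tuple[int, int]]] = {t.id: [] for t in transcripts}

    def free(self, tid: str, start: int, end: int, margin: int = 5) -> bool:
        return all(
            end + margin < s or start - margin > e for s, e in self.occupied[tid]
        )

    def splice(self, tid: str, start: int, site: str) -> None:
        seq = self.seqs[tid]
        end = start + len(site) - 1
        self.seqs[tid] = seq[: start - 1] + site + seq[end:]
        self.occupied[tid].append((start, end))

    def unsplice(self, tid: str, start: int, original: str) -> None:
        end = start + len(original) - 1
        seq = self.seqs[tid]
        self.seqs[tid] = seq[: start - 1] + original + seq[end:]
        self.occupied[tid].remove((start, end))

    def finalize(self) -> list[Transcript]:
        return [
            replace(self.meta[tid], sequence=self.seqs[tid]) for tid in self.meta
        ]


def _sample_region_start(
    rng: np.random.Generator,
    genome: _Genome,
    tid: str,
    width: int,
    *,
    max_end_margin: int = 0,
) -> Optional[int]:
    """Uniform start of a width-nt window inside one structural region."""
    structure = genome.meta[tid].structure
    length = len(genome.seqs[tid])
    regions = [iv for iv in (structure.utr5, structure.cds, structure.utr3)
               if iv is not None and iv[1] - iv[0] + 1 >= width + 2]
    if not regions:
        return None
    for _ in range(60):
        rs, re = regions[rng.integers(0, len(regions))]
        hi = min(re - width + 1, length - width + 1 - max_end_margin)
        if hi <= rs:
            continue
        start = int(rng.integers(rs, hi + 1))
        if genome.free(tid, start, start + width - 1):
            return start
    return None


def generate(config: SimConfig) -> SimResult:
    """Generate miRNAs, a structured transcriptome, degradome libraries
    and the truth ledger, fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)

    # --- miRNAs
    lengths = sorted(config.mirna_length_weights)
    weights = np.array([config.mirna_length_weights[k] for k in lengths], dtype=float)
    weights /= weights.sum()
    mirnas = []
    for k in range(config.n_mirnas):
        L = int(rng.choice(lengths, p=weights))
        first = "U" if rng.random() < config.p_5prime_U else "ACG"[rng.integers(0, 3)]
        mirnas.append(
            MiRNA(id=f"mir{k:03d}", sequence=first + _random_seq(rng, L - 1),
                  family=f"FAM{k:03d}")
        )

    # --- transcripts with 5'UTR-CDS-3'UTR structure
    transcripts = []
    for k in range(config.n_transcripts):
        u5 = int(rng.integers(config.utr5_range[0], config.utr5_range[1] + 1))
        cds = int(rng.integers(config.cds_range[0], config.cds_range[1] + 1))
        u3 = int(rng.integers(config.utr3_range[0], config.utr3_range[1] + 1))
        structure = TranscriptStructure(
            utr5=(1, u5), cds=(u5 + 1, u5 + cds), utr3=(u5 + cds + 1, u5 + cds + u3)
        )
        transcripts.append(
            Transcript(
                id=f"tr{k:04d}.1",
                gene_id=f"gene{k:04d}",
                sequence=_random_seq(rng, u5 + cds + u3),
                structure=structure,
            )
        )
    genome = _Genome(transcripts)
    truth_rows: list[dict] = []

    def pick_transcript(plant_index: int, role: str) -> str:
        if config.disjoint_cascades:
            offset = 0 if role == "mimic" else 1
            return transcripts[2 * plant_index + offset].id
        return transcripts[rng.integers(0, len(transcripts))].id

    def pick_mirna(plant_index: int) -> MiRNA:
        if config.disjoint_cascades:
            return mirnas[plant_index]
        return mirnas[rng.integers(0, len(mirnas))]

    # --- planted valid mimic sites
    sequestered_pool: list[MiRNA] = []
    for j in range(config.n_planted_mimics):
        mirna = pick_mirna(j)
        if all(m.id != mirna.id for m in sequestered_pool):
            sequestered_pool.append(mirna)
        L = len(mirna)
        m_start, m_end = middle_region(L)
        bulge_len = int(rng.integers(3, 6))
        insertion = int(rng.integers(m_start, m_end))
        lo, hi = config.mimic_mismatch_range
        n_mm = int(rng.integers(lo, hi + 1))
        nonmiddle = [p for p in range(1, L + 1) if not m_start <= p <= m_end]
        mm_positions = _sample_mismatch_positions(rng, n_mm, nonmiddle) if n_mm else []
        site = build_mimic_site_seq(rng, mirna.sequence, bulge_len, insertion, mm_positions)
        start = _plant(rng, genome, pick_transcript(j, "mimic"), site,
                       config.disjoint_cascades)
        truth_rows.append(
            dict(
                kind="mimic",
                mirna_id=mirna.id,
                transcript_id=_tid_of(start),
                start=start[1],
                end=start[1] + len(site) - 1,
                bulge_len=bulge_len,
                insertion_point=insertion,
                n_mismatches=n_mm,
                violation="",
                expected_verdict="accept",
                expected_cleavage_position=0,
            )
        )

    # --- near-miss decoys (each violates exactly one rule)
    scan_params = ScanParams()
    for j in range(config.n_decoys):
        kind = config.decoy_kinds[j % len(config.decoy_kinds)]
        placed = _plant_decoy(rng, genome, mirnas, kind, scan_params)
        truth_rows.append(placed)

    # --- planted cleavable target sites (and weak-signal decoy targets)
    # targets belong to sequestered miRNAs (the downstream half of the
    # mimic -> miRNA -> target cascades the pipeline reconstructs)
    target_plants: list[dict] = []
    for j in range(config.n_planted_targets + config.n_decoy_targets):
        is_decoy = j >= config.n_planted_targets
        if config.disjoint_cascades:
            mirna = pick_mirna(j)
        elif sequestered_pool:
            mirna = sequestered_pool[rng.integers(0, len(sequestered_pool))]
        else:
            mirna = pick_mirna(j)
        L = len(mirna)
        site = reverse_complement(mirna.sequence)
        tid = pick_transcript(j, "target")
        start = None
        for _ in range(80):
            start = _sample_region_start(rng, genome, tid, L, max_end_margin=25)
            if start is not None:
                break
            if not config.disjoint_cascades:
                tid = pick_transcript(j, "target")
        if start is None:
            raise RuntimeError(f"no room to plant target site for {mirna.id}")
        genome.splice(tid, start, site)
        end = start + L - 1
        row = dict(
            kind="target_decoy" if is_decoy else "target",
            mirna_id=mirna.id,
            transcript_id=tid,
            start=start,
            end=end,
            bulge_len=0,
            insertion_point=0,
            n_mismatches=0,
            violation="weak-signal" if is_decoy else "",
            expected_verdict="not_validated" if is_decoy else "validated",
            expected_cleavage_position=end - 9,
        )
        truth_rows.append(row)
        target_plants.append(row)

    if config.disjoint_cascades:
        _enforce_cascade_independence(rng, genome, mirnas, truth_rows)

    final_transcripts = genome.finalize()
    seq_of = {t.id: t.sequence for t in final_transcripts}

    # --- degradome libraries: signal reads at cleavage positions + noise
    libraries = []
    binding = {}
    for row in target_plants:
        binding.setdefault(row["transcript_id"], []).append((row["start"], row["end"]))
    lo_bg, hi_bg = config.background_count_range
    for ln in range(config.n_libraries):
        reads: dict[str, int] = {}

        def add_read(seq: str, raw: int) -> None:
            reads[seq] = reads.get(seq, 0) + raw

        for row in target_plants:
            pos = row["expected_cleavage_position"]
            seq = seq_of[row["transcript_id"]]
            read_len = int(rng.integers(20, 22))
            fragment = seq[pos - 1 : pos - 1 + read_len]
            raw = (
                config.decoy_signal_raw_count
                if row["kind"] == "target_decoy"
                else config.signal_raw_count
            )
            add_read(fragment, raw)
        for t in final_transcripts:
            seq = seq_of[t.id]
            intervals = binding.get(t.id, [])
            placed = 0
            guard = 0
            while placed < config.background_positions and guard < 500:
                guard += 1
                pos = int(rng.integers(1, len(seq) - 21))
                if any(s <= pos <= e for s, e in intervals):
                    continue
                read_len = int(rng.integers(20, 22))
                add_read(seq[pos - 1 : pos - 1 + read_len],
                         int(rng.integers(lo_bg, hi_bg + 1)))
                placed += 1
        libraries.append(
            DegradomeLibrary(
                library_id=f"lib{ln:02d}",
                reads=tuple(sorted(reads.items())),
            )
        )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS).sort_values(
        ["kind", "mirna_id", "transcript_id", "start"], kind="mergesort"
    ).reset_index(drop=True)
    return SimResult(
        config=config,
        mirnas=mirnas,
        transcripts=final_transcripts,
        libraries=libraries,
        truth=truth,
    )


# planting helpers keep (transcript_id, start) together
def _plant(rng, genome: _Genome, tid: str, site: str, disjoint: bool) -> tuple[str, int]:
    start = None
    for _ in range(80):
        start = _sample_region_start(rng, genome, tid, len(site))
        if start is not None:
            break
        if not disjoint:
            tids = list(genome.seqs)
            tid = tids[rng.integers(0, len(tids))]
    if start is None:
        raise RuntimeError("no room to plant a mimic site")
    genome.splice(tid, start, site)
    return (tid, start)


def _tid_of(placement: tuple[str, int]) -> str:
    return placement[0]


def _decoy_site(rng, mirna: MiRNA, kind: str) -> tuple[str, dict]:
    """Site sequence plus geometry metadata for one near-miss decoy."""
    L = len(mirna)
    m_start, m_end = middle_region(L)
    nonmiddle = [p for p in range(1, L + 1) if not m_start <= p <= m_end]
    insertion = int(rng.integers(m_start, m_end))
    geometry = dict(bulge_len=3, insertion_point=insertion, n_mismatches=0)
    if kind == "R1-small":
        geometry["bulge_len"] = 2
        site = build_mimic_site_seq(rng, mirna.sequence, 2, insertion)
        reason = "reject:R1-bulge"
    elif kind == "R1-large":
        geometry["bulge_len"] = 6
        site = build_mimic_site_seq(rng, mirna.sequence, 6, insertion)
        reason = "reject:R1-bulge"
    elif kind == "R2-count":
        positions = _sample_mismatch_positions(rng, 5, nonmiddle)
        geometry["n_mismatches"] = 5
        site = build_mimic_site_seq(rng, mirna.sequence, 3, insertion, positions)
        reason = "reject:R2-count"
    elif kind == "R2-run":
        positions = _run_of(rng, 3, nonmiddle)
        geometry["n_mismatches"] = 3
        site = build_mimic_site_seq(rng, mirna.sequence, 3, insertion, positions)
        reason = "reject:R2-run"
    elif kind == "off-middle":
        off = max(2, m_start - 4)
        geometry["insertion_point"] = off
        site = build_mimic_site_seq(rng, mirna.sequence, 3, off)
        reason = "reject:R1-position"
    elif kind == "R3-extra":
        extra_after = 3 if m_start > 4 else m_end + 2
        site = build_mimic_site_seq(
            rng, mirna.sequence, 3, insertion, extra_indel_after=extra_after
        )
        reason = "reject:R3-indel"
    else:
        raise ValueError(f"unknown decoy kind {kind!r}")
    geometry["reason"] = reason
    return site, geometry


def _plant_decoy(rng, genome: _Genome, mirnas: Sequence[MiRNA], kind: str,
                 scan_params: ScanParams) -> dict:
    """Plant one decoy and re-verify it admits no accepted placement.

    Decoy nucleotides — and the sequestering miRNA itself — are resampled
    until the scanner, run over a window around the plant, accepts
    nothing overlapping the decoy interval. The re-check matters because
    a near-miss geometry can occasionally be rescued by an alternative
    legal alignment (e.g. an extra 1-nt bulge re-read as a longer middle
    bulge with a few mismatches when the miRNA repeats adjacent bases);
    resampling keeps the ledger's "reject" verdicts exact.
    """
    for _ in range(120):
        mirna = mirnas[rng.integers(0, len(mirnas))]
        L = len(mirna)
        site, geometry = _decoy_site(rng, mirna, kind)
        tids = list(genome.seqs)
        tid = tids[rng.integers(0, len(tids))]
        start = _sample_region_start(rng, genome, tid, len(site))
        if start is None:
            continue
        original = genome.seqs[tid][start - 1 : start + len(site) - 1]
        genome.splice(tid, start, site)
        end = start + len(site) - 1
        if _window_clean(genome, tid, mirna, start, end, L, scan_params):
            return dict(
                kind="decoy",
                mirna_id=mirna.id,
                transcript_id=tid,
                start=start,
                end=end,
                bulge_len=geometry["bulge_len"],
                insertion_point=geometry["insertion_point"],
                n_mismatches=geometry["n_mismatches"],
                violation=kind,
                expected_verdict=geometry["reason"],
                expected_cleavage_position=0,
            )
        genome.unsplice(tid, start, original)
    raise RuntimeError(f"could not plant a clean {kind} decoy")


def _window_clean(genome: _Genome, tid: str, mirna: MiRNA, start: int, end: int,
                  L: int, scan_params: ScanParams) -> bool:
    w0 = max(1, start - (L + 6))
    w1 = min(len(genome.seqs[tid]), end + (L + 6))
    window = Transcript(
        id=tid, gene_id=tid, sequence=genome.seqs[tid][w0 - 1 : w1]
    )
    for site in scan_transcript(mirna, window, scan_params):
        gs = site.alignment.site_start + w0 - 1
        ge = site.alignment.site_end + w0 - 1
        if gs <= end and ge >= start:
            return False
    return True


def _redraw_background(rng, genome: _Genome, tid: str) -> None:
    """Resample every nucleotide of a transcript outside planted intervals."""
    seq = list(genome.seqs[tid])
    occupied = genome.occupied[tid]
    fresh = _random_seq(rng, len(seq))
    for k in range(len(seq)):
        if not any(s <= k + 1 <= e for s, e in occupied):
            seq[k] = fresh[k]
    genome.seqs[tid] = "".join(seq)


def _enforce_cascade_independence(rng, genome: _Genome, mirnas: list[MiRNA],
                                  truth_rows: list[dict]) -> None:
    """Rejection-sample background until cascades are truly independent.

    Chance complementarity in random background can create accepted mimic
    sites or high-scoring target predictions between unrelated cascades
    (the same phenomenon that yields genome-wide mimic candidates in real
    transcriptomes). The disjoint-cascade preset promises K isolated
    mimic -> miRNA -> target components, so transcripts carrying stray
    cross-pair hits have their non-planted sequence redrawn until the
    only surviving interactions are the planted ones.
    """
    from .validate import predict_all_targets  # deferred: avoids import cycle

    planted_mimic = {
        (r["mirna_id"], r["transcript_id"]) for r in truth_rows if r["kind"] == "mimic"
    }
    planted_target = {
        (r["mirna_id"], r["transcript_id"]) for r in truth_rows if r["kind"] == "target"
    }
    for _ in range(30):
        current = genome.finalize()
        offending: set[str] = set()
        table = scan_transcriptome(mirnas, current)
        for row in table[table["accepted"]].itertuples(index=False):
            if (row.mirna_id, row.transcript_id) not in planted_mimic:
                offending.add(row.transcript_id)
        for pair in predict_all_targets(mirnas, current):
            if (pair.mirna_id, pair.transcript_id) not in planted_target:
                offending.add(pair.transcript_id)
        if not offending:
            return
        for tid in sorted(offending):
            _redraw_background(rng, genome, tid)
    raise RuntimeError("could not isolate planted cascades from background hits")


# ---------------------------------------------------------------------------
# scoring pipeline outputs against the ledger

def score_pipeline_against_truth(
    truth: pd.DataFrame,
    mimic_table: Optional[pd.DataFrame] = None,
    validated_pairs: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-stage confusion counts of pipeline output vs the planted truth.

    Mimic calls match on exact (miRNA, transcript, interval); decoys
    count as false positives when any accepted site for the same miRNA
    overlaps the decoy interval. Validated targets match on pair identity
    and binding interval; weak-signal decoy targets count as false
    positives when validated.
    """
    rows = []
    if mimic_table is not None:
        accepted = mimic_table[mimic_table["accepted"]]
        keys = set(
            zip(accepted["mirna_id"], accepted["transcript_id"],
                accepted["site_start"], accepted["site_end"])
        )
        planted = truth[truth["kind"] == "mimic"]
        tp = sum(
            (r.mirna_id, r.transcript_id, r.start, r.end) in keys
            for r in planted.itertuples(index=False)
        )
        decoys = truth[truth["kind"] == "decoy"]
        fp = 0
        for d in decoys.itertuples(index=False):
            hits = accepted[
                (accepted["mirna_id"] == d.mirna_id)
                & (accepted["transcript_id"] == d.transcript_id)
                & (accepted["site_start"] <= d.end)
                & (accepted["site_end"] >= d.start)
            ]
            fp += int(not hits.empty)
        rows.append(("mimic_scan", len(planted), tp, len(decoys), fp))
    if validated_pairs is not None:
        validated = validated_pairs[validated_pairs["validated"]]
        keys = set(
            zip(validated["mirna_id"], validated["transcript_id"],
                validated["binding_start"], validated["binding_end"])
        )
        planted = truth[truth["kind"] == "target"]
        tp = sum(
            (r.mirna_id, r.transcript_id, r.start, r.end) in keys
            for r in planted.itertuples(index=False)
        )
        decoys = truth[truth["kind"] == "target_decoy"]
        fp = sum(
            (r.mirna_id, r.transcript_id, r.start, r.end) in keys
            for r in decoys.itertuples(index=False)
        )
        rows.append(("target_validation", len(planted), tp, len(decoys), fp))
    out = pd.DataFrame(
        rows, columns=["stage", "n_planted", "n_recovered", "n_decoys", "n_false_positive"]
    )
    out["sensitivity"] = np.where(
        out["n_planted"] > 0, out["n_recovered"] / out["n_planted"], np.nan
    )
    return out
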