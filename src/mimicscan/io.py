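"""Readers and writers for the external formats the pipeline touches.

FASTA (sequences), the 7-column tab-delimited transcript structure table,
degradome libraries (two dialects: sequence<TAB>count TSV and collapsed
FASTA with ``_N`` count suffixes in headers), and plain TSV tables.
"""
from __future__ import annotations

import os
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    DegradomeLibrary,
    StructureError,
    Transcript,
    TranscriptStructure,
    normalize_rna,
)

STRUCTURE_COLUMNS = [
    "transcript_id",
    "utr5_start",
    "utr5_end",
    "cds_start",
    "cds_end",
    "utr3_start",
    "utr3_end",
]


def read_fasta(path: str | os.PathLike, alphabet_mode: str = "rna") -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``.

    IDs are the first whitespace token of each header. With
    ``alphabet_mode='rna'`` sequences are uppercased, T->U converted and
    validated against {A,C,G,U}; ``'raw'`` only uppercases.
    Duplicate IDs and empty files are errors.
    """
    if alphabet_mode not in ("rna", "raw"):
        raise ValueError(f"unknown alphabet_mode {alphabet_mode!r}")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if alphabet_mode == "rna":
            seq = normalize_rna(seq, context=f"record {rec.id}")
        else:
            seq = seq.upper()
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_structure_table(path: str | os.PathLike) -> dict[str, TranscriptStructure]:
    """Read the 7-column structure table; empty UTRs are encoded ``0 0``.

    Interval consistency against sequence lengths is checked when
    structures are attached to transcripts (:func:`attach_structures`).
    """
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0] == "transcript_id":  # tolerate a header row
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] != 7:
        raise ValueError(f"{path}: expected 7 columns, got {df.shape[1]}")
    df.columns = STRUCTURE_COLUMNS
    out: dict[str, TranscriptStructure] = {}
    for row in df.itertuples(index=False):
        tid = row.transcript_id
        if tid in out:
            raise ValueError(f"{path}: duplicate transcript id {tid!r}")

        def interval(s: str, e: str, name: str) -> Optional[tuple[int, int]]:
            start, end = int(s), int(e)
            if (start, end) == (0, 0):
                return None
            if start < 1 or end < start:
                raise StructureError(f"{tid}: bad {name} interval [{start},{end}]")
            return (start, end)

        cds = interval(row.cds_start, row.cds_end, "CDS")
        if cds is None:
            raise StructureError(f"{tid}: CDS interval may not be empty")
        out[tid] = TranscriptStructure(
            utr5=interval(row.utr5_start, row.utr5_end, "5'UTR"),
            cds=cds,
            utr3=interval(row.utr3_start, row.utr3_end, "3'UTR"),
        )
    return out


def write_structure_table(
    path: str | os.PathLike, structures: dict[str, TranscriptStructure]
) -> None:
    rows = []
    for tid in sorted(structures):
        s = structures[tid]
        u5 = s.utr5 or (0, 0)
        u3 = s.utr3 or (0, 0)
        rows.append((tid, *u5, *s.cds, *u3))
    pd.DataFrame(rows, columns=STRUCTURE_COLUMNS).to_csv(
        str(path), sep="\t", header=False, index=False
    )


def attach_structures(
    records: Iterable[tuple[str, str]],
    structures: Optional[dict[str, TranscriptStructure]] = None,
    gene_ids: Optional[dict[str, str]] = None,
) -> list[Transcript]:
    """Join FASTA records with a structure table into :class:`Transcript` objects.

    Gene ids default to the transcript id with a trailing ``.N`` splice
    suffix stripped (the TAIR/TIGR convention). Structure tiling is
    validated here and never silently repaired.
    """
    structures = structures or {}
    transcripts = []
    for tid, seq in records:
        gene = (gene_ids or {}).get(tid) or tid.rsplit(".", 1)[0]
        transcripts.append(
            Transcript(id=tid, gene_id=gene, sequence=seq, structure=structures.get(tid))
        )
    return transcripts


def read_degradome(path: str | os.PathLike, format: Optional[str] = None,
                   library_id: Optional[str] = None) -> DegradomeLibrary:
    """Read a degradome library.

    ``format`` is ``'tsv'`` (sequence<TAB>raw_count per line) or
    ``'collapsed-fasta'`` (count parsed from the ``_N`` header suffix);
    inferred from the extension when omitted. Zero-count records are
    dropped; negative or non-integer counts are errors.
    """
    path = str(path)
    if format is None:
        format = "collapsed-fasta" if path.endswith((".fa", ".fasta")) else "tsv"
    lib_id = library_id or os.path.splitext(os.path.basename(path))[0]
    reads: list[tuple[str, int]] = []
    if format == "tsv":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{path}:{ln}: expected 'sequence<TAB>count'")
                seq, raw = fields
                count = _parse_count(raw, f"{path}:{ln}")
                if count == 0:
                    continue
                reads.append((normalize_rna(seq, context=f"{path}:{ln}"), count))
    elif format == "collapsed-fasta":
        for rec in SeqIO.parse(path, "fasta"):
            head, _, suffix = rec.id.rpartition("_")
            if not head:
                raise ValueError(f"{path}: header {rec.id!r} lacks a _N count suffix")
            count = _parse_count(suffix, f"{path} record {rec.id}")
            if count == 0:
                continue
            reads.append((normalize_rna(str(rec.seq), context=rec.id), count))
    else:
        raise ValueError(f"unknown degradome format {format!r}")
    return DegradomeLibrary(library_id=lib_id, reads=tuple(reads))


def _parse_count(text: str, where: str) -> int:
    try:
        count = int(text)
    except ValueError as exc:
        raise ValueError(f"{where}: non-integer count {text!r}") from exc
    if count < 0:
        raise ValueError(f"{where}: negative count {count}")
    return count


def write_degradome_tsv(path: str | os.PathLike, library: DegradomeLibrary) -> None:
    with open(str(path), "w") as fh:
        for seq, raw in library.reads:
            fh.write(f"{seq}\t{raw}\n")


def write_table(path: str | os.PathLike, df: pd.DataFrame) -> None:
    """Deterministically formatted TSV output used by every stage."""
    df.to_csv(str(path), sep="\t", index=False, float_format="%.6g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")
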