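"""Region assignment and distribution statistics for mimic sites.

Five site categories are defined on structured transcripts: 5'UTR, CDS,
3'UTR, and the two junction-spanning categories 5'UTR-CDS and CDS-3'UTR.
Normalized densities (sites per 1000 nt) are computed for the three
plain regions by dividing unique-site counts by the summed length of the
region across all structured transcripts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .models import Transcript, TranscriptStructure

logger = logging.getLogger(__name__)

REGIONS = ["5UTR", "CDS", "3UTR"]
CATEGORIES = ["5UTR", "CDS", "3UTR", "5UTR-CDS", "CDS-3UTR"]


@dataclass(frozen=True)
class DistributionSummary:
    """Counts, percentages and densities of unique mimic sites by region."""

    counts: dict[str, int]
    percentages: dict[str, float]
    densities: dict[str, float]
    region_lengths: dict[str, int]
    n_unique_sites: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in CATEGORIES:
            rows.append(
                (
                    cat,
                    self.counts[cat],
                    self.percentages[cat],
                    self.region_lengths.get(cat, 0),
                    self.densities.get(cat, float("nan")),
                )
            )
        return pd.DataFrame(
            rows,
            columns=["category", "count", "percentage", "summed_length", "density_per_kb"],
        )


def _overlap(a: tuple[int, int], b: tuple[int, int] | None) -> int:
    if b is None:
        return 0
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def assign_region(site_interval: tuple[int, int], structure: TranscriptStructure) -> str:
    """Assign a site to one of the five region categories.

    Wholly contained sites take their region; sites crossing one junction
    take the corresponding boundary category. A site spanning both
    junctions of a tiny CDS takes the region of majority overlap, ties
    broken toward CDS.
    """
    start, end = site_interval
    ov = {r: _overlap((start, end), getattr(structure, iv)) for r, iv in
          [("5UTR", "utr5"), ("CDS", "cds"), ("3UTR", "utr3")]}
    length = end - start + 1
    if sum(ov.values()) != length:
        raise ValueError(f"site [{start},{end}] outside the structured transcript")
    touched = [r for r in REGIONS if ov[r] > 0]
    if len(touched) == 1:
        return touched[0]
    if touched == ["5UTR", "CDS"]:
        return "5UTR-CDS"
    if touched == ["CDS", "3UTR"]:
        return "CDS-3UTR"
    # spans both junctions: majority overlap, ties toward CDS
    return max(REGIONS, key=lambda r: (ov[r], r == "CDS"))


def dedup_sites(mimic_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse the interaction table to unique (transcript, interval) sites.

    One mimic site may be recognized by several miRNAs (family members in
    particular); for distribution analysis each site is considered once,
    with the miRNA multiplicity kept as an attribute.
    """
    accepted = mimic_table[mimic_table["accepted"]] if "accepted" in mimic_table else mimic_table
    if accepted.empty:
        return pd.DataFrame(
            columns=["transcript_id", "site_start", "site_end", "multiplicity", "mirna_ids"]
        )
    grouped = (
        accepted.groupby(["transcript_id", "site_start", "site_end"], sort=True)["mirna_id"]
        .agg(lambda ids: sorted(set(ids)))
        .reset_index()
    )
    grouped["multiplicity"] = grouped["mirna_id"].map(len)
    grouped["mirna_ids"] = grouped["mirna_id"].map(",".join)
    return grouped.drop(columns=["mirna_id"])


def annotate_sites(
    unique_sites: pd.DataFrame, transcripts: Sequence[Transcript]
) -> pd.DataFrame:
    """Attach a region category to every unique site on a structured transcript.

    Sites on transcripts without structure are dropped (with a log note),
    mirroring the restriction of the distribution analysis to structured
    transcripts.
    """
    by_id = {t.id: t for t in transcripts}
    rows = []
    n_unstructured = 0
    for row in unique_sites.itertuples(index=False):
        t = by_id.get(row.transcript_id)
        if t is None or t.structure is None:
            n_unstructured += 1
            continue
        category = assign_region((row.site_start, row.site_end), t.structure)
        rows.append((*row, category))
    if n_unstructured:
        logger.info("%d unique sites on unstructured transcripts excluded", n_unstructured)
    return pd.DataFrame(rows, columns=list(unique_sites.columns) + ["category"])


def distribution_summary(
    unique_sites: pd.DataFrame,
    transcripts: Sequence[Transcript],
    *,
    denominator: str = "all",
) -> DistributionSummary:
    """Percentages over the five categories and densities per 1000 nt.

    ``denominator='all'`` sums region lengths over every structured
    transcript (a transcriptome-wide density, the default);
    ``'mimic_bearing'`` restricts to transcripts carrying at least one
    unique site. Boundary-category sites do not enter the three-region
    density numerators.
    """
    annotated = (
        unique_sites
        if "category" in unique_sites.columns
        else annotate_sites(unique_sites, transcripts)
    )
    counts = {cat: int((annotated["category"] == cat).sum()) for cat in CATEGORIES} \
        if not annotated.empty else {cat: 0 for cat in CATEGORIES}
    n_unique = int(sum(counts.values()))
    percentages = {
        cat: (100.0 * counts[cat] / n_unique if n_unique else 0.0) for cat in CATEGORIES
    }

    if denominator == "all":
        pool = [t for t in transcripts if t.structure is not None]
    elif denominator == "mimic_bearing":
        bearing = set(annotated["transcript_id"]) if not annotated.empty else set()
        pool = [t for t in transcripts if t.structure is not None and t.id in bearing]
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    region_lengths = {
        region: sum(t.structure.region_length(region) for t in pool) for region in REGIONS
    }
    densities = {}
    for region in REGIONS:
        length = region_lengths[region]
        if length == 0:
            if counts[region] > 0:
                raise ValueError(
                    f"{counts[region]} sites in {region} but summed region length is 0"
                )
            logger.warning("summed %s length is 0; density reported as 0", region)
            densities[region] = 0.0
        else:
            densities[region] = counts[region] / length * 1000.0
    return DistributionSummary(
        counts=counts,
        percentages=percentages,
        densities=densities,
        region_lengths=region_lengths,
        n_unique_sites=n_unique,
    )


def per_gene_tally(unique_sites: pd.DataFrame, transcripts: Sequence[Transcript]) -> pd.DataFrame:
    """Mimic tallies at both transcript and gene level.

    Splice variants of one gene are distinct transcripts; how they should
    be merged when counting mimic genes is not uniquely defined, so both
    tallies are reported.
    """
    gene_of = {t.id: t.gene_id for t in transcripts}
    if unique_sites.empty:
        return pd.DataFrame(columns=["level", "n_units_with_sites", "n_sites"])
    df = unique_sites.copy()
    df["gene_id"] = df["transcript_id"].map(gene_of)
    return pd.DataFrame(
        [
            ("transcript", df["transcript_id"].nunique(), len(df)),
            ("gene", df["gene_id"].nunique(), len(df)),
        ],
        columns=["level", "n_units_with_sites", "n_sites"],
    )
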