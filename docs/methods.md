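# Methods

## The mimic model

A target mimic site is an antiparallel miRNA–transcript duplex in which
miRNA position 1 pairs the 3′-most nucleotide of the site and a single
bulge of unpaired transcript nucleotides sits opposite the center of the
miRNA. Coordinates are 1-based inclusive throughout ("position 10" is
the tenth nucleotide from the miRNA 5′ end); all comparisons run in RNA
space (T→U at input boundaries).

The middle region is length-dependent and fixed by table:

| miRNA length | middle positions |
|---|---|
| 19 | 9–11 |
| 20 | 10–11 |
| 21 | 10–12 |
| 22 | 11–12 |
| 23 | 11–13 |
| 24 | 12–13 |

Acceptance rules, applied to every enumerated placement:

- **R1** — the target-side bulge is 3–5 nt long and both miRNA positions
  flanking the insertion lie inside the middle region. This is the
  tightest reading of "bulge located in the middle" and reproduces the
  canonical geometry of a 3-nt bulge between positions 10 and 11 of a
  21-mer.
- **R2** — at most 4 mismatches at non-middle positions, and no run of
  more than 2 consecutive non-middle mismatches. A middle position
  interrupts a run. Middle-region mismatches are counted and reported
  but unlimited by default (`max_middle_mismatches` caps them when set).
- **R3** — no indel anywhere except the single middle bulge. The scanner
  only ever constructs single-bulge geometries, so R3 is structural;
  the rule checker also rejects externally supplied multi-indel
  alignments.

**G:U wobble.** Wobble pairs are counted as mismatches by default — the
stringent choice; a switch scores them as matches for sensitivity
analyses, and the scanner's oracle-equivalence tests cover both modes.

**Candidate generation.** Rather than ranking heuristic alignments, the
scanner enumerates every (site start, bulge length 3–5, legal insertion
point) placement exhaustively. Acceptance is therefore decided by the
rules alone. A vectorized mismatch-count prefilter (numpy sliding
comparisons per miRNA position) makes this linear in transcript length;
survivors are re-classified exactly, position by position. Accepted
placements describing the same transcript interval are collapsed to the
one with fewest mismatches, ties broken toward the smaller insertion
point. Because full-length miRNA coverage is required, duplexes with
terminal overhangs are never called — possibly stricter than heuristics
that admit truncated local alignments.

## Region statistics

Only transcripts with a declared 5′UTR–CDS–3′UTR structure (validated
as a contiguous tiling of the transcript, never silently repaired)
enter the distribution analysis. Sites hit by several miRNAs — common
within miRNA families — are counted once, with the multiplicity kept as
an attribute. Five categories are assigned: the three plain regions and
the two junction-spanning categories; a site spanning both junctions of
a very short CDS takes the region of majority overlap with ties broken
toward CDS (degenerate, documented, covered by a test). Densities are
computed only for the three plain regions: unique-site count divided by
the summed length of that region across **all** structured transcripts,
× 1000. The all-transcripts denominator is the default because it gives
a transcriptome-wide density; a mimic-bearing-only denominator is
available as an option since the choice is not uniquely determined.
Per-transcript and per-gene tallies are both reported because the
de-duplication of splice variants when counting "mimic genes" is
likewise a free choice.

## miRNA profiles

Length histograms, 5′/3′ terminal composition, and end-anchored 15-nt
positional frequency matrices for the sequestered set (miRNAs with at
least one accepted mimic) versus the control set (everything else; the
two sets partition the input). Information content per position is
R_p = 2 − H_p bits with H_p the Shannon entropy of the base frequencies;
no pseudocounts and no small-sample correction by default (the e_n
correction is available behind a flag). Profiles are emitted as TSV
matrices; logo rendering is external tooling's job.

## Target prediction and degradome validation

The cleavable-target scorer is an explicit weighted penalty scheme:
mismatch 1.0, G:U 0.5, indel 2.0, with penalties at core miRNA
positions 2–13 doubled and total penalty ≤ 3.0 accepted. Ungapped and
single 1-nt-indel duplexes are scored. The expected cleavage position is
the transcript nucleotide pairing miRNA position 10 (the 5′ boundary of
the downstream fragment a slicer leaves). Under this scheme a canonical
mimic duplex (3-nt middle bulge) can never be accepted as a cleavable
target — the indel alone costs 4.0 — encoding the dichotomy between
sequestration and slicing.

Validation proceeds per degradome library:

1. **Normalization** — RPM = raw count / library total × 10⁶; totals are
   conserved exactly.
2. **Mapping** — perfect-match occurrences only; every occurrence
   receives the read's full RPM at its 5′ end (no fractional allocation
   for multi-mappers), and co-located signals sum. The number of
   distinct read species per position is tracked alongside the raw sum.
3. **First filter** — a pair survives if any single library holds a
   position inside the binding site whose summed raw count reaches 3.
   The threshold is a raw-count sum by default; `species_mode` switches
   to counting distinct read species, since "three reads with identical
   5′ ends" admits both readings.
4. **t-plots** — global (whole-transcript) and local (±50 nt window,
   clipped at the ends with coordinates preserved) RPM arrays per
   library, written as TSV for plotting.
5. **Prominence filter** — the automated stand-in for manual t-plot
   curation: validated iff some library's in-site peak reaches
   `prominence_fraction` (default 1.0, i.e. the transcript-wide maximum)
   and lies within the canonical window opposite miRNA positions 9–11
   (expected position ± 1 nt). The defaults encode "a cleavage signal
   easy to recognize"; both knobs are configurable.

## Networks

Nodes are miRNAs and transcripts; a transcript sequestering one miRNA
and cleaved by another is a single dual-role node with roles
{mimic, target}. Mimicry edges run mimic → miRNA, cleavage edges
miRNA → target; type discipline is asserted on every build and import.
Nodes are mature-miRNA-level by default; an optional family-collapse
pass merges nodes sharing a family label. Components are counted on the
undirected projection; subnetworks are induced subgraphs within an
undirected radius of seed nodes. GraphML round-trips all attributes;
SIF carries typed edges with node kinds/roles in a sidecar TSV (the
format itself has no attribute slots); the TSV edge list ships with a
node table.

## Synthetic data

The generator emulates the statistical shape of plant miRNA/transcript
inputs, with every draw taken from a single seeded PCG64 stream so that
identical configs give byte-identical outputs:

- miRNA lengths 19–24 nt peaked at 21 (weights 0.03/0.10/0.55/0.17/
  0.05/0.10), 5′ U with probability 0.7;
- transcripts with uniform 5′UTR 100–300 nt, CDS 300–1500 nt, 3′UTR
  100–500 nt;
- planted mimic sites: exact reverse complements with a random 3–5 nt
  middle bulge and 0–2 planted non-middle mismatches (mutations chosen
  to be neither Watson–Crick nor wobble);
- near-miss decoys violating exactly one rule each (bulge 2 nt, bulge
  6 nt, 5 mismatches, a run of 3, off-middle insertion, extra non-middle
  bulge);
- planted cleavable target sites (perfect complements) assigned to
  sequestered miRNAs, so the mimic → miRNA → target cascade the pipeline
  reconstructs actually exists in the simulation;
- degradome libraries: one 20–21-nt read with raw count 50 at each
  planted cleavage position (raw 2 for weak-signal decoy targets), plus
  20 background positions per transcript with counts 1–3, placed outside
  binding sites.

Planted features never overlap (placement by rejection sampling).
Decoy plants are re-verified at generation time: a near-miss geometry
can occasionally be rescued by an *alternative* legal alignment — an
extra 1-nt bulge re-reads as a longer middle bulge with a few mismatches
whenever the miRNA repeats adjacent bases — so decoy nucleotides and the
hosting miRNA are resampled until no accepted placement overlaps the
decoy interval. The independent brute-force oracle used by the test
suite plays no part in generation.

The disjoint-cascade preset (`cascade_config(k)`) promises k isolated
three-node cascades. Chance complementarity in random background — the
same phenomenon that yields genome-wide mimic candidates in real
transcriptomes, at roughly 10⁻⁶ per placement for a 21-mer — would
occasionally wire unrelated cascades together, so in this mode
non-planted sequence is redrawn until the only surviving interactions
are the planted ones.

**What the generator does not model:** codon structure, expression
levels, sequencing error, read-length distributions beyond 20–21 nt,
miRNA families with correlated sequences, and conservation across
species. Passing tests therefore demonstrate the correctness of the
rules, filters and bookkeeping under the declared signal/noise
conditions — not the biological error rates the workflow would achieve
on real degradome data, where noise is structured and curation
judgement matters.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale genomes chosen to make
every property measurable in seconds: 500 random scanner instances on
≤ 60-nt transcripts for oracle equivalence, a 50-miRNA / 200-transcript
genome with 100 planted mimics and 100 decoys for recovery, 20
replicates of 6-miRNA / 15-transcript genomes for degradome validation,
and K = 7 cascades for network truth. RPM totals are checked to 10⁻⁶
relative tolerance; frequency rows to 10⁻⁹; percentages close to 100
within rounding. Ties in site collapsing, region assignment and peak
selection are broken deterministically (smallest insertion point, CDS,
first maximal position respectively), and every output table has a
fixed column order and sort, so reruns are byte-identical.
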