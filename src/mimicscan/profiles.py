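"""Sequence characterization of sequestered vs control miRNAs.

Length distributions, 5'/3' terminal composition, and 15-nt end-anchored
positional frequency profiles with per-position information content
(R_p = 2 - H_p bits, H_p the Shannon entropy of the position's base
frequencies). Profiles are emitted as matrices; logo rendering is left
to external tooling.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import MiRNA

logger = logging.getLogger(__name__)

BASES = ["A", "C", "G", "U"]
PROFILE_SPAN = 15


def length_histogram(mirnas: Sequence[MiRNA]) -> pd.DataFrame:
    """Length -> (count, fraction); fractions sum to 1."""
    if not mirnas:
        raise ValueError("empty miRNA set")
    lengths = pd.Series([len(m) for m in mirnas])
    counts = lengths.value_counts().sort_index()
    return pd.DataFrame(
        {"length": counts.index, "count": counts.values, "fraction": counts.values / len(mirnas)}
    ).reset_index(drop=True)


def terminal_composition(mirnas: Sequence[MiRNA], end: str = "five_prime") -> pd.DataFrame:
    """Base composition of the first (5') or last (3') nucleotide."""
    if not mirnas:
        raise ValueError("empty miRNA set")
    if end not in ("five_prime", "three_prime"):
        raise ValueError(f"end must be five_prime or three_prime, got {end!r}")
    idx = 0 if end == "five_prime" else -1
    series = pd.Series([m.sequence[idx] for m in mirnas])
    fractions = series.value_counts(normalize=True)
    return pd.DataFrame(
        {"base": BASES, "fraction": [float(fractions.get(b, 0.0)) for b in BASES]}
    )


@dataclass(frozen=True)
class PositionalProfile:
    """End-anchored frequency matrix with per-position information content.

    Position p is the p-th nucleotide from the anchored end (5' or 3');
    frequencies at each position sum to 1 and information lies in
    [0, 2] bits.
    """

    anchor: str
    frequencies: pd.DataFrame  # index: position 1..span, columns: A C G U
    information: np.ndarray  # bits per position
    n_sequences: int

    def to_frame(self) -> pd.DataFrame:
        out = self.frequencies.copy()
        out.insert(0, "position", out.index)
        out["information_bits"] = self.information
        return out.reset_index(drop=True)


def positional_profile(
    mirnas: Sequence[MiRNA],
    anchor: str = "five_prime",
    *,
    span: int = PROFILE_SPAN,
    pseudocount: float = 0.0,
    small_sample_correction: bool = False,
) -> PositionalProfile:
    """Frequency matrix over the first ``span`` positions from one end.

    Sequences shorter than ``span`` are skipped with a warning. No
    pseudocounts and no small-sample correction are applied by default;
    the optional correction subtracts the standard e_n = 3 / (2 ln2 n)
    bias term from the information (clipped at 0).
    """
    if anchor not in ("five_prime", "three_prime"):
        raise ValueError(f"anchor must be five_prime or three_prime, got {anchor!r}")
    usable = [m for m in mirnas if len(m) >= span]
    skipped = len(mirnas) - len(usable)
    if skipped:
        logger.warning("%d sequences shorter than %d nt skipped", skipped, span)
    if not usable:
        raise ValueError(f"no sequences of length >= {span}")
    counts = np.full((span, 4), pseudocount, dtype=float)
    base_index = {b: k for k, b in enumerate(BASES)}
    for m in usable:
        window = m.sequence[:span] if anchor == "five_prime" else m.sequence[-span:][::-1]
        for p, nt in enumerate(window):
            counts[p, base_index[nt]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    information = 2.0 - entropy
    if small_sample_correction:
        information = np.clip(information - 3.0 / (2.0 * np.log(2) * len(usable)), 0.0, 2.0)
    return PositionalProfile(
        anchor=anchor,
        frequencies=pd.DataFrame(freqs, index=pd.RangeIndex(1, span + 1, name="position"),
                                 columns=BASES),
        information=information,
        n_sequences=len(usable),
    )


def split_sequestered(
    mirnas: Sequence[MiRNA], sequestered_ids: Iterable[str]
) -> tuple[list[MiRNA], list[MiRNA]]:
    """Partition a miRNA universe into sequestered and control sets.

    The control set is everything not sequestered; the two sets are
    disjoint and together cover the input.
    """
    wanted = set(sequestered_ids)
    unknown = wanted - {m.id for m in mirnas}
    if unknown:
        raise ValueError(f"sequestered ids not in the miRNA set: {sorted(unknown)}")
    sequestered = [m for m in mirnas if m.id in wanted]
    control = [m for m in mirnas if m.id not in wanted]
    return sequestered, control


def compare_sets(
    sequestered: Sequence[MiRNA], control: Sequence[MiRNA]
) -> dict[str, pd.DataFrame]:
    """Side-by-side length and 5' terminal comparisons of the two sets."""
    lh_s = length_histogram(sequestered).assign(set="sequestered")
    lh_c = length_histogram(control).assign(set="control")
    tc_s = terminal_composition(sequestered).assign(set="sequestered")
    tc_c = terminal_composition(control).assign(set="control")
    return {
        "length": pd.concat([lh_s, lh_c], ignore_index=True),
        "terminal_5p": pd.concat([tc_s, tc_c], ignore_index=True),
    }
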