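"""Independent brute-force reference for mimic-site acceptance.

Written straight from the rule text with plain string operations, with no
reuse of the scanner's machinery: every substring, bulge length and
insertion placement is tried directly. Used as the ground truth the
vectorized scanner must agree with.
"""
from __future__ import annotations

MIDDLE = {19: (9, 11), 20: (10, 11), 21: (10, 12), 22: (11, 12), 23: (11, 13), 24: (12, 13)}
WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def oracle_accepted_intervals(
    mirna_seq: str,
    transcript_seq: str,
    *,
    gu_is_mismatch: bool = True,
    max_mismatches: int = 4,
    max_run: int = 2,
) -> set[tuple[int, int]]:
    """All 1-based (start, end) transcript intervals accepted as mimic sites.

    Rule 1: a 3-5 nt bulge on the transcript side between two adjacent
    middle positions of the miRNA. Rule 2: at most 4 mismatches outside
    the middle region, no more than 2 consecutive. Rule 3 is implicit:
    only the single middle bulge geometry is ever constructed.
    """
    L = len(mirna_seq)
    if L not in MIDDLE:
        return set()
    m_start, m_end = MIDDLE[L]
    T = len(transcript_seq)
    accepted: set[tuple[int, int]] = set()
    for bulge in (3, 4, 5):
        width = L + bulge
        for start in range(1, T - width + 2):
            site = transcript_seq[start - 1 : start - 1 + width]
            for i in range(m_start, m_end):  # bulge between i and i+1
                mismatch = []
                for p in range(1, L + 1):
                    # antiparallel: miRNA position 1 pairs the site's 3' end
                    t_nt = site[width - p] if p <= i else site[L - p]
                    pair = (mirna_seq[p - 1], t_nt)
                    ok = pair in WC or (
                        not gu_is_mismatch and set(pair) == {"G", "U"}
                    )
                    mismatch.append(not ok)
                count = sum(
                    mismatch[p - 1]
                    for p in range(1, L + 1)
                    if not m_start <= p <= m_end
                )
                run = best = 0
                for p in range(1, L + 1):
                    if not m_start <= p <= m_end and mismatch[p - 1]:
                        run += 1
                        best = max(best, run)
                    else:
                        run = 0
                if count <= max_mismatches and best <= max_run:
                    accepted.add((start, start + width - 1))
    return accepted
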