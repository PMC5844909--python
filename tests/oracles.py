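"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: word presence is
recounted by substring scan, probabilities are exact rationals, and
primer placement is an exhaustive double loop with no early exits.
"""

from __future__ import annotations

import math
from fractions import Fraction

from co1bayes.primers import IUPAC, reverse_complement


def nb_scores_bruteforce(
    training: list[tuple[str, str]], k: int, query_words: list[str]
) -> dict[str, Fraction]:
    """Exact naive-Bayes word-presence probability per taxon.

    ``training`` is a list of (sequence, taxon) pairs.  Word presence is
    recounted with plain substring containment; the returned value for
    taxon G is the exact rational product over the query words of
    (m_G(w) + P_w) / (M_G + 1) with P_w = (n(w) + 1/2) / (N + 1).
    """
    N = len(training)
    taxa = sorted({t for _, t in training})
    M = {t: sum(1 for _, tt in training if tt == t) for t in taxa}
    out: dict[str, Fraction] = {}
    for taxon in taxa:
        product = Fraction(1)
        for w in query_words:
            n_w = sum(1 for seq, _ in training if w in seq)
            m_gw = sum(1 for seq, t in training if t == taxon and w in seq)
            p_w = Fraction(2 * n_w + 1, 2 * (N + 1))
            product *= (m_gw + p_w) / (M[taxon] + 1)
        out[taxon] = product
    return out


def words_bruteforce(sequence: str, k: int) -> list[str]:
    """Distinct valid k-words by direct window enumeration."""
    seen = []
    for i in range(len(sequence) - k + 1):
        w = sequence[i : i + k]
        if set(w) <= set("ACGT") and w not in seen:
            seen.append(w)
    return seen


def locate_bruteforce(sequence: str, primer_seq: str, direction: str, budget: int):
    """Exhaustive primer scan: every start, full mismatch count, no shortcuts.

    Returns (start, mismatches) of the fewest-mismatch, 5'-most placement
    within budget, else None.
    """
    pattern = reverse_complement(primer_seq) if direction == "reverse" else primer_seq
    plen = len(pattern)
    best = None
    for start in range(len(sequence) - plen + 1):
        mm = 0
        for j in range(plen):
            pb, sb = pattern[j], sequence[start + j]
            if pb == "N":
                ok = True
            else:
                ok = sb in IUPAC[pb]
            if not ok:
                mm += 1
        if best is None or mm < best[1]:
            best = (start, mm)
    if best is None or best[1] > budget:
        return None
    return best
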