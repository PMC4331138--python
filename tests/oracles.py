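"""Independent brute-force reference implementations used as test oracles.

Everything here is written with plain Python loops over word strings and
dictionaries, deliberately sharing no code with the package's vectorised
paths.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Sequence

BASES = "ACGT"


def all_words(k: int) -> List[str]:
    return ["".join(t) for t in itertools.product(BASES, repeat=k)]


def oracle_counts(sequence: str, k: int) -> Dict[str, int]:
    """Window scan over every position; windows with non-ACGT bases skipped."""
    counts: Dict[str, int] = {}
    sequence = sequence.upper()
    for i in range(len(sequence) - k + 1):
        w = sequence[i : i + k]
        if any(b not in BASES for b in w):
            continue
        counts[w] = counts.get(w, 0) + 1
    return counts


def correct_prob(q: float) -> float:
    return 1.0 - 10.0 ** (-q / 10.0)


def oracle_base_freqs(sequence: str) -> Dict[str, float]:
    counts = {b: 0 for b in BASES}
    for ch in sequence.upper():
        if ch in counts:
            counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        return {b: 0.25 for b in BASES}
    return {b: c / total for b, c in counts.items()}


def oracle_qcounts(
    sequence: str,
    qualities: Sequence[float],
    k: int,
    redistribute: bool = False,
) -> Dict[str, float]:
    """Loop over occurrences; with redistribution, loop over every position
    and every alternative base, crediting the neighbour word with the
    missing quality times the other bases' correctness product."""
    sequence = sequence.upper()
    probs = [correct_prob(q) for q in qualities]
    freqs = oracle_base_freqs(sequence)
    if redistribute and any(v == 0 for v in freqs.values()):
        raw = {b: freqs[b] * len(sequence) + 0.5 for b in BASES}
        total = sum(raw.values())
        freqs = {b: v / total for b, v in raw.items()}
    qcounts: Dict[str, float] = {}
    for i in range(len(sequence) - k + 1):
        w = sequence[i : i + k]
        if any(b not in BASES for b in w):
            continue
        window = probs[i : i + k]
        qcounts[w] = qcounts.get(w, 0.0) + math.prod(window)
        if not redistribute:
            continue
        for j in range(k):
            others = math.prod(window[:j] + window[j + 1 :])
            called = w[j]
            alt_total = sum(freqs[b] for b in BASES if b != called)
            for alt in BASES:
                if alt == called:
                    continue
                neighbour = w[:j] + alt + w[j + 1 :]
                mass = (1.0 - window[j]) * (freqs[alt] / alt_total) * others
                qcounts[neighbour] = qcounts.get(neighbour, 0.0) + mass
    return qcounts


def oracle_word_prob(freqs: Dict[str, float], word: str) -> float:
    p = 1.0
    for b in word:
        p *= freqs[b]
    return p


def oracle_d2(X: Dict[str, float], Y: Dict[str, float], k: int) -> float:
    return sum(X.get(w, 0.0) * Y.get(w, 0.0) for w in all_words(k))


def oracle_d2star(X, Y, freqsX, freqsY, nX, nY, k, EX=None) -> float:
    total = 0.0
    for w in all_words(k):
        e = EX.get(w, 1.0) if EX is not None else 1.0
        ex = nX * oracle_word_prob(freqsX, w) * e
        ey = nY * oracle_word_prob(freqsY, w) * e
        den = math.sqrt(ex * ey)
        if den <= 0:
            continue
        total += (X.get(w, 0.0) - ex) * (Y.get(w, 0.0) - ey) / den
    return total


def oracle_d2s(X, Y, freqsX, freqsY, nX, nY, k, EX=None) -> float:
    total = 0.0
    for w in all_words(k):
        e = EX.get(w, 1.0) if EX is not None else 1.0
        ex = nX * oracle_word_prob(freqsX, w) * e
        ey = nY * oracle_word_prob(freqsY, w) * e
        xt = X.get(w, 0.0) - ex
        yt = Y.get(w, 0.0) - ey
        den = math.sqrt(xt * xt + yt * yt)
        if den <= 0:
            continue
        total += xt * yt / den
    return total


def _normalised(X: Dict[str, float], k: int, pseudo: float = 0.0) -> Dict[str, float]:
    vals = {w: X.get(w, 0.0) + pseudo for w in all_words(k)}
    total = sum(vals.values())
    if total == 0:
        return {w: 1.0 / 4 ** k for w in vals}
    return {w: v / total for w, v in vals.items()}


def oracle_l2(X, Y, k) -> float:
    fx = _normalised(X, k)
    fy = _normalised(Y, k)
    return math.sqrt(sum((fx[w] - fy[w]) ** 2 for w in all_words(k)))


def oracle_kl(X, Y, k, pseudo=None) -> float:
    if pseudo is None:
        pseudo = 1.0 / 4 ** k
    fx = _normalised(X, k, pseudo)
    fy = _normalised(Y, k, pseudo)
    return sum(fx[w] * math.log2(fx[w] / fy[w]) for w in all_words(k))
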