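"""Plain and quality-weighted k-mer counting, quality redistribution, and
expected word probabilities.

The count vector X_w holds the number of (overlapping) occurrences of each
word w of length k in a read.  Its quality-weighted analogue X_w^q replaces
each occurrence's contribution of 1 with the probability that the whole
window was read correctly, P_{w,i} = prod_j (1 - 10^(-Q(i+j)/10)).

Quality *redistribution* goes one step further: the probability mass missing
from an uncertain base (1 - p) is credited to the three words obtained by
substituting that base, in proportion to the alternatives' frequencies in
the read.  Only one base is substituted at a time.

Two dataset-level estimators of the expected word probability E(P_w) are
provided: AWP (average word probability, the ratio of total quality-weighted
to total plain counts) and AQP (average quality probability, per-position
mean phred converted back to a product of correctness probabilities).

Words are indexed lexicographically with A<C<G<T via 2-bit codes; windows
are half-open [i, i+k).  Any window containing a non-ACGT base is skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np

from kmerq.fastq_io import Read, base_correct_prob

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """2-bit codes (A=0, C=1, G=2, T=3); non-ACGT bases map to -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def word_to_index(word: str) -> int:
    codes = encode_sequence(word)
    if np.any(codes < 0):
        raise ValueError(f"word {word!r} contains a non-ACGT base")
    idx = 0
    for c in codes:
        idx = idx * 4 + int(c)
    return idx


def index_to_word(index: int, k: int) -> str:
    letters = []
    for _ in range(k):
        letters.append(BASES[index % 4])
        index //= 4
    return "".join(reversed(letters))


@lru_cache(maxsize=None)
def _revcomp_map(k: int) -> np.ndarray:
    """index -> index of the reverse complement word, for all 4^k words."""
    idx = np.arange(4 ** k)
    rc = np.zeros_like(idx)
    rem = idx.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - rem % 4)
        rem //= 4
    return rc


def pool_reverse_complement(vector: np.ndarray, k: int) -> np.ndarray:
    """Pool each word with its reverse complement into the canonical
    (lexicographically smaller) index; non-canonical entries become 0."""
    rc = _revcomp_map(k)
    pooled = np.zeros_like(vector)
    canon = np.minimum(np.arange(vector.size), rc)
    np.add.at(pooled, canon, vector)
    # palindromes (i == rc) must not be doubled
    pal = np.arange(vector.size) == rc
    pooled[pal] = vector[pal]
    return pooled


def _window_indices(codes: np.ndarray, k: int):
    """Return (indices, valid) for all n-k+1 windows; invalid windows
    (containing a non-ACGT base) get index 0 and valid=False."""
    n = codes.size
    if k > n:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = np.all(win >= 0, axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = np.where(win >= 0, win, 0) @ powers
    return idx, valid


def count_kmers(read: Read, k: int) -> np.ndarray:
    """Overlapping occurrence counts of every word of length k, as a vector
    over the 4^k lexicographically ordered words.

    k > read length yields an all-zero vector (logged at warning level).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.zeros(4 ** k, dtype=np.int64)
    if k > len(read):
        logger.warning("k=%d exceeds length of read %r; empty profile", k, read.id)
        return counts
    idx, valid = _window_indices(encode_sequence(read.sequence), k)
    np.add.at(counts, idx[valid], 1)
    return counts


def word_correct_prob(read: Read, i: int, k: int) -> float:
    """Probability that the k-window starting at 0-based position ``i`` was
    read correctly: the product of its bases' correctness probabilities."""
    if i < 0 or i + k > len(read):
        raise ValueError(f"window [{i}, {i + k}) out of range for read of length {len(read)}")
    return float(np.prod(base_correct_prob(read.qualities[i : i + k])))


def base_frequencies(read_or_seq: Union[Read, str]) -> np.ndarray:
    """Per-read ACGT frequencies (non-ACGT bases ignored); uniform if the
    read contains no ACGT base at all."""
    seq = read_or_seq.sequence if isinstance(read_or_seq, Read) else read_or_seq
    codes = encode_sequence(seq)
    counts = np.bincount(codes[codes >= 0], minlength=4).astype(float)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


def redistribution_weights(base_freqs: np.ndarray) -> np.ndarray:
    """4x4 matrix W[c, a]: fraction of a wrong call of base c attributed to
    alternative a, proportional to the read's base frequencies.

    Zero frequencies receive a pseudocount of 0.5 before normalisation so
    degenerate reads still redistribute over all three alternatives.
    """
    freqs = np.asarray(base_freqs, dtype=float)
    if np.any(freqs == 0):
        freqs = freqs + 0.5
        freqs = freqs / freqs.sum()
    W = np.zeros((4, 4))
    for c in range(4):
        alt_total = freqs.sum() - freqs[c]
        for a in range(4):
            if a != c and alt_total > 0:
                W[c, a] = freqs[a] / alt_total
    return W


def substitution_credits(
    correct_probs: Sequence[float],
    base_freqs: np.ndarray,
    word: str,
) -> dict:
    """Redistribute the missing quality of one occurrence of ``word`` over
    its single-substitution neighbours.

    ``correct_probs`` gives the per-base correctness probability of the
    occurrence.  The occurrence's own word receives the full product
    P = prod(correct_probs).  For each position j and each alternative base
    a != word[j], the neighbour word receives
    (1 - p_j) * freq(a) / sum_{a' != word[j]} freq(a') times the product of
    the other k-1 bases' correctness probabilities.

    Returns a dict word -> credited mass (the original word included).
    Masses for a neighbour reachable from several positions accumulate.
    """
    probs = np.asarray(correct_probs, dtype=float)
    k = len(word)
    if probs.size != k:
        raise ValueError("one correctness probability per base required")
    codes = encode_sequence(word)
    if np.any(codes < 0):
        raise ValueError(f"word {word!r} contains a non-ACGT base")
    W = redistribution_weights(base_freqs)
    credits: dict = {word: float(np.prod(probs))}
    for j in range(k):
        others = float(np.prod(np.delete(probs, j)))
        c = int(codes[j])
        for a in range(4):
            if a == c:
                continue
            neighbour = word[:j] + BASES[a] + word[j + 1 :]
            mass = (1.0 - probs[j]) * W[c, a] * others
            credits[neighbour] = credits.get(neighbour, 0.0) + mass
    return credits


def quality_counts(
    read: Read,
    k: int,
    redistribute: bool = False,
    base_freqs: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Quality-weighted counts X_w^q: each occurrence contributes its window
    correctness probability; with ``redistribute``, single-substitution
    neighbours additionally receive the occurrence's missing quality mass.

    ``base_freqs`` overrides the redistribution weights' base composition
    (dataset-global frequencies); default is the read's own composition.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    qcounts = np.zeros(4 ** k, dtype=float)
    if k > len(read):
        logger.warning("k=%d exceeds length of read %r; empty profile", k, read.id)
        return qcounts
    codes = encode_sequence(read.sequence)
    idx, valid = _window_indices(codes, k)
    if not np.any(valid):
        return qcounts
    probs = base_correct_prob(read.qualities)
    pwin = np.lib.stride_tricks.sliding_window_view(probs, k)[valid]
    widx = idx[valid]
    wprob = np.prod(pwin, axis=1)
    np.add.at(qcounts, widx, wprob)
    if not redistribute:
        return qcounts
    if base_freqs is None:
        base_freqs = base_frequencies(read)
    W = redistribution_weights(base_freqs)
    cwin = np.lib.stride_tricks.sliding_window_view(codes, k)[valid]
    # leave-one-out products of window correctness via forward/backward cumprods
    m = pwin.shape[0]
    fwd = np.ones((m, k))
    bwd = np.ones((m, k))
    if k > 1:
        fwd[:, 1:] = np.cumprod(pwin[:, :-1], axis=1)
        bwd[:, :-1] = np.cumprod(pwin[:, :0:-1], axis=1)[:, ::-1]
    loo = fwd * bwd
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    for j in range(k):
        called = cwin[:, j]
        missing = (1.0 - pwin[:, j]) * loo[:, j]
        for a in range(4):
            sel = called != a
            if not np.any(sel):
                continue
            mass = missing[sel] * W[called[sel], a]
            nidx = widx[sel] + (a - called[sel]) * powers[j]
            np.add.at(qcounts, nidx, mass)
    return qcounts


def background_word_prob(base_freqs: np.ndarray, word: str) -> float:
    """i.i.d. null-model probability of ``word``: the product of its
    letters' frequencies."""
    codes = encode_sequence(word)
    if np.any(codes < 0):
        raise ValueError(f"word {word!r} contains a non-ACGT base")
    return float(np.prod(np.asarray(base_freqs, dtype=float)[codes]))


def background_probs(base_freqs: np.ndarray, k: int) -> np.ndarray:
    """Vector of i.i.d. word probabilities over all 4^k words."""
    freqs = np.asarray(base_freqs, dtype=float)
    p = freqs
    for _ in range(k - 1):
        p = np.kron(p, freqs)
    return p


@dataclass
class KmerProfile:
    """Per-read word-count vectors over the 4^k words of length k.

    ``counts`` are plain occurrence counts X_w, ``qcounts`` the
    quality-weighted X_w^q; ``windows`` is the number of valid k-windows
    (n - k + 1 minus windows skipped for non-ACGT bases).
    """

    read_id: str
    k: int
    n: int
    counts: np.ndarray = field(repr=False)
    qcounts: np.ndarray = field(repr=False)
    base_freqs: np.ndarray = field(repr=False)
    windows: int = 0

    def background(self) -> np.ndarray:
        return background_probs(self.base_freqs, self.k)


def build_profile(
    read: Read,
    k: int,
    redistribute: bool = False,
    revcomp: bool = False,
    base_freqs: Optional[np.ndarray] = None,
) -> KmerProfile:
    """Count plain and quality-weighted k-mers for one read.

    With ``revcomp`` each word is pooled with its reverse complement into
    the canonical (smaller-index) word.
    """
    counts = count_kmers(read, k)
    qcounts = quality_counts(read, k, redistribute=redistribute, base_freqs=base_freqs)
    windows = int(counts.sum())
    if revcomp:
        counts = pool_reverse_complement(counts, k)
        qcounts = pool_reverse_complement(qcounts, k)
    freqs = base_frequencies(read) if base_freqs is None else np.asarray(base_freqs, float)
    return KmerProfile(
        read_id=read.id,
        k=k,
        n=len(read),
        counts=counts,
        qcounts=qcounts,
        base_freqs=freqs,
        windows=windows,
    )


@dataclass
class ExpectedWordProbabilities:
    """Dataset-level estimate of E(P_w), the expected probability that an
    occurrence of word w is read correctly.

    ``values`` holds NaN for words never observed; :meth:`resolved` fills
    those with ``fallback``.
    """

    k: int
    estimator: str
    values: np.ndarray = field(repr=False)
    fallback: float = 1.0

    def resolved(self) -> np.ndarray:
        out = self.values.copy()
        out[np.isnan(out)] = self.fallback
        return np.clip(out, 0.0, 1.0)


def default_fallback(reads: Iterable[Read], k: int) -> float:
    """Mean per-base correctness over the whole dataset, raised to k; used
    for words never observed so centred statistics keep finite denominators."""
    total = 0.0
    count = 0
    for read in reads:
        p = base_correct_prob(read.qualities)
        total += float(p.sum())
        count += p.size
    if count == 0:
        raise ValueError("empty read set")
    return (total / count) ** k


def estimate_awp(
    profiles: Sequence[KmerProfile],
    fallback: Optional[float] = None,
) -> ExpectedWordProbabilities:
    """Average Word Probability: E(P_w) ~ (sum_x X_w^q) / (sum_x X_w).

    Profiles must carry non-redistributed qcounts (redistribution modifies
    X_w^q, not the expectation).  If ``fallback`` is omitted the overall
    ratio of total qcounts to total counts is used for unobserved words.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("empty profile collection")
    k = profiles[0].k
    if any(p.k != k for p in profiles):
        raise ValueError("profiles must share k")
    num = np.zeros(4 ** k)
    den = np.zeros(4 ** k)
    for p in profiles:
        num += p.qcounts
        den += p.counts
    values = np.full(4 ** k, np.nan)
    seen = den > 0
    values[seen] = num[seen] / den[seen]
    if fallback is None:
        fallback = float(num.sum() / den.sum()) if den.sum() > 0 else 1.0
    return ExpectedWordProbabilities(k=k, estimator="AWP", values=values, fallback=fallback)


def estimate_aqp(
    reads: Sequence[Read],
    k: int,
    fallback: Optional[float] = None,
) -> ExpectedWordProbabilities:
    """Average Quality Probability: per-position mean phred over all
    occurrences of w, converted back to a product of correctness
    probabilities E(P_w) ~ prod_j (1 - 10^(-Qbar_w[j]/10))."""
    reads = list(reads)
    if not reads:
        raise ValueError("empty read set")
    qsum = np.zeros((4 ** k, k))
    occ = np.zeros(4 ** k)
    for read in reads:
        if k > len(read):
            continue
        codes = encode_sequence(read.sequence)
        idx, valid = _window_indices(codes, k)
        if not np.any(valid):
            continue
        widx = idx[valid]
        qwin = np.lib.stride_tricks.sliding_window_view(
            read.qualities.astype(float), k
        )[valid]
        for j in range(k):
            np.add.at(qsum[:, j], widx, qwin[:, j])
        np.add.at(occ, widx, 1)
    values = np.full(4 ** k, np.nan)
    seen = occ > 0
    if np.any(seen):
        qbar = qsum[seen] / occ[seen, None]
        values[seen] = np.prod(1.0 - np.power(10.0, -qbar / 10.0), axis=1)
    if fallback is None:
        fallback = default_fallback(reads, k)
    return ExpectedWordProbabilities(k=k, estimator="AQP", values=values, fallback=fallback)


def profiles_to_tsv(profiles: Iterable[KmerProfile], dest: IO[str]) -> None:
    """Export profiles as TSV rows (read_id, word, count, qcount); only
    words with nonzero count or qcount are written."""
    dest.write("read_id\tword\tcount\tqcount\n")
    for p in profiles:
        nz = np.nonzero((p.counts != 0) | (p.qcounts != 0))[0]
        for w in nz:
            dest.write(
                f"{p.read_id}\t{index_to_word(int(w), p.k)}\t{int(p.counts[w])}\t{p.qcounts[w]:.10g}\n"
            )
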