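"""Pairwise alignment-free statistics on k-mer profiles.

Classical D-type statistics compare word-count vectors directly (D2, the
inner product) or after centring by the expected count under an i.i.d. null
model (D2*, D2s).  Their quality-weighted counterparts (D2^q, D2*^q, D2^sq)
substitute quality-weighted counts X_w^q and scale the expected count by
E(P_w), the expected probability that an occurrence of w is correct.  L2,
KL and symmetrised KL operate on frequency-normalised vectors.

Similarities are turned into dissimilarities for clustering via the cosine
form 1 - S_xy / sqrt(S_xx * S_yy), clamped to [0, 2].

All kernels sum over the last axis, so they accept a (W,) pair or broadcast
an (N, W) batch against a (W,) centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Optional, Sequence

import numpy as np

#: measure name -> (uses quality-weighted counts, needs E(P_w), is a D-type similarity)
MEASURES = {
    "d2": dict(quality=False, expectation=False, dtype=True),
    "d2star": dict(quality=False, expectation=False, dtype=True),
    "d2s": dict(quality=False, expectation=False, dtype=True),
    "d2q": dict(quality=True, expectation=False, dtype=True),
    "d2star-q": dict(quality=True, expectation=True, dtype=True),
    "d2s-q": dict(quality=True, expectation=True, dtype=True),
    "l2": dict(quality=False, expectation=False, dtype=False),
    "kl": dict(quality=False, expectation=False, dtype=False),
    "symkl": dict(quality=False, expectation=False, dtype=False),
}

_QUALITY_DTYPES = {"d2q", "d2star-q", "d2s-q"}
_EXPECTATION_MEASURES = {"d2star-q", "d2s-q"}


@dataclass
class MeasureSpec:
    """Configuration of one pairwise statistic.

    ``estimator`` ('awp' or 'aqp') is required exactly for the centred
    quality-weighted measures, which need E(P_w); ``redistribute`` controls
    whether profile qcounts include single-substitution redistribution;
    ``pseudocount`` applies to KL-type measures (default 1/4^k at use time).
    """

    name: str
    estimator: Optional[str] = None
    redistribute: bool = False
    pseudocount: Optional[float] = None

    def __post_init__(self) -> None:
        if self.name not in MEASURES:
            raise ValueError(f"unknown measure {self.name!r}; choose from {sorted(MEASURES)}")
        if self.estimator is not None:
            self.estimator = self.estimator.lower()
            if self.estimator not in ("awp", "aqp"):
                raise ValueError("estimator must be 'awp' or 'aqp'")
        needs = self.name in _EXPECTATION_MEASURES
        if needs and self.estimator is None:
            raise ValueError(f"measure {self.name!r} requires an estimator (awp or aqp)")
        if not needs and self.estimator is not None:
            raise ValueError(f"measure {self.name!r} does not take an estimator")
        if self.pseudocount is not None and self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    @property
    def quality(self) -> bool:
        return self.name in _QUALITY_DTYPES

    @property
    def is_dtype(self) -> bool:
        return MEASURES[self.name]["dtype"]


def _check_same_k(X, Y) -> None:
    X = np.asarray(X)
    Y = np.asarray(Y)
    if X.shape[-1] != Y.shape[-1]:
        raise ValueError(f"word-vector lengths differ: {X.shape[-1]} vs {Y.shape[-1]}")


def d2(X, Y):
    """Inner product of word-count vectors."""
    _check_same_k(X, Y)
    return (np.asarray(X, float) * np.asarray(Y, float)).sum(axis=-1)


def _safe_ratio(num, den):
    """num/den with zero-denominator terms contributing 0."""
    den = np.asarray(den, float)
    out = np.zeros(np.broadcast_shapes(np.shape(num), den.shape))
    np.divide(num, den, out=out, where=den > 0)
    return out


def _expected_counts(n, p, E=None):
    """n * p_w (* E_w): expected (quality-weighted) count vector; ``n`` may
    be a scalar or an (N,) batch against (N, W) or (W,) probabilities."""
    n = np.asarray(n, float)
    p = np.asarray(p, float)
    e = n[..., None] * p if n.ndim > 0 else float(n) * p
    if E is not None:
        e = e * np.asarray(E, float)
    return e


def d2star(X, Y, pX, pY, nX, nY):
    """Background-centred, expectation-normalised similarity.

    Centred counts are Xt_w = X_w - nX * pX_w (nX = valid window count);
    the cross denominator is the geometric mean sqrt(nX pX_w * nY pY_w),
    which reduces to the single-n form when both reads share n and p.
    """
    _check_same_k(X, Y)
    eX = _expected_counts(nX, pX)
    eY = _expected_counts(nY, pY)
    Xt = np.asarray(X, float) - eX
    Yt = np.asarray(Y, float) - eY
    den = np.sqrt(eX * eY)
    return _safe_ratio(Xt * Yt, den).sum(axis=-1)


def d2s(X, Y, pX, pY, nX, nY):
    """Self-normalised centred similarity: sum Xt Yt / sqrt(Xt^2 + Yt^2)."""
    _check_same_k(X, Y)
    eX = _expected_counts(nX, pX)
    eY = _expected_counts(nY, pY)
    Xt = np.asarray(X, float) - eX
    Yt = np.asarray(Y, float) - eY
    den = np.sqrt(Xt ** 2 + Yt ** 2)
    return _safe_ratio(Xt * Yt, den).sum(axis=-1)


def d2q(Xq, Yq):
    """Inner product of quality-weighted count vectors."""
    return d2(Xq, Yq)


def d2star_q(Xq, Yq, pX, pY, E, nX, nY):
    """Quality-weighted D2*: centred by the expected quality-weighted count
    nX * p_w * E(P_w), with the geometric-mean cross denominator."""
    _check_same_k(Xq, Yq)
    eX = _expected_counts(nX, pX, E)
    eY = _expected_counts(nY, pY, E)
    Xt = np.asarray(Xq, float) - eX
    Yt = np.asarray(Yq, float) - eY
    den = np.sqrt(eX * eY)
    return _safe_ratio(Xt * Yt, den).sum(axis=-1)


def d2s_q(Xq, Yq, pX, pY, E, nX, nY):
    """Quality-weighted D2s: same centring as d2star_q, D2s denominator."""
    _check_same_k(Xq, Yq)
    eX = _expected_counts(nX, pX, E)
    eY = _expected_counts(nY, pY, E)
    Xt = np.asarray(Xq, float) - eX
    Yt = np.asarray(Yq, float) - eY
    den = np.sqrt(Xt ** 2 + Yt ** 2)
    return _safe_ratio(Xt * Yt, den).sum(axis=-1)


def _normalize(V):
    V = np.asarray(V, float)
    total = V.sum(axis=-1, keepdims=True)
    out = np.full_like(V, 1.0 / V.shape[-1])
    np.divide(V, total, out=out, where=total > 0)
    return out


def l2(X, Y):
    """Euclidean distance between frequency-normalised vectors."""
    _check_same_k(X, Y)
    return np.sqrt(((_normalize(X) - _normalize(Y)) ** 2).sum(axis=-1))


def kl(X, Y, pseudocount: Optional[float] = None):
    """Kullback-Leibler divergence (base-2) between pseudocounted,
    normalised count vectors: sum f_x log2(f_x / f_y)."""
    _check_same_k(X, Y)
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if pseudocount is None:
        pseudocount = 1.0 / X.shape[-1]
    fx = _normalize(X + pseudocount)
    fy = _normalize(Y + pseudocount)
    return (fx * np.log2(fx / fy)).sum(axis=-1)


def sym_kl(X, Y, pseudocount: Optional[float] = None):
    """Symmetrised KL: the average of the two directed divergences."""
    return 0.5 * (kl(X, Y, pseudocount) + kl(Y, X, pseudocount))


def to_dissimilarity(s_xy, s_xx, s_yy):
    """Convert a similarity into a dissimilarity: 1 - S_xy/sqrt(S_xx S_yy),
    clamped to [0, 2].  Requires positive self-similarities."""
    s_xx = np.asarray(s_xx, float)
    s_yy = np.asarray(s_yy, float)
    if np.any(s_xx <= 0) or np.any(s_yy <= 0):
        raise ValueError("self-similarity must be positive to form a dissimilarity")
    d = 1.0 - np.asarray(s_xy, float) / np.sqrt(s_xx * s_yy)
    return np.clip(d, 0.0, 2.0)


def profile_similarity(pa, pb, spec: MeasureSpec, expected=None):
    """Similarity (D-types) or distance (L2/KL-types) between two
    :class:`~kmerq.kmer_quality.KmerProfile` objects under ``spec``.

    ``expected`` is a resolved E(P_w) vector (or
    ExpectedWordProbabilities) for the centred quality measures.
    """
    name = spec.name
    if name == "d2":
        return float(d2(pa.counts, pb.counts))
    if name == "d2q":
        return float(d2q(pa.qcounts, pb.qcounts))
    if name == "l2":
        return float(l2(pa.counts, pb.counts))
    if name == "kl":
        return float(kl(pa.counts, pb.counts, spec.pseudocount))
    if name == "symkl":
        return float(sym_kl(pa.counts, pb.counts, spec.pseudocount))
    pX = pa.background()
    pY = pb.background()
    if name == "d2star":
        return float(d2star(pa.counts, pb.counts, pX, pY, pa.windows, pb.windows))
    if name == "d2s":
        return float(d2s(pa.counts, pb.counts, pX, pY, pa.windows, pb.windows))
    E = expected.resolved() if hasattr(expected, "resolved") else np.asarray(expected, float)
    if name == "d2star-q":
        return float(d2star_q(pa.qcounts, pb.qcounts, pX, pY, E, pa.windows, pb.windows))
    if name == "d2s-q":
        return float(d2s_q(pa.qcounts, pb.qcounts, pX, pY, E, pa.windows, pb.windows))
    raise AssertionError(name)


def profile_dissimilarity(pa, pb, spec: MeasureSpec, expected=None) -> float:
    """Dissimilarity between two profiles: L2/KL-types are already
    distances; D-type similarities go through :func:`to_dissimilarity`."""
    if not spec.is_dtype:
        return profile_similarity(pa, pb, spec, expected)
    s_xy = profile_similarity(pa, pb, spec, expected)
    s_xx = profile_similarity(pa, pa, spec, expected)
    s_yy = profile_similarity(pb, pb, spec, expected)
    return float(to_dissimilarity(s_xy, s_xx, s_yy))


def distance_matrix(profiles: Sequence, spec: MeasureSpec, expected=None) -> np.ndarray:
    """Square symmetric matrix of pairwise dissimilarities."""
    n = len(profiles)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = profile_dissimilarity(profiles[i], profiles[j], spec, expected)
    return D


def write_distance_matrix(profiles: Sequence, D: np.ndarray, dest: IO[str]) -> None:
    """TSV export with read ids as header row and column."""
    ids = [p.read_id for p in profiles]
    dest.write("\t" + "\t".join(ids) + "\n")
    for rid, row in zip(ids, D):
        dest.write(rid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
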