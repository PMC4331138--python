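"""Centroid-based (k-means) clustering of read profiles.

Lloyd-style alternation: assign each read to the nearest centroid under the
configured dissimilarity, recompute centroids as the arithmetic mean of
member vectors.  Some of the supported dissimilarities (symmetrised KL, the
centred D-types) do not guarantee monotone convergence, so a run tracks the
best assignment seen and stops when the assignment reaches a fixpoint, when
``max_iter`` is hit, or when the best distortion has not improved for
``max_no_improve`` consecutive iterations.  The whole procedure is repeated
``runs`` times from different seed-derived initialisations and the
lowest-distortion solution is returned.

Centroids for D-type measures live in raw (or quality-weighted) count space
and are compared to reads via the cosine-style dissimilarity; their expected
-count term uses the mean of the members' valid-window counts and base
frequencies.  L2/KL centroids live in frequency-normalised space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np

from kmerq.fastq_io import Read
from kmerq.kmer_quality import (
    ExpectedWordProbabilities,
    KmerProfile,
    background_probs,
    build_profile,
    default_fallback,
    estimate_awp,
    estimate_aqp,
    pool_reverse_complement,
)
from kmerq.measures import MeasureSpec

logger = logging.getLogger(__name__)

_SQRT2 = float(np.sqrt(2.0))


@dataclass
class ClusteringConfig:
    """Parameters of one clustering job.

    ``runs`` independent restarts are performed (run r uses seed + r) and
    the lowest-distortion solution wins; ``max_no_improve`` is the
    no-improvement stopping threshold within a run.
    """

    c: int
    measure: MeasureSpec
    runs: int = 5
    seed: int = 0
    max_iter: int = 100
    max_no_improve: int = 10

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("number of clusters must be >= 1")
        if self.runs < 1 or self.max_iter < 1 or self.max_no_improve < 1:
            raise ValueError("runs, max_iter and max_no_improve must be positive")


@dataclass
class Centroid:
    """A cluster centre in profile space: mean member vector plus the mean
    window count and base frequencies that define its expected-count term."""

    vector: np.ndarray = field(repr=False)
    windows: float = 0.0
    base_freqs: np.ndarray = field(default=None, repr=False)


@dataclass
class ClusteringResult:
    assignments: Dict[str, int]
    centroids: List[Centroid]
    distortion: float
    iterations: int
    best_run: int
    run_distortions: List[float] = field(default_factory=list)


class _Space:
    """Vectorised view of a profile collection under one measure."""

    def __init__(
        self,
        profiles: Sequence[KmerProfile],
        spec: MeasureSpec,
        expected: Optional[Union[ExpectedWordProbabilities, np.ndarray]] = None,
        revcomp: bool = False,
    ):
        self.spec = spec
        self.ids = [p.read_id for p in profiles]
        self.k = profiles[0].k
        self.revcomp = revcomp
        name = spec.name
        W = profiles[0].counts.size
        if any(p.counts.size != W for p in profiles):
            raise ValueError("profiles must share k")
        if name in ("d2star-q", "d2s-q"):
            if expected is None:
                raise ValueError(f"measure {name!r} requires expected word probabilities")
            self.E = expected.resolved() if hasattr(expected, "resolved") else np.asarray(expected, float)
        else:
            self.E = np.ones(W)
        raw = np.stack([p.qcounts if spec.quality else p.counts for p in profiles]).astype(float)
        self.n = np.array([p.windows for p in profiles], dtype=float)
        self.BF = np.stack([p.base_freqs for p in profiles])
        self.centered = name in ("d2star", "d2s", "d2star-q", "d2s-q")
        if name in ("l2", "kl", "symkl"):
            if name in ("kl", "symkl"):
                pc = spec.pseudocount if spec.pseudocount is not None else 1.0 / W
                raw = raw + pc
            total = raw.sum(axis=1, keepdims=True)
            total[total == 0] = 1.0
            self.V = raw / total
            self.PE = None
            self.Xt = None
        else:
            self.V = raw
            if self.centered:
                # per-read unit expectation p_w * E_w (pooled if revcomp)
                P = np.stack([background_probs(bf, self.k) for bf in self.BF])
                PE = P * self.E
                if revcomp:
                    PE = np.stack([pool_reverse_complement(row, self.k) for row in PE])
                self.PE = PE
                self.Xt = self.V - self.n[:, None] * PE
            else:
                self.PE = None
                self.Xt = None
        self._self_sim = self._self_similarities()

    def _self_similarities(self) -> Optional[np.ndarray]:
        name = self.spec.name
        if name in ("d2", "d2q"):
            return (self.V * self.V).sum(axis=1)
        if name in ("d2star", "d2star-q"):
            e = self.n[:, None] * self.PE
            out = np.zeros_like(self.Xt)
            np.divide(self.Xt ** 2, e, out=out, where=e > 0)
            return out.sum(axis=1)
        if name in ("d2s", "d2s-q"):
            return np.abs(self.Xt).sum(axis=1) / _SQRT2
        return None

    def centroid_from_members(self, members: np.ndarray) -> Centroid:
        return Centroid(
            vector=self.V[members].mean(axis=0),
            windows=float(self.n[members].mean()),
            base_freqs=self.BF[members].mean(axis=0),
        )

    def centroid_from_index(self, i: int) -> Centroid:
        return Centroid(vector=self.V[i].copy(), windows=float(self.n[i]), base_freqs=self.BF[i].copy())

    def _centroid_expectation(self, cen: Centroid) -> np.ndarray:
        pe = background_probs(cen.base_freqs, self.k) * self.E
        if self.revcomp:
            pe = pool_reverse_complement(pe, self.k)
        return cen.windows * pe

    def distances_to(self, cen: Centroid) -> np.ndarray:
        """Dissimilarity of every read to one centroid (vector of length N)."""
        name = self.spec.name
        Vc = cen.vector
        if name == "l2":
            return np.sqrt(((self.V - Vc) ** 2).sum(axis=1))
        if name in ("kl", "symkl"):
            fx, fc = self.V, np.maximum(Vc, 1e-300)
            with np.errstate(divide="ignore", invalid="ignore"):
                lr = np.where(fx > 0, np.log2(np.maximum(fx, 1e-300) / fc), 0.0)
            fwd = (fx * lr).sum(axis=1)
            if name == "kl":
                return fwd
            with np.errstate(divide="ignore", invalid="ignore"):
                lr2 = np.where(fc > 0, np.log2(fc / np.maximum(fx, 1e-300)), 0.0)
            bwd = (fc * lr2).sum(axis=1)
            return 0.5 * (fwd + bwd)
        # D-type similarities -> cosine-style dissimilarity
        if name in ("d2", "d2q"):
            s_xc = self.V @ Vc
            s_cc = float(Vc @ Vc)
            s_xx = self._self_sim
        elif name in ("d2star", "d2star-q"):
            ec = self._centroid_expectation(cen)
            Ct = Vc - ec
            ex = self.n[:, None] * self.PE
            den = np.sqrt(ex * ec)
            num = self.Xt * Ct
            terms = np.zeros_like(num)
            np.divide(num, den, out=terms, where=den > 0)
            s_xc = terms.sum(axis=1)
            cc = np.zeros_like(Ct)
            np.divide(Ct ** 2, ec, out=cc, where=ec > 0)
            s_cc = float(cc.sum())
            s_xx = self._self_sim
        else:  # d2s, d2s-q
            ec = self._centroid_expectation(cen)
            Ct = Vc - ec
            den = np.sqrt(self.Xt ** 2 + Ct ** 2)
            num = self.Xt * Ct
            terms = np.zeros_like(num)
            np.divide(num, den, out=terms, where=den > 0)
            s_xc = terms.sum(axis=1)
            s_cc = float(np.abs(Ct).sum() / _SQRT2)
            s_xx = self._self_sim
        dist = np.full(len(self.ids), 2.0)
        ok = (s_xx > 0) & (s_cc > 0)
        if np.any(ok):
            d = 1.0 - s_xc[ok] / np.sqrt(s_xx[ok] * s_cc)
            dist[ok] = np.clip(d, 0.0, 2.0)
        return dist

    def distance_matrix(self, centroids: Sequence[Centroid]) -> np.ndarray:
        return np.column_stack([self.distances_to(c) for c in centroids])


def _build_space(profiles, spec, expected, revcomp=False):
    order = np.argsort([p.read_id for p in profiles], kind="stable")
    return _Space([profiles[i] for i in order], spec, expected, revcomp=revcomp)


def assign(
    profiles: Sequence[KmerProfile],
    centroids: Sequence[Centroid],
    measure: MeasureSpec,
    expected=None,
    revcomp: bool = False,
) -> Dict[str, int]:
    """Map each read to its nearest centroid; ties break toward the lowest
    centroid index."""
    if not centroids:
        raise ValueError("no centroids")
    space = _build_space(list(profiles), measure, expected, revcomp)
    D = space.distance_matrix(centroids)
    lab = np.argmin(D, axis=1)  # argmin returns the first (lowest) index on ties
    return dict(zip(space.ids, (int(v) for v in lab)))


def update_centroids(
    profiles: Sequence[KmerProfile],
    assignments: Mapping[str, int],
    c: int,
    measure: Optional[MeasureSpec] = None,
    current: Optional[Sequence[Centroid]] = None,
    expected=None,
    revcomp: bool = False,
) -> List[Centroid]:
    """Componentwise-mean centroids per cluster.  An empty cluster is
    reseeded with the profile farthest from its current centroid (requires
    ``measure`` and ``current``); without them it is reseeded with the first
    profile."""
    spec = measure if measure is not None else MeasureSpec("l2")
    space = _build_space(list(profiles), spec, expected, revcomp)
    lab = np.array([assignments[rid] for rid in space.ids])
    out: List[Centroid] = []
    for j in range(c):
        members = np.nonzero(lab == j)[0]
        if members.size:
            out.append(space.centroid_from_members(members))
        elif current is not None and measure is not None:
            far = int(np.argmax(space.distances_to(current[j])))
            out.append(space.centroid_from_index(far))
        else:
            out.append(space.centroid_from_index(0))
    return out


def _single_run(space: _Space, config: ClusteringConfig, rng: np.random.Generator):
    N = len(space.ids)
    init = rng.choice(N, size=config.c, replace=False)
    centroids = [space.centroid_from_index(int(i)) for i in init]
    best_lab = None
    best_dist = np.inf
    best_cents = centroids
    no_improve = 0
    prev_lab = None
    it = 0
    for it in range(1, config.max_iter + 1):
        D = space.distance_matrix(centroids)
        lab = np.argmin(D, axis=1)
        distortion = float(D[np.arange(N), lab].sum())
        if distortion < best_dist:
            best_dist = distortion
            best_lab = lab.copy()
            best_cents = [Centroid(c.vector.copy(), c.windows, c.base_freqs.copy()) for c in centroids]
            no_improve = 0
        else:
            no_improve += 1
        logger.debug("iteration %d distortion %.6g", it, distortion)
        if prev_lab is not None and np.array_equal(lab, prev_lab):
            break
        if no_improve > config.max_no_improve:
            break
        new_cents: List[Centroid] = []
        for j in range(config.c):
            members = np.nonzero(lab == j)[0]
            if members.size:
                new_cents.append(space.centroid_from_members(members))
            else:
                far = int(np.argmax(space.distances_to(centroids[j])))
                new_cents.append(space.centroid_from_index(far))
        centroids = new_cents
        prev_lab = lab
    return best_lab, best_cents, best_dist, it


def kmeans(
    profiles: Sequence[KmerProfile],
    config: ClusteringConfig,
    expected=None,
    revcomp: bool = False,
) -> ClusteringResult:
    """Best-of-``runs`` k-means clustering of profiles under the configured
    measure.  Deterministic given the seed; invariant to the input order of
    profiles (initial centroids are drawn from the id-sorted order)."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to cluster")
    if config.c > len(profiles):
        raise ValueError(f"c={config.c} exceeds number of reads {len(profiles)}")
    space = _build_space(profiles, config.measure, expected, revcomp)
    best = None
    run_dists: List[float] = []
    for r in range(config.runs):
        rng = np.random.default_rng(config.seed + r)
        lab, cents, dist, iters = _single_run(space, config, rng)
        run_dists.append(dist)
        if best is None or dist < best[2]:
            best = (lab, cents, dist, iters, r)
    lab, cents, dist, iters, run = best
    assignments = dict(zip(space.ids, (int(v) for v in lab)))
    return ClusteringResult(
        assignments=assignments,
        centroids=cents,
        distortion=dist,
        iterations=iters,
        best_run=run,
        run_distortions=run_dists,
    )


def cluster_reads(
    reads: Sequence[Read],
    k: int,
    config: ClusteringConfig,
    revcomp: bool = False,
):
    """End-to-end pipeline: profiles, E(P_w) estimation, k-means.

    E(P_w) is estimated once on the whole dataset from non-redistributed
    occurrence probabilities, before any redistribution is applied to the
    profile vectors.  Returns (result, profiles, expected).
    """
    reads = list(reads)
    spec = config.measure
    base = [build_profile(r, k, redistribute=False, revcomp=revcomp) for r in reads]
    expected = None
    if spec.name in ("d2star-q", "d2s-q"):
        if spec.estimator == "awp":
            # AWP needs unpooled plain/quality counts
            plain = base if not revcomp else [build_profile(r, k) for r in reads]
            expected = estimate_awp(plain, fallback=default_fallback(reads, k))
        else:
            expected = estimate_aqp(reads, k)
    if spec.redistribute and spec.quality:
        profiles = [build_profile(r, k, redistribute=True, revcomp=revcomp) for r in reads]
    else:
        profiles = base
    result = kmeans(profiles, config, expected=expected, revcomp=revcomp)
    return result, profiles, expected
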