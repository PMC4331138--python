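"""Synthetic references and quality-annotated reads with controlled error
rates.

The generator emulates a read-simulation experiment at desk scale: a set of
random reference sequences whose base compositions are jittered so they are
distinguishable by k-mer spectra, and fixed-length reads drawn uniformly
from them.  Per-base phred values follow an Illumina-like profile (mean
declining linearly along the read plus integer Gaussian noise) and each
base is substituted with probability 10^(-Q/10), so the emitted qualities
are statistically consistent with the injected errors — the premise of
quality-weighted comparison.  Additional mismatch / insertion / deletion
channels can be layered on top at configured rates; an extra mismatch
lowers the colliding base's quality so qualities stay informative.

A ground-truth table mapping each read id to its source reference is
returned alongside the reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from kmerq.fastq_io import Read
from kmerq.kmer_quality import BASES

_CODES_TO_BASE = np.frombuffer("ACGT".encode("ascii"), dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Reference lengths are drawn uniformly from ``ref_length_range``; read
    qualities decline linearly from ``quality_start`` to ``quality_end``
    (phred) with Gaussian noise of sd ``quality_sd``, clamped to
    [quality_min, quality_max].  ``composition_alpha`` is the per-base
    Dirichlet concentration of the reference compositions (None = no
    jitter, all references share the uniform composition);
    ``ref_compositions`` overrides the compositions explicitly.

    With ``markov_order=1`` (default) each reference is an order-1 Markov
    chain whose transition rows are drawn from
    Dirichlet(composition * transition_concentration) — mean row equal to
    the reference's composition, so every reference acquires its own
    dinucleotide character the way real transcripts do.  Lower
    ``transition_concentration`` means stronger character;
    ``markov_order=0`` gives plain i.i.d. sequences.
    """

    n_refs: int = 3
    ref_length_range: Tuple[int, int] = (500, 10000)
    reads_per_ref: int = 1000
    read_length: int = 200
    mismatch_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    quality_start: float = 38.0
    quality_end: float = 20.0
    quality_sd: float = 3.0
    quality_min: int = 2
    quality_max: int = 40
    composition_alpha: Optional[float] = 25.0
    ref_compositions: Optional[Sequence[Sequence[float]]] = None
    markov_order: int = 1
    transition_concentration: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_refs < 1 or self.reads_per_ref < 1 or self.read_length < 1:
            raise ValueError("n_refs, reads_per_ref and read_length must be positive")
        lo, hi = self.ref_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid reference length range")
        rates = (self.mismatch_rate, self.insertion_rate, self.deletion_rate)
        if any(r < 0 or r >= 1 for r in rates) or sum(rates) >= 1:
            raise ValueError("error rates must be in [0, 1) and sum below 1")
        if self.read_length > lo:
            raise ValueError("read_length exceeds the minimum reference length")
        if self.ref_compositions is not None and len(self.ref_compositions) != self.n_refs:
            raise ValueError("one composition per reference required")
        if self.markov_order not in (0, 1):
            raise ValueError("markov_order must be 0 (i.i.d.) or 1")
        if self.transition_concentration <= 0:
            raise ValueError("transition_concentration must be positive")

    @property
    def n_reads(self) -> int:
        return self.n_refs * self.reads_per_ref


@dataclass
class Reference:
    id: str
    sequence: str
    composition: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.sequence)


def generate_references(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[Reference]:
    """i.i.d. random references with Dirichlet-jittered base compositions;
    deterministic given ``config.seed``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.ref_length_range
    refs = []
    for i in range(config.n_refs):
        if config.ref_compositions is not None:
            comp = np.asarray(config.ref_compositions[i], dtype=float)
            comp = comp / comp.sum()
        elif config.composition_alpha is None:
            comp = np.full(4, 0.25)
        else:
            comp = rng.dirichlet(np.full(4, config.composition_alpha))
        length = int(rng.integers(lo, hi + 1))
        if config.markov_order == 0:
            codes = rng.choice(4, size=length, p=comp)
        else:
            T = np.stack(
                [rng.dirichlet(np.maximum(comp, 1e-6) * config.transition_concentration) for _ in range(4)]
            )
            cum = np.cumsum(T, axis=1)
            codes = np.empty(length, dtype=np.int64)
            codes[0] = rng.choice(4, p=comp)
            draws = rng.random(length)
            for j in range(1, length):
                codes[j] = np.searchsorted(cum[codes[j - 1]], draws[j])
        seq = bytes(_CODES_TO_BASE[codes]).decode("ascii")
        refs.append(Reference(id=f"ref{i}", sequence=seq, composition=comp))
    return refs


def _quality_profile(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    L = config.read_length
    pos = np.arange(L)
    mean = config.quality_start + (config.quality_end - config.quality_start) * pos / max(L - 1, 1)
    q = np.rint(mean + rng.normal(0.0, config.quality_sd, size=L)).astype(np.int64)
    return np.clip(q, config.quality_min, config.quality_max)


def _walk_with_indels(
    ref_codes: np.ndarray,
    start: int,
    L: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Emit L base codes walking the reference from ``start``: deletions
    skip a reference base, insertions emit a uniform random base without
    advancing."""
    out = np.empty(L, dtype=np.int64)
    pos = start
    i = 0
    p_del = config.deletion_rate
    p_ins = config.insertion_rate
    while i < L:
        u = rng.random()
        if u < p_del:
            pos += 1
            continue
        if u < p_del + p_ins:
            out[i] = rng.integers(4)
            i += 1
            continue
        if pos >= ref_codes.size:
            raise ValueError("read extends past the reference end")
        out[i] = ref_codes[pos]
        pos += 1
        i += 1
    return out


def simulate_reads(
    references: Sequence[Reference],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[Read], Dict[str, str]]:
    """Draw ``config.n_reads`` reads: reference and start uniform, per-base
    substitution with probability 10^(-Q/10), plus the configured extra
    mismatch / insertion / deletion channels.

    Returns (reads, truth) where truth maps read id -> reference id.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.read_length
    # margin so deletions cannot run off the reference end
    need = L + 10 + math.ceil(3 * L * config.deletion_rate / max(1e-9, 1 - config.deletion_rate))
    need = max(need, L)
    ref_codes = []
    base_lookup = np.full(128, -1, dtype=np.int64)
    for i, b in enumerate(BASES):
        base_lookup[ord(b)] = i
    for ref in references:
        codes = base_lookup[np.frombuffer(ref.sequence.encode("ascii"), dtype=np.uint8)]
        if codes.size < (need if config.deletion_rate > 0 else L):
            raise ValueError(f"reference {ref.id!r} shorter than a read plus deletion margin")
        ref_codes.append(codes)
    mism_q = None
    if config.mismatch_rate > 0:
        mism_q = int(np.clip(round(-10 * math.log10(config.mismatch_rate)), config.quality_min, config.quality_max))
    reads: List[Read] = []
    truth: Dict[str, str] = {}
    width = len(str(config.n_reads - 1))
    has_indels = config.insertion_rate > 0 or config.deletion_rate > 0
    span = need if has_indels else L
    for i in range(config.n_reads):
        r = int(rng.integers(len(references)))
        codes = ref_codes[r]
        start = int(rng.integers(0, codes.size - span + 1))
        if has_indels:
            emitted = _walk_with_indels(codes, start, L, config, rng)
        else:
            emitted = codes[start : start + L].copy()
        quals = _quality_profile(config, rng)
        # quality-implied substitutions: qualities stay truthful about them
        p_err = np.power(10.0, -quals / 10.0)
        flip = rng.random(L) < p_err
        if np.any(flip):
            emitted[flip] = (emitted[flip] + rng.integers(1, 4, size=int(flip.sum()))) % 4
        if config.mismatch_rate > 0:
            extra = rng.random(L) < config.mismatch_rate
            if np.any(extra):
                emitted[extra] = (emitted[extra] + rng.integers(1, 4, size=int(extra.sum()))) % 4
                quals[extra] = np.minimum(quals[extra], mism_q)
        rid = f"read{i:0{width}d}"
        seq = bytes(_CODES_TO_BASE[emitted]).decode("ascii")
        reads.append(Read(id=rid, sequence=seq, qualities=quals))
        truth[rid] = references[r].id
    return reads, truth


def simulate_dataset(config: SimulationConfig):
    """References, reads and truth table from one seed-derived RNG stream."""
    rng = np.random.default_rng(config.seed)
    references = generate_references(config, rng)
    reads, truth = simulate_reads(references, config, rng)
    return references, reads, truth
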