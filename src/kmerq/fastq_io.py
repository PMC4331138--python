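"""FASTQ input/output and phred-score semantics.

A phred score Q encodes the probability that the called base is wrong as
P_err = 10^(-Q/10); Q=30 means a 1-in-1000 chance of error.  Everything
downstream works with the complementary per-base *correctness* probability
1 - 10^(-Q/10).
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

import numpy as np

logger = logging.getLogger(__name__)

#: Highest phred value representable in Sanger FASTQ ('~' with offset 33).
MAX_PHRED = 93


class FastqParseError(ValueError):
    """Raised on a malformed FASTQ record; the message names the record index."""


@dataclass
class Read:
    """One sequencing read with per-base phred qualities.

    ``qualities`` holds one integer per base.  Reads parsed from FASTQ have
    qualities in [0, 93]; programmatically constructed reads may exceed the
    encodable range (useful for modelling error-free bases, since
    1 - 10^(-q/10) rounds to exactly 1.0 in double precision for q > 160).
    """

    id: str
    sequence: str
    qualities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )
        if self.qualities.size and self.qualities.min() < 0:
            raise ValueError(f"read {self.id!r}: negative quality value")

    def __len__(self) -> int:
        return len(self.sequence)

    def correct_probs(self) -> np.ndarray:
        """Per-base correctness probabilities 1 - 10^(-Q/10)."""
        return base_correct_prob(self.qualities)


def base_correct_prob(q):
    """Probability that a base with phred score ``q`` was called correctly.

    Accepts a scalar or array; returns the same shape.  Strictly increasing
    in q and bounded in [0, 1).

    >>> base_correct_prob(30)
    0.999
    """
    arr = np.asarray(q, dtype=float)
    if np.any(arr < 0):
        raise ValueError("phred quality must be >= 0")
    out = 1.0 - np.power(10.0, -arr / 10.0)
    if np.isscalar(q) or arr.ndim == 0:
        return float(out)
    return out


def _open_text(path_or_stream, mode: str = "rt") -> IO[str]:
    if isinstance(path_or_stream, (str, Path)):
        p = Path(path_or_stream)
        if p.suffix == ".gz":
            return gzip.open(p, mode)
        return open(p, mode)
    return path_or_stream


def parse_fastq(
    source: Union[str, Path, IO[str]],
    offset: int = 33,
) -> Iterator[Read]:
    """Yield :class:`Read` objects from a 4-line-per-record FASTQ source.

    Parameters
    ----------
    source:
        Path (``.gz`` accepted) or open text stream.
    offset:
        Phred encoding offset, 33 (Sanger, default) or 64.

    Raises
    ------
    FastqParseError
        On a record whose header lacks '@', whose separator lacks '+', or
        whose quality string length differs from its sequence length.  The
        error message names the 0-based record index.
    """
    if offset not in (33, 64):
        raise ValueError(f"phred offset must be 33 or 64, got {offset}")
    handle = _open_text(source)
    close = isinstance(source, (str, Path))
    n_high = 0
    n_bases = 0
    try:
        record = 0
        while True:
            header = handle.readline()
            if not header:
                break
            header = header.rstrip("\n")
            if not header.strip() and not handle.readline():
                break  # trailing blank line
            if not header.startswith("@"):
                raise FastqParseError(f"record {record}: header does not start with '@'")
            seq = handle.readline().rstrip("\n")
            sep = handle.readline().rstrip("\n")
            qual = handle.readline().rstrip("\n")
            if not sep.startswith("+"):
                raise FastqParseError(f"record {record}: separator does not start with '+'")
            if len(qual) != len(seq):
                raise FastqParseError(
                    f"record {record}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - offset
            if quals.size and quals.min() < 0:
                raise FastqParseError(
                    f"record {record}: quality character below offset {offset}"
                )
            # cap: guards against offset-64 files read as offset-33
            n_high += int(np.count_nonzero(quals > 60))
            n_bases += quals.size
            quals = np.minimum(quals, MAX_PHRED)
            yield Read(id=header[1:].split()[0] if len(header) > 1 else "", sequence=seq, qualities=quals)
            record += 1
        if offset == 33 and n_bases and n_high > 0.1 * n_bases:
            logger.warning(
                "%.0f%% of bases have phred > 60 under offset 33; "
                "input may be phred+64 encoded",
                100.0 * n_high / n_bases,
            )
    finally:
        if close:
            handle.close()


def write_fastq(
    reads: Iterable[Read],
    dest: Union[str, Path, IO[str]],
    offset: int = 33,
) -> None:
    """Write reads as 4-line FASTQ records; qualities clipped to the encodable range."""
    handle = _open_text(dest, "wt")
    close = isinstance(dest, (str, Path))
    try:
        for read in reads:
            q = np.clip(read.qualities, 0, MAX_PHRED) + offset
            qual = bytes(q.astype(np.uint8)).decode("ascii")
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")
    finally:
        if close:
            handle.close()


def reads_to_string(reads: Iterable[Read], offset: int = 33) -> str:
    """Render reads as a FASTQ string (convenience for tests and determinism checks)."""
    buf = io.StringIO()
    write_fastq(reads, buf, offset=offset)
    return buf.getvalue()
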