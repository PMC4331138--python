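"""Recall-rate evaluation of a clustering against ground-truth read origins.

For each source sequence S, the cluster C holding the plurality of S's
reads is found; recall(S) is the fraction of S's reads that landed in C.
The reported recall rate is the unweighted mean over sources.  Note the
definition's degeneracy: a single all-encompassing cluster scores 1.0, so
the measure is informative only at a fixed number of clusters.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from pathlib import Path
from typing import IO, Dict, Mapping, Tuple, Union


def per_source_recall(
    assignments: Mapping[str, int],
    truth: Mapping[str, str],
) -> Dict[str, float]:
    """Recall of every source: fraction of its reads in its plurality
    cluster (ties broken toward the lowest cluster index)."""
    a_ids = set(assignments)
    t_ids = set(truth)
    if a_ids != t_ids:
        missing = (a_ids - t_ids) or (t_ids - a_ids)
        raise ValueError(
            f"assignments and truth cover different read ids "
            f"({len(missing)} mismatched, e.g. {sorted(missing)[:3]})"
        )
    by_source: Dict[str, Counter] = defaultdict(Counter)
    totals: Dict[str, int] = defaultdict(int)
    for rid, source in truth.items():
        by_source[source][assignments[rid]] += 1
        totals[source] += 1
    recalls = {}
    for source, counts in by_source.items():
        best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
        recalls[source] = best[1] / totals[source]
    return recalls


def recall_rate(assignments: Mapping[str, int], truth: Mapping[str, str]) -> float:
    """Unweighted mean of per-source recalls."""
    recalls = per_source_recall(assignments, truth)
    return sum(recalls.values()) / len(recalls)


def read_truth_table(source: Union[str, Path, IO[str]]) -> Dict[str, str]:
    """Load a 2-column TSV (read_id, source_id); a header line starting
    with 'read_id' is skipped."""
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            return read_truth_table(handle)
    truth: Dict[str, str] = {}
    for line_no, line in enumerate(source):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if line_no == 0 and parts[0] == "read_id":
            continue
        if len(parts) != 2:
            raise ValueError(f"truth table line {line_no}: expected 2 columns, got {len(parts)}")
        if parts[0] in truth:
            raise ValueError(f"duplicate read id {parts[0]!r} in truth table")
        truth[parts[0]] = parts[1]
    return truth


def write_truth_table(truth: Mapping[str, str], dest: Union[str, Path, IO[str]]) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as handle:
            write_truth_table(truth, handle)
        return
    dest.write("read_id\tsource_id\n")
    for rid, source in truth.items():
        dest.write(f"{rid}\t{source}\n")


def write_recall_report(
    assignments: Mapping[str, int],
    truth: Mapping[str, str],
    dest: IO[str],
) -> Tuple[Dict[str, float], float]:
    """Write a per-source recall TSV plus the mean; returns both."""
    recalls = per_source_recall(assignments, truth)
    mean = sum(recalls.values()) / len(recalls)
    dest.write("source_id\trecall\n")
    for source in sorted(recalls):
        dest.write(f"{source}\t{recalls[source]:.6f}\n")
    dest.write(f"mean\t{mean:.6f}\n")
    return recalls, mean
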