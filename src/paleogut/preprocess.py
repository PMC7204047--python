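"""Read pre-processing: adapter trimming, length / quality / complexity
filtering, exact-duplicate collapsing and negative-control subtraction.

The filter order is fixed and logged: adapter -> length -> quality ->
complexity -> dedup -> control subtraction.  Each removed read is counted
once, under the first rule it fails, so input = output + sum(removals).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .containers import Read, ReadSet


@dataclass(frozen=True)
class FilterConfig:
    min_length: int = 25
    min_mean_quality: float = 25.0
    adapter: str = ""
    min_adapter_overlap: int = 4
    max_adapter_mismatch_rate: float = 0.1
    complexity_threshold: float = 0.45
    denylist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.min_length < 0 or self.min_mean_quality < 0:
            raise ValueError("thresholds must be non-negative")


def trim_adapter(
    read: Read, adapter: str, min_overlap: int = 4, max_mismatch_rate: float = 0.1
) -> Read:
    """Remove the longest read-suffix matching an adapter prefix.

    All suffix/prefix overlap lengths from the longest down are examined; the
    longest one whose mismatch rate is <= ``max_mismatch_rate`` is trimmed.
    No qualifying overlap leaves the read unchanged.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not adapter:
        return read
    seq = read.sequence
    max_ov = min(len(seq), len(adapter))
    for ov in range(max_ov, min_overlap - 1, -1):
        tail = seq[-ov:]
        head = adapter[:ov]
        mismatches = sum(a != b for a, b in zip(tail, head))
        if mismatches / ov <= max_mismatch_rate:
            return Read(read.read_id, seq[:-ov], read.quality[:-ov])
    return read


def trinucleotide_complexity(seq: str) -> float:
    """Normalised Shannon entropy of overlapping trinucleotides in [0, 1].

    0 for a homopolymer, 1 when the observed trinucleotides are uniformly
    distributed over the available windows.
    """
    n = len(seq) - 2
    if n <= 1:
        return 0.0
    counts = Counter(seq[i : i + 3] for i in range(n))
    h = -sum((c / n) * math.log(c / n) for c in counts.values())
    h_max = math.log(min(64, n))
    return h / h_max if h_max > 0 else 0.0


def _valid_quality(read: Read) -> bool:
    if len(read.quality) != len(read.sequence):
        return False
    return all(33 <= ord(c) <= 126 for c in read.quality)


def filter_reads(
    readset: ReadSet, config: FilterConfig
) -> tuple[ReadSet, dict[str, int]]:
    """Apply adapter, length, mean-quality and complexity filters.

    Removal counts are partitioned by the first failing rule in the order
    malformed -> length -> quality -> complexity.
    """
    kept: list[Read] = []
    removed = {"malformed": 0, "length": 0, "quality": 0, "complexity": 0}
    for read in readset:
        if config.adapter:
            read = trim_adapter(
                read,
                config.adapter,
                config.min_adapter_overlap,
                config.max_adapter_mismatch_rate,
            )
        if not _valid_quality(read):
            removed["malformed"] += 1
            continue
        if len(read) < config.min_length:
            removed["length"] += 1
            continue
        if read.mean_phred() < config.min_mean_quality:
            removed["quality"] += 1
            continue
        if trinucleotide_complexity(read.sequence) < config.complexity_threshold:
            removed["complexity"] += 1
            continue
        if read.sequence in config.denylist:
            removed.setdefault("denylist", 0)
            removed["denylist"] += 1
            continue
        kept.append(read)
    out = ReadSet(sample_id=readset.sample_id, reads=kept, history=list(readset.history))
    out.log_stage("filter", {"kept": len(kept), **removed})
    return out, removed


def dedupe_and_subtract(
    readset: ReadSet, control_readsets: Sequence[ReadSet] = ()
) -> tuple[ReadSet, dict[str, int]]:
    """Collapse exact-sequence duplicates and purge control-matching reads.

    Duplicates are byte-identical full sequences (qualities ignored); the
    first occurrence is kept.  Any read whose sequence occurs in any control
    readset is removed, mirroring negative-control (E-LPC) subtraction.
    """
    control_seqs: set[str] = set()
    for cs in control_readsets:
        control_seqs.update(r.sequence for r in cs)
    seen: set[str] = set()
    kept: list[Read] = []
    counts = {"duplicate": 0, "control": 0}
    for read in readset:
        if read.sequence in control_seqs:
            counts["control"] += 1
            continue
        if read.sequence in seen:
            counts["duplicate"] += 1
            continue
        seen.add(read.sequence)
        kept.append(read)
    out = ReadSet(sample_id=readset.sample_id, reads=kept, history=list(readset.history))
    out.log_stage("dedupe_subtract", {"kept": len(kept), **counts})
    return out, counts


def preprocess_readset(
    readset: ReadSet,
    config: FilterConfig,
    control_readsets: Sequence[ReadSet] = (),
) -> tuple[ReadSet, dict[str, int]]:
    """Full pre-processing pass; removal accounting is conserving."""
    n_in = len(readset)
    filtered, removed = filter_reads(readset, config)
    final, dd = dedupe_and_subtract(filtered, control_readsets)
    counts = {**removed, **dd, "input": n_in, "output": len(final)}
    return final, counts
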