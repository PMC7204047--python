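"""Seed-and-extend read alignment and LCA taxonomic assignment.

A lightweight exact-k-mer aligner (ungapped extension over seed diagonals,
both strands) stands in for a full database search at desk scale.  Retained
hits are reduced MEGAN-style: identity and score floors, top-percent
retention relative to the best hit, lowest-common-ancestor assignment, and
a bottom-up min-support sweep that lifts sparse taxa to their parents.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import AlignedRead, Read, ReadSet, revcomp
from .simulate import RANKS, ReferencePanel


@dataclass(frozen=True)
class Node:
    node_id: str
    name: str
    rank: str
    parent: str | None  # None only for the root


class TaxonomyTree:
    """A single-rooted taxonomy over panel taxa plus their internal ranks."""

    def __init__(self, nodes: Iterable[Node]):
        self.nodes: dict[str, Node] = {n.node_id: n for n in nodes}
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, got {len(roots)}")
        self.root = roots[0].node_id
        for n in self.nodes.values():
            if n.parent is not None and n.parent not in self.nodes:
                raise ValueError(f"dangling parent {n.parent!r} for {n.node_id!r}")

    @classmethod
    def from_panel(cls, panel: ReferencePanel) -> "TaxonomyTree":
        nodes: dict[str, Node] = {}
        for t in panel.taxa:
            parent = None
            for rank, name in t.lineage:
                node_id = name if rank != "species" else t.taxon_id
                if node_id not in nodes:
                    nodes[node_id] = Node(node_id, name, rank, parent)
                parent = node_id
        return cls(nodes.values())

    def parent(self, node_id: str) -> str | None:
        return self.nodes[node_id].parent

    def path_to_root(self, node_id: str) -> list[str]:
        if node_id not in self.nodes:
            raise KeyError(f"taxon {node_id!r} not in taxonomy")
        path = [node_id]
        while (p := self.nodes[path[-1]].parent) is not None:
            path.append(p)
        return path

    def depth(self, node_id: str) -> int:
        return len(self.path_to_root(node_id)) - 1

    def lca(self, node_ids: Sequence[str]) -> str:
        paths = [list(reversed(self.path_to_root(n))) for n in set(node_ids)]
        if not paths:
            raise ValueError("lca of empty set")
        anc = self.root
        for level in range(min(len(p) for p in paths)):
            candidates = {p[level] for p in paths}
            if len(candidates) == 1:
                anc = candidates.pop()
            else:
                break
        return anc

    def children(self, node_id: str) -> list[str]:
        return sorted(n.node_id for n in self.nodes.values() if n.parent == node_id)


@dataclass(frozen=True)
class Hit:
    read_id: str
    taxon_id: str
    score: int  # matches - mismatches over the aligned span
    identity: float  # percent, in [0, 100]
    read_start: int  # aligned span on the read, as given (strand of the hit)
    read_end: int
    ref_start: int
    ref_end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity out of [0, 100]")


class KmerIndex:
    """Exact k-mer index over the forward strands of a reference panel."""

    def __init__(self, panel: ReferencePanel, k: int = 13):
        if k < 4:
            raise ValueError("k must be >= 4")
        self.panel = panel
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for tid in panel.taxon_ids:
            seq = panel.sequences[tid]
            for pos in range(len(seq) - k + 1):
                self.index[seq[pos : pos + k]].append((tid, pos))

    def seeds(self, seq: str) -> dict[tuple[str, int], int]:
        """Candidate (taxon, diagonal-offset) pairs with seed counts."""
        hits: dict[tuple[str, int], int] = defaultdict(int)
        k = self.k
        for p in range(len(seq) - k + 1):
            for tid, rpos in self.index.get(seq[p : p + k], ()):
                hits[(tid, rpos - p)] += 1
        return hits


def _extend(seq: str, ref: str, offset: int) -> tuple[int, int, int, int]:
    """Ungapped scoring of ``seq`` against ``ref`` on one diagonal.

    Returns (matches, span, read_start, read_end) for the overlap of the read
    with the reference at that offset.
    """
    a = max(0, -offset)
    b = min(len(seq), len(ref) - offset)
    matches = sum(seq[i] == ref[offset + i] for i in range(a, b))
    return matches, b - a, a, b


def align_read(read: Read, index: KmerIndex, max_candidates: int = 50) -> list[Hit]:
    """All per-taxon best placements of a read against the panel.

    Seeds on both strands; each candidate diagonal is extended ungapped to
    the full read overlap.  One best-scoring placement is kept per taxon,
    ties broken by strand ('+' first) then smaller reference offset.
    """
    if len(read.sequence) < index.k:
        return []
    best: dict[str, tuple] = {}
    for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
        cands = index.seeds(seq)
        ordered = sorted(cands, key=lambda kv: (-cands[kv], kv))[:max_candidates]
        for tid, offset in ordered:
            ref = index.panel.sequences[tid]
            matches, span, a, b = _extend(seq, ref, offset)
            if span <= 0:
                continue
            score = 2 * matches - span  # matches - mismatches
            identity = 100.0 * matches / span
            key = (score, strand == "+", -offset)
            prev = best.get(tid)
            if prev is None or key > prev[0]:
                best[tid] = (
                    key,
                    Hit(
                        read_id=read.read_id,
                        taxon_id=tid,
                        score=score,
                        identity=round(identity, 4),
                        read_start=a,
                        read_end=b,
                        ref_start=offset + a,
                        ref_end=offset + b,
                        strand=strand,
                    ),
                )
    return sorted((v[1] for v in best.values()), key=lambda h: (-h.score, h.taxon_id))


def hit_alignment(read: Read, hit: Hit, panel: ReferencePanel) -> AlignedRead:
    """Build the as-sequenced read/reference pair for damage profiling."""
    ref_seg = panel.sequences[hit.taxon_id][hit.ref_start : hit.ref_end]
    L = len(read.sequence)
    if hit.strand == "+":
        frag = read.sequence[hit.read_start : hit.read_end]
        offset = hit.read_start
    else:
        ref_seg = revcomp(ref_seg)
        frag = read.sequence[L - hit.read_end : L - hit.read_start]
        offset = L - hit.read_end
    return AlignedRead(
        read_id=read.read_id,
        taxon_id=hit.taxon_id,
        read_frag=frag,
        ref_frag=ref_seg,
        read_offset=offset,
        read_length=L,
    )


def assign_lca(
    hits: Sequence[Hit],
    tree: TaxonomyTree,
    min_identity: float = 97.0,
    top_percent: float = 10.0,
    min_score: float = 30.0,
) -> str | None:
    """Top-percent retention + LCA over a read's filtered hits.

    Hits below the identity or score floor are dropped; the retained set is
    every hit with score >= (1 - top_percent/100) * best.  A single retained
    taxon is assigned directly, several collapse to their LCA, none yields
    ``None`` (unassigned).
    """
    passing = [h for h in hits if h.identity >= min_identity and h.score >= min_score]
    if not passing:
        return None
    for h in passing:
        if h.taxon_id not in tree.nodes:
            raise KeyError(f"hit taxon {h.taxon_id!r} missing from taxonomy")
    best = max(h.score for h in passing)
    threshold = (1.0 - top_percent / 100.0) * best
    retained = sorted({h.taxon_id for h in passing if h.score >= threshold})
    if len(retained) == 1:
        return retained[0]
    return tree.lca(retained)


def apply_min_support(
    assignments: Mapping[str, str | None],
    tree: TaxonomyTree,
    min_support: int = 10,
) -> dict[str, str | None]:
    """Lift reads of under-supported taxa to their parents, bottom-up.

    Any taxon holding fewer than ``min_support`` reads has those reads
    re-assigned to its parent; the sweep repeats (deepest nodes first,
    deterministic id order within a depth) until stable.  Reads that reach
    the root without support become unassigned (``None``).
    """
    assigned = dict(assignments)
    while True:
        counts: dict[str, int] = defaultdict(int)
        for t in assigned.values():
            if t is not None:
                counts[t] += 1
        weak = [
            t
            for t, c in counts.items()
            if 0 < c < min_support
        ]
        if not weak:
            return assigned
        # deepest, then id order: one deterministic lift per iteration
        weak.sort(key=lambda t: (-tree.depth(t), t))
        target = weak[0]
        parent = tree.parent(target)
        for rid, t in assigned.items():
            if t == target:
                assigned[rid] = parent  # None when target is the root
    return assigned


@dataclass
class TaxonCountTable:
    """Taxa x samples integer counts with taxonomy and mean mapped lengths."""

    counts: pd.DataFrame
    mean_length: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate row or column labels")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def build_count_table(
    assignments_by_sample: Mapping[str, Mapping[str, str | None]],
    read_lengths_by_sample: Mapping[str, Mapping[str, int]],
    tree: TaxonomyTree,
) -> TaxonCountTable:
    """Tabulate assigned reads and mean mapped read length per taxon/sample."""
    samples = list(assignments_by_sample)
    taxa = sorted(
        {t for m in assignments_by_sample.values() for t in m.values() if t is not None}
    )
    counts = pd.DataFrame(0, index=taxa, columns=samples, dtype=int)
    mean_len = pd.DataFrame(np.nan, index=taxa, columns=samples, dtype=float)
    for sample, mapping in assignments_by_sample.items():
        lengths = read_lengths_by_sample.get(sample, {})
        per_taxon: dict[str, list[int]] = defaultdict(list)
        for rid, taxon in mapping.items():
            if taxon is None:
                continue
            counts.loc[taxon, sample] += 1
            if rid in lengths:
                per_taxon[taxon].append(lengths[rid])
        for taxon, ls in per_taxon.items():
            mean_len.loc[taxon, sample] = float(np.mean(ls))
    ranks = {t: tree.nodes[t].rank for t in taxa}
    lineage = {}
    for t in taxa:
        path = tree.path_to_root(t)
        by_rank = {tree.nodes[n].rank: tree.nodes[n].name for n in path}
        lineage[t] = {r: by_rank.get(r, "") for r in RANKS}
    taxonomy = pd.DataFrame.from_dict(lineage, orient="index")
    taxonomy["rank"] = pd.Series(ranks)
    return TaxonCountTable(counts=counts, mean_length=mean_len, taxonomy=taxonomy)
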