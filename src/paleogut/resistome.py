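"""Antibiotic-resistance-gene detection by alignment coverage.

A gene is called present in a sample when reads cover at least a threshold
fraction (default 80%) of its positions — the gene-fraction rule used by
coverage-based resistome tools.  Abundance profiles are rarefied to a
common depth and prevalence-filtered (> 5 in at least 20% of samples) for
heatmap input.  Presence is decided per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ecology import prevalence_filter, rarefy


@dataclass
class ARGProfile:
    sample_id: str
    table: pd.DataFrame  # gene x (reads, covered_fraction_pct, present)


def arg_coverage(
    placements: Sequence[tuple[str, int, int]] | pd.DataFrame,
    gene_lengths: Mapping[str, int],
    sample_id: str = "",
    threshold_pct: float = 80.0,
) -> ARGProfile:
    """Per-gene read counts and covered-fraction calls for one sample.

    ``placements`` are (gene_id, ref_start, ref_end) intervals (0-based,
    half-open); DataFrame input needs columns gene_id/ref_start/ref_end.
    Fraction = 100 * (positions covered by >= 1 read) / gene length;
    present iff fraction >= threshold (strict 79.9% stays absent).
    """
    for g, L in gene_lengths.items():
        if L <= 0:
            raise ValueError(f"non-positive length for gene {g!r}")
    if isinstance(placements, pd.DataFrame):
        rows = placements[["gene_id", "ref_start", "ref_end"]].itertuples(index=False)
    else:
        rows = placements
    covered = {g: np.zeros(L, dtype=bool) for g, L in gene_lengths.items()}
    counts = {g: 0 for g in gene_lengths}
    for gene, start, end in rows:
        if gene not in covered:
            continue
        L = gene_lengths[gene]
        covered[gene][max(0, int(start)) : min(L, int(end))] = True
        counts[gene] += 1
    recs = []
    for g in sorted(gene_lengths):
        frac = 100.0 * covered[g].sum() / gene_lengths[g]
        recs.append(
            {
                "gene": g,
                "reads": counts[g],
                "covered_fraction_pct": frac,
                "present": bool(frac >= threshold_pct),
            }
        )
    return ARGProfile(sample_id=sample_id, table=pd.DataFrame(recs).set_index("gene"))


def arg_abundance(
    profiles: Sequence[ARGProfile],
    rarefy_depth: int | None = None,
    min_sample_total: int = 0,
    seed: int = 0,
    prevalence_min_count: int = 5,
    prevalence_min_fraction: float = 0.2,
) -> dict:
    """Rarefied relative-abundance ARG x sample table.

    Samples whose total ARG-aligned reads fall below ``min_sample_total``
    are excluded (and listed).  Retained samples are rarefied without
    replacement to ``rarefy_depth`` (default: the smallest retained total),
    converted to relative abundance, and a prevalence-filtered copy
    ("> 5 in at least 20% of samples" on the rarefied counts) is returned
    as heatmap input.
    """
    counts = pd.DataFrame(
        {p.sample_id: p.table["reads"] for p in profiles}
    ).fillna(0).astype(int)
    totals = counts.sum(axis=0)
    excluded = list(totals.index[totals < min_sample_total])
    kept = counts.drop(columns=excluded)
    if kept.shape[1] == 0:
        raise ValueError("all samples excluded by the minimum-assignment floor")
    if rarefy_depth is None:
        rarefy_depth = int(kept.sum(axis=0).min())
    rarefied = rarefy(kept, depth=rarefy_depth, seed=seed)
    rel = rarefied.div(rarefied.sum(axis=0).replace(0, np.nan), axis=1) * 100.0
    heat = prevalence_filter(
        rarefied, min_count=prevalence_min_count, min_fraction=prevalence_min_fraction
    )
    return {
        "counts": kept,
        "rarefied": rarefied,
        "relative_abundance": rel.fillna(0.0),
        "heatmap_input": heat,
        "excluded_samples": excluded,
        "depth": rarefy_depth,
    }
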