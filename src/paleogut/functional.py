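"""Taxon-linked functional (KEGG-ortholog) profiling and group tests.

KO abundances are derived from a taxon -> KO capability matrix multiplied
by taxon read counts, restricted to an authenticated taxon list, so the
analysis structure ("KO genes linked to specific taxa") is preserved
without per-read protein search.  Group significance uses tie-corrected
Kruskal-Wallis H with Benjamini-Hochberg FDR q-values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class KOTable:
    counts: pd.DataFrame  # KO x samples
    link_map: dict[str, list[str]]  # KO -> contributing taxa
    pathway_map: dict[str, list[str]] | None = None  # KO -> pathway id(s)


def build_ko_table(
    count_table: pd.DataFrame,
    taxon_ko: pd.DataFrame,
    restrict_to: Sequence[str],
    pathway_map: Mapping[str, Sequence[str]] | None = None,
) -> KOTable:
    """KO x sample counts from taxon counts and a 0/1 capability matrix.

    ``taxon_ko`` has taxa as rows and KO ids as columns; the KO count per
    sample is the sum of read counts of the restricted taxa that carry it.
    KOs carried by no restricted taxon are absent from the result.  An empty
    restriction is an error — pass the full taxon list for an all-taxa run.
    """
    restrict = list(restrict_to)
    if not restrict:
        raise ValueError("empty taxon restriction; pass the full list explicitly")
    missing = set(restrict) - set(taxon_ko.index)
    if missing:
        raise KeyError(f"taxa missing from capability matrix: {sorted(missing)[:5]}")
    present = [t for t in restrict if t in count_table.index]
    counts = count_table.loc[present]
    cap = (taxon_ko.loc[present] > 0).astype(int)
    ko_counts = cap.T @ counts
    ko_counts = ko_counts.loc[ko_counts.sum(axis=1) > 0]
    link = {
        ko: sorted(cap.index[cap[ko] > 0]) for ko in ko_counts.index
    }
    pmap = {k: list(v) for k, v in pathway_map.items()} if pathway_map else None
    return KOTable(counts=ko_counts, link_map=link, pathway_map=pmap)


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p-value.

    All values identical across groups gives (0, 1) by convention.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if len(flat) < 3:
        raise ValueError("need at least three observations")
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def group_significance(
    ko_counts: pd.DataFrame,
    labels: Sequence[str],
    reference_group: str | None = None,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-KO Kruskal-Wallis across cohorts with BH-FDR q-values.

    Returns every KO (H, raw p, q, per-group means, enrichment direction
    relative to ``reference_group``); callers typically report the subset
    with p < 0.05, q alongside.
    """
    labels = np.asarray(labels)
    if len(labels) != ko_counts.shape[1]:
        raise ValueError("labels do not match sample columns")
    group_names = sorted(set(labels))
    if reference_group is None:
        reference_group = group_names[0]
    rows = []
    for ko in ko_counts.index:
        vals = ko_counts.loc[ko].to_numpy(dtype=float)
        groups = [vals[labels == g] for g in group_names]
        h, p = kruskal_wallis(groups)
        means = {f"mean_{g}": float(np.mean(gv)) for g, gv in zip(group_names, groups)}
        ref_mean = means[f"mean_{reference_group}"]
        other = np.mean([m for k, m in means.items() if k != f"mean_{reference_group}"])
        rows.append(
            {"ko": ko, "H": h, "p": p, **means,
             "direction": "enriched" if ref_mean > other else "depleted"}
        )
    out = pd.DataFrame(rows).set_index("ko")
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["p"] < p_threshold
    return out


def shared_unique_sets(
    tables_by_cohort: Mapping[str, pd.DataFrame],
    min_samples_present: int = 1,
) -> dict:
    """Venn-region KO counts across cohorts plus the shared-by-all fraction.

    A KO is present in a cohort iff nonzero in at least
    ``min_samples_present`` of its samples.  Region keys are sorted '+'
    joined cohort subsets; region counts sum to the KO universe size.
    """
    cohorts = sorted(tables_by_cohort)
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts")
    presence = {
        c: set(t.index[(t > 0).sum(axis=1) >= min_samples_present])
        for c, t in tables_by_cohort.items()
    }
    universe = sorted(set().union(*presence.values()))
    regions: dict[str, int] = {}
    for ko in universe:
        member = tuple(c for c in cohorts if ko in presence[c])
        key = "+".join(member)
        regions[key] = regions.get(key, 0) + 1
    shared = regions.get("+".join(cohorts), 0)
    n = len(universe)
    return {
        "universe": n,
        "regions": regions,
        "shared_all": shared,
        "shared_all_pct": 100.0 * shared / n if n else float("nan"),
    }


def pathway_coabundance(
    ko_table: KOTable,
    labels: Sequence[str],
    log10: bool = False,
) -> pd.DataFrame:
    """Pathway x cohort mean abundance (member-KO counts summed per sample,
    averaged within cohort; optional log10(x + 1))."""
    if ko_table.pathway_map is None:
        raise ValueError("KO table has no pathway map")
    labels = np.asarray(labels)
    counts = ko_table.counts
    pathways = sorted({p for ps in ko_table.pathway_map.values() for p in ps})
    per_sample = pd.DataFrame(0.0, index=pathways, columns=counts.columns)
    for ko in counts.index:
        for p in ko_table.pathway_map.get(ko, ()):
            per_sample.loc[p] += counts.loc[ko].astype(float)
    out = {}
    for g in sorted(set(labels)):
        out[g] = per_sample.loc[:, labels == g].mean(axis=1)
    res = pd.DataFrame(out)
    if log10:
        res = np.log10(res + 1.0)
    return res
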