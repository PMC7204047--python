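"""Community-ecology statistics for feature (taxon / KO / ARG) tables.

Tables are pandas DataFrames with features as rows and samples as columns.
Provided here: relative abundance and rank aggregation, the
Firmicutes/Bacteroidetes ratio and enterotype call, rarefaction,
prevalence filtering, the Hellinger transform, Bray-Curtis dissimilarities
(weighted and presence/absence), principal coordinates analysis, ANOSIM
with an add-one permutation p-value, and correlation-based hierarchical
clustering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._util import round_half_up

ENTEROTYPE_GENERA = {"Bacteroides": 1, "Prevotella": 2, "Ruminococcus": 3}


def relative_abundance(
    table: pd.DataFrame, subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Percent abundance per sample column (columns sum to 100).

    With ``subset``, percentages are taken over the subset's column totals
    only.  Rounding is left to report time.
    """
    t = table.loc[list(subset)] if subset is not None else table
    totals = t.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("cannot normalise a sample with zero total")
    return t.div(totals, axis=1) * 100.0


def aggregate_by_rank(table: pd.DataFrame, groups: Mapping[str, str]) -> pd.DataFrame:
    """Sum feature counts within rank groups (e.g. genus -> phylum)."""
    missing = set(table.index) - set(groups)
    if missing:
        raise KeyError(f"no rank group for features: {sorted(missing)[:5]}")
    key = pd.Series({f: groups[f] for f in table.index})
    return table.groupby(key).sum()


def fb_ratio(phylum_table: pd.DataFrame) -> float:
    """Firmicutes / Bacteroidetes read-count ratio (table rows = phyla).

    Zero Firmicutes gives 0.0; zero Bacteroidetes is undefined and raises.
    """
    f = float(phylum_table.loc["Firmicutes"].sum()) if "Firmicutes" in phylum_table.index else 0.0
    b = float(phylum_table.loc["Bacteroidetes"].sum()) if "Bacteroidetes" in phylum_table.index else 0.0
    if b == 0:
        raise ValueError("Bacteroidetes total is zero; F/B ratio undefined")
    return f / b


def enterotype(genus_table: pd.DataFrame) -> tuple[int | None, dict[str, float]]:
    """Dominant-genus enterotype call (1 Bacteroides, 2 Prevotella,
    3 Ruminococcus) on pooled relative abundance; exact ties return None."""
    pooled = genus_table.sum(axis=1)
    total = pooled.sum()
    if total <= 0:
        raise ValueError("empty table")
    shares = {
        g: float(pooled.get(g, 0.0)) / total * 100.0 for g in ENTEROTYPE_GENERA
    }
    best = max(shares.values())
    winners = [g for g, v in shares.items() if v == best]
    if len(winners) != 1:
        return None, shares
    return ENTEROTYPE_GENERA[winners[0]], shares


def rarefy(table: pd.DataFrame, depth: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Subsample each sample column without replacement to a common depth.

    Multivariate-hypergeometric per column; ``depth`` defaults to the
    smallest column total.  Deterministic per seed.
    """
    totals = table.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    offenders = totals[totals < depth]
    if len(offenders) > 0:
        raise ValueError(
            f"depth {depth} exceeds totals of sample(s): {list(offenders.index)}"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for col in table.columns:
        colors = table[col].to_numpy(dtype=np.int64)
        out[col] = rng.multivariate_hypergeometric(colors, depth)
    return pd.DataFrame(out, index=table.index)


def prevalence_filter(
    table: pd.DataFrame, min_count: int = 3, min_fraction: float = 0.2
) -> pd.DataFrame:
    """Keep features with count strictly > min_count in >= ceil(min_fraction
    * n_samples) samples (the "> 3 in at least 20% of samples" rule)."""
    if table.shape[1] == 0:
        return table
    need = math.ceil(min_fraction * table.shape[1])
    keep = (table > min_count).sum(axis=1) >= need
    return table.loc[keep]


def hellinger(table: pd.DataFrame) -> pd.DataFrame:
    """sqrt(count / column total); squared entries sum to 1 per column."""
    totals = table.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("cannot Hellinger-transform a sample with zero total")
    return np.sqrt(table.div(totals, axis=1))


def bray_curtis(table: pd.DataFrame, weighted: bool = True) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between sample columns.

    ``weighted=False`` first binarises (count > 0 -> 1), giving the
    presence/absence (Sorensen) form.  A pair of all-zero samples is
    defined as distance 0 (with a warning).
    """
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative entries")
    if not weighted:
        x = (x > 0).astype(float)
    cols = list(table.columns)
    n = len(cols)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (x[:, i] + x[:, j]).sum()
            if denom == 0:
                warnings.warn("Bray-Curtis of two empty samples defined as 0")
                val = 0.0
            else:
                val = np.abs(x[:, i] - x[:, j]).sum() / denom
            d[i, j] = d[j, i] = val
    return pd.DataFrame(d, index=cols, columns=cols)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # relative to sum of positive eigenvalues


def pcoa(dm: pd.DataFrame) -> OrdinationResult:
    """Principal coordinates analysis (Gower double-centring).

    Axes are eigenvectors scaled by sqrt(eigenvalue); negative eigenvalues
    (non-Euclidean input) are recorded in ``eigenvalues`` but contribute no
    axis.
    """
    d = dm.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix diagonal must be zero")
    n = d.shape[0]
    a = -0.5 * d**2
    centre = np.eye(n) - np.ones((n, n)) / n
    b = centre @ a @ centre
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    total = evals[pos].sum()
    prop = evals / total if total > 0 else np.zeros_like(evals)
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dm.index, columns=axes),
        eigenvalues=evals,
        proportion_explained=prop,
    )


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("R out of [-1, 1]")


def anosim(
    dm: pd.DataFrame,
    labels: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities on a precomputed dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    midranks over all M = n(n-1)/2 pairwise dissimilarities; the p-value is
    the add-one permutation estimator (1 + #{R_perm >= R_obs}) /
    (1 + n_permutations).
    """
    labels = np.asarray(labels)
    n = len(labels)
    if dm.shape != (n, n):
        raise ValueError("labels do not match distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dm.to_numpy()[iu])  # midranks for ties
    m = len(ranks)
    denom = m / 2.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if r_stat(labels[rng.permutation(n)]) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return AnosimResult(r=float(r_obs), p_value=float(p), n_permutations=n_permutations, seed=seed)


def correlation_cluster(
    table: pd.DataFrame, correlation: str = "spearman", linkage: str = "complete"
) -> np.ndarray:
    """Agglomerative clustering of sample columns on 1 - rank correlation.

    Returns the scipy linkage (merge-tree) matrix.  Supported linkages:
    complete and ward.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two samples")
    if linkage not in ("complete", "ward"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    corr = table.corr(method=correlation)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    return hierarchy.linkage(squareform(dist, checks=False), method=linkage)


def format_percent(x: float, decimals: int = 2) -> float:
    """Report-time percentage rounding (half-up, matching printed tables)."""
    return round_half_up(x, decimals)
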