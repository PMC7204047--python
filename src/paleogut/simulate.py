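"""Synthetic ancient-DNA metagenome simulation.

Generates reference panels with a simple four-level taxonomy, communities of
short fragments carrying post-mortem deamination damage, and multi-cohort
count tables, all with a recorded per-read truth so downstream stages
(assignment, damage profiling, authentication, ecology) can be tested
against known ground truth.

Damage model
------------
Post-mortem cytosine deamination is fastest in the single-stranded overhangs
left by strand breaks.  We parameterise the probability that the site at
1-based distance ``i`` from a fragment end lies in an overhang as ``q**i``
(geometric persistence), giving the per-site C->T substitution probability

    d(i) = delta_ss * q**i + delta_ds * (1 - q**i)

at distance ``i`` from the 5' end, and symmetrically G->A at distance ``i``
from the 3' end (double-stranded library polarity).  An independent,
position-independent sequencing error then flips any base to one of the
other three with probability ``epsilon`` (uniform over alternatives, so the
C->T error contribution is ``epsilon / 3``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import AlignedRead, Read, ReadSet, revcomp

RANKS = ("root", "phylum", "genus", "species")

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class TaxonRecord:
    taxon_id: str
    name: str
    lineage: tuple[tuple[str, str], ...]  # ((rank, name), ...) root first

    def rank_name(self, rank: str) -> str:
        for r, n in self.lineage:
            if r == rank:
                return n
        raise KeyError(rank)


@dataclass
class ReferencePanel:
    """A set of single-sequence reference taxa with a shared-root taxonomy."""

    taxa: list[TaxonRecord]
    sequences: dict[str, str]
    gc_fraction: float

    def __post_init__(self) -> None:
        ids = [t.taxon_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate taxon ids in panel")
        for tid in ids:
            seq = self.sequences.get(tid, "")
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"sequence for {tid} empty or not ACGT-only")

    @property
    def taxon_ids(self) -> list[str]:
        return [t.taxon_id for t in self.taxa]

    def taxonomy_frame(self) -> pd.DataFrame:
        rows = [
            {rank: t.rank_name(rank) for rank in RANKS} | {"taxon_id": t.taxon_id}
            for t in self.taxa
        ]
        return pd.DataFrame(rows).set_index("taxon_id")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.taxa:
                fh.write(f">{t.taxon_id} {t.name}\n")
                seq = self.sequences[t.taxon_id]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def taxonomy_to_tsv(self, path) -> None:
        self.taxonomy_frame().to_csv(path, sep="\t")


@dataclass(frozen=True)
class DamageParams:
    """Deamination, overhang-persistence and sequencing-error parameters."""

    delta_ss: float = 0.4
    delta_ds: float = 0.01
    q: float = 0.6
    epsilon: float = 0.001
    contam_frac: float = 0.0

    def __post_init__(self) -> None:
        for name in ("delta_ss", "delta_ds", "epsilon", "contam_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.q < 1.0 + 1e-15:
            raise ValueError(f"q must be in [0, 1), got {self.q}")

    def rate(self, i):
        """C->T (or mirrored G->A) probability at 1-based distance ``i``."""
        qi = np.power(float(self.q), np.maximum(i, 1))
        return self.delta_ss * qi + self.delta_ds * (1.0 - qi)

    @classmethod
    def none(cls) -> "DamageParams":
        return cls(delta_ss=0.0, delta_ds=0.0, q=0.0, epsilon=0.0)


@dataclass(frozen=True)
class CommunitySpec:
    """Composition, depth and fragment-length model for one simulated sample."""

    sample_id: str
    sample_class: str  # faecal_interior | sediment_control | blank_control | modern_cohort
    composition: dict[str, float]
    depth: int
    length_model: tuple = ("normal", 65.0, 12.0)
    modern_taxa: frozenset[str] = frozenset()

    CLASSES = ("faecal_interior", "sediment_control", "blank_control", "modern_cohort")

    def __post_init__(self) -> None:
        if self.sample_class not in self.CLASSES:
            raise ValueError(f"unknown sample class {self.sample_class!r}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition sums to {total}, expected 1")


CONTAMINANT_LENGTH_MODEL = ("normal", 150.0, 20.0)
MIN_FRAGMENT_LENGTH = 25


def build_reference_panel(
    n_taxa: int, seed: int, gc: float = 0.5, length: int = 10_000
) -> ReferencePanel:
    """Simulate ``n_taxa`` independent ACGT references with a 4-level lineage.

    Species are attached round-robin to genera, and genera round-robin to
    phyla, so sibling structure exists for LCA tests whenever n_taxa > 2.
    Deterministic for a fixed seed.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    n_genera = max(1, (n_taxa + 1) // 2)
    n_phyla = max(1, (n_genera + 1) // 2)
    taxa, sequences = [], {}
    for i in range(n_taxa):
        g = i % n_genera
        p = g % n_phyla
        tid = f"sp{i + 1:03d}"
        lineage = (
            ("root", "root"),
            ("phylum", f"phylum{p + 1:02d}"),
            ("genus", f"genus{g + 1:02d}"),
            ("species", tid),
        )
        taxa.append(TaxonRecord(tid, f"Species {i + 1}", lineage))
        codes = rng.choice(4, size=length, p=probs)
        sequences[tid] = _BASE_BYTES[codes].tobytes().decode()
    return ReferencePanel(taxa=taxa, sequences=sequences, gc_fraction=gc)


def apply_damage(
    fragment: str, params: DamageParams, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str, str, str]]]:
    """Apply deamination then sequencing error to one oriented fragment.

    Returns the damaged read and a log of ``(position0, cause, from, to)``
    with cause in {"CT5", "GA3", "err"}.
    """
    L = len(fragment)
    if L < 1:
        raise ValueError("fragment must be non-empty")
    seq = list(fragment)
    log: list[tuple[int, str, str, str]] = []
    for idx, ch in enumerate(fragment):
        if ch == "C":
            if rng.random() < params.rate(idx + 1):
                seq[idx] = "T"
                log.append((idx, "CT5", "C", "T"))
        elif ch == "G":
            if rng.random() < params.rate(L - idx):
                seq[idx] = "A"
                log.append((idx, "GA3", "G", "A"))
    if params.epsilon > 0.0:
        for idx in range(L):
            if rng.random() < params.epsilon:
                old = seq[idx]
                alternatives = [b for b in "ACGT" if b != old]
                new = alternatives[rng.integers(3)]
                seq[idx] = new
                log.append((idx, "err", old, new))
    return "".join(seq), log


def _draw_lengths(model: tuple, n: int, ref_len: int, rng) -> np.ndarray:
    name = model[0]
    if name == "normal":
        raw = rng.normal(model[1], model[2], size=n)
    elif name == "lognormal":
        raw = rng.lognormal(model[1], model[2], size=n)
    elif name == "constant":
        raw = np.full(n, float(model[1]))
    else:
        raise ValueError(f"unknown length model {name!r}")
    return np.clip(np.rint(raw).astype(int), MIN_FRAGMENT_LENGTH, ref_len)


def _simulate_fragments(
    ref_codes: np.ndarray,
    lengths: np.ndarray,
    params: DamageParams,
    damaged: np.ndarray,
    rng: np.random.Generator,
):
    """Vectorised fragment draw + damage for one reference.

    Returns (read_codes, ref_as_sequenced_codes, starts, strands, valid_mask,
    ct_mask, ga_mask, err_mask); code 3-x is the complement (A<->T, C<->G).
    """
    n = len(lengths)
    ref_len = len(ref_codes)
    max_l = int(lengths.max())
    starts = rng.integers(0, ref_len - lengths + 1)
    reverse = rng.random(n) < 0.5
    j = np.arange(max_l)[None, :]
    valid = j < lengths[:, None]
    idx_f = starts[:, None] + j
    idx_r = starts[:, None] + lengths[:, None] - 1 - j
    idx = np.where(reverse[:, None], idx_r, idx_f)
    np.clip(idx, 0, ref_len - 1, out=idx)
    base = ref_codes[idx]
    base = np.where(reverse[:, None], 3 - base, base)
    ref_as_seq = base.copy()
    rate_vec = params.rate(np.arange(1, max_l + 1))  # rate depends only on distance
    i3 = np.clip(lengths[:, None] - j, 1, max_l)
    u = rng.random(base.shape)
    dmask = valid & damaged[:, None]
    ct = (base == 1) & (u < rate_vec[None, :]) & dmask
    ga = (base == 2) & (u < rate_vec[i3 - 1]) & dmask
    base = np.where(ct, 3, base)
    base = np.where(ga, 0, base)
    err = np.zeros(base.shape, dtype=bool)
    if params.epsilon > 0.0:
        err = (rng.random(base.shape) < params.epsilon) & valid
        rows, cols = np.nonzero(err)
        shift = rng.integers(1, 4, size=rows.size)
        base[rows, cols] = (base[rows, cols] + shift) % 4
    return base, ref_as_seq, starts, reverse, valid, ct, ga, err


def simulate_sample(
    panel: ReferencePanel,
    spec: CommunitySpec,
    params: DamageParams,
    seed: int,
    phred: int = 40,
) -> tuple[ReadSet, pd.DataFrame]:
    """Simulate one sample: a ReadSet (FASTQ-ready) plus a per-read truth table.

    Read counts per taxon are multinomial around the composition.  A fraction
    ``params.contam_frac`` of reads (plus all reads of ``spec.modern_taxa``)
    are drawn undamaged with the longer modern-contaminant length model.
    Deterministic per seed; the truth table records source taxon, reference
    coordinates (0-based half-open, forward strand), strand, damaged
    positions and the contaminant flag.
    """
    unknown = set(spec.composition) - set(panel.taxon_ids)
    if unknown:
        raise ValueError(f"composition taxa absent from panel: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    taxa = sorted(spec.composition)
    probs = np.array([spec.composition[t] for t in taxa], dtype=float)
    counts = rng.multinomial(spec.depth, probs / probs.sum())
    qual_char = chr(phred + 33)

    reads: list[Read] = []
    truth_rows: list[dict] = []
    read_no = 0
    for taxon, n in zip(taxa, counts):
        if n == 0:
            continue
        ref = panel.sequences[taxon]
        ref_codes = np.frombuffer(ref.encode(), dtype=np.uint8).copy()
        lut = np.zeros(256, dtype=np.uint8)
        for b, c in _CODE.items():
            lut[ord(b)] = c
        ref_codes = lut[ref_codes]
        is_modern_taxon = taxon in spec.modern_taxa
        contam = rng.random(n) < params.contam_frac
        if is_modern_taxon:
            contam[:] = True
        lengths = _draw_lengths(spec.length_model, n, len(ref), rng)
        cont_lengths = _draw_lengths(CONTAMINANT_LENGTH_MODEL, n, len(ref), rng)
        lengths = np.where(contam, cont_lengths, lengths)
        damaged = ~contam
        base, _, starts, reverse, valid, ct, ga, err = _simulate_fragments(
            ref_codes, lengths, params, damaged, rng
        )
        seq_bytes = _BASE_BYTES[base]
        for r in range(n):
            L = int(lengths[r])
            rid = f"{spec.sample_id}:{read_no:06d}"
            read_no += 1
            seq = seq_bytes[r, :L].tobytes().decode()
            reads.append(Read(rid, seq, qual_char * L))
            events = []
            for kind, mask in (("CT", ct), ("GA", ga), ("err", err)):
                pos = np.nonzero(mask[r, :L])[0]
                events.extend(f"{kind}:{p}" for p in pos)
            truth_rows.append(
                {
                    "read_id": rid,
                    "taxon_id": taxon,
                    "start": int(starts[r]),
                    "end": int(starts[r]) + L,
                    "strand": "-" if reverse[r] else "+",
                    "is_contaminant": bool(contam[r]),
                    "damage": ";".join(events),
                }
            )
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order]) if truth_rows else pd.DataFrame(
        columns=["read_id", "taxon_id", "start", "end", "strand", "is_contaminant", "damage"]
    )
    rs = ReadSet(sample_id=spec.sample_id, reads=reads)
    rs.log_stage("simulate", {"reads": len(reads)})
    return rs, truth


def truth_alignments(
    panel: ReferencePanel, readset: ReadSet, truth: pd.DataFrame
) -> list[AlignedRead]:
    """Reconstruct oracle alignments (read vs pre-damage reference fragment).

    The reference fragment is re-oriented to the read's as-sequenced strand,
    which is what damage profiling expects.
    """
    by_id = {r.read_id: r for r in readset}
    out = []
    for row in truth.itertuples(index=False):
        read = by_id.get(row.read_id)
        if read is None:
            continue
        ref = panel.sequences[row.taxon_id][row.start : row.end]
        if row.strand == "-":
            ref = revcomp(ref)
        out.append(
            AlignedRead(
                read_id=row.read_id,
                taxon_id=row.taxon_id,
                read_frag=read.sequence,
                ref_frag=ref,
            )
        )
    return out


def simulate_damage_profile(
    params: DamageParams,
    n_reads: int,
    length_model: tuple = ("normal", 65.0, 12.0),
    gc: float = 0.5,
    ref_length: int = 50_000,
    K: int = 25,
    seed: int = 0,
):
    """Read-level damage simulation tallied straight into a profile.

    Simulates ``n_reads`` fragments from one random reference under the full
    damage + error model (same vectorised core as :func:`simulate_sample`)
    and returns the resulting misincorporation profile without materialising
    read strings — the fast path for calibration and power experiments.
    """
    from .damage import MisincorporationProfile  # local import: no cycle at module load

    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    ref_codes = rng.choice(4, size=ref_length, p=probs).astype(np.uint8)
    lengths = _draw_lengths(length_model, n_reads, ref_length, rng)
    damaged = np.ones(n_reads, dtype=bool)
    base, ref_as_seq, _, _, valid, _, _, _ = _simulate_fragments(
        ref_codes, lengths, params, damaged, rng
    )
    pair = ref_as_seq.astype(np.int16) * 4 + base
    bases = "ACGT"
    grid5 = {(a, b): np.zeros(K, dtype=np.int64) for a in bases for b in bases}
    grid3 = {(a, b): np.zeros(K, dtype=np.int64) for a in bases for b in bases}
    kmax = min(K, pair.shape[1])
    for j in range(kmax):
        counts = np.bincount(pair[valid[:, j], j], minlength=16)
        for code in range(16):
            grid5[(bases[code // 4], bases[code % 4])][j] = counts[code]
    rows = np.arange(n_reads)
    for d in range(1, K + 1):
        ok = lengths >= d
        cols = lengths[ok] - d
        counts = np.bincount(pair[rows[ok], cols], minlength=16)
        for code in range(16):
            grid3[(bases[code // 4], bases[code % 4])][d - 1] = counts[code]
    return MisincorporationProfile(K=K, grid5=grid5, grid3=grid3, n_reads=n_reads)


def simulate_cohort_tables(
    n_cohorts: int = 2,
    samples_per_cohort: int = 4,
    n_features: int = 200,
    effect: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Negative-binomial feature-by-sample count tables with cohort structure.

    ``effect=None`` yields exchangeable samples (a permutation null for
    ANOSIM / Kruskal-Wallis calibration).  Otherwise ``effect`` is a dict
    with keys ``fraction`` (share of features shifted) and ``fold`` (the
    per-cohort multiplicative shift; cohort ``c`` gets ``fold ** c``).
    """
    if n_cohorts < 2:
        raise ValueError("n_cohorts must be >= 2")
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(mean=3.0, sigma=1.0, size=n_features)
    size = 5.0  # NB dispersion (shape); larger = closer to Poisson
    n_aff = 0
    fold = 1.0
    if effect:
        n_aff = int(round(effect.get("fraction", 1.0) * n_features))
        fold = float(effect.get("fold", 1.0))
    cols, labels = {}, []
    for c in range(n_cohorts):
        shift = np.ones(n_features)
        if n_aff and fold != 1.0:
            shift[:n_aff] = fold**c
        for s in range(samples_per_cohort):
            m = mu * shift
            p = size / (size + m)
            name = f"c{c + 1}s{s + 1}"
            cols[name] = rng.negative_binomial(size, p)
            labels.append(f"cohort{c + 1}")
    table = pd.DataFrame(cols, index=[f"f{i + 1:04d}" for i in range(n_features)])
    return table, labels
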