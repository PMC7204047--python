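"""Calibration, power and soundness experiments.

Reusable, seeded experiment drivers for the statistical guarantees the
package makes: damage-parameter recovery from deep simulated read sets,
type-I error and power of the terminal C->T test, end-to-end
authentication soundness on communities with known ancient / modern truth,
and permutation-test calibration for the ecology statistics.  Problem
sizes default to the values used in the reported experiments; every
function is a pure function of its arguments and seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .authenticate import AuthConfig
from .authenticate import authenticate as _authenticate
from .damage import ct_terminal_test, fit_damage_model, ga_terminal_check, misincorporation_profile
from .ecology import anosim, bray_curtis, hellinger
from .functional import kruskal_wallis
from .simulate import (
    CommunitySpec,
    DamageParams,
    build_reference_panel,
    simulate_cohort_tables,
    simulate_damage_profile,
    simulate_sample,
    truth_alignments,
)
from .taxassign import TaxonomyTree, build_count_table

RECOVERY_PARAMS = DamageParams(delta_ss=0.4, delta_ds=0.01, q=0.6, epsilon=0.001)
#: undamaged null for test calibration: sequencing error at the Phred-25
#: filter floor, depth chosen so the discrete exact test operates in its
#: near-continuous regime (see docs/methods.md)
CALIBRATION_PARAMS = DamageParams(delta_ss=0.0, delta_ds=0.0, q=0.0, epsilon=0.003)
CALIBRATION_READS = 20_000
POWER_PARAMS = DamageParams(delta_ss=0.2, delta_ds=0.01, q=0.6, epsilon=0.001)


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def damage_recovery(
    n_seeds: int = 20, n_reads: int = 100_000, params: DamageParams = RECOVERY_PARAMS,
    seed: int = 0,
) -> dict:
    """Fit the damage model to deep simulated read sets; report recovery error."""
    errs, estimates = [], []
    for k in range(n_seeds):
        prof = simulate_damage_profile(params, n_reads, seed=_child_seed(seed, k))
        fit = fit_damage_model(prof)
        estimates.append(fit.delta_ss_hat)
        errs.append(abs(fit.delta_ss_hat - params.delta_ss))
    return {
        "delta_ss_true": params.delta_ss,
        "delta_ss_hat_mean": float(np.mean(estimates)),
        "mean_abs_error": float(np.mean(errs)),
        "max_abs_error": float(np.max(errs)),
        "n_seeds": n_seeds,
        "n_reads": n_reads,
    }


def terminal_test_type1(
    n_reps: int = 1000, n_reads: int = CALIBRATION_READS,
    params: DamageParams = CALIBRATION_PARAMS, alpha: float = 0.05, seed: int = 0,
) -> dict:
    """Rejection rate of the terminal test under undamaged simulation."""
    rej = 0
    for k in range(n_reps):
        prof = simulate_damage_profile(params, n_reads, seed=_child_seed(seed, k))
        rej += ct_terminal_test(prof).p_value < alpha
    return {"rejection_rate": rej / n_reps, "n_reps": n_reps, "n_reads": n_reads}


def terminal_test_power(
    n_reps: int = 200, n_reads: int = 500, params: DamageParams = POWER_PARAMS,
    alpha: float = 0.05, seed: int = 0,
) -> dict:
    """Rejection rate under genuine damage at modest read depth."""
    rej = 0
    for k in range(n_reps):
        prof = simulate_damage_profile(params, n_reads, seed=_child_seed(seed, k))
        rej += ct_terminal_test(prof).p_value < alpha
    return {"power": rej / n_reps, "n_reps": n_reps, "n_reads": n_reads}


def authentication_soundness(
    n_seeds: int = 20,
    depth: int = 4000,
    params: DamageParams | None = None,
    seed: int = 0,
) -> dict:
    """Authenticate synthetic communities of 5 ancient + 2 contaminant taxa.

    Each seed simulates three faecal-interior samples, one sediment control
    and one blank control from a fresh panel; counts and damage profiles
    come from the recorded truth.  Reports sensitivity over the ancient
    taxa and the number of contaminant taxa ever called ancient.
    """
    params = params or DamageParams(delta_ss=0.3, delta_ds=0.01, q=0.6, epsilon=0.001)
    ancient = [f"sp{i:03d}" for i in range(1, 6)]
    modern = ["sp006", "sp007"]
    hits = misses = false_auth = 0
    for k in range(n_seeds):
        panel = build_reference_panel(7, seed=_child_seed(seed, 10_000 + k), length=4000)
        tree = TaxonomyTree.from_panel(panel)
        faecal_comp = {t: 0.16 for t in ancient} | {modern[0]: 0.12, modern[1]: 0.08}
        blank_comp = {modern[0]: 0.6, modern[1]: 0.4}
        sediment_comp = {t: 1 / 7 for t in ancient + modern}
        specs = [
            CommunitySpec(f"BRS{i}", "faecal_interior", faecal_comp, depth,
                          modern_taxa=frozenset(modern))
            for i in (2, 3, 4)
        ] + [
            CommunitySpec("SC1", "sediment_control", sediment_comp, depth // 4,
                          modern_taxa=frozenset(modern)),
            CommunitySpec("ELPC", "blank_control", blank_comp, depth // 8,
                          modern_taxa=frozenset(modern)),
        ]
        classes = {s.sample_id: s.sample_class for s in specs}
        assignments, lengths, dmg, ga = {}, {}, {}, {}
        for j, spec in enumerate(specs):
            rs, truth = simulate_sample(
                panel, spec, params, seed=_child_seed(seed, 100 * k + j)
            )
            by_taxon: dict[str, list] = {}
            for aln in truth_alignments(panel, rs, truth):
                by_taxon.setdefault(aln.taxon_id, []).append(aln)
            for taxon, alns in by_taxon.items():
                prof = misincorporation_profile(alns)
                dmg[(taxon, spec.sample_id)] = ct_terminal_test(prof)
                ga[(taxon, spec.sample_id)] = ga_terminal_check(prof)[0]
            assignments[spec.sample_id] = dict(zip(truth["read_id"], truth["taxon_id"]))
            lengths[spec.sample_id] = {r.read_id: len(r) for r in rs}
        table = build_count_table(assignments, lengths, tree)
        verdicts = _authenticate(table, dmg, classes, AuthConfig(), ga)
        for t in ancient:
            if verdicts[t].verdict == "AUTHENTICATED_ANCIENT":
                hits += 1
            else:
                misses += 1
        false_auth += sum(
            verdicts[t].verdict == "AUTHENTICATED_ANCIENT" for t in modern
        )
    return {
        "sensitivity_pct": 100.0 * hits / (hits + misses),
        "false_authenticated": false_auth,
        "n_seeds": n_seeds,
        "n_ancient_decisions": hits + misses,
    }


def environmental_pattern_verdict(seed: int = 0) -> str:
    """The sediment-restricted pattern: damage significant only in the
    control sample must classify as ENVIRONMENTAL_ANCIENT."""
    params = DamageParams(delta_ss=0.3, delta_ds=0.01, q=0.6, epsilon=0.001)
    panel = build_reference_panel(3, seed=_child_seed(seed, 1), length=4000)
    tree = TaxonomyTree.from_panel(panel)
    focal, others = "sp001", ["sp002", "sp003"]
    specs = [
        # faecal samples: focal taxon present only as modern (undamaged) traces
        CommunitySpec(f"BRS{i}", "faecal_interior",
                      {focal: 0.1, others[0]: 0.5, others[1]: 0.4}, 2500,
                      modern_taxa=frozenset({focal}))
        for i in (2, 3, 4)
    ] + [
        CommunitySpec("SC1", "sediment_control",
                      {focal: 0.7, others[0]: 0.2, others[1]: 0.1}, 2000),
    ]
    classes = {s.sample_id: s.sample_class for s in specs}
    assignments, lengths, dmg, ga = {}, {}, {}, {}
    for j, spec in enumerate(specs):
        rs, truth = simulate_sample(panel, spec, params, seed=_child_seed(seed, 50 + j))
        by_taxon: dict[str, list] = {}
        for aln in truth_alignments(panel, rs, truth):
            by_taxon.setdefault(aln.taxon_id, []).append(aln)
        for taxon, alns in by_taxon.items():
            prof = misincorporation_profile(alns)
            dmg[(taxon, spec.sample_id)] = ct_terminal_test(prof)
            ga[(taxon, spec.sample_id)] = ga_terminal_check(prof)[0]
        assignments[spec.sample_id] = dict(zip(truth["read_id"], truth["taxon_id"]))
        lengths[spec.sample_id] = {r.read_id: len(r) for r in rs}
    table = build_count_table(assignments, lengths, tree)
    verdicts = _authenticate(table, dmg, classes, AuthConfig(), ga)
    return verdicts[focal].verdict


def separated_anosim_r(seed: int = 0) -> float:
    """ANOSIM R on a fully separated 2 + 2 dissimilarity fixture (= 1)."""
    d = pd.DataFrame(
        [
            [0.0, 0.1, 0.9, 0.8],
            [0.1, 0.0, 0.85, 0.95],
            [0.9, 0.85, 0.0, 0.12],
            [0.8, 0.95, 0.12, 0.0],
        ]
    )
    return anosim(d, ["a", "a", "b", "b"], n_permutations=99, seed=seed).r


def anosim_type1(
    n_reps: int = 1000,
    n_permutations: int = 99,
    samples_per_cohort: int = 8,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """ANOSIM rejection rate on exchangeable negative-binomial cohorts.

    Eight samples per cohort: with two groups of four the permutation
    distribution has only 35 distinct groupings, so the exact test's size
    cannot exceed 1/35 at alpha = 0.05; 8 + 8 gives ~6.4e3 groupings and a
    practically continuous null.
    """
    rej = 0
    for k in range(n_reps):
        table, labels = simulate_cohort_tables(
            n_cohorts=2,
            samples_per_cohort=samples_per_cohort,
            n_features=40,
            seed=_child_seed(seed, k),
        )
        d = bray_curtis(hellinger(table + 1))
        res = anosim(d, labels, n_permutations=n_permutations, seed=_child_seed(seed, 70_000 + k))
        rej += res.p_value <= alpha
    return {"rejection_rate": rej / n_reps, "n_reps": n_reps}


def kruskal_wallis_type1(
    n_features: int = 1000, n_cohorts: int = 3, samples_per_cohort: int = 8,
    alpha: float = 0.05, seed: int = 0,
) -> dict:
    """Kruskal-Wallis rejection rate over exchangeable features."""
    table, labels = simulate_cohort_tables(
        n_cohorts=n_cohorts,
        samples_per_cohort=samples_per_cohort,
        n_features=n_features,
        seed=seed,
    )
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    rej = 0
    for ko in table.index:
        vals = table.loc[ko].to_numpy(dtype=float)
        _, p = kruskal_wallis([vals[labels == g] for g in groups])
        rej += p < alpha
    return {"rejection_rate": rej / n_features, "n_features": n_features}
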