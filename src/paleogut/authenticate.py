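"""Five-criterion authentication of taxa as ancient.

Each taxon x sample is scored on (1) mirrored terminal G->A support,
(2) significant terminal C->T damage, (3) negative-control (E-LPC)
abundance comparison, (4) mean mapped read length, and (5) ecological
conformity (a deny-list of implausible taxa).  Verdicts per taxon:

* ``AUTHENTICATED_ANCIENT`` — damage-significant, G->A-supported and
  short-read in at least one faecal-interior sample;
* ``ENVIRONMENTAL_ANCIENT`` — damage-significant only in sediment-control
  samples (ancient, but of sedimentary rather than faecal origin);
* ``CONTAMINANT`` — ecologically denied, or control-dominated in every
  damage-significant sample;
* ``NOT_AUTHENTICATED`` — everything else (including insufficient data).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import round_half_up
from .damage import DamageTestResult
from .taxassign import TaxonCountTable

VERDICTS = (
    "AUTHENTICATED_ANCIENT",
    "ENVIRONMENTAL_ANCIENT",
    "NOT_AUTHENTICATED",
    "CONTAMINANT",
)


@dataclass(frozen=True)
class AuthConfig:
    p_threshold: float = 0.05
    max_mean_length: float = 100.0
    max_control_ratio: float = 0.1
    min_reads: int = 150
    denylist: frozenset[str] = frozenset()
    require_ga: bool = True
    bh_correct: bool = False  # per-taxon raw p at 0.05 is the default contract


@dataclass
class AuthVerdict:
    taxon: str
    verdict: str
    trail: pd.DataFrame  # per-sample criterion booleans
    significant_samples: list[str]

    def to_dict(self) -> dict:
        return {
            "taxon": self.taxon,
            "verdict": self.verdict,
            "significant_samples": self.significant_samples,
            "trail": self.trail.to_dict(orient="index"),
        }


def evaluate_criteria(
    table: TaxonCountTable,
    damage_results: Mapping[tuple[str, str], DamageTestResult],
    sample_classes: Mapping[str, str],
    config: AuthConfig = AuthConfig(),
    ga_results: Mapping[tuple[str, str], bool] | None = None,
    sample_totals: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per taxon x sample criteria vector.

    ``control_ratio`` compares counts-per-million in blank (E-LPC) controls
    against counts-per-million in the sample (max over blank controls);
    taxa absent from every control score 0 and pass.  A taxon/sample missing
    from ``damage_results`` is marked insufficient, never silently passed.
    ``sample_totals`` (filtered reads per sample) defaults to the table's
    column sums.
    """
    for s in table.counts.columns:
        if s not in sample_classes:
            raise ValueError(f"sample {s!r} has no declared class")
    counts = table.counts
    totals = pd.Series(sample_totals) if sample_totals else counts.sum(axis=0)
    totals = totals.replace(0, np.nan)
    cpm = counts.div(totals, axis=1) * 1e6
    blanks = [s for s, c in sample_classes.items() if c == "blank_control" and s in cpm]
    rows = []
    for taxon in counts.index:
        genus = table.taxonomy.loc[taxon, "genus"] if taxon in table.taxonomy.index else ""
        denied = taxon in config.denylist or genus in config.denylist
        blank_cpm = max((cpm.loc[taxon, b] for b in blanks), default=0.0)
        blank_cpm = 0.0 if math.isnan(blank_cpm) else blank_cpm
        for sample in counts.columns:
            cls = sample_classes[sample]
            if cls == "blank_control":
                continue
            n = int(counts.loc[taxon, sample])
            res = damage_results.get((taxon, sample))
            p = res.p_value if res is not None else float("nan")
            sufficient = bool(res.sufficient_data) if res is not None else False
            damage_sig = bool(sufficient and not math.isnan(p) and p < config.p_threshold)
            ga_ok = True
            if ga_results is not None:
                ga = ga_results.get((taxon, sample))
                ga_ok = bool(ga) if ga is not None else False
            mean_len = table.mean_length.loc[taxon, sample]
            length_ok = bool(
                not math.isnan(mean_len) and mean_len <= config.max_mean_length
            ) if n > 0 else False
            sample_cpm = cpm.loc[taxon, sample]
            if n == 0 or math.isnan(sample_cpm):
                control_ratio = float("inf") if blank_cpm > 0 else 0.0
            else:
                control_ratio = blank_cpm / sample_cpm
            rows.append(
                {
                    "taxon": taxon,
                    "sample": sample,
                    "sample_class": cls,
                    "reads": n,
                    "mean_read_length": mean_len,
                    "p_value": p,
                    "sufficient_data": sufficient,
                    "damage_significant": damage_sig,
                    "ga_ok": ga_ok,
                    "length_ok": length_ok,
                    "control_ratio": control_ratio,
                    "control_ok": bool(control_ratio < config.max_control_ratio),
                    "eco_flag": "denied" if denied else "allowed",
                }
            )
    return pd.DataFrame(rows)


def classify_taxon(
    criteria: pd.DataFrame, config: AuthConfig = AuthConfig()
) -> AuthVerdict:
    """Collapse one taxon's per-sample criteria into a single verdict."""
    taxa = criteria["taxon"].unique()
    if len(taxa) != 1:
        raise ValueError("classify_taxon expects criteria for exactly one taxon")
    taxon = taxa[0]
    known = set(criteria["sample_class"]) - {
        "faecal_interior",
        "sediment_control",
        "modern_cohort",
    }
    if known:
        raise ValueError(f"unknown sample class(es): {sorted(known)}")
    if not (criteria["sample_class"] == "faecal_interior").any():
        raise ValueError("at least one faecal-interior sample is required")
    trail = criteria.set_index("sample")[
        [
            "sample_class",
            "reads",
            "damage_significant",
            "ga_ok",
            "length_ok",
            "control_ok",
            "eco_flag",
        ]
    ]
    sig = criteria[criteria["damage_significant"]]
    significant_samples = list(sig["sample"])
    denied = (criteria["eco_flag"] == "denied").any()
    if denied:
        verdict = "CONTAMINANT"
    elif len(sig) > 0 and not sig["control_ok"].any():
        verdict = "CONTAMINANT"
    else:
        full = sig[
            (sig["sample_class"] == "faecal_interior")
            & (sig["ga_ok"] if config.require_ga else True)
            & sig["length_ok"]
        ]
        if len(full) > 0:
            verdict = "AUTHENTICATED_ANCIENT"
        elif len(sig) > 0 and (sig["sample_class"] == "sediment_control").all():
            verdict = "ENVIRONMENTAL_ANCIENT"
        else:
            verdict = "NOT_AUTHENTICATED"
    return AuthVerdict(
        taxon=taxon, verdict=verdict, trail=trail, significant_samples=significant_samples
    )


def replay_verdict(verdict: AuthVerdict, config: AuthConfig = AuthConfig()) -> str:
    """Recompute the verdict from the stored trail alone (audit contract)."""
    t = verdict.trail
    if (t["eco_flag"] == "denied").any():
        return "CONTAMINANT"
    sig = t[t["damage_significant"]]
    if len(sig) > 0 and not sig["control_ok"].any():
        return "CONTAMINANT"
    full = sig[
        (sig["sample_class"] == "faecal_interior")
        & (sig["ga_ok"] if config.require_ga else True)
        & sig["length_ok"]
    ]
    if len(full) > 0:
        return "AUTHENTICATED_ANCIENT"
    if len(sig) > 0 and (sig["sample_class"] == "sediment_control").all():
        return "ENVIRONMENTAL_ANCIENT"
    return "NOT_AUTHENTICATED"


def authenticate(
    table: TaxonCountTable,
    damage_results: Mapping[tuple[str, str], DamageTestResult],
    sample_classes: Mapping[str, str],
    config: AuthConfig = AuthConfig(),
    ga_results: Mapping[tuple[str, str], bool] | None = None,
) -> dict[str, AuthVerdict]:
    """Evaluate criteria and classify every taxon in the table."""
    criteria = evaluate_criteria(
        table, damage_results, sample_classes, config, ga_results
    )
    out = {}
    for taxon, sub in criteria.groupby("taxon", sort=True):
        out[taxon] = classify_taxon(sub, config)
    return out


def authentication_report(
    verdicts: Mapping[str, AuthVerdict],
    table: TaxonCountTable,
    config: AuthConfig = AuthConfig(),
) -> pd.DataFrame:
    """Study-table-style report: per-sample counts, totals, percentages of
    the authenticated total, mean lengths (1 d.p.), p-values with
    significance marks, and the verdict."""
    if not verdicts:
        return pd.DataFrame()
    samples = list(table.counts.columns)
    auth = [t for t, v in verdicts.items() if v.verdict == "AUTHENTICATED_ANCIENT"]
    auth_total = float(table.counts.loc[auth].to_numpy().sum()) if auth else 0.0
    rows = []
    for taxon, v in sorted(verdicts.items()):
        counts = table.counts.loc[taxon]
        row: dict = {"taxon": taxon, "verdict": v.verdict}
        for s in samples:
            row[f"reads_{s}"] = int(counts[s])
            ml = table.mean_length.loc[taxon, s]
            row[f"mean_len_{s}"] = round_half_up(ml, 1) if not math.isnan(ml) else None
            sub = v.trail
            if s in sub.index:
                p = None
                # trail stores booleans; p-values live in criteria; re-derive mark
                row[f"significant_{s}"] = bool(sub.loc[s, "damage_significant"])
        total = int(counts.sum())
        row["total_reads"] = total
        row["pct_of_authenticated"] = (
            round_half_up(100.0 * total / auth_total, 2)
            if v.verdict == "AUTHENTICATED_ANCIENT" and auth_total > 0
            else None
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("taxon")


def verdicts_to_json(verdicts: Mapping[str, AuthVerdict], path) -> None:
    payload = {t: v.to_dict() for t, v in sorted(verdicts.items())}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
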