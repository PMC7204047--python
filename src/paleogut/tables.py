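"""Packaged study tables and their derived summary statistics.

The package ships the two published read-count tables of a mid-15th-century
South African palaeo-faecal specimen ("BRS") — 24 authenticated commensal
gut taxa and 12 authenticated potentially pathogenic taxa — as TSV
fixtures, plus the printed KO Venn counts.  Sample columns: one pooled negative-control
(E-LPC) column, the surface sediment control BRS1 (SC1), the three faecal
interior sub-samples BRS2-BRS4, and the deeper sediment control BRS5 (SC2).
The "BRS IM" total is the faecal-interior (BRS2+BRS3+BRS4) read count.

``table_fixture_check`` recomputes every summary the tables imply (phylum
and genus relative abundances, the F/B ratio, the enterotype, grand totals
and mean-length summaries, the shared-KO fraction) through the ecology and
functional modules and compares them with the printed values.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from ._util import round_half_up
from .ecology import enterotype as _enterotype
from .ecology import fb_ratio as _fb_ratio

IM_SAMPLES = ["brs2", "brs3", "brs4"]


def _data_path(name: str):
    return resources.files("paleogut").joinpath("data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """The 24 authenticated commensal gut taxa (read counts, lengths, p-values)."""
    with resources.as_file(_data_path("table1_commensal.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_table2() -> pd.DataFrame:
    """The 12 authenticated potentially pathogenic taxa."""
    with resources.as_file(_data_path("table2_pathogenic.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_ko_venn() -> dict:
    """Printed KO Venn counts (universe, shared by all cohorts, BRS-unique)."""
    with resources.as_file(_data_path("ko_venn.json")) as p:
        return json.loads(p.read_text())


def im_count_table(table1: pd.DataFrame) -> pd.DataFrame:
    """Genus x faecal-interior-sample count table from the commensal table."""
    return table1.set_index("genus")[IM_SAMPLES]


def phylum_percentages(table1: pd.DataFrame) -> pd.Series:
    """Phylum relative abundance (%) over the faecal-interior total."""
    im = table1.set_index("genus")["brs_im_total"]
    phyla = table1.set_index("genus")["phylum"]
    agg = im.groupby(phyla).sum()
    return (agg / agg.sum() * 100.0).sort_values(ascending=False)


def genus_percentages(table1: pd.DataFrame) -> pd.Series:
    im = table1.set_index("genus")["brs_im_total"]
    return (im / im.sum() * 100.0).sort_values(ascending=False)


def fb_ratio_from_table(table1: pd.DataFrame) -> float:
    agg = table1.groupby("phylum")["brs_im_total"].sum().to_frame("total")
    return _fb_ratio(agg)


def enterotype_from_table(table1: pd.DataFrame) -> tuple[int | None, dict[str, float]]:
    return _enterotype(table1.set_index("genus")[["brs_im_total"]])


def mean_length_summary(table: pd.DataFrame) -> float:
    """Mean of the per-taxon mean mapped read lengths (bp)."""
    return float(table["mean_read_length_bp"].mean())


PRINTED = {
    # phylum % of the faecal-interior (IM) total
    "proteobacteria_pct": 41.73,
    "bacteroidetes_pct": 31.25,
    "firmicutes_pct": 13.44,
    "actinobacteria_pct": 8.89,
    "euryarchaeota_pct": 4.68,
    # genus % of the IM total
    "enterobacter_pct": 34.45,
    "bacteroides_pct": 22.36,
    "cellulomonas_pct": 8.68,
    "flavobacterium_pct": 6.33,
    "prevotella_pct": 0.63,
    "ruminococcus_pct": 1.57,
    "top_four_bulk_pct": 71.82,  # sum of the four rounded genus percentages
    "fb_ratio": 0.4,
    "enterotype": 1,
    "commensal_grand_total": 688089,
    "commensal_mean_length_bp": 66.83,
    "pathogen_grand_total": 625001,
    "pathogen_mean_length_bp": 67.55,
    "shared_ko_pct": 7.86,  # printed value; 117/1487*100 = 7.8681
}


def derived_statistics() -> dict[str, float]:
    """Recompute every table-derived summary from the packaged fixtures."""
    t1, t2 = load_table1(), load_table2()
    venn = load_ko_venn()
    ph = phylum_percentages(t1)
    ge = genus_percentages(t1)
    top4 = ["Enterobacter", "Bacteroides", "Cellulomonas", "Flavobacterium"]
    ent, _ = enterotype_from_table(t1)
    return {
        "proteobacteria_pct": round_half_up(ph["Proteobacteria"], 2),
        "bacteroidetes_pct": round_half_up(ph["Bacteroidetes"], 2),
        "firmicutes_pct": round_half_up(ph["Firmicutes"], 2),
        "actinobacteria_pct": round_half_up(ph["Actinobacteria"], 2),
        "euryarchaeota_pct": round_half_up(ph["Euryarchaeota"], 2),
        "enterobacter_pct": round_half_up(ge["Enterobacter"], 2),
        "bacteroides_pct": round_half_up(ge["Bacteroides"], 2),
        "cellulomonas_pct": round_half_up(ge["Cellulomonas"], 2),
        "flavobacterium_pct": round_half_up(ge["Flavobacterium"], 2),
        "prevotella_pct": round_half_up(ge["Prevotella"], 2),
        "ruminococcus_pct": round_half_up(ge["Ruminococcus"], 2),
        "top_four_bulk_pct": round_half_up(
            sum(round_half_up(ge[g], 2) for g in top4), 2
        ),
        "fb_ratio": round_half_up(fb_ratio_from_table(t1), 1),
        "enterotype": ent,
        "commensal_grand_total": int(t1["brs_im_total"].sum()),
        "commensal_mean_length_bp": round_half_up(mean_length_summary(t1), 2),
        "pathogen_grand_total": int(t2["total"].sum()),
        "pathogen_mean_length_bp": round_half_up(mean_length_summary(t2), 2),
        "shared_ko_pct": round_half_up(
            100.0 * venn["shared_all"] / venn["universe"], 2
        ),
    }


def table_fixture_check(tolerances: dict[str, float] | None = None) -> pd.DataFrame:
    """Compare recomputed table statistics against the printed values.

    Returns one row per statistic (computed, printed, ok).  The shared-KO
    percentage allows 0.015 because the printed 7.86 is a truncation of
    7.8681; everything else must match the printed precision exactly.
    """
    tol = {"shared_ko_pct": 0.015}
    if tolerances:
        tol.update(tolerances)
    computed = derived_statistics()
    rows = []
    for key, printed in PRINTED.items():
        got = computed[key]
        ok = abs(float(got) - float(printed)) <= tol.get(key, 1e-9)
        rows.append({"statistic": key, "computed": got, "printed": printed, "ok": ok})
    return pd.DataFrame(rows).set_index("statistic")
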