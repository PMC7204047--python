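"""Five-criterion authentication logic: deny-list, control-ratio and
read-length criteria, the verdict state machine (including the
environmental-ancient pattern), replayability and threshold monotonicity."""

import math

import numpy as np
import pandas as pd
import pytest

import paleogut as pg
from paleogut.authenticate import replay_verdict
from paleogut.damage import DamageTestResult
from paleogut.taxassign import TaxonCountTable


def _result(p, sufficient=True):
    return DamageTestResult(p, 0.2, 0.01, 100, int(100 * 0.2), "binomial-terminal", sufficient)


def _table(counts: dict, mean_len=70.0, taxonomy=None):
    df = pd.DataFrame(counts).T  # taxa x samples
    ml = pd.DataFrame(mean_len, index=df.index, columns=df.columns, dtype=float)
    tax = taxonomy or pd.DataFrame(
        {"root": "root", "phylum": "p", "genus": list(df.index), "rank": "species"},
        index=df.index,
    )
    return TaxonCountTable(counts=df, mean_length=ml, taxonomy=tax)


SAMPLES = {"SC1": "sediment_control", "BRS2": "faecal_interior",
           "BRS3": "faecal_interior", "BRS4": "faecal_interior",
           "SC2": "sediment_control", "ELPC": "blank_control"}


def _counts(brs=500, sc=0, elpc=0):
    return {"SC1": sc, "BRS2": brs, "BRS3": brs, "BRS4": brs, "SC2": sc, "ELPC": elpc}


class TestEvaluateCriteria:
    def test_denied_taxon_flagged_regardless_of_damage(self):
        table = _table({"Oryza": _counts(), "Bacteroides": _counts()})
        dmg = {(t, s): _result(1e-6) for t in table.counts.index for s in SAMPLES}
        cfg = pg.AuthConfig(denylist=frozenset({"Oryza"}))
        crit = pg.evaluate_criteria(table, dmg, SAMPLES, cfg)
        assert (crit.loc[crit["taxon"] == "Oryza", "eco_flag"] == "denied").all()
        assert (crit.loc[crit["taxon"] == "Bacteroides", "eco_flag"] == "allowed").all()

    def test_control_ratio_near_one_fails(self):
        # same counts-per-million in E-LPC and sample -> ratio ~ 1 -> fail
        table = _table({"t1": _counts(brs=9000, elpc=9000),
                        "t2": _counts(brs=9000, elpc=9000)})
        dmg = {(t, s): _result(1e-6) for t in table.counts.index for s in SAMPLES}
        crit = pg.evaluate_criteria(table, dmg, SAMPLES, pg.AuthConfig()).set_index(
            ["taxon", "sample"]
        )
        r1 = crit.loc[("t1", "BRS2")]
        assert r1["control_ratio"] == pytest.approx(1.0, rel=0.05)
        assert not r1["control_ok"]

    def test_taxon_absent_from_controls_passes(self):
        table = _table({"t1": _counts(brs=500, elpc=0), "t2": _counts(brs=10, elpc=300)})
        dmg = {(t, s): _result(0.5) for t in table.counts.index for s in SAMPLES}
        crit = pg.evaluate_criteria(table, dmg, SAMPLES, pg.AuthConfig()).set_index(
            ["taxon", "sample"]
        )
        assert crit.loc[("t1", "BRS2"), "control_ratio"] == 0.0
        assert crit.loc[("t1", "BRS2"), "control_ok"]

    def test_missing_damage_result_marked_insufficient(self):
        table = _table({"t1": _counts()})
        crit = pg.evaluate_criteria(table, {}, SAMPLES, pg.AuthConfig())
        assert not crit["sufficient_data"].any()
        assert not crit["damage_significant"].any()

    def test_unknown_sample_class_is_error(self):
        table = _table({"t1": _counts()})
        with pytest.raises(ValueError, match="no declared class"):
            pg.evaluate_criteria(table, {}, {"BRS2": "faecal_interior"}, pg.AuthConfig())

    def test_long_reads_fail_length_criterion(self):
        table = _table({"t1": _counts()}, mean_len=150.0)
        dmg = {("t1", s): _result(1e-6) for s in SAMPLES}
        crit = pg.evaluate_criteria(table, dmg, SAMPLES, pg.AuthConfig())
        assert not crit["length_ok"].any()


class TestClassifyTaxon:
    def _classify(self, counts, dmg_p, cfg=None, mean_len=70.0, ga=None):
        cfg = cfg or pg.AuthConfig()
        table = _table({"t1": counts}, mean_len=mean_len)
        dmg = {
            ("t1", s): _result(p, sufficient=not math.isnan(p))
            for s, p in dmg_p.items()
        }
        crit = pg.evaluate_criteria(table, dmg, SAMPLES, cfg, ga_results=ga)
        return pg.classify_taxon(crit, cfg)

    def test_significant_in_faecal_samples_authenticated(self):
        v = self._classify(
            _counts(), {"SC1": float("nan"), "BRS2": 1e-4, "BRS3": 1e-7,
                        "BRS4": 0.3, "SC2": float("nan")}
        )
        assert v.verdict == "AUTHENTICATED_ANCIENT"
        assert set(v.significant_samples) == {"BRS2", "BRS3"}

    def test_significant_only_in_surface_control_environmental(self):
        # the sediment-restricted pattern: ancient but environmental
        v = self._classify(
            _counts(brs=400, sc=900),
            {"SC1": 1e-7, "BRS2": 0.35, "BRS3": 0.1, "BRS4": 0.88, "SC2": float("nan")},
        )
        assert v.verdict == "ENVIRONMENTAL_ANCIENT"

    def test_insufficient_reads_everywhere_not_authenticated(self):
        v = self._classify(
            _counts(brs=40),
            {s: float("nan") for s in SAMPLES},
        )
        assert v.verdict == "NOT_AUTHENTICATED"

    def test_denied_taxon_contaminant(self):
        cfg = pg.AuthConfig(denylist=frozenset({"t1"}))
        v = self._classify(_counts(), {s: 1e-8 for s in SAMPLES}, cfg=cfg)
        assert v.verdict == "CONTAMINANT"

    def test_long_reads_block_authentication(self):
        v = self._classify(
            _counts(), {"SC1": 0.5, "BRS2": 1e-6, "BRS3": 1e-6, "BRS4": 1e-6, "SC2": 0.5},
            mean_len=140.0,
        )
        assert v.verdict != "AUTHENTICATED_ANCIENT"

    def test_control_dominated_significant_samples_contaminant(self):
        counts = _counts(brs=500, elpc=600)
        v = self._classify(
            counts, {"SC1": 0.9, "BRS2": 1e-6, "BRS3": 1e-6, "BRS4": 1e-6, "SC2": 0.9}
        )
        assert v.verdict == "CONTAMINANT"

    def test_replayability(self):
        v = self._classify(
            _counts(), {"SC1": 0.2, "BRS2": 1e-4, "BRS3": 0.5, "BRS4": 0.5, "SC2": 0.7}
        )
        assert replay_verdict(v) == v.verdict

    def test_p_threshold_monotonicity(self):
        # raising the threshold never demotes AUTHENTICATED -> NOT_AUTHENTICATED
        dmg = {"SC1": 0.5, "BRS2": 0.02, "BRS3": 0.5, "BRS4": 0.5, "SC2": 0.5}
        low = self._classify(_counts(), dmg, cfg=pg.AuthConfig(p_threshold=0.05))
        high = self._classify(_counts(), dmg, cfg=pg.AuthConfig(p_threshold=0.2))
        assert low.verdict == "AUTHENTICATED_ANCIENT"
        assert high.verdict == "AUTHENTICATED_ANCIENT"

    def test_requires_faecal_sample(self):
        table = _table({"t1": {"SC1": 10}})
        crit = pg.evaluate_criteria(
            table, {}, {"SC1": "sediment_control"}, pg.AuthConfig()
        )
        with pytest.raises(ValueError, match="faecal-interior"):
            pg.classify_taxon(crit)


class TestAuthenticationReport:
    def test_synthetic_truth_authenticates_only_ancient_taxa(self, panel):
        # 3 damaged taxa + 2 modern contaminants, verdicts from truth data
        ancient = ["sp001", "sp002", "sp003"]
        modern = ["sp006", "sp007"]
        comp = {t: 0.3 for t in ancient} | {t: 0.05 for t in modern}
        params = pg.DamageParams(delta_ss=0.35, delta_ds=0.01, q=0.6, epsilon=0.001)
        classes = {"BRS2": "faecal_interior", "BRS3": "faecal_interior", "ELPC": "blank_control"}
        tables, dmg, ga = {}, {}, {}
        assignments, lengths = {}, {}
        for i, sample in enumerate(["BRS2", "BRS3"]):
            spec = pg.CommunitySpec(
                sample, "faecal_interior", comp, 4000, modern_taxa=frozenset(modern)
            )
            rs, truth = pg.simulate_sample(panel, spec, params, seed=100 + i)
            alns = pg.truth_alignments(panel, rs, truth)
            by_taxon = {}
            for a in alns:
                by_taxon.setdefault(a.taxon_id, []).append(a)
            for taxon, sub in by_taxon.items():
                prof = pg.misincorporation_profile(sub)
                dmg[(taxon, sample)] = pg.ct_terminal_test(prof)
                ga[(taxon, sample)] = pg.ga_terminal_check(prof)[0]
            assignments[sample] = dict(zip(truth["read_id"], truth["taxon_id"]))
            lengths[sample] = {r.read_id: len(r) for r in rs}
        # empty blank control column
        assignments["ELPC"] = {}
        lengths["ELPC"] = {}
        tree = pg.TaxonomyTree.from_panel(panel)
        table = pg.build_count_table(assignments, lengths, tree)
        verdicts = pg.authenticate(table, dmg, classes, pg.AuthConfig(), ga)
        got_auth = {t for t, v in verdicts.items() if v.verdict == "AUTHENTICATED_ANCIENT"}
        assert got_auth == set(ancient)
        report = pg.authentication_report(verdicts, table)
        pct = report["pct_of_authenticated"].dropna()
        assert pct.sum() == pytest.approx(100.0, abs=0.05)

    def test_empty_input_empty_report(self):
        assert pg.authentication_report({}, None).empty
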