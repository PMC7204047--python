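"""Ecology statistics: hand-arithmetic oracles for transforms and
dissimilarities, PCoA geometry recovery, ANOSIM rank arithmetic and
independent cross-checks against scipy/scikit-bio implementations."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.cluster import hierarchy

import paleogut as pg
from paleogut import tables
from paleogut.ecology import aggregate_by_rank, format_percent, pcoa


def _df(data, columns=None):
    return pd.DataFrame(data, columns=columns)


class TestRelativeAbundance:
    def test_single_taxon_is_100(self):
        t = _df({"s1": [7]})
        assert pg.relative_abundance(t).iloc[0, 0] == 100.0

    def test_simple_proportions(self):
        t = _df({"s1": [1, 1, 2]})
        assert list(pg.relative_abundance(t)["s1"]) == [25.0, 25.0, 50.0]

    def test_columns_sum_to_100_before_rounding(self):
        rng = np.random.default_rng(1)
        t = _df(rng.integers(1, 50, size=(20, 5)))
        assert np.allclose(pg.relative_abundance(t).sum(axis=0), 100.0)


class TestAggregateAndTableSummaries:
    def test_bacteroidetes_genus_sum_matches_printed_rows(self):
        t1 = tables.load_table1()
        agg = aggregate_by_rank(
            t1.set_index("genus")[["brs_im_total"]],
            dict(zip(t1["genus"], t1["phylum"])),
        )
        assert int(agg.loc["Bacteroidetes", "brs_im_total"]) == 215_042

    def test_split_then_aggregate_equals_direct_sum(self, rng):
        t = _df(rng.integers(0, 100, size=(12, 3)))
        groups = {i: f"g{rng.integers(0, 4)}" for i in t.index}
        agg = aggregate_by_rank(t, groups)
        # oracle: brute-force partition sum
        for g in set(groups.values()):
            members = [i for i, v in groups.items() if v == g]
            assert (agg.loc[g] == t.loc[members].sum(axis=0)).all()

    def test_fb_ratio_conventions(self):
        t = pd.DataFrame({"s": [10, 10]}, index=["Firmicutes", "Bacteroidetes"])
        assert pg.fb_ratio(t) == 1.0
        t0 = pd.DataFrame({"s": [0, 10]}, index=["Firmicutes", "Bacteroidetes"])
        assert pg.fb_ratio(t0) == 0.0
        bad = pd.DataFrame({"s": [10]}, index=["Firmicutes"])
        with pytest.raises(ValueError):
            pg.fb_ratio(bad)

    def test_enterotype_prevotella_dominance(self):
        t = pd.DataFrame({"s": [100, 2]}, index=["Prevotella", "Bacteroides"])
        label, _ = pg.enterotype(t)
        assert label == 2

    def test_enterotype_tie_flagged(self):
        t = pd.DataFrame({"s": [5, 5]}, index=["Prevotella", "Bacteroides"])
        label, shares = pg.enterotype(t)
        assert label is None


class TestRarefy:
    def test_identity_at_full_depth(self):
        t = _df({"s1": [5, 5], "s2": [3, 7]})
        out = pg.rarefy(t, depth=10, seed=0)
        assert out.equals(t)

    def test_depth_one(self):
        t = _df({"s1": [5, 5, 5]})
        out = pg.rarefy(t, depth=1, seed=1)
        assert out["s1"].sum() == 1 and (out["s1"] >= 0).all()

    def test_expectation_matches_hypergeometric_moments(self):
        t = _df({"s1": [60, 30, 10]})
        reps = np.stack(
            [pg.rarefy(t, depth=50, seed=s)["s1"].to_numpy() for s in range(600)]
        )
        expected = 50 * np.array([0.6, 0.3, 0.1])
        # MVH variance: n p (1-p) (N-n)/(N-1)
        var = 50 * expected / 50 * (1 - expected / 50) * (100 - 50) / 99
        se = np.sqrt(var / 600)
        assert np.all(np.abs(reps.mean(axis=0) - expected) < 3 * se)

    def test_error_names_offending_sample(self):
        t = _df({"ok": [10, 10], "small": [1, 1]})
        with pytest.raises(ValueError, match="small"):
            pg.rarefy(t, depth=10)


class TestPrevalenceFilter:
    def test_boundary_cases(self):
        t = _df(
            {f"s{i}": col for i, col in enumerate(
                np.array([[4, 3], [4, 3], [0, 3], [0, 3], [0, 3]]))}
        )
        out = pg.prevalence_filter(t, min_count=3, min_fraction=0.2)
        # feature 0: >3 in 2/5 samples -> kept; feature 1: 3 is not > 3 -> dropped
        assert list(out.index) == [0]

    def test_empty_table_passthrough(self):
        t = pd.DataFrame()
        assert pg.prevalence_filter(t).empty


class TestHellinger:
    def test_hand_arithmetic(self):
        t = _df({"s1": [1, 4, 4]})
        out = pg.hellinger(t)
        assert np.allclose(out["s1"], [1 / 3, 2 / 3, 2 / 3])

    def test_squared_entries_sum_to_one(self, rng):
        t = _df(rng.integers(0, 40, size=(15, 4)) + 1)
        out = pg.hellinger(t)
        assert np.allclose((out**2).sum(axis=0), 1.0)

    def test_euclidean_on_hellinger_equals_hellinger_distance(self, rng):
        t = _df(rng.integers(1, 50, size=(10, 5)))
        h = pg.hellinger(t)
        d_euc = squareform(pdist(h.T.to_numpy()))
        p = t.div(t.sum(axis=0), axis=1).to_numpy()
        d_hel = squareform(pdist(np.sqrt(p.T)))
        assert np.allclose(d_euc, d_hel)


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        t = _df({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert pg.bray_curtis(t).loc["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        t = _df({"a": [5, 0], "b": [0, 7]})
        assert pg.bray_curtis(t).loc["a", "b"] == 1.0

    def test_hand_arithmetic_third(self):
        t = _df({"x": [1, 2, 3], "y": [3, 2, 1]})
        assert pg.bray_curtis(t).loc["x", "y"] == pytest.approx(4 / 12)

    def test_unweighted_equals_weighted_on_binarised(self, rng):
        t = _df(rng.integers(0, 5, size=(12, 4)))
        assert np.allclose(
            pg.bray_curtis(t, weighted=False), pg.bray_curtis((t > 0).astype(int))
        )

    def test_matches_scipy(self, rng):
        t = _df(rng.integers(0, 30, size=(10, 5)) + 1)
        ours = pg.bray_curtis(t).to_numpy()
        theirs = squareform(pdist(t.T.to_numpy(), metric="braycurtis"))
        assert np.allclose(ours, theirs)

    def test_range_symmetry_zero_diagonal(self, rng):
        t = _df(rng.integers(0, 9, size=(8, 6)))
        d = pg.bray_curtis(t + 1).to_numpy()
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        assert d.min() >= 0 and d.max() <= 1


class TestPcoa:
    def test_two_samples_at_distance_d(self):
        d = pd.DataFrame([[0, 0.8], [0.8, 0]], index=["a", "b"], columns=["a", "b"])
        res = pg.pcoa(d)
        coords = res.coordinates["PC1"].to_numpy()
        assert np.allclose(np.abs(coords), 0.4)
        assert coords[0] == pytest.approx(-coords[1])

    def test_recovers_euclidean_configuration(self, rng):
        pts = rng.normal(size=(7, 2))
        d = pd.DataFrame(squareform(pdist(pts)))
        res = pg.pcoa(d)
        rec = res.coordinates.to_numpy()[:, :2]
        # Procrustes: align recovered to original, residual ~ 0
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, rec)
        assert disparity < 1e-8
        assert np.all(res.eigenvalues[2:] < 1e-8)

    def test_all_zero_distances(self):
        d = pd.DataFrame(np.zeros((4, 4)))
        res = pg.pcoa(d)
        assert res.coordinates.shape[1] == 0 or np.allclose(res.coordinates, 0)

    def test_matches_skbio(self, rng):
        t = _df(rng.integers(1, 30, size=(10, 6)))
        d = pg.bray_curtis(t)
        ours = pg.pcoa(d)
        import skbio

        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.to_numpy(), ids=[str(c) for c in d.columns])
        )
        k = ours.coordinates.shape[1]
        assert np.allclose(
            np.sort(ours.eigenvalues)[::-1][:k],
            np.sort(theirs.eigvals.to_numpy())[::-1][:k],
            atol=1e-8,
        )
        assert np.allclose(
            np.abs(ours.coordinates.to_numpy()[:, 0]),
            np.abs(theirs.samples.iloc[:, 0].to_numpy()),
            atol=1e-8,
        )


class TestAnosim:
    def test_fully_separated_two_plus_two_r_is_one(self):
        # within ranks {1.5, 1.5}, between ranks {3.5..6} -> R = 1 by rank arithmetic
        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.8],
                [0.1, 0.0, 0.85, 0.95],
                [0.9, 0.85, 0.0, 0.12],
                [0.8, 0.95, 0.12, 0.0],
            ]
        )
        dm = pd.DataFrame(d)
        res = pg.anosim(dm, ["g1", "g1", "g2", "g2"], n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_identical_matrix_r_zero_by_midranks(self):
        d = np.full((6, 6), 0.5)
        np.fill_diagonal(d, 0.0)
        res = pg.anosim(pd.DataFrame(d), ["a", "a", "a", "b", "b", "b"], 99, seed=0)
        assert res.r == 0.0

    def test_singleton_group_rejected(self):
        d = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            pg.anosim(d, ["a", "a", "b"], 99, seed=0)

    def test_r_matches_skbio(self, rng):
        t = _df(rng.integers(1, 40, size=(15, 8)))
        d = pg.bray_curtis(t)
        labels = ["a"] * 4 + ["b"] * 4
        ours = pg.anosim(d, labels, n_permutations=99, seed=0)
        import skbio

        theirs = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(d.to_numpy(), ids=[str(c) for c in d.columns]),
            grouping=labels,
            permutations=99,
        )
        assert ours.r == pytest.approx(theirs["test statistic"], abs=1e-12)


class TestCorrelationCluster:
    def test_perfectly_rank_correlated_merge_at_zero(self):
        t = _df({"a": [1, 2, 3, 4], "b": [10, 20, 30, 40], "c": [4, 3, 2, 1]})
        z = pg.correlation_cluster(t)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)  # first merge height

    def test_anticorrelated_distance_two(self):
        t = _df({"a": [1, 2, 3], "b": [3, 2, 1]})
        z = pg.correlation_cluster(t)
        assert z[0, 2] == pytest.approx(2.0)

    def test_five_sample_complete_linkage_matches_oracle(self, rng):
        t = _df(rng.normal(size=(30, 5)))
        z = pg.correlation_cluster(t, linkage="complete")
        corr = t.corr(method="spearman").to_numpy()
        dist = 1 - corr
        np.fill_diagonal(dist, 0)
        oracle = hierarchy.linkage(squareform(dist, checks=False), method="complete")
        assert np.allclose(z, oracle)
        # oracle cross-check of the first merge: the closest pair overall
        iu = np.triu_indices(5, 1)
        assert z[0, 2] == pytest.approx(dist[iu].min())

    def test_ward_supported_others_rejected(self, rng):
        t = _df(rng.normal(size=(20, 4)))
        pg.correlation_cluster(t, linkage="ward")
        with pytest.raises(ValueError):
            pg.correlation_cluster(t, linkage="single")


def test_report_rounding_is_half_up():
    assert format_percent(66.825, 2) == 66.83
    assert format_percent(0.125, 2) == 0.13
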