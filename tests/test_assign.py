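"""Aligner and LCA-assignment contracts: identity arithmetic, top-percent
retention, min-support lifting and truth-driven count-table accuracy."""

import numpy as np
import pytest

import paleogut as pg
from paleogut.containers import Read
from paleogut.simulate import ReferencePanel, TaxonRecord
from paleogut.taxassign import hit_alignment


def _lineage(phylum, genus, species):
    return (
        ("root", "root"),
        ("phylum", phylum),
        ("genus", genus),
        ("species", species),
    )


@pytest.fixture(scope="module")
def shared_panel():
    """Two siblings sharing a 60 bp island, plus an unrelated taxon."""
    rng = np.random.default_rng(42)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    def rand_seq(n):
        return bases[rng.integers(0, 4, n)].tobytes().decode()
    island = rand_seq(60)
    seq_a = rand_seq(400) + island + rand_seq(400)
    seq_b = rand_seq(400) + island + rand_seq(400)
    seq_c = rand_seq(860)
    taxa = [
        TaxonRecord("spA", "A", _lineage("p1", "g1", "spA")),
        TaxonRecord("spB", "B", _lineage("p1", "g1", "spB")),
        TaxonRecord("spC", "C", _lineage("p2", "g2", "spC")),
    ]
    return ReferencePanel(
        taxa=taxa, sequences={"spA": seq_a, "spB": seq_b, "spC": seq_c}, gc_fraction=0.5
    ), island


class TestAlignRead:
    def test_exact_substring_single_hit_identity_100(self, shared_panel):
        panel, _ = shared_panel
        index = pg.KmerIndex(panel, k=13)
        read = Read("r", panel.sequences["spC"][100:150], "I" * 50)
        hits = pg.align_read(read, index)
        top = [h for h in hits if h.score == max(x.score for x in hits)]
        assert len(top) == 1 and top[0].taxon_id == "spC"
        assert top[0].identity == 100.0

    def test_shared_island_hits_both_siblings_equally(self, shared_panel):
        panel, island = shared_panel
        index = pg.KmerIndex(panel, k=13)
        read = Read("r", island[5:55], "I" * 50)
        hits = {h.taxon_id: h for h in pg.align_read(read, index)}
        assert {"spA", "spB"} <= set(hits)
        assert hits["spA"].score == hits["spB"].score

    def test_reverse_strand_reads_found(self, shared_panel):
        panel, _ = shared_panel
        index = pg.KmerIndex(panel, k=13)
        read = Read("r", pg.revcomp(panel.sequences["spC"][200:260]), "I" * 60)
        hits = pg.align_read(read, index)
        best = hits[0]
        assert best.taxon_id == "spC" and best.strand == "-"
        assert best.identity == 100.0

    def test_two_mismatches_over_fifty_gives_identity_96(self, shared_panel):
        panel, _ = shared_panel
        index = pg.KmerIndex(panel, k=13)
        frag = list(panel.sequences["spC"][300:350])
        for pos in (40, 45):  # keep an exact 13-mer seed intact at the start
            frag[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[pos]]
        hits = pg.align_read(Read("r", "".join(frag), "I" * 50), index)
        best = next(h for h in hits if h.taxon_id == "spC")
        # brute-force oracle: best ungapped placement over all offsets
        ref = panel.sequences["spC"]
        oracle = max(
            sum(a == b for a, b in zip("".join(frag), ref[off : off + 50]))
            for off in range(len(ref) - 50)
        )
        assert oracle == 48
        assert best.identity == pytest.approx(96.0)
        assert best.score == 2 * 48 - 50

    def test_hit_alignment_is_as_sequenced(self, shared_panel):
        panel, _ = shared_panel
        index = pg.KmerIndex(panel, k=13)
        seq = pg.revcomp(panel.sequences["spC"][500:560])
        read = Read("r", seq, "I" * 60)
        hit = pg.align_read(read, index)[0]
        aln = hit_alignment(read, hit, panel)
        assert aln.read_frag == seq and aln.ref_frag == seq


class TestAssignLCA:
    def test_single_passing_hit(self, shared_panel, tree_shared=None):
        panel, _ = shared_panel
        tree = pg.TaxonomyTree.from_panel(panel)
        h = pg.Hit("r", "spC", 50, 100.0, 0, 50, 0, 50, "+")
        assert pg.assign_lca([h], tree) == "spC"

    def test_sibling_species_collapse_to_genus(self, shared_panel):
        panel, _ = shared_panel
        tree = pg.TaxonomyTree.from_panel(panel)
        hits = [
            pg.Hit("r", "spA", 50, 100.0, 0, 50, 0, 50, "+"),
            pg.Hit("r", "spB", 50, 100.0, 0, 50, 0, 50, "+"),
        ]
        assert pg.assign_lca(hits, tree) == "g1"

    def test_top_percent_threshold_arithmetic(self, shared_panel):
        panel, _ = shared_panel
        tree = pg.TaxonomyTree.from_panel(panel)
        hits = [
            pg.Hit("r", "spA", 50, 100.0, 0, 50, 0, 50, "+"),
            pg.Hit("r", "spB", 44, 100.0, 0, 50, 0, 50, "+"),  # below 45 = 0.9*50
        ]
        assert pg.assign_lca(hits, tree, top_percent=10.0) == "spA"

    def test_no_passing_hits_unassigned(self, shared_panel):
        panel, _ = shared_panel
        tree = pg.TaxonomyTree.from_panel(panel)
        h = pg.Hit("r", "spA", 20, 90.0, 0, 50, 0, 50, "+")
        assert pg.assign_lca([h], tree, min_identity=97.0, min_score=30) is None

    def test_unknown_taxon_raises(self, shared_panel):
        panel, _ = shared_panel
        tree = pg.TaxonomyTree.from_panel(panel)
        h = pg.Hit("r", "spZ", 50, 100.0, 0, 50, 0, 50, "+")
        with pytest.raises(KeyError):
            pg.assign_lca([h], tree)


class TestMinSupport:
    def test_sparse_taxon_lifted_to_parent(self, tree):
        assignments = {f"r{i}": "sp001" for i in range(9)}
        assignments |= {f"p{i}": "genus01" for i in range(100)}
        out = pg.apply_min_support(assignments, tree, min_support=10)
        assert all(v == "genus01" for v in out.values())

    def test_boundary_exactly_min_support_unchanged(self, tree):
        assignments = {f"r{i}": "sp001" for i in range(10)}
        out = pg.apply_min_support(assignments, tree, min_support=10)
        assert all(v == "sp001" for v in out.values())

    def test_chain_accumulates_upward(self, tree):
        # oracle: brute-force bottom-up lifting on counts
        assignments = (
            {f"a{i}": "sp001" for i in range(4)}
            | {f"b{i}": "sp005" for i in range(4)}  # sp005 shares genus01 with sp001
            | {f"c{i}": "genus01" for i in range(4)}
        )
        out = pg.apply_min_support(assignments, tree, min_support=10)
        # 4+4+4 = 12 accumulate at genus01, which reaches support
        assert all(v == "genus01" for v in out.values())

    def test_root_failure_unassigned(self, tree):
        assignments = {f"r{i}": "sp001" for i in range(3)}
        out = pg.apply_min_support(assignments, tree, min_support=10)
        assert all(v is None for v in out.values())


class TestCountTable:
    def test_truth_driven_counts_and_species_accuracy(self, panel, tree):
        # undamaged reads from distinct references: 100% species-level accuracy
        spec = pg.CommunitySpec(
            "s1", "faecal_interior", {"sp001": 0.5, "sp004": 0.5}, 400
        )
        rs, truth = pg.simulate_sample(panel, spec, pg.DamageParams.none(), seed=6)
        index = pg.KmerIndex(panel, k=13)
        assigned = {}
        lengths = {}
        for read in rs:
            hits = pg.align_read(read, index)
            assigned[read.read_id] = pg.assign_lca(hits, tree, min_identity=97.0)
            lengths[read.read_id] = len(read)
        expected = truth.set_index("read_id")["taxon_id"]
        hit_rate = np.mean([assigned[r] == expected[r] for r in assigned])
        assert hit_rate == 1.0
        table = pg.build_count_table({"s1": assigned}, {"s1": lengths}, tree)
        vc = truth["taxon_id"].value_counts()
        assert int(table.counts.loc["sp001", "s1"]) == int(vc["sp001"])
        assert int(table.counts.loc["sp004", "s1"]) == int(vc["sp004"])
        # conservation: assigned + unassigned = input
        n_unassigned = sum(v is None for v in assigned.values())
        assert int(table.counts["s1"].sum()) + n_unassigned == len(rs)

    def test_zero_for_absent_taxon_and_mean_length(self, tree):
        assigned = {"r1": "sp001", "r2": "sp001"}
        lengths = {"r1": 60, "r2": 70}
        table = pg.build_count_table({"s": assigned}, {"s": lengths}, tree)
        assert table.mean_length.loc["sp001", "s"] == pytest.approx(65.0)
        assert (table.counts.drop(index="sp001")["s"] == 0).all() if len(table.counts) > 1 else True

    def test_damage_moves_reads_up_not_sideways(self, panel, tree):
        # heavy damage: misassignment may lift reads in rank, never across clades
        spec = pg.CommunitySpec("s1", "faecal_interior", {"sp001": 1.0}, 300)
        params = pg.DamageParams(delta_ss=0.6, delta_ds=0.05, q=0.7, epsilon=0.01)
        rs, _ = pg.simulate_sample(panel, spec, params, seed=13)
        index = pg.KmerIndex(panel, k=13)
        allowed = set(tree.path_to_root("sp001")) | {None}
        for read in rs:
            got = pg.assign_lca(pg.align_read(read, index), tree, min_identity=80.0)
            assert got in allowed
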