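import io

import dendropy
import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from crfkit.architecture import ArchitectureCall, Category
from crfkit.motif_profile import DomainHit, DomainKind
from crfkit.phylogeny import (
    NON_MONOPHYLETIC_OUTGROUP,
    bootstrap_support,
    extract_domain_alignment,
    neighbor_joining,
    p_distance,
    read_newick,
    root_on_outgroup,
    write_newick,
)
from crfkit.seq_io import AlignedBlock

from oracles import (
    congruent_block,
    edge_lengths_by_split,
    patristic,
    random_binary_tree,
    tree_splits,
)


class TestPDistance:
    def test_identical_rows_are_distance_zero(self):
        block = AlignedBlock((("a", "MKVQWLGAAC"), ("b", "MKVQWLGAAC")))
        assert p_distance(block)["a", "b"] == 0.0

    def test_fraction_of_differing_columns(self):
        block = AlignedBlock((("a", "MKVQWLGAAC"), ("b", "MKVQWLGTTT")))
        assert p_distance(block)["a", "b"] == pytest.approx(0.3)

    def test_pairwise_deletion_of_gapped_columns(self):
        block = AlignedBlock((("a", "MK-VQWLGAA"), ("b", "MKAVQWLGAT")))
        assert p_distance(block)["a", "b"] == pytest.approx(1 / 9)

    def test_no_comparable_columns_error_names_the_pair(self):
        block = AlignedBlock((("a", "MK--"), ("b", "--VQ"), ("c", "MKVQ")))
        with pytest.raises(ValueError, match="'a' and 'b'"):
            p_distance(block)

    def test_metric_axioms_on_gapless_blocks(self, rng):
        rows = tuple(
            (f"t{i}", "".join(rng.choice(list("ACDEFGHIKL"), size=30)))
            for i in range(6)
        )
        dm = p_distance(AlignedBlock(rows))
        data = dm.data
        assert np.allclose(data, data.T)
        assert np.all(np.diag(data) == 0)
        assert np.all(data >= 0)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix([[0, 3, 5], [3, 0, 6], [5, 6, 0]], ids=list("ABC"))
        tree = neighbor_joining(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 4.0})

    def test_additive_four_taxon_matrix_recovers_split_and_lengths(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> dAB=3 dAC=5 dAD=6 dBC=6 dBD=7 dCD=7
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        tree = neighbor_joining(DistanceMatrix(d, ids=list("ABCD")))
        assert tree_splits(tree) == {frozenset({"C", "D"})}
        paths = patristic(tree)
        for (i, a) in enumerate("ABCD"):
            for b in "ABCD"[i + 1 :]:
                assert paths[frozenset((a, b))] == pytest.approx(d[i]["ABCD".index(b)])

    def test_leaf_set_is_conserved(self, rng):
        n = 7
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"t{i}" for i in range(n)]
        tree = neighbor_joining(DistanceMatrix(d, ids=ids))
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == set(ids)

    def test_basal_node_has_degree_three(self, rng):
        n = 6
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tree = neighbor_joining(DistanceMatrix(d, ids=[f"t{i}" for i in range(n)]))
        assert len(tree.seed_node.child_nodes()) == 3

    def test_fewer_than_three_taxa_is_error(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))

    @pytest.mark.parametrize("seed", range(25))
    def test_consistency_on_random_additive_matrices(self, seed):
        rng = np.random.default_rng(31000 + seed)
        n = int(rng.integers(4, 9))
        labels = [f"t{i}" for i in range(n)]
        true_splits, dist = random_binary_tree(rng, labels)
        d = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels[i + 1 :], start=i + 1):
                d[i, j] = d[j, i] = dist[frozenset((a, b))]
        tree = neighbor_joining(DistanceMatrix(d, ids=labels))
        assert tree_splits(tree) == true_splits
        paths = patristic(tree)
        for pair, value in dist.items():
            assert paths[pair] == pytest.approx(value, abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_reference_nj_on_noisy_matrices(self, seed):
        rng = np.random.default_rng(32000 + seed)
        n = int(rng.integers(5, 9))
        labels = [f"t{i}" for i in range(n)]
        _, dist = random_binary_tree(rng, labels)
        d = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels[i + 1 :], start=i + 1):
                noise = 1.0 + 0.05 * rng.standard_normal()
                d[i, j] = d[j, i] = dist[frozenset((a, b))] * max(noise, 0.5)
        mine = neighbor_joining(DistanceMatrix(d, ids=labels))
        ref = skbio_nj(DistanceMatrix(d, ids=labels))
        ref_tree = read_newick(str(ref))
        assert tree_splits(mine) == tree_splits(ref_tree)


class TestBootstrap:
    def test_congruent_block_gets_full_support(self, rng):
        block, true_splits = congruent_block(rng)
        tree = bootstrap_support(block, 100, rng_seed=5)
        supports = {
            node.annotations.get_value("support")
            for node in tree.preorder_node_iter()
            if node.annotations.get_value("support") is not None
        }
        assert supports == {100}
        assert tree_splits(tree) == true_splits

    def test_single_replicate_supports_are_zero_or_hundred(self, rng):
        block, _ = congruent_block(rng, n_copies=4)
        tree = bootstrap_support(block, 1, rng_seed=9)
        supports = [
            node.annotations.get_value("support")
            for node in tree.preorder_node_iter()
            if node.annotations.get_value("support") is not None
        ]
        assert supports and set(supports) <= {0, 100}

    def test_fixed_seed_reproduces_support_vector(self, rng):
        sim_rows = tuple(
            (f"t{i}", "".join(rng.choice(list("ACDEFG"), size=40))) for i in range(8)
        )
        block = AlignedBlock(sim_rows)

        def vector(seed):
            tree = bootstrap_support(block, 100, rng_seed=seed)
            return sorted(
                (tuple(sorted(s)), node.annotations.get_value("support"))
                for node in tree.preorder_node_iter()
                if node.annotations.get_value("support") is not None
                for s in [
                    {lf.taxon.label for lf in node.leaf_iter()}
                ]
            )

        assert vector(17) == vector(17)

    def test_low_support_marked_below_threshold(self, rng):
        sim_rows = tuple(
            (f"t{i}", "".join(rng.choice(list("ACDEFGHIKL"), size=25)))
            for i in range(8)
        )
        tree = bootstrap_support(AlignedBlock(sim_rows), 50, rng_seed=2)
        marks = [
            (node.annotations.get_value("support"), node.annotations.get_value("below_threshold"))
            for node in tree.preorder_node_iter()
            if node.annotations.get_value("support") is not None
        ]
        assert marks
        for support, below in marks:
            assert below == (support < 50)

    def test_incomparable_replicates_are_redrawn(self):
        rows = (
            ("a", "AC--------"),
            ("b", "-CDE------"),
            ("c", "ACDEFGHIKL"),
        )
        tree = bootstrap_support(AlignedBlock(rows), 30, rng_seed=1)
        assert tree.annotations.get_value("n_redrawn") >= 1

    def test_support_in_unit_range_and_more_signal_never_hurts(self, rng):
        # grow the number of congruent columns; true-split support can only go up
        last_min = -1
        for copies in (2, 6, 20):
            block, true_splits = congruent_block(
                np.random.default_rng(77), n_copies=copies
            )
            tree = bootstrap_support(block, 60, rng_seed=13)
            supports = []
            leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
            anchor = min(leaves)
            for node in tree.preorder_node_iter():
                s = node.annotations.get_value("support")
                if s is None:
                    continue
                assert 0 <= s <= 100
                below = {lf.taxon.label for lf in node.leaf_iter()}
                side = frozenset(leaves - below) if anchor in below else frozenset(below)
                if side in true_splits:
                    supports.append(s)
            assert supports
            assert min(supports) >= last_min
            last_min = min(supports)


class TestRooting:
    @staticmethod
    def _quartet():
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        return neighbor_joining(DistanceMatrix(d, ids=list("ABCD")))

    def test_single_outgroup_roots_on_its_pendant_edge(self):
        rooted = root_on_outgroup(self._quartet(), {"A"})
        assert rooted.is_rooted
        children = rooted.seed_node.child_nodes()
        labels = {c.taxon.label if c.taxon else None for c in children}
        assert "A" in labels
        ingroup = next(c for c in children if c.taxon is None or c.taxon.label != "A")
        assert {lf.taxon.label for lf in ingroup.leaf_iter()} == {"B", "C", "D"}

    def test_root_splits_edge_length_equally(self):
        tree = self._quartet()
        pendant = next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label == "A"
        ).edge.length
        rooted = root_on_outgroup(tree, {"A"})
        child_lengths = sorted(
            c.edge.length for c in rooted.seed_node.child_nodes()
        )
        assert child_lengths[0] == pytest.approx(pendant / 2)

    def test_monophyletic_pair_outgroup(self):
        rooted = root_on_outgroup(self._quartet(), {"C", "D"})
        sides = [
            {lf.taxon.label for lf in c.leaf_iter()}
            for c in rooted.seed_node.child_nodes()
        ]
        assert {"C", "D"} in sides
        assert rooted.annotations.get_value("warnings") is None

    def test_non_monophyletic_outgroup_warns(self):
        rooted = root_on_outgroup(self._quartet(), {"A", "C"})
        assert rooted.annotations.get_value("warnings") == NON_MONOPHYLETIC_OUTGROUP

    def test_unknown_taxon_is_error(self):
        with pytest.raises(ValueError, match="unknown"):
            root_on_outgroup(self._quartet(), {"Z"})

    def test_outgroup_covering_all_leaves_is_error(self):
        with pytest.raises(ValueError):
            root_on_outgroup(self._quartet(), set("ABCD"))


class TestNewick:
    def test_three_leaf_star_format(self):
        dm = DistanceMatrix([[0, 2, 2], [2, 0, 2], [2, 2, 0]], ids=list("ABC"))
        tree = neighbor_joining(dm)
        buf = io.StringIO()
        write_newick(tree, buf)
        assert buf.getvalue() == "(A:1.000000,B:1.000000,C:1.000000);\n"

    def test_support_appears_as_internal_node_label(self, rng):
        block, _ = congruent_block(rng, n_copies=10)
        tree = bootstrap_support(block, 20, rng_seed=3)
        buf = io.StringIO()
        write_newick(tree, buf)
        assert ")100:" in buf.getvalue()

    def test_write_then_parse_roundtrip(self, rng):
        block, _ = congruent_block(rng, n_copies=10)
        tree = bootstrap_support(block, 20, rng_seed=3)
        buf = io.StringIO()
        write_newick(tree, buf)
        back = read_newick(buf.getvalue())
        assert tree_splits(back) == tree_splits(tree)
        orig, reread = edge_lengths_by_split(tree), edge_lengths_by_split(back)
        for split in orig:
            assert reread[split] == pytest.approx(orig[split], abs=1e-6)
        supports = sorted(
            n.label for n in back.preorder_node_iter() if n.label and not n.is_leaf()
        )
        expected = sorted(
            n.label
            for n in tree.preorder_node_iter()
            if n.label and not n.is_leaf()
        )
        assert supports == expected


class TestExtractDomainAlignment:
    @staticmethod
    def _call(seq_id, category, hits):
        return ArchitectureCall(seq_id, category, tuple(hits), frozenset())

    def test_span_arithmetic_on_gapless_rows(self, rng):
        n_cols = 200
        rows = tuple(
            (f"t{i}", "".join(rng.choice(list("ACDEFGHIKL"), size=n_cols)))
            for i in range(4)
        )
        calls = [
            self._call(
                f"t{i}",
                Category.CRF_CLADE_B,
                [
                    DomainHit(f"t{i}", DomainKind.CRF_CORE, 10, 50, 0.0),
                    DomainHit(f"t{i}", DomainKind.AP2, 110, 175, 0.0),
                ],
            )
            for i in range(4)
        ]
        out = extract_domain_alignment(AlignedBlock(rows), calls)
        assert out.n_cols == 105  # 40 core + 65 AP2 columns
        assert out.rows[0][1] == rows[0][1][10:50] + rows[0][1][110:175]

    def test_non_crf_rows_are_excluded(self, rng):
        rows = (("crf", "ACDEFGHIKL"), ("erf", "ACDEFGHIKL"))
        calls = [
            self._call(
                "crf",
                Category.CRF_CLADE_B,
                [
                    DomainHit("crf", DomainKind.CRF_CORE, 0, 3, 0.0),
                    DomainHit("crf", DomainKind.AP2, 5, 9, 0.0),
                ],
            ),
            self._call("erf", Category.ERF_NON_CRF, []),
        ]
        out = extract_domain_alignment(AlignedBlock(rows), calls)
        assert out.ids == ("crf",)

    def test_gap_aware_coordinate_lift(self):
        # residues of "crf": ACDEF (cols 0,2,3,5,6); hit [1,4) -> cols 2,3,5
        rows = (("crf", "A-CD-EF"), ("other", "AGCDGEF"))
        calls = [
            self._call(
                "crf",
                Category.CRF_CLADE_B,
                [
                    DomainHit("crf", DomainKind.CRF_CORE, 1, 4, 0.0),
                    DomainHit("crf", DomainKind.AP2, 4, 5, 0.0),
                ],
            ),
            self._call(
                "other",
                Category.CRF_CLADE_B,
                [
                    DomainHit("other", DomainKind.CRF_CORE, 1, 4, 0.0),
                    DomainHit("other", DomainKind.AP2, 4, 5, 0.0),
                ],
            ),
        ]
        out = extract_domain_alignment(AlignedBlock(rows), calls)
        # union of columns: crf lifts [1,4)->{2,3,5}, [4,5)->{6};
        # other lifts [1,4)->{1,2,3}, [4,5)->{4}
        assert out.row("crf") == "-CD-EF"
        assert out.row("other") == "GCDGEF"

    def test_missing_sequence_is_error(self):
        calls = [
            self._call(
                "ghost",
                Category.CRF_CLADE_A,
                [DomainHit("ghost", DomainKind.CRF_CORE, 0, 2, 0.0)],
            )
        ]
        with pytest.raises(ValueError, match="ghost"):
            extract_domain_alignment(AlignedBlock((("x", "AC"),)), calls)

    def test_hit_beyond_row_residues_is_error(self):
        rows = (("crf", "A--C"),)
        calls = [
            self._call(
                "crf",
                Category.CRF_CLADE_B,
                [DomainHit("crf", DomainKind.CRF_CORE, 0, 3, 0.0)],
            )
        ]
        with pytest.raises(ValueError, match="exceeds"):
            extract_domain_alignment(AlignedBlock(rows), calls)
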