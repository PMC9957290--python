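"""Domain excision, midpoint/outgroup rooting, iTOL annotation export."""

import numpy as np
import pytest

from ibparch import tree_tools as tt
from ibparch.model import DomainHit, LeafAnnotation


def hit(protein, start, end, acc="pfam11999"):
    return DomainHit(protein_id=protein, pfam_acc=acc, env_start=start,
                     env_end=end, bit_score=100.0, i_evalue=1e-20)


class TestExciseDomains:
    def test_slice_arithmetic(self):
        seqs = {"p1": "M" * 300}
        recs = tt.excise_domains(seqs, [hit("p1", 10, 210)])
        assert recs == [("p1/10-210", "M" * 201)]

    def test_multi_copy_protein_yields_two_records(self):
        seqs = {"p1": "A" * 500}
        recs = tt.excise_domains(seqs, [hit("p1", 10, 200), hit("p1", 250, 450)])
        assert [r[0] for r in recs] == ["p1/10-200", "p1/250-450"]

    def test_envelope_beyond_sequence_is_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            tt.excise_domains({"p1": "A" * 300}, [hit("p1", 200, 301)])

    def test_non_target_hits_skipped(self):
        recs = tt.excise_domains({"p1": "A" * 300}, [hit("p1", 1, 100, acc="pfam16130")])
        assert recs == []


def random_tree(rng, n_leaves):
    """Random binary tree with uniform branch lengths, as newick text."""
    nodes = [f"L{i}:{rng.uniform(0.05, 2.0):.6f}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.05, 2.0):.6f}")
    return nodes[0].rsplit(":", 1)[0] + ";"


class TestMidpointRooting:
    def test_three_leaf_worked_example(self):
        # longest path B-C has length 5; midpoint is 2.5 from each tip,
        # i.e. on C's branch, 0.5 away from the internal node
        tree = tt.load_tree("(A:1,(B:2,C:3):0.0);")
        tt.root_tree(tree, mode="midpoint")
        depths = {}
        for child in tree.seed_node.child_nodes():
            for leaf in child.leaf_iter():
                pass
            labels = sorted(l.taxon.label for l in child.leaf_iter())
            depths[tuple(labels)] = child.edge.length
        assert depths[("C",)] == pytest.approx(2.5)
        assert tt.root_balance(tree) <= 1e-9

    def test_midpoint_idempotent(self):
        tree = tt.load_tree("(A:1,(B:2,C:3):0.5);")
        tt.root_tree(tree, mode="midpoint")
        before = tree.as_string(schema="newick")
        tt.root_tree(tree, mode="midpoint")
        assert tree.as_string(schema="newick") == before

    def test_balance_and_distance_preservation_random_trees(self):
        """Midpoint rooting balances the two root-adjacent depths to 1e-9
        and never changes any leaf-to-leaf path length."""
        rng = np.random.default_rng(17)
        for _ in range(30):
            nwk = random_tree(rng, int(rng.integers(4, 25)))
            t0 = tt.load_tree(nwk)
            before = tt.leaf_distance_matrix(t0)
            total_before = t0.length()
            tt.root_tree(t0, mode="midpoint")
            assert tt.root_balance(t0) <= 1e-9
            after = tt.leaf_distance_matrix(t0)
            assert after.keys() == before.keys()
            for k in before:
                assert after[k] == pytest.approx(before[k], abs=1e-9)
            assert t0.length() == pytest.approx(total_before, abs=1e-9)


class TestOutgroupRooting:
    def _tree_with_clade(self, rng, n_in=20, n_out=5):
        ingroup = random_tree(rng, n_in)[:-1]  # strip ';'
        out_leaves = [f"O{i}:{rng.uniform(0.1, 1.0):.4f}" for i in range(n_out)]
        og = out_leaves[0]
        for leaf in out_leaves[1:]:
            og = f"({og},{leaf}):{rng.uniform(0.1, 1.0):.4f}"
        return f"({ingroup}:0.7,{og});", [f"O{i}" for i in range(n_out)]

    def test_root_edge_subtends_exactly_the_outgroup(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            nwk, outgroup = self._tree_with_clade(rng)
            tree = tt.load_tree(nwk)
            tt.root_tree(tree, outgroup, min_leaves_for_outgroup=2, mode="outgroup")
            children = tree.seed_node.child_nodes()
            leaf_sets = [
                {l.taxon.label for l in ch.leaf_iter()} for ch in children
            ]
            assert set(outgroup) in leaf_sets

    def test_distances_preserved_by_outgroup_rooting(self):
        rng = np.random.default_rng(29)
        nwk, outgroup = self._tree_with_clade(rng, n_in=12, n_out=4)
        t0 = tt.load_tree(nwk)
        before = tt.leaf_distance_matrix(t0)
        total = t0.length()
        tt.root_tree(t0, outgroup, min_leaves_for_outgroup=2, mode="outgroup")
        after = tt.leaf_distance_matrix(t0)
        for k in before:
            assert after[k] == pytest.approx(before[k], abs=1e-9)
        assert t0.length() == pytest.approx(total, abs=1e-9)

    def test_missing_outgroup_leaves_error_lists_ids(self):
        tree = tt.load_tree("(A:1,(B:2,C:3):0.5);")
        with pytest.raises(ValueError, match="ZZ"):
            tt.root_tree(tree, ["ZZ", "B"], min_leaves_for_outgroup=2, mode="outgroup")

    def test_auto_mode_small_tree_falls_back_to_midpoint(self):
        tree = tt.load_tree("(A:1,(B:2,C:3):0.0);")
        tt.root_tree(tree, ["B"], min_leaves_for_outgroup=60, mode="auto")
        assert tt.root_balance(tree) <= 1e-9  # midpoint rule applied


class TestItolExport:
    def _annotations(self):
        return [
            LeafAnnotation("A", environment="interior_ice", arch_class="single",
                           localization_class="sp_only", phylum="Bacteroidetes",
                           order="Flavobacteriales", abundance_rpkm=12.5),
            LeafAnnotation("B", environment="epipelagic", arch_class="double",
                           localization_class="none", phylum="Gammaproteobacteria",
                           order=None, abundance_rpkm=0.5),
        ]

    def test_strip_files_and_colors(self, tmp_path):
        tree = tt.load_tree("(A:1,B:2);")
        paths = tt.export_itol_rings(tree, self._annotations(), tmp_path)
        env = paths["environment"].read_text()
        assert "DATASET_COLORSTRIP" in env
        assert f"A\t{tt.ENVIRONMENT_COLORS['interior_ice']}" in env
        assert f"B\t{tt.ENVIRONMENT_COLORS['epipelagic']}" in env

    def test_missing_order_gets_unknown_white(self, tmp_path):
        tree = tt.load_tree("(A:1,B:2);")
        paths = tt.export_itol_rings(tree, self._annotations(), tmp_path)
        lines = paths["order"].read_text().splitlines()
        b_line = next(l for l in lines if l.startswith("B\t"))
        assert tt.UNKNOWN_COLOR in b_line and "unknown" in b_line

    def test_abundance_bar_passthrough(self, tmp_path):
        tree = tt.load_tree("(A:1,B:2);")
        paths = tt.export_itol_rings(tree, self._annotations(), tmp_path)
        bar = paths["abundance"].read_text()
        assert "A\t12.5" in bar and "B\t0.5" in bar

    def test_duplicate_leaf_ids_error(self, tmp_path):
        tree = tt.load_tree("(A:1,B:2);")
        anns = self._annotations() + [LeafAnnotation("A")]
        with pytest.raises(ValueError, match="duplicate"):
            tt.export_itol_rings(tree, anns, tmp_path)
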