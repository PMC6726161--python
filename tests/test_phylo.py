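"""MSA, distances, neighbor joining, bootstrap, subfamily grouping."""

import numpy as np
import pytest

from genefam import phylo
from genefam.phylo import (
    DistanceMatrix, MultipleAlignment, TreeNode, assign_subfamilies,
    bootstrap_support, msa_proteins, nj_tree, protein_distance,
    tree_path_distances, tree_splits,
)


def random_additive_tree(n, rng):
    """Random unrooted binary tree with positive branch lengths."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.05, 1.0)))
             for i in range(3)]
    root = TreeNode(children=nodes)
    leaves = nodes[:]
    for i in range(3, n):
        leaf = leaves[int(rng.integers(0, len(leaves)))]
        parent = next(nd for nd in root.postorder() if leaf in nd.children)
        new_leaf = TreeNode(name=f"t{i}", length=float(rng.uniform(0.05, 1.0)))
        mid = TreeNode(length=leaf.length / 2, children=[leaf, new_leaf])
        leaf.length /= 2
        parent.children[parent.children.index(leaf)] = mid
        leaves.append(new_leaf)
    return root


class TestMsa:
    def test_identical_pair_gapless(self):
        msa = msa_proteins({"a": "MKVLST", "b": "MKVLST"})
        assert msa.rows == ["MKVLST", "MKVLST"]

    def test_removing_gaps_recovers_inputs(self):
        seqs = {"a": "MKVLSTAGRN", "b": "MKVSTAGR", "c": "MKVLSTGRND"}
        msa = msa_proteins(seqs)
        for i, name in enumerate(msa.ids):
            assert msa.ungapped(i) == seqs[name]

    def test_column_count_at_least_longest(self):
        seqs = {"a": "MKVLSTAGRN", "b": "MKV", "c": "MKVLST"}
        msa = msa_proteins(seqs)
        assert msa.n_columns >= 10

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            msa_proteins({})


class TestDistances:
    def test_identical_rows_zero(self):
        msa = MultipleAlignment(["a", "b"], ["MKVL", "MKVL"])
        dm = protein_distance(msa, model="p")
        assert dm.matrix[0, 1] == 0.0

    def test_p_distance_arithmetic(self):
        msa = MultipleAlignment(["a", "b"], ["MKVLSTAGRN", "MKVLSTAGRC"])
        dm = protein_distance(msa, model="p")
        assert dm.matrix[0, 1] == pytest.approx(0.1)

    def test_poisson_saturation_flagged(self):
        msa = MultipleAlignment(["a", "b"], ["MKVL", "ACDE"])
        dm = protein_distance(msa, model="poisson")
        assert np.isinf(dm.matrix[0, 1])

    def test_pairwise_deletion(self):
        msa = MultipleAlignment(["a", "b"], ["MK-L", "MKV-"])
        dm = protein_distance(msa, model="p")
        assert dm.matrix[0, 1] == 0.0  # only 2 shared columns, both equal

    def test_no_shared_columns_rejected(self):
        msa = MultipleAlignment(["a", "b"], ["MK--", "--VL"])
        with pytest.raises(ValueError):
            protein_distance(msa)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        m = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], m))
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths == {"a": 2.0, "b": 3.0, "c": 7.0}

    @pytest.mark.parametrize("n", [5, 6, 8])
    def test_additive_matrix_recovery(self, n):
        rng = np.random.default_rng(n)
        for rep in range(5):
            true = random_additive_tree(n, rng)
            dm = tree_path_distances(true)
            est = nj_tree(dm)
            assert set(tree_splits(est)) == set(tree_splits(true))
            err = np.abs(tree_path_distances(est).matrix - dm.matrix).max()
            assert err < 1e-9

    def test_identical_rows_are_siblings(self):
        m = np.array([
            [0, 0.0, 0.8, 0.9],
            [0.0, 0, 0.8, 0.9],
            [0.8, 0.8, 0, 0.3],
            [0.9, 0.9, 0.3, 0],
        ])
        tree = nj_tree(DistanceMatrix(list("abcd"), m))
        assert frozenset("ab") in tree_splits(tree)

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(list("abc"), m))

    def test_leaf_set_preserved(self):
        rng = np.random.default_rng(0)
        true = random_additive_tree(7, rng)
        est = nj_tree(tree_path_distances(true))
        assert est.leaf_names() == true.leaf_names()


def _two_clade_msa():
    """Two clearly separated clades of 3 similar sequences each."""
    base_a = "MKVLSTAGRNDEQPWYFHCIMKVLSTAGRN"
    base_b = "GGEDNSTRPLVVAKIHWYQCGGEDNSTRPL"
    seqs = {}
    for i, (base, sub) in enumerate([(base_a, "A"), (base_a, "S"), (base_a, "T"),
                                     (base_b, "G"), (base_b, "N"), (base_b, "D")]):
        name = f"{'ab'[i >= 3]}{i}"
        seqs[name] = base[:i + 3] + sub + base[i + 4:]
    return seqs


class TestBootstrap:
    def test_strong_clade_high_support(self):
        msa = msa_proteins(_two_clade_msa())
        tree = bootstrap_support(msa, n_reps=100, seed=1, model="p")
        splits = tree_splits(tree)
        key = frozenset(["a0", "a1", "a2"])
        key = min(key, tree.leaf_names() - key,
                  key=lambda s: (len(s), tuple(sorted(s))))
        assert key in splits
        assert splits[key].support >= 95

    def test_zero_reps_zero_support(self):
        msa = msa_proteins(_two_clade_msa())
        tree = bootstrap_support(msa, n_reps=0, seed=1, model="p")
        assert all(node.support == 0 for node in tree_splits(tree).values())

    def test_reproducible_given_seed(self):
        msa = msa_proteins(_two_clade_msa())
        t1 = bootstrap_support(msa, n_reps=50, seed=9, model="p")
        t2 = bootstrap_support(msa, n_reps=50, seed=9, model="p")
        assert t1.to_newick() == t2.to_newick()


class TestSubfamilies:
    def _supported_tree(self, supports):
        a = TreeNode(children=[TreeNode(name="a1", length=0.1),
                               TreeNode(name="a2", length=0.1)],
                     length=0.5, support=supports[0])
        b = TreeNode(children=[TreeNode(name="b1", length=0.1),
                               TreeNode(name="b2", length=0.1)],
                     length=0.5, support=supports[1])
        return TreeNode(children=[a, b, TreeNode(name="out", length=0.9)])

    def test_low_support_all_ungrouped(self):
        tree = self._supported_tree([10, 20])
        labels = assign_subfamilies(tree, support_threshold=50)
        assert set(labels.values()) == {"ungrouped"}

    def test_two_supported_clades(self):
        tree = self._supported_tree([99, 100])
        labels = assign_subfamilies(tree, support_threshold=50)
        groups = {v for v in labels.values() if v != "ungrouped"}
        assert len(groups) == 2
        assert labels["a1"] == labels["a2"]
        assert labels["b1"] == labels["b2"]
        assert labels["out"] == "ungrouped"

    def test_six_planted_clades_recovered(self):
        """Star radiation of six clades from one ancestor -> six groups."""
        rng = np.random.default_rng(3)
        aa = "ADEFGIKLMNPQRSTVWY"

        def mutate(s, k):
            s = list(s)
            for i in rng.choice(len(s), size=k, replace=False):
                s[int(i)] = aa[int(rng.integers(0, 18))]
            return "".join(s)

        ancestor = "".join(aa[i] for i in rng.integers(0, 18, 120))
        seqs = {}
        for c in range(6):
            clade_anc = mutate(ancestor, 30)
            for m in range(3):
                seqs[f"c{c}_{m}"] = mutate(clade_anc, 2)
        msa = msa_proteins(seqs)
        tree = bootstrap_support(msa, n_reps=100, seed=4, model="p")
        labels = assign_subfamilies(tree, support_threshold=50)
        groups = {}
        for leaf, lab in labels.items():
            groups.setdefault(lab, set()).add(leaf)
        clades = [set(f"c{c}_{m}" for m in range(3)) for c in range(6)]
        assert sum(any(g == clade for g in groups.values())
                   for clade in clades) == 6


class TestNewick:
    def test_round_trip_via_dendropy(self):
        import dendropy

        rng = np.random.default_rng(5)
        tree = random_additive_tree(6, rng)
        for node in tree_splits(tree).values():
            node.support = 87
        nwk = tree.to_newick()
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == tree.leaf_names()
        pdm = parsed.phylogenetic_distance_matrix()
        ours = tree_path_distances(tree)
        taxa = {t.label: t for t in parsed.taxon_namespace}
        for i, a in enumerate(ours.ids):
            for j, b in enumerate(ours.ids):
                if i < j:
                    assert pdm.patristic_distance(taxa[a], taxa[b]) == \
                        pytest.approx(ours.matrix[i, j], abs=1e-9)
        labels = {int(n.label) for n in parsed.preorder_internal_node_iter()
                  if n.label and n.label.isdigit()}
        assert labels == {87}
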