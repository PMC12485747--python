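import dendropy
import numpy as np
import pytest

from invstruct.trees import (
    CalibrationPoint,
    calibrate_node_ages,
    nj_tree,
    rf_distance,
    rf_matrix,
    rf_mds,
    rf_normalized,
    select_ld_windows,
)

# ---------------------------------------------------------------------------
# generators and independent oracles
# ---------------------------------------------------------------------------


def random_binary_newick(rng, labels):
    """Random binary topology over ``labels`` with unit branch lengths."""
    nodes = [f"{l}:1" for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):1"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0][: nodes[0].rfind(":")] + ";"


def brute_force_bipartitions(tree):
    """Oracle: nontrivial splits as canonicalized frozen leaf sets."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(all_leaves)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or len(side) > len(all_leaves) - 2:
            continue
        splits.add(side if ref not in side else all_leaves - side)
    return splits


def brute_force_rf(t1, t2):
    return len(brute_force_bipartitions(t1) ^ brute_force_bipartitions(t2))


def _parse_pair(nwk1, nwk2):
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tns)
    return t1, t2


def random_clock_tree(rng, n):
    """Ultrametric tree built by successive merges; returns true ages."""
    tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    nodes = [dendropy.Node(taxon=tns.get_taxon(f"t{i}")) for i in range(n)]
    ages = {id(nd): 0.0 for nd in nodes}
    h = 0.0
    while len(nodes) > 1:
        h += float(rng.uniform(0.5, 2.0))
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = h - ages[id(child)]
        ages[id(parent)] = h
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = True
    return tree, ages


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = nj_tree(D, ["a", "b", "c"])
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 8])
    def test_exact_recovery_of_additive_trees(self, n_leaves):
        """On additive input NJ reproduces topology and path distances."""
        rng = np.random.default_rng(n_leaves)
        for rep in range(10):
            labels = [f"t{i}" for i in range(n_leaves)]
            nwk = random_binary_newick(rng, labels)
            tns = dendropy.TaxonNamespace()
            source = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns)
            for edge in source.preorder_edge_iter():
                if edge.head_node.parent_node is not None:
                    edge.length = float(rng.uniform(0.5, 3.0))
            pdm = source.phylogenetic_distance_matrix()
            taxa = [tns.get_taxon(l) for l in labels]
            D = np.array([[pdm.distance(a, b) for b in taxa] for a in taxa])
            result = nj_tree(D, labels)
            # path distances reproduce the input matrix exactly
            pdm_out = result.phylogenetic_distance_matrix()
            taxa_out = [result.taxon_namespace.get_taxon(l) for l in labels]
            D_out = np.array(
                [[pdm_out.distance(a, b) for b in taxa_out] for a in taxa_out]
            )
            assert np.allclose(D, D_out, atol=1e-9)
            # and the unrooted topology matches the generating tree
            relabeled = dendropy.Tree.get(
                data=result.as_string(schema="newick"),
                schema="newick", taxon_namespace=tns,
            )
            assert brute_force_rf(source, relabeled) == 0

    def test_equidistant_tie_break_is_deterministic(self):
        """All-equal distances: the lowest-index pair joins first."""
        D = np.ones((4, 4)) - np.eye(4)
        labels = ["t0", "t1", "t2", "t3"]
        for _ in range(3):
            tree = nj_tree(D, labels)
            splits = brute_force_bipartitions(tree)
            # the (t0,t1) join induces the split t0t1|t2t3, whose
            # canonical form is the side without the reference leaf t0
            assert splits == {frozenset({"t2", "t3"})}

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(D, ["a", "b", "c"])

    def test_agrees_with_skbio_on_random_matrices(self):
        """Independent cross-check against scikit-bio's NJ."""
        import io

        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(99)
        for rep in range(5):
            n = 6
            x = rng.uniform(1.0, 10.0, size=(n, n))
            D = (x + x.T) / 2.0
            np.fill_diagonal(D, 0.0)
            labels = [f"t{i}" for i in range(n)]
            mine = nj_tree(D, labels)
            theirs = skbio_nj(DistanceMatrix(D, labels))
            buf = io.StringIO()
            theirs.write(buf)
            t1, t2 = _parse_pair(mine.as_string(schema="newick"), buf.getvalue())
            assert brute_force_rf(t1, t2) == 0


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------


class TestRobinsonFoulds:
    def test_identical_trees_distance_zero(self):
        t1, t2 = _parse_pair("((A,B),(C,D),E);", "((A,B),(C,D),E);")
        assert rf_distance(t1, t2) == 0

    def test_hand_computed_five_leaf_case(self):
        """((A,B),(C,D),E) vs ((A,C),(B,D),E): symmetric difference 4."""
        t1, t2 = _parse_pair("((A,B),(C,D),E);", "((A,C),(B,D),E);")
        assert rf_distance(t1, t2) == 4
        assert rf_normalized(t1, t2) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_pairs(self):
        """200 random pairs with <= 7 leaves against the bipartition oracle."""
        rng = np.random.default_rng(7)
        for rep in range(200):
            n = int(rng.integers(4, 8))
            labels = [f"t{i}" for i in range(n)]
            t1, t2 = _parse_pair(
                random_binary_newick(rng, labels),
                random_binary_newick(rng, labels),
            )
            assert rf_distance(t1, t2) == brute_force_rf(t1, t2)

    def test_maximum_attained_on_disjoint_splits(self):
        """Binary n-leaf trees max out at 2(n-3); caterpillar orderings
        with interleaved leaves reach it."""
        t1, t2 = _parse_pair(
            "(((((A,B),C),D),E),F);", "(((((A,D),F),B),E),C);"
        )
        assert rf_distance(t1, t2) == 2 * (6 - 3)
        assert rf_distance(t1, t2) == brute_force_rf(t1, t2)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(17)
        for rep in range(40):
            n = int(rng.integers(4, 8))
            labels = [f"t{i}" for i in range(n)]
            tns = dendropy.TaxonNamespace()
            ts = [
                dendropy.Tree.get(
                    data=random_binary_newick(rng, labels),
                    schema="newick", taxon_namespace=tns,
                )
                for _ in range(3)
            ]
            d01, d10 = rf_distance(ts[0], ts[1]), rf_distance(ts[1], ts[0])
            d02, d12 = rf_distance(ts[0], ts[2]), rf_distance(ts[1], ts[2])
            assert d01 == d10  # symmetry
            assert rf_distance(ts[0], ts[0]) == 0  # identity
            assert d01 <= d02 + d12  # triangle inequality

    def test_mismatched_leaf_sets_rejected(self):
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data="((A,B),(C,E));", schema="newick",
                               taxon_namespace=tns)
        with pytest.raises(ValueError, match="leaf sets"):
            rf_distance(t1, t2)

    def test_polytomies_allowed(self):
        t1, t2 = _parse_pair("((A,B),C,D,E);", "((A,B),(C,D),E);")
        # {A,B} shared; {C,D} only in t2
        assert rf_distance(t1, t2) == 1


# ---------------------------------------------------------------------------
# LD window selection
# ---------------------------------------------------------------------------


class TestSelectWindows:
    def test_argmin_selection(self):
        rf = np.array(
            [
                [0, 5, 6, 4],
                [5, 0, 7, 6],
                [6, 7, 0, 2],
                [4, 6, 2, 0],
            ],
            dtype=float,
        )
        assert select_ld_windows(rf, k=1) == [2, 3]

    def test_tie_breaks_toward_genomically_nearer_window(self):
        rf = np.zeros((4, 4))
        rf[0, 3] = rf[3, 0] = 2.0
        rf[1, 3] = rf[3, 1] = 2.0
        rf[2, 3] = rf[3, 2] = 2.0
        # all tie at 2: window 2 is nearest the anchor (index 3)
        assert select_ld_windows(rf, k=1) == [2, 3]

    def test_k_covering_everything_returns_all(self):
        rf = np.random.default_rng(0).uniform(1, 5, (5, 5))
        rf = (rf + rf.T) / 2
        np.fill_diagonal(rf, 0)
        assert select_ld_windows(rf, k=4) == [0, 1, 2, 3, 4]
        assert select_ld_windows(rf, k=99) == [0, 1, 2, 3, 4]

    def test_windowed_tree_pipeline(self):
        """Windows sharing the anchor's topology are selected over others."""
        rng = np.random.default_rng(23)
        labels = [f"t{i}" for i in range(6)]
        tns = dendropy.TaxonNamespace()
        base = random_binary_newick(rng, labels)
        other = random_binary_newick(rng, labels)
        trees = [
            dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns)
            for nwk in (other, other, base, other, base)
        ]
        rf = rf_matrix(trees)
        assert select_ld_windows(rf, k=1) == [2, 4]


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


class TestCalibration:
    def test_linear_scaling_from_calibration_node(self):
        """Calibration node at half the root height, age 18.13 -> root 36.26."""
        tree = dendropy.Tree.get(
            data="(((A:1,B:1):1,C:2):2,(D:2,E:2):2);", schema="newick"
        )
        tree.is_rooted = True
        calib = CalibrationPoint(frozenset({"A", "B", "C"}), 18.13)
        ages = calibrate_node_ages(tree, calib)
        mrca = tree.mrca(taxa=[t for t in tree.taxon_namespace
                               if t.label in {"A", "B", "C"}])
        assert mrca.age == pytest.approx(18.13)
        assert tree.seed_node.age == pytest.approx(36.26)

    def test_scale_invariance(self):
        nwk = "(((A:1,B:1):1,C:2):2,(D:2,E:2):2);"
        ages = []
        for factor in (1.0, 2.0):
            tree = dendropy.Tree.get(data=nwk, schema="newick")
            tree.is_rooted = True
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    edge.length *= factor
            calibrate_node_ages(
                tree, CalibrationPoint(frozenset({"D", "E"}), 7.74)
            )
            ages.append(sorted(nd.age for nd in tree.preorder_node_iter()))
        assert np.allclose(ages[0], ages[1])

    def test_clock_tree_round_trip(self):
        """Generated ultrametric trees: all ages recovered to 1e-9."""
        rng = np.random.default_rng(31)
        for rep in range(10):
            tree, true_ages = random_clock_tree(rng, int(rng.integers(5, 12)))
            internal = [
                nd for nd in tree.preorder_node_iter()
                if not nd.is_leaf() and true_ages[id(nd)] > 0
            ]
            cal_node = internal[int(rng.integers(len(internal)))]
            clade = frozenset(l.taxon.label for l in cal_node.leaf_iter())
            calibrate_node_ages(
                tree, CalibrationPoint(clade, true_ages[id(cal_node)])
            )
            for nd in tree.preorder_node_iter():
                assert nd.age == pytest.approx(true_ages[id(nd)], rel=1e-9, abs=1e-12)

    def test_zero_height_calibration_is_hard_error(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
        tree.is_rooted = True
        with pytest.raises(ValueError, match="zero height"):
            calibrate_node_ages(tree, CalibrationPoint(frozenset({"A"}), 5.0))

    def test_missing_clade_rejected(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
        with pytest.raises(ValueError, match="missing"):
            calibrate_node_ages(tree, CalibrationPoint(frozenset({"A", "Z"}), 5.0))


def test_rf_mds_embeds_distances():
    """Classical MDS of a small RF matrix approximates the distances."""
    rf = np.array(
        [[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float
    )
    coords = rf_mds(rf, k=2)
    assert coords.shape == (3, 2)
    d01 = np.linalg.norm(coords[0] - coords[1])
    d02 = np.linalg.norm(coords[0] - coords[2])
    assert d01 < d02
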