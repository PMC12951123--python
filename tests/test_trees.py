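import numpy as np
import pytest

from phylodecline.trees import (
    NewickParseError,
    TreeValidationError,
    parse_newick,
    patristic_distances,
    perturb_topology,
    phylo_eigenvectors,
    vcv,
    write_newick,
)
from phylodecline.synthetic import gen_tree


class TestParseWrite:
    def test_three_tip_depths(self, three_tip_tree):
        assert sorted(three_tip_tree.tips) == ["A", "B", "C"]
        depths = three_tip_tree.tip_depths()
        assert depths == {"A": 2.0, "B": 2.0, "C": 2.0}

    def test_single_tip_accepted_with_warning(self):
        with pytest.warns(UserWarning, match="single-tip"):
            t = parse_newick("(A:1);")
        assert t.tips == ["A"]

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeValidationError, match="duplicate"):
            parse_newick("((A:1,A:1):1,C:2);")

    def test_malformed_reports_position(self):
        with pytest.raises(NewickParseError, match="column"):
            parse_newick("((A:1,B:1:1,C:2);")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_roundtrip_preserves_branch_lengths(self, seed):
        tree = gen_tree(30, seed=seed)
        again = parse_newick(write_newick(tree))
        lengths = sorted(
            e.length for e in tree._tree.preorder_edge_iter()
            if e.length is not None
        )
        lengths2 = sorted(
            e.length for e in again._tree.preorder_edge_iter()
            if e.length is not None
        )
        assert len(lengths) == len(lengths2)
        np.testing.assert_allclose(lengths, lengths2, atol=1e-9)
        m1, m2 = vcv(tree), vcv(again)
        order = [m2.labels.index(t) for t in m1.labels]
        np.testing.assert_allclose(
            m1.matrix, m2.matrix[np.ix_(order, order)], atol=1e-7
        )


def _vcv_oracle(tree):
    """Shared-edge enumeration over root-to-tip paths (independent of vcv)."""
    dt = tree._tree
    paths = {}
    for leaf in dt.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append((id(node), node.edge.length))
            node = node.parent_node
        paths[leaf.taxon.label] = edges
    labels = sorted(paths)
    n = len(labels)
    mat = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            ids_b = {e for e, _ in paths[b]}
            mat[i, j] = sum(l for e, l in paths[a] if e in ids_b)
    return labels, mat


class TestVcv:
    def test_analytic_three_tip(self, three_tip_tree):
        pc = vcv(three_tip_tree)
        m = pc.matrix
        i = {lab: k for k, lab in enumerate(pc.labels)}
        assert m[i["A"], i["A"]] == m[i["B"], i["B"]] == m[i["C"], i["C"]] == 2.0
        assert m[i["A"], i["B"]] == 1.0
        assert m[i["A"], i["C"]] == m[i["B"], i["C"]] == 0.0

    def test_star_tree_is_scaled_identity(self):
        t = parse_newick("(A:1.5,B:1.5,C:1.5,D:1.5);")
        np.testing.assert_allclose(vcv(t).matrix, 1.5 * np.eye(4), atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_shared_edge_oracle(self, seed):
        tree = gen_tree(np.random.default_rng(seed).integers(4, 13), seed=seed)
        labels, expected = _vcv_oracle(tree)
        pc = vcv(tree)
        order = [pc.labels.index(l) for l in labels]
        np.testing.assert_allclose(
            pc.matrix[np.ix_(order, order)], expected, atol=1e-9
        )

    def test_ultrametric_diagonal_equals_height(self, bd_tree_50):
        pc = vcv(bd_tree_50)
        np.testing.assert_allclose(
            np.diag(pc.matrix), bd_tree_50.height(), atol=1e-9
        )

    def test_psd_and_symmetric(self, bd_tree_50):
        m = vcv(bd_tree_50).matrix
        np.testing.assert_allclose(m, m.T)
        assert np.linalg.eigvalsh(m).min() >= -1e-8

    def test_correlation_scaling_unit_diagonal(self, bd_tree_50):
        a = vcv(bd_tree_50).correlation().matrix
        np.testing.assert_allclose(np.diag(a), 1.0, atol=1e-9)

    def test_fewer_than_two_tips_rejected(self):
        with pytest.warns(UserWarning):
            t = parse_newick("(A:1);")
        with pytest.raises(TreeValidationError):
            vcv(t)


class TestEigenvectors:
    def test_two_tip_antisymmetric(self):
        t = parse_newick("(A:1,B:1);")
        _, vecs = phylo_eigenvectors(t, 1)
        assert vecs[0, 0] == pytest.approx(-vecs[1, 0], abs=1e-12)
        assert vecs[0, 0] > 0  # sign convention

    def test_balanced_four_tip_separates_cherries(self, balanced_four_tip_tree):
        labels, vecs = phylo_eigenvectors(balanced_four_tip_tree, 1)
        v = dict(zip(labels, vecs[:, 0]))
        assert np.sign(v["A"]) == np.sign(v["B"]) != np.sign(v["C"])
        np.testing.assert_allclose(abs(vecs[:, 0]), abs(vecs[0, 0]), atol=1e-9)

    def test_matches_bruteforce_eigendecomposition(self, balanced_four_tip_tree):
        labels, dist = patristic_distances(balanced_four_tip_tree)
        n = len(labels)
        j = np.eye(n) - np.ones((n, n)) / n
        g = -0.5 * j @ (dist**2) @ j
        w, u = np.linalg.eigh(g)
        top = u[:, np.argmax(w)]
        _, vecs = phylo_eigenvectors(balanced_four_tip_tree, 1)
        got = vecs[:, 0]
        if np.sign(top[np.nonzero(top)[0][0]]) != np.sign(got[np.nonzero(got)[0][0]]):
            top = -top
        np.testing.assert_allclose(got, top, atol=1e-9)

    def test_eigenvalues_nonincreasing(self, bd_tree_50):
        labels, dist = patristic_distances(bd_tree_50)
        n = len(labels)
        j = np.eye(n) - np.ones((n, n)) / n
        w = np.linalg.eigvalsh(-0.5 * j @ (dist**2) @ j)[::-1]
        assert (np.diff(w) <= 1e-9).all()

    def test_k_too_large_rejected(self, three_tip_tree):
        with pytest.raises(ValueError):
            phylo_eigenvectors(three_tip_tree, 3)


class TestPerturbTopology:
    def test_requires_positive_n(self, bd_tree_50):
        with pytest.raises(ValueError):
            perturb_topology(bd_tree_50, 0, seed=1)

    def test_tip_set_preserved(self, bd_tree_50):
        for t in perturb_topology(bd_tree_50, 5, seed=3):
            assert sorted(t.tips) == sorted(bd_tree_50.tips)

    def test_deterministic_given_seed(self, bd_tree_50):
        a = perturb_topology(bd_tree_50, 4, seed=9)
        b = perturb_topology(bd_tree_50, 4, seed=9)
        assert [write_newick(t) for t in a] == [write_newick(t) for t in b]

    def test_identity_with_zero_moves_and_jitter(self, bd_tree_50):
        (t,) = perturb_topology(
            bd_tree_50, 1, seed=1, n_moves=0, jitter_sigma=0.0
        )
        assert write_newick(t) == write_newick(bd_tree_50)


def test_prune_to_subset(bd_tree_50):
    keep = bd_tree_50.tips[:10]
    sub = bd_tree_50.prune_to(keep)
    assert sorted(sub.tips) == sorted(keep)
    full = vcv(bd_tree_50)
    part = vcv(sub)
    fi = {l: k for k, l in enumerate(full.labels)}
    pi = {l: k for k, l in enumerate(part.labels)}
    for a in keep:
        for b in keep:
            assert full.matrix[fi[a], fi[b]] == pytest.approx(
                part.matrix[pi[a], pi[b]], abs=1e-9
            )
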