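"""Tree input/output and tree-derived algebra.

Everything downstream consumes trees through this module: the phylogenetic
covariance matrix (shared root-to-tip path lengths) and its correlation-scaled
form A, patristic distances, phylogenetic eigenvectors for imputation, pruning,
and the seeded nearest-neighbor-interchange (NNI) perturbation used to build a
synthetic topology ensemble standing in for a Bayesian posterior sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np


class NewickParseError(ValueError):
    """Malformed Newick input; carries the reader's line/column position."""


class TreeValidationError(ValueError):
    """Structurally valid Newick that violates a tree invariant."""


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths, wrapping a dendropy tree.

    Tip labels must be unique and nonempty; branch lengths nonnegative.
    Multifurcations are allowed (consensus trees contain polytomies).
    """

    _tree: dendropy.Tree = field(repr=False)

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- depths ------------------------------------------------------------

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip."""
        self._tree.calc_node_root_distances(return_leaf_distances_only=False)
        return {
            leaf.taxon.label: leaf.root_distance
            for leaf in self._tree.leaf_node_iter()
        }

    def height(self) -> float:
        return max(self.tip_depths().values())

    def rescale_height(self, target: float = 1.0) -> "PhyloTree":
        """Return a copy with all branch lengths scaled so height == target."""
        h = self.height()
        if h <= 0:
            raise TreeValidationError("tree has zero height; cannot rescale")
        out = self.copy()
        for edge in out._tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= target / h
        return out

    def prune_to(self, labels) -> "PhyloTree":
        """Subtree restricted to ``labels`` (suppressing unifurcations)."""
        keep = set(labels)
        missing = keep - set(self.tips)
        if missing:
            raise TreeValidationError(
                f"labels not in tree: {sorted(missing)}"
            )
        out = self.copy()
        taxa = [t for t in out._tree.taxon_namespace if t.label in keep]
        out._tree.retain_taxa(taxa)
        return out

    def to_newick(self) -> str:
        return write_newick(self)

    def _validate(self):
        tips = self.tips
        if any(not t for t in tips):
            raise TreeValidationError("empty tip label")
        seen, dups = set(), set()
        for t in tips:
            if t in seen:
                dups.add(t)
            seen.add(t)
        if dups:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dups)}")
        for edge in self._tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length {edge.length}"
                )
        for node in self._tree.preorder_node_iter():
            if not node.is_leaf() and len(node.child_nodes()) == 1:
                # tolerated only at the root of a single-tip tree
                if node.parent_node is not None or self.n_tips > 1:
                    raise TreeValidationError(
                        "internal node with a single child"
                    )


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`.

    Raises :class:`NewickParseError` (with the reader's position) on malformed
    input and :class:`TreeValidationError` on duplicate or empty tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        msg = str(exc)
        if "Duplicate taxon" in msg or "Multiple occurrences" in msg:
            raise TreeValidationError(f"duplicate tip labels: {msg}") from exc
        raise NewickParseError(msg) from exc
    out = PhyloTree(tree)
    out._validate()
    if out.n_tips == 1:
        warnings.warn("single-tip degenerate tree", stacklevel=2)
    return out


def write_newick(tree: PhyloTree) -> str:
    """Serialize with 9 significant digits on branch lengths."""
    return tree._tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".9g",
    ).strip() + "\n"


# ---------------------------------------------------------------------------
# Covariance / distance algebra
# ---------------------------------------------------------------------------


@dataclass
class PhyloCov:
    """Shared root-to-tip path lengths between tips.

    ``matrix[i, j]`` is the summed branch length common to the root-to-tip
    paths of tips ``labels[i]`` and ``labels[j]``; the diagonal holds tip
    depths. Symmetric positive semi-definite by construction.
    """

    labels: list[str]
    matrix: np.ndarray

    def correlation(self) -> "PhyloCov":
        """Scale by the maximum diagonal entry (unit diagonal when ultrametric).

        This scaled matrix is the A used as the random-effect correlation
        structure, making the phylogenetic variance parameter comparable
        across trees of different heights.
        """
        scale = float(np.max(np.diag(self.matrix)))
        if scale <= 0:
            raise TreeValidationError("zero-depth tree has no covariance scale")
        return PhyloCov(list(self.labels), self.matrix / scale)


def vcv(tree: PhyloTree) -> PhyloCov:
    """Phylogenetic variance-covariance matrix of a tree.

    Entry (i, j) is the depth of the most recent common ancestor of tips i
    and j; entry (i, i) is the depth of tip i.
    """
    if tree.n_tips < 2:
        raise TreeValidationError("vcv needs >= 2 tips")
    dtree = tree._tree
    for edge in dtree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise TreeValidationError("missing branch length")
    labels = tree.tips
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    cov = np.zeros((n, n))

    # depth of every node from the root; a stem edge above the root is
    # shared by all tips and excluded by convention
    depth: dict[int, float] = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + (
                node.edge.length or 0.0
            )

    def tipset(node) -> list[int]:
        if node.is_leaf():
            i = index[node.taxon.label]
            cov[i, i] = depth[id(node)]
            return [i]
        groups = [tipset(c) for c in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        cov[i, j] = cov[j, i] = d
        return [i for g in groups for i in g]

    tipset(dtree.seed_node)
    return PhyloCov(labels, cov)


def patristic_distances(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Pairwise path-length distances between tips.

    d(i, j) = depth_i + depth_j - 2 * depth(MRCA(i, j)).
    """
    pc = vcv(tree)
    v = np.diag(pc.matrix)
    dist = v[:, None] + v[None, :] - 2.0 * pc.matrix
    np.fill_diagonal(dist, 0.0)
    return pc.labels, dist


def phylo_eigenvectors(tree: PhyloTree, k: int) -> tuple[list[str], np.ndarray]:
    """First k eigenvectors of the double-centered squared patristic distances.

    Classical-MDS-style decomposition of G = -1/2 * J D^2 J (J the centering
    matrix); columns are unit-norm eigenvectors ordered by descending
    eigenvalue, with the sign fixed so each column's first nonzero entry is
    positive. These serve as covariates encoding phylogenetic position.
    """
    labels, dist = patristic_distances(tree)
    n = len(labels)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    d2 = dist**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    g = (g + g.T) / 2.0
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    vecs = eigvec[:, order[:k]]
    for col in range(vecs.shape[1]):
        v = vecs[:, col]
        nz = np.nonzero(np.abs(v) > 1e-12)[0]
        if nz.size and v[nz[0]] < 0:
            vecs[:, col] = -v
    return labels, vecs


# ---------------------------------------------------------------------------
# Topology ensemble
# ---------------------------------------------------------------------------


def _nni_once(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    """One rooted NNI: swap a child of an internal node with its 'uncle'."""
    candidates = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        siblings = [c for c in node.parent_node.child_nodes() if c is not node]
        if siblings and node.child_nodes():
            candidates.append((node, siblings))
    if not candidates:
        return
    node, siblings = candidates[int(rng.integers(len(candidates)))]
    uncle = siblings[int(rng.integers(len(siblings)))]
    child = node.child_nodes()[int(rng.integers(len(node.child_nodes())))]
    parent = node.parent_node
    parent.remove_child(uncle)
    node.remove_child(child)
    node.add_child(uncle)
    parent.add_child(child)


def perturb_topology(
    tree: PhyloTree,
    n: int,
    seed: int,
    n_moves: int = 2,
    jitter_sigma: float = 0.05,
) -> list[PhyloTree]:
    """Generate ``n`` perturbed trees as a synthetic topology ensemble.

    Each tree results from ``n_moves`` seeded NNI moves followed by
    multiplicative lognormal branch-length jitter with log-scale standard
    deviation ``jitter_sigma``. The tip set is preserved; the output is
    reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if tree.n_tips < 4:
        raise TreeValidationError("perturbation needs >= 4 tips")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        t = tree.copy()
        for _ in range(n_moves):
            _nni_once(t._tree, rng)
        if jitter_sigma > 0:
            for edge in t._tree.preorder_edge_iter():
                if edge.length is not None and edge.head_node.parent_node is not None:
                    edge.length *= float(
                        np.exp(rng.normal(0.0, jitter_sigma))
                    )
        out.append(t)
    return out
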