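"""Phylogenetic numerics shared by the niche-evolution stages.

A rooted binary ultrametric tree is stored in flat arrays (parent pointers,
branch lengths, postorder) for fast traversal; Newick parsing and writing go
through dendropy.  On top of it sit the three primitives everything else
uses: the phylogenetic covariance matrix C (shared root-to-MRCA path length
per tip pair), maximum-likelihood ancestral states under Brownian motion
(the GLS solution, obtained from the weighted graph Laplacian), and BM tip
simulation.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np


class Tree:
    """Rooted binary tree with branch lengths, tips indexed ``0..n_tips-1``.

    Internal nodes are indexed ``n_tips..2*n_tips-2``; the root is the last
    index.  ``heights`` measures time from the root; for an ultrametric tree
    the age of a node is ``depth - height``.
    """

    def __init__(
        self,
        parent: np.ndarray,
        lengths: np.ndarray,
        tip_names: Sequence[str],
    ) -> None:
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.tip_names = list(tip_names)
        self.n_tips = len(self.tip_names)
        self.n_nodes = len(self.parent)
        self.root = self.n_nodes - 1
        if self.n_nodes != 2 * self.n_tips - 1:
            raise ValueError("tree must be binary and rooted")
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes - 1):
            self.children[self.parent[i]].append(i)
        for i in range(self.n_tips, self.n_nodes):
            if len(self.children[i]) != 2:
                raise ValueError(f"internal node {i} has {len(self.children[i])} children")
        # preorder from root; postorder is its reverse
        self.preorder = np.empty(self.n_nodes, dtype=int)
        stack, k = [self.root], 0
        while stack:
            node = stack.pop()
            self.preorder[k] = node
            k += 1
            stack.extend(self.children[node])
        self.postorder = self.preorder[::-1].copy()
        self.heights = np.zeros(self.n_nodes)
        for node in self.preorder[1:]:
            self.heights[node] = self.heights[self.parent[node]] + self.lengths[node]
        self.depth = float(self.heights[: self.n_tips].max())

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree) -> "Tree":
        nodes = list(dt.postorder_node_iter())
        tips = [n for n in nodes if n.is_leaf()]
        internals = [n for n in nodes if not n.is_leaf()]
        index = {}
        for i, n in enumerate(tips):
            index[id(n)] = i
        for j, n in enumerate(internals):
            index[id(n)] = len(tips) + j
        n_nodes = len(nodes)
        parent = np.full(n_nodes, -1, dtype=int)
        lengths = np.zeros(n_nodes)
        for n in nodes:
            i = index[id(n)]
            if n.parent_node is not None:
                parent[i] = index[id(n.parent_node)]
                lengths[i] = float(n.edge.length or 0.0)
        names = [t.taxon.label if t.taxon else f"tip{i}" for i, t in enumerate(tips)]
        return cls(parent, lengths, names)

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if node < self.n_tips:
                label = self.tip_names[node].replace(" ", "_")
            else:
                a, b = self.children[node]
                label = f"({render(a)},{render(b)})"
            if node == self.root:
                return label + ";"
            return f"{label}:{float(self.lengths[node])!r}"

        return render(self.root)

    # -- geometry ----------------------------------------------------------

    def node_ages(self) -> np.ndarray:
        """Age (time before present) of every node; tips ~ 0 for ultrametric."""
        return self.depth - self.heights

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        tip_h = self.heights[: self.n_tips]
        return bool(np.ptp(tip_h) <= rtol * max(self.depth, 1e-300))

    def tip_sets(self) -> list[set[int]]:
        """Per-node set of descendant tip indices."""
        sets: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for node in self.postorder:
            if node < self.n_tips:
                sets[node] = {node}
            else:
                for c in self.children[node]:
                    sets[node] |= sets[c]
        return sets

    def mrca_matrix(self) -> np.ndarray:
        """(n_tips × n_tips) matrix of MRCA node indices (diagonal = tip)."""
        M = np.zeros((self.n_tips, self.n_tips), dtype=int)
        np.fill_diagonal(M, np.arange(self.n_tips))
        sets = self.tip_sets()
        for node in range(self.n_tips, self.n_nodes):
            a, b = self.children[node]
            for i in sets[a]:
                for j in sets[b]:
                    M[i, j] = M[j, i] = node
        return M

    def rescale(self, depth: float = 1.0) -> "Tree":
        """Return a copy with branch lengths scaled to the given depth."""
        f = depth / self.depth
        return Tree(self.parent.copy(), self.lengths * f, self.tip_names)

    def prune(self, keep: Sequence[str]) -> "Tree":
        """Restrict the tree to a subset of tips, collapsing unary nodes."""
        missing = set(keep) - set(self.tip_names)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise ValueError("need at least 2 tips after pruning")
        dt = dendropy.Tree.get(data=self.to_newick(), schema="newick")
        dt.retain_taxa_with_labels([n.replace("_", " ") for n in keep])
        dt.suppress_unifurcations()
        pruned = Tree.from_dendropy(dt)
        pruned.tip_names = [n.replace(" ", "_") for n in pruned.tip_names]
        return pruned

    def tip_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.tip_names)}
        return np.array([lookup[n] for n in names], dtype=int)


def phylo_covariance(tree: Tree) -> np.ndarray:
    """Brownian-motion covariance matrix C: C[i, j] = root-to-MRCA(i, j) path.

    Diagonal equals each tip's height (the tree depth when ultrametric);
    symmetric positive definite for positive branch lengths.
    """
    M = tree.mrca_matrix()
    C = tree.heights[M]
    np.fill_diagonal(C, tree.heights[: tree.n_tips])
    return C


def bm_ancestral_states(tree: Tree, tip_values: np.ndarray) -> np.ndarray:
    """ML ancestral states under Brownian motion.

    The BM log-likelihood is maximized by the internal-node values minimizing
    sum over edges of (Δx)²/length — a weighted graph-Laplacian linear system
    with the tips held fixed.  Returns one value per internal node, ordered
    ``n_tips..2*n_tips-2`` (root last); the root entry equals the GLS root
    state (1ᵀC⁻¹1)⁻¹ 1ᵀC⁻¹ x.
    """
    x = np.asarray(tip_values, dtype=float)
    if x.shape[-1] != tree.n_tips:
        raise ValueError("need one value per tip")
    if not np.all(np.isfinite(x)):
        raise ValueError("tip values must be finite")
    if np.any(tree.lengths[: tree.n_nodes - 1] <= 0):
        raise ValueError("zero or negative branch length: GLS system singular")
    n_int = tree.n_tips - 1
    w = np.zeros(tree.n_nodes)
    w[:-1] = 1.0 / tree.lengths[:-1]  # root carries no edge
    L = np.zeros((n_int, n_int))
    b_coef = np.zeros((n_int, tree.n_tips))
    for child in range(tree.n_nodes - 1):
        par = tree.parent[child]
        pi = par - tree.n_tips
        L[pi, pi] += w[child]
        if child < tree.n_tips:
            b_coef[pi, child] += w[child]
        else:
            ci = child - tree.n_tips
            L[ci, ci] += w[child]
            L[pi, ci] -= w[child]
            L[ci, pi] -= w[child]
    # solve for all trait columns at once
    sol = np.linalg.solve(L, b_coef @ np.atleast_2d(x).T)
    return sol[:, 0] if np.ndim(tip_values) == 1 else sol.T


def bm_simulate(
    tree: Tree,
    root_value: float,
    rate: float,
    n_sims: int = 1,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate tip values under Brownian motion; returns (n_sims, n_tips).

    Each edge contributes an independent Normal(0, rate·length) increment.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(rng)
    values = np.empty((n_sims, tree.n_nodes))
    values[:, tree.root] = root_value
    sd = np.sqrt(rate * np.maximum(tree.lengths, 0.0))
    incr = rng.standard_normal((n_sims, tree.n_nodes)) * sd
    for node in tree.preorder[1:]:
        values[:, node] = values[:, tree.parent[node]] + incr[:, node]
    return values[:, : tree.n_tips]


def bm_rate_estimate(tree: Tree, tip_values: np.ndarray, reml: bool = True) -> float:
    """Brownian rate σ² from tip data by (RE)ML phylogenetic variance.

    σ² = (x − â)ᵀ C⁻¹ (x − â) / (n − 1)   (REML; ML divides by n),
    with â the GLS root estimate.
    """
    x = np.asarray(tip_values, dtype=float)
    C = phylo_covariance(tree)
    Ci = np.linalg.inv(C)
    one = np.ones(tree.n_tips)
    a = (one @ Ci @ x) / (one @ Ci @ one)
    r = x - a
    dof = tree.n_tips - 1 if reml else tree.n_tips
    return float(r @ Ci @ r) / dof
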