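"""Rooted phylogenies with branch lengths.

The :class:`Phylogeny` container backs every phylogenetic computation in the
package: Brownian-motion variance-covariance matrices for trait simulation and
mixed models, patristic distances for Ornstein-Uhlenbeck covariances, and
node-level covariances for ancestral state reconstruction.  Trees are stored
as parent-pointer arrays; newick interchange goes through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny", "NewickParseError"]


class NewickParseError(ValueError):
    """Malformed newick input (carries the character offset when known)."""


@dataclass
class Phylogeny:
    """A rooted tree with nonnegative branch lengths.

    Parameters
    ----------
    parent
        ``parent[i]`` is the parent node index of node ``i``; the root has
        parent ``-1``.  Nodes are indexed ``0 .. n_nodes-1`` in no particular
        order.
    edge_length
        ``edge_length[i]`` is the length of the branch above node ``i``
        (ignored for the root).
    labels
        Per-node labels; every leaf must carry a unique label.
    """

    parent: np.ndarray
    edge_length: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.edge_length = np.asarray(self.edge_length, dtype=float)
        n = self.parent.size
        if self.edge_length.size != n or len(self.labels) != n:
            raise ValueError("parent, edge_length and labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        self._root = int(roots[0])
        if np.any(self.edge_length[np.arange(n) != self._root] < 0):
            raise ValueError("negative branch length")
        # connectivity / acyclicity: every node must reach the root
        for i in range(n):
            seen = 0
            j = i
            while self.parent[j] >= 0:
                j = self.parent[j]
                seen += 1
                if seen > n:
                    raise ValueError("cycle detected in parent pointers")
        tips = self.tip_indices()
        tip_labels = [self.labels[i] for i in tips]
        if any(lab is None or lab == "" for lab in tip_labels):
            raise ValueError("every tip must be labelled")
        if len(set(tip_labels)) != len(tip_labels):
            raise ValueError("duplicate tip labels")

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return self._root

    def children(self) -> list:
        kids: list = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        return kids

    def tip_indices(self) -> np.ndarray:
        has_child = np.zeros(self.n_nodes, dtype=bool)
        has_child[self.parent[self.parent >= 0]] = True
        return np.flatnonzero(~has_child)

    @property
    def n_tips(self) -> int:
        return self.tip_indices().size

    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_indices()]

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length for every node (root depth 0)."""
        depth = np.zeros(self.n_nodes)
        for i in self.postorder()[::-1]:  # preorder
            p = self.parent[i]
            if p >= 0:
                depth[i] = depth[p] + self.edge_length[i]
        return depth

    @property
    def height(self) -> float:
        """Maximum root-to-tip depth."""
        return float(self.node_depths()[self.tip_indices()].max())

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        d = self.node_depths()[self.tip_indices()]
        return bool(d.max() - d.min() <= tol)

    def postorder(self) -> list:
        """Node indices, children always before parents."""
        kids = self.children()
        order: list = []
        stack = [self._root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(kids[v])
        return order[::-1]

    # -------------------------------------------------------------- covariance
    def mrca_depth_matrix(self) -> np.ndarray:
        """Depth of the most recent common ancestor for every node pair.

        ``M[u, v]`` is the root-to-MRCA(u, v) path length; the diagonal is the
        node's own depth.  This is the Brownian-motion covariance kernel (up
        to the rate sigma^2) evaluated at all nodes, internal ones included.
        """
        n = self.n_nodes
        depth = self.node_depths()
        kids = self.children()
        M = np.zeros((n, n))
        desc: list = [None] * n
        for v in self.postorder():
            groups = [desc[c] for c in kids[v]]
            mine = [v]
            for g in groups:
                mine.extend(g)
            # pairs in different child subtrees (and v itself vs descendants)
            # have v as their MRCA
            covered = [np.array([v])] + [np.asarray(g) for g in groups]
            for a in range(len(covered)):
                for b in range(a + 1, len(covered)):
                    M[np.ix_(covered[a], covered[b])] = depth[v]
                    M[np.ix_(covered[b], covered[a])] = depth[v]
            M[v, v] = depth[v]
            desc[v] = mine
        return M

    def vcv(self, normalize: str = "raw") -> tuple:
        """Brownian-motion covariance among tips.

        ``C[i, j]`` is the shared root-to-MRCA path length of tips i and j;
        the diagonal holds root-to-tip depths.  ``normalize="unit_height"``
        divides by the tree height so the (ultrametric) diagonal is 1.

        Returns ``(C, tip_labels)`` with rows ordered like ``tip_labels()``.
        """
        if normalize not in ("raw", "unit_height"):
            raise ValueError(f"unknown normalize mode {normalize!r}")
        tips = self.tip_indices()
        C = self.mrca_depth_matrix()[np.ix_(tips, tips)].copy()
        np.fill_diagonal(C, self.node_depths()[tips])
        if normalize == "unit_height":
            C /= self.height
        return C, [self.labels[i] for i in tips]

    def patristic_matrix(self) -> np.ndarray:
        """Tip-to-tip path-length (patristic distance) matrix."""
        tips = self.tip_indices()
        depth = self.node_depths()[tips]
        A = self.mrca_depth_matrix()[np.ix_(tips, tips)]
        D = depth[:, None] + depth[None, :] - 2.0 * A
        np.fill_diagonal(D, 0.0)
        return D

    # ------------------------------------------------------------------ newick
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        """Parse a newick string (branch lengths required, labels on tips)."""
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=False
            )
        except Exception as exc:  # dendropy raises several error classes
            offset = getattr(exc, "column", None)
            loc = f" near character {offset}" if offset is not None else ""
            raise NewickParseError(f"malformed newick{loc}: {exc}") from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "Phylogeny":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        length = np.zeros(len(nodes))
        labels: list = [None] * len(nodes)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                length[i] = float(nd.edge.length or 0.0)
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label is not None:
                labels[i] = nd.label
        return cls(parent=parent, edge_length=length, labels=labels)

    def to_newick(self, node_comments: dict | None = None) -> str:
        """Render newick; ``node_comments`` maps node index -> text emitted
        as a ``[&...]`` comment after the node's label."""
        kids = self.children()
        comments = node_comments or {}

        def render(v: int) -> str:
            lab = (self.labels[v] or "").replace(" ", "_")
            if v in comments:
                lab += f"[&{comments[v]}]"
            if not kids[v]:
                return f"{lab}:{self.edge_length[v]:.12g}"
            inner = ",".join(render(c) for c in kids[v])
            if v == self._root:
                return f"({inner}){lab}"
            return f"({inner}){lab}:{self.edge_length[v]:.12g}"

        return render(self._root) + ";"

    # ------------------------------------------------------------------ misc
    def tip_index_of(self, labels: list) -> np.ndarray:
        """Map species labels to positions in the ``vcv`` tip ordering."""
        order = {lab: k for k, lab in enumerate(self.tip_labels())}
        try:
            return np.array([order[lab] for lab in labels], dtype=int)
        except KeyError as exc:
            raise KeyError(f"species {exc.args[0]!r} is not a tip of the tree")
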