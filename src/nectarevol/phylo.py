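"""Rooted time-calibrated phylogenies and Newick I/O.

The central container is :class:`Phylogeny`, an array-backed rooted tree
with branch lengths in millions of years (Ma).  Trees are read and written
through dendropy but all comparative-method computations (shared-depth
covariance, Hansen regime weights, Pagel λ transforms) operate on the
array representation directly.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny", "read_newick", "write_newick", "PhylogenyError"]


class PhylogenyError(ValueError):
    """Raised for malformed trees (parse failures, duplicate tips...)."""


class Phylogeny:
    """Rooted (typically ultrametric) phylogeny with branch lengths in Ma.

    Nodes are integers ``0 .. n_nodes-1``; tips come first (``0 .. n_tips-1``)
    in the order of ``tip_labels`` and the root is ``parent == -1``.

    Parameters
    ----------
    parent
        ``parent[v]`` is the parent node of ``v`` (``-1`` for the root).
    edge_length
        ``edge_length[v]`` is the length of the branch above ``v``
        (the root's entry is its stem length, usually 0).
    tip_labels
        Labels of nodes ``0 .. n_tips-1``.
    """

    def __init__(
        self,
        parent: Sequence[int],
        edge_length: Sequence[float],
        tip_labels: Sequence[str],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.tip_labels = list(tip_labels)
        self.n_nodes = len(self.parent)
        self.n_tips = len(self.tip_labels)
        if self.n_tips == 0:
            raise PhylogenyError("tree has no tips")
        if len(set(self.tip_labels)) != self.n_tips:
            raise PhylogenyError("duplicate tip labels")
        if any(not lbl for lbl in self.tip_labels):
            raise PhylogenyError("empty tip label")
        if np.any(self.edge_length < 0):
            raise PhylogenyError("negative branch length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise PhylogenyError(f"expected exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            p = int(self.parent[v])
            if p >= 0:
                self.children[p].append(v)
        for v in range(self.n_tips):
            if self.children[v]:
                raise PhylogenyError("tip node has children")
        self._depths: np.ndarray | None = None
        self._postorder: list[int] | None = None

    # ------------------------------------------------------------------
    # traversals and derived geometry
    # ------------------------------------------------------------------
    @property
    def postorder(self) -> list[int]:
        """Node ids in postorder (children before parents)."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            order.reverse()
            self._postorder = order
        return self._postorder

    @property
    def preorder(self) -> list[int]:
        return self.postorder[::-1]

    @property
    def depths(self) -> np.ndarray:
        """Distance from the root to every node (root depth 0)."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            for v in self.preorder:
                p = int(self.parent[v])
                if p >= 0:
                    d[v] = d[p] + self.edge_length[v]
            self._depths = d
        return self._depths

    @property
    def crown_age(self) -> float:
        """Maximum root-to-tip distance, in Ma."""
        return float(self.depths[: self.n_tips].max())

    def is_ultrametric(self, rel_tol: float = 1e-3) -> bool:
        """True if all root-to-tip paths agree with crown_age to ``rel_tol``."""
        t = self.crown_age
        if t == 0:
            return True
        dev = np.abs(self.depths[: self.n_tips] - t) / t
        return bool(dev.max() <= rel_tol)

    def tip_index(self, labels: Iterable[str] | None = None) -> dict[str, int]:
        idx = {lbl: i for i, lbl in enumerate(self.tip_labels)}
        if labels is not None:
            missing = [l for l in labels if l not in idx]
            if missing:
                raise PhylogenyError(f"labels not in tree: {missing}")
        return idx

    def shared_depth_matrix(self) -> np.ndarray:
        """Tip × tip matrix of MRCA depths (the BM covariance structure C).

        ``C[i, j]`` is the depth of the most recent common ancestor of tips
        i and j; ``C[i, i]`` is the root-to-tip distance of tip i.
        """
        n = self.n_tips
        C = np.zeros((n, n))
        below: list[np.ndarray | None] = [None] * self.n_nodes
        d = self.depths
        for v in self.postorder:
            if v < n:
                below[v] = np.array([v])
                C[v, v] = d[v]
            else:
                kids = [below[c] for c in self.children[v]]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        ia = kids[a]
                        ib = kids[b]
                        C[np.ix_(ia, ib)] = d[v]
                        C[np.ix_(ib, ia)] = d[v]
                below[v] = np.concatenate(kids)
                for c in self.children[v]:
                    below[c] = None  # free
        return C

    def mrca_matrix(self) -> np.ndarray:
        """Tip × tip matrix of MRCA node ids (diagonal: the tip itself)."""
        n = self.n_tips
        M = np.zeros((n, n), dtype=np.int64)
        below: list[np.ndarray | None] = [None] * self.n_nodes
        for v in self.postorder:
            if v < n:
                below[v] = np.array([v])
                M[v, v] = v
            else:
                kids = [below[c] for c in self.children[v]]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        M[np.ix_(kids[a], kids[b])] = v
                        M[np.ix_(kids[b], kids[a])] = v
                below[v] = np.concatenate(kids)
                for c in self.children[v]:
                    below[c] = None
        return M

    def lineage_edges(self, tip: int) -> list[int]:
        """Edges (as child-node ids) on the root→tip path, rootmost first."""
        path = []
        v = tip
        while v != self.root:
            path.append(v)
            v = int(self.parent[v])
        path.reverse()
        return path

    # ------------------------------------------------------------------
    # transforms / editing
    # ------------------------------------------------------------------
    def with_lambda(self, lam: float) -> "Phylogeny":
        """Pagel-λ tree transform: internal node depths scaled by λ.

        Tip depths are preserved, so shared path (off-diagonal covariance)
        scales by λ while total tip variance is unchanged.  λ=0 gives a
        star tree, λ=1 returns an identical tree.
        """
        if not 0.0 <= lam <= 1.0 + 1e-12:
            raise ValueError(f"lambda must lie in [0, 1], got {lam}")
        d = self.depths
        new_depth = d.copy()
        new_depth[self.n_tips :] = lam * d[self.n_tips :]
        new_len = np.zeros(self.n_nodes)
        for v in range(self.n_nodes):
            p = int(self.parent[v])
            if p >= 0:
                new_len[v] = new_depth[v] - new_depth[p]
        return Phylogeny(self.parent, new_len, self.tip_labels)

    def prune_to(self, keep: Sequence[str]) -> "Phylogeny":
        """Subtree restricted to the given tip labels (suppressing unifurcations)."""
        keep_set = set(keep)
        missing = keep_set - set(self.tip_labels)
        if missing:
            raise PhylogenyError(f"cannot keep absent tips: {sorted(missing)}")
        tree = self.to_dendropy()
        taxa = [t for t in tree.taxon_namespace if t.label in keep_set]
        tree.retain_taxa(taxa)
        # dendropy may leave a knuckle at the root; suppress it
        tree.suppress_unifurcations()
        return Phylogeny.from_dendropy(tree)

    # ------------------------------------------------------------------
    # dendropy bridge and Newick I/O
    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        labels = []
        for nd in tips:
            lbl = nd.taxon.label if nd.taxon is not None else nd.label
            if not lbl:
                raise PhylogenyError("tip without a label")
            labels.append(lbl)
        if len(set(labels)) != len(labels):
            raise PhylogenyError("duplicate tip labels")
        internal = [nd for nd in nodes if not nd.is_leaf()]
        index = {id(nd): i for i, nd in enumerate(tips)}
        index.update({id(nd): len(tips) + j for j, nd in enumerate(internal)})
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        elen = np.zeros(n)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise PhylogenyError(f"missing branch length above node {i}")
                if nd.edge.length < 0:
                    raise PhylogenyError("negative branch length")
                elen[i] = float(nd.edge.length)
            else:
                elen[i] = float(nd.edge.length or 0.0)
        return cls(parent, elen, labels)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace(self.tip_labels)
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = {self.root: tree.seed_node}
        tree.seed_node.edge.length = float(self.edge_length[self.root])
        for v in self.preorder:
            if v == self.root:
                continue
            nd = dendropy.Node()
            nd.edge.length = float(self.edge_length[v])
            nodes[int(self.parent[v])].add_child(nd)
            nodes[v] = nd
        for i, lbl in enumerate(self.tip_labels):
            nodes[i].taxon = taxa.get_taxon(lbl)
        return tree

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise PhylogenyError(f"Newick parse error: {exc}") from exc
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        tree = self.to_dendropy()
        out = io.StringIO()
        tree.write(
            file=out,
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".17g",
        )
        return out.getvalue().strip() + "\n"


def read_newick(source: str) -> Phylogeny:
    """Parse a Newick string (or read a path ending in .nwk/.tre/.newick)."""
    text = source
    if "(" not in source:  # treat as a path
        with open(source) as fh:
            text = fh.read()
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny, path: str | None = None) -> str:
    text = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
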