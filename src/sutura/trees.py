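"""Unrooted trees over taxon labels.

A minimal adjacency-based container tuned for parsimony scoring and
branch-swapping, where topologies are edited thousands of times per
search.  Newick reading and writing delegates to DendroPy; equality is by
bipartition set, the natural identity for unrooted topologies.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterable, List, Optional, Set, Tuple

import dendropy

__all__ = ["Tree"]


class Tree:
    """Unrooted tree: integer nodes, adjacency sets, labelled leaves."""

    def __init__(self) -> None:
        self.adj: Dict[int, Set[int]] = {}
        self.leaf_label: Dict[int, str] = {}
        self.lengths: Dict[frozenset, float] = {}
        self._next_id = 0

    # -- construction -------------------------------------------------

    def new_node(self, label: Optional[str] = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self.adj[nid] = set()
        if label is not None:
            self.leaf_label[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float = 1.0) -> None:
        self.adj[u].add(v)
        self.adj[v].add(u)
        self.lengths[frozenset((u, v))] = length

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self.lengths.pop(frozenset((u, v)), None)

    def remove_node(self, u: int) -> None:
        for v in list(self.adj[u]):
            self.remove_edge(u, v)
        del self.adj[u]
        self.leaf_label.pop(u, None)

    def edge_length(self, u: int, v: int) -> float:
        return self.lengths.get(frozenset((u, v)), 1.0)

    # -- inspection ---------------------------------------------------

    @property
    def leaves(self) -> List[int]:
        return sorted(self.leaf_label)

    @property
    def labels(self) -> List[str]:
        return sorted(self.leaf_label.values())

    def edges(self) -> List[Tuple[int, int]]:
        seen = set()
        out = []
        for u, nbrs in self.adj.items():
            for v in nbrs:
                key = frozenset((u, v))
                if key not in seen:
                    seen.add(key)
                    out.append((u, v))
        return sorted(out)

    def is_binary(self) -> bool:
        if len(self.leaf_label) < 3:
            return True
        return all(
            len(nbrs) == (1 if u in self.leaf_label else 3)
            for u, nbrs in self.adj.items()
        )

    def copy(self) -> "Tree":
        t = Tree()
        t.adj = {u: set(v) for u, v in self.adj.items()}
        t.leaf_label = dict(self.leaf_label)
        t.lengths = dict(self.lengths)
        t._next_id = self._next_id
        return t

    # -- traversal ----------------------------------------------------

    def postorder_edges(self, root: int) -> List[Tuple[int, int]]:
        """(child, parent) pairs in postorder when rooted at ``root``."""
        order = []
        stack = [(root, None)]
        visit = []
        while stack:
            node, parent = stack.pop()
            visit.append((node, parent))
            for nbr in self.adj[node]:
                if nbr != parent:
                    stack.append((nbr, node))
        for node, parent in reversed(visit):
            if parent is not None:
                order.append((node, parent))
        return order

    def component(self, start: int, blocked: Optional[Set[int]] = None) -> Set[int]:
        blocked = blocked or set()
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                if v not in seen and v not in blocked:
                    seen.add(v)
                    stack.append(v)
        return seen

    def bipartitions(self, nontrivial_only: bool = True) -> Set[frozenset]:
        """Each edge's split, encoded as the side not containing the
        alphabetically first leaf label (a rooting-free canonical form)."""
        if not self.leaf_label:
            return set()
        ref = min(self.leaf_label, key=self.leaf_label.get)
        out = set()
        for u, v in self.edges():
            side = self.component(u, blocked={v})
            labels_side = frozenset(
                self.leaf_label[n] for n in side if n in self.leaf_label
            )
            if ref in side:
                labels_side = frozenset(self.labels) - labels_side
            if nontrivial_only and (
                len(labels_side) < 2 or len(labels_side) > len(self.leaf_label) - 2
            ):
                continue
            out.add(labels_side)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        return (
            set(self.labels) == set(other.labels)
            and self.bipartitions() == other.bipartitions()
        )

    def __hash__(self) -> int:
        return hash((frozenset(self.labels), frozenset(self.bipartitions())))

    # -- edits --------------------------------------------------------

    def suppress_degree_two(self, node: int) -> None:
        if node in self.leaf_label or len(self.adj.get(node, ())) != 2:
            return
        a, b = sorted(self.adj[node])
        la = self.edge_length(node, a)
        lb = self.edge_length(node, b)
        self.remove_node(node)
        self.add_edge(a, b, la + lb)

    def prune_leaves(self, labels: Iterable[str]) -> "Tree":
        """Return a copy with the named leaves removed and degree-2 nodes
        suppressed."""
        labels = set(labels)
        missing = labels - set(self.leaf_label.values())
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        if len(self.leaf_label) - len(labels) < 3:
            raise ValueError("pruning would leave fewer than three leaves")
        t = self.copy()
        for node, label in list(t.leaf_label.items()):
            if label in labels:
                (nbr,) = t.adj[node]
                t.remove_node(node)
                t.suppress_degree_two(nbr)
        return t

    def restricted(self, labels: Iterable[str]) -> "Tree":
        """Induced subtree on ``labels`` (the complement is pruned)."""
        keep = set(labels)
        drop = [l for l in self.leaf_label.values() if l not in keep]
        return self.prune_leaves(drop)

    # -- path lengths -------------------------------------------------

    def leaf_path_lengths(self) -> Dict[frozenset, float]:
        """Sum of branch lengths between every pair of leaves."""
        out: Dict[frozenset, float] = {}
        for leaf in self.leaves:
            dist = {leaf: 0.0}
            stack = [leaf]
            while stack:
                u = stack.pop()
                for v in self.adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + self.edge_length(u, v)
                        stack.append(v)
            for other in self.leaves:
                if other > leaf:
                    out[frozenset((self.leaf_label[leaf],
                                   self.leaf_label[other]))] = dist[other]
        return out

    # -- Newick I/O (via DendroPy) ------------------------------------

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        ns = taxon_namespace or dendropy.TaxonNamespace(sorted(self.labels))
        dtree = dendropy.Tree(taxon_namespace=ns)
        if not self.leaf_label:
            return dtree
        if len(self.leaf_label) == 1:
            ((node, label),) = self.leaf_label.items()
            dtree.seed_node.taxon = ns.get_taxon(label)
            return dtree
        # root at an internal node if one exists, else at a leaf's neighbor
        root = next(
            (u for u in self.adj if u not in self.leaf_label), self.leaves[0]
        )
        dnodes = {root: dtree.seed_node}
        stack = [(root, None)]
        while stack:
            node, parent = stack.pop()
            for nbr in sorted(self.adj[node]):
                if nbr == parent:
                    continue
                child = dnodes[node].new_child(
                    edge_length=self.edge_length(node, nbr)
                )
                if nbr in self.leaf_label:
                    child.taxon = ns.require_taxon(self.leaf_label[nbr])
                dnodes[nbr] = child
                stack.append((nbr, node))
        return dtree

    def newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True
        ).strip()

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Tree":
        t = cls()
        mapping = {}
        for node in dtree.preorder_node_iter():
            label = node.taxon.label if node.taxon is not None else None
            nid = t.new_node(label if node.is_leaf() else None)
            mapping[node] = nid
            if node.parent_node is not None:
                length = node.edge.length if node.edge.length is not None else 1.0
                t.add_edge(mapping[node.parent_node], nid, length)
        # unroot: a rooted binary tree has a degree-2 seed node
        t.suppress_degree_two(mapping[dtree.seed_node])
        return t

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(dtree)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Tree with {len(self.leaf_label)} leaves>"
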