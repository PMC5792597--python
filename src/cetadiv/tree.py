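"""Rooted, branch-length phylogenies.

Newick parsing is delegated to dendropy; the parsed tree is converted to a
small immutable-ish node structure on which the comparative machinery
(pruning, shared-path covariance, patristic distances, independent
contrasts) operates directly.  Branch lengths are required — the
comparative methods are meaningless without them — unless the caller
explicitly asks for unit substitution.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .errors import TreeError, ValidationError

__all__ = ["Node", "PhyloTree", "read_newick"]


@dataclass
class Node:
    """One node of a rooted tree. ``length`` is the edge above the node."""

    label: Optional[str]
    length: float
    children: List["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(self.label, self.length, [c.copy() for c in self.children])


class PhyloTree:
    """A rooted tree with branch lengths and unique tip labels."""

    def __init__(self, root: Node):
        self.root = root
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, text: str, missing_lengths: str = "error") -> "PhyloTree":
        """Parse a Newick string.

        ``missing_lengths``: "error" (default) rejects any non-root edge
        without a length; "unit" substitutes 1.0.
        """
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=False)
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"Newick parse error: {exc}") from exc

        def convert(nd, is_root: bool) -> Node:
            length = nd.edge.length
            if length is None:
                if is_root:
                    length = 0.0
                elif missing_lengths == "unit":
                    length = 1.0
                else:
                    where = nd.taxon.label if nd.taxon else "an internal node"
                    raise TreeError(
                        f"missing branch length above {where}; pass "
                        f"missing_lengths='unit' to substitute unit lengths")
            length = float(length)
            if length < 0:
                raise TreeError(f"negative branch length {length}")
            label = nd.taxon.label if nd.taxon is not None else nd.label
            return Node(label, length, [convert(c, False) for c in nd.child_nodes()])

        return cls(convert(dtree.seed_node, True))

    @classmethod
    def read(cls, path, **kwargs) -> "PhyloTree":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick(fh.read(), **kwargs)

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            label = node.label or ""
            if node.is_leaf:
                return f"{label}:{node.length:.12g}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){label}:{node.length:.12g}"
        inner = ",".join(fmt(c) for c in self.root.children)
        label = self.root.label or ""
        return f"({inner}){label};"

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------- queries
    @property
    def tip_labels(self) -> List[str]:
        out: List[str] = []

        def rec(node: Node):
            if node.is_leaf:
                out.append(node.label)
            for c in node.children:
                rec(c)
        rec(self.root)
        return out

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def is_binary(self) -> bool:
        def rec(node: Node) -> bool:
            if node.is_leaf:
                return True
            return len(node.children) == 2 and all(rec(c) for c in node.children)
        return rec(self.root)

    def total_depth(self) -> float:
        """Maximum root-to-tip path length."""
        def rec(node: Node) -> float:
            if node.is_leaf:
                return node.length
            return node.length + max(rec(c) for c in node.children)
        return rec(self.root)

    # ------------------------------------------------------------ matrices
    def shared_path_matrix(self, order: Optional[Sequence[str]] = None
                           ) -> Tuple[List[str], np.ndarray]:
        """Brownian-motion covariance structure: shared root-to-MRCA path.

        Entry (i, j) is the summed length of the branches on the path from
        the root to the most recent common ancestor of tips i and j; the
        diagonal holds root-to-tip depths.
        """
        labels = self.tip_labels
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        C = np.zeros((n, n))

        def rec(node: Node, depth: float) -> List[int]:
            d = depth + node.length
            if node.is_leaf:
                i = idx[node.label]
                C[i, i] = d
                return [i]
            groups = [rec(c, d) for c in node.children]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            C[i, j] = C[j, i] = d
            return [i for g in groups for i in g]

        rec(self.root, 0.0)
        if order is not None:
            perm = [idx[l] for l in order]
            return list(order), C[np.ix_(perm, perm)]
        return labels, C

    def patristic_matrix(self, order: Optional[Sequence[str]] = None
                         ) -> Tuple[List[str], np.ndarray]:
        """All-pairs path-length (patristic) distances between tips."""
        labels, C = self.shared_path_matrix(order=order)
        depths = np.diag(C)
        D = depths[:, None] + depths[None, :] - 2.0 * C
        np.fill_diagonal(D, 0.0)
        return labels, D

    # ------------------------------------------------------ restructuring
    def prune(self, keep: Iterable[str]) -> "PhyloTree":
        """Restrict the tree to ``keep``, collapsing degree-2 nodes.

        Branch lengths of collapsed chains are summed, so every retained
        root-to-tip and tip-to-tip path length is preserved exactly.
        """
        keep = set(keep)
        unknown = keep - set(self.tip_labels)
        if unknown:
            raise TreeError(f"unknown tip labels in keep set: {sorted(unknown)}")
        if not keep:
            raise TreeError("keep set is empty")

        def rec(node: Node) -> Optional[Node]:
            if node.is_leaf:
                return Node(node.label, node.length) if node.label in keep else None
            kids = [k for k in (rec(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                child = kids[0]
                child.length += node.length
                return child
            return Node(node.label, node.length, kids)

        return PhyloTree(rec(self.root))

    def resolve_binary(self) -> "PhyloTree":
        """Deterministic binary resolution for contrast computation.

        Children are ordered lexicographically by the smallest tip label in
        their subtree; polytomies are folded left-to-right with zero-length
        internal branches.
        """
        def rec(node: Node) -> Tuple[Node, str]:
            if node.is_leaf:
                return Node(node.label, node.length), node.label
            pairs = sorted((rec(c) for c in node.children), key=lambda p: p[1])
            kids = [p[0] for p in pairs]
            smallest = pairs[0][1]
            while len(kids) > 2:
                merged = Node(None, 0.0, [kids[0], kids[1]])
                kids = [merged] + kids[2:]
            return Node(node.label, node.length, kids), smallest

        return PhyloTree(rec(self.root)[0])


def read_newick(path, missing_lengths: str = "error") -> PhyloTree:
    """Read a Newick file into a :class:`PhyloTree`."""
    return PhyloTree.read(path, missing_lengths=missing_lengths)
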