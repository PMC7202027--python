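"""Rooted phylogenies with stable branch identifiers.

Newick parsing/writing is delegated to dendropy; internally the tree is
flattened to parent/children index arrays for fast pruning.  Every non-root
node defines the branch leading to it; the branch identifier is the sorted
"+"-joined set of leaf names it subtends (just the leaf name for terminal
branches), so identifiers survive re-reading and re-rooting.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np


class PhyloTree:
    """Rooted tree flattened to arrays, nodes indexed in postorder."""

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        leaf_names: Mapping[int, str],
    ) -> None:
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.n_nodes = len(self.parent)
        self.leaf_name = dict(leaf_names)
        self.leaf_index = {v: k for k, v in self.leaf_name.items()}
        (root,) = np.flatnonzero(self.parent < 0)
        self.root = int(root)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            if v != self.root:
                self.children[self.parent[v]].append(v)
        self.postorder = self._postorder()
        self._leafsets = self._compute_leafsets()
        self.branch_index = {self.branch_id(v): v for v in self.branches()}

    # ------------------------------------------------------------ topology
    def _postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order[::-1]

    def _compute_leafsets(self) -> list[frozenset[str]]:
        sets: list[frozenset[str]] = [frozenset()] * self.n_nodes
        for v in self.postorder:
            if not self.children[v]:
                sets[v] = frozenset([self.leaf_name[v]])
            else:
                acc: set[str] = set()
                for c in self.children[v]:
                    acc |= sets[c]
                sets[v] = frozenset(acc)
        return sets

    @property
    def leaves(self) -> list[str]:
        return [self.leaf_name[v] for v in self.postorder if not self.children[v]]

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def leafset(self, v: int) -> frozenset[str]:
        return self._leafsets[v]

    def branches(self) -> list[int]:
        """All non-root nodes, each standing for its parent branch."""
        return [v for v in self.postorder if v != self.root]

    def branch_id(self, v: int) -> str:
        if self.is_leaf(v):
            return self.leaf_name[v]
        return "+".join(sorted(self._leafsets[v]))

    def branch(self, ident: str | int) -> int:
        """Resolve a branch identifier (or node index) to a node index."""
        if isinstance(ident, (int, np.integer)):
            if not 0 <= ident < self.n_nodes or ident == self.root:
                raise KeyError(f"no branch {ident}")
            return int(ident)
        try:
            return self.branch_index[ident]
        except KeyError:
            raise KeyError(f"branch {ident!r} not in tree") from None

    def is_nested(self, a: str | int, b: str | int) -> bool:
        """True if one branch is ancestral to the other."""
        va, vb = self.branch(a), self.branch(b)
        sa, sb = self._leafsets[va], self._leafsets[vb]
        return sa <= sb or sb <= sa

    def nonnested_pairs(self) -> list[tuple[str, str]]:
        """All unordered branch pairs excluding ancestor-descendant pairs."""
        ids = [self.branch_id(v) for v in self.branches()]
        out = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if not self.is_nested(ids[i], ids[j]):
                    out.append((ids[i], ids[j]))
        return out

    # -------------------------------------------------------------- lengths
    def has_lengths(self) -> bool:
        return not np.isnan(self.lengths[[v for v in self.branches()]]).any()

    def scaled(self, factor: float) -> "PhyloTree":
        t = PhyloTree(self.parent, self.lengths * factor, self.leaf_name)
        return t

    def with_lengths(self, lengths: Mapping[str, float] | Sequence[float]) -> "PhyloTree":
        if isinstance(lengths, Mapping):
            arr = self.lengths.copy()
            for ident, t in lengths.items():
                arr[self.branch(ident)] = t
        else:
            arr = np.asarray(lengths, dtype=float)
        return PhyloTree(self.parent, arr, self.leaf_name)

    def pruned_to(self, taxa: Iterable[str]) -> "PhyloTree":
        """Subtree induced by the given leaves (branch lengths additive)."""
        keep = set(taxa)
        missing = keep - set(self.leaves)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        dt = dendropy.Tree.get(
            data=self.to_newick(), schema="newick", preserve_underscores=True
        )
        dt.retain_taxa_with_labels(sorted(keep))
        # collapse unifurcations created by pruning, merging branch lengths
        for node in list(dt.preorder_node_iter()):
            children = node.child_nodes()
            if len(children) == 1 and node.parent_node is not None:
                child = children[0]
                if child.edge.length is not None and node.edge.length is not None:
                    child.edge.length += node.edge.length
                node.parent_node.add_child(child)
                node.parent_node.remove_child(node)
        return PhyloTree._from_dendropy(dt)

    # ------------------------------------------------------------------- IO
    @classmethod
    def from_newick(
        cls,
        source: str | Path,
        outgroup: str | None = None,
    ) -> "PhyloTree":
        """Parse a Newick tree; optionally (re-)root on a named outgroup.

        ``source`` may be a Newick string or a path to a file.
        """
        text = source
        if isinstance(source, Path) or (isinstance(source, str) and Path(source).is_file()):
            text = Path(source).read_text()
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        if outgroup is not None:
            node = None
            for leaf in dt.leaf_node_iter():
                if leaf.taxon and leaf.taxon.label == outgroup:
                    node = leaf
                    break
            if node is None:
                raise KeyError(f"outgroup {outgroup!r} not found")
            if node.parent_node is not dt.seed_node or len(dt.seed_node.child_nodes()) != 2:
                length = node.edge.length
                if length is None:
                    dt.reroot_at_edge(node.edge, update_bipartitions=False)
                else:
                    dt.reroot_at_edge(
                        node.edge, length1=length / 2, length2=length / 2,
                        update_bipartitions=False,
                    )
        return cls._from_dendropy(dt)

    @classmethod
    def _from_dendropy(cls, dt: dendropy.Tree) -> "PhyloTree":
        nodes = list(dt.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        parent, lengths, leaf_names = [], [], {}
        for i, n in enumerate(nodes):
            parent.append(index[id(n.parent_node)] if n.parent_node else -1)
            lengths.append(np.nan if n.edge.length is None else float(n.edge.length))
            if n.is_leaf():
                leaf_names[i] = n.taxon.label if n.taxon else ""
        return cls(parent, lengths, leaf_names)

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            if self.is_leaf(v):
                label = self.leaf_name[v]
            else:
                label = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
            t = self.lengths[v]
            if v != self.root and not np.isnan(t):
                label += f":{t:.10g}"
            return label

        return fmt(self.root) + ";"

    def __repr__(self) -> str:
        return f"PhyloTree({self.n_nodes} nodes, {len(self.leaves)} leaves)"
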