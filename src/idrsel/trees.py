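"""Array-backed rooted phylogenies for simulation and pruning likelihoods."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class PhyloTree:
    """Rooted tree over named leaves with per-node branch lengths.

    Nodes ``0..n_leaves-1`` are the leaves, in ``leaf_names`` order; internal
    nodes follow.  ``lengths[v]`` is the length of the edge above node ``v``
    (0 for the root).  Multifurcations are allowed.
    """

    def __init__(self, leaf_names: list[str], parent: np.ndarray, lengths: np.ndarray):
        self.leaf_names = list(leaf_names)
        self.n_leaves = len(leaf_names)
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.n_nodes = len(self.parent)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(v)
        if np.any(self.lengths < 0):
            raise ValueError("branch lengths must be non-negative")
        # postorder: children before parents
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        self.postorder = order
        self.preorder = order[::-1]

    def is_leaf(self, v: int) -> bool:
        return v < self.n_leaves

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder:
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.lengths[v]
        return d

    def leaves_under(self, v: int) -> set[int]:
        out: set[int] = set()
        stack = [v]
        while stack:
            u = stack.pop()
            if self.is_leaf(u):
                out.add(u)
            else:
                stack.extend(self.children[u])
        return out

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if self.is_leaf(v):
                label = self.leaf_names[v]
            else:
                label = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v == self.root:
                return label + ";"
            return f"{label}:{self.lengths[v]:.10g}"

        return rec(self.root)

    @classmethod
    def from_skbio(cls, tree) -> "PhyloTree":
        """Convert a scikit-bio TreeNode (e.g. from neighbor joining)."""
        tips = list(tree.tips())
        index = {id(t): i for i, t in enumerate(tips)}
        names = [t.name for t in tips]
        n_leaves = len(tips)
        internal = [n for n in tree.postorder(include_self=True) if not n.is_tip()]
        for k, node in enumerate(internal):
            index[id(node)] = n_leaves + k
        n_nodes = n_leaves + len(internal)
        parent = np.full(n_nodes, -1, dtype=int)
        lengths = np.zeros(n_nodes)
        for node in tree.postorder(include_self=True):
            v = index[id(node)]
            if node.parent is not None:
                parent[v] = index[id(node.parent)]
                lengths[v] = max(float(node.length or 0.0), 0.0)
        return cls(names, parent, lengths)


@dataclass
class StrainTree:
    """Two-species strain phylogeny: one monophyletic clade per species."""

    tree: PhyloTree
    species_of: dict[str, str]

    def __post_init__(self) -> None:
        names = self.tree.leaf_names
        if len(set(names)) != len(names):
            raise ValueError("strain labels must be unique")
        species = sorted(set(self.species_of.values()))
        if len(species) != 2:
            raise ValueError("exactly two species required")
        for sp in species:
            members = {i for i, n in enumerate(names) if self.species_of[n] == sp}
            if not any(
                self.tree.leaves_under(v) == members
                for v in range(self.tree.n_nodes)
            ):
                raise ValueError(f"species {sp} is not monophyletic")

    @property
    def species(self) -> tuple[str, str]:
        return tuple(sorted(set(self.species_of.values())))  # type: ignore[return-value]
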