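"""Rooted time trees for the comparative analyses.

:class:`TimeTree` is a light array-backed container for a rooted, fully
bifurcating phylogeny with branch lengths in Myr.  Parsing of NEXUS and
Newick files is delegated to dendropy; everything downstream (ancestral
reconstruction, phylogenetic covariances, pruning) works on the arrays.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .io import MalformedInputError

logger = logging.getLogger("morphotraj")


def normalize_label(label: str) -> str:
    """Whitespace/underscore normalization; matching stays case-sensitive."""
    return "_".join(str(label).split())


class TimeTree:
    """Rooted binary tree over taxon labels with Myr branch lengths.

    Nodes are integer indices ``0..2n-2`` with the root first in preorder.
    ``parent[i]`` is -1 for the root; ``length[i]`` is the branch above
    node ``i`` (0.0 for the root).  Tips carry taxon labels; internal
    nodes may carry clade names.
    """

    def __init__(self, parent: Sequence[int], length: Sequence[float],
                 labels: Sequence[Optional[str]]):
        self.parent = np.asarray(parent, dtype=int)
        self.length = np.asarray(length, dtype=float)
        self.labels = [normalize_label(l) if l else None for l in labels]
        n_nodes = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(n_nodes)]
        roots = []
        for i, p in enumerate(self.parent):
            if p < 0:
                roots.append(i)
            else:
                self.children[p].append(i)
        if len(roots) != 1:
            raise MalformedInputError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for i, ch in enumerate(self.children):
            if len(ch) not in (0, 2):
                raise MalformedInputError(
                    f"tree is not fully bifurcating: node {self.labels[i] or i} has "
                    f"{len(ch)} children (resolve polytomies before analysis)"
                )
        self.tips = [i for i in range(n_nodes) if not self.children[i]]
        if any(self.labels[i] is None for i in self.tips):
            raise MalformedInputError("every tip must carry a taxon label")

    # -- basic structure ---------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips]

    def preorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def postorder(self) -> list[int]:
        return self.preorder()[::-1]

    def tip_index(self, label: str) -> int:
        label = normalize_label(label)
        for i in self.tips:
            if self.labels[i] == label:
                return i
        raise KeyError(f"taxon {label!r} not in tree")

    def node_by_name(self, name: str) -> Optional[int]:
        name = normalize_label(name)
        for i in range(self.n_nodes):
            if self.labels[i] == name:
                return i
        return None

    def mrca(self, labels: Sequence[str]) -> int:
        """Most recent common ancestor of the given tip labels."""
        present = [l for l in (normalize_label(x) for x in labels) if l in self.tip_labels]
        if not present:
            raise KeyError(f"none of {list(labels)} are tips of this tree")
        sets = []
        for l in present:
            anc, v = [], self.tip_index(l)
            while v >= 0:
                anc.append(v)
                v = self.parent[v]
            sets.append(anc)
        common = set(sets[0])
        for s in sets[1:]:
            common &= set(s)
        # the deepest common ancestor along any path is the MRCA
        for v in sets[0]:
            if v in common:
                return v
        raise AssertionError("unreachable")

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths in Myr."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            if v != self.root:
                d[v] = d[self.parent[v]] + self.length[v]
        return d

    def clade_tips(self, node: int) -> list[str]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if not self.children[v]:
                out.append(self.labels[v])
            stack.extend(self.children[v])
        return out

    # -- comparative-method matrices --------------------------------------

    def phylo_covariance(self, order: Optional[Sequence[str]] = None) -> np.ndarray:
        """Tip covariance matrix C under Brownian motion: C[i, j] is the
        shared root-to-MRCA path length (Myr) of tips i and j."""
        labels = list(order) if order is not None else self.tip_labels
        idx = [self.tip_index(l) for l in labels]
        depth = self.depths()
        n = len(idx)
        # ancestor chains
        chains = []
        for t in idx:
            anc, v = {}, t
            while v >= 0:
                anc[v] = depth[v]
                v = self.parent[v]
            chains.append(anc)
        C = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                shared = max(d for v, d in chains[i].items() if v in chains[j])
                C[i, j] = C[j, i] = shared
            C[i, i] = depth[idx[i]]
        return C

    # -- editing -----------------------------------------------------------

    def prune_to(self, keep_labels: Sequence[str]) -> "TimeTree":
        """Restrict to a tip subset, retaining the original calibration.

        Degree-2 internal nodes left by the pruning are suppressed and
        their branch lengths summed, so path lengths between surviving
        nodes (and therefore node ages) are unchanged.  Clade names on
        suppressed nodes are dropped; names on surviving nodes persist.
        """
        keep = {normalize_label(l) for l in keep_labels}
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        keep_node = np.zeros(self.n_nodes, dtype=bool)
        for v in self.postorder():
            if not self.children[v]:
                keep_node[v] = self.labels[v] in keep
            else:
                keep_node[v] = any(keep_node[c] for c in self.children[v])
        # new structure: walk from the new root, skipping unifurcations
        def surviving_children(v):
            out = []
            for c in self.children[v]:
                if not keep_node[c]:
                    continue
                length = self.length[c]
                while True:
                    live = [g for g in self.children[c] if keep_node[g]]
                    if len(live) == 1:
                        length += self.length[live[0]]
                        c = live[0]
                    else:
                        break
                out.append((c, length))
            return out

        new_root = self.root
        while True:
            live = [c for c in self.children[new_root] if keep_node[c]]
            if len(live) == 1:
                new_root = live[0]
            else:
                break
        parent, length, labels, mapping = [], [], [], {}

        def build(old, par, blen):
            idx = len(parent)
            mapping[old] = idx
            parent.append(par)
            length.append(blen)
            labels.append(self.labels[old])
            for child, l in surviving_children(old):
                build(child, idx, l)

        build(new_root, -1, 0.0)
        return TimeTree(parent, length, labels)

    # -- I/O ----------------------------------------------------------------

    def to_newick(self, names: bool = True) -> str:
        def rec(v):
            if not self.children[v]:
                return f"{self.labels[v]}:{self.length[v]:g}"
            inner = ",".join(rec(c) for c in self.children[v])
            name = self.labels[v] if (names and self.labels[v]) else ""
            if v == self.root:
                return f"({inner}){name}"
            return f"({inner}){name}:{self.length[v]:g}"
        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        import dendropy
        t = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
        return cls.from_dendropy(t)

    @classmethod
    def from_dendropy(cls, t) -> "TimeTree":
        parent, length, labels = [], [], []
        index = {}
        zero_branches = False
        for node in t.preorder_node_iter():
            idx = len(parent)
            index[id(node)] = idx
            parent.append(index[id(node.parent_node)] if node.parent_node else -1)
            blen = node.edge.length if node.edge.length is not None else 0.0
            if node.parent_node is not None and node.edge.length is not None and blen <= 0:
                zero_branches = True
            length.append(blen if node.parent_node is not None else 0.0)
            if node.taxon is not None:
                labels.append(node.taxon.label)
            else:
                labels.append(node.label)
        if zero_branches:
            logger.warning("tree contains zero-length branches; run calibrate_branch_lengths")
        return cls(parent, length, labels)


def read_nexus_tree(path) -> TimeTree:
    """Read the first tree from a NEXUS TREES block (or a Newick file).

    Tip labels are whitespace/underscore-normalized; matching elsewhere is
    case-sensitive.  Polytomies raise (the pipeline requires bifurcating
    trees); zero-length branches only warn, since the caller is expected
    to time-calibrate.
    """
    import dendropy
    text = open(path).read()
    schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
    t = dendropy.Tree.get(data=text, schema=schema, rooting="force-rooted")
    return TimeTree.from_dendropy(t)
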