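"""Time calibration, squared-change parsimony and phylogenetic signal.

Ancestral shapes and sizes are reconstructed by branch-length-weighted
squared-change parsimony (SCP): the node states minimizing

    sum over branches  ||x_child - x_parent||^2 / branch_length.

Setting the gradient to zero gives a sparse linear system (a weighted
graph Laplacian), solved exactly per coordinate; the minimizer is unique
on a connected tree and coincides with the maximum-likelihood ancestral
states under Brownian motion.  Phylogenetic signal is tested two ways:
by permuting tip states and asking whether the observed weighted tree
length is unusually short, and with the multivariate K statistic
(observed over Brownian-expected signal ratio).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .tree import TimeTree


@dataclass
class AncestralReconstruction:
    """SCP solution: states for every node of ``tree`` (tips included,
    rows indexed by node id) and the minimized weighted tree length."""

    node_states: np.ndarray      # (n_nodes, d)
    tree_length: float
    tree: TimeTree
    tip_order: list[str]

    def state_of(self, node: int) -> np.ndarray:
        return self.node_states[node]

    def state_of_clade(self, tip_labels: Sequence[str]) -> np.ndarray:
        return self.node_states[self.tree.mrca(tip_labels)]


@dataclass
class SignalTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    statistic_name: str
    null_distribution: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# time calibration
# ---------------------------------------------------------------------------


def calibrate_branch_lengths(tree: TimeTree, tip_ages: Mapping[str, float],
                             root_extension: float = 1.0) -> TimeTree:
    """Assign Myr branch lengths from tip ages (Myr before present).

    Each internal node is initially made as old as its oldest descendant
    tip; the root is then pushed back by ``root_extension`` (default 1
    Myr).  Zero-length branches are eliminated by dividing the nearest
    positive ancestral branch equally along the longest chain of zero
    branches hanging from it (side chains become positive as a
    consequence and any remainder is fixed in later passes).  All
    returned branch lengths are strictly positive.
    """
    ages = np.zeros(tree.n_nodes)
    for v in tree.postorder():
        if not tree.children[v]:
            label = tree.labels[v]
            if label not in tip_ages:
                raise KeyError(f"no age for tip {label!r}")
            ages[v] = float(tip_ages[label])
        else:
            ages[v] = max(ages[c] for c in tree.children[v])
    ages[tree.root] += float(root_extension)

    def zero_children(v):
        return [c for c in tree.children[v] if ages[c] >= ages[v] - 1e-12]

    def longest_zero_chain(v):
        """Longest path of consecutive zero branches below v (node list,
        excluding v)."""
        best: list[int] = []
        for c in zero_children(v):
            cand = [c] + longest_zero_chain(c)
            if len(cand) > len(best):
                best = cand
        return best

    for _ in range(tree.n_nodes):
        # shallowest zero branch first: its parent branch is then positive
        target = None
        for v in tree.preorder():
            if v == tree.root:
                continue
            if ages[v] >= ages[tree.parent[v]] - 1e-12:
                target = v
                break
        if target is None:
            break
        p = tree.parent[target]
        g = tree.parent[p]
        if g < 0:
            raise ValueError(
                f"cannot resolve zero-length branch at the root; increase root_extension")
        chain = longest_zero_chain(p)
        span = ages[g] - ages[chain[-1]]
        if span <= 0:
            raise ValueError(
                f"tip {tree.labels[chain[-1]]!r} is older than its assigned ancestor")
        m = len(chain)  # zero branches in the chain
        # space p and the intermediate chain nodes evenly below g
        for i, node in enumerate([p] + chain[:-1]):
            ages[node] = ages[g] - (i + 1) * span / (m + 1)

    lengths = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes):
        if v != tree.root:
            lengths[v] = ages[tree.parent[v]] - ages[v]
            if lengths[v] <= 0:
                raise ValueError(
                    f"non-positive branch above {tree.labels[v] or v} after calibration")
    return TimeTree(tree.parent, lengths, tree.labels)


# ---------------------------------------------------------------------------
# squared-change parsimony
# ---------------------------------------------------------------------------


def _laplacian_blocks(tree: TimeTree):
    """Weighted graph Laplacian of the tree (weights 1/branch length),
    partitioned into tip and internal blocks."""
    if np.any(tree.length[[v for v in range(tree.n_nodes) if v != tree.root]] <= 0):
        raise ValueError("SCP requires strictly positive branch lengths")
    n = tree.n_nodes
    L = np.zeros((n, n))
    for v in range(n):
        if v == tree.root:
            continue
        w = 1.0 / tree.length[v]
        p = tree.parent[v]
        L[v, v] += w
        L[p, p] += w
        L[v, p] -= w
        L[p, v] -= w
    tips = np.array(tree.tips)
    internal = np.array([v for v in range(n) if v not in set(tree.tips)])
    return L, tips, internal


def scp_quadratic_form(tree: TimeTree) -> np.ndarray:
    """Matrix M (tips x tips, tip order = ``tree.tips``) such that the
    minimized weighted tree length for tip data Y is trace(Y' M Y)
    (the Schur complement of the internal block of the Laplacian)."""
    L, tips, internal = _laplacian_blocks(tree)
    Ltt = L[np.ix_(tips, tips)]
    Lti = L[np.ix_(tips, internal)]
    Lii = L[np.ix_(internal, internal)]
    return Ltt - Lti @ np.linalg.solve(Lii, Lti.T)


def ancestral_states_scp(tree: TimeTree, tip_states: Mapping[str, np.ndarray] | np.ndarray,
                         tip_order: Optional[Sequence[str]] = None) -> AncestralReconstruction:
    """Weighted squared-change parsimony reconstruction.

    ``tip_states`` is either a mapping label -> state vector or an array
    whose rows follow ``tip_order`` (default: ``tree.tip_labels``).
    Each coordinate is solved independently through one sparse solve.
    """
    if tip_order is None:
        tip_order = tree.tip_labels
    if isinstance(tip_states, Mapping):
        Y = np.atleast_2d(np.array([np.atleast_1d(tip_states[l]) for l in tip_order], float))
    else:
        Y = np.atleast_2d(np.asarray(tip_states, dtype=float))
        if Y.shape[0] != len(tip_order):
            raise ValueError("one state row per tip required")
    L, tips, internal = _laplacian_blocks(tree)
    # rows of Y follow tip_order; map into node indexing
    node_for_label = {tree.labels[t]: t for t in tree.tips}
    perm = [tips.tolist().index(node_for_label[l]) for l in tip_order]
    Y_nodes = np.empty_like(Y)
    Y_nodes[perm] = Y  # now row i corresponds to tips[i]
    Lii = L[np.ix_(internal, internal)]
    Lit = L[np.ix_(internal, tips)]
    X_internal = np.linalg.solve(Lii, -Lit @ Y_nodes)
    states = np.zeros((tree.n_nodes, Y.shape[1]))
    states[tips] = Y_nodes
    states[internal] = X_internal
    tl = 0.0
    for v in range(tree.n_nodes):
        if v != tree.root:
            diff = states[v] - states[tree.parent[v]]
            tl += float(diff @ diff) / tree.length[v]
    return AncestralReconstruction(states, tl, tree, list(tip_order))


# ---------------------------------------------------------------------------
# phylogenetic signal
# ---------------------------------------------------------------------------


def _as_tip_matrix(tree, tip_states, tip_order):
    if tip_order is None:
        tip_order = tree.tip_labels
    if isinstance(tip_states, Mapping):
        Y = np.array([np.atleast_1d(tip_states[l]) for l in tip_order], dtype=float)
    else:
        Y = np.atleast_2d(np.asarray(tip_states, dtype=float))
        if Y.ndim == 2 and Y.shape[0] != len(tip_order) and Y.shape[1] == len(tip_order):
            Y = Y.T
    return Y, list(tip_order)


def permutation_signal_test(tree: TimeTree, tip_states, n_perm: int = 10000,
                            seed: int = 0, tip_order: Optional[Sequence[str]] = None,
                            keep_null: bool = False) -> SignalTestResult:
    """Tip-permutation test on the SCP weighted tree length.

    Shorter observed tree length than under random reassignment of states
    to tips means phylogenetic signal, so p is the fraction of permuted
    lengths <= the observed one, with the (b+1)/(n+1) correction.
    """
    import warnings
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low for a permutation test")
    Y, tip_order = _as_tip_matrix(tree, tip_states, tip_order)
    node_for_label = {tree.labels[t]: t for t in tree.tips}
    tips = list(tree.tips)
    perm_rows = [tip_order.index(tree.labels[t]) for t in tips]
    Yn = Y[perm_rows]                      # rows in tree-tip order
    M = scp_quadratic_form(tree)
    G = Yn @ Yn.T
    observed = float(np.sum(M * G))
    rng = np.random.default_rng(seed)
    n = len(tips)
    null = np.empty(n_perm)
    for b in range(n_perm):
        ix = rng.permutation(n)
        null[b] = np.sum(M * G[np.ix_(ix, ix)])
    hits = int(np.sum(null <= observed + 1e-12 * max(observed, 1.0)))
    p = (hits + 1) / (n_perm + 1)
    return SignalTestResult(observed, p, n_perm, "scp_tree_length",
                            null if keep_null else None)


def k_mult(tree: TimeTree, tip_states, n_perm: int = 10000, seed: int = 0,
           tip_order: Optional[Sequence[str]] = None,
           keep_null: bool = False) -> SignalTestResult:
    """Multivariate K statistic of phylogenetic signal.

    K is the ratio of mean squared deviation from the phylogenetic
    (generalized-least-squares) mean in the original versus the
    phylogenetically transformed space, divided by its expectation under
    Brownian motion on the tree, so Brownian data give K ~ 1.  The
    p-value permutes states across tips, counting permutations with K at
    least as large as observed.
    """
    Y, tip_order = _as_tip_matrix(tree, tip_states, tip_order)
    C = tree.phylo_covariance(order=tip_order)
    n = C.shape[0]
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("phylogenetic covariance matrix is singular") from exc
    one = np.ones(n)
    denom = float(one @ Cinv @ one)
    w = (Cinv @ one) / denom               # GLS mean weights
    A = np.eye(n) - np.outer(one, w)       # residual maker about the phylo mean
    B_num = A.T @ A
    B_den = A.T @ Cinv @ A
    expected = (np.trace(C) - n / denom) / (n - 1)

    G = Y @ Y.T
    num = float(np.sum(B_num * G))
    if num <= 1e-30:
        raise ValueError("degenerate data: identical states at all tips, K undefined")
    den = float(np.sum(B_den * G))
    K = (num / den) / expected

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        ix = rng.permutation(n)
        Gp = G[np.ix_(ix, ix)]
        null[b] = (np.sum(B_num * Gp) / np.sum(B_den * Gp)) / expected
    hits = int(np.sum(null >= K - 1e-12 * K))
    p = (hits + 1) / (n_perm + 1)
    return SignalTestResult(float(K), p, n_perm, "k_mult", null if keep_null else None)
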