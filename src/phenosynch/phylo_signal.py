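"""Phylogenetic signal in phenological traits.

Consumes a rooted newick tree with branch lengths (the tree is an input,
never estimated here) and provides Felsenstein's independent contrasts,
Blomberg's K, and a tip-shuffling permutation test of signal.

Under Brownian motion the standardized contrasts are i.i.d. normal and
K = 1 in expectation; K well below 1 indicates less trait similarity among
relatives than Brownian evolution predicts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from ._util import substream

logger = logging.getLogger(__name__)


class NewickError(ValueError):
    """The newick input is malformed or violates an invariant."""


def _zero_floor(tree: dendropy.Tree) -> float:
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    return 1e-8 * max(depth, 1.0)


def prepare_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Resolve polytomies to zero-length binary splits, then perturb
    zero-length branches so contrast denominators never vanish."""
    tree.resolve_polytomies()
    eps = _zero_floor(tree)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length <= 0:
            edge.length = eps
    return tree


def read_newick(path) -> dendropy.Tree:
    """Parse a rooted newick tree; branch lengths required, tips unique."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as err:
        raise NewickError(f"failed to parse {path}: {err}") from err
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickError(f"duplicate tip labels {dupes}")
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node is tree.seed_node:
            continue
        if edge.length is None:
            raise NewickError(
                f"missing branch length above node "
                f"{node.taxon.label if node.taxon else '<internal>'}")
    return prepare_tree(tree)


def tip_labels(tree: dendropy.Tree) -> list:
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


def pic_coefficients(tree: dendropy.Tree) -> tuple:
    """Contrast coefficient matrix C of the pruning algorithm.

    Returns (tips, C) with C of shape (n-1, n): each contrast is the linear
    combination C[k] · x of tip values, standardized by the pooled branch
    length.  Ancestral values are the usual inverse-branch-length weighted
    means, and parent branches are extended by b1·b2/(b1+b2).
    """
    tips = tip_labels(tree)
    pos = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    contrasts = []
    state = {}  # node -> (coef vector, working branch length)
    for node in tree.postorder_node_iter():
        blen = node.edge.length if node is not tree.seed_node else 0.0
        if node.is_leaf():
            w = np.zeros(n)
            w[pos[node.taxon.label]] = 1.0
            state[node] = (w, float(blen or 0.0))
            continue
        children = list(node.child_nodes())
        if len(children) == 1:  # unifurcation: pass through, add length
            w, b = state.pop(children[0])
            state[node] = (w, b + float(blen or 0.0))
            continue
        w, b = state.pop(children[0])
        for child in children[1:]:  # binary after prepare_tree
            w2, b2 = state.pop(child)
            if b + b2 <= 0:
                raise NewickError("zero combined branch length at a node")
            contrasts.append((w - w2) / np.sqrt(b + b2))
            w = (b2 * w + b * w2) / (b + b2)
            b = b * b2 / (b + b2)
        state[node] = (w, b + float(blen or 0.0))
    return tips, np.array(contrasts)


def _trait_vector(tips, x) -> np.ndarray:
    missing = [t for t in tips if t not in x]
    if missing:
        raise ValueError(f"traits missing for tips {missing}")
    v = np.array([float(x[t]) for t in tips])
    if not np.all(np.isfinite(v)):
        raise ValueError("trait values must be finite")
    return v


def pic(tree: dendropy.Tree, x: dict) -> np.ndarray:
    """Felsenstein's phylogenetically independent contrasts (n-1 values)."""
    tips, C = pic_coefficients(tree)
    return C @ _trait_vector(tips, x)


def vcv(tree: dendropy.Tree) -> tuple:
    """Brownian-motion covariance: V[i, j] = shared root-to-MRCA path length."""
    tips = tip_labels(tree)
    pos = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))
    depth = {}
    leafsets = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depth[parent] + (node.edge.length or 0)
        depth[node] = d
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = pos[node.taxon.label]
            V[i, i] = depth[node]
            leafsets[node] = [i]
            continue
        children = list(node.child_nodes())
        merged = []
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in leafsets[children[a]]:
                    for j in leafsets[children[b]]:
                        V[i, j] = V[j, i] = depth[node]
        for c in children:
            merged.extend(leafsets.pop(c))
        leafsets[node] = merged
    return tips, V


def _k_from_resid(x, Vinv, trV, n, ones_ViV):
    """Blomberg's K given precomputed V quantities; x may be (n,) or (n, B)."""
    x = np.atleast_2d(x.T).T  # (n, B)
    num_a = Vinv.sum(axis=0) @ x  # 1' Vinv x, per column
    a_hat = num_a / ones_ViV
    r = x - a_hat[None, :]
    mse0 = (r ** 2).sum(axis=0) / (n - 1)
    mse = (r * (Vinv @ r)).sum(axis=0) / (n - 1)
    expected = (trV - n / ones_ViV) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(tree: dendropy.Tree, x: dict) -> float:
    """Blomberg's K: observed MSE₀/MSE over its Brownian-motion expectation."""
    tips, V = vcv(tree)
    if len(tips) < 4:
        raise ValueError("Blomberg's K needs at least 4 tips")
    v = _trait_vector(tips, x)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular phylogenetic covariance: {err}") from err
    ones_ViV = float(Vinv.sum())
    k = _k_from_resid(v, Vinv, float(np.trace(V)), len(tips), ones_ViV)
    return float(k[0])


@dataclass
class SignalResult:
    K: float
    statistic: float
    p_permutation: float
    n_perm: int
    seed: int


def signal_test(tree: dendropy.Tree, x: dict, n_perm: int = 999,
                seed: int = 0, statistic: str = "pic_variance") -> SignalResult:
    """Permutation test of phylogenetic signal by tip-label shuffling.

    The default statistic is the mean squared independent contrast (low
    values = signal); ``statistic="k"`` permutes Blomberg's K instead (high
    values = signal).  p uses the add-one estimator, so p ∈ (0, 1].
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    tips, C = pic_coefficients(tree)
    v = _trait_vector(tips, x)
    K = blomberg_k(tree, x) if len(tips) >= 4 else float("nan")
    rng = substream(seed, "signal_test", statistic, n_perm)
    if np.var(v) == 0:
        logger.warning("constant trait: no signal to test, p = 1")
        return SignalResult(K, float("nan"), 1.0, n_perm, seed)
    perms = np.array([rng.permutation(v) for _ in range(n_perm)]).T  # (n, B)
    if statistic == "pic_variance":
        obs = float(np.mean((C @ v) ** 2))
        null = np.mean((C @ perms) ** 2, axis=0)
        extreme = int(np.sum(null <= obs))
    elif statistic == "k":
        _, V = vcv(tree)
        Vinv = np.linalg.inv(V)
        ones_ViV = float(Vinv.sum())
        trV = float(np.trace(V))
        obs = K
        null = _k_from_resid(perms, Vinv, trV, len(tips), ones_ViV)
        extreme = int(np.sum(null >= obs))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    p = (1.0 + extreme) / (n_perm + 1.0)
    return SignalResult(K, obs, float(p), n_perm, seed)
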