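"""Phylogenetic tree handling: Newick I/O, neighbor joining, splits and
topology distances.

Trees are ``dendropy.Tree`` objects with branch lengths in expected
substitutions per site.  Topology distances are computed on the unrooted
view of a tree: each internal edge induces a bipartition (split) of the
leaf set, stored canonically as the side not containing a fixed reference
leaf (the lexicographically smallest label).

The Matching Split (MS) distance pairs up the two trees' split sets by a
minimum-weight perfect matching, where matching split A|B with C|D costs
``min(|A ^ C|, |A ^ D|)`` (symmetric differences of the sides).  When the
split sets differ in size, the smaller is padded with virtual empty
splits whose cost against A|B is ``min(|A|, |B|)`` — the convention used
by the TreeCmp program.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path
from typing import Literal

import dendropy
import numpy as np
from scipy.optimize import linear_sum_assignment


class TreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"bad newick: {exc}") from exc
    labels = leaf_labels(tree)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate leaf labels: {', '.join(dupes)}")
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        preserve_spaces=True,
        suppress_rooting=True,
    ).strip() + "\n"


def write_newick(tree: dendropy.Tree, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(to_newick(tree))
    return path


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Splits


def split_set(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits of the unrooted tree, as canonical leaf sets.

    Each split is the side not containing the reference (smallest) leaf
    label; a binary unrooted tree on n leaves yields n - 3 splits.
    """
    labels = leaf_labels(tree)
    all_leaves = frozenset(labels)
    ref = min(labels)
    n = len(labels)
    splits: set[frozenset[str]] = set()
    below: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset({node.taxon.label})
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node is tree.seed_node:
            continue
        side = below[node]
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return splits


def _check_same_leaves(t1: dendropy.Tree, t2: dendropy.Tree) -> frozenset[str]:
    l1, l2 = frozenset(leaf_labels(t1)), frozenset(leaf_labels(t2))
    if l1 != l2:
        only1 = sorted(l1 - l2)[:5]
        only2 = sorted(l2 - l1)[:5]
        raise TreeError(
            f"leaf sets differ (only in first: {only1}; only in second: {only2})"
        )
    return l1


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Symmetric-difference count of the two trees' non-trivial splits."""
    _check_same_leaves(t1, t2)
    return len(split_set(t1) ^ split_set(t2))


def matching_split_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> float:
    """Minimum-weight perfect matching between the two split sets."""
    leaves = _check_same_leaves(t1, t2)
    n = len(leaves)
    s1, s2 = sorted(split_set(t1), key=sorted), sorted(split_set(t2), key=sorted)
    k = max(len(s1), len(s2))
    if k == 0:
        return 0.0
    cost = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i < len(s1) and j < len(s2):
                d = len(s1[i] ^ s2[j])
                cost[i, j] = min(d, n - d)
            elif i < len(s1):  # matched against a virtual empty split
                cost[i, j] = min(len(s1[i]), n - len(s1[i]))
            elif j < len(s2):
                cost[i, j] = min(len(s2[j]), n - len(s2[j]))
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum())


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(
    distances: np.ndarray, labels: list[str]
) -> dendropy.Tree:
    """Classic neighbor joining; additive distances are reproduced exactly.

    Ties in the Q criterion break to the smallest index pair, so the
    output is deterministic.
    """
    D = np.array(distances, dtype=float)
    m = len(labels)
    if D.shape != (m, m):
        raise TreeError(f"distance matrix shape {D.shape} != ({m}, {m})")
    if m < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T) or (D < 0).any() or np.diag(D).any():
        raise TreeError("distances must be symmetric, non-negative, zero-diagonal")

    taxon_ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    nodes = []
    for label in labels:
        node = dendropy.Node(taxon=taxon_ns.get_taxon(label))
        nodes.append(node)

    active = list(range(m))
    while len(active) > 2:
        r = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best, best_q = None, np.inf
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        vi = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        vj = D[i, j] - vi
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = max(vi, 0.0)
        parent.add_child(nodes[j])
        nodes[j].edge.length = max(vj, 0.0)
        # distances from the new node
        newD = np.zeros(len(D))
        for k in active:
            if k in (i, j):
                continue
            newD[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newD
        D[:-1, -1] = newD
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(D) - 1]

    i, j = active
    if nodes[i].is_leaf():
        i, j = j, i
    root = nodes[i]
    root.add_child(nodes[j])
    nodes[j].edge.length = max(D[active[0], active[1]], 0.0)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Random trees

NullModel = Literal["yule", "uniform"]


def random_tree(
    n_taxa: int,
    process: NullModel = "yule",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    labels: list[str] | None = None,
    brlen_mean: float = 0.1,
) -> dendropy.Tree:
    """Random unrooted binary tree on `n_taxa` leaves.

    "yule" attaches each new leaf to a uniformly chosen pendant edge (the
    topology of a pure-birth process); "uniform" attaches to a uniformly
    chosen edge of any kind, giving the uniform distribution on unrooted
    labelled topologies.  Branch lengths are exponential with mean
    `brlen_mean`.
    """
    if n_taxa < 3:
        raise TreeError("need at least 3 taxa")
    if rng is None:
        rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise TreeError("labels length mismatch")

    taxon_ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    order = rng.permutation(n_taxa)
    for idx in order[:3]:
        leaf = dendropy.Node(taxon=taxon_ns.get_taxon(labels[idx]))
        root.add_child(leaf)
    for idx in order[3:]:
        edges = [
            node for node in tree.preorder_node_iter()
            if node is not root and (process == "uniform" or node.is_leaf())
        ]
        target = edges[rng.integers(len(edges))]
        parent = target.parent_node
        mid = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(mid)
        mid.add_child(target)
        leaf = dendropy.Node(taxon=taxon_ns.get_taxon(labels[idx]))
        mid.add_child(leaf)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not root:
            edge.length = float(rng.exponential(brlen_mean))
    tree.is_rooted = False
    return tree


@lru_cache(maxsize=64)
def _ms_baseline(
    n_taxa: int, null_model: NullModel, n_samples: int, seed: int
) -> float:
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(n_samples):
        a = random_tree(n_taxa, process=null_model, rng=rng)
        b = random_tree(n_taxa, process=null_model, rng=rng)
        total += matching_split_distance(a, b)
    return total / n_samples


def normalized_ms(
    t1: dendropy.Tree,
    t2: dendropy.Tree,
    null_model: NullModel = "yule",
    n_samples: int = 100,
    seed: int = 0,
) -> float:
    """MS distance divided by its Monte-Carlo mean between random trees.

    The baseline is the average MS distance between independent random
    tree pairs on the same number of leaves, cached per
    (leaf count, null model, sample count, seed).
    """
    ms = matching_split_distance(t1, t2)
    if ms == 0.0:
        return 0.0
    n = len(leaf_labels(t1))
    return ms / _ms_baseline(n, null_model, n_samples, seed)
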