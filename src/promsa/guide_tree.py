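"""Guide-tree preparation for progressive alignment.

The guide tree drives everything downstream: the order in which sequence
groups are pairwise-aligned (the schedule), the branch-proportional weights
that keep dense clades from dominating profiles, and the optional
divide-and-conquer decomposition that bounds how many sequences are held in
memory at once.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "TreeNode",
    "GuideTree",
    "Schedule",
    "SubtreeDecomposition",
    "resolve_polytomies",
    "compute_schedule",
    "decompose_centroid",
    "compute_weights",
    "estimate_fallback_tree",
]


class TreeNode:
    """A rooted-tree node: ordered children, optional branch length to parent."""

    __slots__ = ("children", "parent", "length", "name", "node_id")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
    ) -> None:
        self.children: List["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None
        self.length = length
        self.name = name
        self.node_id: int = -1

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = f"leaf {self.name!r}" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode #{self.node_id} {kind}>"


class GuideTree:
    """Rooted guide tree; branch lengths are optional but all-or-nothing.

    Node ids are assigned in preorder by :meth:`assign_ids` and are the
    deterministic tie-breakers used throughout (centroid search, traversal
    order).
    """

    def __init__(self, root: TreeNode) -> None:
        self.root = root
        self.assign_ids()

    # -- structure ---------------------------------------------------------
    def assign_ids(self) -> None:
        for i, node in enumerate(self.preorder()):
            node.node_id = i

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: List[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> List[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> List[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    @property
    def has_branch_lengths(self) -> bool:
        """True iff every non-root edge carries a length.

        Trees lacking lengths are treated as having uniform branch lengths
        downstream (equal sequence weights).
        """
        return all(
            n.length is not None for n in self.preorder() if n.parent is not None
        )

    def copy(self) -> "GuideTree":
        def _copy(node: TreeNode) -> TreeNode:
            new = TreeNode(name=node.name, length=node.length)
            for c in node.children:
                new.add_child(_copy(c))
            return new

        return GuideTree(_copy(self.root))

    def is_binary(self) -> bool:
        return all(
            len(n.children) == 2 for n in self.preorder() if not n.is_leaf
        )

    # -- serialization -----------------------------------------------------
    def to_newick(self) -> str:
        def _fmt(node: TreeNode) -> str:
            if node.is_leaf:
                base = node.name or ""
            else:
                base = "(" + ",".join(_fmt(c) for c in node.children) + ")"
                if node.name:
                    base += node.name
            if node.length is not None and node.parent is not None:
                base += f":{node.length:g}"
            return base

        return _fmt(self.root) + ";"


@dataclass
class Schedule:
    """Alignment order per node and the independent groups per level.

    Leaves have order 0; every internal node's order is one greater than the
    maximum order of its children, so all nodes at one level depend only on
    already-finished work and may be aligned concurrently.
    """

    order_of: Dict[int, int]
    levels: Dict[int, List[int]]

    @property
    def n_levels(self) -> int:
        return max(self.levels) if self.levels else 0


@dataclass
class SubtreeDecomposition:
    """Result of centroid decomposition: bounded subtrees plus a skeleton.

    The skeleton is a guide tree whose leaves are subtree handles (integer
    indices into ``subtrees``); it records how subalignments are merged back
    together.
    """

    subtrees: List[GuideTree]
    skeleton: GuideTree
    leaf_to_subtree: Dict[str, int]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def resolve_polytomies(tree: GuideTree, seed: int) -> GuideTree:
    """Randomly resolve every multifurcation into cherries (seeded).

    Introduced internal edges get branch length 0 when the tree carries
    lengths, and no length otherwise (so the uniform-lengths flag survives).
    A binary tree is returned as an unchanged copy.
    """
    out = tree.copy()
    rng = random.Random(seed)
    zero = 0.0 if tree.has_branch_lengths else None
    for node in list(out.preorder()):
        while len(node.children) > 2:
            a, b = sorted(rng.sample(range(len(node.children)), 2))
            right = node.children.pop(b)
            left = node.children.pop(a)
            joint = TreeNode(length=zero)
            joint.add_child(left)
            joint.add_child(right)
            joint.parent = node
            node.children.insert(a, joint)
    out.assign_ids()
    return out


def compute_schedule(tree: GuideTree) -> Schedule:
    """Post-order alignment schedule for a strictly binary tree.

    Raises ``ValueError`` on non-binary internal nodes.  ``levels`` lists
    the internal nodes (by id) to be aligned at each order ≥ 1.
    """
    order_of: Dict[int, int] = {}
    levels: Dict[int, List[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            order_of[node.node_id] = 0
            continue
        if len(node.children) != 2:
            raise ValueError(
                f"node #{node.node_id} has {len(node.children)} children; "
                "resolve polytomies before scheduling"
            )
        order = 1 + max(order_of[c.node_id] for c in node.children)
        order_of[node.node_id] = order
        levels.setdefault(order, []).append(node.node_id)
    return Schedule(order_of=order_of, levels=levels)


def _leaf_counts(tree: GuideTree) -> Dict[int, int]:
    counts: Dict[int, int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            counts[node.node_id] = 1
        else:
            counts[node.node_id] = sum(counts[c.node_id] for c in node.children)
    return counts


def _detach(tree: GuideTree, node: TreeNode) -> Tuple[GuideTree, GuideTree]:
    """Split ``tree`` at the edge above ``node``; returns (below, remainder).

    The remainder has unary nodes suppressed (child lengths added through).
    """
    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    below = GuideTree(node)

    # Suppress the now-unary parent.
    while parent is not None and len(parent.children) == 1 and not parent.is_leaf:
        only = parent.children[0]
        if parent.parent is None:
            only.parent = None
            if only.length is not None and parent.length is None:
                pass
            only.length = None
            tree.root = only
            parent = None
        else:
            gp = parent.parent
            idx = gp.children.index(parent)
            if only.length is not None and parent.length is not None:
                only.length = only.length + parent.length
            gp.children[idx] = only
            only.parent = gp
            parent = gp if len(gp.children) == 1 else None
    remainder = GuideTree(tree.root)
    return below, remainder


def decompose_centroid(tree: GuideTree, m: float) -> SubtreeDecomposition:
    """Recursively split at centroid edges until every part has ≤ m leaves.

    The centroid edge is the one whose removal minimizes the larger of the
    two component leaf counts; ties break toward the smaller node id.  The
    skeleton joins the two halves' skeletons at a fresh internal node, so the
    merge phase can walk it like an ordinary (binary) guide tree.
    """
    if m < 1:
        raise ValueError("max-subtree bound must be >= 1")

    subtrees: List[GuideTree] = []

    def _recurse(t: GuideTree) -> TreeNode:
        n = t.n_leaves
        if n <= m:
            handle = TreeNode(name=str(len(subtrees)))
            subtrees.append(t)
            return handle
        counts = _leaf_counts(t)
        best: Optional[TreeNode] = None
        best_imbalance = None
        for node in t.preorder():
            if node.parent is None:
                continue
            below = counts[node.node_id]
            if below == 0 or below == n:
                continue
            imbalance = max(below, n - below)
            if best_imbalance is None or imbalance < best_imbalance or (
                imbalance == best_imbalance and node.node_id < best.node_id
            ):
                best, best_imbalance = node, imbalance
        below_t, rest_t = _detach(t, best)
        joint = TreeNode()
        joint.add_child(_recurse(rest_t))
        joint.add_child(_recurse(below_t))
        return joint

    skeleton = GuideTree(_recurse(tree.copy()))
    leaf_to_subtree = {
        name: idx
        for idx, sub in enumerate(subtrees)
        for name in sub.leaf_names()
    }
    return SubtreeDecomposition(
        subtrees=subtrees, skeleton=skeleton, leaf_to_subtree=leaf_to_subtree
    )


def compute_weights(tree: GuideTree) -> Dict[str, float]:
    """Branch-proportional sequence weights, mean-normalized to 1.

    Each leaf accumulates, over the edges on its root path, the edge length
    divided by the number of leaves sharing that edge (the classic
    branch-sharing rule); long, lonely branches earn large weights.  Without
    branch lengths all weights are 1.  Weights are rescaled to mean 1 so
    profile scores stay on the substitution-matrix scale regardless of group
    size.
    """
    leaves = tree.leaves()
    if not tree.has_branch_lengths:
        return {leaf.name: 1.0 for leaf in leaves}
    for node in tree.preorder():
        if node.parent is not None and node.length < 0:
            raise ValueError(f"negative branch length on node #{node.node_id}")

    counts = _leaf_counts(tree)
    raw: Dict[str, float] = {}

    def _walk(node: TreeNode, acc: float) -> None:
        if node.parent is not None:
            acc = acc + node.length / counts[node.node_id]
        if node.is_leaf:
            raw[node.name] = acc
        else:
            for c in node.children:
                _walk(c, acc)

    _walk(tree.root, 0.0)

    values = np.array(list(raw.values()))
    if values.max() <= 0.0:
        return {name: 1.0 for name in raw}
    # Guard against zero-length pendant paths so weights stay positive.
    floor = 1e-6 * values[values > 0].mean()
    total = sum(max(v, floor) for v in raw.values())
    scale = len(raw) / total
    return {name: max(v, floor) * scale for name, v in raw.items()}


def estimate_fallback_tree(records, k: int = 12, seed: int = 0) -> GuideTree:
    """Rough guide tree from k-mer profile distances + neighbor joining.

    Intended only as a stand-in when no tree is supplied: pairwise distance
    is 1 − cosine similarity of k-mer count vectors, and the tree is built
    by neighbor joining.  Deterministic for a given input regardless of
    seed; the seed is accepted for interface uniformity.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 sequences to estimate a tree")
    names = [r.identifier for r in records]

    vectors = []
    for rec in records:
        counts: Dict[str, int] = {}
        s = rec.residues
        kk = min(k, len(s))
        for i in range(len(s) - kk + 1):
            kmer = s[i : i + kk]
            counts[kmer] = counts.get(kmer, 0) + 1
        vectors.append(counts)

    n = len(records)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = vectors[i], vectors[j]
            dot = sum(v * b.get(kmer, 0) for kmer, v in a.items())
            na = np.sqrt(sum(v * v for v in a.values()))
            nb = np.sqrt(sum(v * v for v in b.values()))
            d = 1.0 - dot / (na * nb) if na > 0 and nb > 0 else 1.0
            dist[i, j] = dist[j, i] = max(d, 0.0)

    if n == 2:
        root = TreeNode()
        root.add_child(TreeNode(name=names[0], length=dist[0, 1] / 2))
        root.add_child(TreeNode(name=names[1], length=dist[0, 1] / 2))
        return GuideTree(root)

    from skbio import DistanceMatrix
    from skbio.tree import nj

    sk_tree = nj(DistanceMatrix(dist, ids=names))

    def _convert(sk_node) -> TreeNode:
        length = sk_node.length
        if length is not None:
            length = max(float(length), 0.0)
        node = TreeNode(name=sk_node.name if sk_node.is_tip() else None, length=length)
        for child in sk_node.children:
            node.add_child(_convert(child))
        return node

    root = _convert(sk_tree.root())
    root.length = None
    return GuideTree(root)
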