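"""Synthetic data and evaluation metrics.

The simulator evolves a random root sequence down a guide tree under a
single-rate (Jukes–Cantor-style) substitution model with insertions and
deletions, tracking per-column homology so the true alignment is exact.
It exists to exercise the aligner, not to model real molecular evolution:
rate variation across sites, GTR-style exchangeabilities and structural
constraints are deliberately absent.

Metrics: sum-of-pairs false positive/negative rates against a true
alignment, and the normalized Robinson–Foulds distance between trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .guide_tree import GuideTree, TreeNode
from .seq_io import GAP, SequenceRecord

__all__ = [
    "SimulationParams",
    "TrueAlignment",
    "random_tree",
    "simulate_msa",
    "sp_error",
    "nrf_distance",
    "shuffled_column_control",
]

_BASES = "ACGT"


@dataclass
class SimulationParams:
    """Study conditions for one simulated dataset.

    ``indel_rate`` is expected indels per substitution event; indel lengths
    are geometric with the given mean; branches without lengths evolve with
    ``default_branch`` expected substitutions per site.
    """

    tree: GuideTree
    root_length: int = 500
    indel_rate: float = 0.12
    mean_indel_length: float = 3.0
    default_branch: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_length < 1:
            raise ValueError("root_length must be positive")
        if self.indel_rate < 0 or self.mean_indel_length < 1:
            raise ValueError("invalid indel parameters")


@dataclass
class TrueAlignment:
    """True simulated MSA with per-column homology identifiers."""

    rows: Dict[str, str]
    column_ids: List[int]

    @property
    def width(self) -> int:
        return len(self.column_ids)


def random_tree(
    n_leaves: int, mean_branch: float = 0.05, seed: int = 0
) -> GuideTree:
    """Random binary tree: repeatedly join two random subtrees (seeded);
    branch lengths are exponential with the given mean."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    nodes: List[TreeNode] = [
        TreeNode(name=f"t{i}", length=float(rng.exponential(mean_branch)))
        for i in range(n_leaves)
    ]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(mean_branch)))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return GuideTree(root)


def jc_identity(branch_length: float) -> float:
    """Expected fraction of identical sites after one branch under the
    single-rate model: 1 - (3/4)(1 - exp(-4b/3))."""
    return 1.0 - 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))


def _substitution_probability(branch_length: float) -> float:
    return 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))


def simulate_msa(
    params: SimulationParams,
) -> Tuple[TrueAlignment, List[SequenceRecord]]:
    """Evolve sequences down the tree, returning truth and unaligned records.

    Substitutions hit each site independently with the single-rate
    probability for the branch length; the number of indel events per branch
    is Poisson with mean indel_rate x b x L, split evenly between insertions
    and deletions, with geometric lengths.  Every column ever created gets a
    stable homology id threaded through a master column ordering, so the
    true alignment is reconstructed exactly.
    """
    rng = np.random.default_rng(params.seed)
    tree = params.tree

    next_id = itertools.count()
    root_seq: List[Tuple[int, str]] = [
        (next(next_id), _BASES[rng.integers(4)]) for _ in range(params.root_length)
    ]
    master: List[int] = [cid for cid, _ in root_seq]

    leaf_seqs: Dict[str, List[Tuple[int, str]]] = {}

    def _evolve(seq: List[Tuple[int, str]], b: float) -> List[Tuple[int, str]]:
        seq = list(seq)
        L = len(seq)
        if L and b > 0:
            p_sub = _substitution_probability(b)
            hits = np.nonzero(rng.random(L) < p_sub)[0]
            for i in hits:
                cid, old = seq[i]
                choices = [c for c in _BASES if c != old]
                seq[i] = (cid, choices[rng.integers(3)])
            n_sub_expected = b * L
            n_indels = rng.poisson(params.indel_rate * n_sub_expected)
            for _ in range(n_indels):
                length = int(rng.geometric(1.0 / params.mean_indel_length))
                if rng.random() < 0.5 and len(seq) > length:
                    start = int(rng.integers(0, len(seq) - length + 1))
                    del seq[start : start + length]
                else:
                    pos = int(rng.integers(0, len(seq) + 1))
                    new_cols = [
                        (next(next_id), _BASES[rng.integers(4)])
                        for _ in range(length)
                    ]
                    # thread the new ids into the master column ordering
                    if pos > 0:
                        anchor = master.index(seq[pos - 1][0]) + 1
                    elif seq:
                        anchor = master.index(seq[0][0])
                    else:
                        anchor = 0
                    master[anchor:anchor] = [cid for cid, _ in new_cols]
                    seq[pos:pos] = new_cols
        return seq

    def _walk(node: TreeNode, seq: List[Tuple[int, str]]) -> None:
        if node.parent is not None:
            b = node.length if node.length is not None else params.default_branch
            seq = _evolve(seq, b)
        if node.is_leaf:
            leaf_seqs[node.name] = seq
        else:
            for child in node.children:
                _walk(child, seq)

    _walk(tree.root, root_seq)

    present: Set[int] = set()
    for seq in leaf_seqs.values():
        present.update(cid for cid, _ in seq)
    column_ids = [cid for cid in master if cid in present]
    col_pos = {cid: i for i, cid in enumerate(column_ids)}

    rows: Dict[str, str] = {}
    records: List[SequenceRecord] = []
    for name in tree.leaf_names():
        seq = leaf_seqs[name]
        row = [GAP] * len(column_ids)
        for cid, base in seq:
            row[col_pos[cid]] = base
        rows[name] = "".join(row)
        records.append(SequenceRecord(name, "".join(b for _, b in seq)))

    return TrueAlignment(rows=rows, column_ids=column_ids), records


def _row_index(row: str) -> Tuple[np.ndarray, np.ndarray]:
    """Per-column residue presence and running residue index for one row."""
    arr = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
    nongap = arr != ord(GAP)
    idx = np.cumsum(nongap) - 1
    return nongap, idx


def residue_pairs(rowA: str, rowB: str) -> Set[Tuple[int, int]]:
    """Homologously aligned residue pairs of two rows: (index-in-A,
    index-in-B) for every column where both rows hold a residue."""
    ngA, idxA = _row_index(rowA)
    ngB, idxB = _row_index(rowB)
    both = ngA & ngB
    return set(zip(idxA[both].tolist(), idxB[both].tolist()))


def sp_error(
    estimated: Dict[str, str], truth: Dict[str, str]
) -> Tuple[float, float, float]:
    """Sum-of-pairs error of an estimated MSA against the truth.

    Over all sequence pairs, compares the sets of homologously aligned
    residue pairs (two residues aligned iff they share a column).  Returns
    (SPFP, SPFN, mean): SPFP is the fraction of estimated pairs absent from
    the truth, SPFN the fraction of true pairs absent from the estimate.
    """
    if set(estimated) != set(truth):
        raise ValueError("estimated and true alignments name different sequences")
    for name in estimated:
        if estimated[name].replace(GAP, "") != truth[name].replace(GAP, ""):
            raise ValueError(f"sequence content differs for {name!r}")
    names = sorted(estimated)
    est_idx = {n: _row_index(estimated[n]) for n in names}
    true_idx = {n: _row_index(truth[n]) for n in names}
    n_est = n_true = n_shared = 0
    for a, b in itertools.combinations(names, 2):
        counts = []
        codes = []
        for idx in (est_idx, true_idx):
            ngA, idxA = idx[a]
            ngB, idxB = idx[b]
            both = ngA & ngB
            # encode a residue pair (ia, ib) as one integer
            codes.append(idxA[both].astype(np.int64) * (idxB.max() + 2) + idxB[both])
            counts.append(int(both.sum()))
        n_est += counts[0]
        n_true += counts[1]
        n_shared += np.intersect1d(codes[0], codes[1], assume_unique=True).size
    spfp = (n_est - n_shared) / n_est if n_est else 0.0
    spfn = (n_true - n_shared) / n_true if n_true else 0.0
    return spfp, spfn, 0.5 * (spfp + spfn)


def _nontrivial_bipartitions(tree: GuideTree) -> Set[frozenset]:
    leaves = frozenset(tree.leaf_names())
    n = len(leaves)
    ref = min(leaves)
    out: Set[frozenset] = set()
    below: Dict[int, Set[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node.node_id] = {node.name}
            continue
        group = set()
        for c in node.children:
            group |= below[c.node_id]
        below[node.node_id] = group
        if node.parent is None:
            continue
        if 2 <= len(group) <= n - 2:
            side = frozenset(group)
            if ref in side:
                side = leaves - side
            out.add(side)
    return out


def nrf_distance(t1: GuideTree, t2: GuideTree) -> float:
    """Normalized Robinson–Foulds distance: symmetric difference of the
    nontrivial bipartitions over their total count (0 identical, 1 maximally
    different)."""
    l1, l2 = set(t1.leaf_names()), set(t2.leaf_names())
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    if len(l1) < 4:
        raise ValueError("nRF needs at least 4 leaves")
    b1 = _nontrivial_bipartitions(t1)
    b2 = _nontrivial_bipartitions(t2)
    total = len(b1) + len(b2)
    if total == 0:
        return 0.0
    return len(b1 ^ b2) / total


def shuffled_column_control(truth: TrueAlignment, seed: int = 0) -> Dict[str, str]:
    """Degenerate control: each row's residues are re-scattered over the
    alignment frame independently (residue order kept, columns randomized),
    destroying the column homology that the SP metric scores."""
    rng = np.random.default_rng(seed)
    width = truth.width
    out: Dict[str, str] = {}
    for name, row in truth.rows.items():
        residues = [c for c in row if c != GAP]
        positions = np.sort(rng.choice(width, size=len(residues), replace=False))
        new_row = [GAP] * width
        for pos, res in zip(positions, residues):
            new_row[pos] = res
        out[name] = "".join(new_row)
    return out
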