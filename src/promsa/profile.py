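"""Profile algebra.

A profile summarizes a group's alignment as an L x 6 table of weighted
character frequencies over {A, C, G, T, N, -}; every column sums to the
group's total weight.  Profiles are the unit of all alignment computation:
pairwise group alignment scores profile columns against each other, and the
merged group's profile is obtained from the two children's profiles plus the
alignment path, never from the raw rows.

Gappy columns (gap fraction strictly above a threshold) are excised before
profile alignment and restored afterwards; excised runs are anchored to the
next retained column so restoration is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np

from .seq_io import ALPHABET, ALPHABET_INDEX, GAP

N_SYMBOLS = len(ALPHABET)
GAP_IDX = ALPHABET_INDEX[GAP]

__all__ = [
    "Profile",
    "GappyColumnStore",
    "build_profile",
    "flag_gappy_columns",
    "excise_columns",
    "restore_gappy_columns",
    "apply_path_to_rows",
    "expand_profile",
    "merge_profiles",
]


@dataclass
class Profile:
    """Per-column weighted frequency table plus the group's total weight."""

    freq: np.ndarray  # shape (L, 6), nonnegative
    total_weight: float

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=np.float64)
        if self.freq.ndim != 2 or self.freq.shape[1] != N_SYMBOLS:
            raise ValueError("profile frequency table must be L x 6")
        if self.total_weight <= 0:
            raise ValueError("total weight must be positive")

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    def gap_fraction(self) -> np.ndarray:
        return self.freq[:, GAP_IDX] / self.total_weight

    def check_conservation(self, rtol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.freq.sum(axis=1), self.total_weight, rtol=rtol)
        )


@dataclass
class GappyColumnStore:
    """Excised gappy columns, grouped into runs anchored in the reduced profile.

    Each run is (anchor, columns): ``anchor`` is the reduced-profile index of
    the retained column immediately following the run (== reduced length for
    a trailing run); ``columns`` is the ordered (len, 6) block of original
    frequency columns.
    """

    runs: List[Tuple[int, np.ndarray]] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return sum(cols.shape[0] for _, cols in self.runs)

    def by_anchor(self) -> Dict[int, np.ndarray]:
        return {anchor: cols for anchor, cols in self.runs}


RowsLike = Union[Mapping[str, str], Sequence[Tuple[str, str]]]


def _row_items(rows: RowsLike) -> List[Tuple[str, str]]:
    if isinstance(rows, Mapping):
        return list(rows.items())
    return list(rows)


def build_profile(rows: RowsLike, weights: Mapping[str, float]) -> Profile:
    """Weighted character counts per column: freq[i,c] = sum_k w_k [row_k[i]=c]."""
    items = _row_items(rows)
    if not items:
        raise ValueError("cannot build a profile from zero rows")
    length = len(items[0][1])
    for ident, row in items:
        if len(row) != length:
            raise ValueError(f"ragged row {ident!r}: {len(row)} != {length}")
    freq = np.zeros((length, N_SYMBOLS))
    total = 0.0
    cols = np.arange(length)
    for ident, row in items:
        w = float(weights[ident])
        idx = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
        sym = _SYMBOL_LOOKUP[idx]
        np.add.at(freq, (cols, sym), w)
        total += w
    return Profile(freq=freq, total_weight=total)


_SYMBOL_LOOKUP = np.full(256, ALPHABET_INDEX["N"], dtype=np.int64)
for _c, _i in ALPHABET_INDEX.items():
    _SYMBOL_LOOKUP[ord(_c)] = _i


def flag_gappy_columns(p: Profile, threshold: float) -> np.ndarray:
    """Mask of columns whose gap fraction strictly exceeds the threshold."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    return p.gap_fraction() > threshold


def excise_columns(p: Profile, mask: np.ndarray) -> Tuple[Profile, GappyColumnStore]:
    """Drop masked columns, recording them as anchored runs for restoration."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (p.length,):
        raise ValueError("mask length must equal profile length")
    if mask.all():
        raise ValueError("all columns are gappy; nothing left to align")
    keep = ~mask
    reduced = Profile(freq=p.freq[keep], total_weight=p.total_weight)

    runs: List[Tuple[int, np.ndarray]] = []
    i = 0
    reduced_pos = 0
    L = p.length
    while i < L:
        if mask[i]:
            j = i
            while j < L and mask[j]:
                j += 1
            runs.append((reduced_pos, p.freq[i:j].copy()))
            i = j
        else:
            reduced_pos += 1
            i += 1
    return reduced, GappyColumnStore(runs=runs)


def apply_path_to_rows(rows: RowsLike, side_path: str) -> Dict[str, str]:
    """Insert new-gap columns into aligned rows per a binary side path.

    ``side_path`` has one character per output column: '0' consumes the next
    existing column, '1' inserts a gap in every row.  The number of '0's must
    equal the current row length.
    """
    items = _row_items(rows)
    n_keep = side_path.count("0")
    out: Dict[str, str] = {}
    template = None
    for ident, row in items:
        if len(row) != n_keep:
            raise ValueError(
                f"path consumes {n_keep} columns but row {ident!r} has {len(row)}"
            )
        if template is None:
            # positions of '0's, computed once
            template = [c == "0" for c in side_path]
        it = iter(row)
        out[ident] = "".join(next(it) if keep else GAP for keep in template)
    return out


def expand_profile(p: Profile, side_path: str) -> Profile:
    """Insert all-gap columns into a profile per a binary side path."""
    n_keep = side_path.count("0")
    if n_keep != p.length:
        raise ValueError(
            f"path consumes {n_keep} columns but profile has {p.length}"
        )
    L = len(side_path)
    freq = np.zeros((L, N_SYMBOLS))
    keep = np.frombuffer(side_path.encode("ascii"), dtype=np.uint8) == ord("0")
    freq[keep] = p.freq
    freq[~keep, GAP_IDX] = p.total_weight
    return Profile(freq=freq, total_weight=p.total_weight)


def merge_profiles(pA: Profile, pB: Profile, pathA: str, pathB: str) -> Profile:
    """Profile of the merged group: expanded child profiles added column-wise."""
    ea = expand_profile(pA, pathA)
    eb = expand_profile(pB, pathB)
    if ea.length != eb.length:
        raise ValueError("expanded profiles disagree in length")
    return Profile(freq=ea.freq + eb.freq, total_weight=ea.total_weight + eb.total_weight)


def restore_gappy_columns(result, storeA: GappyColumnStore, storeB: GappyColumnStore):
    """Re-insert excised gappy columns around a reduced-profile alignment.

    Walks the alignment of the two reduced profiles.  A run is emitted
    immediately before its anchor column is consumed.  When both sides emit
    runs at the same aligned position (a MATCH consuming both anchors, or
    trailing runs at the end), the runs are merged left-aligned: the first
    min(a, b) column pairs share output columns and the excess pairs with
    new gaps, so max(a, b) columns are emitted.  A lone run pairs entirely
    with new gaps.  The returned result carries the expanded operation list
    and per-side binary paths over the *original* (unreduced) profiles; the
    score is unchanged.
    """
    from .pair_align import AlignmentResult, MATCH, GAP_IN_A, GAP_IN_B

    runsA = storeA.by_anchor()
    runsB = storeB.by_anchor()
    if len(runsA) != len(storeA.runs) or len(runsB) != len(storeB.runs):
        raise ValueError("inconsistent anchors: duplicate run anchor")

    ops: List[str] = []
    pathA: List[str] = []
    pathB: List[str] = []

    def emit_pair(a_cols: int, b_cols: int) -> None:
        shared = min(a_cols, b_cols)
        for _ in range(shared):
            ops.append(MATCH)
            pathA.append("0")
            pathB.append("0")
        for _ in range(a_cols - shared):
            ops.append(GAP_IN_B)
            pathA.append("0")
            pathB.append("1")
        for _ in range(b_cols - shared):
            ops.append(GAP_IN_A)
            pathA.append("1")
            pathB.append("0")

    rA = rB = 0
    for op in result.ops:
        if op == MATCH:
            a = runsA.pop(rA, None)
            b = runsB.pop(rB, None)
            emit_pair(0 if a is None else a.shape[0], 0 if b is None else b.shape[0])
            ops.append(MATCH)
            pathA.append("0")
            pathB.append("0")
            rA += 1
            rB += 1
        elif op == GAP_IN_B:  # consumes a column of A only
            a = runsA.pop(rA, None)
            emit_pair(0 if a is None else a.shape[0], 0)
            ops.append(GAP_IN_B)
            pathA.append("0")
            pathB.append("1")
            rA += 1
        elif op == GAP_IN_A:  # consumes a column of B only
            b = runsB.pop(rB, None)
            emit_pair(0, 0 if b is None else b.shape[0])
            ops.append(GAP_IN_A)
            pathA.append("1")
            pathB.append("0")
            rB += 1
        else:  # pragma: no cover - defensive
            raise ValueError(f"unknown alignment op {op!r}")

    # Trailing runs anchor past the last retained column and coincide at the
    # end of the alignment, so they merge with each other.
    a = runsA.pop(rA, None)
    b = runsB.pop(rB, None)
    emit_pair(0 if a is None else a.shape[0], 0 if b is None else b.shape[0])

    if runsA or runsB:
        raise ValueError(
            f"inconsistent anchors: unconsumed runs at {sorted(runsA) + sorted(runsB)}"
        )

    return AlignmentResult(
        ops="".join(ops),
        score=result.score,
        pathA="".join(pathA),
        pathB="".join(pathB),
    )
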