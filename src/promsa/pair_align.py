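"""Pairwise profile alignment.

Global alignment of two profiles under a three-table affine-gap recurrence:

    H(i,j) = max( H(i-1,j-1), I(i-1,j-1), D(i-1,j-1) ) + ps(i,j)
    I(i,j) = max( H(i-1,j) + gopA_i,  I(i-1,j) + gepA_i )
    D(i,j) = max( H(i,j-1) + gopB_j,  D(i,j-1) + gepB_j )

where ps(i,j) is the weighted sum-of-pairs substitution score of column i of
profile A against column j of profile B.  Vertical gaps (new gaps in B)
charge profile A's per-column penalties and horizontal gaps charge B's.
Note that I opens only from H and D only from H: a vertical gap cannot
immediately follow a horizontal one without an intervening match.
Boundaries: H(0,0)=0, H(i,0)=I(i,0), H(0,j)=D(0,j); the first row/column
accrue gop + (k-1)*gep.

Three entry points share one anti-diagonal (wavefront) engine so their
results are bit-identical whenever they complete:

* :func:`align_profiles_full` — every cell, exact optimum;
* :func:`align_profiles_banded` — X-drop pruning: cells scoring more than
  ``xdrop`` below the running best are dropped (``BAND_FAIL`` if the band
  dies or the end cell is pruned);
* :func:`align_profiles_tiled` — X-drop plus constant-memory traceback.
  Full traceback pointers are kept only for a bounded window of wavefronts
  (a tile); past the tile's boundary pair of wavefronts (the marker), each
  live DP entry carries a single convergence pointer to the boundary entry
  its best path last crossed.  Once every live pointer agrees, the tile is
  traced back and the next tile starts at the convergence point, so pointer
  storage depends on the tile size, never on sequence length.  Wavefronts
  wider than the tile size, or failure to converge within a tile's worth of
  wavefronts, give ``TILE_FAIL``.

Ties in every max prefer the diagonal source (H), then vertical (I), then
horizontal (D), making tracebacks deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .profile import Profile
from .seq_io import ALPHABET_INDEX

MATCH = "M"
GAP_IN_B = "B"  # consumes a column of A; new gap in B
GAP_IN_A = "A"  # consumes a column of B; new gap in A

_NEG = -1.0e30
_DEAD = -1.0e29  # anything below this counts as unreachable

# traceback pointer codes
_FROM_H, _FROM_I, _FROM_D = 0, 1, 2
_MIRROR_D, _MIRROR_I = 4, 5  # boundary cells where H mirrors D or I

__all__ = [
    "MATCH",
    "GAP_IN_A",
    "GAP_IN_B",
    "SubstitutionScheme",
    "AlignmentResult",
    "BAND_FAIL",
    "TILE_FAIL",
    "default_scheme",
    "position_gap_penalties",
    "profile_cell_score",
    "align_profiles_full",
    "align_profiles_banded",
    "align_profiles_tiled",
    "align_with_fallback",
]


class _AlignFailure:
    """Typed non-result: banding or tiling could not complete."""

    def __init__(self, name: str) -> None:
        self.name = name

    def __repr__(self) -> str:
        return self.name

    def __bool__(self) -> bool:
        return False


BAND_FAIL = _AlignFailure("BAND_FAIL")
TILE_FAIL = _AlignFailure("TILE_FAIL")


@dataclass(frozen=True)
class SubstitutionScheme:
    """6x6 symmetric score table plus affine gap penalties.

    ``gop``/``gep`` are the (negative) gap-open and gap-extension penalties;
    ``psgp_enabled`` switches on position-specific penalties for columns
    that already contain gaps.
    """

    s: np.ndarray
    gop: float
    gep: float
    psgp_enabled: bool = False

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=np.float64)
        if s.shape != (6, 6):
            raise ValueError("substitution table must be 6x6")
        if not np.array_equal(s, s.T):
            raise ValueError("substitution table must be symmetric")
        if not (self.gop <= self.gep <= 0):
            raise ValueError("require gop <= gep <= 0")
        object.__setattr__(self, "s", s)

    def score(self, p: str, q: str) -> float:
        return float(self.s[ALPHABET_INDEX[p], ALPHABET_INDEX[q]])


def default_scheme(psgp_enabled: bool = False) -> SubstitutionScheme:
    """Default nucleotide scoring: +18 match, +5 transition, -8 transversion.

    Gap mismatches score -5 for every residue (including N); N against any
    non-gap symbol and gap-against-gap are neutral (0).  Gap open -50, gap
    extend -5.
    """
    s = np.zeros((6, 6))
    purines = {"A", "G"}
    pyrimidines = {"C", "T"}
    for p in "ACGT":
        for q in "ACGT":
            i, j = ALPHABET_INDEX[p], ALPHABET_INDEX[q]
            if p == q:
                s[i, j] = 18.0
            elif (p in purines and q in purines) or (
                p in pyrimidines and q in pyrimidines
            ):
                s[i, j] = 5.0
            else:
                s[i, j] = -8.0
    gap = ALPHABET_INDEX["-"]
    for p in "ACGTN":
        s[ALPHABET_INDEX[p], gap] = -5.0
        s[gap, ALPHABET_INDEX[p]] = -5.0
    # N is neutral against non-gap symbols; gap-gap is neutral.
    return SubstitutionScheme(s=s, gop=-50.0, gep=-5.0, psgp_enabled=psgp_enabled)


@dataclass
class AlignmentResult:
    """A pairwise profile alignment.

    ``ops`` is the operation string over {M, B, A}; ``pathA``/``pathB`` are
    the per-side binary strings ('0' = consume the next existing column of
    that profile, '1' = insert a new gap).  ``pointer_cells`` reports the
    peak number of traceback pointers held at once (meaningful for the
    tiled engine).
    """

    ops: str
    score: float
    pathA: str
    pathB: str
    pointer_cells: int = 0

    def __post_init__(self) -> None:
        if not (len(self.ops) == len(self.pathA) == len(self.pathB)):
            raise ValueError("ops and paths must have equal length")


def _paths_from_ops(ops: str) -> Tuple[str, str]:
    pathA = "".join("0" if op in (MATCH, GAP_IN_B) else "1" for op in ops)
    pathB = "".join("0" if op in (MATCH, GAP_IN_A) else "1" for op in ops)
    return pathA, pathB


def position_gap_penalties(
    p: Profile, scheme: SubstitutionScheme
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-column gap penalties: cheaper gaps where gaps already exist.

    Columns with any gap frequency get open = gop * 0.3 * (1 - gap_fraction)
    and extend = 0.5 * gep; gap-free columns keep (gop, gep).
    """
    gap_frac = p.gap_fraction()
    has_gap = gap_frac > 0
    gop = np.where(has_gap, scheme.gop * 0.3 * (1.0 - gap_frac), scheme.gop)
    gep = np.where(has_gap, 0.5 * scheme.gep, scheme.gep)
    return gop, gep


def profile_cell_score(
    pA: Profile, i: int, pB: Profile, j: int, scheme: SubstitutionScheme
) -> float:
    """Weighted sum-of-pairs score of column i of A against column j of B:
    (1 / (wA wB)) * sum_p sum_q fA[i,p] fB[j,q] s(p,q)."""
    if pA.total_weight <= 0 or pB.total_weight <= 0:
        raise ValueError("profiles must have positive total weight")
    return float(
        pA.freq[i] @ scheme.s @ pB.freq[j] / (pA.total_weight * pB.total_weight)
    )


def _cell_score_matrix(
    pA: Profile, pB: Profile, scheme: SubstitutionScheme
) -> np.ndarray:
    return (pA.freq @ scheme.s) @ pB.freq.T / (pA.total_weight * pB.total_weight)


def _gap_penalty_arrays(
    p: Profile, scheme: SubstitutionScheme
) -> Tuple[np.ndarray, np.ndarray]:
    if scheme.psgp_enabled:
        return position_gap_penalties(p, scheme)
    L = p.length
    return np.full(L, scheme.gop), np.full(L, scheme.gep)


def _take(arr: Optional[np.ndarray], arr_lo: int, want_lo: int, size: int) -> np.ndarray:
    """Slice ``arr`` (aligned at row index arr_lo) onto rows
    [want_lo, want_lo + size), padding out-of-range entries with the
    unreachable sentinel."""
    out = np.full(size, _NEG)
    if arr is None or arr.size == 0:
        return out
    a0 = want_lo - arr_lo
    s0 = max(a0, 0)
    s1 = min(a0 + size, arr.size)
    if s1 > s0:
        out[s0 - a0 : s1 - a0] = arr[s0:s1]
    return out


def _take_conv(
    arr: Optional[np.ndarray], arr_lo: int, want_lo: int, size: int
) -> np.ndarray:
    out = np.full(size, -1, dtype=np.int64)
    if arr is None or arr.size == 0:
        return out
    a0 = want_lo - arr_lo
    s0 = max(a0, 0)
    s1 = min(a0 + size, arr.size)
    if s1 > s0:
        out[s0 - a0 : s1 - a0] = arr[s0:s1]
    return out


class _PointerStore:
    """Per-wavefront traceback pointers, with peak-usage accounting."""

    def __init__(self) -> None:
        self.data: Dict[int, Tuple[int, np.ndarray, np.ndarray, np.ndarray]] = {}
        self.peak_cells = 0

    def put(self, k: int, lo: int, pH: np.ndarray, pI: np.ndarray, pD: np.ndarray) -> None:
        self.data[k] = (lo, pH, pI, pD)
        cells = sum(arrs[1].size for arrs in self.data.values())
        self.peak_cells = max(self.peak_cells, cells)

    def clear(self) -> None:
        self.data.clear()


def _traceback(
    store: _PointerStore,
    i: int,
    k: int,
    state: int,
    origin: Tuple[int, int, int],
) -> List[str]:
    """Walk pointers from (row i, wavefront k, state) back to the origin
    (exclusive); returns the ops in forward order."""
    oi, ok, ostate = origin
    rev: List[str] = []
    while k > ok:
        lo, pH, pI, pD = store.data[k]
        pos = i - lo
        if state == _FROM_H:
            code = int(pH[pos])
            if code == _MIRROR_D:
                state = _FROM_D
                continue
            if code == _MIRROR_I:
                state = _FROM_I
                continue
            rev.append(MATCH)
            i -= 1
            k -= 2
            state = code
        elif state == _FROM_I:
            code = int(pI[pos])
            rev.append(GAP_IN_B)
            i -= 1
            k -= 1
            state = _FROM_H if code == _FROM_H else _FROM_I
        else:
            code = int(pD[pos])
            rev.append(GAP_IN_A)
            k -= 1
            state = _FROM_H if code == _FROM_H else _FROM_D
    if i != oi or state != ostate:
        raise RuntimeError(
            "traceback did not land on the tile origin "
            f"(got row {i} state {state}, expected row {oi} state {ostate})"
        )
    rev.reverse()
    return rev


def _live_conv_values(wf) -> set:
    (_, H, I, D, cH, cI, cD) = wf
    values = set()
    for table, conv in ((H, cH), (I, cI), (D, cD)):
        if conv is None:
            continue
        values.update(np.unique(conv[table > _DEAD]).tolist())
    values.discard(-1)
    return values


_INITIAL_WF = (
    0,
    np.array([0.0]),
    np.array([_NEG]),
    np.array([_NEG]),
    None,
    None,
    None,
)


def _snap_to_wf(snap) -> tuple:
    lo, H, I, D, _best, _window = snap
    return (lo, H, I, D, None, None, None)


def _wavefront_align(
    PS: np.ndarray,
    gopA: np.ndarray,
    gepA: np.ndarray,
    gopB: np.ndarray,
    gepB: np.ndarray,
    xdrop: Optional[float] = None,
    width_cap: Optional[int] = None,
    tile_size: Optional[int] = None,
):
    """Shared wavefront engine; see module docstring for the three modes.

    Returns an :class:`AlignmentResult`, or ``BAND_FAIL``/``TILE_FAIL``.
    """
    LA, LB = PS.shape
    nk = LA + LB
    store = _PointerStore()

    if nk == 0:
        return AlignmentResult(ops="", score=0.0, pathA="", pathB="")

    tiled = tile_size is not None
    origin = (0, 0, _FROM_H)  # (row, wavefront, state)
    origin_wf = _INITIAL_WF
    w0 = 0
    marker = w0 + tile_size if tiled else nk + 1
    segments: List[List[str]] = []
    snapshots: Dict[int, tuple] = {}
    best = 0.0
    replaying = False  # after a terminal-in-phase-2 rewind

    prev2 = None
    prev = _INITIAL_WF
    window = (0, 0)  # candidate row range for the next wavefront
    prev_dead = False  # a single dead wavefront can be skipped diagonally

    k = 1
    while k <= nk:
        phase2 = tiled and k > marker
        if phase2 and not replaying and k - marker > tile_size:
            return TILE_FAIL

        lo = max(0, k - LB, window[0])
        hi = min(LA, k, window[1] + 1)
        if lo > hi:
            return BAND_FAIL
        size = hi - lo + 1
        i_vec = np.arange(lo, hi + 1)
        j_vec = k - i_vec

        (plo, pH_, pI_, pD_, cH_, cI_, cD_) = prev
        Hup = _take(pH_, plo, lo - 1, size)
        Iup = _take(pI_, plo, lo - 1, size)
        Hleft = _take(pH_, plo, lo, size)
        Dleft = _take(pD_, plo, lo, size)
        if prev2 is not None:
            (qlo, qH, qI, qD, _, _, _) = prev2
            Hd = _take(qH, qlo, lo - 1, size)
            Id = _take(qI, qlo, lo - 1, size)
            Dd = _take(qD, qlo, lo - 1, size)
        else:
            Hd = Id = Dd = np.full(size, _NEG)

        iA = np.clip(i_vec - 1, 0, max(LA - 1, 0))
        jB = np.clip(j_vec - 1, 0, max(LB - 1, 0))
        gopA_c = gopA[iA] if LA else np.zeros(size)
        gepA_c = gepA[iA] if LA else np.zeros(size)
        gopB_c = gopB[jB] if LB else np.zeros(size)
        gepB_c = gepB[jB] if LB else np.zeros(size)

        I_open = Hup + gopA_c
        I_ext = Iup + gepA_c
        I_new = np.maximum(I_open, I_ext)
        pI = np.where(I_open >= I_ext, _FROM_H, _FROM_I).astype(np.int8)

        D_open = Hleft + gopB_c
        D_ext = Dleft + gepB_c
        D_new = np.maximum(D_open, D_ext)
        pD = np.where(D_open >= D_ext, _FROM_H, _FROM_D).astype(np.int8)

        diag_best = Hd.copy()
        pH = np.full(size, _FROM_H, dtype=np.int8)
        better = Id > diag_best
        diag_best[better] = Id[better]
        pH[better] = _FROM_I
        better = Dd > diag_best
        diag_best[better] = Dd[better]
        pH[better] = _FROM_D
        valid_diag = (i_vec >= 1) & (j_vec >= 1)
        ps_vec = np.zeros(size)
        if valid_diag.any():
            ps_vec[valid_diag] = PS[i_vec[valid_diag] - 1, j_vec[valid_diag] - 1]
        H_new = diag_best + ps_vec

        # boundary mirrors: H(i,0) = I(i,0), H(0,j) = D(0,j)
        at_j0 = j_vec == 0
        at_i0 = i_vec == 0
        H_new[at_j0] = I_new[at_j0]
        pH[at_j0] = _MIRROR_I
        H_new[at_i0] = D_new[at_i0]
        pH[at_i0] = _MIRROR_D

        value = np.maximum(H_new, np.maximum(I_new, D_new))
        alive = value > _DEAD
        if xdrop is not None:
            alive &= value >= best - xdrop
        if not alive.any():
            # Diagonal moves jump two wavefronts, so one dead wavefront can
            # still be crossed; two in a row cannot.
            if prev_dead or k == nk:
                return BAND_FAIL
            prev_dead = True
            if (not tiled) or k <= marker:
                store.put(k, lo, pH, pI, pD)
            H_new[:] = _NEG
            I_new[:] = _NEG
            D_new[:] = _NEG
            if tiled and not replaying and marker - 2 <= k <= marker:
                snapshots[k] = (
                    lo,
                    H_new.copy(),
                    I_new.copy(),
                    D_new.copy(),
                    best,
                    (window[0] + 1, window[1] + 1),
                )
            prev2 = prev
            prev = (lo, H_new, I_new, D_new, None, None, None)
            window = (window[0] + 1, window[1] + 1)
            k += 1
            continue
        prev_dead = False
        H_new[~alive] = _NEG
        I_new[~alive] = _NEG
        D_new[~alive] = _NEG

        alive_idx = np.nonzero(alive)[0]
        lo_alive = lo + int(alive_idx[0])
        hi_alive = lo + int(alive_idx[-1])
        if width_cap is not None and hi_alive - lo_alive + 1 > width_cap:
            return TILE_FAIL
        best = max(best, float(value[alive].max()))

        # convergence pointers (tiled): every path leaving the stored window
        # last touches a cell on wavefront marker-1 or marker, so entries on
        # those two wavefronts self-encode and later entries inherit the
        # pointer of their chosen predecessor.
        cH = cI = cD = None
        if tiled and not replaying:
            if k in (marker - 1, marker):
                which = 1 if k == marker else 0
                base = (i_vec.astype(np.int64) * 4) * 2 + which
                cH = np.where(H_new > _DEAD, base + _FROM_H * 2, -1)
                cI = np.where(I_new > _DEAD, base + _FROM_I * 2, -1)
                cD = np.where(D_new > _DEAD, base + _FROM_D * 2, -1)
            elif k > marker:
                cH_up = _take_conv(cH_, plo, lo - 1, size)
                cI_up = _take_conv(cI_, plo, lo - 1, size)
                cH_left = _take_conv(cH_, plo, lo, size)
                cD_left = _take_conv(cD_, plo, lo, size)
                if prev2 is not None:
                    (qlo, _, _, _, qcH, qcI, qcD) = prev2
                    cH_d = _take_conv(qcH, qlo, lo - 1, size)
                    cI_d = _take_conv(qcI, qlo, lo - 1, size)
                    cD_d = _take_conv(qcD, qlo, lo - 1, size)
                else:
                    cH_d = cI_d = cD_d = np.full(size, -1, dtype=np.int64)
                cI = np.where(pI == _FROM_H, cH_up, cI_up)
                cD = np.where(pD == _FROM_H, cH_left, cD_left)
                cH = np.where(
                    pH == _FROM_H, cH_d, np.where(pH == _FROM_I, cI_d, cD_d)
                )
                cH = np.where(pH == _MIRROR_I, cI, cH)
                cH = np.where(pH == _MIRROR_D, cD, cH)
                cH = np.where(H_new > _DEAD, cH, -1)
                cI = np.where(I_new > _DEAD, cI, -1)
                cD = np.where(D_new > _DEAD, cD, -1)

        if (not tiled) or k <= marker:
            store.put(k, lo, pH, pI, pD)

        cur = (lo, H_new, I_new, D_new, cH, cI, cD)

        if tiled and not replaying and marker - 2 <= k <= marker:
            snapshots[k] = (
                lo,
                H_new.copy(),
                I_new.copy(),
                D_new.copy(),
                best,
                (lo_alive, hi_alive),
            )

        if k == nk:
            ti = LA - lo
            if not (0 <= ti < size) or not alive[ti]:
                return BAND_FAIL
            if tiled and k > marker and not replaying:
                # The end cell lies beyond the stored window: rewind scoring
                # to the marker snapshot and replay with pointers kept,
                # extending the window by one tile (the end is at most
                # tile_size wavefronts past the marker).
                old_marker = marker
                snap = snapshots[old_marker]
                prev = _snap_to_wf(snap)
                if old_marker - 1 == w0:
                    prev2 = origin_wf
                else:
                    prev2 = _snap_to_wf(snapshots[old_marker - 1])
                best = snap[4]
                window = snap[5]
                prev_dead = not bool(np.max(prev[1]) > _DEAD or np.max(prev[2]) > _DEAD or np.max(prev[3]) > _DEAD)
                marker = old_marker + tile_size
                replaying = True
                k = old_marker + 1
                continue
            cand = [
                (float(H_new[ti]), _FROM_H),
                (float(I_new[ti]), _FROM_I),
                (float(D_new[ti]), _FROM_D),
            ]
            score, state = max(cand, key=lambda t: (t[0], -t[1]))
            segments.append(_traceback(store, LA, nk, state, origin))
            ops = "".join("".join(seg) for seg in segments)
            pathA, pathB = _paths_from_ops(ops)
            return AlignmentResult(
                ops=ops,
                score=score,
                pathA=pathA,
                pathB=pathB,
                pointer_cells=store.peak_cells,
            )

        # convergence check (phase 2): only the last two wavefronts can feed
        # future cells, so their live pointers decide.
        if phase2 and not replaying:
            conv = _live_conv_values(cur) | _live_conv_values(prev)
            if len(conv) == 1:
                target = conv.pop()
                which = target & 1
                mi, mstate = divmod(target >> 1, 4)
                mk = marker - 1 + which
                segments.append(_traceback(store, mi, mk, mstate, origin))
                origin = (mi, mk, mstate)
                store.clear()
                snap = snapshots[mk]
                if mk - 1 in snapshots:
                    prev2 = _snap_to_wf(snapshots[mk - 1])
                else:
                    # mk-1 is the old tile origin's wavefront (tile_size == 2)
                    prev2 = origin_wf
                origin_wf = _snap_to_wf(snap)
                prev = origin_wf
                w0 = mk
                best = snap[4]
                window = snap[5]
                prev_dead = not bool(np.max(prev[1]) > _DEAD or np.max(prev[2]) > _DEAD or np.max(prev[3]) > _DEAD)
                k = mk + 1
                marker = mk + tile_size
                snapshots = {}
                continue

        prev2 = prev
        prev = cur
        window = (lo_alive, hi_alive)
        k += 1

    raise RuntimeError("wavefront loop exited without reaching the end cell")


def _prepare(pA: Profile, pB: Profile, scheme: SubstitutionScheme):
    PS = _cell_score_matrix(pA, pB, scheme)
    gopA, gepA = _gap_penalty_arrays(pA, scheme)
    gopB, gepB = _gap_penalty_arrays(pB, scheme)
    return PS, gopA, gepA, gopB, gepB


def align_profiles_full(
    pA: Profile, pB: Profile, scheme: SubstitutionScheme
) -> AlignmentResult:
    """Exact global optimum over every DP cell (the oracle backend)."""
    return _wavefront_align(*_prepare(pA, pB, scheme))


def align_profiles_banded(
    pA: Profile, pB: Profile, scheme: SubstitutionScheme, xdrop: float
):
    """X-drop banded DP; equals the full DP when the optimum stays in band."""
    if xdrop < 0:
        raise ValueError("xdrop must be nonnegative")
    return _wavefront_align(*_prepare(pA, pB, scheme), xdrop=xdrop)


def align_profiles_tiled(
    pA: Profile,
    pB: Profile,
    scheme: SubstitutionScheme,
    tile_size: int,
    xdrop: float,
):
    """Banded DP with tiled constant-memory traceback (see module docstring)."""
    if tile_size < 2:
        raise ValueError("tile_size must be >= 2")
    return _wavefront_align(
        *_prepare(pA, pB, scheme),
        xdrop=xdrop,
        width_cap=tile_size,
        tile_size=tile_size,
    )


def align_with_fallback(
    pA: Profile, pB: Profile, scheme: SubstitutionScheme, config
) -> AlignmentResult:
    """Tiled first; on BAND_FAIL/TILE_FAIL fall back to the full DP."""
    xdrop = config.effective_xdrop(scheme.gep)
    result = align_profiles_tiled(pA, pB, scheme, config.tile_size, xdrop)
    if isinstance(result, _AlignFailure):
        result = align_profiles_full(pA, pB, scheme)
    return result
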