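"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's DP engine: a brute-force
path enumerator and a plain-Python three-table DP serve as references for
the wavefront implementation.
"""

from __future__ import annotations

import itertools
import random
from typing import Dict, List, Optional, Tuple

import numpy as np
import pytest

from promsa.profile import Profile, build_profile
from promsa.pair_align import SubstitutionScheme, default_scheme, profile_cell_score

NEG = -1.0e30


@pytest.fixture(scope="session")
def scheme() -> SubstitutionScheme:
    return default_scheme()


def single_profile(seq: str, weight: float = 1.0) -> Profile:
    """Profile of one ungapped sequence with the given weight."""
    if not seq:
        return Profile(freq=np.zeros((0, 6)), total_weight=weight)
    return build_profile({"_": seq}, {"_": weight})


def random_profile(rng: random.Random, length: int, n_rows: int = 3) -> Profile:
    """Profile built from a random small alignment with random weights."""
    rows = {}
    weights = {}
    for r in range(n_rows):
        rows[f"r{r}"] = "".join(rng.choice("ACGTN-") for _ in range(length))
        weights[f"r{r}"] = rng.uniform(0.2, 2.0)
    # avoid all-gap rows producing empty effective content; profiles allow it
    return build_profile(rows, weights)


def mutate_sequence(rng: random.Random, s: str, psub: float, pindel: float) -> str:
    out: List[str] = []
    for c in s:
        x = rng.random()
        if x < pindel / 2:
            continue
        if x < pindel:
            out.append(c)
            out.append(rng.choice("ACGT"))
        elif x < pindel + psub:
            out.append(rng.choice("ACGT"))
        else:
            out.append(c)
    return "".join(out) or rng.choice("ACGT")


def dp_oracle_score(
    pA: Profile,
    pB: Profile,
    scheme: SubstitutionScheme,
    gapsA: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    gapsB: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> float:
    """Independent plain-Python evaluation of the three-table recurrence."""
    la, lb = pA.length, pB.length
    PS = [
        [profile_cell_score(pA, i, pB, j, scheme) for j in range(lb)]
        for i in range(la)
    ]
    gopA, gepA = gapsA if gapsA else ([scheme.gop] * la, [scheme.gep] * la)
    gopB, gepB = gapsB if gapsB else ([scheme.gop] * lb, [scheme.gep] * lb)
    H = [[NEG] * (lb + 1) for _ in range(la + 1)]
    I = [[NEG] * (lb + 1) for _ in range(la + 1)]
    D = [[NEG] * (lb + 1) for _ in range(la + 1)]
    H[0][0] = 0.0
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 and j == 0:
                continue
            if i >= 1:
                I[i][j] = max(H[i - 1][j] + gopA[i - 1], I[i - 1][j] + gepA[i - 1])
            if j >= 1:
                D[i][j] = max(H[i][j - 1] + gopB[j - 1], D[i][j - 1] + gepB[j - 1])
            if i >= 1 and j >= 1:
                H[i][j] = (
                    max(H[i - 1][j - 1], I[i - 1][j - 1], D[i - 1][j - 1])
                    + PS[i - 1][j - 1]
                )
            elif j == 0:
                H[i][j] = I[i][j]
            else:
                H[i][j] = D[i][j]
    return max(H[la][lb], I[la][lb], D[la][lb])


def enumerate_alignment_score(
    pA: Profile, pB: Profile, scheme: SubstitutionScheme
) -> float:
    """Exhaustive enumeration over every legal alignment path (tiny inputs).

    Paths are monotone walks of M/B/A ops with the affine state machine
    (a vertical gap opens only after a match or at the start of its run's
    row context, mirroring the recurrence).
    """
    la, lb = pA.length, pB.length
    PS = [
        [profile_cell_score(pA, i, pB, j, scheme) for j in range(lb)]
        for i in range(la)
    ]
    best = [NEG]

    def rec(i: int, j: int, state: str, score: float) -> None:
        if i == la and j == lb:
            best[0] = max(best[0], score)
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, "H", score + PS[i][j])
        if i < la:
            if state in ("H", "I"):
                pen = scheme.gop if state == "H" else scheme.gep
                rec(i + 1, j, "I", score + pen)
            elif state == "D" and i == 0:
                # boundary mirror H(0,j) = D(0,j): I may open along the top row
                rec(i + 1, j, "I", score + scheme.gop)
        if j < lb:
            if state in ("H", "D"):
                pen = scheme.gop if state == "H" else scheme.gep
                rec(i, j + 1, "D", score + pen)
            elif state == "I" and j == 0:
                # boundary mirror H(i,0) = I(i,0): D may open along the left column
                rec(i, j + 1, "D", score + scheme.gop)

    rec(0, 0, "H", 0.0)
    return best[0]
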