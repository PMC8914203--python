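"""Minimum-free-energy RNA secondary structure for short windows.

A Zuker-style dynamic program over nested (pseudoknot-free) structures with
nearest-neighbour stacking energies and tabulated loop initiation terms
(Turner-2004-style parameters; no dangles, no coaxial stacking, no terminal
mismatches).  The model is deliberately desk-scale: it is exact under its own
energy function, which :func:`structure_energy` evaluates for an arbitrary
structure so that the DP can be checked against exhaustive enumeration on
short sequences.  Absolute free energies differ somewhat from full-featured
folding engines, so thresholds derived from them (e.g. the structured/
unstructured split) are configuration-exposed rather than hard-coded; a
different engine can be plugged in wherever a ``fold_fn`` argument is
accepted.

Energies are kcal/mol at 37 C; allowed pairs are Watson-Crick plus GU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

INF = 1e9
MIN_HAIRPIN = 3  # minimum unpaired bases closed by a pair
MAXLOOP = 30  # largest bulge/internal loop considered by the DP

# multiloop affine model: a + b * branches (closing pair included) + c * unpaired
ML_CLOSE = 3.4
ML_BRANCH = 0.4
ML_UNPAIRED = 0.0

_BASES = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

# pair-type indices: 0 CG, 1 GC, 2 GU, 3 UG, 4 AU, 5 UA, -1 unpairable
_PAIR_TYPE = -np.ones((4, 4), dtype=np.int64)
for _idx, (_a, _b) in enumerate([(1, 2), (2, 1), (2, 3), (3, 2), (0, 3), (3, 0)]):
    _PAIR_TYPE[_a, _b] = _idx

# stacking free energies: row = outer pair (i,j), column = inner pair (i+1,j-1)
#                 CG     GC     GU     UG     AU     UA
_STACK = np.array(
    [
        [-3.3, -2.4, -1.4, -2.1, -2.1, -2.1],  # CG
        [-3.4, -3.3, -1.5, -2.5, -2.4, -2.2],  # GC
        [-2.5, -2.1, -0.5, +1.3, -1.3, -1.4],  # GU
        [-1.5, -1.4, +0.3, -0.5, -1.0, -0.6],  # UG
        [-2.2, -2.1, -0.6, -1.4, -0.9, -1.1],  # AU
        [-2.4, -2.1, -1.0, -1.3, -1.3, -0.9],  # UA
    ]
)

_RT_JS = 1.75 * 0.616  # Jacobson-Stockmayer extrapolation coefficient


def _loop_tables(max_len: int = 400):
    hairpin = np.full(max_len + 1, INF)
    bulge = np.full(max_len + 1, INF)
    internal = np.full(max_len + 1, INF)
    h0 = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
    b0 = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
    i0 = {2: 1.5, 3: 1.8, 4: 2.0, 5: 2.2, 6: 2.5}
    for n in range(3, max_len + 1):
        hairpin[n] = h0[n] if n <= 9 else h0[9] + _RT_JS * np.log(n / 9.0)
    for n in range(1, max_len + 1):
        bulge[n] = b0[n] if n <= 6 else b0[6] + _RT_JS * np.log(n / 6.0)
    for n in range(2, max_len + 1):
        internal[n] = i0[n] if n <= 6 else i0[6] + _RT_JS * np.log(n / 6.0)
    return hairpin, bulge, internal


_HAIRPIN, _BULGE, _INTERNAL = _loop_tables()


def encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    try:
        return np.array([_BASES[ch] for ch in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGU/T character in sequence: {exc}") from None


@njit(cache=False)
def _fill(codes, pair_type, stack, hairpin, bulge, internal, a, b, c):  # pragma: no cover
    n = codes.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            pt = pair_type[codes[i], codes[j]]
            if pt >= 0:
                best = hairpin[j - i - 1]
                # single enclosed pair: stack, bulge, or internal loop
                for k in range(i + 1, j - MIN_HAIRPIN - 1):
                    left = k - i - 1
                    if left > MAXLOOP:
                        break
                    for l in range(k + MIN_HAIRPIN + 1, j):
                        right = j - l - 1
                        size = left + right
                        if size > MAXLOOP:
                            continue
                        if V[k, l] >= INF:
                            continue
                        ptin = pair_type[codes[k], codes[l]]
                        if ptin < 0:
                            continue
                        if size == 0:
                            e = stack[pt, ptin]
                        elif left == 0 or right == 0:
                            e = bulge[size]
                        else:
                            e = internal[size]
                        cand = V[k, l] + e
                        if cand < best:
                            best = cand
                # multiloop: at least two branches inside
                for k in range(i + 2, j - 1):
                    if WM[i + 1, k - 1] < INF and WM[k, j - 1] < INF:
                        cand = a + b + WM[i + 1, k - 1] + WM[k, j - 1]
                        if cand < best:
                            best = cand
                V[i, j] = best
            # WM: segment of a multiloop holding >= 1 branch
            best = INF
            if i + 1 <= j and WM[i + 1, j] < INF:
                best = WM[i + 1, j] + c
            if j - 1 >= i and WM[i, j - 1] < INF and WM[i, j - 1] + c < best:
                best = WM[i, j - 1] + c
            if V[i, j] < INF and V[i, j] + b < best:
                best = V[i, j] + b
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] < INF and WM[k, j] < INF:
                    cand = WM[i, k - 1] + WM[k, j]
                    if cand < best:
                        best = cand
            WM[i, j] = best
    W = np.zeros(n)
    for j in range(n):
        best = W[j - 1] if j > 0 else 0.0
        for i in range(0, j):
            if V[i, j] < INF:
                prev = W[i - 1] if i > 0 else 0.0
                cand = prev + V[i, j]
                if cand < best:
                    best = cand
        if V[0, j] < INF and V[0, j] < best:
            best = V[0, j]
        W[j] = best
    return V, WM, W


def _loop_energy(codes, i, j, k, l):
    """Energy of the two-pair loop closed by (i,j) enclosing (k,l)."""
    left = k - i - 1
    right = j - l - 1
    size = left + right
    if size == 0:
        return _STACK[_PAIR_TYPE[codes[i], codes[j]], _PAIR_TYPE[codes[k], codes[l]]]
    if left == 0 or right == 0:
        return _BULGE[size]
    return _INTERNAL[size]


@dataclass
class FoldResult:
    sequence: str
    dG: float  # kcal/mol, <= 0 (0 means the open chain is optimal)
    pairs: list[tuple[int, int]]  # 0-based (i, j), i < j


def fold_energy(sequence: str) -> FoldResult:
    """Minimum-free-energy structure of ``sequence`` under the package model.

    Deterministic; raises on non-ACGU/T characters and on sequences longer
    than 200 nt (cubic DP cost bound).
    """
    if len(sequence) > 200:
        raise ValueError("sequence longer than 200 nt")
    codes = encode(sequence)
    n = len(codes)
    if n < MIN_HAIRPIN + 2:
        return FoldResult(sequence, 0.0, [])
    V, WM, W = _fill(
        codes, _PAIR_TYPE, _STACK, _HAIRPIN, _BULGE, _INTERNAL,
        ML_CLOSE, ML_BRANCH, ML_UNPAIRED,
    )
    dG = float(W[n - 1])
    if dG >= -1e-9:
        return FoldResult(sequence, 0.0, [])
    pairs = _traceback(codes, V, WM, W)
    return FoldResult(sequence, dG, sorted(pairs))


_EPS = 1e-6


def _traceback(codes, V, WM, W):
    n = len(codes)
    pairs: list[tuple[int, int]] = []
    stack: list[tuple] = [("W", n - 1)]
    while stack:
        item = stack.pop()
        if item[0] == "W":
            j = item[1]
            if j < 0:
                continue
            if j > 0 and abs(W[j] - W[j - 1]) < _EPS:
                stack.append(("W", j - 1))
                continue
            done = False
            for i in range(0, j + 1):
                prev = W[i - 1] if i > 0 else 0.0
                if V[i, j] < INF and abs(W[j] - (prev + V[i, j])) < _EPS:
                    stack.append(("V", i, j))
                    if i > 0:
                        stack.append(("W", i - 1))
                    done = True
                    break
            if not done and j > 0:
                stack.append(("W", j - 1))
        elif item[0] == "V":
            _, i, j = item
            pairs.append((i, j))
            e = V[i, j]
            if abs(e - _HAIRPIN[j - i - 1]) < _EPS:
                continue
            found = False
            for k in range(i + 1, j - MIN_HAIRPIN - 1):
                if k - i - 1 > MAXLOOP:
                    break
                for l in range(k + MIN_HAIRPIN + 1, j):
                    if (k - i - 1) + (j - l - 1) > MAXLOOP:
                        continue
                    if V[k, l] >= INF or _PAIR_TYPE[codes[k], codes[l]] < 0:
                        continue
                    if abs(e - (V[k, l] + _loop_energy(codes, i, j, k, l))) < _EPS:
                        stack.append(("V", k, l))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            for k in range(i + 2, j - 1):
                cand = ML_CLOSE + ML_BRANCH + WM[i + 1, k - 1] + WM[k, j - 1]
                if WM[i + 1, k - 1] < INF and WM[k, j - 1] < INF and abs(e - cand) < _EPS:
                    stack.append(("WM", i + 1, k - 1))
                    stack.append(("WM", k, j - 1))
                    break
        else:  # WM
            _, i, j = item
            e = WM[i, j]
            if V[i, j] < INF and abs(e - (V[i, j] + ML_BRANCH)) < _EPS:
                stack.append(("V", i, j))
                continue
            if i + 1 <= j and WM[i + 1, j] < INF and abs(e - (WM[i + 1, j] + ML_UNPAIRED)) < _EPS:
                stack.append(("WM", i + 1, j))
                continue
            if j - 1 >= i and WM[i, j - 1] < INF and abs(e - (WM[i, j - 1] + ML_UNPAIRED)) < _EPS:
                stack.append(("WM", i, j - 1))
                continue
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] < INF and WM[k, j] < INF and abs(
                    e - (WM[i, k - 1] + WM[k, j])
                ) < _EPS:
                    stack.append(("WM", i, k - 1))
                    stack.append(("WM", k, j))
                    break
    return pairs


def structure_energy(sequence: str | np.ndarray, pairs) -> float:
    """Free energy of an explicit nested structure under the package model.

    Decomposes the structure into hairpin / stack / bulge / internal /
    multibranch loops.  Used as the shared scorer for oracle enumeration;
    raises if ``pairs`` violates nesting, complementarity, or the minimum
    hairpin size.
    """
    codes = sequence if isinstance(sequence, np.ndarray) else encode(sequence)
    n = len(codes)
    pairs = sorted(pairs)
    partner = {}
    for i, j in pairs:
        if not (0 <= i < j < n):
            raise ValueError("pair out of range")
        if j - i - 1 < MIN_HAIRPIN:
            raise ValueError("hairpin loop too small")
        if _PAIR_TYPE[codes[i], codes[j]] < 0:
            raise ValueError(f"non-complementary pair ({i},{j})")
        if i in partner or j in partner:
            raise ValueError("base in two pairs")
        partner[i] = j
        partner[j] = i
    # nesting check
    open_stack = []
    for p in range(n):
        if p in partner and partner[p] > p:
            open_stack.append(partner[p])
        elif p in partner:
            if not open_stack or open_stack[-1] != p:
                raise ValueError("crossing pairs")
            open_stack.pop()
    total = 0.0
    for i, j in pairs:
        children = []
        unpaired = 0
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        if not children:
            total += _HAIRPIN[j - i - 1]
        elif len(children) == 1:
            total += _loop_energy(codes, i, j, children[0][0], children[0][1])
        else:
            total += ML_CLOSE + ML_BRANCH * (1 + len(children)) + ML_UNPAIRED * unpaired
    return float(total)


def interaction_frequency(pair_lists, length: int) -> np.ndarray:
    """Fraction of structures pairing each position pair.

    ``pair_lists`` is one base-pair list per folded sequence (0-based indices
    into a common window of ``length`` positions).  Entry (i, j) is the
    fraction of structures in which positions i and j are paired; the matrix
    is symmetric with entries in [0, 1].
    """
    mat = np.zeros((length, length))
    m = len(pair_lists)
    if m == 0:
        return mat
    for plist in pair_lists:
        for i, j in plist:
            mat[i, j] += 1.0
            mat[j, i] += 1.0
    return mat / m
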