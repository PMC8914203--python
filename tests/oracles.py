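"""Independent brute-force oracles used to cross-check the implementations.

Each oracle re-derives its answer by exhaustive enumeration or a naive
re-scan, sharing only the energy tables / thresholds with the code under
test, never its algorithms.
"""

import numpy as np

from strep_regulome.fold import MIN_HAIRPIN, _PAIR_TYPE, structure_energy


def enumerate_structures(codes, i, j, memo=None):
    """All nested pair sets on codes[i..j] (min hairpin respected)."""
    if memo is None:
        memo = {}
    if j - i < MIN_HAIRPIN + 1:
        return [frozenset()]
    key = (i, j)
    if key in memo:
        return memo[key]
    out = list(enumerate_structures(codes, i + 1, j, memo))
    for k in range(i + MIN_HAIRPIN + 1, j + 1):
        if _PAIR_TYPE[codes[i], codes[k]] >= 0:
            inside = enumerate_structures(codes, i + 1, k - 1, memo)
            after = enumerate_structures(codes, k + 1, j, memo)
            for a in inside:
                for b in after:
                    out.append(a | b | {(i, k)})
    memo[key] = out
    return out


def brute_force_mfe(seq_codes):
    """Minimum energy over every enumerated structure (0 for the open chain)."""
    structs = enumerate_structures(seq_codes, 0, len(seq_codes) - 1)
    best = 0.0
    for s in structs:
        if s:
            best = min(best, structure_energy(seq_codes, list(s)))
    return best


def brute_force_evaluate_pair(tss_pos, tep_pos, strand, raw_cov, norm_cov,
                              window=200, inset=100, min_fraction=0.05,
                              raw_floor=5.0):
    """Naive window re-scan mirroring the TU continuity definition."""
    lo, hi = sorted((tss_pos, tep_pos))
    if hi - lo + 1 >= 200:
        lo, hi = lo + inset, hi - inset
        if hi < lo:
            lo, hi = sorted((tss_pos, tep_pos))
    w = min(window, hi - lo + 1)
    for phase in raw_cov:
        raw = raw_cov[phase]
        norm = norm_cov[phase]
        region = norm[lo - 1 : hi]
        region_mean = region.mean()
        ok = True
        for start in range(lo, hi - w + 2):
            raw_mean = raw[start - 1 : start - 1 + w].mean()
            norm_mean = norm[start - 1 : start - 1 + w].mean()
            if raw_mean < raw_floor or norm_mean < min_fraction * region_mean:
                ok = False
                break
        if ok:
            return True
    return False


def union_find_components(intervals):
    """Connected components of closed intervals under >= 1 nt overlap."""
    n = len(intervals)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a[0] <= b[1] and b[0] <= a[1]:
                union(i, j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return sorted(frozenset(c) for c in comps.values())


def largest_gap_split(positions, heights, sd_threshold):
    """Exhaustive recursive largest-gap splitter (independent re-derivation)."""
    positions = list(positions)
    heights = list(heights)
    if len(positions) == 1 or float(np.std(positions)) < sd_threshold:
        return [tuple(positions)]
    gaps = [positions[k + 1] - positions[k] for k in range(len(positions) - 1)]
    cut = gaps.index(max(gaps)) + 1
    return largest_gap_split(positions[:cut], heights[:cut], sd_threshold) + \
        largest_gap_split(positions[cut:], heights[cut:], sd_threshold)
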