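"""Meta-profiles of normalized RNA density around TSSs/TEPs and the
read-through fraction.

Each anchor's -300..+300 window (transcription direction) is scaled so its
maximum is 1, then the scaled windows are averaged position-wise over
anchors.  The read-through fraction of a TEP divides the summed normalized
counts at offsets 0..+300 by the sum at -300..0; offset 0 appears in both
sums (set ``include_zero=False`` to exclude it).  Fractions are computed per
anchor, not on the averaged profile.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np


@dataclass
class MetaProfile:
    anchor_kind: str  # 'TSS' or 'TEP'
    offsets: np.ndarray  # -window..+window
    mean_density: np.ndarray
    n_anchors: int
    n_dropped: int


def _anchor_window(cov: np.ndarray, pos: int, strand: str, window: int):
    i = pos - 1
    if i - window < 0 or i + window >= len(cov):
        return None
    win = cov[i - window : i + window + 1].astype(float)
    if strand == "-":
        win = win[::-1]
    return win


def normalized_density(
    cov_by_strand: dict,
    anchors: list,
    window: int = 300,
    anchor_kind: str = "TEP",
) -> MetaProfile:
    """Average max-normalized density around anchors ``(position, strand)``.

    Anchors too close to a chromosome edge, or with an all-zero window, are
    dropped (counted in ``n_dropped``) with a warning.
    """
    acc = np.zeros(2 * window + 1)
    used = dropped = 0
    for pos, strand in anchors:
        win = _anchor_window(cov_by_strand[strand], pos, strand, window)
        if win is None or win.max() <= 0:
            dropped += 1
            continue
        acc += win / win.max()
        used += 1
    if dropped:
        print(f"[profiles] {dropped} anchor(s) dropped (edge or all-zero)",
              file=sys.stderr)
    mean = acc / used if used else acc
    return MetaProfile(anchor_kind, np.arange(-window, window + 1), mean, used, dropped)


def read_through_fraction(
    cov_by_strand: dict,
    anchor: tuple,
    window: int = 300,
    include_zero: bool = True,
) -> float:
    """Downstream/upstream normalized-count ratio across one TEP.

    Returns NaN (flagged via warning) when the upstream sum is zero.  The
    window is max-normalized first, which cancels in the ratio but matches
    the profile definition.
    """
    pos, strand = anchor
    win = _anchor_window(cov_by_strand[strand], pos, strand, window)
    if win is None:
        return float("nan")
    m = win.max()
    if m <= 0:
        return float("nan")
    win = win / m
    if include_zero:
        up = win[: window + 1].sum()
        dn = win[window:].sum()
    else:
        up = win[:window].sum()
        dn = win[window + 1 :].sum()
    if up <= 0:
        print(f"[profiles] zero upstream sum at {pos}{strand}", file=sys.stderr)
        return float("nan")
    return float(dn / up)


def read_through_table(cov_by_strand: dict, anchors: list, window: int = 300):
    """Per-anchor read-through fractions as a list parallel to ``anchors``."""
    return [read_through_fraction(cov_by_strand, a, window) for a in anchors]
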