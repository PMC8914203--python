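"""Peak clustering shared by TSS and TEP calling.

End-count peaks separated by less than ``gap`` bp go into one cluster;
clusters are then recursively split at the largest positional gap until every
sub-cluster's positional standard deviation falls below ``sd_threshold``
(10 bp for 5'-end peaks, 25 bp for 3'-end peaks by default).  The
sub-cluster's maximum-intensity peak is its representative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SubCluster:
    positions: np.ndarray  # sorted, 1-based
    heights: np.ndarray

    @property
    def representative(self) -> int:
        """Maximum-height member; leftmost on ties."""
        return int(self.positions[int(np.argmax(self.heights))])

    @property
    def rep_height(self) -> float:
        return float(self.heights.max())

    @property
    def positional_sd(self) -> float:
        return float(np.std(self.positions))


@dataclass
class PeakCluster:
    positions: np.ndarray
    heights: np.ndarray
    subclusters: list


def _split_recursive(pos: np.ndarray, h: np.ndarray, sd_threshold: float) -> list:
    if len(pos) == 1 or np.std(pos) < sd_threshold:
        return [SubCluster(pos, h)]
    gaps = np.diff(pos)
    cut = int(np.argmax(gaps)) + 1  # first largest gap on ties
    return _split_recursive(pos[:cut], h[:cut], sd_threshold) + _split_recursive(
        pos[cut:], h[cut:], sd_threshold
    )


def cluster_and_subcluster(
    positions: np.ndarray,
    heights: np.ndarray,
    gap: int = 100,
    sd_threshold: float = 10.0,
) -> list:
    """Cluster peaks and sub-cluster by positional spread.

    ``positions`` need not be sorted; order does not affect the result.
    Returns a list of :class:`PeakCluster`; representatives are read off the
    sub-clusters.
    """
    if len(positions) == 0:
        return []
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be > 0")
    order = np.argsort(positions, kind="stable")
    pos = np.asarray(positions)[order]
    h = np.asarray(heights)[order]
    breaks = np.flatnonzero(np.diff(pos) >= gap) + 1
    clusters = []
    for chunk_pos, chunk_h in zip(np.split(pos, breaks), np.split(h, breaks)):
        subs = _split_recursive(chunk_pos, chunk_h, sd_threshold)
        clusters.append(PeakCluster(chunk_pos, chunk_h, subs))
    return clusters


def representatives(clusters: list) -> list:
    """(position, height) of every sub-cluster representative, sorted."""
    out = []
    for c in clusters:
        for s in c.subclusters:
            out.append((s.representative, s.rep_height))
    return sorted(out)
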