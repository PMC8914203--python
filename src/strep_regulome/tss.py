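"""TSS calling from dRNA-seq 5'-end tracks.

A position is accepted as a transcription start site when it is the
representative of a 5'-end peak sub-cluster, shows more than a 1.5-fold
TAP+/TAP- intensity ratio (primary, triphosphorylated 5' ends survive TAP
treatment; processed monophosphorylated ends do not), and is present in both
replicate libraries.  Accepted TSSs are then categorized by their position
relative to annotated genes and, for gene-assigned TSSs, by 5'-UTR length
class: lmRNA (leaderless, 0-10 nt), mmRNA (11-100 nt), emRNA (>100 nt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenomeAnnotation
from .peaks import cluster_and_subcluster, representatives


@dataclass
class TSSRecord:
    position: int
    strand: str
    tap_ratio: float
    height: float = 0.0
    category: str | None = None
    gene_id: str | None = None
    utr_len: int | None = None
    leader_class: str | None = None
    overflow: bool = False
    chrom: str = "chr1"
    feature_type: str = "TSS"

    def attributes(self) -> dict:
        out = {"category": self.category or ".",
               "tap_ratio": f"{self.tap_ratio:.3g}"}
        if self.utr_len is not None:
            out["utr_len"] = self.utr_len
            out["leader_class"] = self.leader_class
        return out


def _present(arr: np.ndarray, pos: int, tol: int = 2) -> bool:
    i = pos - 1
    lo, hi = max(i - tol, 0), min(i + tol + 1, len(arr))
    return arr[lo:hi].sum() >= 1


def call_tss(
    tap_plus: list,
    tap_minus: list,
    strand: str,
    gap: int = 100,
    sd_threshold: float = 10.0,
    min_ratio: float = 1.5,
    presence_tol: int = 2,
    min_count: int = 8,
) -> list:
    """Call TSSs on one strand from replicate TAP+/TAP- 5'-end arrays.

    ``tap_plus``/``tap_minus`` are per-replicate dense count arrays.  The
    ratio pools replicates; a pseudocount of 1 replaces a zero TAP-
    denominator.  ``min_count`` is a pooled-intensity floor standing in for
    the manual curation step (stray replicated singleton read ends are
    library noise, not initiation sites).  Raises if fewer than two
    replicates are supplied.
    """
    if len(tap_plus) < 2 or len(tap_minus) < 2:
        raise ValueError("two replicates per TAP condition are required")
    pooled_plus = np.sum(tap_plus, axis=0)
    pooled_minus = np.sum(tap_minus, axis=0)
    peak_idx = np.flatnonzero(pooled_plus > 0)
    clusters = cluster_and_subcluster(peak_idx + 1, pooled_plus[peak_idx],
                                      gap=gap, sd_threshold=sd_threshold)
    records = []
    for pos, height in representatives(clusters):
        if height < min_count:
            continue
        minus = pooled_minus[pos - 1]
        ratio = float(pooled_plus[pos - 1] / (minus if minus > 0 else 1.0))
        if ratio <= min_ratio:
            continue
        if not all(_present(rep, pos, presence_tol) for rep in tap_plus):
            continue
        records.append(TSSRecord(pos, strand, ratio, height=height))
    return records


def categorize_tss(
    records: list,
    annotation: GenomeAnnotation,
    utr_window: int = 500,
    antisense_margin: int = 100,
) -> list:
    """Assign positional categories, gene links, and leader classes in place.

    Precedence: a TSS within ``utr_window`` nt upstream of a same-strand gene
    start is gene-assigned (strongest per gene = primary, rest secondary);
    otherwise inside a same-strand gene = internal; otherwise within
    ``antisense_margin`` of an opposite-strand gene = antisense; else orphan.
    """
    assigned: dict = {}
    rest = []
    for rec in records:
        best = None
        for g in annotation.genes_on(rec.chrom, rec.strand):
            d = (g.tss_side - rec.position) if rec.strand == "+" else (
                rec.position - g.tss_side)
            if 0 <= d <= utr_window and (best is None or d < best[1]):
                best = (g, d)
        if best is not None:
            g, d = best
            rec.gene_id = g.gene_id
            rec.utr_len = d
            rec.leader_class = ("lmRNA" if d <= 10 else
                                "mmRNA" if d <= 100 else "emRNA")
            rec.overflow = d > 500
            assigned.setdefault(g.gene_id, []).append(rec)
        else:
            rest.append(rec)
    for gid, recs in assigned.items():
        recs.sort(key=lambda r: (-r.height, r.position))
        recs[0].category = "primary"
        for r in recs[1:]:
            r.category = "secondary"
    for rec in rest:
        inside_sense = any(
            g.start <= rec.position <= g.end
            for g in annotation.genes_on(rec.chrom, rec.strand)
        )
        if inside_sense:
            rec.category = "internal"
            continue
        opposite = "-" if rec.strand == "+" else "+"
        near_anti = any(
            g.start - antisense_margin <= rec.position <= g.end + antisense_margin
            for g in annotation.genes_on(rec.chrom, opposite)
        )
        rec.category = "antisense" if near_anti else "orphan"
    return records
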