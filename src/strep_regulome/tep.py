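"""Transcript 3'-end position (TEP) calling from Term-seq tracks.

Candidate 3'-end peaks are sub-cluster representatives that carry at least
four counts, appear in both replicates, and are locally enriched over the
surrounding "peak shadows" (Z-score > 6).  A KNN classifier separates real
TEPs from residual shadows: its positive controls are candidates whose RNA
coverage visibly drops across the peak (read-through below a cutoff), and
its negative controls are sampled from the -20..+20 bp positions around each
positive.  Accepted TEPs are finally categorized by position relative to
annotated genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler

from .io import GenomeAnnotation
from .peaks import cluster_and_subcluster, representatives

FEATURE_NAMES = (
    "log10_height",
    "zscore",
    "rel_height_25",
    "rna_readthrough_300",
    "dist_to_representative",
)

_ZCAP = 50.0  # cap on finite Z inside feature vectors
_ZFLAGGED = 0.0  # feature value when Z is the sentinel: no enrichment info


@dataclass
class TEPCandidate:
    position: int
    strand: str
    height: float
    zscore: float
    z_flagged: bool  # True when Z is the +inf sentinel (no usable neighbours)
    features: np.ndarray | None = None
    knn_label: str | None = None  # 'tep' / 'shadow'


@dataclass
class TEPRecord:
    position: int
    strand: str
    zscore: float
    height: float
    knn_label: str
    category: str | None = None
    subcategory: str | None = None
    terminal: bool | None = None
    dG: float | None = None
    chrom: str = "chr1"
    feature_type: str = "TEP"

    def attributes(self) -> dict:
        out = {"category": self.category or ".",
               "zscore": f"{self.zscore:.3g}",
               "knn_label": self.knn_label}
        if self.subcategory is not None:
            out["subcategory"] = self.subcategory
        if self.terminal is not None:
            out["terminal"] = "T" if self.terminal else "NT"
        return out


def zscore(position: int, track: np.ndarray, window: int = 100) -> tuple[float, bool]:
    """Peak-height enrichment of ``position`` over its non-zero neighbours.

    Z = (h - mean) / sd over non-zero heights within +-window, the focal
    position excluded; sample (ddof=1) standard deviation.  With fewer than
    three non-zero neighbours, or zero spread, returns (+inf, flagged=True):
    an isolated spike is trivially enriched but cannot be scored.
    """
    if window < 20:
        raise ValueError("window must be >= 20 nt each side")
    i = position - 1
    lo, hi = max(i - window, 0), min(i + window + 1, len(track))
    neigh = np.concatenate([track[lo:i], track[i + 1 : hi]])
    neigh = neigh[neigh > 0]
    if len(neigh) < 3:
        return float("inf"), True
    sd = float(np.std(neigh, ddof=1))
    if sd == 0.0:
        # a peak exactly matching its uniform neighbours is unenriched (Z=0);
        # otherwise the spread carries no information -> sentinel
        if track[i] == neigh.mean():
            return 0.0, False
        return float("inf"), True
    return float((track[i] - neigh.mean()) / sd), False


def _readthrough(cov: np.ndarray, pos: int, strand: str, window: int = 300) -> float:
    i = pos - 1
    n = len(cov)
    if strand == "+":
        up = cov[max(i - window, 0) : i + 1].sum()
        dn = cov[i : min(i + window + 1, n)].sum()
    else:
        up = cov[i : min(i + window + 1, n)].sum()
        dn = cov[max(i - window, 0) : i + 1].sum()
    if up <= 0:
        return 2.0
    return float(min(dn / up, 2.0))


def _features(pos: int, strand: str, track: np.ndarray, cov: np.ndarray,
              rep_pos: int, z: float, flagged: bool) -> np.ndarray:
    i = pos - 1
    h = float(track[i])
    lo, hi = max(i - 25, 0), min(i + 26, len(track))
    local_max = float(track[lo:hi].max())
    rel = h / local_max if local_max > 0 else 0.0
    return np.array([
        np.log10(h + 1.0),
        min(z, _ZCAP) if not flagged else _ZFLAGGED,
        rel,
        _readthrough(cov, pos, strand),
        abs(pos - rep_pos),
    ])


def find_candidates(
    term_tracks: list,
    rna_cov: np.ndarray,
    strand: str,
    gap: int = 100,
    sd_threshold: float = 25.0,
    min_count: int = 4,
    min_z: float = 6.0,
    z_window: int = 100,
    presence_tol: int = 2,
) -> list:
    """Filter Term-seq peaks down to classifier candidates on one strand.

    ``term_tracks`` holds the per-replicate 3'-end arrays; ``rna_cov`` is the
    pooled normalized RNA coverage used for the read-through feature.
    The count / replicate / Z filters are monotone in the candidate's counts.
    """
    if len(term_tracks) < 2:
        raise ValueError("two Term-seq replicates are required")
    pooled = np.sum(term_tracks, axis=0)
    idx = np.flatnonzero(pooled > 0)
    clusters = cluster_and_subcluster(idx + 1, pooled[idx], gap=gap,
                                      sd_threshold=sd_threshold)
    out = []
    for pos, height in representatives(clusters):
        if height < min_count:
            continue
        if not all(_present_rep(rep, pos, presence_tol) for rep in term_tracks):
            continue
        z, flagged = zscore(pos, pooled, window=z_window)
        if not (z > min_z):
            continue
        cand = TEPCandidate(pos, strand, float(height), z, flagged)
        cand.features = _features(pos, strand, pooled, rna_cov, pos, z, flagged)
        out.append(cand)
    return out


def _present_rep(arr: np.ndarray, pos: int, tol: int) -> bool:
    i = pos - 1
    return arr[max(i - tol, 0) : min(i + tol + 1, len(arr))].sum() >= 1


def build_training_set(
    candidates: list,
    term_pooled: np.ndarray,
    rna_cov: np.ndarray,
    strand: str,
    positive_cutoff: float = 0.5,
    negatives_per_positive: int = 2,
    seed: int = 0,
):
    """Rule-derived positive/negative control peaks with features.

    Positives: candidates whose downstream/upstream RNA ratio across the peak
    is below ``positive_cutoff`` and whose Z-score is informative (an
    isolated singleton with the sentinel Z cannot be confidently selected as
    a control, mirroring the visual-curation step it replaces).  Negatives:
    positions sampled uniformly in -20..+20 bp around each positive (the
    positive itself excluded).  Returns ``(X, y, meta)``; raises when fewer
    than 10 positives are found.
    """
    rng = np.random.default_rng(seed)
    positives = [c for c in candidates
                 if not c.z_flagged
                 and _readthrough(rna_cov, c.position, strand) < positive_cutoff]
    if len(positives) < 10:
        raise ValueError(
            f"only {len(positives)} positive controls; supply more input data"
        )
    X, y, meta = [], [], []
    cand_pos = {c.position for c in candidates}
    for c in positives:
        X.append(c.features)
        y.append(1)
        meta.append(("pos", c.position))
        picked = 0
        for off in rng.permutation(np.concatenate([np.arange(-20, 0), np.arange(1, 21)])):
            p = c.position + int(off)
            if p in cand_pos or not (1 <= p <= len(term_pooled)):
                continue
            z, fl = zscore(p, term_pooled)
            X.append(_features(p, strand, term_pooled, rna_cov, c.position, z, fl))
            y.append(0)
            meta.append(("neg", p))
            picked += 1
            if picked >= negatives_per_positive:
                break
    return np.array(X), np.array(y), meta


def knn_classify(candidates: list, X: np.ndarray, y: np.ndarray, k: int = 5) -> list:
    """Label candidates tep/shadow by k-nearest-neighbour majority vote.

    Features are z-standardized with the training set's statistics; ``k``
    must be odd (no ties) and no larger than the training set.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if k > len(X):
        raise ValueError("k exceeds training-set size")
    scaler = StandardScaler().fit(X)
    clf = KNeighborsClassifier(n_neighbors=k).fit(scaler.transform(X), y)
    records = []
    for c in candidates:
        label = int(clf.predict(scaler.transform(c.features[None, :]))[0])
        c.knn_label = "tep" if label == 1 else "shadow"
        if c.knn_label == "tep":
            records.append(TEPRecord(c.position, c.strand, c.zscore, c.height,
                                     c.knn_label))
    return records


def categorize_tep(
    records: list,
    annotation: GenomeAnnotation,
    tss_records: list | None = None,
    downstream_window: int = 200,
    early_cds: int = 150,
    antisense_margin: int = 100,
) -> list:
    """Positional categories for accepted TEPs (in place).

    Precedence: premature (between a gene-assigned TSS and the early part of
    its gene's CDS) > primary (strongest TEP within ``downstream_window``
    downstream of a same-strand gene stop) > secondary (further such TEPs of
    the same gene) > internal (inside a same-strand gene) > antisense >
    intergenic.
    """
    stops: dict = {}
    premature_spans = []
    if tss_records:
        for t in tss_records:
            if t.gene_id is None:
                continue
            g = annotation.by_id[t.gene_id]
            if g.strand == "+":
                premature_spans.append((t.strand, t.position, g.end - early_cds))
            else:
                premature_spans.append((t.strand, g.start + early_cds, t.position))
    undecided = []
    for rec in records:
        rec.category = None
        for strand, lo, hi in premature_spans:
            if rec.strand == strand and lo <= rec.position <= hi:
                rec.category = "premature"
                break
        if rec.category is None:
            undecided.append(rec)
    by_gene: dict = {}
    rest = []
    for rec in undecided:
        best = None
        for g in annotation.genes_on(rec.chrom, rec.strand):
            d = (rec.position - g.stop_side) if rec.strand == "+" else (
                g.stop_side - rec.position)
            if 0 <= d <= downstream_window and (best is None or d < best[1]):
                best = (g, d)
        if best is not None:
            by_gene.setdefault(best[0].gene_id, []).append(rec)
        else:
            rest.append(rec)
    for gid, recs in by_gene.items():
        recs.sort(key=lambda r: (-r.height, r.position))
        recs[0].category = "primary"
        for r in recs[1:]:
            r.category = "secondary"
    for rec in rest:
        if any(g.start <= rec.position <= g.end
               for g in annotation.genes_on(rec.chrom, rec.strand)):
            rec.category = "internal"
            continue
        opposite = "-" if rec.strand == "+" else "+"
        near_anti = any(
            g.start - antisense_margin <= rec.position <= g.end + antisense_margin
            for g in annotation.genes_on(rec.chrom, opposite)
        )
        rec.category = "antisense" if near_anti else "intergenic"
    return records
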