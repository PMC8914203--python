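"""Transcription-unit assembly from TSS/TEP calls and RNA coverage.

Every same-strand (TSS, TEP) pair with the TEP downstream is a TU candidate.
The pair is accepted when a 200-nt window slid base-by-base across the
connected region (inset 100 nt from each end; no insets when the span is
under 200 nt) shows continuous transcription in at least one growth phase:
each window must carry a raw mean of at least 5 reads and a normalized mean
of at least 5% of the whole-region normalized mean.  (A window below the
5-read floor is treated as failing — a silent window cannot evidence
continuity; see docs/methods.md.)

Accepted TUs are grouped into transcription-unit clusters (TUCs): connected
components under >= 1 nt span overlap on the same strand.  A TEP is terminal
in its TUC when no member TU extends past it in transcription direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenomeAnnotation


@dataclass
class TranscriptionUnit:
    tss_index: int
    tep_index: int
    strand: str
    start: int  # genomic span, 1-based closed (start <= end)
    end: int
    gene_ids: list = field(default_factory=list)
    category: str | None = None
    chrom: str = "chr1"
    feature_type: str = "TU"

    def attributes(self) -> dict:
        return {"category": self.category or ".",
                "genes": ",".join(self.gene_ids) or "."}


@dataclass
class TUCluster:
    tu_indices: list
    strand: str
    span: tuple
    terminal_teps: list = field(default_factory=list)
    nonterminal_teps: list = field(default_factory=list)
    nonterminal_no_downstream_tss: list = field(default_factory=list)


def evaluate_pair(
    tss_pos: int,
    tep_pos: int,
    strand: str,
    raw_cov: dict,
    norm_cov: dict,
    window: int = 200,
    inset: int = 100,
    min_fraction: float = 0.05,
    raw_floor: float = 5.0,
) -> tuple:
    """Coverage-continuity test for one TSS-TEP pair.

    ``raw_cov``/``norm_cov`` map phase -> dense per-position array (replicate
    averages; raw counts vs size-factor-normalized counts).  Returns
    ``(accepted, diagnostics)`` where diagnostics records the per-phase
    outcome.  Raises when the TEP is not downstream of the TSS.
    """
    if strand == "+":
        if tep_pos <= tss_pos:
            raise ValueError("TEP must lie downstream of the TSS")
        span_lo, span_hi = tss_pos, tep_pos
    else:
        if tep_pos >= tss_pos:
            raise ValueError("TEP must lie downstream of the TSS")
        span_lo, span_hi = tep_pos, tss_pos
    span_len = span_hi - span_lo + 1
    if span_len < 200:
        lo, hi = span_lo, span_hi
    else:
        lo, hi = span_lo + inset, span_hi - inset
    if hi < lo:
        lo, hi = span_lo, span_hi
    region_len = hi - lo + 1
    w = min(window, region_len)
    diagnostics = {}
    accepted = False
    for phase in raw_cov:
        raw = raw_cov[phase][lo - 1 : hi]
        norm = norm_cov[phase][lo - 1 : hi]
        n_windows = region_len - w + 1
        cs_raw = np.concatenate([[0.0], np.cumsum(raw)])
        cs_norm = np.concatenate([[0.0], np.cumsum(norm)])
        raw_means = (cs_raw[w:] - cs_raw[:-w]) / w
        norm_means = (cs_norm[w:] - cs_norm[:-w]) / w
        region_mean = norm.mean()
        ok = bool(
            np.all(raw_means >= raw_floor)
            and np.all(norm_means >= min_fraction * region_mean)
        )
        diagnostics[phase] = {
            "ok": ok,
            "n_windows": int(n_windows),
            "min_raw": float(raw_means.min()),
            "min_norm": float(norm_means.min()),
            "region_mean": float(region_mean),
        }
        accepted = accepted or ok
    return accepted, diagnostics


def _categorize(tu: TranscriptionUnit, annotation: GenomeAnnotation,
                tss_record) -> str:
    same = annotation.genes_on(tu.chrom, tu.strand)
    complete = [g for g in same if g.start >= tu.start and g.end <= tu.end]
    tu.gene_ids = [g.gene_id for g in complete]
    if len(complete) >= 2:
        return "polycistronic"
    if len(complete) == 1:
        return "monocistronic"
    # no complete gene: premature if the TU ends before the stop of the gene
    # its TSS serves, else partial-sense / antisense / intergenic
    if tss_record is not None and tss_record.gene_id is not None:
        g = annotation.by_id[tss_record.gene_id]
        tep_pos = tu.end if tu.strand == "+" else tu.start
        before_stop = (tep_pos < g.stop_side) if tu.strand == "+" else (
            tep_pos > g.stop_side)
        if before_stop:
            return "premature"
    partial_sense = any(g.start <= tu.end and g.end >= tu.start for g in same)
    if partial_sense:
        return "monocistronic"
    opposite = annotation.genes_on(tu.chrom, "-" if tu.strand == "+" else "+")
    if any(g.start <= tu.end and g.end >= tu.start for g in opposite):
        return "antisense"
    return "intergenic"


def assemble_tus(
    tss_records: list,
    tep_records: list,
    raw_cov: dict,
    norm_cov: dict,
    annotation: GenomeAnnotation,
    max_span: int = 50_000,
    **eval_kwargs,
) -> list:
    """Test all same-strand downstream (TSS, TEP) combinations.

    ``raw_cov``/``norm_cov`` map strand -> phase -> array.  Pairs separated
    by more than ``max_span`` nt are not evaluated (configurable cap on the
    quadratic search).  Returns accepted :class:`TranscriptionUnit` objects
    with categories assigned.
    """
    tus = []
    for i, tss in enumerate(tss_records):
        for j, tep in enumerate(tep_records):
            if tep.strand != tss.strand:
                continue
            d = (tep.position - tss.position) if tss.strand == "+" else (
                tss.position - tep.position)
            if d <= 0 or d > max_span:
                continue
            accepted, _ = evaluate_pair(
                tss.position, tep.position, tss.strand,
                raw_cov[tss.strand], norm_cov[tss.strand], **eval_kwargs,
            )
            if not accepted:
                continue
            lo = min(tss.position, tep.position)
            hi = max(tss.position, tep.position)
            tu = TranscriptionUnit(i, j, tss.strand, lo, hi)
            tu.category = _categorize(tu, annotation, tss)
            tus.append(tu)
    return tus


def cluster_tucs(tus: list, tss_records: list, tep_records: list) -> list:
    """Connected components of TUs overlapping by >= 1 nt (per strand).

    Labels each member TEP terminal iff no TU in the cluster extends beyond
    it in transcription direction, and lists the non-terminal TEPs that have
    no downstream TSS inside the cluster (the subset whose effect on the
    downstream gene can be read directly).
    """
    clusters = []
    for strand in ("+", "-"):
        idx = [i for i, t in enumerate(tus) if t.strand == strand]
        idx.sort(key=lambda i: tus[i].start)
        current: list = []
        cur_hi = None
        for i in idx:
            if current and tus[i].start > cur_hi:
                clusters.append(_finish_cluster(current, strand, tus,
                                                tss_records, tep_records))
                current = []
                cur_hi = None
            current.append(i)
            cur_hi = tus[i].end if cur_hi is None else max(cur_hi, tus[i].end)
        if current:
            clusters.append(_finish_cluster(current, strand, tus,
                                            tss_records, tep_records))
    return clusters


def _finish_cluster(members, strand, tus, tss_records, tep_records) -> TUCluster:
    lo = min(tus[i].start for i in members)
    hi = max(tus[i].end for i in members)
    tep_idx = sorted({tus[i].tep_index for i in members})
    terminal, nonterminal = [], []
    for j in tep_idx:
        pos = tep_records[j].position
        if strand == "+":
            extends = any(tus[i].end > pos for i in members)
        else:
            extends = any(tus[i].start < pos for i in members)
        (nonterminal if extends else terminal).append(j)
    no_ds_tss = []
    member_tss = {tus[i].tss_index for i in members}
    for j in nonterminal:
        pos = tep_records[j].position
        if strand == "+":
            has_ds = any(lo <= tss_records[t].position <= hi and
                         tss_records[t].position > pos for t in member_tss)
        else:
            has_ds = any(lo <= tss_records[t].position <= hi and
                         tss_records[t].position < pos for t in member_tss)
        if not has_ds:
            no_ds_tss.append(j)
    return TUCluster(members, strand, (lo, hi), terminal, nonterminal, no_ds_tss)


def premature_intensity(
    tu: TranscriptionUnit,
    cds_gene,
    norm_cov_reps: dict,
) -> dict:
    """Premature-TU to CDS read-count ratio per phase (mean, sd over reps).

    ``norm_cov_reps`` maps phase -> list of per-replicate normalized arrays
    for the TU's strand.  The ratio divides the summed normalized counts in
    the premature TU span by the sum over its downstream CDS; zero CDS
    signal yields NaN with a flag.
    """
    out = {}
    for phase, reps in norm_cov_reps.items():
        ratios = []
        flagged = False
        for arr in reps:
            pre = arr[tu.start - 1 : tu.end].sum()
            cds = arr[cds_gene.start - 1 : cds_gene.end].sum()
            if cds <= 0:
                flagged = True
                ratios.append(np.nan)
            else:
                ratios.append(pre / cds)
        out[phase] = {
            "mean": float(np.nanmean(ratios)) if not all(np.isnan(ratios)) else float("nan"),
            "sd": float(np.nanstd(ratios, ddof=1)) if len(ratios) > 1 else 0.0,
            "flagged": flagged,
        }
    return out
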