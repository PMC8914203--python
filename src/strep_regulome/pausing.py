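"""Ribosome pausing scores from RPF 3'-end count tracks.

The 3' end of a ribosome-protected footprint maps ~14 nt downstream of the
P-site codon's middle position, so the pausing score of CDS position p reads
the 3'-end count at p+14 (translation direction) and divides by the gene's
mean 3'-end count: score 1 = no enrichment.  The first and last 10 codons
are excluded (initiation/termination effects), as are genes averaging <= 1
RPF count per nucleotide (low-coverage scores are unstable).  The A-site
codon score sums the position scores at the -1, 0 and +1 nucleotides of the
P-site codon.  Top-scoring sites are compared with random CDS positions for
codon usage (chi-square), downstream GC and folding free energy (rank-sum).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fold import fold_energy
from .io import GenomeAnnotation

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
SENSE_CODONS = sorted(c for c, aa in _CODON_TABLE.items() if aa != "*")


def _cds_track(track_by_strand: dict, gene) -> np.ndarray:
    """Per-position 3'-end counts along the CDS in translation direction."""
    arr = track_by_strand[gene.strand][gene.start - 1 : gene.end]
    return arr[::-1].copy() if gene.strand == "-" else arr.astype(float)


def pausing_scores(
    track_by_strand: dict,
    annotation: GenomeAnnotation,
    phase: str,
    shift: int = 14,
    min_density: float = 1.0,
    end_exclusion_codons: int = 10,
) -> pd.DataFrame:
    """Per-position pausing scores for all genes passing the density filter.

    Returns a table with gene, cds_pos (0-based nt), score, p_codon, a_codon
    and amino acid of the A-site codon.  Genes shorter than 63 nt (21
    codons) are skipped with a log line, as are genes whose mean 3'-end
    count per nucleotide does not exceed ``min_density``.
    """
    rows = []
    for gene in annotation.genes:
        L = gene.length
        ncod = L // 3
        if L < 63:
            print(f"[pausing] {gene.gene_id}: CDS too short, skipped", file=sys.stderr)
            continue
        counts = _cds_track(track_by_strand, gene)
        mean = counts.mean()
        if not (mean > min_density):
            continue
        seq = annotation.sequence(gene.chrom, gene.start, gene.end, gene.strand)
        lo = end_exclusion_codons * 3
        hi = (ncod - end_exclusion_codons) * 3  # exclusive
        pos = np.arange(lo, min(hi, L - shift))
        scores = counts[pos + shift] / mean
        k = pos // 3
        p_codons = [seq[3 * kk : 3 * kk + 3] for kk in k]
        a_codons = [seq[3 * (kk + 1) : 3 * (kk + 1) + 3] for kk in k]
        for p, s, pc, ac in zip(pos, scores, p_codons, a_codons):
            rows.append((gene.gene_id, int(p), float(s), pc, ac))
    df = pd.DataFrame(rows, columns=["gene", "cds_pos", "score", "p_codon", "a_codon"])
    df["aa"] = df["a_codon"].map(_CODON_TABLE)
    df["phase"] = phase
    return df


def codon_pausing(table: pd.DataFrame, return_sites: bool = False):
    """A-site codon scores and per-codon / per-amino-acid averages.

    The A-site codon score at P-site codon k sums the position scores at
    nucleotides 3k-1, 3k and 3k+1.  Stop codons are excluded (61 sense
    codons).  Returns per-codon rows (n, mean A-site score, amino acid);
    with ``return_sites=True`` also the per-site A-score table.
    """
    scores = []
    for gene, sub in table.groupby("gene", sort=False):
        s = dict(zip(sub["cds_pos"], sub["score"]))
        a_codon = dict(zip(sub["cds_pos"], sub["a_codon"]))
        for p in sub["cds_pos"]:
            if p % 3:
                continue
            neigh = [s.get(p - 1), s.get(p), s.get(p + 1)]
            if any(v is None for v in neigh):
                continue
            cod = a_codon[p]
            if _CODON_TABLE.get(cod, "*") == "*":
                continue
            scores.append((gene, p, cod, float(sum(neigh))))
    asite = pd.DataFrame(scores, columns=["gene", "p_site_pos", "a_codon", "a_score"])
    agg = (
        asite.groupby("a_codon")["a_score"]
        .agg(["count", "mean"])
        .reindex(SENSE_CODONS)
        .rename(columns={"count": "n", "mean": "mean_score"})
    )
    agg["aa"] = [(_CODON_TABLE[c]) for c in agg.index]
    return (agg, asite) if return_sites else agg


def amino_acid_pausing(codon_stats: pd.DataFrame) -> pd.DataFrame:
    """Per-amino-acid averages, weighted by codon occurrence counts."""
    df = codon_stats.dropna(subset=["mean_score"]).copy()
    df["total"] = df["n"] * df["mean_score"]
    out = df.groupby("aa").agg(n=("n", "sum"), total=("total", "sum"))
    out["mean_score"] = out["total"] / out["n"]
    return out.drop(columns="total")


def top_sites_analysis(
    table: pd.DataFrame,
    annotation: GenomeAnnotation,
    n: int = 1000,
    seed: int = 0,
    shift: int = 14,
    fold_window: int = 40,
    fold_fn=fold_energy,
) -> dict:
    """Codon usage, downstream GC and folding energy of top-scoring sites.

    rel_freq(codon) = codon frequency among the top-n sites minus frequency
    among all scored sites (sums to ~0).  GC and minimum free energy of the
    ``fold_window`` nt immediately downstream of the ribosome 3' boundary
    (site + shift) are compared against two independent random-site control
    groups drawn from the same scored-site pool: chi-square on codon counts,
    Wilcoxon rank-sum on dG.  Ties at the top-n boundary break by (gene,
    position); fewer than n sites reduces n with a warning.
    """
    if len(table) < n:
        print(f"[pausing] only {len(table)} scored sites; top-n reduced",
              file=sys.stderr)
        n = len(table)
    ranked = table.sort_values(["score", "gene", "cds_pos"],
                               ascending=[False, True, True], kind="stable")
    top = ranked.head(n)
    all_freq = table["a_codon"].value_counts(normalize=True)
    top_freq = top["a_codon"].value_counts(normalize=True)
    rel = (top_freq.reindex(SENSE_CODONS).fillna(0.0)
           - all_freq.reindex(SENSE_CODONS).fillna(0.0))

    # chi-square: observed top-n codon counts vs expectation from all sites
    obs = top["a_codon"].value_counts().reindex(SENSE_CODONS).fillna(0.0)
    exp = all_freq.reindex(SENSE_CODONS).fillna(0.0) * n
    keep = exp > 0
    chi2, chi_p = stats.chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum())

    rng = np.random.default_rng(seed)
    controls = [table.iloc[rng.choice(len(table), size=n, replace=False)]
                for _ in range(2)]

    def gc_and_dg(sub: pd.DataFrame):
        gcs, dgs = [], []
        for gene_id, p in zip(sub["gene"], sub["cds_pos"]):
            g = annotation.by_id[gene_id]
            start = p + shift + 1
            if start + fold_window > g.length:
                continue
            if g.strand == "+":
                lo = g.start + start
                seq = annotation.sequence(g.chrom, lo, lo + fold_window - 1, "+")
            else:
                hi = g.end - start
                seq = annotation.sequence(g.chrom, hi - fold_window + 1, hi, "-")
            gcs.append((seq.count("G") + seq.count("C")) / len(seq))
            dgs.append(fold_fn(seq).dG)
        return np.array(gcs), np.array(dgs)

    top_gc, top_dg = gc_and_dg(top)
    ctrl = [gc_and_dg(c) for c in controls]

    def _mean(x):
        return float(x.mean()) if len(x) else float("nan")

    ranksum_p = [
        float(stats.ranksums(top_dg, c_dg).pvalue)
        if len(top_dg) and len(c_dg) else float("nan")
        for _gc, c_dg in ctrl
    ]
    return {
        "n": n,
        "rel_freq": rel,
        "chi2_p": float(chi_p),
        "top_gc_mean": _mean(top_gc),
        "control_gc_means": [_mean(g) for g, _ in ctrl],
        "top_dg_mean": _mean(top_dg),
        "control_dg_means": [_mean(d) for _, d in ctrl],
        "ranksum_p": ranksum_p,
        "top_dg": top_dg,
        "control_dg": [d for _, d in ctrl],
    }
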