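"""Gene-level expression: TPM, differential expression, DEG/TE grouping,
and hypergeometric functional enrichment.

The differential-expression test is a DESeq2-like approximation: counts are
scaled by median-of-ratios size factors, a per-gene negative-binomial
dispersion is estimated by method of moments (moderated toward the
across-gene median), and a Wald test is applied to the log fold change.  The
downstream classification consumes only (log2FC, p) with fixed thresholds
|log2FC| > 1 and p < 0.05, so exact replication of DESeq2 shrinkage is not
attempted.

Nine expression groups combine the E->T (ET) and T->S (TS) calls, each
upregulated (U), downregulated (D) or no significant change (N):

    I=U-U  II=U-D  III=U-N  IV=D-U  V=D-D  VI=D-N  VII=N-U  VIII=N-D  IX=N-N

Translation efficiency TE = TPM_RPF / TPM_RNA, defined where RNA TPM passes
a floor in both phases of a transition; genes with no significant expression
fall into the N calls, as in the grouping's definition.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import GROUP_MAP  # fixed (ET, TS) -> group bijection

PHASES = ("E", "T", "S")
TRANSITIONS = {"ET": ("E", "T"), "TS": ("T", "S")}


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million matrix (genes x samples).

    Per sample: rate = counts / length_kb, TPM = rate / sum(rate) * 1e6, so
    each column sums to 1e6.  An all-zero sample yields all-zero TPM with a
    warning; zero-length genes raise.
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths / 1e3, axis=0)
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        print(f"[expression] warning: all-zero sample(s): "
              f"{list(totals.index[zero])}", file=sys.stderr)
        totals = totals.replace(0, 1.0)
    return rate.div(totals, axis=1) * 1e6


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with all-positive counts."""
    logs = np.log(counts.where(counts > 0))
    ref = logs.mean(axis=1)
    usable = np.isfinite(ref)
    if usable.sum() == 0:
        return pd.Series(1.0, index=counts.columns)
    sf = np.exp((logs.loc[usable].sub(ref[usable], axis=0)).median(axis=0))
    return sf.fillna(1.0)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def differential_expression(
    counts: pd.DataFrame,
    group_a: list,
    group_b: list,
    min_dispersion: float = 1e-3,
) -> pd.DataFrame:
    """Per-gene log2FC (B over A) and Wald p-value from replicate counts.

    ``group_a``/``group_b`` name the replicate columns of the two phases
    (each needs >= 2).  Genes with zero counts throughout get log2FC = NaN,
    p = 1 and ``flagged=True``.  Swapping the two groups negates log2FC
    exactly (symmetric pseudocount of 0.5 on the normalized means).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("at least two replicates per phase are required")
    cols = list(group_a) + list(group_b)
    sf = size_factors(counts[cols])
    norm = counts[cols].div(sf, axis=1)
    a = norm[list(group_a)].to_numpy(float)
    b = norm[list(group_b)].to_numpy(float)
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    all_zero = (mu_a == 0) & (mu_b == 0)

    # method-of-moments dispersion pooled within groups, moderated toward
    # the across-gene median (two replicates give a very noisy estimate)
    def mom(x, mu):
        var = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (var - mu) / mu**2
        return phi

    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)  # all-NaN rows are handled below
        phi = np.nanmean(np.vstack([mom(a, mu_a), mom(b, mu_b)]), axis=0)
    phi = np.where(np.isfinite(phi), phi, np.nan)
    phi_med = np.nanmedian(phi)
    if not np.isfinite(phi_med):
        phi_med = min_dispersion
    phi = np.where(np.isfinite(phi), 0.5 * phi + 0.5 * phi_med, phi_med)
    phi = np.maximum(phi, min_dispersion)

    lfc = np.log2((mu_b + 0.5) / (mu_a + 0.5))
    with np.errstate(divide="ignore", invalid="ignore"):
        var_ln = (1.0 / np.maximum(mu_a, 0.5) + phi) / a.shape[1] + (
            1.0 / np.maximum(mu_b, 0.5) + phi) / b.shape[1]
        z = lfc * np.log(2.0) / np.sqrt(var_ln)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    lfc = np.where(all_zero, np.nan, lfc)
    p = np.where(all_zero, 1.0, p)
    return pd.DataFrame(
        {"log2FC": lfc, "p": p, "mean_a": mu_a, "mean_b": mu_b,
         "dispersion": phi, "flagged": all_zero},
        index=counts.index,
    )


def _call(lfc: float, p: float, alpha: float, lfc_cut: float) -> str:
    if np.isnan(lfc) or p >= alpha:
        return "N"
    if lfc > lfc_cut:
        return "U"
    if lfc < -lfc_cut:
        return "D"
    return "N"


@dataclass
class DEGGroupLabel:
    et_call: str
    ts_call: str
    group: str


def classify_deg_groups(
    fc_table: pd.DataFrame, alpha: float = 0.05, lfc_cut: float = 1.0
) -> pd.DataFrame:
    """Nine-group labels from a table with {et,ts}_{log2FC,p} columns.

    U requires log2FC > 1 and p < 0.05; D the mirror image; everything else
    (including genes with no significant expression) is N.  The nine groups
    partition the input.
    """
    et = [
        _call(l, p, alpha, lfc_cut)
        for l, p in zip(fc_table["et_log2FC"], fc_table["et_p"])
    ]
    ts = [
        _call(l, p, alpha, lfc_cut)
        for l, p in zip(fc_table["ts_log2FC"], fc_table["ts_p"])
    ]
    group = [GROUP_MAP[(a, b)] for a, b in zip(et, ts)]
    return pd.DataFrame(
        {"et_call": et, "ts_call": ts, "group": group}, index=fc_table.index
    )


# ---------------------------------------------------------------------------
# translation efficiency
# ---------------------------------------------------------------------------

def compute_te(
    rna_tpm: pd.DataFrame,
    rpf_tpm: pd.DataFrame,
    min_rna_tpm: float = 1.0,
) -> pd.DataFrame:
    """TE per phase and log2 TE fold change per transition.

    Input TPM frames are genes x phases (columns E/T/S, replicates already
    averaged).  TE = TPM_RPF / TPM_RNA where RNA TPM >= ``min_rna_tpm``;
    a transition's TE_FC needs TE defined in both its phases.
    """
    out = pd.DataFrame(index=rna_tpm.index)
    for p in PHASES:
        defined = rna_tpm[p] >= min_rna_tpm
        out[f"TE_{p}"] = np.where(defined, rpf_tpm[p] / rna_tpm[p].where(defined), np.nan)
    for name, (pa, pb) in TRANSITIONS.items():
        out[f"te_lfc_{name.lower()}"] = np.log2(out[f"TE_{pb}"] / out[f"TE_{pa}"])
    return out


def te_group(
    rna_lfc: float, rpf_lfc: float, te_lfc: float, lfc_cut: float = 1.0
) -> str:
    """TE pattern label for one transition, e.g. 'RNA-down_TE-high'.

    RNA is 'down' when log2(RNA_FC) < ``lfc_cut`` fails the increase test
    (i.e. < 1), matching the grouping used for translationally induced
    regulators; TE is 'high' when log2(TE_FC) > 1, 'up' when > 0.
    """
    if np.isnan(te_lfc):
        return "undefined"
    if te_lfc > lfc_cut and rna_lfc < lfc_cut:
        return "RNA-down_TE-high"
    if te_lfc > 0 and rna_lfc < lfc_cut and rpf_lfc < lfc_cut:
        return "RNA-down_RPF-down_TE-up"
    if te_lfc < -lfc_cut:
        return "TE-low"
    return "other"


# ---------------------------------------------------------------------------
# functional enrichment
# ---------------------------------------------------------------------------

def enrichment_test(
    gene_set: set,
    term_sets: dict,
    universe: set,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation with Benjamini-Hochberg FDR.

    For each term with K genes in a universe of M, drawing n = |gene_set|
    genes containing k term members, p = P(X >= k) from the hypergeometric
    tail.  Returns all terms with q-values; ``significant`` marks q < fdr.
    """
    if not gene_set <= universe:
        raise ValueError("gene set must be a subset of the universe")
    if not gene_set:
        return pd.DataFrame(columns=["term", "k", "K", "p", "q", "significant"])
    M, n = len(universe), len(gene_set)
    rows = []
    for term, members in term_sets.items():
        members = members & universe
        K = len(members)
        k = len(members & gene_set)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append({"term": term, "k": k, "K": K, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if len(df):
        rej, q, *_ = multipletests(df["p"], alpha=fdr, method="fdr_bh")
        df["q"] = q
        df["significant"] = rej
    return df.sort_values("p").reset_index(drop=True)


# ---------------------------------------------------------------------------
# convenience: full table from a counts.tsv layout
# ---------------------------------------------------------------------------

def expression_table(
    counts: pd.DataFrame, alpha: float = 0.05, lfc_cut: float = 1.0,
    min_rna_tpm: float = 1.0,
) -> pd.DataFrame:
    """DEG + TE analysis of a counts table with {phase}_{rep}_{assay} columns.

    Expects columns ``gene``, ``length`` and one column per sample; returns a
    per-gene table with TPM means, fold changes, p-values, group labels, TE
    and TE fold changes.
    """
    counts = counts.set_index("gene") if "gene" in counts.columns else counts
    lengths = counts["length"]
    out = pd.DataFrame(index=counts.index)
    tpm_means = {}
    for assay in ("rna", "rpf"):
        cols = [c for c in counts.columns if c.endswith(f"_{assay}")]
        tpm = compute_tpm(counts[cols], lengths)
        means = pd.DataFrame(
            {p: tpm[[c for c in cols if c.startswith(f"{p}_")]].mean(axis=1)
             for p in PHASES}
        )
        tpm_means[assay] = means
        for name, (pa, pb) in TRANSITIONS.items():
            de = differential_expression(
                counts,
                [f"{pa}_1_{assay}", f"{pa}_2_{assay}"],
                [f"{pb}_1_{assay}", f"{pb}_2_{assay}"],
            )
            out[f"{assay}_{name.lower()}_log2FC"] = de["log2FC"]
            out[f"{assay}_{name.lower()}_p"] = de["p"]
    groups = classify_deg_groups(
        out.rename(columns={
            "rna_et_log2FC": "et_log2FC", "rna_et_p": "et_p",
            "rna_ts_log2FC": "ts_log2FC", "rna_ts_p": "ts_p",
        })[["et_log2FC", "et_p", "ts_log2FC", "ts_p"]],
        alpha=alpha, lfc_cut=lfc_cut,
    )
    out = out.join(groups)
    te = compute_te(tpm_means["rna"], tpm_means["rpf"], min_rna_tpm=min_rna_tpm)
    out = out.join(te)
    for name in ("et", "ts"):
        out[f"te_group_{name}"] = [
            te_group(r, f, t, lfc_cut)
            for r, f, t in zip(out[f"rna_{name}_log2FC"],
                               out[f"rpf_{name}_log2FC"],
                               out[f"te_lfc_{name}"])
        ]
    return out
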