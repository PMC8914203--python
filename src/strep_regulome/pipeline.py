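"""End-to-end orchestration: io -> expression -> tss -> tep -> tu ->
profiles -> motifs -> pausing, with a manifest tying every output to the
inputs, parameters and seed.

Every stage threshold defaults to the value the analysis is built around
(TAP ratio 1.5, cluster gap 100 bp, sub-cluster SD 10/25 bp, Term-seq count
floor 4, Z > 6, KNN k = 5, DEG alpha 0.05 / |log2FC| > 1, structured/
unstructured split -25 kcal/mol, pausing shift 14 nt, top-1000 sites).
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression as expr
from . import fold as fold_mod
from . import motifs as motifs_mod
from . import pausing as pausing_mod
from . import profiles as profiles_mod
from . import tep as tep_mod
from . import tss as tss_mod
from . import tu as tu_mod
from .io import GenomeAnnotation, load_genome, load_track, write_results
from .simulate import PHASES, SimConfig, generate_genome, simulate_tracks


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "results/run"
    # synthetic mode (inputs generated in-process) or a dataset directory
    synthetic: SimConfig | None = None
    dataset_dir: str | None = None
    # stage thresholds, defaults as printed in the methods
    tap_ratio: float = 1.5
    cluster_gap: int = 100
    tss_sd: float = 10.0
    tep_sd: float = 25.0
    tep_min_count: int = 4
    tep_min_z: float = 6.0
    knn_k: int = 5
    positive_cutoff: float = 0.5
    deg_alpha: float = 0.05
    deg_lfc: float = 1.0
    min_rna_tpm: float = 1.0
    utr_window: int = 500
    tu_max_span: int = 50_000
    tu_min_fraction: float = 0.05
    tu_raw_floor: float = 5.0
    profile_window: int = 300
    tep_motif_width: int = 10
    motif_p: float = 0.01
    dg_split: float = -25.0
    pausing_shift: int = 14
    pausing_min_density: float = 1.0
    top_n_sites: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.synthetic = SimConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunResult:
    config: RunConfig
    annotation: GenomeAnnotation
    truth: object | None
    tracks: dict
    counts: pd.DataFrame
    expression: pd.DataFrame = None
    tss_records: list = field(default_factory=list)
    tep_records: list = field(default_factory=list)
    tus: list = field(default_factory=list)
    tucs: list = field(default_factory=list)
    readthrough: dict = field(default_factory=dict)
    metaprofiles: dict = field(default_factory=dict)
    premature: dict = field(default_factory=dict)
    tep_pwm: object = None
    tep_dg: dict = field(default_factory=dict)
    interaction: object = None
    promoter: dict = field(default_factory=dict)
    pausing_tables: dict = field(default_factory=dict)
    codon_stats: dict = field(default_factory=dict)
    top_sites: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _log(stage: str, t0: float, msg: str) -> None:
    print(f"[{stage}] {time.time() - t0:6.1f}s {msg}", file=sys.stderr)


def load_dataset(dataset_dir: str | Path):
    """Load a dataset directory written by the generator (or compatible)."""
    d = Path(dataset_dir)
    annotation = load_genome(d / "genome.fasta", d / "genes.gff3")
    L = annotation.chrom_length("chr1")
    tracks = {}
    specs = [("drna_tap_plus", "dRNA_TAP+", None), ("drna_tap_minus", "dRNA_TAP-", None),
             ("term", "termseq", None)]
    for p in PHASES:
        specs += [(f"rna_{p}", "rna_cov", p), (f"rpf_{p}", "rpf_3end", p)]
    for stem, assay, phase in specs:
        for rep in (1, 2):
            counts = {}
            for strand, sfx in (("+", "plus"), ("-", "minus")):
                path = d / f"{stem}_{rep}.{sfx}.bedgraph"
                counts[strand] = load_track(path, strand, assay, L).counts[strand]
            sid = f"{stem}_{rep}"
            from .io import EndCountTrack
            tracks[sid] = EndCountTrack(sid, assay, counts, phase=phase, rep=rep)
    counts_df = pd.read_csv(d / "counts.tsv", sep="\t")
    return annotation, None, tracks, counts_df


def run_all(cfg: RunConfig, write: bool = True) -> RunResult:
    """Run every stage in dependency order; returns in-memory results.

    With ``write=True`` the stage outputs and a manifest land in
    ``cfg.outdir``.  A stage failure aborts with the stage name; outputs of
    completed stages are preserved on disk.
    """
    t0 = time.time()
    outdir = Path(cfg.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": cfg.to_dict(), "stages": {}, "seed": cfg.seed}

    # --- stage: io / simulate ---------------------------------------------
    stage = "io"
    try:
        if cfg.synthetic is not None:
            genome, annotation, truth = generate_genome(cfg.synthetic)
            tracks, counts_df = simulate_tracks(annotation, truth, cfg.synthetic)
        elif cfg.dataset_dir is not None:
            annotation, truth, tracks, counts_df = load_dataset(cfg.dataset_dir)
        else:
            raise ValueError("config needs either synthetic: or dataset_dir:")
        res = RunResult(cfg, annotation, truth, tracks, counts_df)
        L = annotation.chrom_length("chr1")
        manifest["stages"][stage] = {"genes": len(annotation.genes),
                                     "tracks": len(tracks)}
        _log(stage, t0, f"{len(annotation.genes)} genes, {len(tracks)} tracks")
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # --- stage: expression -------------------------------------------------
    stage = "expression"
    try:
        res.expression = expr.expression_table(
            counts_df, alpha=cfg.deg_alpha, lfc_cut=cfg.deg_lfc,
            min_rna_tpm=cfg.min_rna_tpm)
        if write:
            res.expression.reset_index().rename(columns={"index": "gene"}).to_csv(
                outdir / "deg_table.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"genes": len(res.expression)}
        _log(stage, t0, f"{len(res.expression)} genes classified")
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # normalized coverage shared by tu / profiles / tep features
    rna_cols = [c for c in counts_df.columns if c.endswith("_rna")]
    sf = expr.size_factors(counts_df.set_index("gene")[rna_cols]
                           if "gene" in counts_df.columns
                           else counts_df[rna_cols])
    raw_cov = {s: {} for s in "+-"}
    norm_cov = {s: {} for s in "+-"}
    for p in PHASES:
        for s in "+-":
            reps_raw = [tracks[f"rna_{p}_{r}"].counts[s] for r in (1, 2)]
            reps_norm = [arr / sf[f"{p}_{r}_rna"]
                         for r, arr in zip((1, 2), reps_raw)]
            raw_cov[s][p] = np.mean(reps_raw, axis=0)
            norm_cov[s][p] = np.mean(reps_norm, axis=0)
    pooled_norm = {s: sum(norm_cov[s][p] for p in PHASES) for s in "+-"}

    # --- stage: tss --------------------------------------------------------
    stage = "tss"
    try:
        records = []
        for s in "+-":
            recs = tss_mod.call_tss(
                [tracks[f"drna_tap_plus_{r}"].counts[s] for r in (1, 2)],
                [tracks[f"drna_tap_minus_{r}"].counts[s] for r in (1, 2)],
                s, gap=cfg.cluster_gap, sd_threshold=cfg.tss_sd,
                min_ratio=cfg.tap_ratio)
            records.extend(recs)
        tss_mod.categorize_tss(records, annotation, utr_window=cfg.utr_window)
        res.tss_records = sorted(records, key=lambda r: r.position)
        if write:
            write_results(res.tss_records, outdir / "tss.gff3", "gff3")
        manifest["stages"][stage] = {"tss": len(records)}
        _log(stage, t0, f"{len(records)} TSSs")
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # --- stage: tep --------------------------------------------------------
    stage = "tep"
    try:
        tep_records = []
        for s in "+-":
            term_reps = [tracks[f"term_{r}"].counts[s] for r in (1, 2)]
            cands = tep_mod.find_candidates(
                term_reps, pooled_norm[s], s, gap=cfg.cluster_gap,
                sd_threshold=cfg.tep_sd, min_count=cfg.tep_min_count,
                min_z=cfg.tep_min_z)
            if not cands:
                continue
            X, y, _meta = tep_mod.build_training_set(
                cands, np.sum(term_reps, axis=0), pooled_norm[s], s,
                positive_cutoff=cfg.positive_cutoff, seed=cfg.seed)
            tep_records.extend(tep_mod.knn_classify(cands, X, y, k=cfg.knn_k))
        tep_mod.categorize_tep(tep_records, annotation, res.tss_records)
        res.tep_records = sorted(tep_records, key=lambda r: r.position)
        manifest["stages"][stage] = {"tep": len(tep_records)}
        _log(stage, t0, f"{len(tep_records)} TEPs")
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # --- stage: tu ---------------------------------------------------------
    stage = "tu"
    try:
        res.tus = tu_mod.assemble_tus(
            res.tss_records, res.tep_records, raw_cov, norm_cov, annotation,
            max_span=cfg.tu_max_span, min_fraction=cfg.tu_min_fraction,
            raw_floor=cfg.tu_raw_floor)
        res.tucs = tu_mod.cluster_tucs(res.tus, res.tss_records, res.tep_records)
        terminal = {j for c in res.tucs for j in c.terminal_teps}
        nonterminal = {j for c in res.tucs for j in c.nonterminal_teps}
        for j, rec in enumerate(res.tep_records):
            rec.terminal = (j in terminal) if (j in terminal or j in nonterminal) else None
        # premature-TU intensity against the downstream CDS
        res.premature = {}
        norm_reps = {s: {p: [tracks[f"rna_{p}_{r}"].counts[s] / sf[f"{p}_{r}_rna"]
                             for r in (1, 2)] for p in PHASES} for s in "+-"}
        for ti, tu in enumerate(res.tus):
            if tu.category != "premature":
                continue
            tssr = res.tss_records[tu.tss_index]
            if tssr.gene_id is None:
                continue
            gene = annotation.by_id[tssr.gene_id]
            res.premature[ti] = tu_mod.premature_intensity(
                tu, gene, norm_reps[tu.strand])
        if write:
            write_results(res.tus, outdir / "tu.gff3", "gff3")
            rows = []
            for ci, c in enumerate(res.tucs):
                rows.append({
                    "tuc": ci, "strand": c.strand, "start": c.span[0],
                    "end": c.span[1],
                    "tus": ",".join(map(str, c.tu_indices)),
                    "terminal_teps": ",".join(
                        str(res.tep_records[j].position) for j in c.terminal_teps),
                    "nonterminal_teps": ",".join(
                        str(res.tep_records[j].position) for j in c.nonterminal_teps),
                })
            pd.DataFrame(rows).to_csv(outdir / "tuc.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"tu": len(res.tus), "tuc": len(res.tucs),
                                     "premature": len(res.premature)}
        _log(stage, t0, f"{len(res.tus)} TUs in {len(res.tucs)} TUCs")
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # --- stage: profiles ---------------------------------------------------
    stage = "profiles"
    try:
        tep_anchors = [(r.position, r.strand) for r in res.tep_records]
        tss_anchors = [(r.position, r.strand) for r in res.tss_records]
        res.metaprofiles["TEP"] = profiles_mod.normalized_density(
            pooled_norm, tep_anchors, window=cfg.profile_window, anchor_kind="TEP")
        res.metaprofiles["TSS"] = profiles_mod.normalized_density(
            pooled_norm, tss_anchors, window=cfg.profile_window, anchor_kind="TSS")
        res.readthrough = {
            a: profiles_mod.read_through_fraction(pooled_norm, a,
                                                  window=cfg.profile_window)
            for a in tep_anchors}
        if write:
            pd.DataFrame({
                "offset": res.metaprofiles["TEP"].offsets,
                "tep_density": res.metaprofiles["TEP"].mean_density,
                "tss_density": res.metaprofiles["TSS"].mean_density,
            }).to_csv(outdir / "metaprofile.tsv", sep="\t", index=False)
            pd.DataFrame([
                {"position": p, "strand": s, "readthrough": v}
                for (p, s), v in res.readthrough.items()
            ]).to_csv(outdir / "readthrough.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"anchors": len(tep_anchors)}
        _log(stage, t0, "meta-profiles done")
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # --- stage: motifs / structure ----------------------------------------
    stage = "motifs"
    try:
        res.tep_pwm = None
        if len(res.tep_records) >= 10:
            windows = motifs_mod.extract_windows(
                [(r.position, r.strand) for r in res.tep_records],
                annotation, -40, 20)
            seqs = [w for _a, w in windows]
            anchors = [a for a, _w in windows]
            res.tep_pwm = motifs_mod.discover_motif(
                seqs, width=cfg.tep_motif_width, mode="zoops", seed=cfg.seed)
            # motif membership = zoops site assignment (a window either
            # carries the conserved element or it does not); the scan with
            # per-position p-values serves regulon searches instead
            hit_anchor_idx = {i for (i, _off) in res.tep_pwm.sites}
            dgs = motifs_mod.tep_fold_energies(res.tep_records, annotation)
            res.tep_dg = dgs
            for i, rec in enumerate(res.tep_records):
                fr = dgs.get(rec.position)
                rec.dG = fr.dG if fr else None
                anchor_i = next((k for k, a in enumerate(anchors)
                                 if a[0] == rec.position), None)
                has_hit = anchor_i in hit_anchor_idx
                if fr is not None:
                    rec.subcategory = motifs_mod.classify_tep_subcategory(
                        fr.dG, has_hit, dg_split=cfg.dg_split)
        # base-pairing interaction frequencies over the 100 nt upstream of TEPs
        if res.tep_records:
            up = motifs_mod.extract_windows(
                [(r.position, r.strand) for r in res.tep_records],
                annotation, -100, 0)
            folds = [fold_mod.fold_energy(seq) for _a, seq in up]
            res.interaction = fold_mod.interaction_frequency(
                [f.pairs for f in folds], 101)
            if write:
                pd.DataFrame(res.interaction).to_csv(
                    outdir / "interaction_matrix.tsv", sep="\t",
                    index=False, header=False)
        # promoter -10/-35 motifs and spacers from primary TSSs
        prim = [(r.position, r.strand) for r in res.tss_records
                if r.category == "primary"]
        res.promoter = {}
        if len(prim) >= 10:
            w10 = motifs_mod.extract_windows(prim, annotation, -25, 1)
            w35 = motifs_mod.extract_windows(prim, annotation, -40, -25)
            pwm10 = motifs_mod.discover_motif([s for _a, s in w10], width=6,
                                              mode="oops", seed=cfg.seed)
            pwm35 = motifs_mod.discover_motif([s for _a, s in w35], width=4,
                                              mode="oops", seed=cfg.seed)
            # spacer: offsets back in TSS-relative coordinates
            h10 = {i: (off - 25, off - 25 + 5) for i, off in pwm10.sites}
            h35 = {i: (off - 40, off - 40 + 3) for i, off in pwm35.sites}
            spacers = motifs_mod.spacer_lengths(h35, h10)
            res.promoter = {"pwm10": pwm10, "pwm35": pwm35, "spacers": spacers}
        if write and res.tep_pwm is not None:
            (outdir / "pwm.json").write_text(json.dumps(res.tep_pwm.to_dict()))
            write_results(res.tep_records, outdir / "tep.gff3", "gff3")
            pd.DataFrame([
                {"position": r.position, "strand": r.strand, "dG": r.dG,
                 "subcategory": r.subcategory} for r in res.tep_records
            ]).to_csv(outdir / "fold.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "tep_motif_consensus": res.tep_pwm.consensus if res.tep_pwm else None,
            "promoter_spacer_mode": (
                int(pd.Series(list(res.promoter["spacers"].values())).mode()[0])
                if res.promoter.get("spacers") else None),
        }
        _log(stage, t0, "motifs/structure done")
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # --- stage: pausing ----------------------------------------------------
    stage = "pausing"
    try:
        for p in PHASES:
            track = {s: (tracks[f"rpf_{p}_1"].counts[s]
                         + tracks[f"rpf_{p}_2"].counts[s]) / 2.0 for s in "+-"}
            table = pausing_mod.pausing_scores(
                track, annotation, p, shift=cfg.pausing_shift,
                min_density=cfg.pausing_min_density)
            res.pausing_tables[p] = table
            res.codon_stats[p] = pausing_mod.codon_pausing(table)
        res.top_sites["T"] = pausing_mod.top_sites_analysis(
            res.pausing_tables["T"], annotation, n=cfg.top_n_sites,
            seed=cfg.seed, shift=cfg.pausing_shift)
        if write:
            pd.concat(res.pausing_tables.values()).to_csv(
                outdir / "pausing.tsv", sep="\t", index=False)
            pd.concat({p: df for p, df in res.codon_stats.items()},
                      names=["phase"]).to_csv(outdir / "codon_stats.tsv", sep="\t")
        manifest["stages"][stage] = {
            "scored_sites": {p: len(t) for p, t in res.pausing_tables.items()},
            "top_n": res.top_sites["T"]["n"],
        }
        _log(stage, t0, "pausing done")
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    res.manifest = manifest
    if write:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                         default=str))
    return res
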