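"""Synthetic multi-omics generator with a machine-readable planted truth set.

Emulates the four track types the pipeline consumes on a small high-GC
bacterial genome: dRNA-seq 5'-end counts (TAP+/TAP-, duplicate libraries,
growth phases pooled), Term-seq 3'-end counts with surrounding shadow peaks,
step-shaped strand-specific RNA coverage for three growth phases (E/T/S,
duplicates), and RPF 3'-end counts with planted ribosome pausing sites.
Every planted feature is recorded in a :class:`TruthSet` so each downstream
stage is testable by recovery.

Modelling choices (rationale in docs/methods.md):

* per-position coverage and gene-level counts are negative-binomial
  (gamma-Poisson) with configurable dispersion; sharp end-count peaks are
  Poisson, a single-position end count carrying no excess variance beyond
  sampling in this model;
* every true TSS gets one processed-end decoy 50-500 nt downstream whose
  TAP+/TAP- ratio is drawn in [0.8, 1.3], exercising the 1.5x filter;
* terminators at motif-class TEPs carry a GC-rich stem-loop followed by a
  CGT/T-rich tract; structured non-motif TEPs carry a stem-loop only;
  unstructured TEPs sit in an AT-rich patch;
* coordinates in the truth set are 1-based and strand-aware, matching GFF3.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import EndCountTrack, Gene, GenomeAnnotation, write_fasta, write_gff3, write_track, write_results

PHASES = ("E", "T", "S")
STOP_CODONS = {"TAA", "TAG", "TGA"}

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX"]
# fixed bijection between (ET call, TS call) and group number
GROUP_MAP = {
    ("U", "U"): "I", ("U", "D"): "II", ("U", "N"): "III",
    ("D", "U"): "IV", ("D", "D"): "V", ("D", "N"): "VI",
    ("N", "U"): "VII", ("N", "D"): "VIII", ("N", "N"): "IX",
}
_CALLS_OF_GROUP = {g: calls for calls, g in GROUP_MAP.items()}
_LFC_OF_CALL = {"U": 2.0, "D": -2.0, "N": 0.0}


class SimulationSizingError(ValueError):
    """Genome too short for the requested gene count (or too few genes)."""


@dataclass
class SimConfig:
    genome_length: int = 60_000
    gc: float = 0.72
    n_genes: int = 40
    seed: int = 0
    # coverage / counts noise; background stays below the 5-raw-count window
    # floor so silent gaps between units cannot evidence continuity
    background_cov: float = 2.0
    cov_dispersion: float = 0.1
    count_dispersion: float = 0.05
    count_depth: float = 400.0  # expected gene counts = level * length / this
    # dRNA-seq
    tap_enrichment: float = 4.0
    tss_peak_mean: float = 80.0
    decoy_peak_mean: float = 100.0
    # Term-seq
    tep_peak_mean: float = 60.0
    shadow_mean: float = 6.0
    readthrough_terminal: float = 0.1
    readthrough_nonterminal: float = 0.3
    # feature frequencies
    p_secondary_tss: float = 0.3
    p_internal_tss: float = 0.25
    p_orphan_tss: float = 0.15
    p_premature: float = 0.2
    p_nonterminal: float = 0.35
    p_term_decoy: float = 0.5
    n_antisense: int = 2
    n_intergenic: int = 2
    # ribosome profiling
    rpf_background: float = 0.05
    pause_sites_per_gene: float = 6.0
    pause_stem_fraction: float = 0.7
    n_tta_genes: int = 6
    tta_intensity: float = 25.0

    def validate(self) -> None:
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("GC fraction must be in [0, 1]")
        if self.n_genes < 2:
            raise SimulationSizingError("at least 2 genes are required")
        if self.genome_length < 2000:
            raise SimulationSizingError("genome too short")


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------

@dataclass
class TrueTSS:
    position: int  # 1-based
    strand: str
    category: str  # primary / secondary / internal / antisense / orphan
    tap_ratio: float
    gene_id: str | None = None
    utr_len: int | None = None
    leader_class: str | None = None
    peak_mean: float = 80.0


@dataclass
class TrueDecoy:
    position: int
    strand: str
    tap_ratio: float
    peak_mean: float = 40.0


@dataclass
class TrueTEP:
    position: int
    strand: str
    subcategory: str | None  # motif / structured / unstructured / None (uncontrolled)
    terminal: bool
    readthrough: float
    category: str  # primary / premature / antisense / intergenic
    peak_mean: float = 60.0


@dataclass
class TrueTU:
    tss_index: int
    tep_index: int
    gene_ids: list[str]
    category: str  # monocistronic / polycistronic / premature / antisense / intergenic


@dataclass
class TruePause:
    gene_id: str
    cds_pos: int  # 0-based nt offset of the P-site codon's first nt
    codon: str  # A-site codon
    intensity: dict  # phase -> multiplier
    has_stem: bool


@dataclass
class TruthSet:
    tss_list: list
    decoy_list: list
    tep_list: list
    tu_list: list
    deg_table: pd.DataFrame  # per gene: lfc / levels / group / te class
    pausing_sites: list

    def validate(self, annotation: GenomeAnnotation) -> None:
        for tu in self.tu_list:
            tss = self.tss_list[tu.tss_index]
            tep = self.tep_list[tu.tep_index]
            assert tss.strand == tep.strand
            if tss.strand == "+":
                assert tss.position < tep.position
            else:
                assert tss.position > tep.position
        for row in self.deg_table.itertuples():
            et = "U" if row.rna_lfc_et > 1 else "D" if row.rna_lfc_et < -1 else "N"
            ts = "U" if row.rna_lfc_ts > 1 else "D" if row.rna_lfc_ts < -1 else "N"
            assert GROUP_MAP[(et, ts)] == row.group
        for p in self.pausing_sites:
            gene = annotation.by_id[p.gene_id]
            ncod = gene.length // 3
            assert 30 <= p.cds_pos <= (ncod - 11) * 3

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tss_list": [dataclasses.asdict(t) for t in self.tss_list],
            "decoy_list": [dataclasses.asdict(t) for t in self.decoy_list],
            "tep_list": [dataclasses.asdict(t) for t in self.tep_list],
            "tu_list": [dataclasses.asdict(t) for t in self.tu_list],
            "deg_table": self.deg_table.to_dict(orient="list"),
            "pausing_sites": [dataclasses.asdict(t) for t in self.pausing_sites],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        d = json.loads(Path(path).read_text())
        return cls(
            tss_list=[TrueTSS(**r) for r in d["tss_list"]],
            decoy_list=[TrueDecoy(**r) for r in d["decoy_list"]],
            tep_list=[TrueTEP(**r) for r in d["tep_list"]],
            tu_list=[TrueTU(**r) for r in d["tu_list"]],
            deg_table=pd.DataFrame(d["deg_table"]),
            pausing_sites=[TruePause(**r) for r in d["pausing_sites"]],
        )


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _rand_bases(rng, n, gc):
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _rand_codon(rng, gc):
    while True:
        c = _rand_bases(rng, 3, gc)
        if c not in STOP_CODONS and c != "TTA":
            return c


def _hairpin_seq(rng, stem: int, loop: int = 4) -> str:
    left = "".join(rng.choice(["G", "C"], size=stem))
    loop_s = "".join(rng.choice(["A", "C"], size=loop))
    return left + loop_s + _revcomp(left)


# GC-only codons used when a stem is written inside a CDS (no stops, no TTA)
_GC_CODONS = ["GGC", "GCC", "CGG", "CCG", "GCG", "CGC", "GGG", "CCC"]


# ---------------------------------------------------------------------------
# cassette plan (transcription-local coordinates, 0-based)
# ---------------------------------------------------------------------------

@dataclass
class _Unit:
    seq: list = field(default_factory=list)
    strand: str = "+"
    # (local, category, peak_mean); index 0 is the primary TSS when genes exist
    tss: list = field(default_factory=list)
    decoys: list = field(default_factory=list)  # local positions
    genes: list = field(default_factory=list)  # (cds_start, cds_end) local closed
    gene_ids: list = field(default_factory=list)
    teps: list = field(default_factory=list)  # dicts
    pauses: list = field(default_factory=list)  # dicts
    term_decoys: list = field(default_factory=list)
    group: str = "IX"
    buffered: bool = False
    base_level: float = 600.0
    rpf_density: float = 5.0
    premature_att: dict | None = None
    offset: int = 0  # 0-based genome offset after placement

    def glob(self, local: int) -> int:
        if self.strand == "+":
            return self.offset + local + 1
        return self.offset + (len(self.seq) - 1 - local) + 1

    def rna_lfc(self):
        et, ts = _CALLS_OF_GROUP[self.group]
        return _LFC_OF_CALL[et], _LFC_OF_CALL[ts]

    def rpf_lfc(self):
        if self.buffered:
            return 0.0, 0.0
        return self.rna_lfc()

    def levels(self, kind: str = "rna") -> dict:
        l_et, l_ts = self.rna_lfc() if kind == "rna" else self.rpf_lfc()
        base = self.base_level if kind == "rna" else self.rpf_density
        e = base
        t = e * 2.0 ** l_et
        s = t * 2.0 ** l_ts
        return {"E": e, "T": t, "S": s}


def _nb(rng, mean, dispersion):
    mean = np.maximum(np.asarray(mean, dtype=float), 0.0)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return np.asarray(rng.poisson(lam), dtype=float)


# ---------------------------------------------------------------------------
# cassette construction
# ---------------------------------------------------------------------------

def _build_cassette(rng, config: SimConfig, size: int, group: str) -> _Unit:
    """One transcribed unit with ``size`` genes (0 = intergenic unit)."""
    u = _Unit()
    u.group = group
    u.strand = "+" if rng.random() < 0.6 else "-"
    u.buffered = rng.random() < 0.15
    u.base_level = float(rng.uniform(400, 1200))
    u.rpf_density = float(rng.uniform(3.0, 8.0)) if rng.random() > 0.12 else 0.5
    gc = config.gc
    seq = u.seq

    def emit(s: str) -> int:
        start = len(seq)
        seq.extend(s)
        return start

    premature = size >= 1 and rng.random() < config.p_premature
    nonterminal = size >= 2 and not premature and rng.random() < config.p_nonterminal

    emit(_rand_bases(rng, 60, gc))
    emit("TGAC")  # -35 element, ends 25 nt upstream of the TSS
    emit(_rand_bases(rng, 12, gc))  # 12-nt spacer
    emit("TA" + _rand_bases(rng, 3, gc) + "T")  # -10 element at -12..-7
    emit(_rand_bases(rng, 6, gc))
    tss_local = len(seq)
    u.tss.append((tss_local, "primary" if size else "orphan", config.tss_peak_mean))

    if size == 0:
        emit(_rand_bases(rng, 250, gc))
    elif premature:
        # deep 5'-UTR so the -300 read-through window of the premature TEP is
        # mostly covered; attenuation strongest in E, weakest in S
        utr = int(rng.integers(280, 311))
        utr_start = len(seq)
        emit(_rand_bases(rng, utr, gc))
        ploc = utr_start + int(rng.integers(230, utr - 45))
        subcat = "structured" if rng.random() < 0.5 else "unstructured"
        _write_tep_element(seq, rng, ploc, subcat)
        u.teps.append(dict(local=ploc, subcat=subcat, terminal=False, kind="premature",
                           readthrough=None, peak=config.tep_peak_mean * 0.8))
        u.premature_att = {"E": 0.1, "T": 0.2, "S": 0.4}
    else:
        cls = rng.choice(["lm", "mm", "em"], p=[0.2, 0.55, 0.25])
        utr = int(rng.integers(0, 11) if cls == "lm"
                  else rng.integers(11, 101) if cls == "mm"
                  else rng.integers(101, 301))
        emit(_rand_bases(rng, utr, gc))

    for gi in range(size):
        cds_start = len(seq)
        ncod = int(rng.integers(150, 225))
        codons = ["ATG"] + [_rand_codon(rng, min(gc + 0.05, 0.95)) for _ in range(ncod - 2)]
        codons.append("TGA")
        _plant_pauses(u, rng, config, gi, codons)
        emit("".join(codons))
        u.genes.append((cds_start, len(seq) - 1))
        for p in u.pauses:
            if p["gene_index"] == gi and "cds_start" not in p:
                p["cds_start"] = cds_start
        if gi < size - 1:
            if nonterminal and gi == 0:
                gap_start = len(seq)
                emit(_rand_bases(rng, 115, gc))
                ploc = gap_start + 52
                subcat = "structured" if rng.random() < 0.5 else "unstructured"
                _write_tep_element(seq, rng, ploc, subcat)
                u.teps.append(dict(local=ploc, subcat=subcat, terminal=False,
                                   kind="internal",
                                   readthrough=config.readthrough_nonterminal,
                                   peak=config.tep_peak_mean * 0.7))
            else:
                emit(_rand_bases(rng, int(rng.integers(25, 60)), gc))

    # 3' end: short UTR, then the terminal TEP with its element
    emit(_rand_bases(rng, int(rng.integers(25, 45)), gc))
    tep_local = len(seq) + 44
    emit(_rand_bases(rng, 65, gc))
    subcat = str(rng.choice(["motif", "structured", "unstructured"], p=[0.4, 0.3, 0.3]))
    _write_tep_element(seq, rng, tep_local, subcat)
    # termination efficiency is ordered by class: motif terminators drop
    # hardest, unstructured 3' ends read through the most
    rt = config.readthrough_terminal * {"motif": 0.5, "structured": 1.0,
                                        "unstructured": 2.0}[subcat]
    u.teps.append(dict(local=tep_local, subcat=subcat, terminal=True, kind="terminal",
                       readthrough=rt, peak=config.tep_peak_mean))

    # read-through tail; sequence here is plain background
    emit(_rand_bases(rng, 440, gc))

    _plan_extra_sites(u, rng, config, size, tep_local)
    return u


def _write_tep_element(seq: list, rng, tep_local: int, subcat: str) -> None:
    def put(at: int, s: str):
        seq[at : at + len(s)] = list(s)

    if subcat == "motif":
        put(tep_local - 34, _hairpin_seq(rng, stem=11, loop=4))  # 26 nt, ends at -9
        put(tep_local - 4, "CGT" + "T" * 8)
    elif subcat == "structured":
        put(tep_local - 37, _hairpin_seq(rng, stem=13, loop=4))  # 30 nt, ends at -8
    else:
        # A-rich, T-poor patch: no U-tract (so no terminator-motif mimicry)
        # and few A:U partners (so no stable hairpin in the fold window)
        probs = [0.45, 0.2, 0.2, 0.15]
        patch = list("".join(rng.choice(list("ACGT"), size=48, p=probs)))
        prev_t = False
        for k, ch in enumerate(patch):
            if ch == "T" and prev_t:
                patch[k] = str(rng.choice(["A", "C", "G"]))
            prev_t = patch[k] == "T"
        patch = "".join(patch).replace("CGT", "CAA")
        put(tep_local - 42, patch)


def _plant_pauses(u: _Unit, rng, config: SimConfig, gene_index: int, codons: list) -> None:
    if u.rpf_density <= 1.0:
        return
    ncod = len(codons)
    if ncod < 60:
        return
    placed = []
    for _ in range(rng.poisson(config.pause_sites_per_gene)):
        k_p = int(rng.integers(12, ncod - 24))  # P-site codon index
        if any(abs(k_p - q) < 25 for q in placed):
            continue
        placed.append(k_p)
        has_stem = rng.random() < config.pause_stem_fraction
        if has_stem:
            # GC stem inside the +40 nt window downstream of the RPF 3' boundary
            c0 = (3 * k_p + 17) // 3
            for ci in range(c0, min(c0 + 10, ncod - 1)):
                codons[ci] = _GC_CODONS[int(rng.integers(0, len(_GC_CODONS)))]
            stem = _hairpin_seq(rng, stem=12, loop=4)  # 28 nt
            block = list("".join(codons[c0 : c0 + 10]))
            block[1 : 1 + 28] = list(stem)
            for ci in range(10):
                if c0 + ci < ncod - 1:
                    cod = "".join(block[3 * ci : 3 * ci + 3])
                    if cod in STOP_CODONS or cod == "TTA":
                        cod = "GC" + cod[2]
                    codons[c0 + ci] = cod
        intensity = float(rng.uniform(8, 30))
        u.pauses.append(dict(gene_index=gene_index, k_p=k_p,
                             intensity={p: intensity for p in PHASES},
                             has_stem=has_stem, codon=codons[k_p + 1]))


def _plan_extra_sites(u: _Unit, rng, config: SimConfig, size: int, term_local: int) -> None:
    """Secondary/internal/orphan TSSs, 5'-end decoys, Term-seq decoy clusters."""
    primary_loc = u.tss[0][0]
    taken = [primary_loc]
    if size == 0:
        return
    # one processed-end decoy per true TSS
    for _ in range(40):
        cand = primary_loc + int(rng.integers(50, 501))
        if cand < term_local - 60 and all(abs(cand - q) >= 30 for q in taken):
            u.decoys.append(cand)
            taken.append(cand)
            break
    if rng.random() < config.p_secondary_tss:
        loc = primary_loc - int(rng.integers(35, 51))
        u.tss.append((loc, "secondary", config.tss_peak_mean * 0.35))
        taken.append(loc)
    if rng.random() < config.p_internal_tss:
        gs, ge = u.genes[-1]
        if ge - gs > 280:
            loc = int(rng.integers(gs + 60, ge - 210))
            if all(abs(loc - q) >= 30 for q in taken):
                u.tss.append((loc, "internal", config.tss_peak_mean * 0.3))
                taken.append(loc)
    if rng.random() < config.p_orphan_tss:
        loc = term_local + 80
        u.tss.append((loc, "orphan", config.tss_peak_mean * 0.5))
        taken.append(loc)
    if rng.random() < config.p_term_decoy:
        gs, ge = u.genes[0]
        if ge - gs > 320:
            center = int(rng.integers(gs + 120, ge - 120))
            offs = np.sort(rng.choice(np.arange(-30, 31), size=8, replace=False))
            u.term_decoys.append(dict(center=center, offsets=offs.tolist(),
                                      heights=rng.uniform(5, 12, size=8).tolist()))


# ---------------------------------------------------------------------------
# generate_genome
# ---------------------------------------------------------------------------

def generate_genome(config: SimConfig):
    """Build genome sequence, annotation and planted truth; seed-deterministic.

    Returns ``(genome_str, GenomeAnnotation, TruthSet)``.  Raises
    :class:`SimulationSizingError` when the requested genes cannot fit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    units: list[_Unit] = []
    group_cycle = 0
    genes_left = config.n_genes
    while genes_left > 0:
        size = min(int(rng.choice([1, 2, 3], p=[0.45, 0.35, 0.2])), genes_left)
        genes_left -= size
        units.append(_build_cassette(rng, config, size, ROMAN[group_cycle % 9]))
        group_cycle += 1
    for _ in range(config.n_intergenic):
        units.append(_build_cassette(rng, config, 0, "IX"))

    # TTA pause codons: T-phase-specific pausing in well-translated genes
    candidates = [u for u in units
                  if u.genes and u.rpf_density > 1.0 and u.levels("rpf")["T"] >= 2.0]
    order = rng.permutation(len(candidates))
    for ui in order[: config.n_tta_genes]:
        u = candidates[ui]
        gs, ge = u.genes[0]
        ncod = (ge - gs + 1) // 3
        for _ in range(50):
            k_p = int(rng.integers(12, ncod - 24))
            if all(abs(k_p - p["k_p"]) >= 25 for p in u.pauses if p["gene_index"] == 0):
                break
        else:
            continue
        a0 = gs + 3 * (k_p + 1)
        u.seq[a0 : a0 + 3] = list("TTA")
        u.pauses.append(dict(gene_index=0, k_p=k_p, cds_start=gs,
                             intensity={"E": 1.0, "T": config.tta_intensity, "S": 1.0},
                             has_stem=False, codon="TTA"))

    # placement
    genome_len = config.genome_length
    seq_arr = np.full(genome_len, "", dtype="U1")
    cursor = 20
    for u in units:
        clen = len(u.seq)
        if cursor + clen > genome_len - 20:
            raise SimulationSizingError(
                f"genome length {genome_len} too short for {config.n_genes} genes"
            )
        u.offset = cursor
        cass = "".join(u.seq)
        if u.strand == "-":
            cass = _revcomp(cass)
        seq_arr[cursor : cursor + clen] = list(cass)
        cursor += clen + int(rng.integers(140, 220))

    truth, annotation = _assemble_truth(units, config)
    _plant_antisense(units, truth, rng, config, genome_len)

    # tune background GC so the whole genome lands on the configured fraction
    assigned = seq_arr != ""
    n_free = int((~assigned).sum())
    if n_free > 0:
        gc_assigned = int(np.isin(seq_arr[assigned], ["G", "C"]).sum())
        gc_fill = float(np.clip((config.gc * genome_len - gc_assigned) / n_free, 0.05, 0.95))
        seq_arr[~assigned] = list(_rand_bases(rng, n_free, gc_fill))
    genome = "".join(seq_arr)
    annotation.seqs = {"chr1": genome}
    annotation.__post_init__()
    truth.validate(annotation)
    truth._units = units  # internal handle used by simulate_tracks
    return genome, annotation, truth


def _assemble_truth(units, config: SimConfig):
    genes, tss_list, decoy_list, tep_list, tu_list, pausing, deg_rows = [], [], [], [], [], [], []
    counter = 0
    rng = np.random.default_rng(config.seed + 999)  # decoy TAP ratios only

    for u in units:
        for (s_loc, e_loc) in u.genes:
            gid = f"g{counter:04d}"
            counter += 1
            a, b = u.glob(s_loc), u.glob(e_loc)
            genes.append(Gene(gid, "chr1", u.strand, min(a, b), max(a, b)))
            u.gene_ids.append(gid)
            l_et, l_ts = u.rna_lfc()
            r_et, r_ts = u.rpf_lfc()
            deg_rows.append(dict(
                gene_id=gid, length=abs(b - a) + 1, group=u.group,
                rna_lfc_et=l_et, rna_lfc_ts=l_ts, rpf_lfc_et=r_et, rpf_lfc_ts=r_ts,
                buffered=u.buffered, base_level=u.base_level, rpf_density=u.rpf_density,
            ))

        unit_tss_indices = []
        for (loc, cat, peak) in u.tss:
            gene_id = utr = lclass = None
            if cat in ("primary", "secondary") and u.genes:
                gene_id = u.gene_ids[0]
            if cat == "primary" and u.genes:
                utr = u.genes[0][0] - loc
                lclass = "lmRNA" if utr <= 10 else "mmRNA" if utr <= 100 else "emRNA"
            tss_list.append(TrueTSS(u.glob(loc), u.strand, cat, config.tap_enrichment,
                                    gene_id=gene_id, utr_len=utr, leader_class=lclass,
                                    peak_mean=peak))
            unit_tss_indices.append((loc, cat, len(tss_list) - 1))

        for dloc in u.decoys:
            decoy_list.append(TrueDecoy(u.glob(dloc), u.strand,
                                        float(rng.uniform(0.8, 1.3)),
                                        peak_mean=config.decoy_peak_mean))

        unit_tep_indices = []
        for t in u.teps:
            cat = "premature" if t["kind"] == "premature" else (
                "intergenic" if not u.genes else "primary")
            tep_list.append(TrueTEP(u.glob(t["local"]), u.strand, t["subcat"],
                                    t["terminal"],
                                    t["readthrough"] if t["readthrough"] is not None else 1.0,
                                    cat, peak_mean=t["peak"]))
            unit_tep_indices.append((t, len(tep_list) - 1))

        for (loc, cat, ti) in unit_tss_indices:
            if cat == "orphan" and u.genes:
                continue  # orphan TSS sits in the tail, downstream of all TEPs
            for t, tj in unit_tep_indices:
                if t["local"] <= loc:
                    continue
                contained = [gid for gid, (gs, ge) in zip(u.gene_ids, u.genes)
                             if gs >= loc and ge <= t["local"]]
                if not u.genes:
                    cat_tu = "intergenic"
                elif t["kind"] == "premature" and not contained:
                    cat_tu = "premature"
                elif len(contained) >= 2:
                    cat_tu = "polycistronic"
                else:
                    cat_tu = "monocistronic"
                tu_list.append(TrueTU(ti, tj, contained, cat_tu))

        for p in u.pauses:
            pausing.append(TruePause(u.gene_ids[p["gene_index"]], 3 * p["k_p"],
                                     p["codon"], p["intensity"], p["has_stem"]))

    deg = pd.DataFrame(deg_rows)
    annotation = GenomeAnnotation(seqs={"chr1": ""}, genes=genes)
    return TruthSet(tss_list, decoy_list, tep_list, tu_list, deg, pausing), annotation


def _plant_antisense(units, truth: TruthSet, rng, config: SimConfig, genome_len: int):
    """Antisense TSS/TEP/TU records on the strand opposite a host gene.

    No sequence is written (the antisense transcript reads the existing
    opposite strand), so the TEP subcategory is uncontrolled (None).
    """
    hosts = [u for u in units if u.strand == "+" and u.genes
             and (u.genes[0][1] - u.genes[0][0]) > 450]
    order = rng.permutation(len(hosts))
    for hi in order[: config.n_antisense]:
        u = hosts[int(hi)]
        gs, ge = u.genes[0]
        tep_local = gs + int(rng.integers(60, 120))
        tss_local = tep_local + int(rng.integers(260, 340))
        tss_g, tep_g = u.glob(tss_local), u.glob(tep_local)  # host is '+'
        strand = "-"
        truth.tss_list.append(TrueTSS(tss_g, strand, "antisense", config.tap_enrichment,
                                      peak_mean=config.tss_peak_mean * 0.5))
        truth.tep_list.append(TrueTEP(tep_g, strand, None, True,
                                      config.readthrough_terminal, "antisense",
                                      peak_mean=config.tep_peak_mean * 0.7))
        truth.tu_list.append(TrueTU(len(truth.tss_list) - 1, len(truth.tep_list) - 1,
                                    [], "antisense"))
        u.term_decoys = [d for d in u.term_decoys
                         if abs(d["center"] - tep_local) > 400]


# ---------------------------------------------------------------------------
# simulate_tracks
# ---------------------------------------------------------------------------

def simulate_tracks(annotation: GenomeAnnotation, truth: TruthSet, config: SimConfig):
    """Sample all end-count and coverage tracks plus gene-level count tables.

    Returns ``(tracks, counts)`` where ``tracks`` maps sample id to
    :class:`EndCountTrack` and ``counts`` is a per-gene DataFrame with one
    column per sample (``{phase}_{rep}_{rna|rpf}``).
    """
    rng = np.random.default_rng(config.seed + 1)
    units = truth._units
    L = annotation.chrom_length("chr1")

    # --- expected RNA coverage per phase, per strand -----------------------
    profiles = {p: {"+": np.full(L, config.background_cov),
                    "-": np.full(L, config.background_cov)} for p in PHASES}
    for u in units:
        levels = u.levels("rna")
        for p in PHASES:
            _add_unit_coverage(profiles[p][u.strand], u, levels[p], p, config, L)
    _add_antisense_coverage(profiles, truth, config, L)

    tracks = {}
    for p in PHASES:
        for rep in (1, 2):
            counts = {s: _nb(rng, profiles[p][s], config.cov_dispersion)
                      for s in ("+", "-")}
            sid = f"rna_{p}_{rep}"
            tracks[sid] = EndCountTrack(sid, "rna_cov", counts, phase=p, rep=rep)

    # --- dRNA-seq 5' end tracks (phases pooled) ----------------------------
    for rep in (1, 2):
        plus = {s: np.zeros(L) for s in ("+", "-")}
        minus = {s: np.zeros(L) for s in ("+", "-")}
        for t in truth.tss_list:
            i = t.position - 1
            plus[t.strand][i] += rng.poisson(t.peak_mean)
            minus[t.strand][i] += rng.poisson(t.peak_mean / t.tap_ratio)
        for d in truth.decoy_list:
            i = d.position - 1
            plus[d.strand][i] += rng.poisson(d.peak_mean * d.tap_ratio)
            minus[d.strand][i] += rng.poisson(d.peak_mean)
        for arr_set in (plus, minus):
            for s in ("+", "-"):
                idx = rng.integers(0, L, size=L // 150)
                np.add.at(arr_set[s], idx, rng.poisson(1.0, size=idx.size) + 1)
        tracks[f"drna_tap_plus_{rep}"] = EndCountTrack(
            f"drna_tap_plus_{rep}", "dRNA_TAP+", plus, rep=rep)
        tracks[f"drna_tap_minus_{rep}"] = EndCountTrack(
            f"drna_tap_minus_{rep}", "dRNA_TAP-", minus, rep=rep)

    # --- Term-seq 3' end tracks (phases pooled) ----------------------------
    shadow_plan = []
    for t in truth.tep_list:
        offs = np.sort(rng.choice(np.concatenate([np.arange(-45, -7), np.arange(8, 46)]),
                                  size=5, replace=False))
        shadow_plan.append((t, offs, rng.uniform(4, 9, size=5)))
    for rep in (1, 2):
        term = {s: np.zeros(L) for s in ("+", "-")}
        for t, offs, means in shadow_plan:
            i = t.position - 1
            term[t.strand][i] += rng.poisson(t.peak_mean)
            for o, m in zip(offs, means):
                j = i + int(o)
                if 0 <= j < L:
                    term[t.strand][j] += rng.poisson(m)
        for u in units:
            for d in u.term_decoys:
                for o, m in zip(d["offsets"], d["heights"]):
                    j = u.glob(d["center"] + int(o)) - 1
                    if 0 <= j < L:
                        term[u.strand][j] += rng.poisson(m)
        for s in ("+", "-"):
            idx = rng.integers(0, L, size=L // 200)
            np.add.at(term[s], idx, rng.poisson(0.8, size=idx.size) + 1)
        tracks[f"term_{rep}"] = EndCountTrack(f"term_{rep}", "termseq", term, rep=rep)

    # --- RPF 3'-end tracks -------------------------------------------------
    pause_by_gene = {}
    for ps in truth.pausing_sites:
        pause_by_gene.setdefault(ps.gene_id, []).append(ps)
    for p in PHASES:
        base = {s: np.full(L, config.rpf_background) for s in ("+", "-")}
        for u in units:
            dens = u.levels("rpf")[p]
            for gid, (gs, ge) in zip(u.gene_ids, u.genes):
                g = annotation.by_id[gid]
                base[g.strand][g.start - 1 : g.end] = dens
                for ps in pause_by_gene.get(gid, []):
                    off = ps.cds_pos + 14
                    pos = (g.start - 1 + off) if g.strand == "+" else (g.end - 1 - off)
                    base[g.strand][pos] = dens * ps.intensity[p]
        for rep in (1, 2):
            counts = {s: _nb(rng, base[s], config.cov_dispersion) for s in ("+", "-")}
            sid = f"rpf_{p}_{rep}"
            tracks[sid] = EndCountTrack(sid, "rpf_3end", counts, phase=p, rep=rep)

    # --- gene-level count tables -------------------------------------------
    rows = []
    for u in units:
        rna = u.levels("rna")
        rpf = u.levels("rpf")
        for gid, (gs, ge) in zip(u.gene_ids, u.genes):
            length = ge - gs + 1
            row = {"gene": gid, "length": length}
            for p in PHASES:
                for rep in (1, 2):
                    row[f"{p}_{rep}_rna"] = float(
                        _nb(rng, rna[p] * length / config.count_depth,
                            config.count_dispersion))
                    row[f"{p}_{rep}_rpf"] = float(
                        _nb(rng, rpf[p] * 40.0 * length / config.count_depth,
                            config.count_dispersion))
            rows.append(row)
    counts_df = pd.DataFrame(rows)
    return tracks, counts_df


def _add_unit_coverage(arr, u: _Unit, level: float, phase: str, config: SimConfig, L: int):
    def seg(lo_local, hi_local, value):
        if hi_local < lo_local:
            return
        a, b = u.glob(lo_local), u.glob(hi_local)
        lo, hi = min(a, b), max(a, b)
        lo = max(lo, 1)
        hi = min(hi, L)
        arr[lo - 1 : hi] += value

    # orphan TSSs in gene units sit in the read-through tail and drive no
    # transcript of their own; an intergenic unit's lone (orphan) TSS does
    skip_orphan = bool(u.genes)
    tss_sorted = sorted(loc for loc, cat, _ in u.tss
                        if not (skip_orphan and cat == "orphan"))
    if not tss_sorted:
        return
    start = min(tss_sorted)
    primary = u.tss[0][0]
    teps = sorted(u.teps, key=lambda t: t["local"])
    term = [t for t in u.teps if t["terminal"]][0] if any(
        t["terminal"] for t in u.teps) else teps[-1]

    # upstream extension from a secondary TSS runs at reduced level
    if start < primary:
        seg(start, primary - 1, 0.35 * level)
    cur = primary
    running = level
    for t in teps:
        seg(cur, t["local"], running)
        cur = t["local"] + 1
        if t["kind"] == "premature":
            running = level * (u.premature_att or {}).get(phase, 1.0)
        elif not t["terminal"]:
            running = running * t["readthrough"]
    # read-through tail after the terminal TEP: flat 300 nt, then linear decay
    tail_level = running * term["readthrough"]
    seg(cur, cur + 299, tail_level)
    for k in range(120):
        seg(cur + 300 + k, cur + 300 + k, tail_level * (1 - (k + 1) / 120.0))


def _add_antisense_coverage(profiles, truth: TruthSet, config: SimConfig, L: int):
    level = 300.0
    for tu in truth.tu_list:
        if tu.category != "antisense":
            continue
        tss = truth.tss_list[tu.tss_index]
        tep = truth.tep_list[tu.tep_index]
        lo, hi = min(tss.position, tep.position), max(tss.position, tep.position)
        for p in PHASES:
            arr = profiles[p][tss.strand]
            arr[lo - 1 : hi] += level
            tail = level * tep.readthrough
            # transcription direction for '-' is decreasing coordinates
            a = max(lo - 300, 1)
            arr[a - 1 : lo - 1] += tail


# ---------------------------------------------------------------------------
# standalone count simulator (gene-level only, for expression-stage studies)
# ---------------------------------------------------------------------------

def simulate_counts(n_genes: int = 900, depth: float = 1e6, dispersion: float = 0.05,
                    lfc: float = 2.0, buffered_fraction: float = 0.1, seed: int = 0):
    """Gene-level RNA/RPF count tables with planted nine-group DEG structure.

    Genes are split evenly over the nine (ET x TS) expression groups with
    planted |log2FC| of ``lfc`` or 0; a ``buffered_fraction`` of genes keep
    RPF flat regardless of RNA (translational buffering).  Returns
    ``(counts_df, truth_df)``.
    """
    rng = np.random.default_rng(seed)
    groups = [ROMAN[i % 9] for i in range(n_genes)]
    lengths = rng.integers(400, 2000, size=n_genes) * 3 // 3
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    rows, truth_rows = [], []
    rna_means = {p: np.zeros(n_genes) for p in PHASES}
    rpf_means = {p: np.zeros(n_genes) for p in PHASES}
    buffered = rng.random(n_genes) < buffered_fraction
    for i in range(n_genes):
        et, ts = _CALLS_OF_GROUP[groups[i]]
        r_et = _LFC_OF_CALL[et] / 2.0 * lfc
        r_ts = _LFC_OF_CALL[ts] / 2.0 * lfc
        rna_means["E"][i] = base[i]
        rna_means["T"][i] = base[i] * 2.0 ** r_et
        rna_means["S"][i] = rna_means["T"][i] * 2.0 ** r_ts
        p_et, p_ts = (0.0, 0.0) if buffered[i] else (r_et, r_ts)
        rpf_means["E"][i] = base[i]
        rpf_means["T"][i] = base[i] * 2.0 ** p_et
        rpf_means["S"][i] = rpf_means["T"][i] * 2.0 ** p_ts
        truth_rows.append(dict(gene=f"g{i:04d}", group=groups[i],
                               rna_lfc_et=r_et, rna_lfc_ts=r_ts,
                               rpf_lfc_et=p_et, rpf_lfc_ts=p_ts,
                               buffered=bool(buffered[i])))
    data = {"gene": [f"g{i:04d}" for i in range(n_genes)], "length": lengths}
    for p in PHASES:
        for assay, means in (("rna", rna_means), ("rpf", rpf_means)):
            scaled = means[p] * lengths / (means[p] * lengths).sum() * depth
            for rep in (1, 2):
                data[f"{p}_{rep}_{assay}"] = _nb(rng, scaled, dispersion)
    return pd.DataFrame(data), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# on-disk emission
# ---------------------------------------------------------------------------

def write_dataset(outdir: str | Path, config: SimConfig):
    """Generate and write the full synthetic dataset to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotation, truth = generate_genome(config)
    tracks, counts = simulate_tracks(annotation, truth, config)
    write_fasta({"chr1": genome}, outdir / "genome.fasta")
    write_gff3(annotation.genes, outdir / "genes.gff3")
    for sid, tr in tracks.items():
        write_track(tr, outdir / sid)
    counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    return genome, annotation, truth, tracks, counts
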