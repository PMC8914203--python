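"""Readers and writers for the on-disk formats shared by every pipeline stage.

Internal coordinates are 1-based closed intervals, matching GFF3.  bedGraph
files are 0-based half-open, so ``load_track``/``write_track`` convert on the
way in and out; the conversion is its own inverse.  "Upstream"/"downstream"
throughout the package are defined by transcription direction, i.e. they flip
on the minus strand.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class GFF3ParseError(ValueError):
    """Raised for malformed GFF3 input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class BedGraphParseError(ValueError):
    pass


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int  # 1-based closed
    end: int
    frame_ok: bool = True  # False when CDS length not divisible by 3

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def tss_side(self) -> int:
        """Coordinate of the gene start in transcription direction."""
        return self.start if self.strand == "+" else self.end

    @property
    def stop_side(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class GenomeAnnotation:
    """Genome sequence(s) plus gene records indexed by id and by position."""

    seqs: dict[str, str]
    genes: list[Gene]
    by_id: dict[str, Gene] = field(init=False)

    def __post_init__(self):
        self.seqs = {c: s.upper() for c, s in self.seqs.items()}
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene ids are not unique")
        for g in self.genes:
            if g.start > g.end:
                raise ValueError(f"gene {g.gene_id}: end < start")
        self.by_id = {g.gene_id: g for g in self.genes}

    def chrom_length(self, chrom: str) -> int:
        return len(self.seqs[chrom])

    def genes_on(self, chrom: str, strand: str | None = None) -> list[Gene]:
        return [
            g
            for g in self.genes
            if g.chrom == chrom and (strand is None or g.strand == strand)
        ]

    def sequence(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """1-based closed slice, reverse-complemented on the minus strand."""
        s = self.seqs[chrom][start - 1 : end]
        if strand == "-":
            s = str(Seq(s).reverse_complement())
        return s


@dataclass
class EndCountTrack:
    """Strand-specific per-position counts of read ends (or coverage).

    ``counts`` maps strand to a dense int/float array of length equal to the
    chromosome; index 0 is genomic position 1.
    """

    sample_id: str
    assay: str  # dRNA_TAP+ / dRNA_TAP- / termseq / rna_cov / rpf_3end
    counts: dict[str, np.ndarray]
    phase: str | None = None  # E / T / S, None for pooled libraries
    rep: int | None = None
    chrom: str = "chr1"

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.counts.values()))

    def __post_init__(self):
        for strand, arr in self.counts.items():
            if np.any(arr < 0):
                raise ValueError(f"negative counts on strand {strand}")


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=c, description="") for c, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(genes: Iterable[Gene], path: str | Path, source: str = "strep_regulome") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )


def _parse_attributes(field9: str) -> dict[str, str]:
    out = {}
    for item in field9.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def load_genome(fasta_path: str | Path, gff3_path: str | Path) -> GenomeAnnotation:
    """Load a FASTA + GFF3 pair into a :class:`GenomeAnnotation`.

    Genes whose length is not divisible by 3 are kept but flagged
    (``frame_ok=False``) with a warning on stderr.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    genes: list[Gene] = []
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3ParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}", lineno
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if ftype not in ("gene", "CDS"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GFF3ParseError(f"non-integer coordinates: {exc}", lineno) from None
            if end < start:
                raise GFF3ParseError(f"end {end} < start {start}", lineno)
            if strand not in ("+", "-"):
                raise GFF3ParseError(f"bad strand {strand!r}", lineno)
            attrs = _parse_attributes(attrs_s)
            gid = attrs.get("ID", f"{ftype}_{lineno}")
            frame_ok = (end - start + 1) % 3 == 0
            if not frame_ok:
                print(
                    f"[genome_io] warning: gene {gid} CDS length not divisible by 3",
                    file=sys.stderr,
                )
            genes.append(Gene(gid, chrom, strand, start, end, frame_ok=frame_ok))
    return GenomeAnnotation(seqs=seqs, genes=genes)


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------

def write_track(track: EndCountTrack, prefix: str | Path) -> list[Path]:
    """Write one bedGraph per strand (suffix .plus / .minus), run-compressed."""
    paths = []
    for strand, suffix in (("+", ".plus.bedgraph"), ("-", ".minus.bedgraph")):
        if strand not in track.counts:
            continue
        arr = track.counts[strand]
        path = Path(str(prefix) + suffix)
        with open(path, "w") as fh:
            # run-length encode equal consecutive values, omit zero runs
            n = len(arr)
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [n]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                v_out = int(v) if float(v).is_integer() else float(v)
                fh.write(f"{track.chrom}\t{s}\t{e}\t{v_out}\n")
        paths.append(path)
    return paths


def load_track(
    path: str | Path,
    strand: str,
    assay: str,
    chrom_length: int,
    phase: str | None = None,
    rep: int | None = None,
    sample_id: str | None = None,
) -> EndCountTrack:
    """Read one strand of a bedGraph into a dense per-position array.

    bedGraph intervals are 0-based half-open: the record ``chr 9 10 5`` puts
    count 5 at 1-based position 10 (array index 9).
    """
    arr = np.zeros(chrom_length, dtype=float)
    chrom = "chr1"
    p = Path(path)
    if p.stat().st_size > 0:
        df = pd.read_csv(p, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"])
        if (df["value"] < 0).any():
            raise BedGraphParseError(f"{path}: negative value in bedGraph")
        starts = df["start"].to_numpy(int)
        ends = df["end"].to_numpy(int)
        if np.any(starts[1:] < ends[:-1]) and df["chrom"].nunique() == 1:
            raise BedGraphParseError(f"{path}: overlapping bedGraph intervals")
        if np.any(ends > chrom_length):
            raise BedGraphParseError(f"{path}: interval beyond chromosome bounds")
        for s, e, v in zip(starts, ends, df["value"].to_numpy(float)):
            arr[s:e] += v
        chrom = str(df["chrom"].iloc[0])
    if sample_id is None:
        sample_id = p.stem
    return EndCountTrack(
        sample_id=sample_id,
        assay=assay,
        counts={strand: arr},
        phase=phase,
        rep=rep,
        chrom=chrom,
    )


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

def write_results(records, path: str | Path, kind: str) -> None:
    """Emit called features (GFF3) or tables (TSV).

    kind='gff3' expects records with .chrom/.position or .start/.end, .strand
    and an .attributes() dict; kind='tsv' expects a pandas DataFrame.
    """
    if kind == "tsv":
        records.to_csv(path, sep="\t", index=False)
        return
    if kind != "gff3":
        raise ValueError(f"unknown kind {kind!r}")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            if hasattr(rec, "start") and hasattr(rec, "end"):
                start, end = rec.start, rec.end
            else:
                start = end = rec.position
            attrs = rec.attributes() if hasattr(rec, "attributes") else {}
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            ftype = getattr(rec, "feature_type", "feature")
            chrom = getattr(rec, "chrom", "chr1")
            fh.write(
                f"{chrom}\tstrep_regulome\t{ftype}\t{start}\t{end}\t.\t{rec.strand}\t.\t{attr_s}\n"
            )
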