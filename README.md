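# strep-regulome

Regulatory-element analysis of bacterial multi-omics end-count data, built
around the workflow used to map transcription and translation regulation in
*Streptomyces griseus* across growth phases.  The package takes
strand-specific per-position read-end count tracks — dRNA-seq 5' ends
(TAP+/TAP−), Term-seq 3' ends, RNA-seq coverage and ribosome-profiling (RPF)
3' ends — plus a genome FASTA/GFF3 pair, and produces:

* **TSSs** — 5'-end peak sub-cluster representatives with TAP+/TAP− ratio
  > 1.5 present in both replicates, categorized (primary / secondary /
  internal / antisense / orphan) with 5'-UTR leader classes
  (lmRNA 0–10 nt, mmRNA 11–100 nt, emRNA > 100 nt);
* **TEPs** — Term-seq 3'-end peaks filtered by count ≥ 4, replicate
  presence and shadow-relative Z-score > 6, then separated from residual
  shadows by a k-nearest-neighbour classifier trained on rule-derived
  positive/negative control peaks;
* **transcription units (TUs)** — every same-strand (TSS, TEP) pair whose
  connecting region shows continuous RNA coverage: each sliding 200-nt
  window must hold ≥ 5 raw reads and ≥ 5 % of the region's normalized mean
  in at least one growth phase; TUs cluster into TUCs (≥ 1 nt overlap) with
  terminal / non-terminal TEP labels and premature-termination intensities;
* **DEG / TE grouping** — TPM, median-of-ratios size factors, a
  negative-binomial Wald test per transition (E→T, T→S), the nine-group
  classification I=U-U … IX=N-N under |log₂FC| > 1 and *p* < 0.05,
  translation efficiency TE = TPM_RPF/TPM_RNA, and hypergeometric term
  enrichment with Benjamini–Hochberg FDR;
* **terminator motifs and structure** — in-house EM motif discovery
  (oops/zoops) and log-odds scanning with exact DP p-values; a Zuker-style
  minimum-free-energy fold of the −40..+1 window classifies TEPs into
  motif / structured (< −25 kcal/mol) / unstructured subcategories, plus
  base-pair interaction-frequency matrices and −10/−35 promoter spacers;
* **ribosome pausing** — per-position scores count(p+14)/CDS mean with the
  first/last 10 codons excluded, A-site codon scores (sum over the −1, 0,
  +1 nucleotides of the P-site codon), per-codon/amino-acid averages, and
  codon-usage / downstream-GC / ΔG analysis of the top-1000 sites.

Because the original sequencing data cannot be re-analysed at desk scale,
the package ships a first-class synthetic generator
(`strep_regulome.simulate`) that emits all four track types from a small
high-GC genome with a machine-readable planted truth set — every pipeline
stage is tested by recovering what was planted.

## Worked example

```
python analysis/01_simulate.py
python analysis/03_call_boundaries.py
python analysis/06_pausing.py
```

prints (seed 11, 100 kb genome, 80 genes):

```
genome: 100,000 nt, GC 0.720, 80 genes
planted: 88 TSSs (+46 processed-end decoys), 72 TEPs, 106 TUs, 231 pausing sites
TSS: 88 called; recall 1.000 vs 88 planted; decoy acceptance 0.000
TEP: 74 called; precision 0.973, recall 1.000
T phase: top A-site codons TTA (21.8, n=6), TTG (3.7, n=62), TCT (3.6, n=58)
top-1000 pausing sites (T phase): downstream +40 nt dG -16.1 kcal/mol vs
controls [-13.8, -13.6] (rank-sum p ['8.8e-07', '9.4e-09'])
```

Every planted TSS is recovered while the planted processed-end decoys
(TAP ratio 0.8–1.3) are rejected by the 1.5× filter; the rare TTA leucine
codon planted with T-phase-specific pausing tops the per-codon score table
in exactly that phase; and the GC stems planted downstream of pausing sites
depress the top-site folding energies relative to random-position controls.
The remaining drivers (`02_expression.py`, `04_transcription_units.py`,
`05_motifs_structure.py`) report the nine-group DEG composition, TU/TUC
assembly with read-through fractions, and the recovered promoter (−10
"TAnnnT", −35 "TGAC", modal 12-nt spacer) and terminator (CGT/U-tract)
elements.

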