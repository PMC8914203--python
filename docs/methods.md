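# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage, what the synthetic generator does and does not emulate,
and the known limitations.

## Coordinates and data model

Internal coordinates are 1-based closed, matching GFF3; bedGraph I/O
converts to/from 0-based half-open intervals and the conversion is its own
inverse.  "Upstream/downstream" always follow transcription direction, so
all windows flip on the minus strand.  Tracks are dense per-position arrays
per strand; genes are single-CDS records (bacterial annotation), flagged
but kept when their length is not divisible by three.

## TSS calling

5'-end peaks (pooled over replicates) are clustered at < 100 bp separation
and recursively split at the largest positional gap until each sub-cluster's
positional standard deviation falls below 10 bp; the maximum-intensity
member represents the sub-cluster.  "< N standard deviations" is read as a
bound in base pairs — the deterministic largest-gap interpretation is
verified against an independent exhaustive splitter in the tests.  A
representative is accepted when TAP+/TAP− > 1.5 (pseudocount 1 in a zero
denominator) and it carries ≥ 1 count within ±2 nt in both replicates (the
±2 nt absorbs single-base jitter).  A pooled-intensity floor
(`min_count = 8`) replaces the visual curation step of the original
workflow: replicated singleton read ends are library noise, not initiation
sites; the floor is configurable.

Categories take the first matching rule: gene-assigned (within 500 nt
upstream of a same-strand gene start — the window matching the upper bound
of extended leaders; strongest per gene = primary, others secondary),
internal (inside a same-strand gene), antisense (within 100 nt of an
opposite-strand gene), orphan.  5'-UTR length is the TSS→start-codon
distance; classes lmRNA 0–10, mmRNA 11–100, emRNA > 100 nt, with an
`overflow` flag beyond 500 nt.

## TEP calling

Same clustering with a 25-bp sub-cluster SD.  Candidates additionally need
a pooled count ≥ 4, replicate presence, and Z > 6, where Z is computed over
the non-zero neighbour heights within ±100 nt (sample SD).  The ±100 window
spans the clustering gap, so the shadows of one 3'-end cluster are always in
scope; a narrower window left distant shadows with < 3 usable neighbours.
With < 3 non-zero neighbours or zero spread the Z is a flagged +∞ sentinel
(an isolated spike is trivially "enriched" but cannot be scored); a peak
exactly equal to its uniform neighbours gets Z = 0.

The KNN classifier (k = 5, Euclidean distance on z-standardized features)
uses five features: log10(height+1); Z (sentinel mapped to 0 = "no
information", finite values capped at 50); height relative to the ±25 nt
maximum; the RNA read-through fraction in ±300 nt; distance to the
sub-cluster representative.  Positive controls are candidates whose RNA
read-through is below 0.5 **and** whose Z is informative (the second clause
stands in for the visual selection of positive peaks); negative controls
are sampled in the −20..+20 band around each positive (2 per positive,
seeded).  Positional categories mirror the TSS rules with premature
(between a gene-assigned TSS and the first 150 nt of its gene's CDS) taking
precedence, then primary/secondary within 200 nt downstream of a stop,
internal, antisense, intergenic.

## Transcription units

All same-strand (TSS, TEP) pairs with the TEP downstream and span ≤ 50 kb
(configurable cap on the quadratic search) are tested.  The connected
region is inset 100 nt from each end (no insets under 200 nt span); 200-nt
windows slide by 1 nt.  A pair is accepted when, in at least one growth
phase, **every** window carries a raw mean ≥ 5 reads and a normalized mean
≥ 5 % of the whole-region normalized mean.  A window below the raw floor is
treated as *failing* rather than ignored: a silent window cannot evidence
transcription continuity, and ignoring such windows would connect every
TSS to every downstream TEP across silent gaps.  "Normalized" means scaled
by median-of-ratios size factors from the gene-count table, keeping phases
comparable.  The implementation is checked against a naive window re-scan
on random synthetic pairs.

Categories: ≥ 2 fully-contained same-strand genes = polycistronic, 1 =
monocistronic; with none, a TU whose TEP ends before the stop codon of the
gene its TSS serves is premature, a partially-overlapped sense gene still
counts as monocistronic, opposite-strand-only overlap is antisense, no
overlap is intergenic.  TUCs are connected components under ≥ 1 nt span
overlap, computed per strand by a sorted sweep and verified against a
union-find oracle.  A TEP is terminal iff no member TU extends past it in
transcription direction; the non-terminal TEPs with no downstream TSS
inside the TUC are reported separately.  Premature-TU intensity divides the
summed normalized counts in the TU span by the sum over the downstream CDS,
per phase, with mean ± SD over replicates.

## Profiles and read-through

Meta-profiles max-normalize each anchor's −300..+300 window before
averaging.  The read-through fraction divides the normalized sums at
offsets 0..+300 by −300..0; offset 0 is counted in both sums exactly as
defined (a flag excludes it).  Fractions are per-anchor, not computed on
the averaged profile.  The estimator includes whatever background coverage
the window contains, so very weakly expressed units read a few percent
high; recovery is therefore asserted on the median error across planted
terminators.

## Motifs

`discover_motif` is EM over site offsets: oops assigns exactly one site per
sequence, zoops adds a no-site alternative with prior 0.5.  20 seeded
restarts, 60 iterations, pseudocount 0.25, background from the input
sequences; the highest-likelihood PWM wins and its maximum-responsibility
sites are reported (under zoops only where the site posterior beats the
no-site prior).  `scan_pwm` scores log-odds (clipped at −30 bits/column,
discretized at 0.005 bits) and computes exact p-values by dynamic
programming over the discretized score distribution, FIMO-style; p-values
are calibrated against empirical hit rates in the tests.  Membership in the
conserved 3'-end motif class uses the zoops site assignment, not a
per-position scan: with ~50 offsets per window, a per-offset p < 0.01 scan
fires false hits in ~40 % of windows by construction, whereas the site
posterior must beat the no-site alternative once per window.  Promoter
spacers count the nucleotides strictly between the −35 motif's 3' end and
the −10 motif's 5' start (negative = overlapping, flagged).

## RNA folding

A Zuker-style dynamic program over nested structures: Watson–Crick + GU
pairs, nearest-neighbour stacking energies (Turner-2004-style table),
tabulated hairpin/bulge/internal initiation terms with Jacobson–Stockmayer
extrapolation, an affine multiloop model (a = 3.4, b = 0.4 per branch,
c = 0 per unpaired), minimum hairpin loop 3 nt, interior loops ≤ 30 nt,
no dangles, terminal mismatches or coaxial stacking.  `structure_energy`
scores an arbitrary nested structure by loop decomposition under the same
tables, which lets the DP be verified against exhaustive enumeration of all
structures for sequences ≤ 20 nt.  Numba compiles the fill; the traceback
runs in Python with a 1e-6 energy tolerance (ties resolve to the first
option in a fixed scan order).  Energies are deliberately simplified:
absolute ΔG differs from full-featured engines, so the −25 kcal/mol
structured/unstructured split is configuration-exposed and a `fold_fn`
hook accepts a different engine.  ΔG is reported as min(0, MFE): the open
chain is always available.

## Expression

TPM per sample (columns sum to 1e6).  The DE test is a DESeq2-like
approximation: median-of-ratios size factors; per-gene method-of-moments
NB dispersion pooled within phases, averaged 50/50 with the across-gene
median (two replicates alone are too noisy) and floored at 1e-3; Wald test
on ln-fold change with delta-method variance.  The log2FC uses a symmetric
pseudocount of 0.5 on normalized means, so swapping phases negates it
exactly; all-zero genes get NaN/p = 1/flagged.  The classification consumes
only (log2FC, p) at |log₂FC| > 1, p < 0.05, so DESeq2's shrinkage details
are out of scope.  Group numbering I=U-U, II=U-D, III=U-N, IV=D-U, V=D-D,
VI=D-N, VII=N-U, VIII=N-D, IX=N-N; genes with no significant expression
fall into N by the same thresholds.  TE needs RNA TPM ≥ 1 in both phases
of a transition.  Enrichment is the hypergeometric upper tail with BH FDR
over flat term sets.

## Ribosome pausing

score(p) = 3'-end count at p+14 (translation direction) ÷ mean 3'-end count
over the full CDS.  The +14 shift maps the RPF 3' boundary back to the
P-site codon's middle; the equivalent description — shift the 3'-end
profile 14 nt upstream — is the same mapping read from the other end.  The
first and last 10 codons are excluded from scoring but not from the
normalizing mean; genes under 21 codons or averaging ≤ 1 count/nt are
skipped.  A-site codon score = score sums at the −1/0/+1 *nucleotides* of
the P-site codon (the nucleotide reading of an ambiguous definition,
giving a 3-nt footprint); stop codons are excluded from per-codon tables.
Top-n analysis ranks positions by score (ties broken by gene id and
coordinate), subtracts overall codon frequencies from top-n frequencies
(sums to 0), and compares downstream +40 nt GC and ΔG against two
independent seeded random-position control groups drawn from the same
scored-site pool (which already excludes 10 codons from each end; a config
option widens the exclusion to 100 nt, since both conventions appear in
the source workflows' descriptions).  Chi-square tests the codon counts,
Wilcoxon rank-sum the ΔG shift.

## Synthetic data generator

The generator lays transcription cassettes (promoter with planted −35
"TGAC" + 12-nt spacer + "TAnnnT" −10 element, 5'-UTR with planted leader
class, 1–3 CDSs, terminator, read-through tail) on a GC-tuned genome
(background GC adjusted so the whole sequence lands on the target, default
0.72).  Planted signals:

* TSSs at fixed positions with Poisson peak heights, TAP+ = 4× TAP−; one
  processed-end decoy per TSS, 50–500 nt downstream, TAP ratio drawn in
  [0.8, 1.3]; secondary/internal/orphan TSSs and antisense units at fixed
  per-unit probabilities;
* TEPs with class-defining sequence elements: motif (11-bp GC stem-loop +
  CGT/T₈ tract straddling the 3' end), structured (13-bp stem-loop only),
  unstructured (A-rich, T-poor patch — runs of T are broken so the patch
  neither mimics the terminator tract nor folds); terminal read-through
  0.05/0.1/0.2 for motif/structured/unstructured (the class ordering of
  termination efficiency), non-terminal TEPs 0.3; Term-seq shadows at 5
  fixed offsets within ±45 nt, plus diffuse in-gene decoy clusters;
* step-shaped RNA coverage per phase from the nine-group fold-change plan
  (|log₂FC| = 2 or 0 per transition), NB per-position noise (dispersion
  0.1), background 2 reads/nt — deliberately below the 5-read window floor
  so silent gaps cannot support TU continuity;
* premature TUs in deep 5'-UTRs with attenuation pass-through 0.1/0.2/0.4
  in E/T/S (strongest premature termination in E, ordered release later);
* RPF 3'-end counts at the per-gene density with planted pause sites
  (intensity 8–30×); ~6 genes carry a TTA A-site codon paused 25× only in
  T phase (TTA is otherwise excluded from random codons so the planted
  association is clean); 70 % of pause sites carry a 12-bp GC stem inside
  the +40 nt window downstream of the RPF boundary.

End-count peaks are Poisson (a single-position count has no excess
biological variance in this model); coverage and gene-count tables are
negative binomial.  `simulate_counts` is a standalone gene-level simulator
(default 900 genes, depth 1e6, dispersion 0.05) planting the nine groups
evenly plus a 10 % translationally buffered subset.

What the generator does **not** emulate: read-level artifacts (mapping
bias, multi-mapping, sequencing error), condition-specific TSS usage,
rho-dependent termination shapes, operon-internal promoter occlusion, or
compositional biases beyond GC.  Passing recovery tests therefore shows the
stages implement their definitions correctly under clean-but-noisy planted
signals, not that the thresholds are optimal for real libraries.

## Known limitations

* The folding energy model is simplified; absolute ΔG values shift relative
  to full Turner implementations, hence the configurable −25 kcal/mol split.
* The DE test approximates DESeq2 (no shrinkage, normal Wald); with two
  replicates its p-values are anti-conservative for outlier-dispersed genes.
* Secondary TEPs are classified but not planted by the generator (planting
  them would redefine the terminal labels of their operons); the category
  is covered by toy-data tests only.
* The KNN features assume the RNA-drop signal is visible in pooled-phase
  coverage; condition-specific terminators would need per-phase features.
* Genome scale: analyses here run on 50–100 kb genomes with 40–80 genes —
  ample for exercising every rule, far below a real genome's multiplicity.
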