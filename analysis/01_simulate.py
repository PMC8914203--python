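"""Generate the synthetic multi-omics dataset the downstream analyses use.

Writes the genome, annotation, end-count/coverage tracks, gene-level count
tables and the machine-readable planted truth to results/dataset/.
"""

from collections import Counter

from strep_regulome.simulate import SimConfig, write_dataset

OUT = "results/dataset"

cfg = SimConfig(genome_length=100_000, n_genes=80, seed=11)
genome, annotation, truth, tracks, counts = write_dataset(OUT, cfg)

gc = (genome.count("G") + genome.count("C")) / len(genome)
print(f"genome: {len(genome):,} nt, GC {gc:.3f}, {len(annotation.genes)} genes")
print(f"planted: {len(truth.tss_list)} TSSs (+{len(truth.decoy_list)} processed-end "
      f"decoys), {len(truth.tep_list)} TEPs, {len(truth.tu_list)} TUs, "
      f"{len(truth.pausing_sites)} pausing sites")
print("TEP subcategories:", dict(Counter(t.subcategory for t in truth.tep_list)))
print("DEG groups:", dict(Counter(truth.deg_table["group"])))
print(f"tracks written: {len(tracks)} samples -> {OUT}/")
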