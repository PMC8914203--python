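import numpy as np
import pytest

from strep_regulome.simulate import (
    SimConfig, SimulationSizingError, TruthSet, generate_genome,
    simulate_counts, simulate_tracks,
)


def test_seed_determinism_and_divergence():
    cfg = SimConfig(genome_length=50_000, n_genes=40, seed=7)
    g1, a1, t1 = generate_genome(cfg)
    g2, a2, t2 = generate_genome(SimConfig(genome_length=50_000, n_genes=40, seed=7))
    assert g1 == g2
    assert len(a1.genes) == 40
    assert [x.position for x in t1.tss_list] == [x.position for x in t2.tss_list]
    g3, *_ = generate_genome(SimConfig(genome_length=50_000, n_genes=40, seed=8))
    assert g1 != g3


def test_gc_fraction_hits_target():
    g, *_ = generate_genome(SimConfig(genome_length=60_000, n_genes=40, gc=0.72, seed=1))
    gc = (g.count("G") + g.count("C")) / len(g)
    assert abs(gc - 0.72) <= 0.02


def test_degenerate_configs_raise_sizing_errors():
    with pytest.raises(SimulationSizingError):
        generate_genome(SimConfig(n_genes=0))
    with pytest.raises(SimulationSizingError):
        generate_genome(SimConfig(genome_length=5_000, n_genes=40, seed=0))
    with pytest.raises(ValueError):
        SimConfig(gc=1.5).validate()


def test_genes_do_not_overlap_on_the_same_strand(small_dataset):
    _sim, _g, annotation, *_ = small_dataset
    for strand in "+-":
        genes = sorted(annotation.genes_on("chr1", strand), key=lambda g: g.start)
        for a, b in zip(genes, genes[1:]):
            assert a.end < b.start


def test_motif_teps_carry_stem_and_t_tract(small_dataset):
    _sim, _g, annotation, truth, *_ = small_dataset
    for t in truth.tep_list:
        if t.subcategory != "motif":
            continue
        if t.strand == "+":
            tract = annotation.sequence("chr1", t.position - 5, t.position + 6, "+")
            stem = annotation.sequence("chr1", t.position - 36, t.position - 7, "+")
        else:
            tract = annotation.sequence("chr1", t.position - 6, t.position + 5, "-")
            stem = annotation.sequence("chr1", t.position + 7, t.position + 36, "-")
        # a CGT/T-rich tract straddles the 3' end, preceded by a GC-rich stem
        assert tract.count("T") >= 6
        assert (stem.count("G") + stem.count("C")) / len(stem) > 0.6


def test_planted_tap_excess_and_decoy_band(small_dataset):
    sim, _g, annotation, truth, tracks, _c = small_dataset
    for rep in (1, 2):
        plus = tracks[f"drna_tap_plus_{rep}"].counts
        minus = tracks[f"drna_tap_minus_{rep}"].counts
        ratios = []
        for t in truth.tss_list:
            i = t.position - 1
            ratios.append(plus[t.strand][i] / max(minus[t.strand][i], 1.0))
        assert np.median(ratios) >= 1.5  # TAP+ excess by construction
    assert all(0.8 <= d.tap_ratio <= 1.3 for d in truth.decoy_list)


def test_planted_readthrough_reproduced_by_track(small_dataset):
    _sim, _g, annotation, truth, tracks, _c = small_dataset
    cov = {s: sum(tracks[f"rna_{p}_{r}"].counts[s] for p in "ETS" for r in (1, 2))
           for s in "+-"}
    errs = []
    for t in truth.tep_list:
        if not t.terminal:
            continue
        i = t.position - 1
        if t.strand == "+":
            up = cov["+"][i - 300 : i + 1].sum()
            dn = cov["+"][i : i + 301].sum()
        else:
            up = cov["-"][i : i + 301].sum()
            dn = cov["-"][i - 300 : i + 1].sum()
        errs.append(abs(dn / up - t.readthrough))
    assert np.median(errs) < 0.03


def test_planted_pausing_spike_in_rpf_track(small_dataset):
    _sim, _g, annotation, truth, tracks, _c = small_dataset
    boosted = [p for p in truth.pausing_sites if max(p.intensity.values()) >= 15]
    assert boosted
    hits = 0
    for p in boosted[:10]:
        gene = annotation.by_id[p.gene_id]
        phase = max(p.intensity, key=p.intensity.get)
        track = tracks[f"rpf_{phase}_1"].counts[gene.strand]
        off = p.cds_pos + 14
        pos = gene.start - 1 + off if gene.strand == "+" else gene.end - 1 - off
        local = track[max(pos - 50, 0) : pos + 51]
        hits += track[pos] > 4 * np.median(local[local > 0])
    assert hits >= 8  # spikes stand out over the local footprint background


def test_truth_json_round_trip(tmp_path, small_dataset):
    *_, truth, _tracks, _c = (small_dataset[2], small_dataset[3],
                              small_dataset[4], small_dataset[5])
    truth = small_dataset[3]
    truth.to_json(tmp_path / "truth.json")
    back = TruthSet.from_json(tmp_path / "truth.json")
    assert [t.position for t in back.tep_list] == [t.position for t in truth.tep_list]
    assert back.deg_table["group"].tolist() == truth.deg_table["group"].tolist()
    assert [p.codon for p in back.pausing_sites] == \
        [p.codon for p in truth.pausing_sites]


def test_count_simulator_plants_nine_groups_evenly():
    counts, truth = simulate_counts(n_genes=90, depth=1e5, seed=0)
    assert sorted(truth["group"].value_counts()) == [10] * 9
    assert set(counts.columns) >= {"gene", "length", "E_1_rna", "S_2_rpf"}
    c2, t2 = simulate_counts(n_genes=90, depth=1e5, seed=0)
    assert counts.equals(c2)
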