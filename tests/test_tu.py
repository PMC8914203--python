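import numpy as np
import pytest

from strep_regulome.io import Gene, GenomeAnnotation
from strep_regulome.tep import TEPRecord
from strep_regulome.tss import TSSRecord
from strep_regulome.tu import (
    TranscriptionUnit, assemble_tus, cluster_tucs, evaluate_pair,
    premature_intensity,
)

from .oracles import brute_force_evaluate_pair, union_find_components


def _cov(arr):
    return {"E": np.asarray(arr, dtype=float)}


def test_uniform_coverage_is_accepted():
    cov = _cov(np.full(3000, 100.0))
    ok, diag = evaluate_pair(100, 2500, "+", cov, cov)
    assert ok and diag["E"]["ok"]


def test_internal_zero_gap_rejects_the_pair():
    arr = np.full(3000, 100.0)
    arr[1200:1500] = 0.0
    cov = _cov(arr)
    ok, _ = evaluate_pair(100, 2500, "+", cov, cov)
    assert not ok


def test_short_span_drops_the_end_insets():
    arr = np.zeros(3000)
    arr[99:250] = 80.0  # covered exactly between TSS 100 and TEP 250
    cov = _cov(arr)
    ok, _ = evaluate_pair(100, 250, "+", cov, cov)
    assert ok


def test_tep_upstream_of_tss_raises():
    cov = _cov(np.full(500, 10.0))
    with pytest.raises(ValueError):
        evaluate_pair(400, 100, "+", cov, cov)
    with pytest.raises(ValueError):
        evaluate_pair(100, 400, "-", cov, cov)


def test_evaluate_pair_matches_brute_force_rescan():
    rng = np.random.default_rng(4)
    for _ in range(40):
        L = 3000
        arr = rng.poisson(rng.uniform(2, 60), size=L).astype(float)
        if rng.random() < 0.5:  # sometimes carve a low stretch
            a = rng.integers(500, 2000)
            arr[a : a + rng.integers(50, 400)] *= rng.uniform(0, 0.1)
        norm = arr * rng.uniform(0.5, 2.0)
        tss, tep = sorted(rng.integers(50, L - 50, size=2))
        if tep - tss < 10:
            continue
        got, _ = evaluate_pair(int(tss), int(tep), "+", _cov(arr), _cov(norm))
        want = brute_force_evaluate_pair(int(tss), int(tep), "+",
                                         {"E": arr}, {"E": norm})
        assert got == want


def _toy_world():
    genes = [Gene("gA", "chr1", "+", 300, 899), Gene("gB", "chr1", "+", 950, 1549)]
    ann = GenomeAnnotation({"chr1": "G" * 4000}, genes)
    arr = np.zeros(4000)
    arr[249:1650] = 200.0  # operon block
    cov = {"+": {"E": arr}, "-": {"E": np.zeros(4000)}}
    tss = [TSSRecord(250, "+", 3.0, height=80, gene_id="gA", category="primary")]
    teps = [TEPRecord(920, "+", 9, 40, "tep"), TEPRecord(1600, "+", 9, 60, "tep")]
    return ann, cov, tss, teps


def test_assembled_tu_categories_by_gene_content():
    ann, cov, tss, teps = _toy_world()
    tus = assemble_tus(tss, teps, cov, cov, ann)
    cats = {(t.tss_index, t.tep_index): t.category for t in tus}
    assert cats[(0, 0)] == "monocistronic"  # spans gA only
    assert cats[(0, 1)] == "polycistronic"  # spans gA and gB


def test_premature_category_requires_gene_assigned_tss():
    genes = [Gene("gA", "chr1", "+", 600, 1199)]
    ann = GenomeAnnotation({"chr1": "G" * 2000}, genes)
    arr = np.zeros(2000)
    arr[299:1300] = 150.0
    cov = {"+": {"E": arr}, "-": {"E": np.zeros(2000)}}
    tss = [TSSRecord(300, "+", 3.0, height=80, gene_id="gA", category="primary")]
    teps = [TEPRecord(500, "+", 9, 40, "tep")]  # ends inside the 5'-UTR
    tus = assemble_tus(tss, teps, cov, cov, ann)
    assert len(tus) == 1 and tus[0].category == "premature"


def test_shared_tss_yields_one_tuc_with_nonterminal_inner_tep():
    ann, cov, tss, teps = _toy_world()
    tus = assemble_tus(tss, teps, cov, cov, ann)
    tucs = cluster_tucs(tus, tss, teps)
    assert len(tucs) == 1
    c = tucs[0]
    assert c.nonterminal_teps == [0] and c.terminal_teps == [1]
    assert c.nonterminal_no_downstream_tss == [0]  # no TSS past the inner TEP


def test_disjoint_tus_make_singleton_tucs_with_terminal_teps():
    tss = [TSSRecord(100, "+", 3.0), TSSRecord(2000, "+", 3.0)]
    teps = [TEPRecord(600, "+", 9, 9, "tep"), TEPRecord(2600, "+", 9, 9, "tep")]
    tus = [TranscriptionUnit(0, 0, "+", 100, 600),
           TranscriptionUnit(1, 1, "+", 2000, 2600)]
    tucs = cluster_tucs(tus, tss, teps)
    assert len(tucs) == 2
    assert all(c.terminal_teps and not c.nonterminal_teps for c in tucs)


def test_tuc_components_match_union_find_oracle():
    rng = np.random.default_rng(7)
    for _ in range(25):
        n = int(rng.integers(2, 50))
        starts = rng.integers(1, 5000, size=n)
        ends = starts + rng.integers(10, 800, size=n)
        tus = [TranscriptionUnit(i, i, "+", int(s), int(e))
               for i, (s, e) in enumerate(zip(starts, ends))]
        tss = [TSSRecord(int(s), "+", 3.0) for s in starts]
        teps = [TEPRecord(int(e), "+", 9, 9, "tep") for e in ends]
        got = {frozenset(c.tu_indices) for c in cluster_tucs(tus, tss, teps)}
        want = set(union_find_components(list(zip(starts, ends))))
        assert got == want


def test_tuc_count_never_exceeds_tu_count(pipeline_result):
    assert len(pipeline_result.tucs) <= len(pipeline_result.tus)
    labelled = {j for c in pipeline_result.tucs
                for j in c.terminal_teps + c.nonterminal_teps}
    for c in pipeline_result.tucs:
        assert not (set(c.terminal_teps) & set(c.nonterminal_teps))
    assert labelled <= set(range(len(pipeline_result.tep_records)))


def test_premature_intensity_arithmetic_and_flags():
    tu = TranscriptionUnit(0, 0, "+", 101, 200)
    gene = Gene("g", "chr1", "+", 301, 400)
    arr = np.zeros(500)
    arr[100:200] = 0.8  # premature sum 80
    arr[300:400] = 0.2  # CDS sum 20
    out = premature_intensity(tu, gene, {"E": [arr, arr]})
    assert out["E"]["mean"] == pytest.approx(4.0)
    equal = np.zeros(500)
    equal[100:200] = 0.5
    equal[300:400] = 0.5
    out2 = premature_intensity(tu, gene, {"E": [equal]})
    assert out2["E"]["mean"] == pytest.approx(1.0)
    none = np.zeros(500)
    none[100:200] = 0.5
    out3 = premature_intensity(tu, gene, {"E": [none]})
    assert out3["E"]["flagged"] and np.isnan(out3["E"]["mean"])


def test_planted_riboswitch_attenuation_is_phase_ordered(pipeline_result):
    """Premature termination is strongest in E and weakest in S."""
    res = pipeline_result
    assert res.premature, "no premature TUs were assembled"
    ratios_e, ratios_s = [], []
    for ti, per_phase in res.premature.items():
        ratios_e.append(per_phase["E"]["mean"])
        ratios_s.append(per_phase["S"]["mean"])
    assert np.nanmedian(ratios_e) > np.nanmedian(ratios_s)
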