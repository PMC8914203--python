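import numpy as np
import pytest

from strep_regulome.io import Gene, GenomeAnnotation
from strep_regulome.tss import TSSRecord, call_tss, categorize_tss

L = 2000


def _tracks(peaks_plus, peaks_minus):
    """Two identical replicates with the given {pos: count} spikes."""
    plus = np.zeros(L)
    minus = np.zeros(L)
    for p, c in peaks_plus.items():
        plus[p - 1] = c
    for p, c in peaks_minus.items():
        minus[p - 1] = c
    return [plus.copy(), plus.copy()], [minus.copy(), minus.copy()]


def test_tap_ratio_accepts_two_fold_rejects_one_point_four():
    tp, tm = _tracks({500: 30, 900: 14}, {500: 15, 900: 10})
    recs = call_tss(tp, tm, "+", min_count=1)
    # pooled 60/30 = 2.0 accepted; pooled 28/20 = 1.4 rejected
    assert [r.position for r in recs] == [500]
    assert recs[0].tap_ratio == pytest.approx(2.0)


def test_zero_tap_minus_uses_pseudocount_denominator():
    tp, tm = _tracks({300: 10}, {})
    recs = call_tss(tp, tm, "+", min_count=1)
    assert recs[0].tap_ratio == pytest.approx(20.0)  # pooled 20 / max(0,1)


def test_peak_absent_from_one_replicate_is_removed():
    tp, tm = _tracks({400: 20}, {400: 1})
    tp[1][:] = 0  # wipe replicate 2
    assert call_tss(tp, tm, "+", min_count=1) == []


def test_fewer_than_two_replicates_raises():
    tp, tm = _tracks({400: 20}, {400: 1})
    with pytest.raises(ValueError):
        call_tss(tp[:1], tm, "+")


def _annotation():
    genes = [Gene("gA", "chr1", "+", 500, 799),
             Gene("gB", "chr1", "-", 1200, 1499)]
    return GenomeAnnotation({"chr1": "G" * L}, genes)


def test_categories_and_leader_classes():
    ann = _annotation()
    recs = [
        TSSRecord(470, "+", 2.0, height=90),   # 30 nt upstream -> primary mmRNA
        TSSRecord(420, "+", 2.0, height=30),   # weaker, same gene -> secondary
        TSSRecord(650, "+", 2.0, height=20),   # inside gA, sense -> internal
        TSSRecord(1300, "+", 2.0, height=20),  # inside gB, opposite -> antisense
        TSSRecord(1900, "+", 2.0, height=20),  # nothing near -> orphan
        TSSRecord(1499, "-", 2.0, height=50),  # at gB start codon -> lmRNA
    ]
    categorize_tss(recs, ann)
    assert [r.category for r in recs] == [
        "primary", "secondary", "internal", "antisense", "orphan", "primary"]
    assert recs[0].utr_len == 30 and recs[0].leader_class == "mmRNA"
    assert recs[5].utr_len == 0 and recs[5].leader_class == "lmRNA"


def test_extended_leader_class_boundaries():
    ann = _annotation()
    rec_mm = TSSRecord(400, "+", 2.0, height=10)   # 100 nt -> mmRNA
    rec_em = TSSRecord(300, "+", 2.0, height=90)   # 200 nt -> emRNA
    categorize_tss([rec_em, rec_mm], ann)
    assert rec_em.leader_class == "emRNA" and rec_em.category == "primary"
    assert rec_mm.leader_class == "mmRNA" and rec_mm.category == "secondary"


def test_strand_mirror_symmetry():
    """Mirroring the genome maps '+' calls onto mirrored '-' calls."""
    tp, tm = _tracks({500: 30, 900: 40}, {500: 5, 900: 8})
    fwd = call_tss(tp, tm, "+", min_count=1)
    tp_m = [a[::-1].copy() for a in tp]
    tm_m = [a[::-1].copy() for a in tm]
    rev = call_tss(tp_m, tm_m, "-", min_count=1)
    assert sorted(L + 1 - r.position for r in rev) == sorted(r.position for r in fwd)


def test_categories_are_exhaustive_and_exclusive(pipeline_result):
    cats = {"primary", "secondary", "internal", "antisense", "orphan"}
    assert all(r.category in cats for r in pipeline_result.tss_records)
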