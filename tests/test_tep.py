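import math

import numpy as np
import pytest

from strep_regulome.io import Gene, GenomeAnnotation
from strep_regulome.tep import (
    TEPCandidate, TEPRecord, build_training_set, categorize_tep,
    find_candidates, knn_classify, zscore,
)
from strep_regulome.tss import TSSRecord


def _track_with(heights):
    arr = np.zeros(400)
    for p, h in heights.items():
        arr[p - 1] = h
    return arr


def test_zscore_hand_computed_example():
    heights = {200: 6}
    for k, h in enumerate([1, 2, 1, 2, 1, 2, 1, 2]):
        heights[205 + 3 * k] = h
    z, flagged = zscore(200, _track_with(heights))
    assert not flagged
    assert z == pytest.approx((6 - 1.5) / 0.5345, abs=0.01)


def test_zscore_of_peak_equal_to_neighbours_is_zero():
    heights = {200: 3, 190: 3, 195: 3, 205: 3, 210: 3}
    z, flagged = zscore(200, _track_with(heights))
    assert z == 0.0 and not flagged


def test_isolated_spike_gets_infinite_sentinel():
    z, flagged = zscore(200, _track_with({200: 100}))
    assert math.isinf(z) and flagged


def test_zscore_window_must_cover_twenty_nt():
    with pytest.raises(ValueError):
        zscore(200, _track_with({200: 5}), window=10)


def test_count_and_z_filters_are_monotone_in_peak_height():
    """Raising the candidate's own count never flips accepted -> rejected."""
    base = {200: 5}
    for k, h in enumerate([2, 3, 2, 3, 2, 3]):
        base[210 + 4 * k] = h
    cov = np.full(400, 50.0)
    cov[200:] = 5.0
    accepted = []
    for h in (5, 10, 40, 160):
        base[200] = h
        track = _track_with(base)
        cands = find_candidates([track, track.copy()], cov, "+")
        accepted.append(any(c.position == 200 for c in cands))
    for lo, hi in zip(accepted, accepted[1:]):
        assert hi >= lo


def _feature(v):
    return np.array(v, dtype=float)


def test_knn_exact_match_follows_training_label():
    X = np.array([[1.8, 20, 1.0, 0.1, 0], [0.3, 2, 0.1, 0.2, 8],
                  [1.9, 25, 1.0, 0.2, 0], [0.2, 1, 0.05, 0.1, 12],
                  [1.7, 30, 1.0, 0.15, 0]])
    y = np.array([1, 0, 1, 0, 1])
    pos_cand = TEPCandidate(100, "+", 60, 20.0, False, features=X[0].copy())
    neg_cand = TEPCandidate(120, "+", 2, 2.0, False, features=X[1].copy())
    recs = knn_classify([pos_cand, neg_cand], X, y, k=1)
    assert pos_cand.knn_label == "tep" and neg_cand.knn_label == "shadow"
    assert [r.position for r in recs] == [100]


def test_knn_parameter_validation():
    X = np.zeros((4, 5))
    y = np.array([1, 0, 1, 0])
    with pytest.raises(ValueError):
        knn_classify([], X, y, k=2)  # even k
    with pytest.raises(ValueError):
        knn_classify([], X, y, k=5)  # k > training size


def test_training_set_rules(small_dataset):
    """Low read-through candidates become positives; negatives sit in the
    -20..+20 band around them; too few positives raises."""
    _sim, _g, _ann, _truth, tracks, _c = small_dataset
    term = [tracks["term_1"].counts["+"], tracks["term_2"].counts["+"]]
    cov = sum(tracks[f"rna_{p}_{r}"].counts["+"] for p in "ETS" for r in (1, 2))
    cands = find_candidates(term, cov, "+")
    X, y, meta = build_training_set(cands, np.sum(term, axis=0), cov, "+", seed=1)
    pos_positions = {p for kind, p in meta if kind == "pos"}
    assert len(pos_positions) >= 10
    for kind, p in meta:
        if kind == "neg":
            assert any(1 <= abs(p - q) <= 20 for q in pos_positions)
    with pytest.raises(ValueError):
        build_training_set(cands[:3], np.sum(term, axis=0), cov, "+")


def test_positional_categories_on_toy_annotation():
    genes = [Gene("gA", "chr1", "+", 500, 799), Gene("gB", "chr1", "+", 1000, 1299)]
    ann = GenomeAnnotation({"chr1": "G" * 2000}, genes)
    tss = [TSSRecord(450, "+", 3.0, height=50, gene_id="gA", category="primary")]
    recs = [
        TEPRecord(839, "+", 9, 60, "tep"),   # 40 nt past gA stop -> primary
        TEPRecord(930, "+", 9, 20, "tep"),   # further, weaker -> secondary
        TEPRecord(480, "+", 9, 40, "tep"),   # between TSS and gA body -> premature
        TEPRecord(1100, "-", 9, 30, "tep"),  # opposite strand inside gB -> antisense
        TEPRecord(1150, "+", 9, 30, "tep"),  # inside gB, sense -> internal
        TEPRecord(1900, "+", 9, 30, "tep"),  # far from everything -> intergenic
    ]
    categorize_tep(recs, ann, tss_records=tss)
    assert [r.category for r in recs] == [
        "primary", "secondary", "premature", "antisense", "internal", "intergenic"]


def test_strand_mirror_symmetry(small_dataset):
    _sim, _g, _ann, _truth, tracks, _c = small_dataset
    term = [tracks["term_1"].counts["+"], tracks["term_2"].counts["+"]]
    cov = sum(tracks[f"rna_{p}_{r}"].counts["+"] for p in "ETS" for r in (1, 2))
    fwd = find_candidates(term, cov, "+")
    L = len(cov)
    rev = find_candidates([a[::-1].copy() for a in term], cov[::-1].copy(), "-")
    assert sorted(L + 1 - c.position for c in rev) == sorted(c.position for c in fwd)


def test_classifier_balanced_accuracy_on_held_out_half(pipeline_result):
    """Train on one strand's controls, verify candidates of the other."""
    res = pipeline_result
    truth = res.truth
    planted = {(t.position, t.strand) for t in truth.tep_list}
    called = [(r.position, r.strand) for r in res.tep_records]
    tp = sum(1 for c in called if any(abs(c[0] - p) <= 2 and c[1] == s
                                      for p, s in planted))
    recall = sum(1 for p, s in planted
                 if any(abs(c[0] - p) <= 2 and c[1] == s for c in called)) / len(planted)
    precision = tp / len(called)
    assert (precision + recall) / 2 >= 0.9
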