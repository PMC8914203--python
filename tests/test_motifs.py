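import numpy as np
import pytest

from strep_regulome.io import GenomeAnnotation
from strep_regulome.motifs import (
    PWM, classify_tep_subcategory, discover_motif, extract_windows, scan_pwm,
    score_distribution, spacer_lengths,
)


def _ann(seq):
    return GenomeAnnotation({"chr1": seq}, [])


def test_window_extraction_plus_and_minus():
    ann = _ann("AACCGGTTAACCGGTT")
    out = extract_windows([(10, "+")], ann, -3, 1)
    assert out[0][1] == "TTAAC"  # genome[7..11]
    out_m = extract_windows([(10, "-")], ann, -3, 1)
    # -3..+1 on '-' = genomic 9..13 reverse-complemented
    assert out_m[0][1] == "CGGTT"


def test_out_of_bounds_anchor_dropped(capsys):
    ann = _ann("ACGTACGTACGT")
    out = extract_windows([(2, "+"), (8, "+")], ann, -4, 0)
    assert len(out) == 1 and out[0][0] == (8, "+")


def _planted_sequences(word, n=20, length=40, offset=12, seed=0, gc=0.7):
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = []
    for _ in range(n):
        s = list("".join(rng.choice(list("ACGT"), size=length, p=probs)))
        s[offset : offset + len(word)] = list(word)
        seqs.append("".join(s))
    return seqs


def test_oops_recovers_planted_word():
    seqs = _planted_sequences("TATCCT")
    pwm = discover_motif(seqs, width=6, mode="oops", seed=1)
    matches = sum(a == b for a, b in zip(pwm.consensus, "TATCCT"))
    assert matches >= 5
    assert {off for _i, off in pwm.sites} == {12}


def test_identical_sequences_give_maximal_information_content():
    pwm = discover_motif(["ACGTAC"] * 12, width=6, mode="oops", seed=0,
                         pseudocount=1e-6)
    assert pwm.consensus == "ACGTAC"
    assert pwm.information_content > 0.9 * 2 * 6


def test_random_sequences_score_below_planted_motif():
    planted = discover_motif(_planted_sequences("TATCCTGA", seed=3), width=8,
                             mode="zoops", seed=3)
    rng = np.random.default_rng(4)
    random_seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(20)]
    random_pwm = discover_motif(random_seqs, width=8, mode="zoops", seed=3)
    assert random_pwm.information_content < planted.information_content


def test_discovery_input_validation():
    with pytest.raises(ValueError):
        discover_motif(["ACGT"] * 12, width=10, mode="oops")
    with pytest.raises(ValueError):
        discover_motif(["ACGTACGT"] * 5, width=4, mode="oops")
    with pytest.raises(ValueError):
        discover_motif(["ACGTACGT"] * 12, width=4, mode="meme")


def test_exact_word_pwm_hit_probability():
    word = "ACGT"
    probs = np.zeros((4, 4))
    for i, b in enumerate(word):
        probs[i, "ACGT".index(b)] = 1.0
    pwm = PWM(probs, np.full(4, 0.25))
    offset, dist = score_distribution(pwm)
    hits = scan_pwm(pwm, [word], p_threshold=1e-2)
    assert len(hits) == 1
    assert hits[0].p == pytest.approx(0.25 ** 4, rel=1e-9)


def test_threshold_one_hits_every_position():
    probs = np.full((3, 4), 0.25)
    pwm = PWM(probs, np.full(4, 0.25))
    hits = scan_pwm(pwm, ["ACGTACGT"], p_threshold=1.01)
    assert len(hits) == 8 - 3 + 1


def test_scan_recall_on_planted_versus_shuffled():
    seqs = _planted_sequences("TATCCTGA", n=30, seed=5)
    pwm = discover_motif(seqs, width=8, mode="oops", seed=5)
    hits = scan_pwm(pwm, seqs, p_threshold=0.01)
    assert len({h.seq_index for h in hits}) >= 27  # recall >= 0.9
    rng = np.random.default_rng(6)
    shuffled = ["".join(rng.permutation(list(s))) for s in seqs]
    false_hits = {h.seq_index for h in scan_pwm(pwm, shuffled, p_threshold=1e-4)}
    assert len(false_hits) <= 6


def test_scan_pvalues_match_empirical_hit_rates():
    """Exact p-values are calibrated: hit rate on uniform random sequences
    matches the threshold within two binomial standard errors."""
    rng = np.random.default_rng(8)
    probs = rng.dirichlet([1, 1, 1, 1], size=6)
    pwm = PWM(probs, np.full(4, 0.25))
    p_thr = 0.05
    seqs = ["".join(rng.choice(list("ACGT"), size=6)) for _ in range(4000)]
    hits = scan_pwm(pwm, seqs, p_threshold=p_thr)
    rate = len(hits) / 4000
    se = np.sqrt(p_thr * (1 - p_thr) / 4000)
    assert abs(rate - p_thr) <= max(2 * se, 0.01)


def test_spacer_length_hand_count_and_adjacency():
    # -35 occupying -36..-29 and -10 occupying -16..-9 leave -28..-17: 12 nt
    assert spacer_lengths({"p": (-36, -29)}, {"p": (-16, -9)}) == {"p": 12}
    assert spacer_lengths({"p": (-20, -17)}, {"p": (-16, -9)}) == {"p": 0}
    overlapping = spacer_lengths({"p": (-20, -12)}, {"p": (-16, -9)})
    assert overlapping["p"] < 0  # flagged downstream


def test_tep_subcategory_precedence():
    assert classify_tep_subcategory(-40.0, has_motif_hit=True) == "motif"
    assert classify_tep_subcategory(-30.0, False) == "structured_non_motif"
    assert classify_tep_subcategory(-10.0, False) == "unstructured_non_motif"


def test_promoter_spacer_mode_is_twelve(pipeline_result):
    spacers = list(pipeline_result.promoter["spacers"].values())
    values, counts = np.unique(spacers, return_counts=True)
    assert values[np.argmax(counts)] == 12
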