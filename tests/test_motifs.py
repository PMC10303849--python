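import numpy as np
import pytest

from explainn.motifs import (PFM, PWM, pfm_to_pwm, pwm_similarity,
                             scan_best_hit, resize_profile, read_jaspar,
                             write_jaspar, read_meme, write_meme)
from explainn.benchmarks import make_pwm
from explainn.encoding import one_hot_encode, reverse_complement


def random_pfm(width, seed, n_sites=50):
    gen = np.random.default_rng(seed)
    counts = gen.multinomial(n_sites, [0.25] * 4, size=width).T.astype(float)
    return PFM(counts, float(n_sites), id=f"r{seed}")


# -- PFM/PWM conversion -------------------------------------------------------

def test_uniform_column_gives_zero_log_odds():
    pfm = PFM(np.full((4, 3), 10.0), 40.0)
    pwm = pfm_to_pwm(pfm, pseudocount=1.0)
    assert np.allclose(pwm.probs, 0.25)
    assert np.allclose(pwm.log_odds, 0.0)


def test_pseudocount_arithmetic():
    # column (A:3, C:0, G:0, T:0), pseudocount 1:
    # p_A = (3 + 0.25) / (3 + 1) = 0.8125; log2(0.8125 / 0.25) = log2(3.25)
    pfm = PFM(np.array([[3.0], [0.0], [0.0], [0.0]]), 3.0)
    pwm = pfm_to_pwm(pfm, pseudocount=1.0)
    assert pwm.probs[0, 0] == pytest.approx(0.8125)
    assert pwm.log_odds[0, 0] == pytest.approx(np.log2(3.25), abs=1e-6)


def test_pwm_columns_sum_to_one_for_random_pfms():
    for seed in range(20):
        pwm = pfm_to_pwm(random_pfm(7, seed))
        assert np.allclose(pwm.probs.sum(axis=0), 1.0)


def test_empty_pfm_rejected():
    with pytest.raises(ValueError):
        pfm_to_pwm(PFM(np.zeros((4, 5)), 0.0))


def test_consensus_and_reverse_complement():
    pwm = make_pwm("GATTACA")
    assert pwm.consensus() == "GATTACA"
    assert pwm.reverse_complement().consensus() == reverse_complement("GATTACA")
    assert np.allclose(pwm.reverse_complement().reverse_complement().probs,
                       pwm.probs)


# -- similarity ---------------------------------------------------------------

def test_similarity_self_match_is_one():
    pwm = make_pwm("GATTACAG")
    score, offset, strand = pwm_similarity(pwm, pwm)
    assert score == pytest.approx(1.0)
    assert offset == 0 and strand == "+"


def test_similarity_matches_reverse_complement():
    pwm = make_pwm("GATTACAG")
    score, _, strand = pwm_similarity(pwm, pwm.reverse_complement())
    assert score == pytest.approx(1.0)
    assert strand == "-"


def test_uniform_query_matches_nothing():
    uniform = PWM(np.full((4, 8), 0.25))
    informative = make_pwm("GATTACAG")
    score, _, _ = pwm_similarity(uniform, informative)
    assert score < 0.8


def test_similarity_equals_bruteforce_over_offsets():
    query = pfm_to_pwm(random_pfm(9, 1))
    target = pfm_to_pwm(random_pfm(6, 2))
    best = -np.inf
    for tgt in (target, target.reverse_complement()):
        for offset in range(-5, 9):  # all overlaps >= 1 column
            lo, hi = max(0, offset), min(9, offset + 6)
            if hi - lo < 5:
                continue
            q = query.probs[:, lo:hi].ravel()
            t = tgt.probs[:, lo - offset:hi - offset].ravel()
            qc, tc = q - q.mean(), t - t.mean()
            denom = np.sqrt((qc ** 2).sum() * (tc ** 2).sum())
            if denom > 0:
                best = max(best, float(qc @ tc / denom))
    score, _, _ = pwm_similarity(query, target, min_overlap=5)
    assert score == pytest.approx(best, abs=1e-12)


# -- scanning -----------------------------------------------------------------

def bruteforce_best_hit(pwm, seq):
    best = -np.inf
    for strand_seq in (seq, reverse_complement(seq)):
        x = one_hot_encode(strand_seq).matrix
        for p in range(len(seq) - pwm.width + 1):
            best = max(best, float((x[p:p + pwm.width].T * pwm.log_odds).sum()))
    return best


def test_scan_best_hit_tiny_example():
    probs = np.array([[0.1, 0.1], [0.7, 0.1], [0.1, 0.1], [0.1, 0.7]])
    pwm = PWM(probs)  # favors "CT"
    assert scan_best_hit(pwm, "ACAT") == pytest.approx(
        bruteforce_best_hit(pwm, "ACAT"))


def test_scan_best_hit_matches_bruteforce_randomized():
    from conftest import random_sequences

    gen = np.random.default_rng(0)
    for i in range(100):
        width = int(gen.integers(2, 9))
        pwm = pfm_to_pwm(random_pfm(width, i))
        seq = random_sequences(1, int(gen.integers(width, 30)), seed=i)[0]
        assert scan_best_hit(pwm, seq) == pytest.approx(
            bruteforce_best_hit(pwm, seq), abs=1e-9)


def test_palindromic_pwm_symmetric_strands():
    pwm = make_pwm("GAATTC")  # reverse-complement palindrome
    seq = "TTGAATTCAA"
    x = one_hot_encode(seq).matrix
    fwd = max(float((x[p:p + 6].T * pwm.log_odds).sum()) for p in range(5))
    assert scan_best_hit(pwm, seq) == pytest.approx(fwd)


def test_zero_log_odds_scores_zero():
    pwm = PWM(np.full((4, 4), 0.25))
    assert scan_best_hit(pwm, "ACGTACGT") == 0.0


def test_scan_rejects_short_sequence():
    with pytest.raises(ValueError, match="width"):
        scan_best_hit(make_pwm("GATTACAG"), "ACG")


# -- resizing -----------------------------------------------------------------

def test_resize_identity():
    pfm = random_pfm(19, 3)
    out = resize_profile(pfm, 19)
    assert np.array_equal(out.counts, pfm.counts)


def test_resize_pads_with_uniform_columns():
    pfm = random_pfm(17, 4, n_sites=40)
    out = resize_profile(pfm, 19)
    assert out.width == 19
    assert np.allclose(out.counts[:, 0], 10.0)
    assert np.allclose(out.counts[:, -1], 10.0)
    assert np.array_equal(out.counts[:, 1:18], pfm.counts)


def test_resize_odd_padding_goes_right():
    pfm = random_pfm(4, 5, n_sites=8)
    out = resize_profile(pfm, 7)  # pad 3: 1 left, 2 right
    assert np.array_equal(out.counts[:, 1:5], pfm.counts)
    assert np.allclose(out.counts[:, [0, 5, 6]], 2.0)


def test_resize_trims_to_max_ic_window():
    """Information concentrated away from the edges is kept; verified by an
    exhaustive scan over all candidate windows."""
    counts = np.full((4, 21), 5.0)
    sharp = make_pwm("GATTACAGATTACAGATTA").probs * 20
    counts[:, 1:20] = sharp  # columns 1..19 carry the information
    pfm = PFM(counts, 20.0)
    out = resize_profile(pfm, 19, strategy="max_ic")
    assert np.array_equal(out.counts, counts[:, 1:20])

    def window_ic(c):
        p = c / c.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / 0.25), 0.0)
        return terms.sum()

    ics = [window_ic(counts[:, s:s + 19]) for s in range(3)]
    assert np.argmax(ics) == 1


def test_resize_center_strategy():
    pfm = random_pfm(23, 6)
    out = resize_profile(pfm, 19, strategy="center")
    assert np.array_equal(out.counts, pfm.counts[:, 2:21])


# -- file formats -------------------------------------------------------------

def test_jaspar_round_trip_and_idempotence(tmp_path):
    pfms = [random_pfm(8, 1), random_pfm(11, 2)]
    p1 = tmp_path / "a.jaspar"
    write_jaspar(p1, pfms)
    back = read_jaspar(p1)
    assert [b.id for b in back] == [p.id for p in pfms]
    for orig, b in zip(pfms, back):
        assert np.allclose(orig.counts, b.counts)
    p2 = tmp_path / "b.jaspar"
    write_jaspar(p2, back)
    assert p1.read_text() == p2.read_text()  # write -> read -> write stable


def test_jaspar_four_line_dialect(tmp_path):
    path = tmp_path / "raw.pfm"
    path.write_text("1 2 3\n4 5 6\n7 8 9\n10 11 12\n")
    pfm = read_jaspar(path)[0]
    assert np.array_equal(pfm.counts,
                          np.array([[1, 2, 3], [4, 5, 6],
                                    [7, 8, 9], [10, 11, 12]], dtype=float))


def test_meme_round_trip(tmp_path):
    pwms = [make_pwm("GATTACAG", id="m1"), make_pwm("CCACGT", id="m2")]
    path = tmp_path / "x.meme"
    write_meme(path, pwms)
    back = read_meme(path)
    assert [b.id for b in back] == ["m1", "m2"]
    for orig, b in zip(pwms, back):
        assert np.allclose(orig.probs, b.probs, atol=1e-5)
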