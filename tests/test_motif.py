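"""PWM construction, exact p-values, scanning, and ZOOPS-EM discovery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrekit import motif as mo
from nrekit.model import AMINO_ACIDS, NRESegment, SegmentKind, expand


def _seg(seq, pid="P", cls="c"):
    return NRESegment(protein_id=pid, start=1, end=len(seq), sequence=seq,
                      kind=SegmentKind.NKE, class_label=cls)


class TestBackground:
    def test_homopolymer_closed_form(self):
        bg = mo.build_background([_seg("A" * 100)])
        assert bg[0] == pytest.approx(101 / 120)
        assert bg[1] == pytest.approx(1 / 120)

    def test_degenerate_b_splits_between_d_and_n(self):
        bg = mo.build_background([_seg("B")])
        d, n = AMINO_ACIDS.index("D"), AMINO_ACIDS.index("N")
        assert bg[d] == pytest.approx(1.5 / 21)
        assert bg[n] == pytest.approx(1.5 / 21)

    def test_uniform_corpus_near_uniform(self):
        bg = mo.build_background([_seg(AMINO_ACIDS * 50)])
        assert np.allclose(bg, 0.05)


class TestBuildPWM:
    def test_identical_sites_closed_form(self):
        bg = np.full(20, 0.05)
        m = mo.build_pwm(["ACDE"] * 4, bg)
        expected = np.log2(((4 + 0.1 * 0.05) / (4 + 0.1)) / 0.05)
        assert m.log_odds[0, 0] == pytest.approx(expected)

    def test_x_site_contributes_background_proportionally(self):
        bg = np.full(20, 0.05)
        m = mo.build_pwm(["X", "A"], bg)
        # the X spreads 1/20 to every letter: A column has 1 + 1/20 counts
        assert m.counts[0, 0] == pytest.approx(1.05)

    def test_log_odds_always_finite(self):
        bg = np.full(20, 0.05)
        m = mo.build_pwm(["AA", "AA", "AA"], bg)
        assert np.all(np.isfinite(m.log_odds))

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mo.build_pwm(["AAA", "AA"], np.full(20, 0.05))

    def test_degenerate_consensus_letter(self):
        bg = np.full(20, 0.05)
        m = mo.build_pwm(["D", "D", "N", "N"], bg)
        assert m.consensus == "B"


def _brute_force_tail(ints, background):
    """Oracle: enumerate every word, accumulate the exact tail."""
    w, k = ints.shape
    probs = {}
    for word in itertools.product(range(k), repeat=w):
        s = int(sum(ints[i, a] for i, a in enumerate(word)))
        p = float(np.prod([background[a] for a in word]))
        probs[s] = probs.get(s, 0.0) + p
    tail = {}
    acc = 0.0
    for s in sorted(probs, reverse=True):
        acc += probs[s]
        tail[s] = acc
    return tail


class TestExactPValues:
    @pytest.mark.parametrize("width", [1, 2, 3])
    def test_dp_equals_enumeration_full_alphabet(self, width):
        rng = np.random.default_rng(width)
        bg = rng.dirichlet(np.ones(20))
        counts = rng.dirichlet(np.ones(20), size=width) * 30
        m = mo.pwm_from_counts(counts, bg)
        table = mo.pwm_pvalue_table(m, bg)
        oracle = _brute_force_tail(table.int_scores, bg)
        for s, p in oracle.items():
            assert table.pvalue_int(s) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("width", [2, 5, 8])
    def test_dp_equals_enumeration_four_letter_alphabet(self, width):
        rng = np.random.default_rng(width + 100)
        bg4 = rng.dirichlet(np.ones(4))
        freqs = rng.dirichlet(np.ones(4), size=width)
        log_odds = np.log2(freqs / bg4)
        table = mo.score_tail_table(log_odds, bg4)
        oracle = _brute_force_tail(table.int_scores, bg4)
        for s, p in oracle.items():
            assert table.pvalue_int(s) == pytest.approx(p, abs=1e-12)

    def test_max_score_word_probability(self):
        """The top of the tail is exactly the probability of argmax words."""
        rng = np.random.default_rng(9)
        bg = rng.dirichlet(np.ones(20))
        counts = np.zeros((3, 20))
        counts[0, 0] = counts[1, 5] = counts[2, 7] = 50  # strict maxima
        m = mo.pwm_from_counts(counts, bg)
        table = mo.pwm_pvalue_table(m, bg)
        smax = int(table.int_scores.max(axis=1).sum())
        expected = bg[0] * bg[5] * bg[7]
        assert table.pvalue_int(smax) == pytest.approx(expected)

    def test_below_minimum_score_p_is_one(self):
        bg = np.full(20, 0.05)
        m = mo.build_pwm(["AC", "AC", "AD"], bg)
        table = mo.pwm_pvalue_table(m, bg)
        assert table.pvalue_int(table.min_total - 5) == 1.0

    def test_tail_monotone_non_increasing(self):
        rng = np.random.default_rng(4)
        bg = rng.dirichlet(np.ones(20))
        counts = rng.dirichlet(np.ones(20), size=4) * 25
        m = mo.pwm_from_counts(counts, bg)
        table = mo.pwm_pvalue_table(m, bg)
        assert np.all(np.diff(table.tail) <= 1e-15)

    def test_discretization_bound(self):
        """Integerized per-cell scores distort any word score by at most
        width * resolution / 2."""
        rng = np.random.default_rng(5)
        bg = rng.dirichlet(np.ones(20))
        counts = rng.dirichlet(np.ones(20), size=6) * 25
        m = mo.pwm_from_counts(counts, bg)
        table = mo.pwm_pvalue_table(m, bg, resolution=1e-3)
        for _ in range(200):
            word = rng.integers(0, 20, 6)
            exact = sum(m.log_odds[i, a] for i, a in enumerate(word))
            approx = sum(table.int_scores[i, a] for i, a in enumerate(word)) * 1e-3
            assert abs(exact - approx) <= 6 * 1e-3 / 2 + 1e-12


class TestScan:
    @pytest.fixture
    def strong_motif(self):
        bg = np.full(20, 0.05)
        return mo.build_pwm(["FSYEELHQ"] * 20, bg, motif_id="sig"), bg

    def test_consensus_segment_single_match(self, strong_motif):
        m, _ = strong_motif
        matches = mo.scan(m, _seg("FSYEELHQ"))
        assert len(matches) == 1
        assert (matches[0].start, matches[0].end) == (1, 8)
        assert matches[0].p_value <= 0.001

    def test_embedded_consensus_located(self, strong_motif):
        m, _ = strong_motif
        matches = mo.scan(m, _seg("KKKKK" + "FSYEELHQ" + "RRRRR"))
        assert [(x.start, x.end) for x in matches] == [(6, 13)]

    def test_width_exceeding_segment_empty(self, strong_motif):
        m, _ = strong_motif
        assert mo.scan(m, _seg("FSY")) == []

    def test_unrelated_background_rarely_matches(self, strong_motif):
        """Monte-Carlo: random 12-mers of background composition give no
        p <= 0.001 hit in at least 99% of draws."""
        m, _ = strong_motif
        rng = np.random.default_rng(17)
        hits = 0
        for i in range(1000):
            seq = "".join(AMINO_ACIDS[a] for a in rng.integers(0, 20, 12))
            if mo.scan(m, _seg(seq, f"P{i}")):
                hits += 1
        assert hits <= 10

    def test_match_invariant_to_padding(self, strong_motif):
        m, _ = strong_motif
        inner = mo.scan(m, _seg("AAAA" + "FSYEELHQ" + "AAAA"))
        padded = mo.scan(m, _seg("KKKKKKKKAAAA" + "FSYEELHQ" + "AAAAKKKKKKKK"))
        assert padded[0].start - inner[0].start == 8
        assert padded[0].score == pytest.approx(inner[0].score)

    def test_overlap_resolution_keeps_best_p(self):
        bg = np.full(20, 0.05)
        m = mo.build_pwm(["AAAA"] * 10, bg, motif_id="polyA")
        matches = mo.scan(m, _seg("AAAAAA"), p_threshold=1.0)
        assert len(matches) == 1
        assert matches[0].start == 1  # equal p: leftmost wins


class TestZoopsDiscovery:
    def test_planted_motif_recovered(self, discovery200):
        ds, trimmed, disc = discovery200
        planted = "VGPWKTGLSGQLQKAFVTGVP"
        m = disc.motifs_[0]
        agree = sum(1 for a, b in zip(m.consensus, planted) if b in expand(a))
        assert agree >= 19
        assert m.p_value <= 0.005

    def test_site_recall_and_precision(self, discovery200):
        ds, trimmed, disc = discovery200
        predicted = dict(disc.predicted_sites(0))
        truth = {}
        seg_by_id = {s.protein_id: s for s in trimmed}
        for pid, t in ds.truth.items():
            if t.motif_interval:
                truth[pid] = t.motif_interval[0] - seg_by_id[pid].start + 1
        tp = sum(1 for pid, s in predicted.items() if truth.get(pid) == s)
        assert tp / len(truth) >= 0.9    # recall
        assert tp / len(predicted) >= 0.9  # precision

    def test_occurrence_prior_tracks_planting_rate(self, discovery200):
        _, _, disc = discovery200
        assert abs(disc.motifs_[0].gamma - 0.8) < 0.1

    def test_same_seed_reproduces_bit_identical_model(self, discovery200):
        _, trimmed, disc = discovery200
        again = mo.ZoopsDiscovery(width_range=(21, 21), n_motifs=1, seed=3)
        again.fit(trimmed)
        assert np.array_equal(again.motifs_[0].counts, disc.motifs_[0].counts)
        assert again.motifs_[0].consensus == disc.motifs_[0].consensus

    def test_pure_background_finds_nothing_strong(self):
        rng = np.random.default_rng(23)
        segs = [
            _seg("".join(AMINO_ACIDS[a] for a in rng.integers(0, 20, 40)), f"P{i}")
            for i in range(60)
        ]
        disc = mo.ZoopsDiscovery(width_range=(12, 12), n_motifs=1, seed=1,
                                 n_starts=4, max_iter=60)
        disc.fit(segs)
        if disc.motifs_:  # anything reported must be weakly supported
            assert disc.motifs_[0].gamma < 0.5

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError):
            mo.ZoopsDiscovery().fit([_seg("A" * 30)])


class TestMemeRoundTrip:
    def test_write_read_preserves_model(self, tmp_path, discovery200):
        _, _, disc = discovery200
        path = tmp_path / "m.meme"
        mo.write_meme(disc.motifs_, path)
        back = mo.read_meme(path)
        assert len(back) == 1
        assert back[0].id == disc.motifs_[0].id
        assert back[0].width == disc.motifs_[0].width
        assert back[0].consensus == disc.motifs_[0].consensus
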