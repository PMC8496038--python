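import itertools

import numpy as np
import pytest

from regseq.motif_model import reverse_complement
from regseq.pwm_scanner import (
    PwmScorer,
    ScanConfig,
    encode,
    hit_count_features,
    log_odds,
    scan,
    threshold_from_pvalue,
    write_hits_bed,
)
from regseq.synthetic_data import random_background

from .conftest import make_record, one_hot_matrix, random_matrix

UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)


class TestLogOdds:
    def test_uniform_matrix_uniform_bg(self):
        m = random_matrix(np.random.default_rng(0), 4)
        uni = m.probs * 0 + 0.25
        lo = log_odds(type(m)(uni), UNIFORM_BG, pseudocount=0)
        assert np.allclose(lo, 0.0)

    def test_deterministic_consensus_cell(self):
        lo = log_odds(one_hot_matrix("A"), UNIFORM_BG, pseudocount=0)
        assert lo[0, 0] == pytest.approx(2.0)
        assert np.all(np.isinf(lo[0, 1:]))

    def test_max_word_equals_column_max_sum(self, rng):
        m = random_matrix(rng, 6)
        lo = log_odds(m, UNIFORM_BG, pseudocount=1e-3)
        best_enum = max(
            sum(lo[i, w[i]] for i in range(6)) for w in itertools.product(range(4), repeat=6)
        )
        assert best_enum == pytest.approx(lo.max(axis=1).sum())


# independent discretization mirror of the documented contract
def discretized(scores, bins=1000):
    span = scores.max(axis=1).sum() - scores.min(axis=1).sum()
    scale = bins / span if span > 0 else 1.0
    return np.rint(scores * scale).astype(int), scale


def oracle_threshold(q, bg, p):
    """Smallest integer t with P(word score >= t) <= p, by 4^L enumeration."""
    L = len(q)
    words = list(itertools.product(range(4), repeat=L))
    scores = np.array([sum(q[i, w[i]] for i in range(L)) for w in words])
    probs = np.array([np.prod([bg[b] for b in w]) for w in words])
    lattice_min = q.min(axis=1).sum()
    order = np.argsort(scores)[::-1]
    s_desc, cum = scores[order], np.cumsum(probs[order])
    # tail(s) = cum at the last (lowest-ranked) occurrence of s
    last = np.flatnonzero(np.append(s_desc[1:] != s_desc[:-1], True))
    attained, tails = s_desc[last], cum[last]
    over = attained[tails > p + 1e-15]
    return int(over.max()) + 1 if len(over) else int(lattice_min)


class TestThreshold:
    def test_p_one_gives_minimum(self, rng):
        m = random_matrix(rng, 5)
        lo = log_odds(m, UNIFORM_BG, 1e-3)
        t = threshold_from_pvalue(lo, UNIFORM_BG, p=1.0)
        q, scale = discretized(lo)
        assert round(t * scale) == q.min(axis=1).sum()

    def test_single_best_word(self, rng):
        # at p = 1/64 only the consensus word qualifies
        m = random_matrix(rng, 3)
        lo = log_odds(m, UNIFORM_BG, 1e-3)
        t = threshold_from_pvalue(lo, UNIFORM_BG, p=1 / 64)
        q, scale = discretized(lo)
        t_int = round(t * scale)
        passing = [
            w
            for w in itertools.product(range(4), repeat=3)
            if sum(q[i, w[i]] for i in range(3)) >= t_int
        ]
        assert passing == [tuple(q.argmax(axis=1))]

    @pytest.mark.parametrize("length", [3, 4, 5, 6, 7, 8])
    @pytest.mark.parametrize("bg", [UNIFORM_BG, (0.3, 0.2, 0.2, 0.3)])
    def test_dp_equals_enumeration(self, length, bg):
        rng = np.random.default_rng(length * 100 + int(bg[0] * 10))
        m = random_matrix(rng, length)
        lo = log_odds(m, np.asarray(bg), 1e-3)
        q, scale = discretized(lo)
        for p in (0.5, 0.05, 1e-3, 1e-4):
            t = threshold_from_pvalue(lo, bg, p=p)
            assert round(t * scale) == oracle_threshold(q, bg, p)

    def test_monotone_in_p(self, rng):
        m = random_matrix(rng, 6)
        lo = log_odds(m, UNIFORM_BG, 1e-3)
        ps = [1.0, 0.5, 0.1, 1e-2, 1e-3, 1e-4, 1e-5]
        ts = [threshold_from_pvalue(lo, UNIFORM_BG, p=p) for p in ps]
        assert all(a <= b + 1e-12 for a, b in zip(ts, ts[1:]))

    def test_tiny_p_warns_and_returns_above_max(self, rng):
        m = random_matrix(rng, 3)
        lo = log_odds(m, UNIFORM_BG, 1e-3)
        with pytest.warns(UserWarning, match="no word"):
            t = threshold_from_pvalue(lo, UNIFORM_BG, p=1e-9)
        assert t > lo.max(axis=1).sum() - 1e-9


class TestScan:
    def setup_method(self):
        self.motif = make_record("m", one_hot_matrix("ACGTAC"))
        self.cfg = ScanConfig(p_value=4 ** -6)

    def test_consensus_single_forward_hit(self):
        hits = scan("ACGTAC", self.motif, self.cfg)
        assert [(h.start, h.end, h.strand) for h in hits] == [(0, 6, "+")]

    def test_reverse_complement_hit(self):
        hits = scan("GTACGT", self.motif, self.cfg)
        assert [(h.start, h.strand) for h in hits] == [(0, "-")]

    def test_sequence_shorter_than_motif(self):
        assert scan("ACG", self.motif, self.cfg) == []

    def test_ambiguous_base_blocks_hit(self):
        assert scan("ACGNAC", self.motif, self.cfg) == []

    def test_forward_only_config(self):
        cfg = ScanConfig(p_value=4 ** -6, strands="forward")
        assert scan("GTACGT", self.motif, cfg) == []

    def test_palindromic_motif_double_counts_interval(self):
        pal = make_record("pal", one_hot_matrix("CACGTG"))
        hits = scan("CACGTG", pal, ScanConfig(p_value=4 ** -6))
        assert [(h.start, h.strand) for h in hits] == [(0, "+"), (0, "-")]

    def test_hit_scores_meet_threshold(self, rng):
        motif = make_record("r", random_matrix(rng, 6))
        cfg = ScanConfig(p_value=1e-3)
        seq = random_background(5000, 0.5, rng)
        scorer = PwmScorer(motif, cfg)
        for h in scan(seq, motif, cfg):
            assert round(h.score * scorer.scale) >= scorer.t_int

    def test_binomial_expectation(self):
        # deterministic 6-mer at p = 4^-6: expected hits = 2 * (N - 5) * 4^-6
        cfg = ScanConfig(p_value=4 ** -6)
        scorer = PwmScorer(self.motif, cfg)
        rng = np.random.default_rng(2024)
        n_seeds, n = 1000, 2000
        total = 0
        for _ in range(n_seeds):
            codes = rng.integers(0, 4, size=n).astype(np.int8)
            for strand in ("+", "-"):
                starts, _ = scorer.hit_starts(codes, strand)
                total += len(starts)
        lam = 2 * (n - 5) * 4.0 ** -6
        se = np.sqrt(lam / n_seeds)
        assert abs(total / n_seeds - lam) < 3 * se

    def test_numba_and_numpy_paths_agree(self, rng):
        motif = make_record("r", random_matrix(rng, 8))
        cfg = ScanConfig(p_value=1e-3)
        scorer = PwmScorer(motif, cfg)
        codes = encode(random_background(30000, 0.4, rng))
        for strand in ("+", "-"):
            fast_starts, fast_scores = scorer.hit_starts(codes, strand)
            ws = scorer.window_scores(codes, strand)
            slow_starts = np.flatnonzero(ws >= scorer.t_int)
            assert np.array_equal(fast_starts, slow_starts)
            assert np.array_equal(fast_scores, ws[slow_starts])

    def test_concatenation_union_property(self, rng):
        motif = make_record("r", random_matrix(rng, 6))
        cfg = ScanConfig(p_value=1e-2)
        s1 = random_background(400, 0.5, rng)
        s2 = random_background(400, 0.5, rng)
        joint = scan(s1 + s2, motif, cfg)
        solo = scan(s1, motif, cfg) + [
            type(h)(h.sequence_id, h.start + 400, h.end + 400, h.strand, h.motif_id, h.score)
            for h in scan(s2, motif, cfg)
        ]
        solo_keys = {(h.start, h.strand) for h in solo}
        joint_keys = {(h.start, h.strand) for h in joint}
        # joint scan may add junction-window hits only
        assert solo_keys <= joint_keys
        junction = joint_keys - solo_keys
        assert all(400 - 6 < s < 400 for s, _ in junction)


class TestHitCountFeatures:
    def test_implanted_consensi_counted(self, rng):
        motif = make_record("m", one_hot_matrix("ACGTAC"))
        bg = "TTTTTTTTTT"
        seq = bg + "ACGTAC" + bg + "ACGTAC" + bg + "ACGTAC" + bg
        feats = hit_count_features([("s1", seq)], [motif], ScanConfig(p_value=4 ** -6))
        assert feats.loc["s1", "m"] == 3

    def test_matches_per_sequence_scan(self, rng):
        motifs = [make_record(f"m{i}", random_matrix(rng, 6)) for i in range(4)]
        cfg = ScanConfig(p_value=1e-2)
        seqs = [(f"s{i}", random_background(300, 0.5, rng)) for i in range(8)]
        feats = hit_count_features(seqs, motifs, cfg)
        for sid, s in seqs:
            for m in motifs:
                assert feats.loc[sid, m.id] == len(scan(s, m, cfg))

    def test_duplicate_ids_rejected(self, rng):
        m = make_record("dup", random_matrix(rng, 5))
        with pytest.raises(ValueError, match="duplicate"):
            hit_count_features([("s", "ACGT")], [m, m])

    def test_empty_motif_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            hit_count_features([("s", "ACGT")], [])

    def test_shuffled_sequence_changes_counts(self, rng):
        motif = make_record("m", one_hot_matrix("AAACGTCC"))  # non-palindromic
        seq = "T" * 50 + "AAACGTCC" + "T" * 50
        shuffled = "".join(rng.permutation(list(seq)))
        cfg = ScanConfig(p_value=4 ** -8)
        feats = hit_count_features([("orig", seq), ("shuf", shuffled)], [motif], cfg)
        assert sorted(seq) == sorted(shuffled)  # composition preserved
        assert feats.loc["orig", "m"] == 1
        assert feats.loc["shuf", "m"] == 0  # w.h.p. at this stringency


def test_bed_output(tmp_path, rng):
    motif = make_record("m", one_hot_matrix("ACGTAC"))
    hits = scan("TTACGTACTT", motif, ScanConfig(p_value=4 ** -6), sequence_id="chrZ")
    path = tmp_path / "hits.bed"
    write_hits_bed(hits, path)
    fields = path.read_text().strip().split("\t")
    assert fields[0] == "chrZ" and fields[1] == "2" and fields[2] == "8"
    assert fields[3] == "m" and fields[5] == "+"
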