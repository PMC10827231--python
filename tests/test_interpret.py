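import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import fisher_exact, hypergeom

from conftest import random_dna
from m6adeg.interpret import (
    AttributionProfile,
    HighAttributionRegion,
    aggregate_to_nucleotides,
    attribute_sequence,
    call_high_regions,
    extract_motif_windows,
    hypergeometric_motif_test,
    integrated_gradients,
    positionwise_attribution_matrix,
    rbp_enrichment,
)
from m6adeg.io import BindingInterval
from m6adeg.tokenizer import TokenizedSequence, TokenizerConfig, build_vocab, encode


def region(seq_id, start, end, sub, score=1.0):
    return HighAttributionRegion(sequence_id=seq_id, start=start, end=end,
                                 mean_score=score, subsequence=sub)


class TestAggregation:
    def test_constant_field(self):
        cfg = TokenizerConfig(K=3, max_tokens=61)
        vocab = build_vocab(cfg)
        tok = encode(random_dna(np.random.default_rng(0), 30), vocab, cfg)
        scores = np.full(tok.n_kmers, 2.5)
        nt = aggregate_to_nucleotides(scores, tok.coverage, 3)
        np.testing.assert_allclose(nt, 2.5)

    def test_hand_computed_small_case(self):
        cfg = TokenizerConfig(K=3, max_tokens=11)
        vocab = build_vocab(cfg)
        tok = encode("ACGTA", vocab, cfg)  # 3 k-mers, coverage counts 1,2,3,2,1
        nt = aggregate_to_nucleotides(np.array([3.0, 6.0, 9.0]), tok.coverage, 3)
        np.testing.assert_allclose(nt, [3.0, 4.5, 6.0, 7.5, 9.0])

    def test_weighted_sum_identity_on_random_instances(self):
        """sum_i nt[i]*|cov_i| == sum_t score_t * (#nt covered by t)."""
        rng = np.random.default_rng(1)
        for k in (3, 4, 5, 6):
            cfg = TokenizerConfig(K=k, max_tokens=101)
            vocab = build_vocab(cfg)
            seq = random_dna(rng, int(rng.integers(k + 1, 90)))
            tok = encode(seq, vocab, cfg)
            scores = rng.normal(size=tok.n_kmers)
            nt = aggregate_to_nucleotides(scores, tok.coverage, k)
            lhs = sum(nt[i] * len(tok.coverage[i]) for i in range(len(seq)))
            span = [min(j + k, len(seq)) - j for j in range(tok.n_kmers)]
            rhs = float(np.dot(scores, span))
            assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_inconsistent_coverage_rejected(self):
        with pytest.raises(ValueError, match="covered by"):
            aggregate_to_nucleotides(np.array([1.0]), [[1, 2, 3, 4]], 3)


class TestRegionCalling:
    def test_hand_trace(self):
        scores = np.array([1, 1, 1, 5, 5, 5, 5, 5, 1], dtype=float)
        seq = "ACGTACGTA"
        regs = call_high_regions(scores, seq, sequence_id="s1", min_region_len=5)
        assert len(regs) == 1
        assert (regs[0].start, regs[0].end) == (3, 8)
        assert regs[0].subsequence == seq[3:8]

    def test_constant_scores_no_regions(self):
        assert call_high_regions(np.ones(20), "A" * 20) == []

    def test_all_positions_exceed_mean(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=200)
        seq = random_dna(rng, 200)
        for r in call_high_regions(scores, seq, min_region_len=3):
            assert (scores[r.start : r.end] > scores.mean()).all()

    def test_min_length_enforced_and_multiple_regions(self):
        scores = np.array([9, 9, 9, 0, 0, 0, 0, 9, 9, 9, 0, 9], dtype=float)
        regs = call_high_regions(scores, "ACGTACGTACGT", min_region_len=3)
        assert [(r.start, r.end) for r in regs] == [(0, 3), (7, 10)]

    def test_global_threshold_flag(self):
        scores = np.array([1.0, 2.0, 2.0, 2.0, 2.0, 2.0])
        regs = call_high_regions(scores, "ACGTAC", min_region_len=5, threshold=0.0)
        assert [(r.start, r.end) for r in regs] == [(0, 6)]


def hypergeom_pmf_oracle(k, N, n, K):
    """P(X=k) by exact combinatorial enumeration (Fraction arithmetic)."""
    if k < max(0, n + K - N) or k > min(n, K):
        return Fraction(0)
    return Fraction(math.comb(n, k) * math.comb(N - n, K - k), math.comb(N, K))


class TestHypergeometricOracle:
    def test_printed_example(self):
        assert hypergeom_pmf_oracle(2, 10, 4, 5) == Fraction(120, 252)
        assert hypergeom.pmf(2, 10, 4, 5) == pytest.approx(120 / 252, abs=1e-12)

    def test_pmf_agrees_with_enumeration_small_universe(self):
        for N in range(1, 16):
            for n in range(N + 1):
                for K in range(N + 1):
                    for k in range(min(n, K) + 1):
                        want = float(hypergeom_pmf_oracle(k, N, n, K))
                        got = hypergeom.pmf(k, N, n, K)
                        assert got == pytest.approx(want, abs=1e-12)

    def test_pmf_normalizes(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            N = int(rng.integers(2, 40))
            n = int(rng.integers(0, N + 1))
            K = int(rng.integers(0, N + 1))
            total = sum(hypergeom.pmf(k, N, n, K) for k in range(N + 1))
            assert total == pytest.approx(1.0, abs=1e-9)


class TestMotifTest:
    def test_exclusive_motif_is_most_significant(self):
        query = [region("q", 0, 6, "TATTTA") for _ in range(10)]
        query += [region("q", 0, 6, s) for s in ("ACACAC", "GTGTGT") for _ in range(4)]
        other = [region("o", 0, 6, s) for s in ("ACACAC", "GTGTGT") for _ in range(4)]
        res = hypergeometric_motif_test(query, other, min_count=5)
        assert res and res[0].motif == "TATTTA"
        assert res[0].k_in_set == res[0].n_motif == 10
        assert res[0].adjusted_p < 0.05

    def test_low_frequency_candidates_excluded(self):
        query = [region("q", 0, 6, "TATTTA") for _ in range(4)]  # n_motif = 4 < 5
        other = [region("o", 0, 6, "ACACAC") for _ in range(10)]
        assert hypergeometric_motif_test(query, other) == []

    def test_empty_query(self):
        assert hypergeometric_motif_test([], [region("o", 0, 6, "AAAAAA")] * 6) == []

    def test_balanced_occurrences_not_significant(self):
        query = [region("q", 0, 6, "TATTTA") for _ in range(6)]
        other = [region("o", 0, 6, "TATTTA") for _ in range(6)]
        assert hypergeometric_motif_test(query, other) == []

    def test_counts_invariants(self):
        rng = np.random.default_rng(4)
        strings = ["AAAAA", "CCCCC", "GGGGG"]
        query = [region("q", 0, 5, strings[rng.integers(3)]) for _ in range(30)]
        other = [region("o", 0, 5, strings[rng.integers(3)]) for _ in range(30)]
        for c in hypergeometric_motif_test(query, other, alpha=1.0):
            assert c.k_in_set <= min(c.K_set, c.n_motif)
            assert max(c.K_set, c.n_motif) <= c.N_total


class TestMotifWindows:
    def test_centered_full_width(self):
        seq = random_dna(np.random.default_rng(5), 100)
        w = extract_motif_windows(seq, motif_start=47, motif_len=6, width=24)
        assert len(w) == 24
        assert seq[47:53] in w

    def test_clipped_near_edge(self):
        seq = random_dna(np.random.default_rng(6), 100)
        w = extract_motif_windows(seq, motif_start=3, motif_len=6, width=24)
        assert len(w) < 24
        assert w == seq[: len(w)]
        assert seq[3:9] in w

    def test_window_contains_motif(self):
        rng = np.random.default_rng(7)
        seq = random_dna(rng, 60)
        for start in (0, 10, 30, 54):
            w = extract_motif_windows(seq, start, 6)
            assert seq[start : start + 6] in w


def fisher_onesided_oracle(a, b, c, d, direction):
    """One-sided Fisher p as a hypergeometric tail sum with fixed margins."""
    N, K, n = a + b + c + d, a + b, a + c
    lo, hi = max(0, n - (N - K)), min(n, K)
    ks = range(a, hi + 1) if direction == "greater" else range(lo, a + 1)
    return float(sum(hypergeom_pmf_oracle(k, N, n, K) for k in ks))


class TestFisherOracle:
    def test_printed_example(self):
        p = fisher_exact([[3, 0], [0, 3]], alternative="greater")[1]
        assert p == pytest.approx(1 / math.comb(6, 3), abs=1e-12)  # 1/20 = 0.05

    def test_agrees_with_enumeration_for_small_tables(self):
        for total in range(1, 13):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        for alt in ("greater", "less"):
                            want = fisher_onesided_oracle(a, b, c, d, alt)
                            got = fisher_exact([[a, b], [c, d]], alternative=alt)[1]
                            assert got == pytest.approx(want, abs=1e-10)


class TestRBPEnrichment:
    def _setup(self, assoc=True):
        regions, labels, track = {}, {}, []
        for i in range(8):
            sid = f"s{i}"
            labels[sid] = 1 if i < 4 else 0
            regions[sid] = [region(sid, 10, 20, "ACGTACGTAC")]
            if assoc:
                bound = labels[sid] == 0  # bind only negatives
            else:
                bound = i % 2 == 0  # equal in both classes
            if bound:
                track.append(BindingInterval(seq_id=sid, start=12, end=18, protein="RBP1"))
        return regions, labels, track

    def test_perfect_negative_association_detected(self):
        regions, labels, track = self._setup(assoc=True)
        res = rbp_enrichment(regions, labels, track, alpha=0.05)
        assert len(res) == 1
        r = res[0]
        assert r.direction == "negative-enriched"
        assert (r.a, r.b, r.c, r.d) == (0, 4, 4, 0)
        # one-sided p for the [[0,4],[4,0]] table is 1/C(8,4)
        assert r.p_value == pytest.approx(1 / math.comb(8, 4), abs=1e-12)

    def test_balanced_binding_not_significant(self):
        regions, labels, track = self._setup(assoc=False)
        assert rbp_enrichment(regions, labels, track) == []

    def test_offset_mapping_into_track_space(self):
        # region [5,10) in window space maps to [105,110) on the transcript
        regions = {"s0": [region("s0", 5, 10, "ACGTA")], "s1": []}
        labels = {"s0": 0, "s1": 1}
        track = [BindingInterval(seq_id="txA", start=108, end=112, protein="R")]
        offsets = {"s0": ("txA", 100), "s1": ("txB", 0)}
        res = rbp_enrichment(regions, labels, track, region_offsets=offsets, alpha=1.0)
        hit = [r for r in res if r.direction == "negative-enriched"]
        assert hit and (hit[0].c, hit[0].d) == (1, 0)

    def test_no_overlap_when_shifted_away(self):
        regions = {"s0": [region("s0", 5, 10, "ACGTA")], "s1": []}
        labels = {"s0": 0, "s1": 1}
        track = [BindingInterval(seq_id="txA", start=200, end=210, protein="R")]
        offsets = {"s0": ("txA", 100), "s1": ("txB", 0)}
        for r in rbp_enrichment(regions, labels, track, region_offsets=offsets, alpha=1.0):
            assert r.c == 0


class TestIntegratedGradients:
    def test_reference_input_gets_zero_attribution(self, tiny_trained):
        model, vocab, cfg, pos, neg = tiny_trained
        tok = pos[0]
        ref_ids = [vocab.cls_id] + [vocab.pad_id] * (len(tok.ids) - 2) + [vocab.sep_id]
        ref_tok = TokenizedSequence(ids=tuple(ref_ids), n_kmers=tok.n_kmers,
                                    coverage=tok.coverage, source_length=tok.source_length)
        scores, gap = integrated_gradients(model, ref_tok, vocab, n_steps=8)
        np.testing.assert_allclose(scores, 0.0)
        assert gap == 0.0

    def test_invalid_steps(self, tiny_trained):
        model, vocab, cfg, pos, _ = tiny_trained
        with pytest.raises(ValueError, match="n_steps"):
            integrated_gradients(model, pos[0], vocab, n_steps=0)

    def test_profile_shapes_and_gap(self, tiny_trained):
        model, vocab, cfg, pos, _ = tiny_trained
        prof = attribute_sequence(model, pos[0], vocab, sequence_id="p0", n_steps=32)
        assert len(prof.nt_scores) == pos[0].source_length
        assert len(prof.token_scores) == pos[0].n_kmers
        assert prof.completeness_gap < 1e-2


class TestPositionwiseMatrix:
    def test_single_full_profile_layout(self):
        nt = np.arange(11, dtype=float)
        prof = AttributionProfile(sequence_id="s", token_scores=np.zeros(9),
                                  nt_scores=nt, n_steps=1, reference_id="",
                                  completeness_gap=0.0)
        mat, positions, col_mean = positionwise_attribution_matrix([prof], [5], flank=5)
        assert mat.shape == (1, 11)
        np.testing.assert_allclose(mat[0], nt)
        assert positions[0] == -5 and positions[-1] == 5

    def test_default_column_count_is_501(self):
        nt = np.zeros(501)
        prof = AttributionProfile(sequence_id="s", token_scores=np.zeros(499),
                                  nt_scores=nt, n_steps=1, reference_id="",
                                  completeness_gap=0.0)
        mat, positions, _ = positionwise_attribution_matrix([prof], [250])
        assert mat.shape[1] == 501

    def test_trimmed_window_leaves_nan_gaps(self):
        nt = np.ones(7)
        prof = AttributionProfile(sequence_id="s", token_scores=np.zeros(5),
                                  nt_scores=nt, n_steps=1, reference_id="",
                                  completeness_gap=0.0)
        mat, positions, col_mean = positionwise_attribution_matrix([prof], [2], flank=5)
        # center_offset 2: columns -2..+4 filled, rest NaN
        assert np.isnan(mat[0, :3]).all()
        np.testing.assert_allclose(mat[0, 3:10], 1.0)
        assert np.isnan(mat[0, 10])
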