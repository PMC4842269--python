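import math

import numpy as np
import pytest

from tssmapper.io_formats import Replicon
from tssmapper.promoter import (Motif, Pattern, PromoterConfig, build_pwm,
                                cluster_motifs, dinucleotide_shuffle,
                                discover_motifs, enumerate_patterns,
                                extract_upstream, label_motifs, map_promoters,
                                pattern_score, revcomp, score_overrepresentation,
                                score_window)
from tssmapper.simulate import MotifSpec, simulate_upstream_windows
from tssmapper.tss_svm import ScoredTSS


def _tss(pos, strand="+", tss_id="t1", replicon_id="chr"):
    return ScoredTSS(id=tss_id, replicon_id=replicon_id, strand=strand, position=pos,
                     score_free=1.0, detected_in={"Free"})


class TestExtractUpstream:
    def test_plus_strand_window(self):
        rep = Replicon("chr", "".join("ACGT"[i % 4] for i in range(200)))
        (tid, seq), = extract_upstream([_tss(100)], {"chr": rep}, 10)
        assert seq == rep.sequence[89:99]
        assert len(seq) == 10

    def test_minus_strand_window_is_reverse_complement(self):
        rep = Replicon("chr", "".join("ACGT"[i % 4] for i in range(200)))
        (tid, seq), = extract_upstream([_tss(100, "-")], {"chr": rep}, 10)
        assert seq == revcomp(rep.sequence[100:110])

    def test_edge_tss_skipped(self):
        rep = Replicon("chr", "A" * 50)
        assert extract_upstream([_tss(5)], {"chr": rep}, 10) == []


def brute_force_pattern_count(seqs, box_up, box_down, pos_up, pos_down, cfg):
    """Regex-free Hamming scanner, one independent check per sequence."""
    def box_hits(seq, kmer, pos):
        W, k = len(seq), len(kmer)
        for shift in range(-cfg.max_position_shift, cfg.max_position_shift + 1):
            i = pos + shift + W
            if i < 0 or i + k > W:
                continue
            sub = seq[i:i + k]
            if "N" not in sub and sum(a != b for a, b in zip(sub, kmer)) \
                    <= cfg.max_mismatch_per_box:
                return True
        return False

    return sum(1 for s in seqs
               if box_hits(s, box_up, pos_up) and box_hits(s, box_down, pos_down))


class TestEnumerate:
    def test_exact_planting_counts_every_sequence(self):
        cfg = PromoterConfig()
        seqs, _ = simulate_upstream_windows(
            100, 50, 0.5, MotifSpec("m", "TTGACA", "TATAAT", -35, -10, 1.0,
                                    mutation_rate=0.0), 1.0, seed=0)
        patterns = enumerate_patterns(seqs, cfg)
        hit = [p for p in patterns if p.box_up == "TTGACA" and p.box_down == "TATAAT"
               and (p.pos_up, p.pos_down) == (-35, -10)]
        assert hit and hit[0].observed == 100

    def test_mismatch_tolerance_matches_plant_rate(self):
        # one mutated base in ~30% of planted copies: tolerant matching
        # recovers them all, exact matching only the intact ones
        spec = MotifSpec("m", "TTGACA", "TATAAT", -35, -10, 1.0, mutation_rate=0.0)
        seqs, _ = simulate_upstream_windows(200, 50, 0.5, spec, 1.0, seed=1)
        rng = np.random.default_rng(2)
        mutated = []
        n_mut = 0
        for s in seqs:
            s = list(s)
            if rng.random() < 0.3:
                n_mut += 1
                i = 50 - 35 + int(rng.integers(6))  # one base inside the -35 box
                s[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[i]]
            mutated.append("".join(s))
        tol = PromoterConfig(max_mismatch_per_box=1, max_position_shift=0)
        strict = PromoterConfig(max_mismatch_per_box=0, max_position_shift=0)

        def observed(cfg):
            pats = enumerate_patterns(mutated, cfg)
            p = [q for q in pats if q.box_up == "TTGACA" and q.box_down == "TATAAT"
                 and (q.pos_up, q.pos_down) == (-35, -10)]
            return p[0].observed if p else 0

        assert observed(tol) == 200
        assert observed(strict) == 200 - n_mut
        assert observed(tol) == brute_force_pattern_count(
            mutated, "TTGACA", "TATAAT", -35, -10, tol)

    def test_counts_equal_brute_force_scanner(self):
        cfg = PromoterConfig(window=40, min_seed_count=2)
        seqs, _ = simulate_upstream_windows(60, 40, 0.5, None, 0.0, seed=3)
        for p in enumerate_patterns(seqs, cfg):
            assert p.observed == brute_force_pattern_count(
                seqs, p.box_up, p.box_down, p.pos_up, p.pos_down, cfg)


class TestOverrepresentation:
    def test_score_formula_on_absent_pattern(self):
        assert pattern_score(0, 5, 1) == pytest.approx(math.log2(1 / 6))

    def test_planted_pattern_scores_above_threshold(self):
        cfg = PromoterConfig()
        spec = MotifSpec("m", "TTGACA", "TATAAT", -35, -12, 1.0)
        seqs, _ = simulate_upstream_windows(500, 50, 0.64, spec, 0.5, seed=4)
        pats = score_overrepresentation(enumerate_patterns(seqs, cfg), cfg, len(seqs))
        planted = [p for p in pats if p.box_up == "TTGACA" and p.box_down == "TATAAT"]
        assert planted and planted[0].score > cfg.overrep_threshold
        # independent expectation: band match probabilities under the GC model
        # are tiny, so expected co-occurrence is far below 1% of sequences
        assert planted[0].expected < 0.01 * len(seqs)

    def test_gc_background_null_retains_nothing(self, rng):
        cfg = PromoterConfig()
        for rep in range(3):
            seqs, _ = simulate_upstream_windows(300, 50, 0.64, None, 0.0,
                                                seed=100 + rep)
            retained = score_overrepresentation(enumerate_patterns(seqs, cfg),
                                                cfg, len(seqs))
            assert retained == []


class TestPwm:
    def test_identical_kmers_give_near_delta_columns(self):
        pwm = build_pwm(["TATAAT"] * 50, 6, 0.5)
        consensus = "TATAAT"
        for i, b in enumerate(consensus):
            assert pwm["ACGT".index(b), i] > 0.95
        assert np.allclose(pwm.sum(axis=0), 1.0)

    def test_columns_always_stochastic(self):
        rng = np.random.default_rng(0)
        kmers = ["".join("ACGT"[c] for c in rng.integers(0, 4, 6)) for _ in range(40)]
        pwm = build_pwm(kmers, 6, 0.5)
        assert np.allclose(pwm.sum(axis=0), 1.0, atol=1e-9)

    def test_consensus_has_maximal_log_odds(self):
        rng = np.random.default_rng(1)
        freqs = np.full((4, 6), 0.05)
        for i, c in enumerate([3, 0, 3, 0, 0, 3]):
            freqs[c, i] = 0.85
        kmers = ["".join("ACGT"[rng.choice(4, p=freqs[:, i])] for i in range(6))
                 for _ in range(300)]
        pwm = build_pwm(kmers, 6, 0.5)
        consensus = "".join("ACGT"[i] for i in pwm.argmax(axis=0))

        def log_odds(kmer):
            return sum(math.log2(pwm["ACGT".index(b), i] / 0.25)
                       for i, b in enumerate(kmer))

        for _ in range(200):
            other = "".join("ACGT"[c] for c in rng.integers(0, 4, 6))
            assert log_odds(consensus) >= log_odds(other)

    def test_generating_frequencies_recovered(self):
        rng = np.random.default_rng(7)
        freqs = np.full((4, 6), 0.05)
        for i, c in enumerate([3, 0, 3, 0, 0, 3]):
            freqs[c, i] = 0.85
        kmers = ["".join("ACGT"[rng.choice(4, p=freqs[:, i])] for i in range(6))
                 for _ in range(500)]
        pwm = build_pwm(kmers, 6, 0.5)
        assert np.abs(pwm - freqs).max() <= 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="zero matched"):
            build_pwm([], 6)


class TestClustering:
    def test_two_disjoint_families_give_two_motifs(self):
        cfg = PromoterConfig()
        a, _ = simulate_upstream_windows(
            250, 50, 0.64, MotifSpec("d", "TTGACA", "TATAAT", -35, -12, 1.0), 0.7,
            seed=20)
        b, _ = simulate_upstream_windows(
            250, 50, 0.64, MotifSpec("n", "TGGCAC", "TTGCAT", -26, -14, 1.0), 0.7,
            seed=21)
        motifs = discover_motifs(a + b, cfg)
        assert len(motifs) == 2

    def test_one_family_with_mismatch_neighbours_gives_one_motif(self):
        cfg = PromoterConfig()
        seqs, _ = simulate_upstream_windows(
            400, 50, 0.64, MotifSpec("d", "TTGACA", "TATAAT", -35, -12, 1.0,
                                     mutation_rate=0.12), 0.6, seed=22)
        motifs = discover_motifs(seqs, cfg)
        assert len(motifs) == 1

    def test_single_pattern_becomes_its_own_motif(self):
        cfg = PromoterConfig()
        p = Pattern("TTGACA", "TATAAT", -35, -10, observed=30)
        motifs = cluster_motifs([p], cfg)
        assert len(motifs) == 1
        assert motifs[0].consensus_up == "TTGACA"
        assert motifs[0].consensus_down == "TATAAT"

    def test_motif_count_invariant_to_sequence_order(self):
        cfg = PromoterConfig()
        seqs, _ = simulate_upstream_windows(
            300, 50, 0.64, MotifSpec("d", "TTGACA", "TATAAT", -35, -12, 1.0), 0.6,
            seed=23)
        n1 = len(discover_motifs(seqs, cfg))
        n2 = len(discover_motifs(list(reversed(seqs)), cfg))
        assert n1 == n2 == 1


class TestMapping:
    def _planted_motif(self, seed=30):
        cfg = PromoterConfig()
        seqs, _ = simulate_upstream_windows(
            400, 50, 0.64, MotifSpec("d", "TTGACA", "TATAAT", -35, -12, 1.0), 0.5,
            seed=seed)
        return discover_motifs(seqs, cfg)[0], cfg

    def test_consensus_window_beats_any_single_base_variant(self):
        motif, cfg = self._planted_motif()
        rng = np.random.default_rng(0)
        base = list(simulate_upstream_windows(1, 50, 0.64, MotifSpec(
            "d", "TTGACA", "TATAAT", -35, -12, 1.0, mutation_rate=0.0), 1.0,
            seed=31)[0][0])
        best = score_window(motif, "".join(base), cfg)[0]
        for i in (15, 18, 40, 43):  # inside the planted boxes
            for b in "ACGT":
                if b == base[i]:
                    continue
                variant = base.copy()
                variant[i] = b
                assert score_window(motif, "".join(variant), cfg)[0] <= best

    def test_shuffle_null_hit_rate_at_default_threshold(self):
        motif, cfg = self._planted_motif()
        rng = np.random.default_rng(5)
        seqs, _ = simulate_upstream_windows(400, 50, 0.64, None, 0.0, seed=32)
        shuffled = [dinucleotide_shuffle(s, rng) for s in seqs]
        hits = sum(1 for s in shuffled
                   if (r := score_window(motif, s, cfg)) and r[0] >= cfg.map_threshold)
        assert hits / len(shuffled) <= 0.01

    def test_multiple_motifs_can_hit_one_tss(self):
        # a TSS whose upstream region carries both planted architectures
        cfg = PromoterConfig()
        rpod = MotifSpec("d", "TTGACA", "TATAAT", -49, -26, 1.0, mutation_rate=0.0)
        rpon = MotifSpec("n", "TGGCAC", "TTGCAT", -18, -8, 1.0, mutation_rate=0.0)
        sa, _ = simulate_upstream_windows(250, 50, 0.64, rpod, 0.6, seed=33)
        sb, _ = simulate_upstream_windows(250, 50, 0.64, rpon, 0.6, seed=34)
        motifs = discover_motifs(sa + sb, cfg)
        assert len(motifs) == 2
        both = simulate_upstream_windows(1, 50, 0.64, rpod, 1.0, seed=35,
                                         mutation_rate=0.0)[0][0]
        both = list(both)
        for consensus, off in (("TGGCAC", -18), ("TTGCAT", -8)):
            both[50 + off:50 + off + 6] = consensus
        upstream = "".join(both)
        rng = np.random.default_rng(36)
        genome = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        rep = Replicon("chr", genome[:100] + upstream + genome[100:])
        tss = _tss(151)
        hits = map_promoters(motifs, [tss], {"chr": rep}, cfg)
        assert {h.motif_id for h in hits} == {m.id for m in motifs}

    def test_rpon_motif_maps_gg_gc_boxes_at_expected_offsets(self):
        cfg = PromoterConfig()
        spec = MotifSpec("n", "TGGCAC", "TTGCAT", -26, -14, 1.0)
        seqs, _ = simulate_upstream_windows(400, 50, 0.64, spec, 0.5, seed=37)
        motif = discover_motifs(seqs, cfg)[0]
        assert motif.label == "RpoN-like"
        window = simulate_upstream_windows(1, 50, 0.64, spec, 1.0, seed=38,
                                           mutation_rate=0.0)[0][0]
        score, pos_up, pos_down = score_window(motif, window, cfg)
        # GG dinucleotide of the upstream box sits at -24, GC of the
        # downstream box at -12 (boxes start at -26 / -14)
        assert pos_up == -26 and pos_down == -14
        assert window[50 + pos_up + 1:50 + pos_up + 3] == "GG"
        assert window[50 + pos_down + 2:50 + pos_down + 4] == "GC"


class TestLabeling:
    def _motif(self, cu, cd, loc):
        m = Motif("m1", [], pwm_up=build_pwm([cu] * 10, 6, 0.01),
                  pwm_down=build_pwm([cd] * 10, 6, 0.01),
                  location_distribution={loc: 10},
                  spacer_distribution={loc[1] - loc[0] - 6: 10})
        return m

    def test_rpod_architecture(self):
        m = self._motif("TTGACA", "TATAAT", (-35, -12))
        assert label_motifs([m])[0].label == "RpoD-like"

    def test_rpon_architecture(self):
        m = self._motif("TGGCAC", "TTGCAT", (-26, -14))
        assert label_motifs([m])[0].label == "RpoN-like"

    def test_leaderless_extended_minus10(self):
        m = self._motif("CCGCAA", "TGGTAT", (-35, -12))
        assert label_motifs([m])[0].label == "leaderless-like"

    def test_random_consensus_is_other(self):
        m = self._motif("ACCGCA", "CCAGCG", (-35, -12))
        assert label_motifs([m])[0].label == "other"
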