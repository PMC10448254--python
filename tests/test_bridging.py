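import math
import random

import pytest

from helpers import brute_local_score, mutate, random_dna
from mitodbg.bridging import (align_local_affine, cc_bridging, evalue,
                              find_seeding_pairs, gap_distance, karlin_K,
                              karlin_lambda, relative_distance)
from mitodbg.config import Config
from mitodbg.formats import Genome
from mitodbg.graph import build_mdbg
from mitodbg.mapping import ConnectedComponent, MappingPair, build_subgraph


class TestGapDistance:
    def test_worked_example(self):
        a = ConnectedComponent([], 1, 10)
        b = ConnectedComponent([], 23, 40)
        assert gap_distance(a, b, 100) == 12

    def test_adjacent_blocks(self):
        assert gap_distance(ConnectedComponent([], 1, 10),
                            ConnectedComponent([], 12, 20), 100) == 1

    def test_wrap_distance_rotation_invariant(self):
        L = 100
        a = ConnectedComponent([], 90, 98)
        b = ConnectedComponent([], 5, 20)
        d = gap_distance(a, b, L)
        # oracle: rotate both intervals by 30 and recompute
        a2 = ConnectedComponent([], 90 + 30 - L, 98 + 30 - L)
        b2 = ConnectedComponent([], 35, 50)
        assert d == gap_distance(ConnectedComponent([], 20, 28), b2, L) == 6

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            gap_distance(ConnectedComponent([], 1, 30),
                         ConnectedComponent([], 20, 40), 100)


class TestRelativeDistance:
    @pytest.mark.parametrize("d_in,d_db,expected", [
        (20, 30, 0.5),   # rejected in the worked example
        (20, 20, 0.0),   # retained
        (20, 24, 0.2),   # boundary, retained (inclusive bound)
    ])
    def test_values(self, d_in, d_db, expected):
        assert relative_distance(d_in, d_db) == pytest.approx(expected)

    def test_zero_gap_rejected(self):
        with pytest.raises(ValueError):
            relative_distance(0, 5)


def _scenario(d_db: int, d_in: int = 20, delta: int = 12):
    """Two CCs of one database genome separated by d_in on the input and
    d_db on the database genome (the two Figure-4 style scenarios)."""
    L_in, L_db = 400, 400
    cc_i = ConnectedComponent([], 1, 100)
    cc_t = ConnectedComponent([], 100 + delta + 1, 300)
    n = 100                       # seed_I input end = CC end
    o = n + d_in                  # seed_T input start
    cc_i.pairs = [MappingPair(50, n, "r", "+", 50, 100)]
    cc_t.pairs = [MappingPair(o, o + 60, "r", "+", 100 + d_db,
                              100 + d_db + 60)]
    mdbg = build_mdbg([Genome("r", random_dna(random.Random(0), L_db))], 8)
    return cc_i, cc_t, delta, L_in, mdbg


class TestFindSeedingPairs:
    def test_close_pair_with_zero_relative_distance_retained(self):
        cc_i, cc_t, delta, L_in, mdbg = _scenario(d_db=20)
        pairs = find_seeding_pairs(cc_i, cc_t, g=2, delta=delta, L_in=L_in,
                                   mdbg=mdbg)
        assert len(pairs) == 1
        assert pairs[0].input_dist == 20 <= 2 * delta
        assert pairs[0].rel_dist == 0.0

    def test_half_relative_distance_rejected(self):
        cc_i, cc_t, delta, L_in, mdbg = _scenario(d_db=30)
        assert find_seeding_pairs(cc_i, cc_t, g=2, delta=delta, L_in=L_in,
                                  mdbg=mdbg) == []

    def test_distance_bound_excludes_far_seeds(self):
        cc_i, cc_t, delta, L_in, mdbg = _scenario(d_db=30, d_in=30)
        # 30 > g0*delta = 24
        assert find_seeding_pairs(cc_i, cc_t, g=2, delta=delta, L_in=L_in,
                                  mdbg=mdbg) == []
        assert len(find_seeding_pairs(cc_i, cc_t, g=4, delta=delta,
                                      L_in=L_in, mdbg=mdbg)) == 1

    def test_per_genome_only_closest_pair_kept(self):
        cc_i, cc_t, delta, L_in, mdbg = _scenario(d_db=20)
        # a second, farther seed pair of the same genome (d = 22)
        cc_i.pairs.append(MappingPair(40, 98, "r", "+", 40, 98))
        pairs = find_seeding_pairs(cc_i, cc_t, g=2, delta=delta, L_in=L_in,
                                   mdbg=mdbg)
        assert len(pairs) == 1 and pairs[0].input_dist == 20


class TestAlignment:
    def test_identical_sequences_full_score(self):
        res = align_local_affine("ACGTACGTAC", "ACGTACGTAC")
        assert res.score == 10

    def test_disjoint_alphabets_score_zero(self):
        assert align_local_affine("AAAA", "CCCC").score == 0

    def test_matches_exhaustive_enumeration_sample(self):
        rng = random.Random(42)
        for _ in range(30):
            a = random_dna(rng, rng.randint(1, 8))
            b = random_dna(rng, rng.randint(1, 8))
            assert align_local_affine(a, b).score == \
                brute_local_score(a, b), (a, b)

    def test_spans_reported(self):
        res = align_local_affine("TTTACGTACG", "ACGTACG", with_spans=True)
        assert res.query_span == (4, 10)
        assert res.subject_span == (1, 7)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_local_affine("", "ACGT")


class TestEvalue:
    def test_lambda_solves_defining_equation(self):
        lam = karlin_lambda()
        # independent bisection on sum p_i p_j exp(lambda s_ij) = 1
        f = lambda x: 0.25 * math.exp(x) + 0.75 * math.exp(-2 * x) - 1
        lo, hi = 1e-9, 10.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        assert lam == pytest.approx((lo + hi) / 2, abs=1e-6)

    def test_K_in_plausible_range(self):
        assert 0.0 < karlin_K() < 1.0

    def test_monotone_decreasing_in_score(self):
        assert evalue(30, 100, 100) < evalue(20, 100, 100)

    def test_linear_in_lengths(self):
        assert evalue(20, 200, 100) == pytest.approx(
            2 * evalue(20, 100, 100))
        assert evalue(1000, 100, 100) == pytest.approx(0.0, abs=1e-300)

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValueError):
            evalue(10, 0, 5)


def _two_gap_input(seq, rng, diverged=None, insertion=None):
    """An input copy of ``seq`` with a cluster of substitutions around
    position 150 (a bridgeable gap; a single-nucleotide gap is too short to
    reach the E-value threshold) plus either a diverged segment or a novel
    insertion around position 1000, so the circle decomposes into two CCs."""
    out = mutate(seq, [150, 160, 170, 180], rng)
    if diverged:
        start, n_subs = diverged
        # evenly spaced so no clean (k+1)-window survives inside the segment
        positions = [start + 10 * i for i in range(n_subs)]
        out = mutate(out, positions, rng)
    if insertion:
        out = out[:1000] + random_dna(rng, insertion) + out[1000:]
    return out


class TestCCBridging:
    k = 12

    def _run(self, r_in_seq, db_seq):
        db = Genome("g1", db_seq)
        mdbg = build_mdbg([db], self.k)
        match, ccs = build_subgraph(mdbg, Genome("in", r_in_seq))
        bridges, groups, log = cc_bridging(match, ccs, mdbg)
        return ccs, bridges, groups, log

    def test_diverged_segment_bridged_by_original_trail(self):
        rng = random.Random(10)
        seq = random_dna(rng, 2000)
        r_in = _two_gap_input(seq, rng, diverged=(1000, 10))
        ccs, bridges, groups, log = self._run(r_in, seq)
        assert len(ccs) == 2
        assert len(groups) == 1            # merged CC count = 1
        assert any(b.input_i <= 1005 <= b.input_j for b in bridges)
        assert all(e.genome_id == "g1" for e in log)

    def test_novel_insertion_rejected_by_relative_distance(self):
        rng = random.Random(11)
        seq = random_dna(rng, 2000)
        r_in = _two_gap_input(seq, rng, insertion=120)
        ccs, bridges, groups, log = self._run(r_in, seq)
        assert len(ccs) == 2
        # the substitution gap is bridged, the insertion gap is not
        assert all(not (b.input_i <= 1060 <= b.input_j) for b in bridges)
        assert any(b.input_i <= 165 <= b.input_j for b in bridges)
        assert len(groups) == 1  # merged through the substitution gap

    def test_single_component_is_noop(self):
        rng = random.Random(12)
        seq = random_dna(rng, 800)
        ccs, bridges, groups, log = self._run(seq, seq)
        assert len(ccs) == 1 and bridges == [] and len(groups) == 1

    def test_point_mutated_copy_fully_recovered(self):
        rng = random.Random(13)
        seq = random_dna(rng, 3000)
        positions = sorted(rng.sample(range(100, 2900), 6))
        # keep mutations well separated so each creates its own gap
        positions = [p for i, p in enumerate(positions)
                     if i == 0 or p - positions[i - 1] > 100]
        r_in = mutate(seq, positions, rng)
        ccs, bridges, groups, log = self._run(r_in, seq)
        assert len(ccs) == len(positions)
        assert len(groups) == 1            # every gap bridged
        assert {e.genome_id for e in log} == {"g1"}

    def test_accepted_bridges_respect_thresholds(self, loo_case, loo_mdbg):
        cfg = Config()
        match, ccs = build_subgraph(loo_mdbg, loo_case.input_genome, ())
        bridges, groups, log = cc_bridging(match, ccs, loo_mdbg, cfg)
        assert log  # bridging fires under the study conditions
        for e in log:
            assert e.evalue <= cfg.evalue_max
        for b in bridges:
            d_in = b.input_j - b.input_i + 1
            d_db = b.db_j - b.db_i + 1
            assert abs(d_in - d_db) / (d_in + 1) <= cfg.rel_dist_max + 1e-9
            assert b.source == "bridge"

    def test_bridging_never_alters_subgraph_pairs(self, loo_case, loo_mdbg):
        match, ccs = build_subgraph(loo_mdbg, loo_case.input_genome, ())
        before = [(p.input_i, p.input_j, p.genome_id, p.strand, p.db_i,
                   p.db_j) for cc in ccs for p in cc.pairs]
        cc_bridging(match, ccs, loo_mdbg)
        after = [(p.input_i, p.input_j, p.genome_id, p.strand, p.db_i,
                  p.db_j) for cc in ccs for p in cc.pairs]
        assert before == after

    def test_stricter_evalue_never_adds_bridges(self):
        rng = random.Random(14)
        seq = random_dna(rng, 3000)
        positions = [200, 700, 1300, 1900, 2500]
        r_in = mutate(seq, positions, rng)
        db = Genome("g1", seq)
        mdbg = build_mdbg([db], self.k)
        sets = {}
        for emax in (1e-3, 1e-9):
            match, ccs = build_subgraph(mdbg, Genome("in", r_in))
            _, _, log = cc_bridging(match, ccs, mdbg,
                                    Config(evalue_max=emax))
            sets[emax] = {(e.genome_id, e.gap_start, e.gap_end) for e in log}
        assert sets[1e-9] <= sets[1e-3]
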