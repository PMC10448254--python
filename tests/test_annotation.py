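import itertools
import random

import numpy as np
import pytest

from mitodbg.annotation import (Cluster, DendrogramFamily,
                                TransferredFragment, annotate, clusterG,
                                derive_g0_annotations, init_clusters,
                                joined_rfd, mask_noncoding, merge_fragments,
                                merge_quality_t, retrieve_predictions,
                                transfer)
from mitodbg.config import Config
from mitodbg.evaluation import correspond
from mitodbg.formats import AnnotationRecord, Genome
from mitodbg.mapping import MappingPair


def frag(a, b, strand="+", gene="x", donor="g1", key=None, is_g0=False):
    return TransferredFragment(a, b, strand, gene, donor,
                               key or (donor, gene, a, b, strand), is_g0)


class TestDeriveG0:
    def test_fully_covered_genome_yields_nothing(self):
        recs = [AnnotationRecord(1, 30, "x", "+", "a")]
        assert derive_g0_annotations(recs, {"x": (30, True)}) == []

    def test_single_gene_on_circle_gives_wrapped_complement(self):
        recs = [AnnotationRecord(10, 20, "x", "+", "a")]
        g0 = derive_g0_annotations(recs, {"x": (30, True)})
        assert {(r.n, r.m, r.strand) for r in g0} == {(21, 9, "+"), (21, 9, "-")}
        assert all(r.is_g0 for r in g0)

    def test_unannotated_genome_spanning_record(self):
        g0 = derive_g0_annotations([], {"x": (30, True)})
        assert {(r.n, r.m) for r in g0} == {(1, 30)}
        assert len(g0) == 2  # both strands


class TestTransfer:
    def test_strand_flip_worked_example(self):
        pair = MappingPair(5, 11, "r", "-", 20, 26)
        ann = AnnotationRecord(1, 25, "r", "+", "g")
        (f,) = transfer(pair, [ann], L_db=40, db_circular=True, L_in=40)
        assert (f.a, f.b, f.strand, f.gene) == (5, 10, "-", "g")

    def test_containing_annotation_spans_whole_trail(self):
        pair = MappingPair(5, 11, "r", "+", 20, 26)
        ann = AnnotationRecord(1, 40, "r", "+", "g")
        (f,) = transfer(pair, [ann], L_db=40, db_circular=True, L_in=40)
        assert (f.a, f.b, f.strand) == (5, 11, "+")

    def test_disjoint_annotation_no_fragment(self):
        pair = MappingPair(5, 11, "r", "+", 20, 26)
        ann = AnnotationRecord(30, 38, "r", "+", "g")
        assert transfer(pair, [ann], 40, True, 40) == []

    def test_wrapping_annotation_on_circular_donor(self):
        pair = MappingPair(1, 10, "r", "+", 1, 10)
        ann = AnnotationRecord(38, 4, "r", "+", "g")  # wraps 38..40,1..4
        (f,) = transfer(pair, [ann], L_db=40, db_circular=True, L_in=40)
        assert (f.a, f.b) == (1, 4)


class TestMergeFragments:
    def test_same_donor_close_fragments_merge_to_hull(self):
        key = ("g1", "x", 1, 300, "+")
        fs = [frag(10, 50, key=key), frag(81, 120, key=key)]  # 30 nt apart
        (m,) = merge_fragments(fs, 70, 1000)
        assert (m.a, m.b) == (10, 120)

    def test_different_donor_annotations_unchanged(self):
        fs = [frag(10, 50, key=("g1", "x", 1, 300, "+")),
              frag(81, 120, key=("g2", "x", 1, 300, "+"))]
        assert len(merge_fragments(fs, 70, 1000)) == 2

    def test_chain_merges_transitively(self):
        key = ("g1", "x", 1, 500, "+")
        fs = [frag(1, 50, key=key), frag(101, 150, key=key),
              frag(201, 260, key=key)]  # 50 nt gaps
        (m,) = merge_fragments(fs, 70, 1000)
        assert (m.a, m.b) == (1, 260)

    def test_wraparound_merge_on_circle(self):
        key = ("g1", "x", 1, 100, "+")
        fs = [frag(5, 40, key=key), frag(960, 995, key=key)]  # 9 nt circular gap
        (m,) = merge_fragments(fs, 70, 1000)
        assert (m.a, m.b % 1000) == (960, 40)


class TestMaskNoncoding:
    omega = {"x": 0.01, "y": 0.01}

    def test_position_with_only_g0_masked(self):
        fs = [frag(1, 10, is_g0=True, gene="g0")]
        masked = mask_noncoding(fs, 20, self.omega)
        assert masked[:10].all() and not masked[10:].any()

    def test_majority_gene_unmasked(self):
        fs = [frag(1, 10, donor=f"g{i}", key=("k", i)) for i in range(5)]
        fs.append(frag(1, 10, is_g0=True, gene="g0"))
        masked = mask_noncoding(fs, 20, self.omega)
        assert not masked[:10].any()  # 5 > 1 and cumulative freq 1.0 >= 0.8

    def test_g0_outnumbering_best_two_masked(self):
        fs = [frag(1, 10, is_g0=True, gene="g0", key=("k", i))
              for i in range(3)]
        fs += [frag(1, 10, gene="x", key=("x", 0)),
               frag(1, 10, gene="y", key=("y", 0))]
        masked = mask_noncoding(fs, 20, self.omega)
        assert masked[:10].all()  # 3 > 1 + 1


class TestInitClusters:
    def test_single_gene_two_donors_probability_one(self):
        fs = [frag(1, 100, donor="g1"), frag(1, 100, donor="g2")]
        leaves = init_clusters(fs, 120, {"x": 0.01}, "+")
        assert len(leaves) == 100
        assert all(leaf.p == {"x": 1.0} for leaf in leaves)

    def test_single_donor_gene_excluded(self):
        fs = [frag(1, 100, donor="g1")]
        assert init_clusters(fs, 120, {"x": 0.01}, "+") == []

    def test_weighted_normalization(self):
        # gene a: two donors, fragments of length 2 -> S = 4
        # gene b: two donors, fragments of length 6 -> S = 12; equal omega
        fs = [frag(1, 2, gene="a", donor="g1"), frag(1, 2, gene="a", donor="g2"),
              frag(1, 6, gene="b", donor="g1"), frag(1, 6, gene="b", donor="g2")]
        leaves = init_clusters(fs, 10, {"a": 1.0, "b": 1.0}, "+")
        assert leaves[0].p == pytest.approx({"a": 0.25, "b": 0.75})


class TestJoinedRfd:
    def c(self, i, j, s_hat):
        return Cluster(i, j, "+", dict(s_hat), dict(s_hat), frozenset())

    def test_only_shared_support_survives(self):
        p, s = joined_rfd(self.c(1, 1, {"a": 1, "b": 1}),
                          self.c(2, 2, {"b": 2, "c": 5}))
        assert p == {"b": 1.0} and s == {"b": 3}

    def test_identical_distributions_unchanged(self):
        p, _ = joined_rfd(self.c(1, 1, {"a": 1, "b": 3}),
                          self.c(2, 2, {"a": 1, "b": 3}))
        assert p == pytest.approx({"a": 0.25, "b": 0.75})

    def test_hand_evaluated_mixture(self):
        p, _ = joined_rfd(self.c(1, 1, {"a": 1, "b": 1}),
                          self.c(2, 2, {"a": 3, "b": 1}))
        assert p == pytest.approx({"a": 2 / 3, "b": 1 / 3})

    def test_nonadjacent_or_disjoint_rejected(self):
        with pytest.raises(ValueError):
            joined_rfd(self.c(1, 1, {"a": 1}), self.c(3, 3, {"a": 1}))
        with pytest.raises(ValueError):
            joined_rfd(self.c(1, 1, {"a": 1}), self.c(2, 2, {"b": 1}))


class TestMergeQualityT:
    @pytest.mark.parametrize("probs,expected", [
        ({"a": 0.96, "b": 0.04}, 1),
        ({"a": 0.5, "b": 0.45, "c": 0.05}, 2),
        ({f"g{i}": 0.05 for i in range(20)}, 19),
    ])
    def test_prefix_sums(self, probs, expected):
        assert merge_quality_t(probs) == expected

    def test_matches_exhaustive_subset_search(self):
        rng = random.Random(5)
        for _ in range(20):
            n = rng.randint(1, 10)
            raw = [rng.random() for _ in range(n)]
            total = sum(raw)
            p = {f"g{i}": v / total for i, v in enumerate(raw)}
            # oracle: smallest subset (not prefix) reaching 0.95
            best = min(len(sub) for r in range(1, n + 1)
                       for sub in itertools.combinations(p.values(), r)
                       if sum(sub) >= 0.95 - 1e-12)
            assert merge_quality_t(p) == best

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            merge_quality_t({})


def leaf(i, s_hat, strand="+", frag_ids=()):
    return Cluster(i, i, strand, dict(s_hat), dict(s_hat),
                   frozenset(frag_ids))


class TestClusterG:
    def test_two_adjacent_same_gene_one_merge(self):
        fam = clusterG([leaf(1, {"g": 1.0}), leaf(2, {"g": 1.0})], seed=0)
        assert len(fam.roots) == 1
        root = fam.roots[0]
        assert root.interval == (1, 2) and root.p == {"g": 1.0}
        assert len(fam.clusters) == 3

    def test_disjoint_support_never_merged(self):
        leaves = [leaf(1, {"a": 1.0}), leaf(2, {"a": 0.5, "b": 0.5}),
                  leaf(3, {"b": 1.0})]
        fam = clusterG(leaves, seed=0)
        assert len(fam.roots) == 2
        # only sharing-adjacent merges occurred
        for c in fam.clusters:
            if c.children:
                assert set(c.children[0].S_hat) & set(c.children[1].S_hat)

    def test_fixed_seed_reproducible(self):
        rng = random.Random(3)
        leaves = [leaf(i, {rng.choice("ab"): 1.0, "c": rng.random()})
                  for i in range(1, 40)]
        import copy
        fam1 = clusterG(copy.deepcopy(leaves), seed=7)
        fam2 = clusterG(copy.deepcopy(leaves), seed=7)
        assert [(c.i, c.j) for c in fam1.clusters] == \
            [(c.i, c.j) for c in fam2.clusters]

    def test_merge_count_bounded_and_intervals_contiguous(self):
        rng = random.Random(4)
        leaves = [leaf(i, {rng.choice("abc"): 1.0}) for i in range(1, 60)]
        fam = clusterG(leaves, seed=0)
        merges = sum(1 for c in fam.clusters if c.children)
        assert merges <= len(leaves) - 1
        for c in fam.clusters:
            assert c.i <= c.j


class TestRetrieval:
    def test_containment_discards_nested_same_gene_clusters(self):
        # dendrogram family in the retrieval worked example: nested clusters
        # of gene g at [1,2] < [1,3] < [1,5], plus a different gene at [4,5]
        mk = lambda i, j, s: Cluster(i, j, "+", dict(s), dict(s), frozenset())
        clusters = [
            mk(1, 2, {"g": 9, "h": 1}),     # * but nested
            mk(1, 3, {"g": 9, "h": 1}),     # * but nested
            mk(1, 5, {"g": 9, "h": 1}),     # * kept
            mk(4, 5, {"o": 8, "g": 2}),     # * kept (different gene)
            mk(4, 4, {"o": 1, "g": 1}),     # max RFD 0.5 < 0.7, never selected
        ]
        fam = DendrogramFamily("+", clusters, clusters[-3:])
        preds = retrieve_predictions(fam)
        assert {(p.gene, p.start, p.end) for p in preds} == \
            {("g", 1, 5), ("o", 4, 5)}

    def test_single_leaf_prediction(self):
        fam = DendrogramFamily("+", [leaf(3, {"g": 2.0})], [])
        (p,) = retrieve_predictions(fam)
        assert (p.gene, p.start, p.end, p.max_rfd) == ("g", 3, 3, 1.0)

    def test_never_emits_below_retrieval_threshold(self):
        fam = DendrogramFamily("+", [leaf(1, {"a": 0.6, "b": 0.4})], [])
        assert retrieve_predictions(fam) == []

    def test_equal_intervals_same_gene_deduplicated(self):
        c1 = leaf(1, {"g": 1.0})
        c2 = leaf(1, {"g": 2.0})
        fam = DendrogramFamily("+", [c1, c2], [])
        assert len(retrieve_predictions(fam)) == 1


class TestAnnotatePipeline:
    def test_self_annotation_recovers_own_genes(self, loo_case, loo_mdbg):
        # input genome g1 is itself in the database (no exclusion)
        g1 = loo_case.db_genomes[0]
        run = annotate(g1, loo_mdbg, loo_case.db_annotations)
        truth = [a for a in loo_case.db_annotations if a.genome_id == g1.id]
        results, fns = correspond(run.predictions, truth, len(g1))
        assert fns == []
        assert all(r.klass == "equal" for r in results)
        assert all(r.frac_prediction >= 0.75 for r in results)

    def test_no_matches_gives_empty_predictions_with_diagnostic(self):
        from mitodbg.graph import build_mdbg
        rng = random.Random(0)
        db = Genome("x", "".join(rng.choice("ACGT") for _ in range(500)))
        mdbg = build_mdbg([db], 16)
        other = Genome("in", "".join(
            random.Random(1).choice("ACGT") for _ in range(500)))
        run = annotate(other, mdbg, [AnnotationRecord(1, 100, "x", "+", "a")])
        assert run.predictions == [] and run.diagnostics

    def test_rfd_sums_to_one_at_every_node(self, loo_case, loo_mdbg):
        run = annotate(loo_case.input_genome, loo_mdbg,
                       loo_case.db_annotations, exclude={})
        for fam in run.families.values():
            for c in fam.clusters:
                assert sum(c.p.values()) == pytest.approx(1.0, abs=1e-9)
                if c.children:
                    support = set(c.p)
                    assert support <= (set(c.children[0].p)
                                       & set(c.children[1].p))

    def test_deterministic_bed_output(self, loo_case, loo_mdbg, tmp_path):
        from mitodbg.formats import write_predictions_bed
        outs = []
        for name in ("a.bed", "b.bed"):
            run = annotate(loo_case.input_genome, loo_mdbg,
                           loo_case.db_annotations,
                           Config(rng_seed=5), exclude={})
            write_predictions_bed(run.predictions, tmp_path / name,
                                  loo_case.input_genome)
            outs.append((tmp_path / name).read_bytes())
        assert outs[0] == outs[1]
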