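"""Annotation transfer and cluster-based aggregation of gene predictions.

Every mapping pair lifts the overlapping database annotations onto the input
genome as transferred fragments; fragments of one donor annotation separated
by less than the shortest expected gene are merged; positions that look
non-coding (dominated by the no-gene sentinel) are masked; and the remaining
per-position gene evidence is aggregated bottom-up by greedily merging
adjacent position clusters, preferring merges whose joined, length-weighted
relative frequency distribution (RFD) concentrates its mass on few genes.
Final predictions are read off the resulting family of dendrograms.
"""

from __future__ import annotations

import heapq
import logging
import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .config import Config
from .formats import AnnotationRecord, Genome, Prediction
from .graph import MDBG
from .mapping import MappingPair, pos_mod, build_subgraph
from . import bridging as _bridging

logger = logging.getLogger(__name__)

G0_LABEL = "g0"


# --------------------------------------------------------------------------
# Sentinel annotations for unannotated database regions.

def derive_g0_annotations(annotations: Iterable[AnnotationRecord],
                          genomes: Mapping[str, tuple[int, bool]],
                          ) -> list[AnnotationRecord]:
    """Complement intervals of each genome's gene annotations, labeled with
    the no-gene sentinel on both strands (absence of annotation is
    strand-unspecified)."""
    by_genome: dict[str, list[AnnotationRecord]] = {}
    for rec in annotations:
        if not rec.is_g0:
            by_genome.setdefault(rec.genome_id, []).append(rec)
    out: list[AnnotationRecord] = []
    for gid, (L, circular) in genomes.items():
        covered = np.zeros(L, dtype=bool)
        for rec in by_genome.get(gid, []):
            if rec.n <= rec.m:
                covered[rec.n - 1:rec.m] = True
            else:
                covered[rec.n - 1:] = True
                covered[:rec.m] = True
        if covered.all():
            continue
        if not covered.any():
            out.extend(AnnotationRecord(1, L, gid, s, G0_LABEL, is_g0=True)
                       for s in "+-")
            continue
        # maximal uncovered runs on the circle
        free = ~covered
        idx = np.flatnonzero(free)
        runs: list[tuple[int, int]] = []
        start = prev = idx[0]
        for x in idx[1:]:
            if x == prev + 1:
                prev = x
            else:
                runs.append((start, prev))
                start = prev = x
        runs.append((start, prev))
        if circular and len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == L - 1:
            first, last = runs[0], runs.pop()
            runs[0] = (last[0], first[1])  # wrap run, start > end
        for s0, e0 in runs:
            for s in "+-":
                out.append(AnnotationRecord(s0 + 1, e0 + 1, gid, s,
                                            G0_LABEL, is_g0=True))
    return out


# --------------------------------------------------------------------------
# Annotation transfer through mapping pairs.

@dataclass(frozen=True)
class TransferredFragment:
    """A database annotation lifted onto the input genome.

    ``a``..``b`` is 1-based with a in 1..L; b is unrolled (b >= L+1 means the
    fragment wraps). ``donor_key`` identifies the originating database
    annotation so fragments of one origin can be re-joined."""

    a: int
    b: int
    strand: str
    gene: str
    donor_genome: str
    donor_key: tuple
    is_g0: bool = False

    @property
    def length(self) -> int:
        return self.b - self.a + 1


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def transfer(pair: MappingPair,
             annotations: Sequence[AnnotationRecord],
             L_db: int, db_circular: bool, L_in: int,
             in_circular: bool = True) -> list[TransferredFragment]:
    """Lift every database annotation overlapping the pair's database
    interval onto the input: the overlap [n', m'] = [i', j'] ∩ [n, m]
    yields an input fragment from i + (n' - i') to j - (j' - m'), on the
    annotation's strand when database and input trails share strandedness
    and on the opposing strand otherwise."""
    i, j = pair.input_i, pair.input_j
    ip, jp = pair.db_i, pair.db_j
    frags: list[TransferredFragment] = []
    for rec in annotations:
        n, m_u = rec.n, (rec.m if rec.m >= rec.n else rec.m + L_db)
        if db_circular:
            t_lo = (ip - m_u) // L_db
            t_hi = (jp - n) // L_db
            shifts = [t * L_db for t in range(t_lo, t_hi + 1)]
        else:
            shifts = [0]
        for sh in shifts:
            np_, mp = max(ip, n + sh), min(jp, m_u + sh)
            if np_ > mp:
                continue
            a = i + (np_ - ip)
            b = j - (jp - mp)
            if b < a:
                continue  # can happen for bridge pairs of unequal lengths
            a_n = pos_mod(a, L_in)
            b_u = a_n + (b - a)
            if not in_circular and b_u > L_in:
                b_u = L_in
            strand = rec.strand if pair.strand == "+" else _flip(rec.strand)
            frags.append(TransferredFragment(
                a_n, b_u, strand, rec.gene, rec.genome_id,
                donor_key=(rec.genome_id, rec.gene, rec.n, rec.m, rec.strand),
                is_g0=rec.is_g0))
    return frags


def merge_fragments(fragments: Sequence[TransferredFragment],
                    min_gene_length: int, L_in: int,
                    circular: bool = True) -> list[TransferredFragment]:
    """Fixed point of joining fragments of the same donor annotation and
    input strand separated by less than the shortest expected gene; joined
    fragments are replaced by their interval hull."""
    groups: dict[tuple, list[TransferredFragment]] = {}
    for f in fragments:
        groups.setdefault((f.donor_key, f.strand), []).append(f)
    out: list[TransferredFragment] = []
    for (_, strand), fs in groups.items():
        proto = fs[0]
        ivs = sorted((f.a, f.b) for f in fs)
        merged: list[list[int]] = []
        for a, b in ivs:
            if merged and a <= merged[-1][1] + min_gene_length:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        if circular and len(merged) > 1:
            first, last = merged[0], merged[-1]
            if first[0] + L_in <= last[1] + min_gene_length:
                last[1] = max(last[1], first[1] + L_in)
                merged = merged[1:]
        for a, b in merged:
            b = min(b, a + L_in - 1)  # hull never exceeds the full circle
            out.append(TransferredFragment(pos_mod(a, L_in),
                                           pos_mod(a, L_in) + (b - a),
                                           strand, proto.gene,
                                           proto.donor_genome,
                                           proto.donor_key, proto.is_g0))
    out.sort(key=lambda f: (f.a, f.b, f.gene, f.donor_genome))
    return out


# --------------------------------------------------------------------------
# Per-position evidence, masking, and cluster initialization.

def _cover_slices(a: int, b: int, L: int) -> list[slice]:
    """0-based slices covering the (possibly wrapping) interval [a, b]."""
    if b <= L:
        return [slice(a - 1, b)]
    return [slice(a - 1, L), slice(0, b - L)]


def gene_weights(annotations: Iterable[AnnotationRecord],
                 genomes: Mapping[str, tuple[int, bool]]) -> dict[str, float]:
    """omega_g: reciprocal of gene g's mean annotated length over the
    database (the no-gene sentinel carries no weight)."""
    lengths: dict[str, list[int]] = {}
    for rec in annotations:
        if rec.is_g0:
            continue
        L = genomes[rec.genome_id][0]
        lengths.setdefault(rec.gene, []).append(rec.length(L))
    return {g: 1.0 / (sum(v) / len(v)) for g, v in lengths.items()}


@dataclass
class _StrandEvidence:
    """Per-position accumulators for one input strand."""

    L: int
    score: dict[str, np.ndarray]       # gene -> summed fragment lengths
    count: dict[str, np.ndarray]       # gene -> fragment counts
    donors: dict[str, np.ndarray]      # gene -> distinct donor genomes
    g0_count: np.ndarray
    frag_ids: list[list[int]]          # per position, covering fragment ids


def _accumulate(fragments: Sequence[TransferredFragment],
                L: int) -> _StrandEvidence:
    score: dict[str, np.ndarray] = {}
    count: dict[str, np.ndarray] = {}
    donor_sets: dict[str, dict[str, np.ndarray]] = {}
    g0_count = np.zeros(L)
    frag_ids: list[list[int]] = [[] for _ in range(L)]
    for fid, f in enumerate(fragments):
        slices = _cover_slices(f.a, f.b, L)
        if f.is_g0:
            for sl in slices:
                g0_count[sl] += 1
            continue
        if f.gene not in score:
            score[f.gene] = np.zeros(L)
            count[f.gene] = np.zeros(L)
            donor_sets[f.gene] = {}
        dmap = donor_sets[f.gene]
        if f.donor_genome not in dmap:
            dmap[f.donor_genome] = np.zeros(L, dtype=bool)
        for sl in slices:
            score[f.gene][sl] += f.length
            count[f.gene][sl] += 1
            dmap[f.donor_genome][sl] = True
            for pos in range(sl.start, sl.stop):
                frag_ids[pos].append(fid)
    donors = {g: sum(arr.astype(np.int32) for arr in dmap.values())
              for g, dmap in donor_sets.items()}
    return _StrandEvidence(L, score, count, donors, g0_count, frag_ids)


def mask_noncoding(fragments: Sequence[TransferredFragment], L: int,
                   omega: Mapping[str, float],
                   config: Config | None = None,
                   evidence: _StrandEvidence | None = None) -> np.ndarray:
    """Boolean mask of positions presumed non-coding: the no-gene sentinel
    outnumbers the two best-scoring genes, or those genes' cumulative
    relative frequency falls below the threshold."""
    config = config or Config()
    ev = evidence if evidence is not None else _accumulate(fragments, L)
    genes = sorted(ev.score)
    masked = np.zeros(L, dtype=bool)
    if not genes:
        masked[:] = ev.g0_count > 0
        return masked
    shat = np.stack([ev.score[g] * omega.get(g, 0.0) for g in genes])
    cnt = np.stack([ev.count[g] for g in genes])
    order = np.argsort(-shat, axis=0, kind="stable")
    top2 = order[:2] if len(genes) > 1 else order[:1]
    cols = np.arange(L)
    best_cnt = sum(np.where(shat[t, cols] > 0, cnt[t, cols], 0.0) for t in top2)
    best_shat = sum(shat[t, cols] for t in top2)
    total_shat = shat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cum = np.where(total_shat > 0, best_shat / total_shat, 0.0)
    masked = (ev.g0_count > best_cnt) | ((total_shat > 0)
                                         & (cum < config.noncoding_cum_min))
    masked |= (total_shat == 0) & (ev.g0_count > 0)
    return masked


# --------------------------------------------------------------------------
# Clusters and the greedy merging.

@dataclass
class Cluster:
    """A position interval with its gene evidence: raw summed lengths S,
    weighted scores S_hat, and the RFD p = normalized S_hat."""

    i: int
    j: int
    strand: str
    S: dict[str, float]
    S_hat: dict[str, float]
    frag_ids: frozenset[int]
    children: tuple["Cluster", "Cluster"] | None = None
    uid: int = -1
    _p: dict[str, float] | None = field(default=None, repr=False)

    @property
    def p(self) -> dict[str, float]:
        if self._p is None:
            total = sum(self.S_hat.values())
            self._p = {g: v / total for g, v in self.S_hat.items()}
        return self._p

    @property
    def interval(self) -> tuple[int, int]:
        return (self.i, self.j)

    def top_gene(self) -> tuple[str, float]:
        """argmax of the RFD (ties toward the lexicographically smallest
        gene, for determinism)."""
        best = max(self.p.items(), key=lambda kv: (kv[1], kv[0]))
        gene = min((g for g, v in self.p.items() if v == best[1]))
        return gene, best[1]


@dataclass
class DendrogramFamily:
    """All clusters ever created on one strand; roots are the survivors."""

    strand: str
    clusters: list[Cluster]
    roots: list[Cluster]


def init_clusters(fragments: Sequence[TransferredFragment], L: int,
                  omega: Mapping[str, float], strand: str,
                  config: Config | None = None,
                  masked: np.ndarray | None = None) -> list[Cluster]:
    """One leaf cluster per unmasked position with admissible evidence.

    A gene enters a position's distribution only when fragments of at least
    two distinct database genomes cover the position; positions left without
    any gene are dropped."""
    config = config or Config()
    ev = _accumulate(fragments, L)
    if masked is None:
        masked = mask_noncoding(fragments, L, omega, config, evidence=ev)
    leaves: list[Cluster] = []
    genes = sorted(ev.score)
    for pos in range(1, L + 1):
        if masked[pos - 1]:
            continue
        S: dict[str, float] = {}
        for g in genes:
            if ev.donors[g][pos - 1] >= 2 and ev.score[g][pos - 1] > 0:
                S[g] = float(ev.score[g][pos - 1])
        if not S:
            continue
        S_hat = {g: omega[g] * v for g, v in S.items()}
        leaves.append(Cluster(pos, pos, strand, S, S_hat,
                              frozenset(ev.frag_ids[pos - 1])))
    return leaves


def joined_rfd(c1: Cluster, c2: Cluster) -> tuple[dict[str, float],
                                                  dict[str, float]]:
    """Joined RFD and weighted scores of two adjacent clusters: genes absent
    from either side are zeroed, shared genes' scores summed and
    renormalized."""
    if c2.i - c1.j != 1:
        raise ValueError(f"clusters not adjacent: {c1.interval} / {c2.interval}")
    shared = [g for g in c1.S_hat if g in c2.S_hat]
    if not shared:
        raise ValueError("clusters share no gene")
    S_hat = {g: c1.S_hat[g] + c2.S_hat[g] for g in shared}
    total = sum(S_hat.values())
    p = {g: v / total for g, v in S_hat.items()}
    return p, S_hat


def merge_quality_t(p: Mapping[str, float] | Sequence[float],
                    threshold: float = 0.95) -> int:
    """Smallest number of genes whose cumulated relative frequency reaches
    the threshold."""
    probs = sorted(p.values() if isinstance(p, Mapping) else p, reverse=True)
    if not probs:
        raise ValueError("empty distribution")
    cum = 0.0
    for t, v in enumerate(probs, 1):
        cum += v
        if cum >= threshold - 1e-12:
            return t
    return len(probs)


def _merge_key(c1: Cluster, c2: Cluster,
               config: Config) -> tuple[int, float, int] | None:
    """(t, -max score, -prediction count) of the prospective merge, or None
    if the clusters are not mergeable."""
    if c2.i - c1.j != 1:
        return None
    shared = [g for g in c1.S_hat if g in c2.S_hat]
    if not shared:
        return None
    S_hat = {g: c1.S_hat[g] + c2.S_hat[g] for g in shared}
    total = sum(S_hat.values())
    t = merge_quality_t({g: v / total for g, v in S_hat.items()},
                        config.rfd_cum_t)
    if config.tiebreak_weighted_score:
        max_s = max(S_hat.values())
    else:
        max_s = max(c1.S[g] + c2.S[g] for g in shared)
    npred = len(c1.frag_ids | c2.frag_ids)
    return (t, -max_s, -npred)


def _merged_cluster(c1: Cluster, c2: Cluster, uid: int) -> Cluster:
    shared = [g for g in c1.S_hat if g in c2.S_hat]
    S_hat = {g: c1.S_hat[g] + c2.S_hat[g] for g in shared}
    S = {g: c1.S[g] + c2.S[g] for g in shared}
    return Cluster(c1.i, c2.j, c1.strand, S, S_hat,
                   c1.frag_ids | c2.frag_ids, children=(c1, c2), uid=uid)


def clusterG(leaves: Sequence[Cluster], seed: int = 0,
             config: Config | None = None,
             method: str = "heap") -> DendrogramFamily:
    """Greedy bottom-up merging of adjacent clusters.

    At each step the mergeable adjacent pair with minimal t is merged; ties
    prefer the larger maximum score, then the larger number of contributing
    predictions, then a seeded random choice. ``method="naive"`` re-scans
    all pairs each round (the reference semantics used as an oracle in
    tests); ``method="heap"`` is the equivalent lazy-deletion heap version.
    """
    config = config or Config()
    rng = random.Random(seed)
    leaves = sorted(leaves, key=lambda c: c.i)
    for n, leaf in enumerate(leaves):
        leaf.uid = n
    strand = leaves[0].strand if leaves else "+"
    all_clusters: list[Cluster] = list(leaves)
    alive: dict[int, Cluster] = {c.uid: c for c in leaves}
    right_of: dict[int, int] = {}
    left_of: dict[int, int] = {}
    ordered = sorted(alive.values(), key=lambda c: c.i)
    for a, b in zip(ordered, ordered[1:]):
        right_of[a.uid] = b.uid
        left_of[b.uid] = a.uid
    next_uid = len(leaves)

    def pick_among(ties: list[tuple[Cluster, Cluster]]
                   ) -> tuple[Cluster, Cluster]:
        ties = sorted(ties, key=lambda pair: pair[0].i)
        if len(ties) == 1:
            return ties[0]
        return ties[rng.randrange(len(ties))]

    def do_merge(c1: Cluster, c2: Cluster) -> Cluster:
        nonlocal next_uid
        merged = _merged_cluster(c1, c2, next_uid)
        next_uid += 1
        all_clusters.append(merged)
        del alive[c1.uid], alive[c2.uid]
        alive[merged.uid] = merged
        lu, ru = left_of.pop(c1.uid, None), right_of.pop(c2.uid, None)
        right_of.pop(c1.uid, None)
        left_of.pop(c2.uid, None)
        if lu is not None:
            right_of[lu] = merged.uid
            left_of[merged.uid] = lu
        if ru is not None:
            left_of[ru] = merged.uid
            right_of[merged.uid] = ru
        return merged

    if method == "naive":
        while True:
            cands = []
            for c in alive.values():
                r = alive.get(right_of.get(c.uid, -1))
                if r is None:
                    continue
                key = _merge_key(c, r, config)
                if key is not None:
                    cands.append((key, c, r))
            if not cands:
                break
            best = min(k for k, _, _ in cands)
            do_merge(*pick_among([(c, r) for k, c, r in cands if k == best]))
    elif method == "heap":
        heap: list[tuple[tuple[int, float, int], int, int]] = []

        def push(c: Cluster) -> None:
            r = alive.get(right_of.get(c.uid, -1))
            if r is None:
                return
            key = _merge_key(c, r, config)
            if key is not None:
                heapq.heappush(heap, (key, c.uid, r.uid))

        for c in ordered:
            push(c)
        while heap:
            best_key = heap[0][0]
            ties: list[tuple[Cluster, Cluster]] = []
            entries: list[tuple[tuple[int, float, int], int, int]] = []
            while heap and heap[0][0] == best_key:
                key, lu, ru = heapq.heappop(heap)
                c = alive.get(lu)
                if c is None or right_of.get(lu) != ru or ru not in alive:
                    continue  # stale entry
                entries.append((key, lu, ru))
                ties.append((c, alive[ru]))
            if not ties:
                continue
            c1, c2 = pick_among(ties)
            for key, lu, ru in entries:
                if lu != c1.uid:
                    heapq.heappush(heap, (key, lu, ru))
            merged = do_merge(c1, c2)
            lu = left_of.get(merged.uid)
            if lu is not None:
                push(alive[lu])
            push(merged)
    else:
        raise ValueError(f"unknown method {method!r}")
    roots = sorted(alive.values(), key=lambda c: c.i)
    return DendrogramFamily(strand, all_clusters, roots)


def retrieve_predictions(family: DendrogramFamily,
                         config: Config | None = None) -> list[Prediction]:
    """Predictions from all levels of the dendrogram family: clusters whose
    maximal relative frequency reaches the retrieval threshold are selected,
    and a selected cluster is discarded when another selected cluster calls
    the same gene on a strictly larger interval (overlapping calls of
    different genes are kept)."""
    config = config or Config()
    selected = []
    for c in family.clusters:
        gene, top = c.top_gene()
        if top >= config.rfd_retrieval_min - 1e-12:
            selected.append((c, gene, top))
    kept = []
    for c, gene, top in selected:
        contained = any(
            g2 == gene and (c2.i <= c.i and c.j <= c2.j)
            and (c2.i, c2.j) != (c.i, c.j)
            for c2, g2, _ in selected if c2 is not c)
        if not contained:
            kept.append(Prediction(gene, c.i, c.j, family.strand, top))
    # identical (gene, interval, strand) calls collapse to one record
    dedup: dict[tuple, Prediction] = {}
    for p in sorted(kept, key=lambda p: (p.start, p.end, p.gene, -p.max_rfd)):
        dedup.setdefault((p.gene, p.start, p.end, p.strand), p)
    return list(dedup.values())


# --------------------------------------------------------------------------
# End-to-end pipeline.

@dataclass
class AnnotationRun:
    """Predictions plus per-stage diagnostics of one pipeline run."""

    predictions: list[Prediction]
    n_windows: int = 0
    n_matched: int = 0
    n_components: int = 0
    n_components_after_bridging: int = 0
    bridge_log: list = field(default_factory=list)
    fragments: dict[str, list[TransferredFragment]] = field(default_factory=dict)
    families: dict[str, DendrogramFamily] = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)


def _rotation_cut(leaves_by_strand: dict[str, list[Cluster]],
                  L: int) -> int | None:
    """A position with no leaf on either strand (0 offset = no rotation
    needed); None when every position carries a leaf."""
    occupied = np.zeros(L, dtype=bool)
    for leaves in leaves_by_strand.values():
        for c in leaves:
            occupied[c.i - 1] = True
    if occupied[0]:
        free = np.flatnonzero(~occupied)
        return int(free[0]) + 1 if free.size else None
    return 0


def annotate(r_in: Genome, mdbg: MDBG,
             annotations: Sequence[AnnotationRecord],
             config: Config | None = None,
             exclude: Iterable[str] = (),
             no_bridging: bool = False) -> AnnotationRun:
    """Full pipeline: match -> components -> bridging -> transfer -> merge
    -> mask -> cluster -> retrieve, run separately per input strand.

    Deterministic at a fixed ``config.rng_seed``.
    """
    config = config or Config()
    L = len(r_in)
    match, ccs = build_subgraph(mdbg, r_in, exclude)
    run = AnnotationRun(predictions=[], n_windows=match.n_windows,
                        n_matched=len(match.labels_by_window),
                        n_components=len(ccs))
    if not ccs:
        run.diagnostics.append("no input window matches the graph; "
                               "no mapping possible")
        run.n_components_after_bridging = 0
        return run
    pairs: list[MappingPair] = [p for cc in ccs for p in cc.pairs]
    if not no_bridging and len(ccs) > 1:
        bridges, groups, blog = _bridging.cc_bridging(match, ccs, mdbg, config)
        pairs += bridges
        run.bridge_log = blog
        run.n_components_after_bridging = len(groups)
    else:
        run.n_components_after_bridging = len(ccs)

    g0_records = derive_g0_annotations(annotations, mdbg.genomes)
    by_genome: dict[str, list[AnnotationRecord]] = {}
    for rec in list(annotations) + g0_records:
        by_genome.setdefault(rec.genome_id, []).append(rec)
    omega = gene_weights(annotations, mdbg.genomes)

    raw_frags: list[TransferredFragment] = []
    for pair in pairs:
        L_db, db_circ = mdbg.genomes[pair.genome_id]
        raw_frags += transfer(pair, by_genome.get(pair.genome_id, ()),
                              L_db, db_circ, L, r_in.circular)

    leaves_by_strand: dict[str, list[Cluster]] = {}
    for strand in "+-":
        frs = merge_fragments([f for f in raw_frags if f.strand == strand],
                              config.min_gene_length, L, r_in.circular)
        run.fragments[strand] = frs
        leaves_by_strand[strand] = init_clusters(frs, L, omega, strand, config)

    shift = _rotation_cut(leaves_by_strand, L) if r_in.circular else 0
    predictions: list[Prediction] = []
    for strand in "+-":
        leaves = leaves_by_strand[strand]
        if shift:
            leaves = [Cluster((c.i - shift - 1) % L + 1,
                              (c.j - shift - 1) % L + 1, c.strand,
                              c.S, c.S_hat, c.frag_ids) for c in leaves]
        family = clusterG(leaves, seed=config.rng_seed, config=config)
        run.families[strand] = family
        preds = retrieve_predictions(family, config)
        if shift:
            preds = [Prediction(p.gene, (p.start + shift - 1) % L + 1,
                                (p.end + shift - 1) % L + 1,
                                p.strand, p.max_rfd) for p in preds]
        elif shift is None and r_in.circular:
            preds = _stitch_cut(preds, L)
        predictions += preds
    predictions.sort(key=lambda p: (p.start, p.end, p.gene, p.strand))
    run.predictions = predictions
    return run


def _stitch_cut(preds: list[Prediction], L: int) -> list[Prediction]:
    """Post-hoc merge of same-gene predictions abutting the linearization
    cut (used only when no leaf-free cut position exists)."""
    at_end = {(p.gene, p.strand): p for p in preds if p.end == L}
    out = []
    consumed = set()
    for p in preds:
        if p.start == 1 and (p.gene, p.strand) in at_end:
            q = at_end[(p.gene, p.strand)]
            if q is not p:
                out.append(Prediction(p.gene, q.start, p.end, p.strand,
                                      max(p.max_rfd, q.max_rfd)))
                consumed.add(id(q))
                continue
        out.append(p)
    return [p for p in out if id(p) not in consumed]
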