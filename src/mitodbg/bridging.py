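"""Bridging unmapped input segments through database trails.

Between two connected components there is an unmapped stretch of the input.
A database genome that maps near both facing ends (a pair of *seeding*
trails) offers the trail between its two images as a candidate replacement
for the unmapped stretch. Candidates are filtered on locality (seed distance
at most g times the gap size) and on the relative distance between the input
gap and the database gap (at most 0.2 by default), then validated by a local
affine-gap alignment whose E-value must not exceed the acceptance threshold.
Accepted bridges become mapping pairs and merge the two components.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from scipy.optimize import brentq

from .config import Config
from .formats import Genome
from .graph import MDBG, reverse_complement
from .mapping import ConnectedComponent, MappingPair, MatchResult, pos_mod

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Karlin-Altschul statistics for the ungapped (+1, -2) scheme on uniform
# base composition (applied, as is standard pragmatic practice, to gapped
# local scores; the acceptance threshold is permissive).

@lru_cache(maxsize=None)
def karlin_lambda(match: int = 1, mismatch: int = -2,
                  p_match: float = 0.25) -> float:
    """Positive root of sum_ij p_i p_j exp(lambda * s_ij) = 1."""
    if p_match * match + (1 - p_match) * mismatch >= 0:
        raise ValueError("expected score must be negative")

    def f(lam: float) -> float:
        return (p_match * math.exp(lam * match)
                + (1 - p_match) * math.exp(lam * mismatch) - 1.0)

    return brentq(f, 1e-9, 10.0)


@lru_cache(maxsize=None)
def karlin_K(match: int = 1, mismatch: int = -2,
             p_match: float = 0.25, iterations: int = 80) -> float:
    """K by the standard lattice series approximation
    K = d * lambda * exp(-2 sigma) / (H * (1 - exp(-lambda d))), with sigma
    accumulated over j-fold convolutions of the per-column score
    distribution. For (+1, -2) on uniform composition this reproduces the
    classical lambda = 1.33, K = 0.621."""
    lam = karlin_lambda(match, mismatch, p_match)
    lo, hi = min(mismatch, match), max(mismatch, match)
    p = np.zeros(hi - lo + 1)
    p[match - lo] += p_match
    p[mismatch - lo] += 1 - p_match
    av = sum(s * p[s - lo] * math.exp(lam * s) for s in range(lo, hi + 1))
    H = lam * av
    d = math.gcd(abs(match), abs(mismatch))
    cur, cur_lo = p.copy(), lo
    sigma = 0.0
    for j in range(1, iterations + 1):
        if j > 1:
            cur = np.convolve(cur, p)
            cur_lo += lo
        inner = 0.0
        for idx, pr in enumerate(cur):
            s = cur_lo + idx
            if pr > 0.0:
                inner += pr * math.exp(lam * s) if s < 0 else pr
        sigma += inner / j
    return d * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * d)))


def evalue(score: float, m: int, n: int,
           lam: float | None = None, K: float | None = None) -> float:
    """Expected number of local alignments scoring >= score between random
    sequences of lengths m and n: E = K m n exp(-lambda score)."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be positive")
    if lam is None:
        lam = karlin_lambda()
    if K is None:
        K = karlin_K()
    return K * m * n * math.exp(-lam * score)


# --------------------------------------------------------------------------
# Local affine-gap alignment (delegated to Bio.Align.PairwiseAligner).

@dataclass
class AlignmentResult:
    score: float
    evalue: float
    query_span: tuple[int, int] | None = None
    subject_span: tuple[int, int] | None = None


def _aligner(config: Config) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = config.align_match
    aligner.mismatch_score = config.align_mismatch
    # convention: a gap of length l costs open + l*extend
    aligner.open_gap_score = config.align_gap_open + config.align_gap_extend
    aligner.extend_gap_score = config.align_gap_extend
    return aligner


def align_local_affine(a: str, b: str, config: Config | None = None,
                       with_spans: bool = False) -> AlignmentResult:
    """Optimal local alignment score of a vs b under match +1, mismatch -2
    and affine gaps costing open + l*extend for length l, with its E-value
    at the two sequence lengths."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    config = config or Config()
    aligner = _aligner(config)
    score = aligner.score(a, b)
    res = AlignmentResult(score=score, evalue=evalue(score, len(a), len(b)))
    if with_spans and score > 0:
        aln = aligner.align(a, b)[0]
        qs, ss = aln.aligned
        res.query_span = (int(qs[0][0]) + 1, int(qs[-1][1]))
        res.subject_span = (int(ss[0][0]) + 1, int(ss[-1][1]))
    return res


# --------------------------------------------------------------------------
# Seeding-pair search.

@dataclass
class SeedingPair:
    """A candidate bridge: maximal mapping pairs at the facing ends of two
    CCs, same database genome and strand, with the database trail between
    them. ``n``/``o`` are the input positions of the facing seed ends
    (1..L), ``n_prime``/``o_prime`` the database oriented counterparts."""

    seed_I: MappingPair
    seed_T: MappingPair
    genome_id: str
    strand: str
    n: int
    o: int
    n_prime: int
    o_prime: int
    input_dist: int      # o - n, circular
    db_dist: int         # oriented database distance
    rel_dist: float


def gap_distance(cc_a: ConnectedComponent, cc_b: ConnectedComponent,
                 L: int, circular: bool = True) -> int:
    """Number of input positions strictly between a's inducing interval and
    b's, in reading direction (a before b)."""
    a_end = pos_mod(cc_a.end, L)
    b_start = pos_mod(cc_b.start, L)
    if circular:
        delta = (b_start - a_end - 1) % L
        span_a = min(cc_a.span, L)
        # b's start must not fall inside a's interval
        if (b_start - cc_a.start) % L < span_a:
            raise ValueError("overlapping inducing intervals")
        return delta
    if b_start <= a_end:
        raise ValueError("overlapping inducing intervals")
    return b_start - a_end - 1


def relative_distance(input_dist: int, db_dist: int) -> float:
    """|(o - n) - (o' - n')| / (o - n); the Step-1 similarity proxy."""
    if input_dist <= 0:
        raise ValueError("zero or negative input gap")
    return abs(input_dist - db_dist) / input_dist


def find_seeding_pairs(C_I: ConnectedComponent, C_T: ConnectedComponent,
                       g: int, delta: int, L_in: int, mdbg: MDBG,
                       config: Config | None = None,
                       circular: bool = True) -> list[SeedingPair]:
    """Step 1: candidate seeding pairs between two CCs.

    Filters: same (genome, strand) and seed input distance o - n <= g*delta
    admit candidates; per database genome only the closest pair is retained
    (tie -> lower relative distance); the retained pair must then satisfy
    relative distance <= rel_dist_max. Deduplicating *before* the
    relative-distance bound keeps bridging local: a genome whose nearest
    seeds disagree in gap length (e.g. across a novel insertion) is
    rejected rather than stretched until a distant seed pair dilutes the
    disagreement under the bound.
    """
    config = config or Config()
    bound = g * delta

    def circ_dist(frm: int, to: int) -> int:
        return (to - frm) % L_in if circular else to - frm

    candidates: list[SeedingPair] = []
    by_key_T: dict[tuple[str, str], list[MappingPair]] = {}
    for pT in C_T.pairs:
        by_key_T.setdefault((pT.genome_id, pT.strand), []).append(pT)
    for pI in C_I.pairs:
        for pT in by_key_T.get((pI.genome_id, pI.strand), []):
            n = pos_mod(pI.input_j, L_in)
            o = pos_mod(pT.input_i, L_in)
            d = circ_dist(n, o)
            if d <= 0 or d > bound:
                continue
            L_db, db_circ = mdbg.genomes[pI.genome_id]
            n_p = pos_mod(pI.db_oriented_end, L_db)
            o_p = pos_mod(pT.db_oriented_start, L_db)
            if pI.strand == "+":
                d_db = (o_p - n_p) % L_db if db_circ else o_p - n_p
            else:
                d_db = (n_p - o_p) % L_db if db_circ else n_p - o_p
            if d_db <= 0:
                continue
            rd = relative_distance(d, d_db)
            candidates.append(SeedingPair(pI, pT, pI.genome_id, pI.strand,
                                          n, o, n_p, o_p, d, d_db, rd))
    best: dict[str, SeedingPair] = {}
    for cand in sorted(candidates,
                       key=lambda c: (c.input_dist, c.rel_dist,
                                      c.strand, c.n)):
        best.setdefault(cand.genome_id, cand)
    retained = [c for c in best.values() if c.rel_dist <= config.rel_dist_max]
    return sorted(retained, key=lambda c: (c.genome_id, c.n))


# --------------------------------------------------------------------------
# The bridging loop.

@dataclass
class BridgeEvent:
    """One accepted bridge, for the bridge log."""

    gap_start: int
    gap_end: int
    genome_id: str
    strand: str
    trail_start: int
    trail_end: int
    score: float
    evalue: float


@dataclass
class _Group:
    """A merged run of CCs with its hull inducing interval (unrolled)."""

    start: int
    end: int
    members: list[ConnectedComponent]

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def pairs(self) -> list[MappingPair]:
        return [p for cc in self.members for p in cc.pairs]


def _circular_substring(seq: str, start: int, end: int) -> str:
    """1-based inclusive substring with wrap (start/end unrolled)."""
    L = len(seq)
    start, length = pos_mod(start, L), end - start + 1
    doubled = seq + seq
    return doubled[start - 1:start - 1 + length]


def _try_bridge(gI: _Group, gT: _Group, delta: int, r_in: Genome,
                mdbg: MDBG, config: Config
                ) -> tuple[list[MappingPair], list[BridgeEvent]]:
    """Search one CC pair with the doubling g schedule; return accepted
    bridge mapping pairs (empty = pair exhausted without success)."""
    L_in = len(r_in)
    g = config.g0_bridge
    # searched portions grow with g; the pair is exhausted once at least
    # one CC has been searched completely
    limit = min(gI.span, gT.span) + delta
    lam, K = karlin_lambda(config.align_match, config.align_mismatch), \
        karlin_K(config.align_match, config.align_mismatch)
    aligner = _aligner(config)
    while True:
        accepted: list[MappingPair] = []
        events: list[BridgeEvent] = []
        # proxy CCs carrying the group hull and the pooled mapping pairs
        cc_i = ConnectedComponent([], gI.start, gI.end, gI.pairs)
        cc_t = ConnectedComponent([], gT.start, gT.end, gT.pairs)
        for cand in find_seeding_pairs(cc_i, cc_t, g, delta, L_in, mdbg,
                                       config, r_in.circular):
            if cand.db_dist < 2:
                continue  # empty database trail, nothing to align
            gap_seq = _circular_substring(r_in.sequence, cand.n + 1,
                                          cand.n + cand.input_dist - 1)
            L_db, _ = mdbg.genomes[cand.genome_id]
            db_seq = mdbg.sequence(cand.genome_id)
            if cand.strand == "+":
                trail_i, trail_j = cand.n_prime + 1, cand.n_prime + cand.db_dist - 1
                trail_seq = _circular_substring(db_seq, trail_i, trail_j)
            else:
                trail_i, trail_j = cand.n_prime - cand.db_dist + 1, cand.n_prime - 1
                trail_seq = reverse_complement(
                    _circular_substring(db_seq, trail_i, trail_j))
            if not gap_seq or not trail_seq:
                continue
            score = aligner.score(gap_seq, trail_seq)
            E = evalue(score, len(gap_seq), len(trail_seq), lam, K)
            if E <= config.evalue_max:
                accepted.append(MappingPair(
                    cand.n + 1, cand.n + cand.input_dist - 1,
                    cand.genome_id, cand.strand, trail_i, trail_j,
                    source="bridge"))
                events.append(BridgeEvent(
                    pos_mod(cand.n + 1, L_in),
                    pos_mod(cand.n + cand.input_dist - 1, L_in),
                    cand.genome_id, cand.strand,
                    pos_mod(trail_i, L_db), pos_mod(trail_j, L_db),
                    score, E))
        if accepted:
            return accepted, events
        if g * delta >= limit:
            return [], []
        g *= 2


def cc_bridging(match: MatchResult, ccs: list[ConnectedComponent],
                mdbg: MDBG, config: Config | None = None
                ) -> tuple[list[MappingPair], list[_Group], list[BridgeEvent]]:
    """Bridge pairs of connected components (best effort).

    For each component the closest downstream component is attempted first;
    a pair is abandoned when the gap exceeds twice both hull lengths, and
    farther targets are tried when the nearer ones fail. Accepted bridges
    merge the components (including any components lying between them).
    Returns the bridge mapping pairs, the final merged component structure
    and a log of accepted bridges.
    """
    config = config or Config()
    r_in = match.genome
    L = len(r_in)
    groups = [_Group(cc.start, cc.end, [cc]) for cc in ccs]
    bridges: list[MappingPair] = []
    log: list[BridgeEvent] = []
    if len(groups) < 2:
        return bridges, groups, log
    failed: set[tuple[int, int]] = set()
    merged_something = True
    while len(groups) > 1 and merged_something:
        merged_something = False
        groups.sort(key=lambda grp: grp.start)
        for idx in range(len(groups)):
            gI = groups[idx]
            others = groups[idx + 1:] + groups[:idx] if r_in.circular \
                else groups[idx + 1:]
            # downstream targets in reading order == increasing gap distance
            for gT in others:
                try:
                    delta = gap_distance(
                        ConnectedComponent([], gI.start, gI.end),
                        ConnectedComponent([], gT.start, gT.end),
                        L, r_in.circular)
                except ValueError:
                    continue
                if delta == 0:
                    continue
                if delta > 2 * gI.span and delta > 2 * gT.span:
                    break  # farther targets only get worse; next C_I
                key = (gI.start, gT.start)
                if key in failed:
                    continue
                accepted, events = _try_bridge(gI, gT, delta, r_in, mdbg,
                                               config)
                if not accepted:
                    failed.add(key)
                    continue
                bridges.extend(accepted)
                log.extend(events)
                # merge gI .. gT and everything in between (reading order)
                hull_end = gI.start + (pos_mod(gT.end, L) - gI.start) % L \
                    if r_in.circular else gT.end
                span = hull_end - gI.start + 1
                members = []
                survivors = []
                for grp in groups:
                    off = (grp.start - gI.start) % L if r_in.circular \
                        else grp.start - gI.start
                    if 0 <= off < span:
                        members.extend(grp.members)
                    else:
                        survivors.append(grp)
                new_group = _Group(gI.start, hull_end, members)
                groups = survivors + [new_group]
                merged_something = True
                break
            if merged_something:
                break
    groups.sort(key=lambda grp: grp.start)
    return bridges, groups, log
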