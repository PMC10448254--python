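"""Mapping an input genome onto the reference multigraph.

The input genome's (k+1)-mer windows are looked up in the graph; maximal
runs of consecutive matching windows induce connected components (CCs), and
within each CC, maximal co-linear runs of database labels become mapping
pairs — an input trail and a database trail spelling the identical sequence.

Coordinates: window indices are 0-based over the input's window list;
nucleotide coordinates are 1-based. Runs that cross the linearization cut
of a circular sequence are kept "unrolled" (end coordinates may exceed the
sequence length); ``pos_mod`` reduces them back onto the circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .formats import Genome
from .graph import MDBG, EdgeLabel, enumerate_kp1mers


def pos_mod(p: int, L: int) -> int:
    """Reduce an unrolled 1-based position onto the circle 1..L."""
    return (p - 1) % L + 1


@dataclass(frozen=True)
class SGT:
    """A single-genome trail: the subsequence of ``genome_id`` from ``i``
    to ``j`` on strand ``strand`` (i > j means wrap on a circle)."""

    i: int
    j: int
    genome_id: str
    strand: str


@dataclass
class MappingPair:
    """An input trail and a database trail whose windows coincide
    (source="subgraph") or whose sequences align (source="bridge").

    Both intervals are stored unrolled with start <= end; ``strand`` is the
    database strand (the input is always read in its given orientation).
    For strand "-", input position ``input_i`` corresponds to database
    position ``db_j`` and vice versa.
    """

    input_i: int
    input_j: int
    genome_id: str
    strand: str
    db_i: int
    db_j: int
    source: str = "subgraph"

    @property
    def input_len(self) -> int:
        return self.input_j - self.input_i + 1

    def input_sgt(self, L_in: int) -> SGT:
        return SGT(pos_mod(self.input_i, L_in), pos_mod(self.input_j, L_in),
                   "r_in", "+")

    def db_sgt(self, L_db: int) -> SGT:
        return SGT(pos_mod(self.db_i, L_db), pos_mod(self.db_j, L_db),
                   self.genome_id, self.strand)

    # oriented endpoints along the database strand's reading direction:
    # the database position paired with the input start / end.
    @property
    def db_oriented_start(self) -> int:
        return self.db_i if self.strand == "+" else self.db_j

    @property
    def db_oriented_end(self) -> int:
        return self.db_j if self.strand == "+" else self.db_i


@dataclass
class ConnectedComponent:
    """A maximal run of consecutive matching input windows.

    ``windows`` are unrolled window indices (consecutive integers; taken
    modulo the window count for circular inputs). The inducing interval
    [start, end] is the nucleotide span covered by the matched windows,
    with ``end`` unrolled.
    """

    windows: list[int]
    start: int
    end: int
    pairs: list[MappingPair] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class MatchResult:
    """Classification of every input window as matched (with its database
    labels) or unmatched."""

    genome: Genome
    k: int
    n_windows: int
    labels_by_window: dict[int, list[EdgeLabel]]
    mers_by_window: dict[int, str]

    @property
    def matched(self) -> list[tuple[int, str, list[EdgeLabel]]]:
        """(input position of window end, mer, labels) per matched window."""
        L = len(self.genome)
        out = []
        for w in sorted(self.labels_by_window):
            p = (w + self.k) % L + 1 if self.genome.circular else w + self.k + 1
            out.append((p, self.mers_by_window[w], self.labels_by_window[w]))
        return out

    @property
    def unmatched(self) -> list[int]:
        L = len(self.genome)
        out = []
        for w in range(self.n_windows):
            if w not in self.labels_by_window:
                p = (w + self.k) % L + 1 if self.genome.circular else w + self.k + 1
                out.append(p)
        return out


def match_input(mdbg: MDBG, r_in: Genome,
                exclude: Iterable[str] = (),
                skip_ambiguous: bool = True) -> MatchResult:
    """Classify every (k+1)-mer window of the input against the graph.

    Labels of excluded genomes (leave-one-out evaluation) are removed before
    classification; windows with ambiguous bases count as unmatched.
    """
    exclude = set(exclude)
    k = mdbg.k
    seq = r_in.sequence
    L = len(seq)
    if L < k + 1:
        raise ValueError(f"input shorter than k+1 = {k + 1}")
    n_windows = L if r_in.circular else L - k
    labels_by_window: dict[int, list[EdgeLabel]] = {}
    mers_by_window: dict[int, str] = {}
    for mer, p in enumerate_kp1mers(r_in, k, skip_ambiguous):
        w = (p - 1 - k) % L if r_in.circular else p - k - 1
        labels = [lb for lb in mdbg.lookup(mer) if lb.genome_id not in exclude]
        if labels:
            labels_by_window[w] = labels
            mers_by_window[w] = mer
    return MatchResult(r_in, k, n_windows, labels_by_window, mers_by_window)


def connected_components(match: MatchResult) -> list[ConnectedComponent]:
    """Decompose the matched windows into maximal consecutive runs.

    On a circular input a run crossing the linearization cut is one CC.
    Components are ordered by inducing-interval start along the reading
    direction; an empty list signals "no mapping".
    """
    n = match.n_windows
    k = match.k
    circular = match.genome.circular
    mask = [w in match.labels_by_window for w in range(n)]
    if not any(mask):
        return []
    runs: list[list[int]] = []
    if all(mask):
        runs = [list(range(n))]
    else:
        # start scanning right after an unmatched window so circular runs
        # are never split at the cut
        start = mask.index(False) if circular else 0
        cur: list[int] = []
        for t in range(n):
            w = (start + t) % n if circular else t
            if mask[w]:
                cur.append(start + t if circular else t)
            elif cur:
                runs.append(cur)
                cur = []
        if cur:
            runs.append(cur)
    ccs = []
    for run in runs:
        first, last = run[0], run[-1]
        a = first % n + 1 if circular else first + 1
        span = min(len(match.genome), last - first + 1 + k)
        ccs.append(ConnectedComponent(windows=run, start=a, end=a + span - 1))
    ccs.sort(key=lambda c: c.start)
    return ccs


class _Run:
    __slots__ = ("w0", "p0", "genome_id", "strand", "length")

    def __init__(self, w0: int, p0: int, genome_id: str, strand: str):
        self.w0, self.p0 = w0, p0
        self.genome_id, self.strand = genome_id, strand
        self.length = 1


def extract_mapping_pairs(cc: ConnectedComponent, match: MatchResult,
                          mdbg: MDBG) -> list[MappingPair]:
    """Maximal co-linear runs of database labels within one CC.

    Consecutive input windows whose labels advance by +1 (database strand +)
    or -1 (strand -) along the same genome form one pair; parallel labels
    from repeats yield separate, equally valid pairs.
    """
    k = match.k
    n = match.n_windows
    circular = match.genome.circular
    finished: list[_Run] = []
    # active runs keyed by (genome, strand, expected unrolled position)
    active: dict[tuple[str, str, int], list[_Run]] = {}

    def expected_key(run: _Run) -> tuple[str, str, int]:
        nxt = run.p0 + run.length if run.strand == "+" else run.p0 - run.length
        return (run.genome_id, run.strand, nxt)

    for w_unrolled in cc.windows:
        w = w_unrolled % n if circular else w_unrolled
        labels = sorted(match.labels_by_window[w])
        new_active: dict[tuple[str, str, int], list[_Run]] = {}
        for lb in labels:
            L_db, db_circ = mdbg.genomes[lb.genome_id]
            run = None
            # try all unrolled positions congruent to lb.pos that an active
            # run may be expecting (labels are stored reduced to 1..L)
            candidates = [lb.pos]
            if db_circ:
                candidates += [lb.pos + L_db, lb.pos - L_db]
            for cand in candidates:
                key = (lb.genome_id, lb.strand, cand)
                if active.get(key):
                    run = active[key].pop(0)
                    run.length += 1
                    break
            if run is None:
                run = _Run(w_unrolled, lb.pos, lb.genome_id, lb.strand)
            new_active.setdefault(expected_key(run), []).append(run)
        for rs in active.values():
            finished.extend(rs)
        active = new_active
    for rs in active.values():
        finished.extend(rs)

    pairs = []
    for run in finished:
        # input window w covers nucleotides [w+1, w+k+1] (unrolled)
        i_in = run.w0 + 1
        j_in = run.w0 + run.length + k
        if run.strand == "+":
            # first label is the end of the first window
            db_i = run.p0 - k
            db_j = run.p0 + run.length - 1
        else:
            db_i = run.p0 - run.length + 1
            db_j = run.p0 + k
        pairs.append(MappingPair(i_in, j_in, run.genome_id, run.strand,
                                 db_i, db_j))
    pairs.sort(key=lambda p: (p.input_i, p.genome_id, p.strand, p.db_i))
    return pairs


def build_subgraph(mdbg: MDBG, r_in: Genome,
                   exclude: Iterable[str] = ()) -> tuple[MatchResult,
                                                         list[ConnectedComponent]]:
    """Match the input, decompose into CCs, and attach each CC's maximal
    mapping pairs."""
    match = match_input(mdbg, r_in, exclude)
    ccs = connected_components(match)
    for cc in ccs:
        cc.pairs = extract_mapping_pairs(cc, match, mdbg)
    return match, ccs
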