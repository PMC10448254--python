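"""The annotated de Bruijn multigraph over the reference genome set.

Edges are (k+1)-mers; the two k-mer vertices of an edge are implicit as its
prefix/suffix. Every occurrence of a (k+1)-mer in a reference genome yields
one edge label (genome, strand, position), and the reverse complement of the
mer receives a mirrored negative-strand label, so parallel labels encode
repeats and shared sequence across genomes. Positions refer to the positive
strand throughout: a positive-strand label carries the position of the
window's last nucleotide; the mirrored negative-strand label carries the
positive-strand position of the window's *first* nucleotide (which is where
the reverse-complement window ends when read along the negative strand).
"""

from __future__ import annotations

import sqlite3
from pathlib import Path
from typing import Iterable, NamedTuple

from .formats import Genome, VALID_BASES

FORMAT_VERSION = 1

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class EdgeLabel(NamedTuple):
    genome_id: str
    strand: str  # '+' or '-'
    pos: int     # 1-based positive-strand position (see module docstring)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T}; an involution."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters for reverse complement: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def enumerate_kp1mers(genome: Genome, k: int,
                      skip_ambiguous: bool = True) -> list[tuple[str, int]]:
    """All (k+1)-mer windows of a genome with the 1-based position of each
    window's last nucleotide.

    A circular genome of length L contributes L windows (wrap-around windows
    included, their end positions reduced into 1..L); a linear genome
    contributes L-k. Duplicates are retained. Windows containing non-ACGT
    characters are skipped when ``skip_ambiguous`` (otherwise rejected).
    """
    seq = genome.sequence
    L = len(seq)
    if L < k + 1:
        raise ValueError(
            f"genome {genome.id}: length {L} shorter than k+1 = {k + 1}")
    doubled = seq + seq[:k] if genome.circular else seq
    n_windows = L if genome.circular else L - k
    out = []
    for s in range(n_windows):
        mer = doubled[s:s + k + 1]
        if not VALID_BASES.issuperset(mer):
            if skip_ambiguous:
                continue
            raise ValueError(
                f"genome {genome.id}: ambiguous base in window at {s + 1}")
        p = (s + k) % L + 1 if genome.circular else s + k + 1
        out.append((mer, p))
    return out


class MDBG:
    """Annotated de Bruijn multigraph, keyed by (k+1)-mer strings.

    ``edges`` maps each (k+1)-mer to the list of its labels; genomes can be
    added and removed incrementally without touching other genomes' labels.
    """

    def __init__(self, k: int):
        if k < 2:
            raise ValueError("k must be >= 2")
        self.k = k
        self.genomes: dict[str, tuple[int, bool]] = {}  # id -> (length, circular)
        self.edges: dict[str, list[EdgeLabel]] = {}
        self._seq_cache: dict[str, str] = {}

    # -- construction -----------------------------------------------------

    def add_genome(self, genome: Genome, skip_ambiguous: bool = True) -> "MDBG":
        if genome.id in self.genomes:
            raise ValueError(f"duplicate genome id {genome.id!r}")
        k, L = self.k, len(genome)
        for mer, p in enumerate_kp1mers(genome, k, skip_ambiguous):
            self.edges.setdefault(mer, []).append(
                EdgeLabel(genome.id, "+", p))
            # mirrored negative-strand label: position of the forward
            # window's first nucleotide, p - k (mod L on circles)
            p_rc = (p - k - 1) % L + 1 if genome.circular else p - k
            self.edges.setdefault(reverse_complement(mer), []).append(
                EdgeLabel(genome.id, "-", p_rc))
        self.genomes[genome.id] = (L, genome.circular)
        self._seq_cache[genome.id] = genome.sequence
        return self

    def remove_genome(self, genome_id: str) -> "MDBG":
        if genome_id not in self.genomes:
            raise KeyError(f"unknown genome id {genome_id!r}")
        empty = []
        for mer, labels in self.edges.items():
            labels[:] = [lb for lb in labels if lb.genome_id != genome_id]
            if not labels:
                empty.append(mer)
        for mer in empty:
            del self.edges[mer]
        del self.genomes[genome_id]
        self._seq_cache.pop(genome_id, None)
        return self

    # -- queries -----------------------------------------------------------

    def lookup(self, mer: str) -> list[EdgeLabel]:
        return self.edges.get(mer, [])

    def total_labels(self) -> int:
        return sum(len(v) for v in self.edges.values())

    def reconstruct_genome(self, genome_id: str) -> Genome:
        """Rebuild a genome's sequence from its positive-strand edge labels.

        Positions order the windows; concatenating last characters (plus,
        for linear genomes, the prefix of the first window) restores the
        sequence exactly. Positions lost to ambiguity skipping come back
        as N.
        """
        if genome_id not in self.genomes:
            raise KeyError(f"unknown genome id {genome_id!r}")
        L, circular = self.genomes[genome_id]
        chars = ["N"] * L
        first_mer = None
        for mer, labels in self.edges.items():
            for lb in labels:
                if lb.genome_id == genome_id and lb.strand == "+":
                    chars[lb.pos - 1] = mer[-1]
                    if not circular and lb.pos == self.k + 1:
                        first_mer = mer
        if not circular:
            if first_mer is None:
                raise ValueError(
                    f"genome {genome_id}: first window missing, cannot "
                    "reconstruct the leading k characters")
            chars[: self.k] = first_mer[: self.k]
        return Genome(genome_id, "".join(chars), circular)

    def sequence(self, genome_id: str) -> str:
        """Genome sequence (cached; reconstructed from the graph after a
        load from disk)."""
        if genome_id not in self._seq_cache:
            self._seq_cache[genome_id] = self.reconstruct_genome(genome_id).sequence
        return self._seq_cache[genome_id]


def build_mdbg(genomes: Iterable[Genome], k: int,
               skip_ambiguous: bool = True) -> MDBG:
    """Build the multigraph over a reference set."""
    mdbg = MDBG(k)
    for g in genomes:
        mdbg.add_genome(g, skip_ambiguous)
    return mdbg


# -- persistence (single-file indexed sqlite store) -------------------------

def persist(mdbg: MDBG, path: str | Path) -> None:
    """Write the graph to a single-file indexed store (atomic rewrite)."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    if tmp.exists():
        tmp.unlink()
    con = sqlite3.connect(tmp)
    try:
        cur = con.cursor()
        cur.execute("CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT)")
        cur.execute("CREATE TABLE genomes (id TEXT PRIMARY KEY, "
                    "length INTEGER, circular INTEGER)")
        cur.execute("CREATE TABLE edges (mer TEXT, genome TEXT, "
                    "strand TEXT, pos INTEGER)")
        cur.executemany("INSERT INTO meta VALUES (?, ?)",
                        [("format_version", str(FORMAT_VERSION)),
                         ("k", str(mdbg.k))])
        cur.executemany("INSERT INTO genomes VALUES (?, ?, ?)",
                        [(gid, L, int(circ))
                         for gid, (L, circ) in mdbg.genomes.items()])
        cur.executemany(
            "INSERT INTO edges VALUES (?, ?, ?, ?)",
            ((mer, lb.genome_id, lb.strand, lb.pos)
             for mer, labels in mdbg.edges.items() for lb in labels))
        cur.execute("CREATE INDEX idx_edges_mer ON edges (mer)")
        cur.execute("CREATE INDEX idx_edges_genome ON edges (genome)")
        con.commit()
    finally:
        con.close()
    tmp.replace(path)


def load(path: str | Path) -> MDBG:
    """Load a persisted graph; refuses stores with a different format
    version without leaving partial state behind."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    con = sqlite3.connect(path)
    try:
        try:
            meta = dict(con.execute("SELECT key, value FROM meta"))
        except sqlite3.DatabaseError as exc:
            raise ValueError(f"{path}: not a graph store ({exc})") from exc
        version = int(meta.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(
                f"{path}: format version {version} != supported "
                f"{FORMAT_VERSION}")
        mdbg = MDBG(int(meta["k"]))
        for gid, L, circ in con.execute(
                "SELECT id, length, circular FROM genomes"):
            mdbg.genomes[gid] = (L, bool(circ))
        for mer, gid, strand, pos in con.execute(
                "SELECT mer, genome, strand, pos FROM edges"):
            mdbg.edges.setdefault(mer, []).append(EdgeLabel(gid, strand, pos))
        return mdbg
    finally:
        con.close()
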