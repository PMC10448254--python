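"""Reading and writing the formats the pipeline touches.

FASTA genomes in, BED6 predictions out, plus a simple tab-separated
annotation table (genome_id, start, end, strand, gene; 1-based inclusive).
Internally every coordinate is 1-based inclusive; conversion to BED's
0-based half-open convention happens only at the BED boundary.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")


@dataclass
class Genome:
    """A nucleotide sequence, circular by default (mitogenome convention)."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper().replace("U", "T")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationRecord:
    """A gene annotated on genome ``genome_id`` from ``n`` to ``m`` (1-based,
    inclusive; n > m denotes wrap-around on a circular genome).

    ``is_g0`` marks the sentinel label for regions without any gene.
    """

    n: int
    m: int
    genome_id: str
    strand: str
    gene: str
    is_g0: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if not self.gene:
            raise ValueError("gene label must be non-empty")
        if self.n < 1 or self.m < 1:
            raise ValueError(f"coordinates must be >= 1: ({self.n}, {self.m})")

    def validate_against(self, genome: Genome) -> None:
        L = len(genome)
        if self.n > L or self.m > L:
            raise ValueError(
                f"annotation {self.gene} ({self.n},{self.m}) outside "
                f"genome {genome.id} of length {L}")
        if self.n > self.m and not genome.circular:
            raise ValueError(
                f"annotation {self.gene} wraps on linear genome {genome.id}")

    def length(self, L: int) -> int:
        """Span in nt, circular-aware."""
        if self.n <= self.m:
            return self.m - self.n + 1
        return L - self.n + 1 + self.m


@dataclass(frozen=True)
class Prediction:
    """A final gene call on the input genome (1-based inclusive interval)."""

    gene: str
    start: int
    end: int
    strand: str
    max_rfd: float = 1.0


def read_fasta(path: str | Path, circular: bool = True) -> list[Genome]:
    """Read FASTA records into :class:`Genome` objects.

    Sequences are uppercased and U is mapped to T. Ambiguity codes are kept
    in the sequence; windows containing them are skipped during k-mer
    enumeration (see ``Config.skip_ambiguous``).
    """
    path = Path(path)
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        genomes.append(Genome(id=rec.id, sequence=seq, circular=circular))
    if not genomes:
        raise ValueError(f"no FASTA records found in {path}")
    return genomes


def load_synonym_map(path: str | Path | None = None) -> dict[str, str]:
    """Load the gene-name synonym table (two tab-separated columns:
    raw name, canonical name). Defaults to the table shipped with the
    package; the table is user-editable."""
    if path is None:
        text = resources.files("mitodbg.data").joinpath(
            "gene_synonyms.tsv").read_text()
    else:
        text = Path(path).read_text()
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        raw, canonical = line.split("\t")[:2]
        mapping[raw.strip().lower()] = canonical.strip()
    return mapping


def load_gene_classes(path: str | Path | None = None) -> dict[str, str]:
    """Gene -> class (protein/tRNA/rRNA) table, keyed on normalized names."""
    if path is None:
        text = resources.files("mitodbg.data").joinpath(
            "gene_classes.tsv").read_text()
    else:
        text = Path(path).read_text()
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        gene, cls = line.split("\t")[:2]
        mapping[gene.strip()] = cls.strip()
    return mapping


def gene_class(gene: str, class_map: Mapping[str, str]) -> str:
    """Class of a (possibly copy-suffixed) gene label; unknown -> 'other'."""
    base = gene.split("#", 1)[0]
    if base in class_map:
        return class_map[base]
    if base.startswith("trn"):
        return "tRNA"
    return "other"


def normalize_gene_name(raw: str,
                        synonym_map: Mapping[str, str] | None = None) -> str:
    """Map a raw gene name to its canonical form (case-insensitive).

    Unknown names pass through unchanged (with a log message), so the
    lookup is total.
    """
    if synonym_map is None:
        synonym_map = load_synonym_map()
    key = raw.strip().lower()
    if key in synonym_map:
        return synonym_map[key]
    logger.warning("gene name %r not in synonym table; kept as is", raw)
    return raw.strip()


def _disambiguate_copies(records: list[AnnotationRecord]) -> list[AnnotationRecord]:
    """Give every copy of a repeated (genome, gene) pair a distinct label
    (gene#1, gene#2, ... in order of appearance)."""
    counts = Counter((r.genome_id, r.gene) for r in records)
    seen: Counter = Counter()
    out = []
    for r in records:
        key = (r.genome_id, r.gene)
        if counts[key] > 1:
            seen[key] += 1
            r = AnnotationRecord(r.n, r.m, r.genome_id, r.strand,
                                 f"{r.gene}#{seen[key]}", r.is_g0)
        out.append(r)
    return out


def read_annotations(path: str | Path,
                     genomes: Iterable[Genome],
                     dialect: str = "tsv",
                     synonym_map: Mapping[str, str] | None = None,
                     ) -> list[AnnotationRecord]:
    """Read a gene annotation table.

    dialect="tsv": columns genome_id, start, end, strand, gene with 1-based
    inclusive coordinates (the native convention).
    dialect="bed": BED6 (0-based half-open, strand in column 6).

    Gene names are normalized through the synonym table and per-genome
    duplicates receive distinct copy labels.
    """
    if dialect not in ("tsv", "bed"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if synonym_map is None:
        synonym_map = load_synonym_map()
    by_id = {g.id: g for g in genomes}
    records: list[AnnotationRecord] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) == 1:  # tolerate space-separated tables
            cols = line.split()
        try:
            if dialect == "bed":
                gid, start0, end, name = cols[0], int(cols[1]), int(cols[2]), cols[3]
                strand = cols[5] if len(cols) > 5 else "+"
                n, m = start0 + 1, end
            else:
                gid, n, m, strand, name = (cols[0], int(cols[1]), int(cols[2]),
                                           cols[3], cols[4])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed line {raw!r}") from exc
        if gid not in by_id:
            raise ValueError(f"{path}:{lineno}: unknown genome {gid!r}")
        rec = AnnotationRecord(n, m, gid, strand,
                               normalize_gene_name(name, synonym_map))
        rec.validate_against(by_id[gid])
        records.append(rec)
    return _disambiguate_copies(records)


def write_annotations_tsv(records: Iterable[AnnotationRecord],
                          path: str | Path) -> None:
    """Write the native 1-based inclusive annotation table."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.genome_id}\t{r.n}\t{r.m}\t{r.strand}\t{r.gene}\n")


def write_fasta(genomes: Iterable[Genome], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i:i + width] + "\n")


def write_predictions_bed(predictions: Iterable[Prediction],
                          path: str | Path,
                          genome: Genome) -> None:
    """Write predictions as BED6 (0-based half-open).

    Wrap-around predictions on a circular genome are split into two lines
    sharing a ``|wrap`` name suffix (BED has no circular convention).
    """
    L = len(genome)
    lines: list[tuple[int, str, str]] = []
    for p in predictions:
        if p.start <= p.end:
            pieces = [(p.start, p.end, p.gene)]
        else:
            if not genome.circular:
                raise ValueError(f"wrapping prediction {p} on linear genome")
            pieces = [(p.start, L, f"{p.gene}|wrap"), (1, p.end, f"{p.gene}|wrap")]
        for s, e, name in pieces:
            lines.append((s - 1, name,
                          f"{genome.id}\t{s - 1}\t{e}\t{name}\t.\t{p.strand}"))
    lines.sort(key=lambda t: (t[0], t[1]))
    with open(path, "w") as fh:
        for _, _, line in lines:
            fh.write(line + "\n")


def read_predictions_bed(path: str | Path) -> list[Prediction]:
    """Read a BED6 prediction file back (wrap pieces are kept as two
    separate records)."""
    preds = []
    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        cols = raw.split("\t")
        preds.append(Prediction(gene=cols[3], start=int(cols[1]) + 1,
                                end=int(cols[2]), strand=cols[5]))
    return preds
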