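"""Synthetic reference clades with known annotations.

The generator emulates a miniature metazoan mitogenome: a circular ancestor
carrying 13 protein-like, 22 tRNA-like and 2 rRNA-like genes on both strands
plus a control-region gap, from which descendants diverge by per-branch
substitutions (and, optionally, feature-confined indels). Because genes are
assembled block by block, descendant annotation coordinates are exact by
construction, giving every pipeline stage a ground truth without downloads.

What it does not emulate: codon structure, strand-asymmetric mutation,
rearrangements, or inter-feature indels; passing tests therefore demonstrate
coordinate-exact recovery under point divergence, not robustness to genome
rearrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .formats import AnnotationRecord, Genome

BASES = np.frombuffer(b"ACGT", dtype="S1")

# (gene, length, strand); None = unannotated gap (length drawn at runtime).
# A scaled-down 37-gene metazoan-like order, with a handful of features on
# the negative strand.
DEFAULT_FEATURES: list[tuple[str, int, str]] = [
    ("trnF", 70, "+"), ("rrnS", 200, "+"), ("trnV", 70, "+"),
    ("rrnL", 260, "+"), ("trnL", 72, "+"), ("nad1", 240, "+"),
    ("trnI", 70, "+"), ("trnQ", 70, "-"), ("trnM", 70, "+"),
    ("nad2", 210, "+"), ("trnW", 70, "+"), ("trnA", 70, "-"),
    ("trnN", 70, "-"), ("trnC", 72, "-"), ("trnY", 70, "-"),
    ("cox1", 300, "+"), ("trnS", 72, "-"), ("trnD", 70, "+"),
    ("cox2", 210, "+"), ("trnK", 70, "+"), ("atp8", 90, "+"),
    ("atp6", 180, "+"), ("cox3", 210, "+"), ("trnG", 70, "+"),
    ("nad3", 120, "+"), ("trnR", 70, "+"), ("nad4l", 90, "+"),
    ("nad4", 270, "+"), ("trnH", 70, "+"), ("nad5", 300, "+"),
    ("nad6", 120, "-"), ("trnE", 70, "-"), ("cob", 270, "+"),
    ("trnT", 70, "+"), ("trnP", 72, "-"),
]


@dataclass
class SimSpec:
    """Study conditions for one synthetic clade."""

    n_genomes: int = 5
    substitution_rate: float = 0.025  # per site per branch; a star clade at
                                      # this rate sits at ~95% pairwise identity
    indel_rate: float = 0.0           # expected indels per site, per branch
    indel_max_len: int = 8
    duplication: bool = False         # tandem copy of one tRNA in the ancestor
    gap_range: tuple[int, int] = (5, 30)
    control_region: int = 200
    features: list[tuple[str, int, str]] = field(
        default_factory=lambda: list(DEFAULT_FEATURES))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 0.3:
            raise ValueError("substitution_rate outside [0, 0.3]")
        if not 0.0 <= self.indel_rate <= 0.3:
            raise ValueError("indel_rate outside [0, 0.3]")
        if self.n_genomes < 1:
            raise ValueError("need at least one genome")


@dataclass
class Clade:
    genomes: list[Genome]
    annotations: list[AnnotationRecord]          # all genomes pooled
    truth: dict[str, list[AnnotationRecord]]     # per genome
    edits: dict[str, list[tuple[str, int, int, int]]]  # (op, block, pos, len)
    ancestor: Genome
    ancestor_truth: list[AnnotationRecord]
    # (gene or None, ancestor block length, strand or None) per block
    block_layout: list[tuple[str | None, int, str | None]] = field(
        default_factory=list)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def _mutate_block(block: str, rng: np.random.Generator,
                  sub_rate: float, indel_rate: float,
                  indel_max: int) -> tuple[str, list[tuple[str, int, int]]]:
    """Substitute and (optionally) indel within one feature block; returns
    the new block and the edit ops in block-local 0-based coordinates."""
    arr = np.frombuffer(block.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < sub_rate)
    for h in hits:
        choices = BASES[BASES != arr[h]]
        arr[h] = rng.choice(choices)
    seq = arr.tobytes().decode()
    ops: list[tuple[str, int, int]] = []
    if indel_rate > 0:
        n_events = rng.poisson(indel_rate * len(seq))
        for _ in range(n_events):
            length = int(rng.integers(1, indel_max + 1))
            if rng.random() < 0.5 and len(seq) > length + 2:
                x = int(rng.integers(1, len(seq) - length))
                seq = seq[:x] + seq[x + length:]
                ops.append(("del", x, length))
            else:
                x = int(rng.integers(1, len(seq)))
                seq = seq[:x] + _random_seq(rng, length) + seq[x:]
                ops.append(("ins", x, length))
    return seq, ops


def generate_clade(spec: SimSpec) -> Clade:
    """Random ancestor with the configured layout; descendants diverge
    independently from it. Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    features = list(spec.features)
    if spec.duplication:
        # tandem copy of the first tRNA-like feature
        for idx, (name, length, strand) in enumerate(features):
            if name.startswith("trn"):
                features.insert(idx + 1, (name, length, strand))
                break
    # blocks: leading gap, then gene/gap alternation, then control region
    blocks: list[tuple[str | None, str, str | None]] = []  # (gene, seq, strand)
    lo, hi = spec.gap_range
    blocks.append((None, _random_seq(rng, int(rng.integers(lo, hi + 1))), None))
    for name, length, strand in features:
        blocks.append((name, _random_seq(rng, length), strand))
        blocks.append((None, _random_seq(rng, int(rng.integers(lo, hi + 1))),
                       None))
    blocks.append((None, _random_seq(rng, spec.control_region), None))

    def assemble(blks: list[tuple[str | None, str, str | None]],
                 gid: str) -> tuple[Genome, list[AnnotationRecord]]:
        seq_parts, anns, cur = [], [], 0
        for gene, seq, strand in blks:
            if gene is not None:
                anns.append(AnnotationRecord(cur + 1, cur + len(seq), gid,
                                             strand, gene))
            seq_parts.append(seq)
            cur += len(seq)
        from .formats import _disambiguate_copies
        return Genome(gid, "".join(seq_parts)), _disambiguate_copies(anns)

    ancestor, ancestor_truth = assemble(blocks, "ancestor")

    genomes, truth, edits = [], {}, {}
    pooled: list[AnnotationRecord] = []
    for n in range(spec.n_genomes):
        gid = f"g{n + 1}"
        new_blocks = []
        ops: list[tuple[str, int, int, int]] = []
        for bi, (gene, seq, strand) in enumerate(blocks):
            mutated, local_ops = _mutate_block(seq, rng,
                                               spec.substitution_rate,
                                               spec.indel_rate,
                                               spec.indel_max_len)
            ops.extend((op, bi, x, l) for op, x, l in local_ops)
            new_blocks.append((gene, mutated, strand))
        genome, anns = assemble(new_blocks, gid)
        genomes.append(genome)
        truth[gid] = anns
        edits[gid] = ops
        pooled.extend(anns)
    layout = [(gene, len(seq), strand) for gene, seq, strand in blocks]
    return Clade(genomes, pooled, truth, edits, ancestor, ancestor_truth,
                 layout)


@dataclass
class LeaveOneOutCase:
    db_genomes: list[Genome]
    db_annotations: list[AnnotationRecord]
    input_genome: Genome
    truth: list[AnnotationRecord]
    clade: Clade
    insertion_at: int | None = None


def make_leave_one_out_case(spec: SimSpec,
                            insertion_length: int = 0) -> LeaveOneOutCase:
    """Withhold one descendant as the input genome; the rest (with their
    annotations) form the database. Optionally a unique random segment is
    inserted into the input's control region."""
    if spec.n_genomes < 3:
        raise ValueError("need at least 3 genomes for a leave-one-out case")
    clade = generate_clade(spec)
    held_out = clade.genomes[-1]
    db_genomes = clade.genomes[:-1]
    db_ids = {g.id for g in db_genomes}
    db_annotations = [a for a in clade.annotations if a.genome_id in db_ids]
    truth = list(clade.truth[held_out.id])
    insertion_at = None
    if insertion_length > 0:
        rng = np.random.default_rng(spec.seed + 10_000)
        # middle of the control region (the trailing unannotated block)
        last_end = max(a.m for a in truth)
        L = len(held_out)
        insertion_at = last_end + (L - last_end) // 2
        insert = _random_seq(rng, insertion_length)
        seq = held_out.sequence
        held_out = Genome(held_out.id,
                          seq[:insertion_at] + insert + seq[insertion_at:],
                          held_out.circular)
        truth = [AnnotationRecord(
            a.n + insertion_length if a.n > insertion_at else a.n,
            a.m + insertion_length if a.m > insertion_at else a.m,
            a.genome_id, a.strand, a.gene, a.is_g0) for a in truth]
    return LeaveOneOutCase(db_genomes, db_annotations, held_out, truth,
                           clade, insertion_at)
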