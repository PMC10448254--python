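"""Benchmark classification, boundary-deviation summaries, and the
(k+1)-mer randomization experiment.

A prediction corresponds to the reference annotation sharing the largest
number of positions with it, provided at least 75% of the *prediction's*
positions are shared; correspondences are classified as equal (same gene,
same strand), strand_difference, or different, and the remaining predictions
and references are false positives and false negatives respectively.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats import AnnotationRecord, Genome, Prediction, gene_class
from .graph import enumerate_kp1mers


@dataclass
class CorrespondenceResult:
    prediction: Prediction
    reference: AnnotationRecord | None
    klass: str                      # equal | strand_difference | different | FP
    frac_prediction: float          # shared / |prediction|
    frac_reference: float           # shared / |reference|


def _positions(start: int, end: int, L: int) -> frozenset[int]:
    if start <= end:
        return frozenset(range(start, end + 1))
    return frozenset(range(start, L + 1)) | frozenset(range(1, end + 1))


def correspond(predictions: Sequence[Prediction],
               references: Sequence[AnnotationRecord],
               L: int,
               min_overlap: float = 0.75,
               ) -> tuple[list[CorrespondenceResult], list[AnnotationRecord]]:
    """Allocate each prediction to its best-overlapping reference and
    classify; returns the per-prediction results and the false-negative
    references (those never chosen as a correspondent)."""
    ref_pos = [(_positions(r.n, r.m, L), r) for r in references]
    results: list[CorrespondenceResult] = []
    matched_refs: set[int] = set()
    for pred in predictions:
        ppos = _positions(pred.start, pred.end, L)
        best = None
        for idx, (rpos, ref) in enumerate(ref_pos):
            shared = len(ppos & rpos)
            if shared == 0:
                continue
            # ties toward same gene, then same strand, then smaller start
            rank = (shared, ref.gene == pred.gene, ref.strand == pred.strand,
                    -ref.n)
            if best is None or rank > best[0]:
                best = (rank, idx, shared, rpos, ref)
        if best is None or best[2] / len(ppos) < min_overlap:
            results.append(CorrespondenceResult(pred, None, "FP", 0.0, 0.0))
            continue
        _, idx, shared, rpos, ref = best
        matched_refs.add(idx)
        if ref.gene == pred.gene:
            klass = "equal" if ref.strand == pred.strand else "strand_difference"
        else:
            klass = "different"
        results.append(CorrespondenceResult(
            pred, ref, klass, shared / len(ppos), shared / len(rpos)))
    false_negatives = [ref for idx, (_, ref) in enumerate(ref_pos)
                       if idx not in matched_refs]
    return results, false_negatives


def summarize_classes(results: Sequence[CorrespondenceResult],
                      false_negatives: Sequence[AnnotationRecord],
                      class_map: Mapping[str, str] | None = None,
                      ) -> dict[str, Counter]:
    """Per gene-class (and overall) counts of the benchmark classes."""
    from .formats import load_gene_classes
    class_map = class_map or load_gene_classes()
    table: dict[str, Counter] = {"all": Counter()}
    for res in results:
        cls = gene_class(res.prediction.gene, class_map)
        for key in (cls, "all"):
            table.setdefault(key, Counter())[res.klass] += 1
    for ref in false_negatives:
        cls = gene_class(ref.gene, class_map)
        for key in (cls, "all"):
            table.setdefault(key, Counter())["FN"] += 1
    return table


def _circ_dist(a: int, b: int, L: int) -> int:
    d = abs(a - b) % L
    return min(d, L - d)


def boundary_deviation_table(results: Sequence[CorrespondenceResult],
                             L: int,
                             class_map: Mapping[str, str] | None = None,
                             thresholds: Sequence[int] = (5, 10, 25, 50, 70, 100),
                             ) -> dict[str, dict[int, float | None]]:
    """Percentage of corresponding pairs whose start and end deviate by less
    than each threshold (circular distance), per gene class. Classes without
    pairs report None."""
    from .formats import load_gene_classes
    class_map = class_map or load_gene_classes()
    pairs_by_class: dict[str, list[tuple[int, int]]] = {}
    for res in results:
        if res.klass not in ("equal", "strand_difference"):
            continue
        ref = res.reference
        dev = (_circ_dist(res.prediction.start, ref.n, L),
               _circ_dist(res.prediction.end, ref.m, L))
        cls = gene_class(res.prediction.gene, class_map)
        for key in (cls, "all"):
            pairs_by_class.setdefault(key, []).append(dev)
    table: dict[str, dict[int, float | None]] = {}
    for cls in sorted(set(pairs_by_class) | {"protein", "tRNA", "rRNA", "all"}):
        devs = pairs_by_class.get(cls, [])
        row: dict[int, float | None] = {}
        for thr in thresholds:
            if not devs:
                row[thr] = None
            else:
                ok = sum(1 for ds, de in devs if ds < thr and de < thr)
                row[thr] = 100.0 * ok / len(devs)
        table[cls] = row
    return table


# --------------------------------------------------------------------------
# (k+1)-mer randomization experiment.

@dataclass
class KmerExperimentResult:
    k: int
    w_min: int
    values: list[float]     # per-replicate hit fractions
    mean: float
    sd: float
    size_St: int
    size_Sr: int
    n_genomes: int


def true_kmer_multiset(genomes: Sequence[Genome], k: int) -> Counter:
    """S_t: multiset of all (k+1)-mers of the genomes (circular rule
    applied)."""
    St: Counter = Counter()
    for g in genomes:
        St.update(mer for mer, _ in enumerate_kp1mers(g, k))
    return St


def rhit_experiment(genomes: Sequence[Genome], k: int,
                    w_mins: Sequence[int] = (1, 2, 3, 4),
                    replicates: int = 20,
                    seed: int = 0) -> list[KmerExperimentResult]:
    """Shuffle-and-requery experiment: the genomes' concatenation is
    shuffled, split back into chunks of the original lengths, and the
    fraction of random (k+1)-mers found in the true multiset at least
    w_min times is averaged over replicates.

    Each chunk of length L contributes its first L-(k+1) windows, so the
    random multiset size satisfies |S_r| = |S_t| - N(k+1) exactly when all
    genomes are circular.
    """
    lengths = [len(g) for g in genomes]
    if min(lengths) < k + 2:
        raise ValueError("k+1 exceeds a genome length")
    St = true_kmer_multiset(genomes, k)
    size_St = sum(St.values())
    concat = "".join(g.sequence for g in genomes)
    arr = np.frombuffer(concat.encode(), dtype="S1")
    rng = np.random.default_rng(seed)
    per_wmin: dict[int, list[float]] = {w: [] for w in w_mins}
    size_Sr = None
    for _ in range(replicates):
        shuffled = rng.permutation(arr).tobytes().decode()
        Sr: Counter = Counter()
        off = 0
        for L in lengths:
            chunk = shuffled[off:off + L]
            off += L
            for s in range(L - (k + 1)):
                Sr[chunk[s:s + k + 1]] += 1
        size_Sr = sum(Sr.values())
        for w in w_mins:
            hits = sum(cnt for mer, cnt in Sr.items() if St.get(mer, 0) >= w)
            per_wmin[w].append(hits / size_Sr)
    out = []
    for w in w_mins:
        vals = per_wmin[w]
        out.append(KmerExperimentResult(
            k, w, vals, float(np.mean(vals)),
            float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            size_St, size_Sr, len(genomes)))
    return out


def unique_kmer_stats(genomes: Sequence[Genome], k: int,
                      ) -> tuple[int, float, float]:
    """(distinct (k+1)-mers in S_t, their fraction of all 4^(k+1) possible
    mers, fraction of S_t's elements occurring exactly once)."""
    St = true_kmer_multiset(genomes, k)
    distinct = len(St)
    total = sum(St.values())
    n_unique = sum(1 for c in St.values() if c == 1)
    return distinct, distinct / 4 ** (k + 1), n_unique / total
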