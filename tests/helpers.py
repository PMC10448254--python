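"""Independent oracles used by the test suite (kept deliberately separate
from the library's code paths)."""

from __future__ import annotations

import random

NEG = float("-inf")


def global_affine(a: str, b: str, match: int = 1, mism: int = -2,
                  gopen: int = -2, gext: int = -2) -> float:
    """Global alignment score of the full strings; a gap of length l costs
    gopen + l*gext."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gopen + gext * i
    for j in range(1, m + 1):
        Y[0][j] = gopen + gext * j
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mism
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gopen + gext, X[i - 1][j] + gext,
                          Y[i - 1][j] + gopen + gext)
            Y[i][j] = max(M[i][j - 1] + gopen + gext, Y[i][j - 1] + gext,
                          X[i][j - 1] + gopen + gext)
    return max(M[n][m], X[n][m], Y[n][m])


def brute_local_score(a: str, b: str, **kw) -> float:
    """Exhaustive local alignment: best global score over all substring
    pairs (empty alignment scores 0)."""
    best = 0.0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            sub_a = a[i0:i1]
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    best = max(best, global_affine(sub_a, b[j0:j1], **kw))
    return best


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate(seq: str, positions: list[int], rng: random.Random) -> str:
    """Substitute the (0-based) positions with a different base."""
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([c for c in "ACGT" if c != out[p]])
    return "".join(out)
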