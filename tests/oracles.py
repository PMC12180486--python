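"""Independent brute-force oracles used across the test suite.

These deliberately avoid dynamic programming and graph shortcuts: global
alignment scores come from explicit enumeration of every alignment path,
local scores from maximizing the global enumerator over all substring
pairs, and DBSCAN labels from an explicit neighborhood-graph construction.
They are only feasible at tiny sizes, which is the point.
"""

from __future__ import annotations

import sys
from typing import Dict, List, Sequence, Tuple

import numpy as np

sys.setrecursionlimit(100000)


def enumerate_global_score(a: str, b: str, match: int, mismatch: int,
                           gap: int) -> int:
    """Best global alignment score by exhaustive path enumeration.

    Linear gap model: every gap column costs ``gap``.  Exponential in the
    input lengths; intended for sequences of length <= 6.
    """
    best = [-(10**9)]

    def walk(i: int, j: int, score: int) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            walk(i + 1, j + 1, score + s)
        if i < len(a):
            walk(i + 1, j, score + gap)
        if j < len(b):
            walk(i, j + 1, score + gap)

    walk(0, 0, 0)
    return best[0]


def enumerate_local_score(a: str, b: str, match: int, mismatch: int,
                          gap: int) -> int:
    """Best local score: max over all substring pairs, floored at zero."""
    best = 0
    for i in range(len(a)):
        for k in range(i + 1, len(a) + 1):
            for j in range(len(b)):
                for l in range(j + 1, len(b) + 1):
                    s = enumerate_global_score(a[i:k], b[j:l],
                                               match, mismatch, gap)
                    if s > best:
                        best = s
    return best


def brute_force_dbscan(vectors: np.ndarray, eps: float,
                       min_samples: int) -> np.ndarray:
    """Textbook DBSCAN over the explicit cosine-distance neighborhood graph."""
    v = np.asarray(vectors, dtype=np.float64)
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    dist = 1.0 - v @ v.T
    n = len(v)
    neighbors = [np.nonzero(dist[i] <= eps)[0].tolist() for i in range(n)]
    core = [len(nb) >= min_samples for nb in neighbors]
    labels = np.full(n, -1, dtype=np.int64)
    cluster = -1
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        cluster += 1
        labels[i] = cluster
        frontier = list(neighbors[i])
        while frontier:
            j = frontier.pop()
            if labels[j] == -1:
                labels[j] = cluster
                if core[j]:
                    frontier.extend(neighbors[j])
    return labels


def canonical_relabel(labels: Sequence[int]) -> List[int]:
    """Rename cluster ids by first appearance; noise (-1) is preserved."""
    mapping: Dict[int, int] = {}
    out: List[int] = []
    for lab in labels:
        if lab == -1:
            out.append(-1)
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return out


def pairwise_identity_table(sequences: Dict[str, str],
                            aligner) -> Dict[Tuple[str, str], float]:
    """All-pairs identity using a supplied alignment callable."""
    out: Dict[Tuple[str, str], float] = {}
    ids = sorted(sequences)
    for i, x in enumerate(ids):
        for y in ids[i + 1:]:
            res = aligner(sequences[x], sequences[y])
            out[(x, y)] = out[(y, x)] = res.identity
    return out
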