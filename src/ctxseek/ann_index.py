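"""Hierarchical Navigable Small World (HNSW) index over cosine similarity.

A from-scratch implementation of the multi-layer proximity-graph algorithm:
node levels are drawn geometrically (floor(-ln(U) * level_mult)), insertion
descends greedily from the entry point and then runs an ef_construction
bounded best-first search per layer, and neighbors are chosen with the
standard pruning heuristic that prefers candidates closer to the new node
than to any already-selected neighbor.  All vectors are L2-normalized at
ingest, so cosine similarity is a plain inner product and "distance" below
means ``1 - cosine``.

Construction is single-threaded and seed-deterministic: the same data,
insertion order and seed always yield the identical graph.  An exact
brute-force scan is provided as the oracle for recall evaluation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .embedding import EmbeddingDatabase

DEFAULT_M = 16
DEFAULT_EF_CONSTRUCTION = 200
DEFAULT_EF_SEARCH = 128


@dataclass(frozen=True)
class SearchHit:
    subject_id: str
    similarity: float
    rank: int


def _rank_hits(ids: Sequence[str], sims: Sequence[float], k: int) -> List[SearchHit]:
    """Sort by descending similarity, ties by lexicographic id; assign ranks."""
    order = sorted(range(len(ids)), key=lambda i: (-sims[i], ids[i]))[:k]
    return [SearchHit(subject_id=ids[i], similarity=float(sims[i]), rank=r + 1)
            for r, i in enumerate(order)]


def _check_normalized_db(db: EmbeddingDatabase) -> None:
    norms = np.linalg.norm(db.matrix, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("index requires L2-normalized vectors")


class HNSWIndex:
    """Layered proximity graph supporting approximate k-NN under cosine."""

    def __init__(self, db: EmbeddingDatabase, M: int = DEFAULT_M,
                 ef_construction: int = DEFAULT_EF_CONSTRUCTION,
                 level_mult: Optional[float] = None, seed: int = 0):
        if len(db) == 0:
            raise ValueError("cannot index an empty database")
        _check_normalized_db(db)
        self.db = db
        self.M = M
        self.M0 = 2 * M
        self.ef_construction = ef_construction
        self.level_mult = level_mult if level_mult is not None else 1.0 / math.log(M)
        self.seed = seed
        n = len(db)
        self.levels = np.zeros(n, dtype=np.int64)
        # layers[l][node] -> list of neighbor node indices
        self.layers: List[Dict[int, List[int]]] = []
        self.entry_point = -1
        self.max_level = -1
        self._vectors = db.matrix
        rng = np.random.default_rng(seed)
        for i in range(n):
            u = rng.random()
            while u <= 0.0:  # guard log(0)
                u = rng.random()
            level = int(math.floor(-math.log(u) * self.level_mult))
            self._insert(i, level)

    # -- distances ---------------------------------------------------------
    def _dist(self, q: np.ndarray, node: int) -> float:
        return 1.0 - float(self._vectors[node] @ q)

    def _dists(self, q: np.ndarray, nodes: List[int]) -> np.ndarray:
        return 1.0 - self._vectors[np.asarray(nodes)] @ q

    # -- graph search ------------------------------------------------------
    def _search_layer(self, q: np.ndarray, entry: List[Tuple[float, int]],
                      ef: int, layer: int) -> List[Tuple[float, int]]:
        """Bounded best-first search; returns up to ef (dist, node) pairs."""
        import heapq
        links = self.layers[layer]
        visited = {node for _, node in entry}
        candidates = list(entry)  # min-heap by dist
        heapq.heapify(candidates)
        results = [(-d, node) for d, node in entry]  # max-heap via negation
        heapq.heapify(results)
        while len(results) > ef:
            heapq.heappop(results)
        while candidates:
            d_c, c = heapq.heappop(candidates)
            if d_c > -results[0][0] and len(results) >= ef:
                break
            fresh = [e for e in links.get(c, ()) if e not in visited]
            if not fresh:
                continue
            visited.update(fresh)
            dists = self._dists(q, fresh)
            worst = -results[0][0]
            for e, d in zip(fresh, dists):
                if len(results) < ef or d < worst:
                    heapq.heappush(candidates, (d, e))
                    heapq.heappush(results, (-d, e))
                    if len(results) > ef:
                        heapq.heappop(results)
                    worst = -results[0][0]
        return sorted((-nd, node) for nd, node in results)

    def _greedy_descend(self, q: np.ndarray, node: int, d: float,
                        layer: int) -> Tuple[float, int]:
        links = self.layers[layer]
        improved = True
        while improved:
            improved = False
            nbrs = links.get(node, ())
            if not nbrs:
                break
            dists = self._dists(q, list(nbrs))
            j = int(np.argmin(dists))
            if dists[j] < d:
                d, node = float(dists[j]), nbrs[j]
                improved = True
        return d, node

    def _select_neighbors(self, candidates: List[Tuple[float, int]],
                          M: int) -> List[int]:
        """Pruning heuristic: keep candidates closer to the target than to
        any already-selected neighbor."""
        selected: List[int] = []
        for d, e in sorted(candidates):
            if len(selected) == M:
                break
            if not selected:
                selected.append(e)
                continue
            d_to_sel = 1.0 - self._vectors[np.asarray(selected)] @ self._vectors[e]
            if np.all(d_to_sel > d):
                selected.append(e)
        if len(selected) < M:  # backfill with pruned candidates, nearest first
            chosen = set(selected)
            for d, e in sorted(candidates):
                if len(selected) == M:
                    break
                if e not in chosen:
                    selected.append(e)
                    chosen.add(e)
        return selected

    # -- insertion ---------------------------------------------------------
    def _insert(self, i: int, level: int) -> None:
        self.levels[i] = level
        while len(self.layers) <= level:
            self.layers.append({})
        for l in range(level + 1):
            self.layers[l][i] = []
        if self.entry_point < 0:
            self.entry_point = i
            self.max_level = level
            return
        q = self._vectors[i]
        node = self.entry_point
        d = self._dist(q, node)
        for l in range(self.max_level, level, -1):
            d, node = self._greedy_descend(q, node, d, l)
        entry = [(d, node)]
        for l in range(min(level, self.max_level), -1, -1):
            cands = self._search_layer(q, entry, self.ef_construction, l)
            mmax = self.M0 if l == 0 else self.M
            selected = self._select_neighbors(cands, self.M)
            self.layers[l][i] = list(selected)
            for e in selected:
                elinks = self.layers[l][e]
                elinks.append(i)
                if len(elinks) > mmax:
                    ev = self._vectors[e]
                    dists = 1.0 - self._vectors[np.asarray(elinks)] @ ev
                    pruned = self._select_neighbors(
                        list(zip(dists.tolist(), elinks)), mmax)
                    self.layers[l][e] = pruned
            entry = cands
        if level > self.max_level:
            self.entry_point = i
            self.max_level = level

    # -- queries -----------------------------------------------------------
    def search(self, query: np.ndarray, k: int,
               ef_search: int = DEFAULT_EF_SEARCH) -> List[SearchHit]:
        return hnsw_search(self, query, k, ef_search)

    # -- persistence -------------------------------------------------------
    def save(self, prefix) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        layer_blobs = {}
        for l, links in enumerate(self.layers):
            nodes = sorted(links)
            indptr = np.zeros(len(nodes) + 1, dtype=np.int64)
            flat: List[int] = []
            for row, node in enumerate(nodes):
                flat.extend(links[node])
                indptr[row + 1] = len(flat)
            layer_blobs[f"layer{l}_nodes"] = np.asarray(nodes, dtype=np.int64)
            layer_blobs[f"layer{l}_indptr"] = indptr
            layer_blobs[f"layer{l}_flat"] = np.asarray(flat, dtype=np.int64)
        np.savez_compressed(f"{prefix}.graph.npz", levels=self.levels,
                            vectors=self._vectors, **layer_blobs)
        with open(f"{prefix}.json", "w") as fh:
            json.dump({
                "M": self.M, "ef_construction": self.ef_construction,
                "level_mult": self.level_mult, "seed": self.seed,
                "entry_point": self.entry_point, "max_level": self.max_level,
                "n_layers": len(self.layers), "ids": list(self.db.ids),
            }, fh)

    @classmethod
    def load(cls, prefix) -> "HNSWIndex":
        prefix = Path(prefix)
        with open(f"{prefix}.json") as fh:
            header = json.load(fh)
        blobs = np.load(f"{prefix}.graph.npz")
        db = EmbeddingDatabase(ids=header["ids"], matrix=blobs["vectors"])
        obj = cls.__new__(cls)
        obj.db = db
        obj.M = header["M"]
        obj.M0 = 2 * obj.M
        obj.ef_construction = header["ef_construction"]
        obj.level_mult = header["level_mult"]
        obj.seed = header["seed"]
        obj.entry_point = header["entry_point"]
        obj.max_level = header["max_level"]
        obj.levels = blobs["levels"]
        obj._vectors = db.matrix
        obj.layers = []
        for l in range(header["n_layers"]):
            nodes = blobs[f"layer{l}_nodes"]
            indptr = blobs[f"layer{l}_indptr"]
            flat = blobs[f"layer{l}_flat"]
            obj.layers.append({
                int(node): flat[indptr[r]:indptr[r + 1]].tolist()
                for r, node in enumerate(nodes)
            })
        return obj


def build_hnsw(db: EmbeddingDatabase, M: int = DEFAULT_M,
               ef_construction: int = DEFAULT_EF_CONSTRUCTION,
               seed: int = 0) -> HNSWIndex:
    """Build the layered graph by sequential insertion in database order."""
    return HNSWIndex(db, M=M, ef_construction=ef_construction, seed=seed)


def _check_query(index_dim: int, query: np.ndarray) -> np.ndarray:
    q = np.asarray(query, dtype=np.float64).ravel()
    if q.shape[0] != index_dim:
        raise ValueError(f"query dim {q.shape[0]} != index dim {index_dim}")
    n = np.linalg.norm(q)
    if abs(n - 1.0) > 1e-6:
        raise ValueError("query vector must be L2-normalized")
    return q


def hnsw_search(index: HNSWIndex, query: np.ndarray, k: int,
                ef_search: int = DEFAULT_EF_SEARCH) -> List[SearchHit]:
    """Approximate top-k by cosine; ef_search bounds the layer-0 beam."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if ef_search < k:
        ef_search = k
    q = _check_query(index.db.dim, query)
    node = index.entry_point
    d = index._dist(q, node)
    for l in range(index.max_level, 0, -1):
        d, node = index._greedy_descend(q, node, d, l)
    results = index._search_layer(q, [(d, node)], ef_search, 0)
    ids = [index.db.ids[n] for _, n in results]
    sims = [1.0 - dd for dd, _ in results]
    return _rank_hits(ids, sims, k)


def brute_force_search(db: EmbeddingDatabase, query: np.ndarray,
                       k: int) -> List[SearchHit]:
    """Exact top-k by cosine (O(ND) scan); the oracle for recall evaluation."""
    if k < 1:
        raise ValueError("k must be >= 1")
    q = _check_query(db.dim, query)
    sims = db.matrix @ q
    return _rank_hits(db.ids, sims.tolist(), k)


def recall_at_k(approx_hits: Sequence[SearchHit],
                exact_hits: Sequence[SearchHit], k: int) -> float:
    """|approx top-k intersect exact top-k| / k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    a = {h.subject_id for h in approx_hits[:k]}
    e = {h.subject_id for h in exact_hits[:k]}
    return len(a & e) / k


def hits_tsv(query_id: str, hits: Sequence[SearchHit]) -> str:
    lines = ["query_id\tsubject_id\trank\tsimilarity"]
    for h in hits:
        lines.append(f"{query_id}\t{h.subject_id}\t{h.rank}\t{h.similarity:.6f}")
    return "\n".join(lines) + "\n"


def audit_structure(index: HNSWIndex) -> None:
    """Raise AssertionError if any structural invariant is violated."""
    n = len(index.db)
    for node in range(n):
        level = int(index.levels[node])
        for l in range(level + 1):
            assert node in index.layers[l], (node, l)
    for l, links in enumerate(index.layers):
        cap = index.M0 if l == 0 else index.M
        for node, nbrs in links.items():
            assert len(nbrs) <= cap, (l, node, len(nbrs))
            assert node not in nbrs
            assert len(set(nbrs)) == len(nbrs)
            for e in nbrs:
                assert index.levels[e] >= l
    assert index.levels[index.entry_point] == index.max_level
    assert int(index.levels.max()) == index.max_level
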