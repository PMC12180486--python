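"""End-to-end query pipeline and genomic-context analytics.

``search_database`` runs embed -> (optional) project -> normalize -> search
and returns ranked hits.  On top of that sit the context analytics: density
clustering of retrieved neighborhood embeddings to find co-occurring gene
families, the context-homology statistic used to score whether a retrieval
shares its genomic neighborhood with the query, and nearest-annotated-
embedding annotation transfer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.cluster import DBSCAN

from .alignment import AlignmentResult, ScoringScheme, smith_waterman
from .ann_index import HNSWIndex, SearchHit, brute_force_search, hnsw_search
from .contrastive import ProjectionModel
from .embedding import EmbeddingDatabase, EmbeddingVector, SequenceEmbedder
from .genome_io import Neighborhood, ProteinRecord

logger = logging.getLogger(__name__)

DEFAULT_K = 100  # hits returned per query
DEFAULT_EPS = 0.01  # cosine-distance radius for co-occurrence clustering


@dataclass
class QueryResult:
    query_id: str
    hits: List[SearchHit]
    alignments: Dict[str, AlignmentResult] = field(default_factory=dict)
    neighborhoods: Dict[str, Neighborhood] = field(default_factory=dict)
    annotations: Dict[str, Tuple[str, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "query_id": self.query_id,
            "hits": [
                {
                    "subject_id": h.subject_id,
                    "rank": h.rank,
                    "similarity": round(h.similarity, 6),
                    "identity": round(self.alignments[h.subject_id].identity, 4)
                    if h.subject_id in self.alignments else None,
                    "query_coverage": round(
                        self.alignments[h.subject_id].query_coverage, 4)
                    if h.subject_id in self.alignments else None,
                    "subject_coverage": round(
                        self.alignments[h.subject_id].subject_coverage, 4)
                    if h.subject_id in self.alignments else None,
                    "neighborhood": list(
                        self.neighborhoods[h.subject_id].member_protein_ids)
                    if h.subject_id in self.neighborhoods else None,
                    "annotation": self.annotations.get(h.subject_id),
                }
                for h in self.hits
            ],
        }
        return json.dumps(payload, indent=2)


@dataclass
class CooccurrenceCluster:
    member_protein_ids: frozenset
    n_contigs: int
    representative_id: str


def search_database(query: Union[ProteinRecord, EmbeddingVector, np.ndarray],
                    db: EmbeddingDatabase,
                    index: Optional[HNSWIndex] = None,
                    model: Optional[ProjectionModel] = None,
                    k: int = DEFAULT_K,
                    exclude_self: bool = True,
                    embedder: Optional[Callable] = None,
                    ef_search: int = 128) -> QueryResult:
    """Embed (if needed), project (if a model is given), and search.

    When the query id exists in the database and ``exclude_self`` is set,
    the identical-id hit is removed from the ranking.
    """
    if isinstance(query, ProteinRecord):
        embedder = embedder or SequenceEmbedder(dim=db.dim if model is None
                                                else model.d_in)
        vec = embedder(query).values
        query_id = query.id
    elif isinstance(query, EmbeddingVector):
        vec, query_id = query.values, "query"
    else:
        vec, query_id = np.asarray(query, dtype=np.float64), "query"
    if model is not None:
        if vec.shape[0] != model.d_in:
            raise ValueError(
                f"projection stage: query dim {vec.shape[0]} != {model.d_in}")
        vec = vec @ model.weights
    norm = np.linalg.norm(vec)
    if norm == 0:
        raise ValueError("query embedded to a zero vector")
    vec = vec / norm
    if vec.shape[0] != db.dim:
        raise ValueError(f"search stage: query dim {vec.shape[0]} != db dim "
                         f"{db.dim}")
    extra = 1 if exclude_self and query_id in db else 0
    if index is not None:
        hits = hnsw_search(index, vec, min(k + extra, len(db)),
                           ef_search=max(ef_search, k + extra))
    else:
        hits = brute_force_search(db, vec, min(k + extra, len(db)))
    if extra:
        hits = [h for h in hits if h.subject_id != query_id]
    hits = [SearchHit(h.subject_id, h.similarity, r + 1)
            for r, h in enumerate(hits[:k])]
    return QueryResult(query_id=query_id, hits=hits)


def attach_alignments(result: QueryResult, query_record: ProteinRecord,
                      records: Dict[str, ProteinRecord],
                      scoring: Optional[ScoringScheme] = None) -> QueryResult:
    for h in result.hits:
        if h.subject_id in records:
            result.alignments[h.subject_id] = smith_waterman(
                query_record.sequence, records[h.subject_id].sequence, scoring)
    return result


def dbscan_cosine(vectors: np.ndarray, eps: float = DEFAULT_EPS,
                  min_samples: int = 2) -> np.ndarray:
    """DBSCAN over cosine distance (1 - cosine similarity); -1 marks noise.

    Labels are deterministic for a fixed input order (cluster ids follow
    the order in which core points are first visited).
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.size == 0:
        return np.empty(0, dtype=np.int64)
    if eps <= 0:
        raise ValueError("eps must be positive")
    labels = DBSCAN(eps=eps, min_samples=min_samples,
                    metric="cosine").fit_predict(vectors)
    return labels.astype(np.int64)


def cooccurring_genes(result: QueryResult, db: EmbeddingDatabase,
                      records: Optional[Dict[str, ProteinRecord]] = None,
                      embedder: Optional[Callable] = None,
                      top_n: int = 7, eps: float = DEFAULT_EPS,
                      min_samples: int = 2) -> List[CooccurrenceCluster]:
    """Rank gene families recurring in the retrieved genomic contexts.

    Pools all non-focal context proteins across the hits' neighborhoods,
    clusters their embeddings with cosine DBSCAN, and ranks clusters by the
    number of distinct contigs contributing at least one member (ties by
    cluster size, then representative id).
    """
    pool_ids: List[str] = []
    pool_contigs: List[str] = []
    for h in result.hits:
        nb = result.neighborhoods.get(h.subject_id)
        if nb is None:
            continue
        for pid in nb.context_protein_ids:
            pool_ids.append(pid)
            pool_contigs.append(nb.contig_id)
    if not pool_ids:
        logger.warning("no context metadata attached to hits; "
                       "co-occurrence ranking is empty")
        return []
    rows = []
    for pid in pool_ids:
        if pid in db:
            rows.append(db.row(pid))
        elif records is not None and pid in records:
            emb = embedder or SequenceEmbedder(dim=db.dim)
            rows.append(emb(records[pid]).values)
        else:
            raise KeyError(f"context protein {pid!r} has no embedding")
    mat = np.stack(rows)
    labels = dbscan_cosine(mat, eps=eps, min_samples=min_samples)
    clusters: List[CooccurrenceCluster] = []
    for lab in sorted(set(labels) - {-1}):
        mask = labels == lab
        members = frozenset(pid for pid, m in zip(pool_ids, mask) if m)
        contigs = {c for c, m in zip(pool_contigs, mask) if m}
        sub = mat[mask]
        mean_sim = (sub @ sub.T).mean(axis=1)
        member_list = [pid for pid, m in zip(pool_ids, mask) if m]
        best = sorted(zip(-mean_sim, member_list))[0][1]
        clusters.append(CooccurrenceCluster(
            member_protein_ids=members, n_contigs=len(contigs),
            representative_id=best))
    clusters.sort(key=lambda c: (-c.n_contigs, -len(c.member_protein_ids),
                                 c.representative_id))
    return clusters[:top_n]


def context_homology_fraction(query_nb: Neighborhood, hit_nb: Neighborhood,
                              records: Dict[str, ProteinRecord],
                              id_thresh: float = 0.50,
                              cov_thresh: float = 0.50,
                              denominator: str = "available",
                              scoring: Optional[ScoringScheme] = None) -> float:
    """Fraction of the hit's context genes with a homolog in the query's.

    Matching is one-to-one greedy by descending local-alignment identity so
    a single conserved query gene cannot match many hit-side paralogs.
    ``denominator="available"`` divides by the hit context size (edge genes
    are not penalized); ``"ten"`` always divides by the full window of 10.
    """
    q_ids = [p for p in query_nb.context_protein_ids if p in records]
    h_ids = [p for p in hit_nb.context_protein_ids if p in records]
    if not q_ids or not h_ids:
        logger.warning("empty context for %s vs %s",
                       query_nb.focal_protein_id, hit_nb.focal_protein_id)
        return 0.0
    candidates = []
    for hi, hp in enumerate(h_ids):
        for qi, qp in enumerate(q_ids):
            res = smith_waterman(records[hp].sequence, records[qp].sequence,
                                 scoring)
            if (res.identity > id_thresh and res.query_coverage > cov_thresh
                    and res.subject_coverage > cov_thresh):
                candidates.append((-res.identity, hi, qi))
    candidates.sort()
    used_h: set = set()
    used_q: set = set()
    matched = 0
    for _, hi, qi in candidates:
        if hi in used_h or qi in used_q:
            continue
        used_h.add(hi)
        used_q.add(qi)
        matched += 1
    if denominator == "available":
        denom = len(h_ids)
    elif denominator == "ten":
        denom = 10
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return matched / denom


def is_correct_context_retrieval(fraction: float,
                                 threshold: float = 0.7) -> bool:
    """Correct retrieval iff strictly more than 7 of 10 context genes match."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    return fraction > threshold


def predict_annotation(query_vec: Union[EmbeddingVector, np.ndarray],
                       annotated_db: EmbeddingDatabase) -> Tuple[str, float]:
    """Annotation of the nearest annotated embedding (ties by smaller id)."""
    annotated = [(pid, meta["annotation"])
                 for pid, meta in annotated_db.metadata.items()
                 if "annotation" in meta]
    if not annotated:
        raise ValueError("annotated database carries no annotations")
    vec = query_vec.values if isinstance(query_vec, EmbeddingVector) \
        else np.asarray(query_vec, dtype=np.float64)
    vec = vec / np.linalg.norm(vec)
    best: Optional[Tuple[float, str, str]] = None
    for pid, text in annotated:
        sim = float(annotated_db.row(pid) @ vec)
        key = (-sim, pid)
        if best is None or key < (best[0], best[1]):
            best = (-sim, pid, text)
    return best[2], -best[0]


def neighborhood_bed_rows(nb: Neighborhood, contig_genes) -> List[str]:
    """BED-like TSV rows (contig, start, end, strand, protein_id, role)."""
    by_id = {g.protein_id: g for g in contig_genes}
    rows = []
    for pid in nb.member_protein_ids:
        g = by_id[pid]
        role = "focal" if pid == nb.focal_protein_id else "context"
        rows.append(f"{g.contig_id}\t{g.start}\t{g.end}\t{g.strand}\t{pid}\t{role}")
    return rows
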