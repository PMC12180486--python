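"""Retrieval benchmarks: sequence recall, genomic-context correctness,
family/structure cluster retrieval, paired homolog matching, and the
out-of-distribution train/held-out split.

All benchmarks are procedures over any embedder/index backend and report a
``BenchmarkReport`` whose summary metrics are recomputable from its
per-query records.  Search truth for the sequence benchmark is defined by
the in-repo local aligner (best nonself hit above identity/coverage
thresholds), standing in for an alignment-search baseline at the same
thresholds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alignment import ScoringScheme, smith_waterman
from .ann_index import HNSWIndex, brute_force_search, hnsw_search
from .contrastive import TrainConfig, train_projection, project
from .embedding import EmbeddingDatabase, SequenceEmbedder
from .genome_io import Neighborhood, ProteinRecord
from .search_context import (context_homology_fraction,
                             is_correct_context_retrieval, search_database)

logger = logging.getLogger(__name__)

DEFAULT_K_GRID = (1, 5, 10, 30, 100)


@dataclass
class BenchmarkReport:
    name: str
    per_query: List[dict]
    summary: Dict[str, float]
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"name": self.name, "summary": self.summary,
                           "config": self.config,
                           "per_query": self.per_query}, indent=2)

    def per_query_tsv(self) -> str:
        if not self.per_query:
            return ""
        cols = list(self.per_query[0])
        lines = ["\t".join(cols)]
        for row in self.per_query:
            lines.append("\t".join(str(row.get(c, "")) for c in cols))
        return "\n".join(lines) + "\n"


def _nonself_hits(query_id: str, vec: np.ndarray, db: EmbeddingDatabase,
                  index: Optional[HNSWIndex], k: int,
                  ef_search: int = 128):
    from .ann_index import SearchHit
    kk = min(k + 1, len(db))
    if index is not None:
        hits = hnsw_search(index, vec, kk, ef_search=max(ef_search, kk))
    else:
        hits = brute_force_search(db, vec, kk)
    kept = [h for h in hits if h.subject_id != query_id][:k]
    return [SearchHit(h.subject_id, h.similarity, r + 1)
            for r, h in enumerate(kept)]


def sequence_retrieval_benchmark(queries: Sequence[str],
                                 truth: Dict[str, str],
                                 db: EmbeddingDatabase,
                                 index: Optional[HNSWIndex] = None,
                                 K_grid: Sequence[int] = DEFAULT_K_GRID,
                                 ef_search: int = 128) -> BenchmarkReport:
    """recall@K: is the query's true best alignment hit within top-K nonself?"""
    for qid in queries:
        tgt = truth.get(qid)
        if tgt is None:
            continue
        if tgt not in db:
            raise KeyError(f"truth target {tgt!r} missing from database")
        if tgt == qid:
            raise ValueError(f"truth for {qid!r} is a self-hit")
    K_grid = sorted(K_grid)
    kmax = max(K_grid)
    per_query: List[dict] = []
    for qid in queries:
        if qid not in truth:
            continue
        hits = _nonself_hits(qid, db.row(qid), db, index, kmax, ef_search)
        rank = next((h.rank for h in hits if h.subject_id == truth[qid]), None)
        row = {"query_id": qid, "target_id": truth[qid],
               "rank_of_truth": rank if rank is not None else -1}
        for K in K_grid:
            row[f"recall@{K}"] = int(rank is not None and rank <= K)
        per_query.append(row)
    summary = {f"recall@{K}": float(np.mean([r[f"recall@{K}"] for r in per_query]))
               if per_query else 0.0 for K in K_grid}
    return BenchmarkReport(
        name="sequence_retrieval", per_query=per_query, summary=summary,
        config={"K_grid": list(K_grid), "n_queries": len(per_query),
                "backend": "hnsw" if index is not None else "brute_force"})


def make_alignment_truth(records: Sequence[ProteinRecord],
                         id_thresh: float = 0.75, cov_thresh: float = 0.70,
                         scoring: Optional[ScoringScheme] = None
                         ) -> Dict[str, str]:
    """Best nonself local-alignment hit per record, thresholded.

    Keeps records whose best nonself hit passes identity >= id_thresh with
    reciprocal coverage >= cov_thresh on both sides; others are dropped.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    truth: Dict[str, str] = {}
    n = len(records)
    best: List[Tuple[float, Optional[str]]] = [(-1.0, None)] * n
    for i in range(n):
        for j in range(i + 1, n):
            res = smith_waterman(records[i].sequence, records[j].sequence,
                                 scoring)
            if (res.identity >= id_thresh and res.query_coverage >= cov_thresh
                    and res.subject_coverage >= cov_thresh):
                if res.identity > best[i][0]:
                    best[i] = (res.identity, records[j].id)
                if res.identity > best[j][0]:
                    best[j] = (res.identity, records[i].id)
    for rec, (_ident, target) in zip(records, best):
        if target is not None:
            truth[rec.id] = target
    if not truth:
        logger.warning("no record pair passed the truth thresholds")
    return truth


def context_retrieval_benchmark(queries: Sequence[str],
                                db: EmbeddingDatabase,
                                neighborhoods: Dict[str, Neighborhood],
                                records: Dict[str, ProteinRecord],
                                index: Optional[HNSWIndex] = None,
                                top_m: int = 10,
                                id_thresh: float = 0.50,
                                cov_thresh: float = 0.50,
                                scoring: Optional[ScoringScheme] = None
                                ) -> BenchmarkReport:
    """Score whether top retrievals share the query's genomic neighborhood.

    Per query, each of the top_m nonself hits is scored with the
    context-homology fraction; a hit is correct when strictly more than 70%
    of its context genes have a homolog in the query's context.
    """
    missing = [q for q in queries if q not in neighborhoods]
    if missing:
        raise KeyError(f"no context metadata for query {missing[0]!r}")
    per_query: List[dict] = []
    for qid in queries:
        hits = _nonself_hits(qid, db.row(qid), db, index, top_m)
        n_correct = 0
        fractions = []
        for h in hits:
            hit_nb = neighborhoods.get(h.subject_id)
            if hit_nb is None:
                raise KeyError(f"no context metadata for hit {h.subject_id!r}")
            frac = context_homology_fraction(
                neighborhoods[qid], hit_nb, records,
                id_thresh=id_thresh, cov_thresh=cov_thresh, scoring=scoring)
            fractions.append(frac)
            if is_correct_context_retrieval(frac):
                n_correct += 1
        per_query.append({
            "query_id": qid, "n_hits": len(hits), "n_correct": n_correct,
            "mean_fraction": float(np.mean(fractions)) if fractions else 0.0,
        })
    total_hits = sum(r["n_hits"] for r in per_query)
    total_correct = sum(r["n_correct"] for r in per_query)
    summary = {
        "pairwise_correct": total_correct / total_hits if total_hits else 0.0,
        "queries_with_correct_hit": float(np.mean(
            [r["n_correct"] > 0 for r in per_query])) if per_query else 0.0,
    }
    return BenchmarkReport(
        name="context_retrieval", per_query=per_query, summary=summary,
        config={"top_m": top_m, "id_thresh": id_thresh,
                "cov_thresh": cov_thresh, "n_queries": len(per_query)})


def structure_cluster_benchmark(test_db: EmbeddingDatabase,
                                family_labels: Dict[str, str],
                                K_grid: Sequence[int] = (1, 5, 10, 30),
                                index: Optional[HNSWIndex] = None
                                ) -> BenchmarkReport:
    """hit@K: does any top-K nonself retrieval share the query's family?

    Queries whose family has no other member are excluded from the metric
    and counted separately.
    """
    unlabeled = [pid for pid in test_db.ids if pid not in family_labels]
    if unlabeled:
        raise KeyError(f"unlabeled entry {unlabeled[0]!r}")
    sizes: Dict[str, int] = {}
    for pid in test_db.ids:
        sizes[family_labels[pid]] = sizes.get(family_labels[pid], 0) + 1
    K_grid = sorted(K_grid)
    kmax = max(K_grid)
    per_query: List[dict] = []
    n_excluded = 0
    for qid in test_db.ids:
        fam = family_labels[qid]
        if sizes[fam] < 2:
            n_excluded += 1
            continue
        hits = _nonself_hits(qid, test_db.row(qid), test_db, index, kmax)
        first_match = next((h.rank for h in hits
                            if family_labels[h.subject_id] == fam), None)
        row = {"query_id": qid, "family": fam,
               "rank_of_first_match": first_match if first_match else -1}
        for K in K_grid:
            row[f"hit@{K}"] = int(first_match is not None and first_match <= K)
        per_query.append(row)
    summary = {f"hit@{K}": float(np.mean([r[f"hit@{K}"] for r in per_query]))
               if per_query else 0.0 for K in K_grid}
    summary["excluded_singleton_queries"] = float(n_excluded)
    return BenchmarkReport(
        name="structure_cluster", per_query=per_query, summary=summary,
        config={"K_grid": list(K_grid), "n_queries": len(per_query),
                "n_excluded": n_excluded})


def homolog_matching_benchmark(set_a: EmbeddingDatabase,
                               set_b: EmbeddingDatabase,
                               pairs: Dict[str, str],
                               index_b: Optional[HNSWIndex] = None
                               ) -> BenchmarkReport:
    """Top-1 accuracy of matching each query to its paired homolog.

    Queries from set_a search set_b; a query scores when its rank-1 hit is
    exactly its designated partner.
    """
    targets = list(pairs.values())
    if len(set(pairs)) != len(pairs) or len(set(targets)) != len(targets):
        raise ValueError("pairs must be a bijection between id subsets")
    for a, b in pairs.items():
        if a not in set_a:
            raise KeyError(f"pair query {a!r} missing from set_a")
        if b not in set_b:
            raise KeyError(f"pair target {b!r} missing from set_b")
    per_query: List[dict] = []
    for a, b in pairs.items():
        if index_b is not None:
            hits = hnsw_search(index_b, set_a.row(a), 1)
        else:
            hits = brute_force_search(set_b, set_a.row(a), 1)
        top = hits[0].subject_id
        per_query.append({"query_id": a, "target_id": b, "top_hit": top,
                          "correct": int(top == b)})
    summary = {"accuracy": float(np.mean([r["correct"] for r in per_query]))}
    return BenchmarkReport(
        name="homolog_matching", per_query=per_query, summary=summary,
        config={"n_pairs": len(pairs)})


def ood_retrieval_benchmark(train_records: Sequence[ProteinRecord],
                            train_labels: Dict[str, str],
                            heldout_records: Sequence[ProteinRecord],
                            heldout_labels: Dict[str, str],
                            embedder: Optional[Callable] = None,
                            train_config: Optional[TrainConfig] = None,
                            d_out: Optional[int] = None,
                            K_grid: Sequence[int] = (1, 5, 10),
                            truth_id_thresh: float = 0.5,
                            truth_cov_thresh: float = 0.5
                            ) -> BenchmarkReport:
    """Train the projection on train families only; compare recall on
    in-distribution vs held-out query sets.

    The family partition must be disjoint.  Truth for each set is its best
    nonself alignment hit at the given thresholds.
    """
    if not heldout_records:
        raise ValueError("held-out set is empty")
    train_fams = set(train_labels.values())
    heldout_fams = set(heldout_labels.values())
    if train_fams & heldout_fams:
        raise ValueError(f"family partition overlaps: "
                         f"{sorted(train_fams & heldout_fams)[:3]}")
    embedder = embedder or SequenceEmbedder()
    db_train = EmbeddingDatabase.from_records(train_records, embedder)
    db_held = EmbeddingDatabase.from_records(heldout_records, embedder)
    model, _trace = train_projection(db_train, train_labels,
                                     train_config, d_out=d_out)
    proj_train = project(model, db_train)
    proj_held = project(model, db_held)
    reports = {}
    for tag, recs, proj in (("in_distribution", train_records, proj_train),
                            ("held_out", heldout_records, proj_held)):
        truth = make_alignment_truth(list(recs), truth_id_thresh,
                                     truth_cov_thresh)
        reports[tag] = sequence_retrieval_benchmark(
            [r.id for r in recs], truth, proj, index=None, K_grid=K_grid)
    summary: Dict[str, float] = {}
    for K in sorted(K_grid):
        rid = reports["in_distribution"].summary[f"recall@{K}"]
        rood = reports["held_out"].summary[f"recall@{K}"]
        summary[f"in_distribution_recall@{K}"] = rid
        summary[f"held_out_recall@{K}"] = rood
        summary[f"recall_difference@{K}"] = rid - rood
    per_query = ([dict(r, split="in_distribution")
                  for r in reports["in_distribution"].per_query]
                 + [dict(r, split="held_out")
                    for r in reports["held_out"].per_query])
    return BenchmarkReport(
        name="ood_retrieval", per_query=per_query, summary=summary,
        config={"K_grid": list(sorted(K_grid)),
                "n_train": len(train_records),
                "n_held_out": len(heldout_records)})
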