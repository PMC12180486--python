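"""Pluggable protein embedders and the embedding database container.

Two deterministic built-in backends are provided:

* ``embed_sequence`` — a hashed k-mer composition vector (feature hashing
  with signed buckets), L2-normalized.  It is a fast, fully reproducible
  stand-in for a learned protein language model: identical sequences map to
  identical vectors, point mutations move the vector a little, unrelated
  sequences land nearly orthogonal in high dimension.
* ``embed_in_context`` — a convex blend of the focal embedding with the
  mean of its genomic-neighborhood embeddings, making "similar context =>
  similar embedding" literally true and testable.

Hashing uses BLAKE2b keyed by the seed, so embeddings are byte-identical
across runs and platforms (no runtime-salted builtin hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional

import numpy as np

from .genome_io import Neighborhood, ProteinRecord

logger = logging.getLogger(__name__)

DEFAULT_DIM = 256
DEFAULT_K = 3
DEFAULT_SEED = 17


@dataclass
class EmbeddingVector:
    values: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError("embedding must be a 1-D vector")
        if not np.all(np.isfinite(v)):
            raise ValueError("embedding contains NaN/Inf")
        if self.normalized and abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValueError("vector flagged normalized but norm != 1")
        self.values = v

    @property
    def dim(self) -> int:
        return self.values.shape[0]


def _l2norm(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def _hash_kmer(kmer: str, seed: int) -> tuple:
    """Stable (bucket, sign) pair for a k-mer via keyed BLAKE2b."""
    key = struct.pack("<q", seed)
    digest = hashlib.blake2b(kmer.encode("ascii"), digest_size=9, key=key).digest()
    bucket = int.from_bytes(digest[:8], "little")
    sign = 1.0 if digest[8] & 1 else -1.0
    return bucket, sign


def embed_sequence(record: ProteinRecord, dim: int = DEFAULT_DIM,
                   k: int = DEFAULT_K, seed: int = DEFAULT_SEED) -> EmbeddingVector:
    """Hashed k-mer composition embedding, L2-normalized.

    Sequences shorter than k are embedded over their longest available
    k-mer order, so every valid record embeds deterministically.
    """
    if dim < 8:
        raise ValueError("dim must be >= 8")
    seq = record.sequence
    k_eff = min(k, len(seq))
    v = np.zeros(dim, dtype=np.float64)
    for i in range(len(seq) - k_eff + 1):
        bucket, sign = _hash_kmer(seq[i:i + k_eff], seed)
        v[bucket % dim] += sign
    if not np.any(v):
        # pathological all-cancelling case; fall back to residue counts
        for i, c in enumerate(seq):
            bucket, sign = _hash_kmer(c + str(i % 7), seed + 1)
            v[bucket % dim] += sign
    return EmbeddingVector(_l2norm(v))


def embed_in_context(neighborhood: Neighborhood,
                     records: Dict[str, ProteinRecord], alpha: float = 0.5,
                     dim: int = DEFAULT_DIM, k: int = DEFAULT_K,
                     seed: int = DEFAULT_SEED) -> EmbeddingVector:
    """Blend the focal embedding with the mean of its neighbor embeddings.

    ``alpha`` is the context weight: 0 reduces exactly to the sequence
    embedding, 1 uses neighborhood composition alone.  A singleton
    neighborhood returns the focal embedding regardless of alpha.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    missing = [m for m in neighborhood.member_protein_ids if m not in records]
    if missing:
        raise KeyError(f"neighborhood member {missing[0]!r} not resolvable")
    focal = embed_sequence(records[neighborhood.focal_protein_id], dim, k, seed)
    context_ids = neighborhood.context_protein_ids
    if not context_ids:
        return focal
    neighbor_mat = np.stack([
        embed_sequence(records[m], dim, k, seed).values for m in context_ids
    ])
    blended = (1 - alpha) * focal.values + alpha * neighbor_mat.mean(axis=0)
    return EmbeddingVector(_l2norm(blended))


class SequenceEmbedder:
    """Embedder interface: ProteinRecord (+ optional Neighborhood) -> vector."""

    def __init__(self, dim: int = DEFAULT_DIM, k: int = DEFAULT_K,
                 seed: int = DEFAULT_SEED, alpha: float = 0.0):
        self.dim, self.k, self.seed, self.alpha = dim, k, seed, alpha

    def __call__(self, record: ProteinRecord,
                 neighborhood: Optional[Neighborhood] = None,
                 records: Optional[Dict[str, ProteinRecord]] = None
                 ) -> EmbeddingVector:
        if neighborhood is not None and self.alpha > 0:
            if records is None:
                raise ValueError("context embedding needs the record map")
            return embed_in_context(neighborhood, records, self.alpha,
                                    self.dim, self.k, self.seed)
        return embed_sequence(record, self.dim, self.k, self.seed)


@dataclass
class EmbeddingDatabase:
    """Id-indexed matrix of fixed-dimension L2-normalized vectors."""

    ids: List[str]
    matrix: np.ndarray
    metadata: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("row count does not match id count")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in embedding database")
        self._index = {pid: i for i, pid in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, pid: str) -> bool:
        return pid in self._index

    def row(self, pid: str) -> np.ndarray:
        return self.matrix[self._index[pid]]

    def index_of(self, pid: str) -> int:
        return self._index[pid]

    @classmethod
    def from_records(cls, records: Iterable[ProteinRecord],
                     embedder: Optional[Callable] = None,
                     neighborhoods: Optional[Dict[str, Neighborhood]] = None,
                     ) -> "EmbeddingDatabase":
        embedder = embedder or SequenceEmbedder()
        records = list(records)
        record_map = {r.id: r for r in records}
        rows, ids, meta = [], [], {}
        for r in records:
            nb = neighborhoods.get(r.id) if neighborhoods else None
            try:
                rows.append(embedder(r, nb, record_map).values)
            except TypeError:
                rows.append(embedder(r).values)
            ids.append(r.id)
            m: dict = {}
            if r.contig_id is not None:
                m["contig_id"] = r.contig_id
            if r.gene_index is not None:
                m["gene_index"] = r.gene_index
            if m:
                meta[r.id] = m
        return cls(ids=ids, matrix=np.stack(rows), metadata=meta)


def load_embeddings(path) -> EmbeddingDatabase:
    """Load a TSV of id + D float columns; vectors are L2-normalized on load."""
    ids: List[str] = []
    rows: List[np.ndarray] = []
    dim: Optional[int] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            pid, vals = parts[0], parts[1:]
            if dim is None:
                dim = len(vals)
                if dim == 0:
                    raise ValueError(f"{path}: row {lineno}: no float columns")
            elif len(vals) != dim:
                raise ValueError(
                    f"{path}: row {lineno}: expected {dim} values, got {len(vals)}")
            if pid in ids:
                raise ValueError(f"{path}: duplicate id {pid!r}")
            ids.append(pid)
            rows.append(np.array([float(v) for v in vals]))
    if not rows:
        raise ValueError(f"{path}: no embedding rows")
    mat = np.stack(rows)
    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"{path}: zero-norm embedding row")
    if np.any(np.abs(norms - 1.0) > 1e-3):
        logger.warning("%s: %d vectors deviated from unit norm; renormalized",
                       path, int(np.sum(np.abs(norms - 1.0) > 1e-3)))
    return EmbeddingDatabase(ids=ids, matrix=mat / norms[:, None])


def save_embeddings_tsv(db: EmbeddingDatabase, path,
                        precision: int = 8) -> None:
    with open(path, "w") as fh:
        for pid, row in zip(db.ids, db.matrix):
            fh.write(pid + "\t" + "\t".join(f"{x:.{precision}e}" for x in row)
                     + "\n")


def save_embeddings_binary(db: EmbeddingDatabase, prefix) -> None:
    """Two-file binary format: ids text + float32 matrix + JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.ids.txt", "w") as fh:
        fh.write("\n".join(db.ids) + "\n")
    db.matrix.astype(np.float32).tofile(f"{prefix}.mat.f32")
    with open(f"{prefix}.json", "w") as fh:
        json.dump({"dim": db.dim, "n": len(db), "normalized": True,
                   "dtype": "float32", "metadata": db.metadata}, fh)


def load_embeddings_binary(prefix) -> EmbeddingDatabase:
    prefix = Path(prefix)
    with open(f"{prefix}.json") as fh:
        header = json.load(fh)
    with open(f"{prefix}.ids.txt") as fh:
        ids = [l for l in fh.read().splitlines() if l]
    mat = np.fromfile(f"{prefix}.mat.f32", dtype=np.float32).reshape(
        header["n"], header["dim"]).astype(np.float64)
    norms = np.linalg.norm(mat, axis=1)
    return EmbeddingDatabase(ids=ids, matrix=mat / norms[:, None],
                             metadata=header.get("metadata", {}))
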