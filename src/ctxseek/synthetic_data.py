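"""Synthetic fixtures: mutated protein families, operon-bearing contigs,
and cluster-structured embedding spaces.

The generators emulate the statistical structure the retrieval benchmarks
assume: homolog families diverged by point substitutions and short indels,
contigs carrying a conserved multi-gene block (operon-like neighborhood)
embedded in shuffled background genes, and well-separated groups on the
unit sphere.  Substitutions draw the replacement uniformly from the 19
alternative residues; indels are single events with geometric lengths.
This is deliberately the simplest model with tunable identity — it is not
phylogenetically realistic (no rate heterogeneity, no tree structure).

Everything is driven by ``numpy.random.default_rng`` under explicit seeds
and reproduces byte-identical output for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .embedding import EmbeddingDatabase
from .genome_io import Contig, GeneFeature, ProteinRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FamilySpec:
    n_families: int = 20
    members_per_family: int = 8
    ancestor_length: int = 120
    substitution_rate: float = 0.10
    indel_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.ancestor_length < 3:
            raise ValueError("ancestor_length must cover at least one k-mer")


@dataclass(frozen=True)
class GenomeSpec:
    n_contigs: int = 20
    genes_per_contig: int = 15
    operon_block: Tuple[str, ...] = ()
    background_pool: Tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "operon_block", tuple(self.operon_block))
        object.__setattr__(self, "background_pool", tuple(self.background_pool))
        if len(self.operon_block) > self.genes_per_contig:
            raise ValueError("operon block longer than contig")


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=length))


def mutate_sequence(seq: str, substitution_rate: float, indel_rate: float,
                    rng: np.random.Generator, min_length: int = 3) -> str:
    """Apply i.i.d. substitutions then geometric-length indels per site."""
    chars = list(seq)
    for i, c in enumerate(chars):
        if rng.random() < substitution_rate:
            alternatives = AA20.replace(c, "")
            chars[i] = alternatives[rng.integers(0, len(alternatives))]
    if indel_rate > 0:
        out: List[str] = []
        for c in chars:
            if rng.random() < indel_rate:
                length = int(rng.geometric(0.5))
                if rng.random() < 0.5:
                    out.append(random_protein(length, rng) + c)  # insertion
                # else deletion: drop this residue
            else:
                out.append(c)
        chars = list("".join(out))
    if len(chars) < min_length:  # keep records embeddable
        chars.extend(seq[:min_length - len(chars)])
    return "".join(chars)


@dataclass
class FamilySet:
    """Generated families plus the machinery to draw fresh members."""

    spec: FamilySpec
    ancestors: Dict[str, str]
    records: List[ProteinRecord]
    labels: Dict[str, str]  # protein_id -> family_id
    _counters: Dict[str, int] = field(default_factory=dict)

    def family_ids(self) -> List[str]:
        return sorted(self.ancestors)

    def sample_member(self, family_id: str, rng: np.random.Generator,
                      prefix: str = "g") -> ProteinRecord:
        """Draw a fresh mutated member of a family (e.g. per-contig copies)."""
        n = self._counters.get(family_id, 0)
        self._counters[family_id] = n + 1
        seq = mutate_sequence(self.ancestors[family_id],
                              self.spec.substitution_rate,
                              self.spec.indel_rate, rng)
        pid = f"{prefix}_{family_id}_{n:04d}"
        self.labels[pid] = family_id
        return ProteinRecord(id=pid, sequence=seq)


def gen_families(spec: FamilySpec) -> FamilySet:
    """Ancestor per family (uniform residues) + mutation-diverged members."""
    rng = np.random.default_rng(spec.seed)
    ancestors: Dict[str, str] = {}
    records: List[ProteinRecord] = []
    labels: Dict[str, str] = {}
    for f in range(spec.n_families):
        fid = f"fam{f:04d}"
        ancestors[fid] = random_protein(spec.ancestor_length, rng)
        for m in range(spec.members_per_family):
            seq = mutate_sequence(ancestors[fid], spec.substitution_rate,
                                  spec.indel_rate, rng)
            pid = f"{fid}_m{m:03d}"
            records.append(ProteinRecord(id=pid, sequence=seq))
            labels[pid] = fid
    return FamilySet(spec=spec, ancestors=ancestors, records=records,
                     labels=labels)


def gen_genomes(spec: GenomeSpec, families: FamilySet,
                intergenic: int = 50) -> Tuple[List[Contig], List[ProteinRecord]]:
    """Contigs carrying the operon block at a random offset among background.

    The block keeps its family order on every contig; the member sequence
    of each family is drawn fresh per contig.  Gene coordinates are
    consecutive non-overlapping nucleotide intervals on the + strand.
    """
    for fid in spec.operon_block + spec.background_pool:
        if fid not in families.ancestors:
            raise KeyError(f"unknown family id {fid!r}")
    rng = np.random.default_rng(spec.seed)
    contigs: List[Contig] = []
    records: List[ProteinRecord] = []
    n_block = len(spec.operon_block)
    for c in range(spec.n_contigs):
        cid = f"contig{c:04d}"
        offset = int(rng.integers(0, spec.genes_per_contig - n_block + 1)) \
            if n_block < spec.genes_per_contig else 0
        slots: List[Optional[str]] = [None] * spec.genes_per_contig
        for j, fid in enumerate(spec.operon_block):
            slots[offset + j] = fid
        genes: List[GeneFeature] = []
        pos = 0
        for rank, fid in enumerate(slots):
            if fid is None:
                if spec.background_pool:
                    fid = spec.background_pool[
                        int(rng.integers(0, len(spec.background_pool)))]
                    rec = families.sample_member(fid, rng, prefix=cid)
                else:
                    rec = ProteinRecord(
                        id=f"{cid}_bg{rank:03d}",
                        sequence=random_protein(
                            families.spec.ancestor_length, rng))
            else:
                rec = families.sample_member(fid, rng, prefix=cid)
            rec = ProteinRecord(id=rec.id, sequence=rec.sequence,
                                contig_id=cid, gene_index=rank)
            records.append(rec)
            length_nt = 3 * len(rec.sequence) + 3
            genes.append(GeneFeature(contig_id=cid, start=pos,
                                     end=pos + length_nt, strand="+",
                                     protein_id=rec.id, rank=rank))
            pos += length_nt + intergenic
        contigs.append(Contig(id=cid, genes=genes))
    return contigs, records


def gen_clustered_embeddings(n_clusters: int, per_cluster: int, dim: int,
                             spread: float, seed: int = 0
                             ) -> Tuple[EmbeddingDatabase, Dict[str, str]]:
    """Unit-sphere cluster centers with Gaussian member noise, normalized."""
    if spread <= 0:
        raise ValueError("spread must be positive")
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(n_clusters, dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    ids: List[str] = []
    rows: List[np.ndarray] = []
    labels: Dict[str, str] = {}
    for c in range(n_clusters):
        noise = rng.normal(scale=spread, size=(per_cluster, dim))
        members = centers[c] + noise
        members /= np.linalg.norm(members, axis=1, keepdims=True)
        for m in range(per_cluster):
            pid = f"c{c:03d}_m{m:04d}"
            ids.append(pid)
            rows.append(members[m])
            labels[pid] = f"c{c:03d}"
    return EmbeddingDatabase(ids=ids, matrix=np.stack(rows)), labels


def expected_pairwise_identity(substitution_rate: float) -> float:
    """Expected per-site identity between two independently mutated copies.

    A site matches if both copies kept the ancestral residue, or both
    mutated to the same of the 19 alternatives.
    """
    p = substitution_rate
    return (1 - p) ** 2 + p * p / 19.0
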