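"""Sequence/feature I/O, contig gene order, neighborhoods, greedy clustering.

Internal coordinates are 0-based half-open; GFF3 is read and written as
1-based inclusive.  Neighborhoods are defined over gene *rank* (count of CDS
features along the contig), not nucleotide distance: up to ``window`` genes
on each side of the focal gene, truncated silently at contig edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import AA_ALPHABET, ScoringScheme, needleman_wunsch

logger = logging.getLogger(__name__)

_VALID_RESIDUES = frozenset(AA_ALPHABET)


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with identity and optional genomic provenance."""

    id: str
    sequence: str
    contig_id: Optional[str] = None
    gene_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid protein id {self.id!r}")
        seq = self.sequence.upper()
        if len(seq) < 1:
            raise ValueError(f"empty sequence for {self.id}")
        for pos, c in enumerate(seq):
            if c not in _VALID_RESIDUES:
                raise ValueError(
                    f"illegal residue {c!r} at position {pos} in {self.id}")
        if self.gene_index is not None and self.gene_index < 0:
            raise ValueError("gene_index must be non-negative")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class GeneFeature:
    """A CDS on a contig; start/end are 0-based half-open nucleotide offsets."""

    contig_id: str
    start: int
    end: int
    strand: str
    protein_id: str
    rank: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"feature {self.protein_id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.rank < 0:
            raise ValueError("rank must be non-negative")


@dataclass
class Contig:
    id: str
    genes: List[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        starts = [g.start for g in self.genes]
        if starts != sorted(starts):
            raise ValueError(f"contig {self.id}: genes not sorted by start")
        for pos, g in enumerate(self.genes):
            if g.rank != pos:
                raise ValueError(
                    f"contig {self.id}: rank {g.rank} at list position {pos}")


@dataclass(frozen=True)
class Neighborhood:
    """Ordered window of up to 5 genes either side of a focal gene."""

    focal_protein_id: str
    member_protein_ids: tuple
    focal_offset: int
    contig_id: str

    def __post_init__(self) -> None:
        members = tuple(self.member_protein_ids)
        object.__setattr__(self, "member_protein_ids", members)
        if not 1 <= len(members):
            raise ValueError("neighborhood needs at least the focal gene")
        if members[self.focal_offset] != self.focal_protein_id:
            raise ValueError("focal_offset does not point at the focal protein")

    @property
    def context_protein_ids(self) -> tuple:
        """Member ids excluding the focal gene."""
        return (self.member_protein_ids[:self.focal_offset]
                + self.member_protein_ids[self.focal_offset + 1:])


def read_fasta(path) -> List[ProteinRecord]:
    """Read a protein FASTA; ids are the header token before any whitespace.

    Sequences are uppercased and trailing '*' stop characters stripped.
    Duplicate ids, empty sequences, and illegal residues raise ValueError.
    """
    records: List[ProteinRecord] = []
    seen: set = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise ValueError(f"duplicate FASTA id {rid!r}")
        seen.add(rid)
        seq = str(rec.seq).upper().rstrip("*")
        if not seq:
            raise ValueError(f"empty sequence for FASTA entry {rid!r}")
        records.append(ProteinRecord(id=rid, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_gff(gff_path, proteins: List[ProteinRecord],
             id_attribute: str = "ID") -> List[Contig]:
    """Read GFF3 CDS features into contigs with genes ordered by start.

    CDS rows whose id attribute matches no protein are skipped with a
    warning.  GFF 1-based inclusive coordinates become 0-based half-open.
    """
    known = {p.id for p in proteins}
    per_contig: Dict[str, list] = {}
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{gff_path}: line {lineno}: expected 9 tab-separated "
                    f"columns, got {len(fields)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{gff_path}: line {lineno}: non-integer coordinates") from None
            start, end = start1 - 1, end1  # to 0-based half-open
            if end <= start:
                raise ValueError(
                    f"{gff_path}: line {lineno}: end {end1} < start {start1}")
            attr_map = {}
            for item in attrs.split(";"):
                item = item.strip()
                if item and "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k] = v
            pid = attr_map.get(id_attribute)
            if pid is None:
                raise ValueError(
                    f"{gff_path}: line {lineno}: CDS lacks {id_attribute!r} attribute")
            if pid not in known:
                logger.warning("CDS %s on %s matches no protein record; skipped",
                               pid, seqid)
                continue
            per_contig.setdefault(seqid, []).append(
                (start, end, strand if strand in "+-" else "+", pid))
    contigs = []
    for cid in per_contig:
        rows = sorted(per_contig[cid], key=lambda r: (r[0], r[1], r[3]))
        genes = [GeneFeature(cid, s, e, st, pid, rank)
                 for rank, (s, e, st, pid) in enumerate(rows)]
        contigs.append(Contig(id=cid, genes=genes))
    return contigs


def write_gff(contigs: Iterable[Contig], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in contigs:
            for g in contig.genes:
                fh.write("\t".join([
                    contig.id, "ctxseek", "CDS",
                    str(g.start + 1), str(g.end), ".", g.strand, "0",
                    f"ID={g.protein_id}",
                ]) + "\n")


def extract_neighborhood(contig: Contig, focal_rank: int,
                         window: int = 5) -> Neighborhood:
    """Window of genes at ranks [focal_rank - window, focal_rank + window]."""
    n = len(contig.genes)
    if not 0 <= focal_rank < n:
        raise ValueError(f"focal_rank {focal_rank} out of range for contig "
                         f"{contig.id} with {n} genes")
    if window < 0:
        raise ValueError("window must be >= 0")
    lo = max(0, focal_rank - window)
    hi = min(n, focal_rank + window + 1)
    members = tuple(g.protein_id for g in contig.genes[lo:hi])
    return Neighborhood(
        focal_protein_id=contig.genes[focal_rank].protein_id,
        member_protein_ids=members,
        focal_offset=focal_rank - lo,
        contig_id=contig.id,
    )


def _cluster_stats(centroid_seq: str, seq: str,
                   scoring: Optional[ScoringScheme]) -> tuple:
    res = needleman_wunsch(seq, centroid_seq, scoring)
    return res.identity, res.query_coverage, res.subject_coverage


def greedy_cluster(records: List[ProteinRecord], min_identity: float = 0.90,
                   min_coverage: float = 0.90,
                   scoring: Optional[ScoringScheme] = None) -> Dict[str, str]:
    """Greedy incremental clustering (CD-HIT style): longest-first, first fit.

    A record joins the earliest centroid whose global-alignment identity is
    >= min_identity with bidirectional coverage >= min_coverage, otherwise it
    founds a new cluster.  Returns protein_id -> centroid_id; centroids map
    to themselves.
    """
    if not records:
        raise ValueError("greedy_cluster needs at least one record")
    if not (0 < min_identity <= 1 and 0 < min_coverage <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    centroids: List[ProteinRecord] = []
    assignment: Dict[str, str] = {}
    for rec in ordered:
        home = None
        for cen in centroids:
            ident, qcov, scov = _cluster_stats(cen.sequence, rec.sequence, scoring)
            if ident >= min_identity and qcov >= min_coverage and scov >= min_coverage:
                home = cen.id
                break
        if home is None:
            centroids.append(rec)
            home = rec.id
        assignment[rec.id] = home
    return assignment


def write_cluster_tsv(assignment: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tcentroid_id\n")
        for pid in sorted(assignment):
            fh.write(f"{pid}\t{assignment[pid]}\n")


def read_cluster_tsv(path) -> Dict[str, str]:
    out: Dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id"):
            raise ValueError(f"{path}: missing header row")
        for line in fh:
            pid, cid = line.rstrip("\n").split("\t")
            out[pid] = cid
    return out
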