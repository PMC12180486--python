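import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ctxseek.alignment import ScoringScheme
from ctxseek.genome_io import Contig, GeneFeature, ProteinRecord


@pytest.fixture(scope="session")
def simple_scheme():
    return ScoringScheme.simple(match=1, mismatch=-1, gap=-1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_contig(n_genes: int, contig_id: str = "c1", gene_len: int = 30):
    genes = [
        GeneFeature(contig_id=contig_id, start=i * (gene_len + 10),
                    end=i * (gene_len + 10) + gene_len, strand="+",
                    protein_id=f"{contig_id}_p{i}", rank=i)
        for i in range(n_genes)
    ]
    return Contig(id=contig_id, genes=genes)


@pytest.fixture
def twenty_gene_contig():
    return make_contig(20)


def random_records(n: int, length: int, seed: int = 0):
    rng = np.random.default_rng(seed)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return [
        ProteinRecord(id=f"r{i}", sequence="".join(
            aa[j] for j in rng.integers(0, 20, size=length)))
        for i in range(n)
    ]
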