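"""Retrieval benchmark semantics, truth construction, and dominance checks."""

import numpy as np
import pytest

from conftest import random_records
from ctxseek.alignment import needleman_wunsch, smith_waterman
from ctxseek.benchmarks import (context_retrieval_benchmark,
                                homolog_matching_benchmark,
                                make_alignment_truth, ood_retrieval_benchmark,
                                sequence_retrieval_benchmark,
                                structure_cluster_benchmark)
from ctxseek.ann_index import build_hnsw
from ctxseek.contrastive import TrainConfig
from ctxseek.embedding import EmbeddingDatabase, SequenceEmbedder
from ctxseek.genome_io import ProteinRecord, extract_neighborhood
from ctxseek.synthetic_data import (FamilySpec, GenomeSpec,
                                    gen_clustered_embeddings, gen_families,
                                    gen_genomes, mutate_sequence,
                                    random_protein)


class TestSequenceRetrieval:
    def test_exact_duplicates_give_full_recall_at_one(self):
        records = random_records(10, 60, seed=2)
        dupes = [ProteinRecord(f"dup_{r.id}", r.sequence) for r in records]
        db = EmbeddingDatabase.from_records(records + dupes,
                                            SequenceEmbedder(dim=64))
        truth = {r.id: f"dup_{r.id}" for r in records}
        rep = sequence_retrieval_benchmark([r.id for r in records], truth,
                                           db, index=None, K_grid=(1, 5))
        assert rep.summary["recall@1"] == 1.0

    def test_self_truth_rejected(self):
        records = random_records(4, 40, seed=3)
        db = EmbeddingDatabase.from_records(records, SequenceEmbedder(dim=32))
        with pytest.raises(ValueError):
            sequence_retrieval_benchmark([records[0].id],
                                         {records[0].id: records[0].id}, db)

    def test_missing_truth_target_named(self):
        records = random_records(4, 40, seed=3)
        db = EmbeddingDatabase.from_records(records, SequenceEmbedder(dim=32))
        with pytest.raises(KeyError, match="ghost"):
            sequence_retrieval_benchmark([records[0].id],
                                         {records[0].id: "ghost"}, db)

    def test_recall_non_decreasing_in_k(self):
        fams = gen_families(FamilySpec(n_families=10, members_per_family=4,
                                       substitution_rate=0.15, seed=4))
        db = EmbeddingDatabase.from_records(fams.records,
                                            SequenceEmbedder(dim=64))
        truth = make_alignment_truth(fams.records, 0.5, 0.5)
        rep = sequence_retrieval_benchmark(list(truth), truth, db,
                                           K_grid=(1, 5, 10, 30))
        vals = [rep.summary[f"recall@{k}"] for k in (1, 5, 10, 30)]
        assert vals == sorted(vals)

    def test_summary_recomputable_from_per_query(self):
        fams = gen_families(FamilySpec(n_families=6, members_per_family=3,
                                       substitution_rate=0.1, seed=5))
        db = EmbeddingDatabase.from_records(fams.records,
                                            SequenceEmbedder(dim=64))
        truth = make_alignment_truth(fams.records, 0.5, 0.5)
        rep = sequence_retrieval_benchmark(list(truth), truth, db,
                                           K_grid=(1, 10))
        for k in (1, 10):
            assert rep.summary[f"recall@{k}"] == pytest.approx(
                np.mean([r[f"recall@{k}"] for r in rep.per_query]))

    def test_brute_force_dominates_hnsw(self):
        fams = gen_families(FamilySpec(n_families=12, members_per_family=4,
                                       substitution_rate=0.12, seed=6))
        db = EmbeddingDatabase.from_records(fams.records,
                                            SequenceEmbedder(dim=64))
        idx = build_hnsw(db, seed=0)
        truth = make_alignment_truth(fams.records, 0.5, 0.5)
        exact = sequence_retrieval_benchmark(list(truth), truth, db,
                                             index=None, K_grid=(1, 10))
        approx = sequence_retrieval_benchmark(list(truth), truth, db,
                                              index=idx, K_grid=(1, 10),
                                              ef_search=16)
        for k in (1, 10):
            assert exact.summary[f"recall@{k}"] >= \
                approx.summary[f"recall@{k}"] - 1e-12


class TestAlignmentTruth:
    def test_identical_pair_is_mutual(self):
        recs = [ProteinRecord("a", "MKVLWAAGYRMKVLWAAGYR"),
                ProteinRecord("b", "MKVLWAAGYRMKVLWAAGYR")]
        truth = make_alignment_truth(recs)
        assert truth == {"a": "b", "b": "a"}

    def test_unrelated_records_yield_empty_truth(self, caplog):
        recs = random_records(5, 60, seed=7)
        with caplog.at_level("WARNING"):
            truth = make_alignment_truth(recs, 0.75, 0.70)
        assert truth == {}

    def test_three_member_family_best_hit_structure(self):
        # A closest to B, C closer to A than to B; frozen from the pairwise
        # identity table computed with the global DP
        rng = np.random.default_rng(8)
        a = random_protein(150, rng)
        b = mutate_sequence(a, 0.04, 0.0, rng)
        c = mutate_sequence(a, 0.12, 0.0, rng)
        recs = [ProteinRecord("A", a), ProteinRecord("B", b),
                ProteinRecord("C", c)]
        ident = {
            (x.id, y.id): smith_waterman(x.sequence, y.sequence).identity
            for x in recs for y in recs if x.id != y.id
        }
        assert ident[("A", "B")] > ident[("A", "C")] > ident[("B", "C")]
        truth = make_alignment_truth(recs, 0.75, 0.70)
        assert truth == {"A": "B", "B": "A", "C": "A"}


class TestContextRetrieval:
    def _fixture(self, conserved: bool, seed=19):
        fams = gen_families(FamilySpec(
            n_families=14, members_per_family=2, ancestor_length=70,
            substitution_rate=0.03, indel_rate=0.0, seed=seed))
        fam_ids = fams.family_ids()
        focal_fam = fam_ids[5]
        if conserved:
            block = tuple(fam_ids[:11])
            pool = tuple(fam_ids[11:])
        else:
            block = (focal_fam,)
            pool = ()  # unique random background genes per slot
        contigs, records = gen_genomes(
            GenomeSpec(n_contigs=8, genes_per_contig=13, operon_block=block,
                       background_pool=pool, seed=seed + 1), fams)
        record_map = {r.id: r for r in records}
        nbs = {}
        for contig in contigs:
            for g in contig.genes:
                nbs[g.protein_id] = extract_neighborhood(contig, g.rank)
        focal = [r.id for r in records
                 if fams.labels.get(r.id) == focal_fam]
        return focal, records, record_map, nbs

    def test_conserved_operon_scores_perfectly(self):
        focal, records, record_map, nbs = self._fixture(conserved=True)
        db = EmbeddingDatabase.from_records(records,
                                            SequenceEmbedder(alpha=0.5), nbs)
        rep = context_retrieval_benchmark(focal, db, nbs, record_map,
                                          top_m=5)
        assert rep.summary["pairwise_correct"] == 1.0

    def test_shuffled_contexts_score_near_zero(self):
        focal, records, record_map, nbs = self._fixture(conserved=False)
        db = EmbeddingDatabase.from_records(records,
                                            SequenceEmbedder(alpha=0.0), nbs)
        rep = context_retrieval_benchmark(focal, db, nbs, record_map,
                                          top_m=5)
        assert rep.summary["pairwise_correct"] < 0.05

    def test_context_mixing_does_not_hurt_on_operon_fixture(self):
        focal, records, record_map, nbs = self._fixture(conserved=True)
        scores = {}
        for alpha in (0.0, 0.5):
            db = EmbeddingDatabase.from_records(
                records, SequenceEmbedder(alpha=alpha), nbs)
            rep = context_retrieval_benchmark(focal, db, nbs, record_map,
                                              top_m=5)
            scores[alpha] = rep.summary["pairwise_correct"]
        assert scores[0.5] >= scores[0.0]

    def test_missing_context_metadata_rejected(self):
        focal, records, record_map, nbs = self._fixture(conserved=True)
        db = EmbeddingDatabase.from_records(records, SequenceEmbedder())
        with pytest.raises(KeyError):
            context_retrieval_benchmark(focal, db, {}, record_map)


class TestStructureCluster:
    def test_single_family_gives_full_hit_at_one(self):
        db, _ = gen_clustered_embeddings(4, 5, 16, 0.4, seed=9)
        labels = {pid: "everything" for pid in db.ids}
        rep = structure_cluster_benchmark(db, labels, K_grid=(1,))
        assert rep.summary["hit@1"] == 1.0

    def test_all_singletons_are_excluded(self):
        db, _ = gen_clustered_embeddings(3, 1, 8, 0.3, seed=10)
        labels = {pid: pid for pid in db.ids}
        rep = structure_cluster_benchmark(db, labels, K_grid=(1,))
        assert rep.summary["excluded_singleton_queries"] == len(db)
        assert rep.per_query == []

    def test_separated_families_recovered(self):
        db, labels = gen_clustered_embeddings(10, 20, 64, 0.15, seed=11)
        rep = structure_cluster_benchmark(db, labels, K_grid=(1, 5, 30))
        assert rep.summary["hit@1"] >= 0.95
        assert rep.summary["hit@30"] >= rep.summary["hit@1"]

    def test_unlabeled_entry_rejected(self):
        db, labels = gen_clustered_embeddings(2, 3, 8, 0.3, seed=12)
        labels.pop(db.ids[0])
        with pytest.raises(KeyError):
            structure_cluster_benchmark(db, labels)


class TestHomologMatching:
    def test_copied_embeddings_give_perfect_accuracy(self):
        db, _ = gen_clustered_embeddings(16, 1, 32, 0.3, seed=13)
        a = EmbeddingDatabase(ids=[f"a{i}" for i in range(16)],
                              matrix=db.matrix)
        b = EmbeddingDatabase(ids=[f"b{i}" for i in range(16)],
                              matrix=db.matrix)
        rep = homolog_matching_benchmark(a, b,
                                         {f"a{i}": f"b{i}" for i in range(16)})
        assert rep.summary["accuracy"] == 1.0

    def test_independent_embeddings_match_chance_level(self):
        n, reps = 64, 50
        rng = np.random.default_rng(14)
        accs = []
        for _ in range(reps):
            xa = rng.normal(size=(n, 24))
            xb = rng.normal(size=(n, 24))
            xa /= np.linalg.norm(xa, axis=1, keepdims=True)
            xb /= np.linalg.norm(xb, axis=1, keepdims=True)
            a = EmbeddingDatabase(ids=[f"a{i}" for i in range(n)], matrix=xa)
            b = EmbeddingDatabase(ids=[f"b{i}" for i in range(n)], matrix=xb)
            rep = homolog_matching_benchmark(
                a, b, {f"a{i}": f"b{i}" for i in range(n)})
            accs.append(rep.summary["accuracy"])
        mean = np.mean(accs)
        p = 1.0 / n
        se = np.sqrt(p * (1 - p) / (n * reps))
        assert abs(mean - p) <= 3 * se

    def test_mutation_diverged_pairs_beat_chance(self):
        fams = gen_families(FamilySpec(n_families=64, members_per_family=2,
                                       substitution_rate=0.25, seed=15))
        by_fam = {}
        for r in fams.records:
            by_fam.setdefault(fams.labels[r.id], []).append(r)
        a = EmbeddingDatabase.from_records([v[0] for v in by_fam.values()],
                                           SequenceEmbedder(dim=128))
        b = EmbeddingDatabase.from_records([v[1] for v in by_fam.values()],
                                           SequenceEmbedder(dim=128))
        pairs = {v[0].id: v[1].id for v in by_fam.values()}
        rep = homolog_matching_benchmark(a, b, pairs)
        assert rep.summary["accuracy"] > 1.0 / 64

    def test_non_bijective_pairs_rejected(self):
        db, _ = gen_clustered_embeddings(2, 2, 8, 0.3, seed=16)
        a = EmbeddingDatabase(ids=["a0", "a1"], matrix=db.matrix[:2])
        b = EmbeddingDatabase(ids=["b0", "b1"], matrix=db.matrix[2:])
        with pytest.raises(ValueError):
            homolog_matching_benchmark(a, b, {"a0": "b0", "a1": "b0"})


class TestOodRetrieval:
    _cfg = TrainConfig(batch_size=32, steps=60, seed=1)

    def _families(self, seed, prefix, bias=False):
        fams = gen_families(FamilySpec(n_families=8, members_per_family=4,
                                       ancestor_length=80,
                                       substitution_rate=0.08, seed=seed))
        records = [ProteinRecord(f"{prefix}{r.id}", r.sequence)
                   for r in fams.records]
        labels = {f"{prefix}{k}": f"{prefix}{v}"
                  for k, v in fams.labels.items()}
        if bias:
            # shift residue composition so held-out families are genuinely
            # out of the training distribution
            table = str.maketrans("ACDEFGHIKL", "MNPQRSTVWY")
            records = [ProteinRecord(r.id, r.sequence.translate(table))
                       for r in records]
        return records, labels

    def test_same_distribution_recall_gap_is_small(self):
        tr, trl = self._families(20, "t_")
        ho, hol = self._families(21, "h_")
        rep = ood_retrieval_benchmark(tr, trl, ho, hol,
                                      train_config=self._cfg, K_grid=(5,))
        assert abs(rep.summary["recall_difference@5"]) <= 0.15

    def test_composition_biased_heldout_does_not_beat_in_distribution(self):
        tr, trl = self._families(22, "t_")
        ho, hol = self._families(23, "h_", bias=True)
        rep = ood_retrieval_benchmark(tr, trl, ho, hol,
                                      train_config=self._cfg, K_grid=(5,))
        assert rep.summary["in_distribution_recall@5"] >= \
            rep.summary["held_out_recall@5"] - 1e-12

    def test_empty_heldout_rejected(self):
        tr, trl = self._families(24, "t_")
        with pytest.raises(ValueError):
            ood_retrieval_benchmark(tr, trl, [], {},
                                    train_config=self._cfg)

    def test_overlapping_partition_rejected(self):
        tr, trl = self._families(25, "t_")
        with pytest.raises(ValueError):
            ood_retrieval_benchmark(tr, trl, tr, trl,
                                    train_config=self._cfg)
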