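# Methods

This note documents the models and procedures implemented in `ctxseek`,
the parameter choices that matter, what the synthetic data does and does
not emulate, and the numerical conventions that make runs reproducible.

## Pairwise alignment

Global (Needleman-Wunsch) and local (Smith-Waterman) alignment use the
three-state Gotoh recurrence with affine gaps: a gap of length L costs
`gap_open + (L-1)·gap_extend`; setting the two penalties equal recovers
the linear model. The default scheme is BLOSUM62 with open −11 / extend
−1, mirroring common protein-search defaults; simple match/mismatch
schemes are available for controlled experiments. The DP kernels are
numba-compiled; tests verify their scores against (a) exhaustive
enumeration of every alignment path at tiny lengths and (b) Biopython's
`PairwiseAligner` on random pairs under the same scheme.

Traceback is deterministic: ties are resolved diagonal > up > left, so
identical inputs yield byte-identical alignments.

Statistics. *Identity* divides identical aligned pairs by total alignment
columns (gap columns included) in global mode, and by the local
alignment's own columns in local mode. *Coverage* is the number of a
side's residues placed opposite a residue (global) or inside the aligned
span (local), divided by that side's full length — so "reciprocal
coverage" thresholds constrain both sequences. The homology predicate
used by the context statistic is strict: identity > 0.50 **and** both
coverages > 0.50.

## Greedy identity clustering

Database deduplication uses greedy incremental clustering in the CD-HIT
style: records sorted longest-first (ties by id) are assigned to the
first existing centroid whose global-alignment identity is ≥ 0.90 with
bidirectional coverage ≥ 0.90, else they found a new cluster. This is an
approximation of cascaded clusterers such as MMseqs2 at the same
thresholds: first-fit assignment means a record joins the earliest
qualifying centroid, not necessarily the best one. Every record maps to
exactly one centroid and centroids map to themselves, which tests verify
as a partition invariant.

## Embedders

The pipeline is written against a minimal embedder contract: a callable
taking a protein record (and optionally its neighborhood plus the record
map) and returning a fixed-dimension L2-normalized vector. The search
engine never inspects backend internals, so externally computed protein
language-model embeddings drop in through `load_embeddings`.

The built-in backend is a hashed k-mer composition vector (feature
hashing with signed buckets): each overlapping 3-mer is hashed with
keyed BLAKE2b — never Python's runtime-salted `hash` — to a bucket and a
sign, counts are accumulated and L2-normalized. k = 3 is the smallest
order with useful specificity at the default dimension of 256; sequences
shorter than k fall back to their longest available k-mer order. The
embedder is byte-deterministic across runs and platforms for a fixed
seed.

Context awareness is a convex blend:
`normalize((1-α)·e(focal) + α·mean(e(neighbors)))`, with α = 0 reducing
exactly to the sequence embedding and a singleton neighborhood returning
the focal embedding for any α. This is deliberately the simplest
mechanism that makes "similar context ⇒ similar embedding" literally
true and testable. It is **not** a genomic language model: there is no
learned interaction between a gene and its neighbors, no nucleotide or
intergenic signal, and no order sensitivity within the window (the blend
mean-pools neighbors).

## Neighborhoods

A neighborhood is the window of up to five protein-coding genes upstream
and five downstream of a focal gene on the same contig, defined over gene
rank (CDS count), not nucleotide distance, and truncated silently at
contig edges. Strand is preserved in features but ignored for window
membership, and only CDS features count toward the window. Internal
coordinates are 0-based half-open; GFF3 is read and written 1-based
inclusive.

## Contrastive projection

A bias-free linear projection is trained on frozen embeddings so that
members of the same cluster gain cosine similarity. Each step samples
`batch_size` same-cluster (anchor, positive) pairs with distinct members,
projects and re-normalizes both sides, and minimizes InfoNCE against
in-batch negatives. Gradients are closed-form (backprop through the
cosine-softmax and row normalization), checked against central finite
differences at 1e-4 relative tolerance. The optimizer is Adam with
decoupled weight decay (0.1).

Parameter choices:

- **Temperature τ = 0.07**, the common InfoNCE default; configurable and
  recorded in all outputs.
- **Output dimension** defaults to `round(D_in/2.5)` (1280 → 512),
  keeping the dimensionality-reduction ratio used for scalable vector
  search.
- **Desk-scale training defaults**: batch 256, 1000 steps, learning rate
  1e-3. Cluster-scale settings (batch ~32k, 30k steps, lr 1e-4) pass
  through the same config but are impractical on one CPU.
- **Loss direction**: one-directional anchor→positive by default for
  single-modal training; the symmetric average of both directions is a
  flag and is the default for the cross-modal aligner.
- **Initialization**: Gaussian `N(0, 1/D_in)` by default; identity
  initialization (square projections) is available and provably leaves
  cosine rankings unchanged before the first update.
- Pairs are sampled per-batch with replacement across clusters and
  without replacement within a pair (two distinct members).

The cross-modal variant trains two projections — protein side and text
side — into a shared space with the symmetric loss. Text features come
from a deterministic hashed bag-of-words over lowercased tokens; this is
a structural stand-in for a trained biomedical text encoder, adequate for
exercising the alignment machinery (distinct annotations get near-
orthogonal features) but carrying no semantics: synonymous annotations do
not land near each other. Precomputed text vectors are accepted through
the same interface. Annotation transfer then returns the annotation of
the nearest annotated embedding by cosine, ties broken by smaller id.

## HNSW index

The index is a from-scratch Hierarchical Navigable Small World graph:
node levels drawn as `floor(-ln(U)·level_mult)` with `level_mult =
1/ln(M)`, greedy descent from the entry point through upper layers, an
`ef_construction`-bounded best-first search per layer, and the standard
neighbor-selection heuristic that keeps a candidate only if it is closer
to the new node than to every already-selected neighbor (pruned slots are
backfilled nearest-first). Degree caps are M per node per layer and 2M at
layer 0. Vectors are L2-normalized at ingest so cosine similarity is an
inner product.

Defaults M = 16, ef_construction = 200, ef_search = 128 follow common
practice for this graph family. Construction is single-threaded and
seed-deterministic; the single-threaded structure is canonical. After
degree pruning an edge may survive in one direction only — the usual
behavior for this algorithm — so adjacency is near- but not strictly
symmetric; the structural audit checks degree caps, level consistency,
and entry-point maximality. Ranking ties anywhere are broken by
lexicographic id.

In the degenerate limit (M ≥ n and ef_search = n) the layer-0 graph is
complete and search provably equals the brute-force oracle, which tests
exploit as an exactness check. On 5,000 clustered 64-dim vectors the
default settings reach recall@10 ≈ 0.98 against the oracle, and recall is
empirically non-decreasing over ef_search ∈ {16, …, 256}.

## Context analytics

**Co-occurring genes.** All non-focal context proteins across the
retrieved neighborhoods are pooled, embedded, and clustered with DBSCAN
over cosine distance (eps = 0.01, min_samples = 2 — a singleton cannot
"co-occur"). Clusters are ranked by the number of distinct contigs
contributing a member (ties: cluster size, then representative id) and
the top 7 reported by default.

**Context homology.** For a query/hit pair, the statistic is the fraction
of the hit's context genes that have a homolog in the query's context
under the strict >50%/>50% predicate. Matching is one-to-one greedy by
descending identity, so a single conserved query gene cannot absorb
several hit-side paralogs. The denominator is the hit's available context
size (10 when the window is full), so genes at contig edges are not
automatically penalized; a strict /10 mode is available. A retrieval is
*correct* when the fraction strictly exceeds 0.7 (i.e. more than 7 of 10
context genes match).

## Benchmarks

All five benchmarks run over any embedder/index backend, report per-query
records alongside summary metrics, and are seed-deterministic end to end.
Truth for the sequence benchmark is each record's best nonself hit by the
in-repo local aligner at identity ≥ 0.75 and reciprocal coverage ≥ 0.70
(records with no qualifying hit are dropped) — an alignment-search
stand-in at the same thresholds. recall@K uses the grid
{1, 5, 10, 30, 100}. The family-retrieval benchmark excludes queries from
singleton families and counts them separately. Homolog matching scores
strict rank-1 identity of the paired target. The out-of-distribution
benchmark trains the projection on a disjoint family partition and
reports the recall gap between in-distribution and held-out query sets.

## Synthetic data

Families: a uniform-random ancestor per family; members apply i.i.d.
substitutions (replacement uniform over the 19 alternatives) and
geometric-length single-site indels. The expected per-site identity
between two members, `(1-p)² + p²/19`, is verified empirically. Genomes:
each contig carries the operon block at a random offset — family order
fixed, member sequences drawn fresh per contig — surrounded by background
genes, with consecutive non-overlapping coordinates on the + strand.
Embedding fixtures place cluster centers uniformly on the unit sphere
with isotropic Gaussian member noise.

What this does not emulate: phylogenetic tree structure, rate
heterogeneity, codon/composition bias, strand variation, horizontal
transfer, or realistic operon rearrangement. Passing tests therefore
demonstrate correctness of the machinery and the direction of the
context-awareness effect under clean conditions, not performance on real
genomes.

Study-condition defaults fixed once for the evaluation harness: the
contrastive-recovery task uses 3 clusters × 60 members at dim 64,
spread 0.4 (chosen so sequence-space retrieval is imperfect, ~0.7 top-1,
while the cluster subspace is linearly recoverable), projected to 16
dims for 500 steps at batch 256. The operon fixture uses 14 families
(11-gene block), 8 contigs × 13 genes, 3% substitution. The homolog set
uses 256 pairs at 25% substitution, mirroring a curated two-genome
homolog collection's size. The index evaluation uses 5,000 vectors in 50
clusters at spread 0.3 with 100 random unit queries.

## Numerical conventions and degenerate inputs

- Seeds: every random operation takes an explicit seed
  (`numpy.random.default_rng`); the CLI records all resolved parameters.
- Normalization: databases validate unit norms at 1e-6; loaders
  renormalize with a warning at 1e-3 deviation; zero vectors are errors.
- Ties: lexicographic id everywhere a ranking can tie (search hits,
  annotation transfer, co-occurrence representatives).
- Empty inputs: empty-vs-nonempty global alignment yields the all-gap
  alignment at pure gap cost; an empty local alignment has score 0 and
  zero statistics; empty contexts score 0 with a warning; empty databases
  are errors.
- Scale: simulations in tests and the acceptance script are sized to run
  on a single CPU in seconds to tens of seconds (5,000-vector index,
  180-point training task, 8-contig operon fixture), and all conclusions
  they support are stated at those sizes.

## Known limitations

- The hashed k-mer embedder captures composition, not long-range sequence
  or structure; remote homologs below ~40% identity drift apart faster
  than they would under a learned model, which bounds achievable recall
  on the diverged-homolog fixture.
- Greedy first-fit clustering can split clusters that a best-fit or
  cascaded strategy would merge.
- The HNSW implementation is in-memory and single-threaded: correct and
  convenient at ~10^5 vectors, not engineered for 10^8.
- DBSCAN label determinism is guaranteed for a fixed input order (labels
  follow first-visited core points); permutations relabel clusters.
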