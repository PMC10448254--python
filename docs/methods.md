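# Methods

This note records the model implemented by `mitodbg`, the conventions and
numerical choices that were genuinely open, and what the synthetic data do
and do not establish.

## The annotated de Bruijn multigraph

A genome is a string over {A,C,G,T}; circular genomes are linearized at
the rotation given in the input FASTA (no canonical rotation is computed).
Sliding a (k+1)-window over genome *r* yields |r| windows when circular
(wrap-around windows included, end positions reduced into 1…|r|) and
|r|−k when linear. Each window occurrence is stored under its sequence
with the label (r, +, p), p the 1-based position of the window's last
nucleotide; the reverse complement of the window is stored with the label
(r, −, p−k), i.e. the positive-strand position of the forward window's
*first* nucleotide, which is where the reverse-complement window ends when
read along the negative strand. This convention keeps positions meaningful
on the positive strand for both labels and makes trail arithmetic
strand-uniform: along a negative-strand trail, label positions decrease by
one per step.

Vertices (the k-prefix and k-suffix of each window) are not materialized;
every downstream operation consumes edge labels, so the keyed edge store
*is* the graph. Windows containing ambiguity codes are skipped rather than
rejected, because real reference records contain sporadic Ns; positions
lost this way reconstruct as N.

Persistence uses a single-file sqlite store (tables for metadata, genomes
and edge labels, indexed by window and by genome) with a schema-version
header; loading a store with a different version fails without partial
state. Genomes are added and removed incrementally — removal deletes
exactly the labels carrying that genome id and prunes empty keys — so
`add(remove(M, r), r)` reproduces the label multiset.

Input scanning enumerates the input's windows in their given orientation
only. A mirrored scan of the input's negative strand would produce the
same information (an input window matching a database − label is the
mirror of the reverse window matching the + label), so it is omitted; the
database strand σ of a mapping pair carries the orientation, and
transferred fragments land on both input strands through the strand rule.

## Bridging

Gap size δ between two components is the number of input positions
strictly between their inducing intervals, circularly. Candidate seeding
pairs are maximal mapping pairs of the same (genome, strand) in the two
components with input-seed distance o−n ≤ g·δ; the searched portion of
each component therefore grows as g doubles from g₀ = 2, and a component
pair is exhausted once g·δ covers the smaller component, after which the
next-closest target component is tried. A pair of components is abandoned
when δ exceeds twice both inducing-interval lengths (a speed filter; the
weaker "both" reading preserves more bridging opportunities). Per database
genome only the closest seeding pair is retained (ties: lower relative
distance), and the retained pair must satisfy the relative-distance bound
|(o−n) − (o′−n′)|/(o−n) ≤ 0.2, both bounds inclusive ("up to", "upper
bound"). Deduplicating before the relative-distance bound is deliberate:
if the nearest seeds of a genome disagree in gap length — as they do
across a novel insertion, where the input gap has no database counterpart
— the genome is rejected for that gap rather than rescued by ever more
distant seeds that dilute the disagreement to exactly 0.2 and then
transfer coordinate-stretched annotations. A corollary worth stating: a
purely novel insertion is not bridgeable, by design; bridges arise where
the gap sequence has a diverged homolog in some reference.

Validation aligns the pure input gap (n+1 … o−1) against the bridging
trail (n′+1 … o′−1, reverse-complemented for σ = −) with local affine-gap
alignment: match +1, mismatch −2, and a gap of length ℓ costs
open + ℓ·extend = −2 − 2ℓ (the standard Gotoh convention; the alignment
itself is delegated to Biopython's PairwiseAligner with open −4 / extend
−2, which realizes the same cost). Acceptance uses the Karlin–Altschul
E-value E = K·m·n·e^(−λ·score) at E ≤ 10⁻³, with λ solved from
Σ pᵢpⱼ e^(λ sᵢⱼ) = 1 and K from the standard lattice series approximation
(j-fold convolutions of the per-column score distribution, 80 terms);
for (+1, −2) on uniform composition this gives λ = 1.3327, K = 0.6210.
Ungapped parameters are applied to gapped scores — the usual pragmatic
approximation, acceptable here because the threshold is permissive and
only gates candidates that already passed the relative-distance filter.
Sequence lengths enter uncorrected (no effective-length adjustment).
A consequence of the scoring floor: a gap shorter than ~9 nt cannot reach
the threshold even when it aligns perfectly, so single-substitution gaps
are bridged only indirectly, via a longer trail to the next-closest
component; their 1–2 nt coverage holes are closed by fragment merging
instead.

Accepted bridges become mapping pairs and merge the two components along
with any components lying between them; g resets to g₀ for each new
component pair; the loop stops when one component remains or every
admissible pair is exhausted.

## Annotation transfer and clustering

Transfer applies the intersection-and-offset rule literally, including for
σ = − pairs (the formula, not a geometric reflection, defines the result —
the worked example fixes this choice). For bridge pairs the input and
database intervals may differ in length by up to 20 %; the linear offset
mapping then distorts coordinates proportionally, which the clustering
stage absorbs.

The no-gene sentinel g₀ labels the complement of each genome's
annotations, emitted on both strands (absence of annotation is
strand-unspecified). g₀ never enters the RFD — it has no meaningful mean
length — and instead drives the masking rule: a position is masked when
g₀ fragments outnumber the fragments of the two best-scoring genes, or
when those genes' cumulative relative frequency falls below 0.8. Masking
uses all non-g₀ fragments (the two-donor reliability rule applies at
cluster initialization, which happens afterwards).

ω_g is the reciprocal of gene g's mean annotated length over the whole
database. Copy labels (gene#1, gene#2 in per-genome order of appearance)
are treated as the same gene across genomes when base name and index
match.

Clustering is implemented literally at per-position granularity: one leaf
per unmasked position with at least one admissibly supported gene. A
run-length-compressed variant (collapsing identical adjacent leaves) was
considered and rejected: retrieval reads *all* levels of the dendrogram
family, and compression changes which intermediate clusters exist, so the
two variants can retrieve intervals differing by a few positions whenever
a cross-run merge wins a tie-break before a run is fully consolidated.
Instead, the production implementation keeps literal semantics and gets
its speed from a lazy-deletion heap over cluster boundaries (O(n log n)
for n leaves); a naive re-scanning implementation of the same semantics is
retained as `method="naive"` and serves as the oracle in tests. Both
consume the tie-break RNG identically, so they produce identical
dendrograms at a fixed seed.

Merge quality t is the minimal number of genes reaching 0.95 cumulative
RFD mass (a 10⁻¹² tolerance guards float prefix sums); tie-breaks use the
maximum joined weighted score Ŝ (a config switch selects raw S instead,
since the source is ambiguous), then the number of distinct fragments
covering either interval, then a seeded uniform choice among the remaining
ties ordered by interval start.

Retrieval selects clusters with max RFD ≥ 0.7 (argmax ties broken toward
the lexicographically smallest gene), discards a selected cluster when
another selected cluster calls the same gene on a strictly larger
interval, keeps overlapping calls of different genes, and collapses
identical (gene, interval, strand) records.

Circularity: transferred fragments are kept unrolled (end may exceed L)
so merging works on the circle; for clustering, the circle is cut at a
position carrying no leaf when one exists (rotating coordinates so no
cluster spans the boundary), and otherwise cut at position 1 with a
post-hoc merge of same-gene predictions abutting the cut.

## Evaluation conventions

The correspondence threshold is one-sided on the prediction (≥ 75 % of
*its* positions shared); the reference-side fraction is reported but not
thresholded. Ties in largest overlap break toward same gene, then same
strand, then smaller reference start. Boundary deviations use circular
distance and require both |Δstart| and |Δend| below the threshold. The
gene → class (protein/tRNA/rRNA) map ships as an editable table keyed on
normalized names, as does the name-synonym table that replaces
database-specific curation heuristics.

In the shuffle experiment, the shuffled concatenation is split back into
chunks of the original genome lengths and each chunk contributes its first
L−(k+1) windows; this realizes the size identity |S_r| = |S_t| − N(k+1)
exactly for N circular genomes (a plain linear read of the concatenation
would give |S_t| − k). "Fraction unique in the multiset" is the number of
multiplicity-1 windows over |S_t|.

## Synthetic data: what it shows and what it does not

The generator builds a miniature metazoan-like mitogenome: 35 features in
a fixed order (13 protein-like genes of 90–300 nt, 22 tRNA-like genes of
70–72 nt, 2 rRNA-like genes of 200/260 nt, several on the negative
strand), 5–30 nt intergenic gaps, and a 200 nt unannotated control region
covering the linearization cut — about 5.3 kb in total, scaled down from
real (~16 kb) mitogenomes for speed. Descendants diverge from a random
ancestor star-wise; the default per-branch substitution rate of 0.025
yields ~95 % pairwise identity within the clade (so a held-out input sits
at ~5 % divergence from each database relative). Indels are off by default
and, when enabled, are confined to single features so truth coordinates
lift unambiguously; genes are assembled block by block, making the truth
exact by construction.

Because mutations are uniform and independent, genes are unique within a
genome (unless the tandem-duplication option is set), and gene order is
conserved, passing the recovery tests demonstrates coordinate-exact
transfer and aggregation under point divergence — not robustness to
rearrangements, compositional bias, or the paralogy and annotation noise
of real reference databases. Problem sizes in the test suite (5-genome
clades, ~5 kb genomes, k = 16; alignment oracles on ≤ 8 nt pairs;
clustering oracles on ≤ 500-position fixtures) were chosen as the smallest
scales at which every mechanism — wrap-around, bridging, masking,
two-donor support, tie-breaks — is actually exercised.

## Defaults

| parameter | default | meaning |
|---|---|---|
| k | 16 | window size k+1 = 17; below the random-match regime, above the uniqueness cliff |
| min_gene_length | 70 nt | shortest typical gene; fragment-merge distance |
| rel_dist_max | 0.2 | seeding-pair relative-distance bound |
| evalue_max | 10⁻³ | bridge alignment acceptance |
| match/mismatch/gap open/gap extend | +1/−2/−2/−2 | ~95 % conservation scoring |
| g0_bridge | 2 | initial search-extent multiplier |
| rfd_cum_t | 0.95 | mass defining merge quality t |
| rfd_retrieval_min | 0.7 | max-RFD retrieval threshold |
| noncoding_cum_min | 0.8 | masking threshold on best-two genes |
| overlap_eval_min | 0.75 | benchmark correspondence threshold |
| rng_seed | 0 | tie-break seed, recorded with the run |

All thresholds live in `mitodbg.config.Config` and can be loaded from a
flat key = value file (`--config`).

## Known limitations

Linear transfer through bridges distorts coordinates by up to the
relative-distance bound. Protein boundaries are not refined to start/stop
codons (no genetic-code awareness). No taxonomic filtering of the
reference set. The sqlite store is rewritten whole on update, which is
fine at desk scale but would want batched writes for thousands of
genomes. The whole graph is held in memory after loading.
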