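# Methods

## Scope and model

`brevipan` reconstructs the comparative-genomics layer of a bacterial
strain study from annotated protein sets: it does not assemble, annotate or
align genomes at the nucleotide level. Its unit of analysis is the gene
family — a cluster of protein-coding genes connected by filtered
bidirectional similarity — and everything downstream (pan/core curves,
niche screens, plasmid sharedness, the species supertree) is a function of
family membership plus per-gene replicon annotations.

## Similarity and the bidirectional filter

Internal alignments are affine-gap Smith–Waterman computed with
Bio.Align's PairwiseAligner under BLOSUM62 with gap open 11 / extend 1 —
the scoring used by protein BLAST — so internally computed hits and
ingested 12-column tabular hits live on comparable scales. Identity is
matches over alignment columns (gaps included); coverage of a sequence is
the local-alignment footprint over its full length. No E-value is computed
internally: Karlin–Altschul calibration is out of scope, and the E ≤ 10⁻⁴
criterion applies only where ingested hits carry E-values.

A pair qualifies when **both** directed hits reach ≥ 30 % identity and
≥ 80 % query coverage. Requiring both directions to pass is the stricter
reading of "bi-directional"; it is configurable. Coverage is assessed
against the query length in each direction, which the reciprocal
requirement makes effectively symmetric — the underlying convention ("80 %
of the sequence length", which sequence unspecified) is an open choice and
is centralized in `RunConfig`.

The k-mer prefilter skips pairs sharing fewer than
`max(1, ceil(prefilter_frac · min(#k-mers)))` distinct k-mers (k = 4,
`prefilter_frac` = 0.02). For short sequences this degenerates to "share at
least one k-mer". At per-site divergence ≤ 0.2 two homologs conserve a
4-mer with probability ≥ 0.64⁴ ≈ 0.17 per position, so a 50-residue protein
still shares ~8 distinct k-mers in expectation and the prefilter loses no
pair that could pass the 30 %/80 % filter; unrelated 300-residue proteins
share ~0.55 k-mers in expectation and are almost always skipped, which is
what makes all-against-all feasible on ~10⁴ proteins on one CPU.

Edge weight for clustering is `pct_identity · min(query_cov, subject_cov)`,
averaged over the two directions and rescaled to [0, 1]: monotone in both
filtered quantities, bounded, and free of any extra calibration.

## Markov clustering

MCL is implemented in-package with its numerics pinned for determinism:
self-loops at each node's maximum incident weight (floor 10⁻³), column
normalization, expansion by matrix squaring, entrywise inflation
(default 1.5 — the orthoMCL convention for protein families), pruning of
entries below 10⁻⁵ followed by renormalization, and convergence when the
largest entry change drops below 10⁻⁶ (cap 100 iterations; non-convergence
degrades to a warning and the current attractor interpretation). Clusters
are the connected components of attractor support; a node attracted by two
attractor groups is assigned to the group of its lexicographically smallest
attractor. Because MCL on a disjoint union equals the union of per-component
runs, the iteration is executed independently per connected component on a
dense per-component matrix — identical output, and linear rather than
quadratic memory in the number of genes.

Family classes: `core_single` (exactly one member in every genome),
`core_multi` (every genome, ≥ 2 somewhere), `unique` (one genome),
`dispensable` (the rest). Because published counts mix "genes" and
"families", the summary reports both family counts per class and the
per-genome member counts.

## Pan/core accumulation and fits

Orderings are sampled uniformly (default 100) except when the total number
of orderings is ≤ 5040 (7 genomes), where all are enumerated. Fits use the
mean curve across orderings (the median is also emitted; which central
curve the original figures used is unstated, so both are available). The
pan curve is fit by log-log least squares to P(n) = a·nᵇ, and the
pan-genome is called closed when b < 0.5 — reading the published
"exponential value" as the power-law exponent of the pan curve, the
convention of the pan-genome tool the original analysis used; a Heaps-law
(new-genes-per-genome) reading would be an alternative and is why the
threshold is exposed in `RunConfig`. The core curve is fit by nonlinear
least squares to C(n) = c·e^(d·n) + k₀ initialized from
(C(1) − C(max), a log-slope estimate, C(max)); a constant curve
degenerates gracefully to |c| ≈ 0, k₀ ≈ the constant.

## Niche screens and categories

The screen is a deterministic set rule, not an association test: present in
≥ min_pos positive genomes (4 chromosomal, 3 plasmid-only) and ≤ max_neg
(default 0) negative genomes. The published chromosomal list is phrased
only as "present in at least four beer spoilers"; absence from non-spoilers
is implied by the "acquired genes" framing and adopted as the default
(max_neg = 0) — the shipped fixture, which has no non-spoiler columns, is
insensitive to this choice. Functional categories are assigned by an
ordered keyword map over one representative product string per family (most
common member product, ties lexicographic; first matching rule wins,
fallback "hypothetical/unknown"). The default rules group redox enzymes
(flavodoxin, \*reductases, peroxidases, short-chain dehydrogenases),
transcription, transport, membrane/cell-surface and mobilome products.

## Plasmid sharedness

Similarity between plasmids is gene-content based — the fraction of one
plasmid's genes with a qualified partner or shared family on the other —
because the pipeline operates on annotated proteins; it approximates, at
gene level, the published nucleotide-identity statements about plasmid
pairs. A pair is "similar" when both directions reach 0.90; a plasmid is
"unique" when its best sharedness (larger of the two directions against
any other plasmid) stays below 0.10.

## Supertree

Families with exactly one member in every genome, outgroup included, are
each aligned by center-star progressive alignment (center = sequence with
the largest summed pairwise global score, ties by taxon label; merges
follow "once a gap, always a gap") and every column containing a gap is
then removed — the reading of "ungapped alignment" consistent with
concatenating variable-length orthologs. Distances are p-distances on the
concatenated supermatrix and the tree is canonical Saitou–Nei neighbor
joining: Q-matrix ties break on the lexicographically smallest label pair,
and a negative branch length is clamped to zero with the deficit moved to
its sister branch. Distance + NJ stands in for the original
maximum-likelihood step; the package asserts topology recovery on additive
and simulated data, not likelihood-surface properties. Bootstrap resamples
alignment columns uniformly (a per-family block bootstrap is a flag);
support is the count of replicates containing each internal bipartition,
with supports below the display threshold (default 250 of 1000) flagged but
never removed. Rooting places the root at the midpoint of the outgroup's
pendant edge.

## Synthetic pan-genome

The simulator plants a known family structure: core families in every
genome; shell families with occupancies drawn uniformly on 2..n−1 (or from
a user spectrum), always including at least one non-spoiler carrier so that
only niche families can satisfy a spoiler-specific screen; unique families
confined to one genome; and niche families present in ≥ `niche_min_pos`
spoilers and no non-spoiler, on chromosomes by default. Members are
independent per-site mutations of a per-family ancestor (star phylogeny):
with rate r, two copies match at a site with probability (1−r)² + r²/19.
Protein lengths are clipped normal (mean 300, sd 75, min 50 aa) with
uniform residue usage — alignment validation does not need biological
composition. Paralogs are re-mutated duplicates. An optional guide-tree
mode accumulates substitutions along the branches of a fixed newick tree
(edge length = per-site replacement probability on that edge), which is
what the phylogeny tests use.

The simulator deliberately omits gene gain/loss along a phylogeny,
rearrangement/synteny, domain shuffling, compositional bias and
annotation noise. Passing tests therefore demonstrate that the pipeline's
logic is correct under its stated model — not that real, re-annotated
genome sets would reproduce any particular published count, which also
depends on upstream annotation choices.

## Problem sizes and determinism

The default simulated study is 12 genomes (7 spoilers), 800 core + 300
shell + 20 niche families and 5 unique genes per genome at substitution
rate 0.02 (~11.8k proteins) — large enough that prefilter, clustering and
classification are exercised at realistic density while a full run stays
within a few minutes on one CPU; the supertree validation uses a 6-taxon
guide tree over 40 families with 100 bootstrap replicates. All randomness
flows from a single seed (simulator, permutation sampling, bootstrap), and
every stage is deterministic given that seed: nodes are processed in
sorted id order, ties break lexicographically, and re-runs are
byte-identical.

## Known limitations

Gene-level plasmid sharedness under-reports nucleotide-level identity for
plasmids that differ mainly in intergenic or pseudogenized content.
p-distance + NJ can be inconsistent under strong rate heterogeneity where
maximum likelihood would not be. The open/closed verdict is a threshold on
a fitted exponent and inherits the fit's sensitivity to the first few
accumulation points. Coverage against the query length (rather than the
shorter sequence) slightly favors retaining fragment-to-full-length pairs;
the bidirectional requirement bounds the effect.
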