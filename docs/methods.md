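# Methods

## Scope and data model

`formularank` quantifies the role hierarchy of herbs in a multi-herb formula
from five delimited-text inputs: a component table (name, herb, and the
seven descriptors MW, ALogP, HDON, HACC, Caco-2, OB, DL), a component→target
map, a PPI edge list (TSV or SIF), pathway gene sets (GMT), and a
disease-gene table with nonnegative relevance scores; an optional sixth
input lists blood-absorbed component names for wet-lab cross-checking.
Gene/protein symbols are uppercased and component names case-folded with
whitespace collapsed before any set comparison; the matching mode is gene
symbols only (no accession translation). Graphs are simple and undirected:
self-loops are dropped at parse time and duplicate edges collapse to their
maximum weight, since the random-walk machinery assumes a loop-free simple
graph. OB and DL are mandatory per component because they drive the screen;
the other five descriptors may be missing, and descriptor means are computed
over non-missing values with the source n reported. The packaged 114-row
component fixture carries exactly the values its printed source provides
(OB, DL, herb, role); the five unprinted descriptors are absent there.

## ADME screen and chemical space

A component is active iff OB ≥ `ob_min` AND DL ≥ `dl_min`, both inclusive
(defaults 30% and 0.14, the conventional systems-pharmacology cutoffs).
Inclusivity matters at the boundary: 0.14 is kept because the elimination
rule is "DL < 0.14". Unique active names are counted after normalization
across herbs. Per-herb pass *rates* require the pre-filter denominators,
which a post-screen table no longer carries, so rates are only reported when
the caller supplies totals. PCA operates on column-standardized descriptors
(zero mean, unit variance) because MW (hundreds of Da) would otherwise
dominate DL (unit scale); constant columns are dropped with a warning, and
each axis's sign is fixed so its first nonzero loading is positive, making
scores reproducible across BLAS implementations.

## C-T-P network and degree

The C-T graph is bipartite (components ↔ target proteins, unit weights);
merging with the PPI takes the union of nodes and edges, collapsing
duplicates by max weight, and refuses identifier collisions between the
component and protein namespaces. Herb mean degree is the arithmetic mean
degree of the herb's target proteins **in the merged graph** — component
neighbors count — because the statistic is defined on the C-T-P network;
`protein_only=True` restricts to the protein subgraph, and a weighted-degree
variant exists but is off by default.

## Map equation

For partition M of an undirected graph with visit frequencies
p_α = strength(α)/2W, community exit rate q_x↶ = cut(x)/2W (enter = exit at
stationarity), q↶ = Σ_x q_x↶:

    L(M) = q↶·H(Q) + Σ_x (p_x + q_x↶)·H(P^x)

with H(Q) the entropy of {q_x↶/q↶} and H(P^x) the entropy of the community
codebook {q_x↶/(p_x+q_x↶)} ∪ {p_α/(p_x+q_x↶)}. All logs are base 2 and
0·log 0 ≡ 0; a single community gives L equal to the visit-frequency
entropy. One printed form of the index entropy circulating in the
literature has the ratio inside the logarithm inverted (it would exceed 1);
the standard entropy orientation is implemented. Only the two-level (flat)
partition is supported; there is no teleportation — disconnected inputs are
reduced to their largest connected component with a warning, which is the
honest domain of a plain random walk.

The minimizer rewrites L as

    L = plogp(q↶) − 2Σ_x plogp(q_x↶) + Σ_x plogp(p_x+q_x↶) − Σ_α plogp(p_α)

(plogp(z) = z·log2 z), whose last term is constant, so a node move touches
only the two affected communities and evaluates in O(1) after an O(deg)
neighborhood scan. The search is Louvain-style: seeded-shuffled sweeps move
each node to the adjacent community minimizing L (ties broken toward the
smaller community index for determinism), communities aggregate into
supernodes (visit masses summed, internal weight dropped — it never enters
L), and the cycle repeats until no move improves L by more than 1e-10. The
best of `n_restarts` (default 10) restarts is returned, floored by the
all-in-one and singleton partitions, and canonicalized to contiguous labels
by first appearance. Tests verify exact agreement with exhaustive
enumeration of all set partitions on graphs of ≤ 8 nodes and recovery of
planted blocks at n=60, k=3, p_in=0.9, p_out=0.05.

Communities smaller than `min_size` (default 3; a dyad is not a meaningful
functional module) are unreported: a herb's community coverage is the
fraction of its retained components with ≥ 1 target inside a reported
community, and the community/network pathway-similarity metric is the
fraction of network-enriched pathways (hypergeometric p < 0.05) that remain
enriched in the community gene union.

## Enrichment

Enrichment p-values are exact hypergeometric upper tails P(X ≥ k) via
`scipy.stats.hypergeom.sf(k−1, N, K, n)`; no approximation. The background
defaults to the union of all genes in the GMT collection because real
analyses rarely state their universe; a custom universe can be supplied, and
query genes outside it are dropped with a warning. BH-FDR uses the
step-up q_(i) = min_{j≥i}(m·p_(j)/j) capped at 1 (via statsmodels),
order-invariant and equal to p when m = 1. The top-K contribution statistic
ranks pathways by raw p (the stated significance cutoff is raw p < 0.05;
`use_fdr` switches both cutoff and ranking to q), breaks ties at the k-th
place by pathway id, uses all passing pathways with a warning when fewer
than K pass, and reports per herb |targets ∩ top-K gene union| / |targets|.

## Propagation coefficient

Shortest distances from each herb target to each disease gene are computed
with Dijkstra's algorithm (networkx) on the protein-only subgraph — a
component node cannot be a propagation mode; `include_components=True`
flips this. Every tied shortest path with ≤ 3 nodes is then retained by
direct expansion: the (source, sink) edge if its weight equals the
distance, and every common neighbor p with w(s,p)+w(p,t) equal to the
distance (relative tolerance 1e-12; exact for integer weights). Retaining
*all* ties rather than one arbitrary path keeps the statistic deterministic
and order-independent. A source that is itself a disease gene contributes
no path (d = 0 is excluded). With n distinct modes, m distinct effectors:
A = (Σ retained 3-node distances)/n, B = (number of retained paths)/m.
Two-node paths count toward B but not A; when no 3-node path exists at all,
A falls back to the mean distance of the retained direct paths. The printed
form of the statistic is typographically ambiguous between PC = A·B and
PC = A/B, so both readings ship behind a `reading` flag and every output
records which was used; the product is the default because with unweighted
PPIs A ∈ [1, 2] while B is typically large, matching the magnitude such
coefficients are reported at. PC properties: linear in a uniform edge-weight
scale (through A), invariant under disjoint motif duplication and node
relabeling, 0 on an empty path set.

## Role ranking

Each herb's indicator vector (active rate, mean degree, community coverage,
pathway contribution, possession rate, mean relevance, PC, optional blood
overlap) is dense-ranked per metric (ties share a rank; all metrics
higher-is-better by default) and aggregated by Borda rank-sum, ties broken
alphabetically. Borda was chosen over z-score averaging because the metrics
live on wildly different scales (fractions vs degrees vs PC in the
hundreds); a `zmean` alternative is exposed. The first/last/middle herbs
are annotated Jun-like/Zuo-like/Chen-like — explicitly an artifact of this
synthesis, labeled as such in the JSON output, not a claim about any real
prescription. A herb's mean relevance is reported as 0 when its target set
misses the disease genes entirely (the overlap mean is undefined there).

## Synthetic generator

`make_planted_graph` samples an equal-block stochastic block model and, if
disconnected, adds edges along a random spanning tree over the components —
deterministic repair rather than rejection sampling, so a seed always maps
to the same graph. `make_toy_formula` builds a full bundle around it. The
defaults define the test conditions used throughout: 4 herbs with
hubness/disease-overlap biases 0.9, 0.5, 0.5, 0.2; 12 components per herb,
4 targets per component; 120 proteins in 4 blocks with p_in=0.3, p_out=0.02;
40 disease genes drawn with degree-proportional weight and log-normal(1, 1)
relevance scores; 300 extra background genes so targets are a small fraction
of the enrichment universe, as in real pathway collections.

Target sampling weights are (deg+1)^(1+3·hubness) scaled by (1+9·overlap)
on disease genes, and a herb's components avoid re-using its earlier
targets while candidates remain, so a designed principal herb covers many
*distinct* pathogenic hubs instead of piling onto the same few. Dominance
is structural, not statistical: when one herb's bias strictly exceeds all
others', a deterministic repair swaps targets until that herb's target
union strictly contains more disease genes, includes the highest-degree
protein, and has the strictly highest possession rate; herbs with
strictly lower bias are also given "satellite" targets (isolated protein
dyads, probability 0.5·(1−bias) per component) that sit outside reported
communities and outside the walk's largest component, which drives the
community-coverage and PC orderings. Equal-bias specs skip both mechanisms
and stay symmetric. Descriptors are drawn from per-herb shifted normals
(e.g. OB ~ N(30+25·bias, 8), DL ~ N(0.10+0.45·bias, 0.10) clipped to
[0, 1]), so the screen and the PCA separate herbs.

What the generator does **not** emulate: scale-free PPI topology, correlated
target prediction errors, pathway overlap structure, dosage, or any real
pharmacology. Passing the end-to-end tests therefore shows that the
pipeline's statistics respond correctly to the structures they claim to
measure — not that any particular real formula would rank the same way.
Published network-instance numbers (average degrees near 130, specific
possession rates, PC values in the 55–73 range) depend on undeposited
database snapshots and are deliberately not reproduced or asserted.

## Problem sizes and determinism

The test suite and acceptance script run at deliberately small sizes chosen
for exactness of their oracles: exhaustive partition enumeration is feasible
to 8 nodes (4140 partitions), brute-force simple-path enumeration to 12
nodes, block-model recovery at 60 nodes, and the synthetic pipeline at 120
proteins + 4×12 components. Every random draw flows from an explicit integer
seed through `numpy.random.default_rng`; detection, generation and ranking
are bit-reproducible given (inputs, seed).
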