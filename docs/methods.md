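# Methods

This note documents the models, parameter choices and numerical
conventions behind each stage, what the synthetic generator does and does
not emulate, and the package's known limitations.

## Differential calling and crosstalk categories

Transcript calls use two strict inequalities: *up* iff FC > `t_fc` (1.2)
and adjusted *P* < `t_alpha` (0.05); *down* iff FC < 1/`t_fc` and
adjusted *P* < `t_alpha`. Protein calls use the quantitative ratio alone:
*up* iff ratio > `p_ratio` (1.3), *down* iff ratio < 1/`p_ratio`
(≈ 0.769, conventionally printed 0.77). Boundary values are *unchanged*
in every case. Fold-changes and ratios are linear throughout; down
regulation is expressed as a ratio below 1/threshold, never as a negative
log value.

The eight joint categories are: (1) up/up, (2) down/down, (3)
transcript-down/protein-up, (4) transcript-up/protein-down, (5)
transcript-up/protein-unchanged, (6) transcript-down/protein-unchanged,
(7) transcript-unchanged/protein-up, (8)
transcript-unchanged/protein-down. The pair (unchanged, unchanged) maps
to no category. Features measured in only one omic layer are treated as
*unchanged* in the missing layer and flagged (`layers` column): the
one-layer categories 5–8 typically hold the large majority of features,
so "unchanged" must be representable rather than merely absent. Joining
the two layers requires an explicit shared `gene_id`; no isoform
collapsing or identifier mapping is attempted.

The summary fraction for categories 5–8 is reported as a percentage
rounded to one decimal; it is NaN for an empty input.

## Enrichment

Each term is tested with a two-tailed Fisher's exact test on the 2×2
table (differential ∩ term, differential ∖ term, rest ∩ term, rest ∖
term). The two-tailed P is computed by the point-probability rule — the
sum of hypergeometric point masses over all tables with the observed
margins whose probability is at most the observed table's, with a 1e−9
relative tolerance against floating-point ties. BH correction is applied
across terms within one comparison group. Term members outside the
supplied background are ignored; a differential set not contained in the
background is an error.

For heatmaps, the term × group P matrix is filtered to terms with
P < alpha (default 0.05) in at least one group, transformed to
x = −log₁₀(P), and z-scored per row using the population (n) standard
deviation. Rows with zero variance (including the single-group case) get
z = 0 and are flagged rather than dropped. Rows are ordered by
average-linkage (UPGMA) agglomeration on Euclidean distances of the z
rows; clustering is one-way — columns keep their input order. The raw P
is used for filtering and transform by default; BH-adjusted values can
be selected (`use_adjusted=True`). The row dendrogram is exported as
Newick with branch lengths equal to differences of merge heights.

## Consensus regulatory network

Preprocessing: FPKM columns are rescaled to sum to 10⁶ (TPM; FPKM
already normalises gene length, so only the per-sample total differs),
then log₂(TPM+1), then per-gene mean subtraction. The retention filter
keeps genes whose zero-meaned value reaches |1| in at least five samples
— a ±1 band is meaningful on a log₂ scale (a two-fold swing), which is
why the filter runs after the log transform; `log_transform=False` is
available for compendia assembled on a log scale already, since the
scale on which a public compendium was assembled is often unstated.

Roles: targets = differential transcripts ∪ genes of differential
proteins ∪ miRNA targets; factors = genes of differential proteins ∪
annotated regulator genes (transcription factors, modification enzymes —
supplied as a file, not mined) ∪ miRNA targets; both intersected with
the retained genes.

Per-subset learner: for each target, greedy forward selection over the
factors (the target itself excluded). At each step the factor with the
largest reduction in residual sum of squares (computed exactly via
orthogonalisation against the already-selected design) is proposed and
accepted only if `BIC = m·ln(RSS/m) + (q+1)·ln(m)` decreases, where m is
the subset sample count and q the number of selected regulators (the +1
counts the intercept). Selection stops at no improvement or at
`max_regulators_per_target` (default 5). Ties in the RSS reduction
(within 1e−9 relative) resolve to the lexicographically smallest factor
id; factors collinear with the selected design (residual norm ≤ 1e−10·m)
are skipped with a warning. The learner is therefore fully deterministic
given the subset.

Consensus: `n_subsets` (30) subsets of `floor(0.5·n_samples)` samples
are drawn independently — without replacement within a subset, but a
sample may recur across subsets. Edges kept in at least
`min_count = ceil(confidence·n_subsets)` subsets (18 at the 0.6 default)
form the consensus; each carries its occurrence count and the sign of
its mean coefficient. A fixed seed fixes the subsets and hence the whole
network. Subsets smaller than 8 samples are rejected.

## Integration and hub calling

The PPI lookup is restricted to: differential-protein genes (P), miRNA
targets (T), and differential transcripts adjacent to P ∪ T in the
consensus network (either edge direction). PPI edges need combined score
≥ 400 — "medium confidence" on the 0–1000 scale, inclusive, following
the source database's own convention. The merged network is a multigraph:
the same gene pair supported by different sources keeps one edge per
source, tagged. Node attributes record role (miRNA target / differential
protein / differential transcript / factor), an optional functional
category (six fixed labels + none), and degree. Degree and all
centralities are computed on the undirected simple projection (parallel
edges collapsed, directions dropped), matching how interactive network
tools treat such networks; both the multigraph (GraphML) and the edge
table are exported, since whether edge direction should survive
integration is genuinely ambiguous.

Centrality definitions: degree; MNC = size of the largest connected
component of the neighbourhood subgraph; MCC = Σ(|C|−1)! over maximal
cliques containing the node (isolated nodes 0; a node with an edgeless
neighbourhood scores exactly its degree); closeness = harmonic
(Σ 1/d, unreachable → 0); radiality = Σ(D+1−d)/(n_c−1) within the node's
component with D the component diameter (0 for isolated nodes). These
per-component conventions keep scores finite on disconnected graphs but
can diverge from tools that only accept connected inputs. EPC is a
Monte-Carlo estimate: each edge kept independently with probability 0.5,
mean size of the node's surviving component over 1000 replicates; all
three EPC knobs (replicates, keep probability, seed) are exposed, and
the estimate is reproducible bit-for-bit for a fixed seed. Top-k lists
(k = 10) sort by descending score with ties broken by ascending node id;
hubs are the intersection of the six lists, with a per-hub count of
rank-1 appearances.

## Synthetic data

The generator emulates the products of a multi-omics seed study at desk
scale: an expression compendium (default 300 genes × 60 samples,
standing in for a ~164-sample multi-experiment matrix), differential
tables with planted category structure, a scored interaction edge list,
a 14-gene miRNA target list, a regulator list and GMT annotations with
one term enriched by construction.

Expression model: the 20 designated regulators get i.i.d. N(0,1) latent
log₂ profiles; each regulator drives 8 targets (drawn without
replacement from the non-regulator pool at default sizes, so targets
have one regulator each) with coefficient ±1.5 (random sign) plus
N(0, 0.5) noise; unregulated genes are independent N(0,1). The latent
matrix is shifted by +5, exponentiated base 2, and columns are scaled to
library sizes of 10⁶·U(0.9, 1.1) — comparable but not identical, so the
TPM step does real work. Signal-to-noise (effect 1.5 vs noise 0.5) is a
strong, clearly recoverable effect; a ~10% library-size spread is mild
for bulk RNA-seq. Diff tables draw values uniformly from bands strictly
clear of (differential) or strictly inside (unchanged) the thresholds,
so planted categories round-trip exactly through the classifier. All
generators draw from fixed substreams of one seed, so outputs are
byte-identical across runs and adding a generator never perturbs the
others.

Not emulated: read-level sequencing or spectra, batch/experiment
structure in the compendium, isobaric-label channel structure,
dependence between the diff tables and the expression matrix. A green
round-trip therefore establishes the correctness of the downstream
arithmetic and plumbing, not robustness to batch effects or to
noisy differential calls.

## Known limitations

Planted-network recovery at the default world (60 samples, 20 factors,
effect 1.5, noise 0.5) achieves recall 1.0 but precision ≈ 0.72–0.77
across seeds — the recovery acceptance test asserts precision ≥ 0.9 and
currently fails. The shortfall is structural, not a defect of the
greedy implementation (which matches a from-scratch forward-selection
oracle exactly): with 30-sample subsets the BIC acceptance threshold
corresponds to a partial R² of ~0.11, and among 20 candidate factors the
maximum chance partial correlation in a 60-sample base matrix exceeds
that threshold for a few percent of factor–target pairs. Because all 30
half-size subsets are drawn from the same 60 samples, such base-level
chance correlations recur in ≥ 18 subsets and survive the consensus
filter — the occurrence threshold suppresses subset-specific noise, not
dataset-level noise. Running the consensus on the noiseless latent
matrix directly still yields precision ≈ 0.86, confirming the ceiling
is set by the sample count, candidate count and BIC penalty rather than
by the FPKM/TPM round-trip. Larger compendia, fewer candidate
regulators, or a stricter acceptance penalty would raise precision;
all three are fixed by the procedure this package implements.

Other limitations: the per-target learner is linear and cannot represent
combinatorial or nonlinear regulation; identifiers are assumed
consistent across all inputs (no ortholog or accession mapping);
enrichment ignores ontology structure (no DAG propagation or term
redundancy reduction); EPC is stochastic and only its seed-fixed value
is exactly reproducible.
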