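# Methods

`senescape` reconstructs, as one reusable and fully synthetic-testable
pipeline, a landscape analysis of senescence-gene (SnG) co-expression
across tissues: tissue-specific planar-filtered co-expression networks and
their module hierarchies, SnG and cell-type enrichment of modules,
consensus clustering of SnGs across modules, conservation-weighted
aggregation of tissue subnetworks, and single-cell/spatial validation
statistics. This note describes the models, the defaults and why they were
chosen, what the synthetic generators do and do not emulate, and the
numerical decisions that were genuinely open.

## Bulk preprocessing

Per tissue, raw gene×sample counts are filtered to genes with
log2(CPM) > 1 in strictly more than 25% of samples (CPM on raw library
sizes). Libraries are scaled by trimmed-mean-of-M-values (TMM) factors:
reference sample = the one whose upper-quartile CPM is closest to the mean
upper-quartile; M-values (log2 expression ratios) trimmed at 30% per tail
and A-values (mean log abundance) at 5%; the factor is the
precision-weighted (binomial delta-method) mean of the surviving M-values,
normalized so log factors average zero. One test cross-checks the factors
against edgeR's `calcNormFactors` (they agree to ~1e-3 relative on a
composition-skewed fixture).

Expression is log2(CPM + 1); the +1 pseudocount on the CPM scale is a
choice (both it and the strict ">25%" reading are configurable). Per-gene
ordinary-least-squares residuals are taken against a one-hot design of the
sample covariates (collection site, RIN, ischemic time, exonic/rRNA/
intergenic rates, sex; donor age — recorded as decade-bin midpoints 25, 35,
…, 75 — optionally included, producing an age-adjusted network set from
the same code path). Residuals are exactly orthogonal to the design; a
rank-deficient design is rejected naming the collinear columns, and
missing covariates are an error rather than imputed.

## Networks and modules

All gene pairs receive a Pearson correlation; two-sided p-values use the
t-transform `t = r·sqrt((m−2)/(1−r²))` with m−2 degrees of freedom (no
correction for residualized covariates — the networks are comparative, not
inferential, at this step). Edges with Benjamini–Hochberg q ≤ 0.05 are
ranked by |r| (unsigned: correlation sign is ignored throughout), ties
broken lexicographically, and inserted greedily into a planar maximally
filtered graph: an edge is kept iff the graph stays planar under the exact
combinatorial test (`networkx.check_planarity`), stopping at the planar
bound 3|V|−6. Because planarity is component-wise, an edge joining two
components is accepted without testing and intra-component insertions are
tested on that component alone; the result is identical to re-testing the
whole graph at every insertion (a naive oracle asserts this).

Multiscale modules are detected by a documented stand-in built from first
principles (the hierarchy JSON carries the method tag
`recursive-modularity+rewire-null` so its output is not mistaken for any
other multiscale tool's): each connected component of at least
`min_module_size` (default 10) genes is a root; at each level a Louvain
partition is proposed and accepted only if its (unweighted) modularity
exceeds mean + 2 SD of modularity over 100 degree-preserving edge rewires
of the same subgraph, with undersized children merged into the largest
sibling; accepted children are split recursively to depth 4. Two details
matter:

- **Resolution ladder.** Louvain resolutions run coarse to fine by depth
  (default 0.15, 0.5, 1.0), so the first split captures large-scale
  structure and deeper levels refine compactness — this is what makes the
  hierarchy multiscale. On structure-free networks (shuffled expression)
  the rewire null rejects essentially all splits.
- **Weights for search, topology for the gate.** The partition *search*
  uses edge weights (|r|), because planted co-expression travels on strong
  edges; the acceptance *gate* compares unweighted modularity against the
  unweighted rewire null, so the test statistic and its null are
  commensurable.

All community detection runs on sorted, integer-relabelled copies of the
subgraphs: string-keyed set iteration would otherwise leak the Python
process hash seed into Louvain's tie-breaking and destroy cross-process
reproducibility.

Hubs are genes whose within-module degree exceeds the module's mean + 2 SD
(modules under 3 genes get none); a regular ring therefore has no hubs and
a star only its center.

## Module statistics

Enrichment of a module against a gene set is the one-tailed hypergeometric
(Fisher exact) tail `P(X ≥ overlap)` with fold enrichment
`(overlap/module)/(set/universe)`. The universe is the tissue network's
gene set (post-filter), not the genome — configurable, and all five counts
are written out so any FE/p is externally recomputable. BH correction is
applied per tissue across modules by default (scope configurable to
global, and recorded in output metadata). A module eigengene is the first
right-singular vector of the per-gene z-scored submatrix, sign-anchored to
correlate positively with the mean standardized profile;
variance-explained is s₁²/Σs². Age association is Spearman correlation of
the eigengene with donor age; midrank ties are essential because ages are
decade midpoints.

## SnG landscape

The binary presence matrix has SnGs as rows, SnG-enriched modules
(tissue-qualified) as columns, entry 1 iff the SnG is a module member;
all-zero rows/columns are dropped before clustering. Consensus k-means
(k = 4, 100 runs, k-means++ with distinct sub-seeds) accumulates a
co-assignment matrix — the fraction of runs placing two items together —
and final labels cut an average-linkage tree of (1 − co-assignment) into k
groups. The combining rule (co-assignment + hierarchical cut) is the
package's choice of a standard consensus construction. A row-cluster's
tissue breadth is the number of distinct tissues whose flagged modules
contain at least one member; clusters with breadth strictly above half the
surveyed tissues (denominator = tissues with ≥1 flagged module, not all
tissues profiled) contribute all members to the conserved-SnG list.

## Aggregation

Each tissue's subnetwork is the planar network induced on the union of its
SnG-enriched module genes. Merging subnetworks gives node weights (number
of tissues containing the gene) and edge weights (number of subnetworks
containing the link); nodes below the conservation threshold (default 5
tissues) are dropped, then dangling edges. No edge-weight threshold is
applied by default (an optional `min_edge_weight` exists). Seed-gene
consensus neighborhoods merge per-tissue 3-layer breadth-first
neighborhoods (seed at distance 0, layers counted in edges) the same way,
except the seed is always retained so the consensus stays anchored. On the
bundled 3-tissue cohort the threshold is 2, the scaled-down counterpart of
the 5-of-50-tissues cutoff.

## Single cell

Counts are LogNormalized — ln(1 + count/cell_total × 10,000) — so log fold
changes are on the natural-log scale, matching the conventional 0.25
threshold. Clustering: top 2,000 variable genes by variance of the
log-normalized values, per-gene z-scaling, 30 principal components, KNN
graph (k = 20, Euclidean, top 10 PCs), Louvain at resolution 0.05.
Markers: per type one-vs-rest Wilcoxon rank-sum on normalized values; lfc
= ln(mean(expm1)+1) in-type − out-type; fraction expressing = share of
in-type cells with value > 0; BH across all gene×type tests; retained iff
q < 0.05, lfc ≥ 0.25, fraction ≥ 0.25, upregulated only. Pre-annotated
labels bypass clustering.

Per-cell gene-set scoring uses a weighted Kolmogorov–Smirnov running sum
shared verbatim with the spatial module: genes ranked by expression
descending, hits increment by their expression (weight exponent 1,
normalized to sum 1), misses decrement by 1/(N−|S|), ES = the signed
running-sum value of maximum absolute deviation. Significance is a
gene-label permutation test, p = (1 + #{perm ES ≥ obs})/(1 + n_perm), 1,000
permutations, enriched iff p < 0.01. When the SnG annotation carries
inducer/inhibitor roles, only inducers are scored by default. Two
decisions deserve emphasis:

- **Tie-breaking.** Ranking ties are broken by a fixed hash of the gene
  symbol, not alphabetically. Sparse cells have large tied blocks (zeros,
  single counts); alphabetical order would place lexicographically
  clustered sets (gene families, or any systematic naming) systematically
  early inside those blocks and bias ES against the uniform permutation
  null — a calibration test demonstrates the hazard and its absence under
  the hash. The hash is a pure function of the symbol, so results remain
  reproducible.
- **Permutation unit.** The null reassigns set membership uniformly over
  the ranked genes (gene-label permutation). Per-cell rankings have no
  sample phenotype to permute; the choice is recorded in output metadata.

## Interactions

The coexistence proportion of two genes is the share of cells with both
normalized values > 0 — a dropout-robust co-expression proxy. The
coexistence test compares, per cell type, a marker's proportions with a
query gene list against proportions with background genes sampled without
replacement from all matrix genes excluding the marker and query
(two-sided Mann–Whitney with midrank tie handling; proportions tie heavily
at zero). Ligand–receptor communication counts db pairs whose ligand is a
source-type marker and receptor a target-type marker; the null redraws
both marker sets uniformly from the expressed genes (nonzero in ≥1% of
cells by default) at matching sizes, 10,000 permutations; ordered pairs
are directional. Permutation p-values are bounded below by 1/(n_perm+1) by
construction.

## Spatial

Voxels are log-normalized like cells, then each gene is z-scored across
voxels; a voxel's expressed genes (raw count > 0; at least 50 required)
are ranked by the scaled value and scored against the module set with the
same running-sum implementation, hit weights |scaled value|, 1,000
gene-label permutations, enriched iff p < 0.01. Cell-type composition per
voxel is an input contract (synthetic truth or a user table; probabilistic
label transfer is out of scope), and composition weights are compared
between enriched and non-enriched voxels by two-sided Mann–Whitney tests.

## Synthetic data: what it emulates, and what it does not

Bulk tissues: gene modules are one-factor blocks — gene g in a module of
within-correlation ρ has latent log-expression
`μ_g + σ(√ρ·f + √(1−ρ)·ε)` — plus global covariate effects, optional
linear age trends by module, per-sample depth, and Poisson sampling of the
lognormal latent mean (overdispersed counts; the downstream statistics
need rank/correlation structure, not a specific count law). SnGs are
forced into a designated module per tissue. Defaults: 60 samples/tissue,
two 50-gene modules at ρ = 0.7, base mean 150, latent σ = 0.6 — sized so
planted correlation survives CPM normalization with a realized within-
module |r| near the target. Single cells: disjoint marker blocks elevated
by a natural-log fold change (default 2) per type, optional SnG elevation
in designated types, lognormal-Poisson counts, independent Bernoulli
dropout (default 30%). Ligand–receptor tables plant pairs between marker
blocks plus decoys from non-markers. Spatial voxels are composition-
weighted mixtures of cell-type mean profiles with an offset region where a
designated module is multiplied by e^offset.

Deliberately not emulated: batch effects beyond linear covariates,
realistic GTEx covariate distributions, expression-dependent dropout,
spliced/unspliced layers, and histology. Passing tests therefore show the
statistics behave correctly under the assumed generative structure, not
that real-data artifacts (ambient RNA, doublets, segment-specific biases)
are handled.

Two honest behaviors of the defaults are worth knowing. First,
LogNormalize is composition-sensitive: asymmetric planted elevation in one
cell type deflates that type's other genes after depth normalization, and
a minority of unplanted genes then clear the 0.25 lfc threshold in the
*other* types — the bundled cohort reports this as a nonzero marker false
discovery share, which is a property of the threshold rule under
composition shift, not a detection bug (the balanced marker-recovery suite
meets sensitivity ≥ 0.9 / FDP ≤ 0.1). Second, on the bundled slide the
scored module is SnG-heavy and SnGs mark one cell type, so voxels rich in
that type outside the offset region are genuinely module-elevated; the
region-overlap statistic counts them against the Jaccard, while the
composition contrast correctly reports the colocalization.

## Orchestration and reproducibility

`run_pipeline` reads all inputs from plain-text files (TSV/GMT/MTX/JSON),
writes every output as TSV with a `#`-prefixed metadata header (stage,
package version, seed, parameters), and finishes with a manifest carrying
the full config and SHA-256 checksums of all inputs and outputs. One
master seed derives per-stage seeds as the first 8 hex digits of
SHA-256("master:stage") mod 2³¹, so stages are independently re-runnable.
Identical config and inputs give byte-identical manifests across
processes and hash seeds. Unknown config keys are errors. The bundled
small cohort (3 tissues × 300 genes × 40 samples, 800 cells, 400 voxels)
is sized so the complete pipeline runs in about a minute; the acceptance
suite scales permutation counts accordingly where a statistic's check does
not depend on them.
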