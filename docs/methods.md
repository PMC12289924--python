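# Methods

This note documents the models and procedures implemented in
`micoexpress`, the choices made where the design was genuinely open,
and what the synthetic benchmark does and does not demonstrate.

## Normalized transcriptional activity (MTA)

Both omic layers are normalized to transcripts per million,

TPM_i = (R_i / L_i) / Σ_j (R_j / L_j) × 10⁶,

with R_i the read count and L_i the length (bp) of feature i; every
sample column sums to 10⁶. The central quantity is the per-gene
activity ratio MTA = MT TPM / MG TPM, which corrects transcript
abundance for gene (copy) abundance: a gene can be highly transcribed
because its carriers are abundant or because it is actively regulated,
and the ratio isolates the latter.

**Aggregation.** ORF-level features are aggregated to KEGG orthologs
(KOs), and to (taxon, KO) pairs, by summing feature-level TPM. Because
all features share a sample's TPM denominator, TPM is exactly additive
under aggregation; summing raw counts instead would require a single
aggregate length that featureCounts does not define. A consequence we
rely on throughout: the taxon-resolved tensor, whose (taxon t, KO k)
entry is taxon t's MT TPM for k divided by k's total MG TPM, sums over
taxa to exactly the KO-level activity matrix, and its within-KO taxon
shares equal the MT TPM shares.

**Zeros.** With the default pseudocount of 0, entries with MG = 0 and
MT > 0 are undefined — they indicate mapping artifacts rather than
infinite activity — and are missing-coded and counted; 0/0 is 0. A
positive pseudocount is available for users who prefer a dense matrix.

**Prevalence filter.** A gene enters the network when detected
(activity > 0) in at least ⌈f·n⌉ samples, f = 0.5 by default, computed
over the whole cohort (a per-group variant is available).

**Transforms.** The network input is the per-gene Yeo–Johnson power
transform (λ by maximum likelihood, via scikit-learn's
PowerTransformer) followed by standardization to mean 0, SD 1;
constant genes are dropped with a warning. Ordination uses the
centered log-ratio per sample with a default pseudocount of half the
smallest nonzero value (multiplicative replacement).

## Signed co-expression network

Adjacency is the signed WGCNA form a_ij = ((1 + cor(x_i, x_j))/2)^β
with Pearson correlation across samples. The topological overlap
similarity is

TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij), ℓ_ij = Σ_u a_iu a_uj,

with unit diagonal; connectivity k_i excludes the diagonal.

**Soft power.** For each scanned power (1–20 by default) the
scale-free fit index is computed by splitting connectivity into 10
equal-width bins and regressing log₁₀(bin frequency) on log₁₀(mean
bin connectivity); the index is −sign(slope)·R², so only a decaying
degree distribution scores positively. β is the smallest power whose
index reaches 0.9; if none does, the power at the maximum index is
used with a warning. (Equal-occupancy bins cannot work here: they make
the frequency constant by construction.)

**Module detection.** Genes are clustered by average linkage on
1 − TOM. The dynamic tree cut implemented is the tree variant, made
concrete as a *branch-distinctness* rule: a branch of the dendrogram
is a module candidate iff it contains at least `min_module_size` (20)
genes and joins the remainder of the tree at least `min_branch_gap`
(0.02 dissimilarity units) above its own top merge; distinct
sub-branches take precedence over enclosing branches, so a tight core
plus stragglers resolves to the core. Everything else is unassigned
(module M0). This rule rejects the large, loose, weakly intercorrelated
branch that compositional closure creates among background genes
(observed join gaps ≤ 0.007) while keeping genuine modules (gaps
≥ 0.08 in the benchmark).

**Eigengenes and merging.** A module eigengene is the first left
singular vector of the standardized module submatrix (samples
dimension), unit norm, sign-oriented to correlate positively with its
members on average. Modules are merged greedily, closest pair first,
while any pair has eigengene dissimilarity 1 − cor below MEDissThres
= 0.18. Labels are reassigned by size, M1 largest.

**Trait association.** Each eigengene is Pearson-correlated with the
group indicator (HC = 0, PD = 1; positive r = PD-associated), p from
Student's t with n − 2 df, BH q across modules; a module is
trait-associated when p ≤ 0.05, and both p and q are reported because
the correction status of the published module p-values is ambiguous.

## Topology metrics

Per module: intramodular connectivity = within-module adjacency sum
halved (diagonal excluded); mean connectivity = that sum over the
number of member pairs; module diversity mH′ = Shannon entropy (nats)
of member genes' activity summed over samples, normalized within the
module — it is 0 under single-gene domination and ln(size) when
activity is uniform. mH′ is computed on the untransformed ratio, not
the power-transformed network input. Centralities (weighted
clustering, degree = strength/(n−1), closeness and betweenness on
distance = 1/weight, eigenvector = principal eigenvector of the
weighted adjacency per connected component, L2-normalized) are
computed on the whole network after pruning edges with weight ≤ 0.01
(tractability; the threshold is configurable) and averaged per
module. Kruskal–Wallis compares metrics across trait classes, with an
exclusion list for re-testing without a dominant module; Spearman
correlations relate module diversity to the other metrics (BH across
the tested family). Natural log is used for every Shannon-type index.

## Hub genes

Two definitions: (1) *hub genes* — pool all genes of trait-associated
modules and keep those whose whole-network connectivity (kTotal)
reaches the pooled type-7 (linear-interpolation) 95th percentile; with
ties every gene at the threshold is kept, flagged in the output.
(2) *intramodular hubs (iHubs)* — per trait-associated module, the top
⌈10%·size⌉ genes by within-module connectivity (kWithin), ties broken
by gene id so reruns are identical. The pooled variant uses kTotal
(it is a pooled comparison across modules), the intramodular variant
kWithin; the bases are recorded per row.

## Diversity of gene expression

**tDGE (gH′).** For gene g in sample s, the Shannon entropy (nats) of
the expression shares of the taxa expressing g in s; 0 when a single
taxon carries all expression, missing when the gene is silent in that
sample. The "unclassified" taxon bin is excluded by default. Group
comparisons run per gene on the per-sample values (Mann–Whitney, BH
across genes) and at the distribution level on gene-wise means
(HC vs PD overall, within iHubs, within non-iHubs, iHub vs non-iHub).
The tDGE log2 fold change uses a pseudocount of half the minimum
positive tDGE.

**Functional redundancy.** Per sample, FR = D − Q with D the Simpson
diversity 1 − Σp_i² of species expression shares and Q the Rao
quadratic entropy Σ_ij p_i p_j d_ij. Trait profiles are binary
expressed/not per (species, KO); d_ij is the Gower distance on these
binary vectors, which reduces to the fraction of mismatching genes
among genes expressed by either species, so d ∈ [0,1] and FR ∈ [0,D]:
identical profiles give FR = D (full redundancy), disjoint profiles
FR = 0. Abundances p_i are MT-derived expression shares; a sample with
one expressing species gets FR = 0 by convention. Whether the original
analysis used MG or MT abundances and which trait distance it used is
not recoverable; these defaults are the package's documented choice.

**Per-genus expressed-gene diversity.** Per genus and sample: richness
(genes with expression > 0), Shannon, inverse Simpson over gene
proportions; Mann–Whitney per genus and index with BH across the
genus × index family.

## Differential analysis

Per-gene differential activity is rank-based: two-sided Mann–Whitney
on the raw ratio, log2 fold change of group means (PD over HC) with a
pseudocount of half the minimum positive group mean, BH across tested
genes, and tiers at p < 0.05 / q < 0.05. A negative-binomial count
model is deliberately not used: the activity ratio is not a count and
has no NB likelihood. Users wanting a count-based DE can run one on
the MT counts externally and join on gene id. The joint classification
bins genes by expression sign × tDGE sign × iHub status ×
significance tier (zero or missing fold changes are reported as
unclassifiable; bins plus unclassifiable partition the gene set), and
2×2 count tables are tested by two-sided Fisher exact and chi-square
without continuity correction (missing-coded when a margin is zero).

## Pathway enrichment

Genes are ranked per module by kME (correlation with the module
eigengene; deterministic id tie-break). The enrichment score is the
weighted Kolmogorov–Smirnov running sum (hit increments ∝ |stat|^w
normalized over hits, w = 1; miss decrements 1/(N − N_hit); ES = the
maximum deviation). The null permutes gene labels (random same-size
sets). P-values are sign-stratified — computed among permutations
whose ES shares the observed sign — because mixing signs with a fixed
denominator leaves null p-values non-uniform; the floor is
1/(n_perm + 1) and NES = ES / mean|ES_perm, same sign|. BH runs across
the full module × pathway family; sets overlapping the ranking in
fewer than 5 genes are skipped. Unannotated-gene accounting reports
per-module counts and fractions of genes in no pathway set.

## Cross-feeding correlations

All-pairs Spearman correlations between two process gene blocks
(e.g. microcompartment/eut/pdu versus flagellar assembly) across
samples, with BH across all pairs in the call and counts of positive
correlations at p < 0.05 and q < 0.05; available on the activity
ratio and on MT TPM, for all taxa or restricted (and summed) to a
configured genus list, and optionally on hub genes only. Process-level
expression sums are emitted per (genus, process, sample).

## Pipeline and reproducibility

`run_all` executes simulate → quantify → taxa → network → topology →
hubs → diversity → differential → enrichment → crossfeeding, writing
TSV/JSON per stage plus a manifest (config hash, seed, version, row
counts). One global seed is expanded through `SeedSequence` spawning
into per-stage substreams, so toggling one stage does not perturb
another's randomness; a fixed config and seed reproduce every output
byte-for-byte.

## Synthetic benchmark

The generator emulates the statistical structure the analysis
assumes, not real sequence data:

* taxon relative abundances log-normal per sample (per-taxon mean sd
  1.0, within-taxon sd 0.5);
* Bernoulli carriage of KOs by taxa (p = 0.15); each carried
  (taxon, KO) pair is a feature with a shared uniform length
  (300–3000 bp);
* planted modules: per-sample activity factors N(0, σ_f), shared by
  member genes on the log scale; a disease effect shifts affected
  modules' factors by log(group_effect) in PD samples;
* per-(gene, sample) log-normal expression noise (sd σ_e) and
  negative-binomial counts on both layers (shared size 15), MG means ∝
  abundance × carriage × length, MT means ∝ abundance × expression ×
  length, each scaled to the configured library depth;
* dropout: five "specialist" taxa of moderate abundance jointly carry
  a reserved 12-KO block with a 4× expression boost and are
  MT-silenced (p = 0.9) in PD samples only — carriage (MG) is
  untouched. Silencing comparable-share carriers collapses those
  genes' tDGE; keeping the specialists at a few percent of total MT
  mass limits the compositional knock-on onto everything else.

Default cohort: 40 + 40 samples, 40 taxa, 600 KOs, 5 modules × 40
genes, the first two modules depleted 0.5× in PD. With σ_f = 0.45 and
σ_e = 0.17 the realized within-module Pearson correlation on
transformed activity is ≈ 0.70–0.75; the pair (σ_f, σ_e) fixes both
that correlation (their ratio) and the sampling variability of a
module's realized group effect (σ_f√(2/n)), and was chosen so the
planted 2× depletion is reliably detectable at this cohort size.

Two compositional effects of TPM are intentionally present and worth
understanding when interpreting results: depleting a module inflates
every other gene's TPM in PD (so realized fold changes are attenuated
relative to the planted 2×), and sample-level normalization induces a
weak positive correlation among all genes. The benchmark keeps modules
dilute (1/3 of genes) so the first effect is mild, and the
branch-distinctness cut rejects the loose pseudo-module the second
effect creates.

What passing benchmarks do **not** show about real data: no
phylogenetic correlation between taxa, no strain structure, no
read-level errors or mapping ambiguity, identical dispersion for all
genes, a single latent factor per module, and group effects that are
exactly multiplicative. Recovery rates on this benchmark are
best-case figures for data matching these assumptions.

## Problem sizes and numerical checks

The automated checks use: closed-form identities on small matrices;
brute-force oracles (O(n³) TOM loop at n = 15 over 20 seeds;
exhaustive path-enumeration betweenness at n ≤ 10; dense
eigendecomposition; exhaustive hypergeometric enumeration for Fisher
on all 2×2 tables with n ≤ 20 plus 400 random larger tables; a
hand-walked GSEA running sum); planted-structure recovery pooled over
5 default cohorts; and null calibration on a 1000-gene module-free
cohort (independent genes, so binomial bounds apply), with the tDGE
type-I rate averaged over 8 cohorts because tDGE values share each
sample's abundance draw across genes. Permutation resolutions are 499
(GSEA null) and 199 (ordination) in the automated runs; production
defaults are higher.

## Known limitations

* The scale-free criterion rarely holds on dense, factor-driven
  synthetic data; the scan then falls back to the maximum-fit power
  with a warning, which is expected on the benchmark.
* Centrality metrics depend on the edge-pruning threshold; 0.01 is a
  tractability default, not a biological claim. Sensitivity should be
  checked per dataset.
* The branch-gap parameter (0.02) was set from the separation observed
  between genuine and closure-induced branches; extremely weak real
  modules (join gap < 0.02) would be missed.
* Per-gene tests treat samples as exchangeable within groups; no
  covariate adjustment or paired designs are supported.
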