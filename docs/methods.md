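# Methods

## Scope and model

`metagenet` infers a signed gene co-occurrence network from a genes ×
samples abundance table and analyses its modular structure. The statistical
object is the Spearman correlation matrix of relative abundances: rank
correlation is invariant under any strictly increasing per-gene transform,
which makes it robust to the unknown, monotone relationship between true
gene abundance and its measured proxy in a metagenome. Everything downstream
— deconvolution, thresholding, clustering — operates on that matrix or on
the graph derived from it.

The pipeline assumes: samples are exchangeable replicates of one underlying
community ensemble (no time-series or spatial autocorrelation modelling);
absence of a gene in a sample is informative (a zero, not missing data); and
correlation, after deconvolution and thresholding, is an acceptable proxy
for functional association. The last assumption is the method's main caveat:
surviving edges are co-occurrence statements, not demonstrated interactions.

## Stages and parameters

| parameter | default | meaning |
|---|---|---|
| `min_prevalence` | 25 | samples a gene must be detected in (of `n_samples`, read from the table); "detected" = abundance > `min_abundance` (default 0) |
| `alpha` | 1.0 | fraction of strongest entries deconvolved (1 = all) |
| `beta` | 0.99 | spectral radius of the deconvolved matrix |
| RMT grid | 0.30–0.99 step 0.01 | candidate cutoffs scanned |
| `test_alpha` | 0.001 | χ² level for the Poisson spacing test |
| `min_eigen` | 100 | smallest matrix the spacing test is trusted on (40 in tests) |
| `stability_window` | 5 | evaluable grid successors that must also pass Poisson |
| `q_max` | 0.05 | BH-FDR ceiling for an edge |
| `resolutions` | 1..15 | modularity resolution sweep (R; internally γ = 1/R) |
| `min_size` | 10 | smallest dominant cluster |
| `min_within` | 3 | within-cluster degree a DUF candidate needs |

**Prevalence.** Genes present in every sample are core; in
[`min_prevalence`, n) non-core; below, excluded from all network stages.
Rank correlations on very sparse rows are dominated by shared zeros, which
is the rationale for the filter. The three classes partition the gene set
exactly, and classification is invariant under per-sample rescaling.

**Correlation.** ρ is the Pearson correlation of average-ranked values
(average ranks on ties). Two-sided p-values use
t = ρ√((n−2)/(1−ρ²)) on n−2 df, adequate at n ≈ 45; an exact permutation
p-value is available for n < 10. Constant genes get ρ = 0, p = 1 against
all partners. BH-FDR runs over the upper triangle only (one hypothesis per
unordered pair); q ≥ p entrywise by construction.

**Deconvolution.** With G the zero-diagonal correlation matrix and
G = UΛUᵀ, the direct part is U·diag(γλ/(1+γλ))·Uᵀ, the exact inverse of the
transitive-closure series when γ = 1. γ is set in closed form,
γ = min(1, β/((1−β)λ⁺max), β/((1+β)|λ⁻min|)), so the output spectral radius
is at most β with the bound tight on the binding side; the closure oracle
(deconvolve(closure(D)) = D to < 1e−8) validates the implementation. The
diagonal is cleared for correlation inputs because it carries no pairwise
information; oracle round-trips disable that clearing since the forward map
produces an informative diagonal.

Deconvolved entries are much smaller than raw correlations (each
eigenvalue's mass is divided across its eigenvector's support), so the
pipeline rescales the deconvolved matrix by its largest off-diagonal
magnitude before thresholding. The rescaling is strictly positive, hence
sign- and order-preserving: it only re-expresses the threshold grid on the
matrix's own scale.

**RMT threshold.** For each cutoff, entries below it are zeroed, empty
rows/columns dropped, and the eigenvalue spectrum unfolded by a cubic
smoothing spline fit to the empirical cumulative spectral density
(smoothing parameter n^(−1/2); exact duplicate eigenvalues get a seeded
jitter ≤ 1e−12 so the fit abscissae increase strictly). Spacings are
normalised to mean 1 and χ²-tested (30 equal bins on [0, 3], overflow and
tail mass pooled in the last bin, bins expecting < 1 count merged left)
against Poisson e^(−s) and the Wigner surmise (πs/2)e^(−πs²/4). The chosen
threshold is the smallest grid point whose Poisson χ² is below the critical
value at `test_alpha` *and* whose next `stability_window` evaluable grid
successors also pass. Requiring stability across the entire remaining grid
was tried first and rejected: at the top of the grid the retained matrix
degenerates into tiny near-rank-one fragments whose spacing law flickers
off-Poisson for reasons unrelated to the noise/module transition, and a
single such flicker would veto an otherwise long Poisson run. The windowed
rule keeps the choice at the transition and is robust across seeds; both χ²
statistics are recorded per threshold so users can inspect the scan.

**Edge rule and topology.** Edge iff |direct score| > threshold and
q < `q_max`; sign from the correlation sign; degree-0 genes are not nodes
(edge-bearing nodes only, which is why node counts fall well below gene
counts). Clustering coefficient is reported both as mean local clustering
over nodes of degree ≥ 2 (the default) and as global transitivity, since
either convention appears in the literature; diameter is taken on the
largest connected component; both treat edges as unsigned and unweighted.
The scale-free check is a least-squares line on (log₁₀ k, log₁₀ freq(k)),
reported as R² with slope, plus an optional discrete-MLE exponent; the null
is Erdős–Rényi G(n, m) with matched counts.

**Clustering and hierarchy.** Modularity is optimised by the multilevel
(Louvain) heuristic on the positive-edge, unweighted subgraph — standard
modularity is undefined for signed graphs, so negative edges are set aside
during clustering and reattached for the role and negative-edge analyses.
The resolution convention follows the ecological usage in which larger R
produces larger clusters; this is the inverse of the γ-multiplies-null-term
convention, so internally γ = 1/R. Cluster counts across the sweep are
recorded but not forced monotone (the heuristic does not guarantee it).
The hierarchy links each cluster to the cluster at the next resolution
holding the plurality of its nodes (ties to the smallest cluster id); a
merge event is any parent with ≥ 2 children. Dominant clusters are those
with ≥ `min_size` members — the size rule is this package's
operationalisation, as "dominant" has no canonical definition — and every
other node is "loose wired"; dominant + loose node counts partition the
node set exactly. Hubs are each dominant cluster's maximum-total-degree
member (ties: larger within-degree, then lexicographic id); within- and
between-cluster degrees are both recorded since reports in the field are
ambiguous about which "connection number" a hub range refers to.

**Enrichment, DUF prediction, environment.** "Enriched" is operationalised
as the hypergeometric upper tail for a (cluster, category) overlap with the
network-node set as universe, BH across all pairs; DUF-flagged genes are
excluded from both the universe and category counts so predictions cannot
leak their own withheld labels. DUF candidates are DUF genes in dominant
clusters with between-degree 0 and within-degree ≥ `min_within`; the
prediction is the host cluster's enriched categories ranked by q, with the
annotated direct neighbours reported as evidence. Environment–gene links
use raw abundances (not network edges): Spearman per (factor, gene) pair,
BH across all pairs, then a per-(factor, cluster) hypergeometric
concentration test. Whether env links should additionally pass the RMT
threshold is left configurable; the default applies FDR only.

## Synthetic data: what it emulates and what it does not

Gene g in cluster k has latent value w_g·f_k + √(1−w_g²)·ε_g with f_k and
ε_g standard normal per sample, w = 0.95 for the cluster hub and 0.8 for
members, so planted latent correlations are w_i·w_j (hub–member 0.76 >
member–member 0.64). Abundance is exp() of the latent value — a strictly
increasing positive map chosen because it preserves rank correlations
exactly while guaranteeing positivity. Prevalence is imposed after the
transform by zeroing a gene in randomly chosen samples (zero = not
detected, matching detection semantics); the default design has 45 samples
with non-core presence uniform on [25, 44] and planted below-threshold
genes for the filter to remove. Anti-correlated cluster pairs share a
negated factor (empirical coupling ≈ −0.98); nested siblings share a parent
factor at `parent_loading`; environmental factors coupled to a cluster are
that cluster's factor plus noise. Defaults use small K for speed, with a
27-cluster preset mirroring a large survey's shape.

The generator does **not** emulate: compositional (sum-constrained) count
noise, sequencing-depth variation, taxon-level correlation of genes sharing
a genome, spatial/temporal sample structure, or annotation error. Passing
the recovery tests therefore demonstrates that the pipeline's inference is
correct *under its own model assumptions*; it does not certify performance
on real surveys, where those unmodelled features can bias correlations.

A companion graph-level generator plants nested communities directly
(sibling blocks dense, cross-sibling edges at a fixed probability,
cross-parent absent). It exists because hierarchy recovery through the
abundance layer sits near a phase boundary: the empirical coupling between
sibling factors fluctuates by ±0.1 at n = 45–100 samples, and the number of
cross-sibling edges surviving a threshold depends exponentially on that
tail, so merge resolutions vary wildly seed to seed. At the graph level the
cross-edge count is binomially concentrated and recovery of the planted
merge tree is stable, which is what a benchmark of the *hierarchy
machinery* (as opposed to the correlation sampling noise) should measure.

## Numerical choices and degenerate inputs

- One run seed; each stochastic stage (simulation, jitter, clustering tie
  breaks, null graphs) consumes a deterministically derived child seed, so
  full runs are byte-reproducible and stages can be replayed alone.
- Louvain node-visit order and all argmax ties are seeded or broken by id;
  clusters are relabelled by descending size then smallest member id.
- Nodes with only negative edges form singleton clusters (they are absent
  from the positive subgraph the optimiser sees).
- Wilcoxon rank-sum: exact enumeration when n_x + n_y ≤ 12 and tie-free,
  otherwise normal approximation with tie correction; an all-tied input
  returns p = 1.
- Unfolding requires ≥ 31 retained eigenvalues (30 spacings); thresholds
  retaining fewer, or a fully degenerate spectrum, are skipped as
  not-evaluable rather than failing the scan.
- Empty networks, empty dominant sets, all-zero sample columns,
  min_prevalence > n_samples and malformed tables raise immediately with
  the offending stage, id or coordinates named.

## Problem sizes

Tests run the generator at K = 3–6 clusters (≈ 100–250 genes) and the full
pipeline at 27 clusters (≈ 485 genes × 45 samples); the Monte-Carlo
calibrations use 20 replicates per benchmark (500×500 spectra for the
spacing laws, 160×160 planted-block matrices for threshold recovery).
These sizes were chosen so the whole suite gives tight recovery statistics
in a couple of minutes; all of them are parameters, and the pipeline scales
to a few thousand genes (the correlation and scan stages are O(g³) in the
eigendecompositions).

## Known limitations

- Plain Spearman correlation on relative abundances is blind to
  compositional coupling; a SparCC-style estimator is out of scope.
- The deconvolution model (uniform geometric damping of all indirect
  paths) is a linear approximation; α < 1 sparsification is supported but
  untested against real networks.
- Signed modularity is not implemented; negative edges do not influence
  cluster shapes.
- Hub identity is sensitive to threshold choice when degree distributions
  are flat; the hub table records both degree splits so users can audit.
- DUF predictions inherit every upstream error (threshold, clustering,
  enrichment); they are hypotheses for experimental or structural
  follow-up, and the prediction table carries the evidence columns for
  that purpose.
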