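# Methods

This note documents the models, estimators, numerical conventions and
design choices behind each stage, what the synthetic-data generators do and
do not emulate, and the known limitations.

## Motif model and scanning

A motif is a 4 × W count matrix over A,C,G,T. With pseudocount c (default
0.5) and background b (default uniform), column probabilities are
p_ij = (n_ij + c)/(N_j + 4c) and scanning scores a window x₁..x_W as
Σᵢ log2(p_i(xᵢ)/b(xᵢ)) on both strands. `N` bases contribute 0 (background).
Hits are windows scoring at least a threshold, by default 80% of the
motif's maximum achievable score; the fraction is configurable and recorded
in outputs, since no universal convention exists for calling a site
"present". Coordinates are 0-based half-open throughout; promoter offsets
are reported relative to the TSS with negative = upstream.

Promoter windows: for a 0-based TSS t on the + strand the window is
[t − upstream, t + downstream); on the − strand it is
[t − downstream + 1, t + upstream + 1) reverse-complemented, so the
returned string always reads upstream → downstream with the TSS base at
index `upstream`. Windows clipped at contig edges are flagged.

The bundled AP1, SPI1 (ETS) and SP1 matrices are idealised count matrices
written around the published consensus sites (the 11-bp AP1 TRE with
informative flanks, the SPI1 purine box, the SP1 GC box). They are authored
constants, not database exports. AP1 is deliberately 11 columns wide: a
7-mer core alone produces chance hits every 1–2 kb of random sequence,
which would make clade-restricted presence calls meaningless in 1.5-kb
promoters.

Differential enrichment between a primary and a control promoter set counts
sequences with ≥ 1 hit per motif and applies a one-sided Fisher exact test
(enrichment direction) with BH adjustment across motifs. The enrichment
ratio is smoothed as ((a+0.1)/(n₁+0.2)) / ((b+0.1)/(n₂+0.2)) to avoid
division by zero; the pseudocount is configurable and reported. The
significance gate is a q-value threshold (default 0.05); the raw Fisher p
is always reported alongside.

## Maximum parsimony

Sites are encoded as 4-bit state sets; gaps and N are missing data (any
state, zero cost), a common default whose alternative (excluding gapped
sites) is not implemented. Fitch's dynamic program runs vectorised over
unique site patterns with multiplicities.

Topology search: random-addition starting trees, then hill climbing over
the full TBR neighbourhood (every bisection edge × every re-rooting of the
detached fragment × every reattachment edge), accepting the first strictly
shorter neighbour; default 10 restarts. Ties among equally short trees are
broken by the lexicographically smallest canonical Newick (rooted at the
first taxon's edge, children ordered by smallest descendant label), which
makes results deterministic given the seed. An exhaustive enumerator
(≤ 9 taxa) exists for validation.

Bootstrap support resamples alignment columns with replacement, re-runs the
search with reduced restarts per replicate, and reports the percentage of
replicates containing each bipartition of the best tree. Bipartitions are
compared as taxon-label sets, so input order is irrelevant.

Homoplasy indices: CI = M/L and RI = (G−L)/(G−M), with M = Σ(kₛ−1) over
observed states per site, L the Fitch length and G = Σ(nₛ − largest state
class). Conventions: L = 0 ⇒ CI = 1; G = M ⇒ RI undefined (NaN). Both are
also reported restricted to parsimony-informative sites (≥ 2 states each in
≥ 2 taxa). Note RI is unchanged by that restriction: uninformative sites
contribute equally to G, M and L's relevant terms.

## Differential expression and meta-analysis

Counts matrices are transformed to log2(CPM + 0.5); placing the prior on
the CPM scale keeps a sample's column exactly invariant to rescaling its
library, and handles zeros. Per gene, expression is regressed on the
condition indicator (plus optional covariates) by OLS; the log2 fold change
is the condition coefficient with its residual-df t-test. A standard-error
floor of 1e-8 guards noise-free inputs. This is a deliberate
simplification: no empirical-Bayes variance moderation is applied, which
makes per-gene variances noisier at small n than moderated pipelines (see
Limitations).

DerSimonian–Laird pooling per gene: wᵢ = 1/SEᵢ², fixed pooled mean ȳ,
Q = Σwᵢ(yᵢ−ȳ)², τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)), random-effects
weights 1/(SEᵢ²+τ²), pooled SE = (Σw*)^(−1/2), CI = pooled ± 1.96·SE,
I² = max(0, (Q−(k−1))/Q), meta-p from the normal approximation. BH is
applied across genes by the caller. A Hartung–Knapp option rescales the
variance by the weighted residual heterogeneity and uses t with k−1 df.
The implementation reproduces R `metafor` (method="DL", test="knha") to
six decimals on a five-study fixture.

Calibration caveat: with ~10 small studies whose SEs carry only ~8 df each,
the inverse-variance z-statistic is anticonservative — the empirical null
rejection rate at α = 0.05 is ≈ 7%, not 5%, and the Hartung–Knapp variant
does not fully repair it because the weights correlate with the estimated
SEs. Variance moderation is what masks this in mainstream pipelines. Users
testing many genes should rely on the BH-adjusted q-values and treat raw
meta-p near the threshold with care.

## Single-cell stage

AUCell-style scores rank a cell's genes by decreasing count — ties broken
by one seeded permutation shared across cells and recorded — and integrate
the recovery curve of set members over the top ⌈5%·G⌉ ranks, normalised by
the maximum achievable area, giving a value in [0,1] that is invariant to
any monotone transform of the counts. Subclusters are labelled with the
marker set of highest median score when it beats every other set by a
two-sided rank-sum test at BH q ≤ 0.05; otherwise "ambiguous".

Pseudobulking sums raw counts per (sample, cell type) — or per
(sample, subcluster) for the activation contrast — dropping columns with
fewer than 10 cells (configurable; logged). Differential expression then
runs on log2(CPM+0.5) of the pseudobulk columns with the same OLS machinery
as the bulk stage; testing samples rather than cells avoids both
pseudoreplication and the poor behaviour of per-cell tests for sparsely
detected genes. Cell-type specificity compares the target type against
every other type on pseudobulk log2 CPM (one-sided rank-sum per comparison,
BH across comparisons) and flags a gene selective when the fold ratio is
≥ 4 (configurable) against every other type at q ≤ 0.05.

## Co-expression

Signed-hybrid adjacency a_ij = cor(i,j)^β for cor > 0 else 0, zero
diagonal. The soft power is the smallest candidate (default 1–20) whose
connectivity histogram fits log10 frequency ~ log10 k with R² ≥ 0.85 and a
negative slope, using 10 equal-width bins; if none qualifies the argmax-R²
power is returned with a warning. TOM_ij = (Σᵤa_iu a_uj + a_ij)/
(min(kᵢ,kⱼ) + 1 − a_ij) with unit diagonal; modules come from
average-linkage clustering of 1 − TOM with a static cut at height 0.95 and
a minimum module size of 30, clusters below the minimum going to module 0
(unassigned). The static cut replaces dynamic hybrid tree cutting: it
preserves the testable content (planted partitions are recovered exactly)
while staying fully specified. Module labels are deterministic (decreasing
size, ties by smallest member gene). Module overlap reports |A∩B|, the
one-sided hypergeometric tail p, and a seeded size-matched random-module
baseline whose mean converges to |A||B|/|U|.

## Biomarker screen

Stage 1 flags genes with ≥ 1 bp overlap between any AP1-family interval
(JUN, JUNB, JUND, FOS, FOSL1, FOSL2; configurable) and the strand-aware
−2 kb/+1 kb TSS window. Stage 2 requires pooled logFC > 0 with meta
q ≤ 0.05; stage 3 requires logFC > 0 and q ≤ 0.05 in *every* supplied
cohort; stage 4 requires the cell-type selectivity flag. Thresholds are
explicit parameters with the defaults above — the source analyses do not
publish numeric gates, so these are this package's choices. Candidates are
ranked by pooled meta effect. Stage sets are nested, so stage counts are
monotone non-increasing by construction. Gene-id harmonisation across
inputs (orthologs, symbol versions) is the caller's responsibility.

## Synthetic data: what it emulates, and what it does not

All generators derive independent random streams from one global seed by
hashing (seed, generator name), so outputs are byte-identical under a fixed
seed and insensitive to parameter changes in other generators.

**Promoters.** One 1500-bp promoter (1000 up / 500 down of the TSS) per
leaf of a 15-mammal species tree, evolved site-independently with
Jukes–Cantor substitution probabilities along branch lengths in
substitutions/site; no indels, so the ungapped output is already aligned
(real promoter panels require alignment, which is out of scope). The motif
gain is modelled as a single ancestral event: one site instance is sampled
from the motif's probabilities — rejection-sampled to score ≥ 85% of the
maximum, i.e. a functional high-affinity site — and written over the same
offset (default −300 from the TSS) in every clade leaf. Branch lengths are
plausible for mammalian promoter divergence but are not estimates of any
real tree.

**Bulk expression.** Per gene and dataset, the stimulation effect is
δ ~ Normal(θ_g, τ²) (θ = 0, τ = 0 for null genes); samples are a
Uniform(4,12) log2 baseline plus Normal(0, σ²) noise, shifted by δ in the
stimulated group. Defaults θ = 1, τ = 0.3, σ = 0.5, 10 datasets, 5 samples
per group — a moderately powered multi-dataset design; the real datasets'
effect-size distribution is unknown, and these values are simulation
conditions, not estimates. Count-platform datasets are emitted as Poisson
counts around 2^log2-expression.

**Single-cell counts.** Four brain cell types in configurable proportions,
8 samples (half disease), 250 cells per sample, negative-binomial counts
(size 2.0; infinite size = Poisson) around cell-class means with a
log-normal per-cell library factor (SD 0.3). Microglia-specific genes have
8-fold higher microglial means; activation markers rise 4-fold in the
activated subcluster, homeostatic markers are expressed 4-fold above
baseline in homeostatic microglia and fall to baseline in activated ones —
both marker classes are floored at ≥ 1 count/cell baseline because
canonical state markers are well-detected genes; a designated null analogue
is untouched everywhere. Not emulated: doublets, ambient RNA, batch
effects, detection dropout beyond NB sampling, cell-type misassignment. A
test passing on this generator therefore demonstrates the statistical
machinery, not robustness to those artefacts.

**Annotation/intervals.** Genes are laid out on 20-kb territories so
promoter windows can never collide; AP1-family intervals are placed inside
occupied genes' windows, background AP1 intervals only in window-free
intergenic space, and non-AP1 intervals anywhere. Occupancy truth is
therefore exact by construction.

**Screen world.** 2000 genes: 5 biomarkers that pass all four stages and
5 decoys per class that fail exactly one (no AP1 window; null in the
meta-analysis; null in one cohort; pan-cellular). Cohorts use 10 samples
per group with a 2.0 log2FC disease effect — sized by a power analysis so
that a true cohort effect is essentially always detected at BH q ≤ 0.05
among 2000 genes, matching the donor counts of real disease cohorts.
Background genes have 30% random AP1 occupancy and null effects.

## Problem sizes in tests and the acceptance script

The test suite validates search optimality on ≤ 7-taxon alignments against
exhaustive enumeration, Fitch against brute-force internal-labeling
minimisation, Fisher/BH/TOM/AUCell/overlap against direct-summation
oracles, and the stochastic recovery properties over 20 seeds at the
default generator conditions. The acceptance script runs 10–30 seeds per
block. These sizes were chosen to make every check exact or tightly
concentrated while keeping a full run in the minutes range on one CPU.

## Known limitations

- No variance moderation in DE; meta-p calibration caveat above.
- TBR search is a first-improvement hill climb; it is exact on the sizes
  validated here but offers no optimality guarantee at large taxon counts.
- The static TOM cut cannot split nested modules the dynamic hybrid
  algorithm would separate.
- The AUCell threshold fraction (5%), scan threshold fraction (80%),
  specificity fold gate (4) and pseudobulk cell floor (10) are conventions,
  exposed as parameters and recorded in outputs.
- Real-data results additionally depend on upstream steps that are out of
  scope here (alignment, read processing, peak calling, ortholog mapping).
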