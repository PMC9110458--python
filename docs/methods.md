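# Methods

`culmnet` re-implements, as a tested pipeline over synthetic data with known
ground truth, a three-part analysis of developing sugarcane culm
transcriptomes: (i) normalization and filtering of RNA-seq count matrices,
(ii) a Tucker3 (three-way PCA) decomposition of the genotype x gene x
internode expression tensor with rank selection and variance partitioning,
and (iii) weighted co-expression network analysis with module-trait
statistics and a trait-specific candidate-gene filtration.

## The Tucker3 model

The replicate-averaged, per-gene centred expression values are arranged in a
three-way array `X` of dimensions `I x J x K` (genotypes x genes x
internodes) and decomposed as

    x_ijk = sum_p sum_q sum_r  a_ip * b_jq * c_kr * g_pqr  +  e_ijk

with orthonormal loading matrices `A (I x P)`, `B (J x Q)`, `C (K x R)` and a
core array `G (P x Q x R)`.  Because the loadings are orthonormal, the fitted
sum of squares equals `sum g_pqr^2` and each squared core element is the share
of fitted variance carried by one (genotype-component, gene-component,
internode-component) triple.

**Fitting.**  Orthonormal alternating least squares (TUCKALS3): each sweep
replaces one mode's loadings with the leading left singular vectors of the
unfolded tensor projected onto the other two modes, then recomputes the core
as `X x1 A' x2 B' x3 C'`.  Initialisation is the higher-order SVD; optional
restarts draw random orthonormal loadings.  Convergence is declared when the
relative change of fitted SS falls below `tol` (default 1e-8, at most 500
sweeps); hitting the cap flags `converged=False` instead of raising, since a
slightly unconverged model is still usable for scree inspection.  The fitted
SS never decreases across sweeps, so the loss trace (residual SS) is
non-increasing; tests allow a relative slack of 1e-12 for floating-point
round-off at the plateau.

**Conventions.**  Mode-n unfolding orders the remaining modes with the lower
mode varying fastest, so cores are byte-reproducible.  After convergence each
loading column is flipped so its largest-magnitude entry is positive, with
the sign absorbed into the core.  Genes are centred but not scaled before
fitting, so highly expressed genes dominate the decomposition deliberately.

**Rank selection.**  `model_selection_grid` fits every `(P, Q, R)` up to the
given maxima (the canonical search is 5 x 20 x 3 = 300 combinations).
`choose_model` automates scree inspection: candidates are ordered by total
components `S = P + Q + R`; among per-`S` best models it returns the smallest
`S` whose *remaining achievable gain* (best explained fraction at any larger
`S` minus the current one) is below `epsilon` (default 0.01).  The gain to
the immediately next `S` is not usable: raising one mode's rank in isolation
often gains nothing until the matching ranks of the other modes follow, so
the explained-variance curve is a staircase whose flat steps would stop a
consecutive-gain rule prematurely.

**Main-effect partition.**  A mode component is "constant" when the
coefficient of variation of its loadings (sign-fixed so the mean is positive)
is below `cv_threshold` (default 0.2) — e.g. genotype loadings all close to
`1/sqrt(I)` mean every genotype shares that expression profile.  A core
element whose internode component is constant is a genotype main effect, one
whose genotype component is constant is an internode main effect, anything
else genotype x internode interaction; fitted-SS shares are summed per class.
When both components are constant the element is classed genotype-main (the
internode-component test runs first).

## Pre-processing

Two tracks mirror common practice:

* **Count track** (feeds the tensor): genes are kept when they have >= 10
  reads in at least 70% of libraries (inclusive boundary); TMM scaling
  factors are computed (reference = library whose upper quartile is closest
  to the mean upper quartile; 30% two-sided trim on M-values, 5% on
  A-values, precision weights); values become `log2(CPM + 1)`.
* **TPM track**: genes with strictly more than 80% zeros are removed and
  values become `log2(TPM + 1)` with no between-sample scaling.

**TMM conventions.**  By default `compute_tmm_factors` computes M-values on
raw counts, so for scaled copies of one library the factors recover the
scaling ratios exactly (a library doubled gene-wise gets factors
`2^-1/2, 2^1/2` after geometric-mean normalization).  With
`relative_to_library_size=True` counts are first divided by library size,
matching edgeR's convention of factors that multiply library sizes; the
pipeline's CPM step uses this second convention so depth is not corrected
twice.  On simulated negative-binomial data the second convention agrees
with edgeR's `calcNormFactors` to correlation > 0.99.

**Tensor construction.**  Replicates are averaged into `(genotype,
internode)` cells first, then each gene is centred to grand mean zero over
all `I x K` cells.  Missing cells are an error.  Averaging-then-centring
yields the same tensor as the reverse order for balanced designs.

**Clustering.**  Sample and profile dendrograms use classical ward.D linkage
on Euclidean distances: the Lance-Williams ward update applied to the given
dissimilarities without prior squaring.  It is computed via the identity
`ward.D(d) = ward.D2(sqrt(d))` with heights squared, using SciPy's ward
(= ward.D2) underneath; an O(n^3) from-scratch agglomeration oracle verifies
the merge heights in the tests.  The transform `log10(mean TPM + 1)` is used
for genotype x stage profiles; a global sign flip would not change Euclidean
distances, so the sign is irrelevant to the tree.

## Co-expression network

Unsigned weighted adjacency `a_ij = |cor(g_i, g_j)|^beta` (diagonal 0 by
convention), topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),   l = A @ A,

with `TOM_ii = 1`.  The soft-thresholding power is chosen by the scale-free
topology criterion: connectivities are discretized into 10 equal-width bins
and `log10(frequency)` is regressed on `log10(mean k)`; the R^2 is signed by
the slope (a negative slope, the scale-free direction, gives a positive
value), and the smallest candidate power reaching the target R^2 (default
0.80) wins, falling back to the argmax.  Equal-count binning would make the
regression degenerate (all frequencies equal), so equal-width bins are used.
The defaults `beta = 4`, unsigned type and minimum module size 500 are the
reference settings of the analysis this pipeline reproduces; the synthetic
design scales the minimum size to 50 for its 2,000 genes.

**Module detection.**  Genes are clustered on `1 - TOM` with ward.D linkage
and the tree is cut at a single global height searched over the merge
heights.  Branches of at least `min_module_size` genes whose mean internal
cohesion is at least twice the matrix-wide mean are module candidates; each
height is scored by the summed within-branch cohesion of its active
candidates in excess of the matrix-wide expectation, and the best-scoring
height (lowest on ties) defines the modules.  Cohesion is measured on the
soft-thresholded adjacency, not the TOM: TOM mass grows with neighbourhood
size and ranks a large diffuse background cluster above a tight module,
whereas the beta-power transform is precisely what suppresses weak background
correlation.  A bare count of minimum-size branches is not a usable
criterion — correlated background shreds into min-size fragments at low
heights and the count rewards exactly those cuts — and ward merge heights
grow with cluster size, so height gaps cannot identify natural branches
either.  The absolute cohesion guard keeps independent-noise branches grey
regardless of their size.  This is a deliberate simplification relative to
dynamic tree cutting; it is static (one global height) but cohesion-aware.
Modules are named from a fixed colour palette (turquoise, blue, brown, ...)
in decreasing size order, so colour names are reproducible labels, not
claims of matching any particular published module.  "grey" is reserved for
unassigned genes.

**Module and gene statistics.**  The module eigengene is the first principal
component of the module's gene-standardized expression, unit-norm over
samples and sign-fixed to correlate non-negatively with the module's mean
profile.  Module-trait relations and gene significance use Pearson
correlation with the exact t transform `t = r sqrt((n-2)/(1-r^2))` for
two-sided p-values (floored at the smallest positive double).  Gene
significance is `GS = |r|`; module significance is the mean GS over the
module's genes, reported for grey as well.  Missing values are an error, not
silently dropped.

## Candidate-gene filtration

For a trait with a positively-correlated target module and an antagonistic
excluded module: `positive_subset` returns the target module's genes with
`r > 0` and `p < alpha` (default 0.05, unadjusted — mirroring the practice
of reporting uncorrected counts — with an optional Benjamini-Hochberg flag);
`top_k_by_significance` ranks all genes by GS (default k = 100, ties broken
lexicographically by gene id for reproducibility; a signed option exists);
`trait_specific_candidates` intersects the top list with the target module
and removes genes of the excluded module, preserving GS order.  Exclusion
can only remove genes, and fixed inputs give byte-identical lists.

## Synthetic data generator

The generator emulates the study design: 24 genotypes x 5 internode stages x
3 replicates (360 libraries), negative-binomial counts, with three planted
layers.

1. **Tensor signal.**  Orthonormal loadings are drawn as QR factors of
   Gaussian matrices.  The core places a dominant `(1,1,1)` element carrying
   `core_dominance` (default 0.55) of the core SS, secondary anchor elements
   with geometrically decaying shares (ratio 0.6, 80% of the remainder) at
   positions whose complementary index pairs are pairwise distinct in every
   mode, and a Gaussian background with the remaining 20%.  Distinct pairs
   keep every unfolding full-rank — coinciding pairs make unfolding rows
   parallel and silently collapse a mode's effective rank — so each planted
   component stays identifiable.  The core is scaled so the log2-scale
   signal has RMS `signal_rms` (default 1.0) per cell, a typical magnitude
   for developmental expression changes; noise is iid Normal(0, `noise_sd`)
   on the same scale (default 0.1).
2. **Counts.**  Per gene and sample, log2 mean CPM = baseline (uniform on
   [2, 8], spanning low- to high-expressed genes) + the tensor signal of the
   sample's (genotype, internode) cell + the gene's module term.  Counts are
   gamma-Poisson (negative binomial) with shape `nb_dispersion` (default 10,
   a moderately overdispersed bulk library; `inf` gives the Poisson limit)
   at a mean scaled to a library size drawn uniformly from 10-20 million.
3. **Modules and traits.**  Each planted module has a per-sample latent
   factor `f ~ N(0,1)`; member genes receive
   `module_sd * (sqrt(rho) f + sqrt(1-rho) e)` on the log2 scale, which
   targets pairwise correlation about `rho` before count noise
   (`module_sd = 2` keeps the realized median correlation above 0.6 at the
   default noise).  The trait is `sum_m loading_m * standardized(f_m)` plus
   Gaussian noise; a genotype-level option replicates per-genotype noise
   across a genotype's samples, matching per-genotype phenotyping.

A single integer seed feeds one root `SeedSequence`; the tensor, count and
trait generators each draw from a fixed spawn key, so outputs are
byte-identical under a fixed seed and the three operations are independently
reproducible.

**What the generator does not emulate.**  Read-level sequencing artefacts,
transcript isoforms, polyploid allele dosage, GC/length biases, batch
effects, and annotation. Background genes outside the planted modules are
still strongly co-expressed through the low-rank tensor signal — more
structured than real biological background, which has higher-dimensional
covariance — so passing recovery tests demonstrates that the pipeline
separates planted modules from a coherent developmental background, not that
it would meet the same recovery rates on arbitrary real data.  The noise
distribution of expression on the log2 scale is assumed Gaussian; the study
system does not pin this down.

## Problem sizes and determinism

The test-suite and acceptance-script runs use the full replicated design
(360 libraries) with 2,000 genes and two 200-gene modules — enough for
stable correlation estimates while keeping dense gene x gene matrices small
— and a 10 x 200 x 5 tensor for the 300-combination rank-grid enumeration.
All randomness flows from explicit integer seeds; reruns are byte-identical.

## Known limitations

* Static single-height module detection cannot resolve nested module
  structure the way dynamic tree cutting can.
* The ALS fit has no missing-data handling; tensors must be complete.
* Dense `gene x gene` adjacency/TOM matrices bound the practical gene count
  to desk scale (tens of thousands); no block-wise decomposition is
  provided.
* The elbow rule returns the smallest model within `epsilon` of the best
  explained variance seen in the grid; if the grid maxima truncate a still
  rising curve, the choice is relative to the searched region only.
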