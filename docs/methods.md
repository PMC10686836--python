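# Methods

## The problem

During surface colonization, a *Bacillus subtilis* swarm expands from a
~1 mm inoculum to a ~60 mm colony within about six hours.  Samples taken
at different radial positions and times — bulk RNA-seq libraries,
microscopy-derived phenotype measurements, extracellular metabolite
concentrations — live on an awkward, growing space–time domain: late
timepoints have many radial positions, early timepoints few, and each
biological replicate expands from a slightly different starting radius.
`swarmspec` provides the machinery to put all replicates on one common
dimensionless domain, compress each measured field into a small spectral
coefficient vector, and score, select, cluster and embed spatiotemporal
patterns from those vectors.

## Common expansion domain

The boundary radius of each replicate k is modeled as
`b(t) = b0_k * exp(t / tau)` with one shared growth timescale `tau`.
The joint squared loss over all replicates is minimized by profiling each
`b0_k` out analytically (the model is linear in `b0` given `tau`) and
scanning `tau` on a log-spaced grid refined by bounded scalar
minimization — deterministic, no random initialization.  The replicate
with the largest `b0` anchors the time shifts
`t_s_k = tau * (log b0_r - log b0_k) + t_s_r`, after which every fitted
boundary coincides exactly with `p~ = exp(t~)` in the rescaled
coordinates `t~ = (t - t_s_k)/tau`, `p~ = p / b0_common`.  Ties in the
argmax are broken by lowest replicate id.  The common horizon `T` is the
largest dimensionless time covered by *all* replicates; domain
membership (`0 <= t~ <= T`, `0 <= p~ <= exp(t~)`) is boundary-inclusive
on all four constraints, and out-of-domain samples are flagged and
excluded from the spectral fit rather than silently dropped.

## Spectral basis

The basis is built by Gram–Schmidt orthonormalization of the graded
monomials `1, t~, p~, t~^2, t~ p~, p~^2, …` under the weighted inner
product

    <f, g> = ∫_0^T dt~ ∫_0^{exp(t~)} dp~ e^{-t~} f g .

The `e^{-t~}` weight cancels the exponentially growing slice width, so
every time slice contributes equally and `<1, 1> = T`.  Quadrature is a
tensor Gauss–Legendre rule (default 64 × 64 nodes) with the p-interval
mapped to `[0, exp(t~)]` per t-node; the rule is exact in `p~` and
spectrally convergent in `t~` (the reduced integrand contains `e^{k t~}`).
Gram–Schmidt runs modified, with a second re-orthogonalization pass; the
resulting Gram matrix deviates from the identity by ~1e-15, and the
basis is additionally checked in the tests against exact closed-form
monomial inner products obtained from the integration-by-parts recursion
for `∫ t^j e^{k t} dt`.

Design choices: the basis is *orthonormal* (unit norm), which pins the
constant function to `P0 = 1/sqrt(T)` and makes coefficients comparable
across genes; six functions (`M = 5`) are used by default, covering all
monomials up to total degree 2.  Both are configurable.

## Coefficient fits and pattern scores

Each gene's in-domain sample vector is fitted by ordinary least squares
on the basis evaluated at its sample coordinates; replicates are
combined by stacking their design matrices into one regression.
Rank-deficient designs fall back to the minimum-norm solution with a
warning.

For scoring, coefficients are standardized per gene,

    k_m = (c_m - delta_{m,0} * mu / p0) / sigma ,

with `mu`, `sigma` the mean and standard deviation of the gene's
expression over all in-domain samples pooled across replicates
(unweighted).  Only the constant coefficient has the mean term
subtracted — after this rescaling `k_0` is fully determined by the
higher-order terms, so the k-vector describes pattern shape independent
of global shift and scale.  Three quantities follow:

* representation error `E = || (g - mu)/sigma - Σ k_m P_m ||^2`
  (small for smooth fields),
* pattern energy `P = Σ_{m>=1} k_m^2` (large for non-constant fields),
* ranking `R = P / E`.

`R` is invariant under per-gene affine transforms of expression.
Numerical conventions: genes with `sigma = 0` are flagged constant and
scored `R = 0`; genes whose standardized residual is zero up to
round-off (`E < 1e-12`) are perfectly represented and receive an
infinite-R sentinel that always ranks top and is excluded from the
cumulative denominator below.

## Selection, clustering, embedding

Genes are ordered by `R` ascending and the largest index `N_c` is found
whose cumulative R-fraction is ≤ 0.5; genes above `N_c` are selected, so
the selected set carries at least half of the total ranking mass.  A
consequence worth knowing: this weighted-median rule adapts to the score
distribution.  On a cohort where many genes have *comparable* nonzero
rankings, the cut necessarily falls inside that group — it selects the
top half of the score mass, not every gene above a fixed threshold.
Full recall of a planted patterned set is therefore expected exactly
when the non-patterned background carries a comparable share of ranking
mass (as in real transcriptomes) or when patterned genes are perfectly
represented (the sentinel case); synthetic checks of recall are run at
noise 0 for this reason, while clustering and AUROC checks run at the
generator's default noise.

Selected genes are compared by cosine similarity of their k-vectors over
the non-constant modes (`m = 1…M`), clustered with k-medoids on the
distance `1 - similarity` (PAM: greedy BUILD then best-improvement SWAP,
deterministic given the seed), and embedded in 2-D by metric MDS
initialized from classical scaling.  The number of clusters defaults to
6 with the full elbow (total cost vs k) exported; the knee is reported
as the maximum discrete curvature but the choice of k remains a config
parameter.  Phenotype properties run through the identical spectral and
scoring path after per-property standardization, so genes and
phenotypes share one embedding space; function-category counts among the
50 nearest neighbour genes of a phenotype merge categories with fewer
than 10 members into "other".

## Count preprocessing

Genes are kept when at least 2 samples have ≥ 10 reads; samples are then
kept when their total over the retained genes is ≥ 1e6 (genes first, then
samples, and the thresholds are inclusive).  Between-sample
normalization is TMM, re-implemented from its published definition:
reference library chosen by upper-quartile proximity to the mean,
M-values trimmed at 30 % and A-values at 5 %, precision-weighted mean of
the surviving log-ratios, factors scaled to geometric mean 1.  The
implementation agrees with edgeR's `calcNormFactors` to ~1e-10 on random
matrices (cross-checked in the test suite via Rscript).  Expression
values are `log2` counts-per-million on effective library sizes (column
sum × factor) with pseudocount 0.5 — the transform's exact form matters
only up to per-gene affine changes, which the ranking is invariant to.
The dynamic range of a gene is `2^(q95 - q5)` of its pooled log2 values
with linear-interpolation percentiles.

## Phenotype metrics

Inputs are per-frame cell tables (centroid µm, axial orientation rad,
speed µm/s, area µm²), i.e. downstream of segmentation and optical flow.
Conventions are centralized and tested:

| quantity | convention |
|---|---|
| pairwise nematic order | `S = 1.5 cos²(θ) - 0.5`, axial angles mod π |
| local nematic order | mean pair value over neighbours within ≤ 10 µm |
| non-motile | speed < 8 µm/s (strict) |
| motile (rafting) | speed ≥ 10 µm/s (inclusive) |
| non-motile clusters | single linkage at ≤ 2 µm, ≥ 10 cells |
| rafting neighbourhood | ≤ 30 µm, alignment tolerance 15° |
| density fluctuations | 48 µm tiles, population SD per frame, mean over frames; partial edge tiles dropped |
| per-video aggregation | median across the field of view, mean across frames |

The biomass-density circle radius (30 µm) is a package default recorded
in output metadata.  Cells without neighbours are excluded from
neighbourhood metrics rather than scored zero.

## Metabolite timing

Replicate series are summarized as mean ± SD per timepoint with the
replicate count actually present.  Depletion time is the first
linear-interpolated crossing below a threshold fraction of the initial
concentration that is never recovered from.  Peak shifts between
positions are argmax differences of 3-point moving-average smoothed mean
curves; non-unimodal series trigger a warning but are still reported.
The diffusion timescale uses `tau = L² / (4 D)` with
`D = 1e-9 m²/s` (a standard value for small organic acids in water):
10 mm gives 6.94 h ≈ 7 h, far above the ~2 h peak shift produced by a
5 mm/h front over the same distance, which is the quantitative basis for
rejecting diffusion as the dominant transport mechanism in favour of
local secretion-then-consumption.

## Synthetic data: what it emulates, and what it does not

The generator produces every pipeline input with the statistical
structure the analysis assumes:

* boundary series `b0 e^{t/tau}` + Gaussian observation noise, default
  `tau = 6/ln(60) ≈ 1.47 h` (a 60-fold expansion in 6 h) and initial
  radii 0.5/0.55/0.6 mm for three replicates over 6 h;
* sampling grids every 20 min, innermost position 1.5 mm, 1 mm spacing,
  capped at 9 regularly spaced positions inside the boundary;
* log2 expression fields that are exact linear combinations of the
  domain basis plus Gaussian noise (default SD 0.2 log2 units) — the
  measurement-noise model is a stand-in, chosen for analytic
  tractability, since nothing downstream depends on its exact form;
* counts drawn negative-binomially (gamma–Poisson, default dispersion
  0.05) around library-size-scaled linear means, libraries 2–5 million;
* planted pattern families as the axis directions ±e1, ±e2, ±e3 in
  k-space — maximally separated under cosine distance so clustering
  recovery is a construction guarantee, not a coin flip;
* cell configurations (isotropic / raft / non-motile cluster / mixed)
  built to satisfy the detection thresholds with explicit margins
  (raft alignment ±2° ≪ 15°, cluster spacing 1.5 µm < 2 µm, background
  kept > 45 µm away), so the expected detections are provable;
* metabolite kinetics as the product of a logistic rise after front
  arrival and a symmetric logistic fall, peaking one consumption delay
  after arrival.

What the generator does *not* emulate: gene–gene correlation structure,
operon effects, spatially varying library quality, segmentation errors
and tracking noise in cell tables, or mechanistic secretion/uptake
kinetics.  Passing tests therefore demonstrate correctness of the
analysis machinery under the stated statistical assumptions, not
biological validity on real swarm data.

## Problem sizes

The default test and acceptance runs use three replicates sampled every
20–30 min (≈ 220 in-domain samples), cohorts of 600 genes (100
patterned) or 90–602 genes (6 planted families), 64 × 64 quadrature
nodes, 2 000-cell isotropic fields and 60–80-cell constructed scenarios.
These sizes were chosen so every guarantee is exercised end to end while
a full run completes in seconds.

## Known limitations

* `M` is fixed per run; there is no adaptive basis-size selection.
* PAM is exact best-improvement search, O(k·n²) per sweep — fine for
  hundreds of selected genes, slow beyond ~5 000.
* The depletion detector assumes a monotone tail; oscillating recovery
  near the threshold returns the last sustained crossing only.
* TMM requires strictly positive column sums and at least one gene
  expressed in both the reference and each library.
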