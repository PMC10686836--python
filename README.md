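# swarmspec

Spectral analysis of spatiotemporal gene-expression and phenotype
patterns on an exponentially expanding bacterial swarm domain.

## What this is for

A *Bacillus subtilis* swarm expands from a millimetre-sized inoculum to
a centimetres-wide colony within hours.  Measurements taken across the
swarm — RNA-seq counts, microscopy-derived cell behaviour, extracellular
metabolite concentrations — are indexed by sampling time `t` and radial
position `p`, on a domain that grows as the colony expands and differs
slightly between biological replicates.  `swarmspec` is for researchers
who have such space–time sampled data (or want to simulate it) and need
to answer: *which genes and phenotypes are genuinely patterned in space
and time, and what are the distinct pattern types?*

The package:

1. fits a shared exponential boundary `b(t) = b0 · exp(t/τ)` across
   replicates and rescales all samples onto one dimensionless domain
   `0 ≤ t̃ ≤ T`, `0 ≤ p̃ ≤ exp(t̃)`;
2. builds an orthonormal polynomial basis `P0 … PM` on that domain under
   the weighted inner product
   `⟨f,g⟩ = ∫₀ᵀ dt̃ ∫₀^{exp(t̃)} dp̃ e^{−t̃} f g`
   (Gram–Schmidt on the graded monomials `1, t̃, p̃, t̃², t̃p̃, p̃², …`);
3. compresses each gene into coefficients `c_m` by least squares, stacked
   across replicates, and standardizes them to
   `k_m = (c_m − δ_{m,0} μ/p0)/σ`;
4. scores each gene by the ranking `R = P/E`, the ratio of pattern
   energy `P = Σ_{m≥1} k_m²` to the standardized representation error
   `E = ‖(g−μ)/σ − Σ k_m P_m‖²`, selects patterned genes at the
   weighted median of `R`, clusters their k-vectors by k-medoids on
   cosine distance, and embeds them (together with phenotype properties
   scored the same way) by metric MDS;
5. computes the standard swarm phenotype metrics from per-frame cell
   tables (local nematic order, non-motile clusters, local rafting
   ratio, density fluctuations, …) and analyses metabolite time series
   (depletion, peak-time shifts, diffusion-timescale comparison).

A synthetic-data module generates all inputs with the statistical
structure the analysis assumes, so the entire pipeline is testable with
no external data.  It also processes raw counts the standard way (gene
and library-size filters, TMM normalization, log2 CPM).

## Worked example

Simulate a three-replicate swarm experiment (300 genes, 60 of them with
planted spatiotemporal patterns) and run the full transcriptome
pipeline:

```bash
swarmspec simulate --out demo --seed 7 --n-genes 300 --n-patterned 60
swarmspec transcriptome --counts demo/counts.tsv \
    --annotations demo/annotations.tsv --boundary demo/boundary.tsv \
    --out demo_run --seed 0
```

which prints

```json
{
  "n_genes_after_filter": 300,
  "n_samples_after_filter": 224,
  "tau_h": 1.4623225385817302,
  "T": 3.9193583582847142,
  "n_selected": 19,
  "cluster_sizes": [2, 2, 3, 3, 6, 3],
  "seed": 0,
  "M": 5,
  "n_clusters": 6,
  "config_hash": "c1465152ea86"
}
```

Reading the numbers: all 300 genes pass the detection filter and 224 of
the 242 generated samples survive the library-size filter and fall
inside the common domain window.  The fitted growth timescale
`τ ≈ 1.46 h` matches the generator's 60-fold-expansion-in-6-h default
(`6/ln 60 ≈ 1.47 h`), and `T ≈ 3.9` is the dimensionless horizon shared
by all three replicates.  19 genes carry the top half of the
spatiotemporal ranking mass at this noise level and are grouped into 6
pattern clusters.  Per-gene scores, cluster labels, MDS coordinates and
the fitted domain are written to `demo_run/`.

The same pipeline pieces are importable as a library
(`swarmspec.domain.fit_boundary`, `swarmspec.basis.gram_schmidt_basis`,
`swarmspec.patterns.scores`, …); `swarmspec phenotypes` and
`swarmspec metabolites` expose the cell-table metrics and the metabolite
timing report.

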