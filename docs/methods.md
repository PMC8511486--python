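# Methods

## The model

A structural covariance network (SCN) treats brain regions as nodes and the
inter-subject correlation of a morphometric measure — here regional gray
matter (GM) volume — as the edge weight between them. Because the
correlation is computed *across subjects*, an SCN is a group-level object:
each group yields exactly one network, and subject-level inference is not
available. Everything in this package follows from that constraint.

The analysis chain is:

1. **Residualization.** For every region independently, volume is regressed
   by ordinary least squares on an intercept, age, sex (0/1 indicator),
   education, and the subject's mean overall GM volume; the residuals are
   the "corrected" volumes. Fitting is done once on the pooled sample
   (both groups together). This is required for the permutation scheme to
   be well-defined: permuting group labels only makes sense when both
   groups live in the same corrected space. Mean overall GM volume is the
   unweighted mean of the region columns — a proxy for total GM, which
   would require voxel-level data the pipeline deliberately does not touch.
2. **Network construction.** Pearson correlation of corrected volumes
   across each group's subjects gives a symmetric region-by-region matrix
   with unit diagonal. The matrix is binarized over a density grid
   (default 0.05–0.50, step 0.01): at density *d* exactly
   round(*d*·N(N−1)/2) edges are kept, the largest off-diagonal
   correlations by **signed** value. Signed ranking (rather than |r|)
   keeps "covariance" interpretable — a strong negative correlation is not
   evidence of coordinated development — and is the dominant convention in
   the GM covariance literature; an `edge_rank="absolute"` switch is
   provided. Rounding is half-away-from-zero so edge counts are
   platform-stable. Ties are broken lexicographically by region pair.
   Because one shared ranking serves the whole grid, edge sets nest:
   raising density only adds edges.
3. **Topology.** Global measures: clustering coefficient Cp (mean over all
   nodes; degree<2 nodes score 0), characteristic path length Lp, global
   efficiency Eglob, local efficiency Eloc (per node, the global efficiency
   of the subgraph induced on its neighbors), and the normalized indices
   gamma = Cp/⟨Cp_rand⟩, lambda = Lp/⟨Lp_rand⟩, sigma = gamma/lambda
   against an ensemble of degree-matched random networks. Regional
   measure: betweenness centrality (Brandes, fractional geodesic credit),
   reported raw and divided by the network mean so groups are comparable.
   Curves over the density grid are summarized threshold-free by the
   trapezoidal area under the curve (AUC).
4. **Null model.** "Matched" random networks preserve the exact degree
   sequence via Maslov–Sneppen double-edge swaps (10 successful swaps per
   edge; proposals creating self-loops or duplicate edges are rejected).
   Degree-sequence preservation is the field standard for small-world
   normalization. A graph admitting no valid swap is returned unchanged
   with a warning.
5. **Inference.** Group differences are tested by subject-relabeling
   permutation: corrected volumes of all subjects are reassigned to two
   pseudo-groups of the original sizes, both group networks are rebuilt at
   every density, and the difference in each measure forms the null
   distribution. p = (1 + #{|null| ≥ |observed|})/(n_perm + 1), two-sided
   by default — the add-one convention is a valid permutation p-value and
   can never be 0. Benjamini–Hochberg FDR is applied across densities (per
   global metric) or across regions (nodal AUC test); corrected and
   uncorrected results are always reported side by side, as is the
   empirical 95% band of the null differences.
6. **Hubs.** A region is a hub when its betweenness is at least one sample
   standard deviation (ddof = 1) above the network mean, with "≥" at the
   threshold. The default basis is the AUC of normalized betweenness over
   the grid, since hubs defined at a single density are fragile; a
   single-density basis is available. Zero-variance inputs yield an empty,
   flagged hub set.

## Disconnection policy

Thresholded covariance networks are routinely disconnected at low density.
Lp is therefore averaged over **connected** pairs only (the alternative —
infinite path lengths — would make every low-density curve undefined), and
Eglob handles disconnection natively (1/∞ = 0). A `strict=True` mode turns
disconnection into an error for callers who want the textbook definitions.
A graph with no connected pair has undefined Lp; inside permutation loops
such values are flagged and propagated as NaN, never silently dropped.

## Synthetic cohort

No subject-level data ships with the package, so a generator provides
cohorts with known ground truth. Regions are partitioned into modules
(default 90 regions, 6 modules, partitioned as evenly as possible) and the
target correlation is `within_r` for same-module pairs, `between_r`
otherwise — a two-level exchangeable structure that is positive
semi-definite whenever 0 ≤ between_r ≤ within_r < 1 (verified by
eigendecomposition at construction). Volumes are

    baseline + Σ_k effect_k · covariate_k + noise_sd · L z,

with z standard normal and L the symmetric PSD square root of the target
matrix, so the population correlation of the noise equals the target
exactly. Covariates: age ~ U(55, 80) years, sex ~ Bernoulli(0.5),
education ~ U(6, 16) years. Defaults: 38 controls and 32 patients;
within-module correlation 0.6 (control) vs 0.4 (patient) and between-module
0.1 — the planted group difference, a free design choice, not an estimate
of any real effect size; baseline volume 7.5 and noise SD 0.75 (volume
units of ml-scale regional GM); covariate slopes −0.03/yr age, +0.5 sex,
+0.02/yr education, small relative to the noise so residualization matters
but does not dominate. The random stream is consumed per subject
(covariates, then the region noise vector), so growing a group never
perturbs earlier subjects' draws.

What the generator emulates: modular inter-regional covariance, linear
nuisance effects, a group difference in covariance strength that lowers
clustering and local efficiency in the "patient" group. What it does not:
spatially smooth anatomy, distance-dependent correlation decay, hemispheric
symmetry, non-Gaussian volume distributions, site or scanner effects.
Passing tests therefore demonstrate that the pipeline recovers planted
covariance structure of realistic size and noise — not that any clinical
finding replicates.

## Numerical choices

- Correlations are clipped to [−1, 1] and symmetrized before ranking; the
  diagonal is forced to 1.
- All-pairs hop distances use breadth-first boolean matrix expansion
  (dense numpy), exact for unweighted graphs.
- Triangle counts use diag(A³)/2 via BLAS matmul.
- Betweenness delegates to networkx's Brandes implementation
  (`normalized=False`); the test suite checks it against an independent
  geodesic-counting oracle (Floyd–Warshall distances + path counts from
  adjacency-matrix powers) to 1e-10.
- BH-FDR delegates to statsmodels' `multipletests`; tested against the
  hand-computed step-up formula.
- Normalized betweenness with zero mean raw betweenness (e.g. complete
  graphs) is defined as all-zero and flagged, not NaN.
- Permutation streams: partition k is drawn from `default_rng([seed, k])`;
  small-world ensembles inside permutation k use
  `default_rng([seed, 1_000_001 + k])`. The pipeline expands its master
  seed the same way (`[seed, stage_counter]`), so stages re-run in
  isolation reproduce their part of the bundle.

## Problem sizes and ensembles

The observed networks use the full 1,000-network rewired ensemble by
default. Inside permutation loops the ensemble for gamma/lambda/sigma is
capped (default 20 per graph, configurable): a full crossing of 1,000
permutations × 46 densities × 1,000 rewirings is cluster-scale, and since
sigma enters only through an ensemble mean, smaller ensembles widen
Monte-Carlo error without biasing the test statistic. The bundled analysis
scripts use 199 permutations and 100-network ensembles; both are settings,
not limits, and the test suite exercises the same code paths at reduced
sizes with the ensemble reductions documented inline.

## Known limitations

- Binary, undirected graphs only — no weighted, directed or multilayer
  variants, and no rich-club/modularity/assortativity measures.
- No parametric comparison path (t-test/ANCOVA) and no cluster-based
  multiple-comparison schemes.
- The pipeline starts at extracted ROI volumes; segmentation,
  normalization and atlas handling are out of scope, and the BrainNet
  Viewer export uses user-supplied (or synthetic placeholder) coordinates.
- Hub counts depend on the betweenness basis (AUC vs single density) and
  on sampling noise; they are descriptive, not inferential.
- The run log carries wall-clock timestamps and is the one file excluded
  from the byte-identity guarantee of fixed-seed pipeline bundles.
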