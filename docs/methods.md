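# Methods

## The model

`covnet` analyzes *single-subject structural covariance networks*: brain
graphs built from one subject's regional gray-matter morphometry. The node
set is 82 regions — the 68 Desikan-Killiany cortical parcels (mean
thickness, mm) plus 14 subcortical structures (volume, mm³: thalamus,
caudate, putamen, pallidum, hippocampus, amygdala, accumbens per
hemisphere), in a fixed documented order (left cortex, right cortex, left
subcortex, right subcortex).

The pipeline has four stages.

**1. Confound removal and control-referenced standardization.** Each
regional value is regressed (per-region OLS) on age, sex (0/1 indicator,
male = 1) and total intracranial volume. The regression is fitted on the
control group by default and applied to all subjects; a `pooled` option
fits on everyone. TIV is regressed from thickness as well as volume —
harmless when the true coefficient is ~0, and uniform across regions.
Residuals are z-scored with the control-group residual mean and unbiased
(n−1) SD, so a patient z expresses deviation from the covariate-adjusted
control norm. Fitting on controls only avoids disease-related covariate
bias leaking into the confound model.

**2. Joint-variation networks.** For one subject with z-scores
z₁…z₈₂, the edge weight between regions i and j is

    w_ij = exp(−(z_i − z_j)²) ∈ (0, 1],

equal to 1 exactly when two regions deviate identically. The graph is
binarized by *proportional density thresholding*: at density d the
strongest round(d·3321) undirected pairs become edges. Ties are broken by
(weight desc, row index, column index), which makes edge sets nested
across densities and the whole construction deterministic. The profile
runs over d = 0.10…0.40 in steps of 0.01 (31 points) by default — the
range that preserves small-world topology while limiting spurious edges.

**3. Graph metrics.** Per density: Watts-Strogatz nodal clustering
(nodes with degree < 2 get 0), characteristic path length L, local
efficiency (global efficiency of the neighbor-induced subgraph) and
degree. Global metrics are normalized against degree-preserving
Maslov-Sneppen rewired null graphs: γ = C/⟨C_rand⟩, λ = L/⟨L_rand⟩,
σ = γ/λ, with σ > 1.1 the conventional small-world signature. Each metric
profile is summarized by its trapezoidal area under the curve (AUC) over
the density grid, a threshold-free scalar (units: metric × density; a
constant metric of 1 over 0.10–0.40 has AUC 0.30).

**4. Group statistics.** Group differences in AUC metrics are tested by
label permutation of the mean-difference statistic |mean(A) − mean(B)|:
exhaustive enumeration when the number of assignments fits the budget
(p is the exact count ratio), otherwise Monte-Carlo with the add-one
convention p = (1+b)/(1+m), which cannot return 0. Default 5000
permutations. Effect sizes are Hedges' g (pooled-SD standardized mean
difference with small-sample correction J = 1 − 3/(4n−9); sign = first
group minus second). Bonferroni families: the 3 global metrics for global
comparisons; the 82 nodes, per metric, for local comparisons. A nuisance
covariate (by default the clinical dementia rating, available only for
patient groups) is handled by Freedman-Lane residual permutation: regress
the metric on the covariate pooled over both groups, permute the
residuals, re-add fitted values, recompute the statistic. Top-k (default
20) region rankings per group and Spearman correlations (average ranks,
pairwise deletion of missing scores) between global AUCs and clinical
scores complete the outputs. Significant local effects are exported as
BrainNet Viewer `.node` files with node size proportional to |g|, using
packaged *approximate* MNI centroids (suitable for rendering, not for
stereotaxy).

## Disconnected graphs and the path-length policy

At 10% density individual graphs routinely fragment. The
`characteristic_path_length` operation defaults to averaging over
mutually reachable pairs (unreachable pairs excluded), with a
largest-component option. For the *pipeline*, however, the default
disconnected-path policy is `harmonic`: L = 1/E_glob, the reciprocal of
mean inverse distance over all pairs (1/∞ = 0). The reachable-pairs
average has a well-known pathology for group comparisons: a group whose
networks fragment *more* silently drops its longest (inter-fragment)
distances from the average, so a genuine integration deficit can appear
as a *shorter* path length. The harmonic form penalizes disconnection
monotonically and restores the expected ordering; we verified on
synthetic cohorts that the decoupled group's λ inverts direction under
the reachable policy and is stable under the harmonic one. Both
alternatives remain available via `path_policy`.

## Null models

Degree-preserving randomization attempts `swaps_per_edge × |E|`
double-edge swaps (default 10 per edge), each replacing (a,b),(c,d) with
(a,d),(c,b) when the result stays simple; degree sequences are preserved
exactly, and a lattice loses most of its clustering under this budget
(property-tested). The default of 100 nulls per graph per density keeps
the Monte-Carlo noise of ⟨C_rand⟩ and ⟨L_rand⟩ well below typical group
differences; analyses in the test suite use 12 nulls with a 7-point
density grid (0.10…0.40 step 0.05) to keep runtimes short, which widens
per-subject γ/λ noise by only a few percent of the group effects probed.
Swap loops run through a numba-compiled kernel when numba is available,
with an identical pure-Python fallback.

## The synthetic cohort generator

Real single-subject covariance studies draw on access-controlled clinical
morphometry; the generator emulates the *statistical structure* such data
must have for the pipeline to be meaningful:

* **Demographics** follow the emulated study population: 110 controls and
  34 subjects per patient group; ages ≈ 63 ± 7.5 y (controls, svPPA-like
  group) and 68 ± 7.3 y (nfvPPA-like group, deliberately older so
  confound correction is exercised); group-specific sex ratios; TIV ≈
  1.47–1.54 l with group-specific spread. Clinical scores (MMSE, CDR,
  CDR-SOB, semantic/lexical fluency, BNT) are drawn per group from
  study-like means and SDs, truncated to scale bounds; CDR is absent
  (NaN) for controls, as in the emulated study table.
* **Covariate effects**: thickness loses 0.004 mm/y of age; volumes lose
  0.2%/y; males get +0.03 mm / +4%; volumes scale as (TIV/1500 ml)^κ with
  κ = 1.
* **Shared covariance** comes from one latent factor per anatomical lobe
  (frontal, temporal, parietal, occipital, limbic, subcortical): cortical
  loading 0.12 mm against 0.06 mm independent noise (within-lobe r ≈ 0.8,
  total control SD ≈ 0.134 mm, realistic for thickness); subcortical 6% /
  3% of baseline volume. An optional global factor exists but defaults to
  off: a class-uniform additive factor cancels from pairwise-difference
  edge weights and contributes nothing to network structure.
* **Decoupling** is the designed disease effect on covariance: in a
  patient group, selected regions keep only √(1−δ) of their factor
  loading and receive compensating independent noise of variance
  δ·loading², so every region's marginal variance is *exactly* invariant
  to δ — decoupling converts shared variance into private variance
  without an atrophy signature. Defaults: δ = 0.8 on temporal + limbic
  cortex plus hippocampus/amygdala for the svPPA-like group; δ = 0.8 on
  left frontal cortex for the nfvPPA-like group.
* **Atrophy** is a graded mean decrease: nominal 15% (svPPA-like) or 12%
  (nfvPPA-like) of baseline, with per-region severity grades spanning
  ±30% linearly across the affected set and a per-patient severity
  multiplier ~ N(1, 0.3) truncated at 0. The gradation matters: uniform
  atrophy shifts the affected regions' z-scores together and leaves their
  pairwise differences — hence their edges — untouched, whereas graded,
  severity-scaled atrophy widens patient z-dispersion, pushes affected
  nodes to the network periphery and produces the integration deficit
  (higher λ) seen in real patient cohorts.

Generation is a pure function of the config seed.

**What the generator does not emulate**: spatial autocorrelation beyond
lobe communities, long-range (inter-lobe) covariance gradients,
scanner/site effects, non-Gaussian morphometry distributions, realistic
missingness, or any empirically calibrated covariance (no real covariance
matrix is publicly available to fit against). Passing tests therefore
demonstrate that the pipeline recovers *designed* covariance decoupling
and graded atrophy of realistic magnitude under Gaussian assumptions —
not that it would detect a particular clinical effect in real data.

## Numerical choices

* Edge counts: round-half-away-from-zero of d·3321.
* Tie-breaks in thresholding and rankings: deterministic, by index order.
* Permutation p-values: add-one convention when sampled; exact ratio when
  exhaustive; a tolerance of 1e-12 treats numerically equal permuted
  statistics as ties (conservative).
* Degenerate inputs raise informative errors naming the offending region
  or covariate: non-finite z-scores, zero control SD, collinear design,
  empty groups, edgeless graphs.
* All randomness flows from `numpy.random.SeedSequence` spawning; the
  pipeline manifest records the master seed and derived stage seeds, and
  rerunning a config byte-reproduces every CSV.

## Known limitations

* Metrics are binary-graph only; weighted variants are out of scope.
* Bonferroni is the only multiplicity correction offered.
* The nuisance adjustment handles a single covariate.
* The generator's lobe-community covariance is a minimal sufficient
  model, not a fitted one; absolute metric values (not directions) will
  differ from any particular real cohort.
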