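# covnet

Single-subject structural covariance network analysis for gray-matter
morphometry: from a table of regional cortical thickness and subcortical
volume values to joint-variation brain graphs, density-profiled
small-world metrics, and permutation-based group comparisons.

## Who this is for

Neuroimaging groups studying how neurodegeneration — here modeled after
the linguistic variants of frontotemporal dementia (svPPA, nfvPPA) versus
healthy controls — reorganizes the *coordinated variation* of gray-matter
morphometry. The pipeline consumes precomputed FreeSurfer-style tables
(one row per subject: 68 Desikan-Killiany mean-thickness values, 14
subcortical volumes, plus age, sex, TIV, group, and optional clinical
scores). Because such clinical datasets are typically access-controlled,
the package ships a first-class synthetic cohort generator that emulates
the covariate structure, lobe-level shared covariance, and group-specific
regional decoupling/atrophy such data must exhibit.

## The model

For each subject, regional values are residualized against age, sex and
total intracranial volume (per-region OLS fitted on controls), and
z-scored with the control group's residual mean and SD. The edge weight
between regions *i* and *j* is the joint variation

  w_ij = exp(−(z_i − z_j)²) ∈ (0, 1],

maximal when both regions deviate from the control norm identically.
Binary graphs are obtained at proportional densities d = 0.10…0.40; at
each density the package computes clustering C, characteristic path
length L, local efficiency, and degree, normalizes the global metrics
against 100 Maslov-Sneppen degree-preserving null graphs,

  γ = C/⟨C_rand⟩, λ = L/⟨L_rand⟩, σ = γ/λ (small-world when σ > 1.1),

and summarizes each metric by its trapezoidal AUC across densities.
Groups are compared by label permutation (default 5000, add-one p-value
convention), Bonferroni correction (3 global metrics; 82 nodes per local
metric), Hedges' g effect sizes, optional Freedman-Lane adjustment for a
nuisance covariate (e.g. CDR), top-20 region rankings and Spearman
correlations with clinical scores. See `docs/methods.md` for assumptions,
defaults, and numerical policies.

## Worked example

```python
from covnet import CohortConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    cohort=CohortConfig(n_hc=30, n_svppa=12, n_nfvppa=12),
    density_step=0.05,   # 7-point density grid, 0.10 ... 0.40
    n_null=20,           # null graphs per density
    n_perm=2000,
    seed=42,
    out_dir="demo",
)
run_pipeline(config)
```

or equivalently from the shell, with a YAML config:

```bash
covnet run-all --config demo.yaml --seed 42 --out demo/
```

`demo/auc_global.csv` then holds one AUC triple per subject; group means
from this run:

```
        gamma  lambda  sigma
group
HC      0.888   0.417  0.618
nfvPPA  0.774   0.425  0.533
svPPA   0.668   0.436  0.450
```

The temporal-limbic-decoupled (svPPA-like) group loses normalized
clustering (γ AUC 0.888 → 0.668) and gains normalized path length
(λ AUC 0.417 → 0.436): less segregated, less integrated networks. The
corresponding rows of `demo/comparisons.csv`:

```
metric  observed_diff  p_value  p_bonferroni  hedges_g
 gamma       0.219762 0.000500      0.001499  2.080581
lambda      -0.019500 0.041979      0.125937 -0.685238
 sigma       0.167326 0.000500      0.001499  2.119209
```

`observed_diff` is HC minus svPPA; at this small demo size γ and σ
survive Bonferroni while λ does not (it does at the default 110 vs 34
cohort). The run directory also contains per-subject z-scores, weight
matrices (`.edge`, BrainNet-compatible), local-metric AUC tables,
top-20 region rankings, clinical correlations, `.node` files sized by
|Hedges' g| for significant local effects, and a `manifest.json` that
echoes every parameter and seed — rerunning the same config reproduces
all outputs byte-for-byte.

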