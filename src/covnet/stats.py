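"""Permutation group comparisons, effect sizes, rankings, correlations.

The group statistic is the absolute difference of group means of the
AUC-summarized metric.  Significance comes from label permutation:
exhaustive enumeration when the number of distinct group assignments does
not exceed the permutation budget (p is then the exact count ratio), and
Monte-Carlo sampling otherwise with the add-one convention
p = (1 + #{permuted >= observed}) / (1 + n_perm), which can never return 0.

Effect sizes are Hedges' g (bias-corrected standardized mean difference);
multiplicity is handled by Bonferroni; nuisance covariates (e.g. the
clinical dementia rating when comparing patient groups) are handled by a
Freedman-Lane residual-permutation scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class ComparisonResult:
    """One permutation comparison of a metric AUC between two groups."""

    metric: str
    scope: str  # "global" or a node/region name
    group_a: str
    group_b: str
    observed_diff: float  # mean(A) - mean(B), signed
    p_value: float
    p_bonferroni: float
    hedges_g: float
    n_permutations: int
    seed: int | None


def _perm_indices(n: int, n_a: int, n_perm: int, rng: np.random.Generator):
    """Permutation assignments of n pooled values into a group of size n_a.

    Returns (idx, exhaustive): idx is an (R, n) array of pooled-index
    permutations whose first n_a entries form group A.  Exhaustive when
    C(n, n_a) <= n_perm (identity assignment included exactly once).
    """
    total = comb(n, n_a)
    if total <= n_perm:
        rows = np.empty((total, n), dtype=np.intp)
        all_idx = frozenset(range(n))
        for r, a_idx in enumerate(combinations(range(n), n_a)):
            rest = sorted(all_idx - set(a_idx))
            rows[r, :n_a] = a_idx
            rows[r, n_a:] = rest
        return rows, True
    u = rng.random((n_perm, n))
    return np.argsort(u, axis=1), False


def _mean_diff_stats(pooled: np.ndarray, n_a: int, idx: np.ndarray) -> np.ndarray:
    perm = pooled[idx]
    return np.abs(perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1))


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 5000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Two-sample permutation p-value for |mean(A) - mean(B)|."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    idx, exhaustive = _perm_indices(pooled.size, a.size, n_perm, rng)
    stats = _mean_diff_stats(pooled, a.size, idx)
    count = int(np.sum(stats >= obs - _TIE_EPS * max(1.0, obs)))
    if exhaustive:
        return count / idx.shape[0]
    return (1 + count) / (1 + n_perm)


def hedges_g(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Bias-corrected standardized mean difference, mean(A) - mean(B).

    Pooled SD uses the (n1 + n2 - 2) denominator; the small-sample
    correction is J = 1 - 3 / (4 (n1 + n2) - 9).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("pooled standard deviation is zero")
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(j * d)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m) elementwise."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m must be >= number of p-values")
    return np.minimum(1.0, p * m)


def adjust_for_nuisance(
    auc_values_a: np.ndarray,
    auc_values_b: np.ndarray,
    covariate_a: np.ndarray,
    covariate_b: np.ndarray,
    n_perm: int = 5000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Freedman-Lane permutation p-value adjusting for one nuisance covariate.

    The metric is regressed on the covariate pooled across both groups;
    residuals are permuted, fitted values re-added, and the group
    mean-difference statistic recomputed on each permuted reconstruction.
    A constant covariate triggers a warning and an unadjusted test.
    """
    a = np.asarray(auc_values_a, dtype=float)
    b = np.asarray(auc_values_b, dtype=float)
    ca = np.asarray(covariate_a, dtype=float)
    cb = np.asarray(covariate_b, dtype=float)
    if a.size != ca.size or b.size != cb.size:
        raise ValueError("covariate must be available for every subject")
    if not (np.all(np.isfinite(ca)) and np.all(np.isfinite(cb))):
        raise ValueError("covariate must be finite for every subject")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = np.concatenate([a, b])
    cov = np.concatenate([ca, cb])
    n, n_a = y.size, a.size
    if np.ptp(cov) == 0:
        warnings.warn("constant nuisance covariate; falling back to unadjusted test")
        fitted = np.full(n, y.mean())
    else:
        X = np.column_stack([np.ones(n), cov])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
    resid = y - fitted
    obs = abs(y[:n_a].mean() - y[n_a:].mean())
    idx, exhaustive = _perm_indices(n, n_a, n_perm, rng)
    ystar = fitted[None, :] + resid[idx]
    stats = np.abs(ystar[:, :n_a].mean(axis=1) - ystar[:, n_a:].mean(axis=1))
    count = int(np.sum(stats >= obs - _TIE_EPS * max(1.0, obs)))
    if exhaustive:
        return count / idx.shape[0]
    return (1 + count) / (1 + n_perm)


@dataclass(frozen=True)
class RegionRanking:
    """Regions ordered by group-mean AUC of one local metric."""

    metric: str
    group: str
    regions: tuple[str, ...]
    values: tuple[float, ...]


def rank_regions(
    local_auc: pd.DataFrame,
    metric: str,
    group: str,
    k: int = 20,
) -> RegionRanking:
    """Top-k regions by group-mean local-metric AUC (ties: atlas order).

    ``local_auc``: subjects x regions AUC values for one metric, columns
    in atlas order.
    """
    if k > local_auc.shape[1]:
        raise ValueError("k cannot exceed the number of regions")
    means = local_auc.mean(axis=0).to_numpy()
    order = np.lexsort((np.arange(means.size), -means))[:k]
    return RegionRanking(
        metric=metric,
        group=group,
        regions=tuple(local_auc.columns[order]),
        values=tuple(float(means[i]) for i in order),
    )


def spearman_metric_clinical(
    metric_values: np.ndarray,
    clinical_values: np.ndarray,
) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties, two-sided p).

    Subjects with a missing value in either series are dropped pairwise.
    """
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(clinical_values, dtype=float)
    if x.size != y.size:
        raise ValueError("paired series must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        raise ValueError("need at least 3 paired finite observations")
    rho, p = sps.spearmanr(x[keep], y[keep])
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# batched comparisons used by the pipeline

def compare_global(
    global_auc: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    n_perm: int = 5000,
    seed: int | None = None,
    nuisance: pd.Series | None = None,
) -> list[ComparisonResult]:
    """Compare each global metric AUC (gamma, lambda, sigma) between two
    groups; Bonferroni family = the 3 global metrics."""
    return _compare_table(
        global_auc, groups, group_a, group_b, n_perm, seed, nuisance, scope="global"
    )


def compare_local(
    local_auc: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    metric: str,
    n_perm: int = 5000,
    seed: int | None = None,
    nuisance: pd.Series | None = None,
) -> list[ComparisonResult]:
    """Compare one local metric's AUC at every region between two groups;
    Bonferroni family = the number of regions."""
    results = _compare_table(
        local_auc, groups, group_a, group_b, n_perm, seed, nuisance, scope=None
    )
    return [
        ComparisonResult(
            metric=metric,
            scope=r.metric,  # column name = region
            group_a=r.group_a,
            group_b=r.group_b,
            observed_diff=r.observed_diff,
            p_value=r.p_value,
            p_bonferroni=r.p_bonferroni,
            hedges_g=r.hedges_g,
            n_permutations=r.n_permutations,
            seed=r.seed,
        )
        for r in results
    ]


def _compare_table(
    table: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    n_perm: int,
    seed: int | None,
    nuisance: pd.Series | None,
    scope: str | None,
) -> list[ComparisonResult]:
    in_a = (groups == group_a).to_numpy()
    in_b = (groups == group_b).to_numpy()
    m = table.shape[1]
    out: list[ComparisonResult] = []
    ss = np.random.SeedSequence(seed)
    for col, child in zip(table.columns, ss.spawn(m)):
        a = table.loc[in_a, col].to_numpy(float)
        b = table.loc[in_b, col].to_numpy(float)
        rng = np.random.default_rng(child)
        if nuisance is not None:
            p = adjust_for_nuisance(
                a, b,
                nuisance.to_numpy(float)[in_a],
                nuisance.to_numpy(float)[in_b],
                n_perm=n_perm, seed=rng,
            )
        else:
            p = permutation_test(a, b, n_perm=n_perm, seed=rng)
        out.append(
            ComparisonResult(
                metric=str(col),
                scope=scope if scope is not None else str(col),
                group_a=group_a,
                group_b=group_b,
                observed_diff=float(a.mean() - b.mean()),
                p_value=p,
                p_bonferroni=float(bonferroni_adjust([p], m)[0]),
                hedges_g=hedges_g(a, b),
                n_permutations=n_perm,
                seed=seed,
            )
        )
    return out
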