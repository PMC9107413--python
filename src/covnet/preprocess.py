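"""Confound removal and control-referenced standardization.

Each regional value is regressed on age, sex and total intracranial volume
(OLS, fitted per region), and the residual is z-scored using the mean and
the unbiased (n-1) standard deviation of the *control* residuals.  Patient
z-scores therefore express deviation from the covariate-adjusted control
norm, which is what the joint-variation edge weight expects.

The regression is fitted on the reference (control) group by default and
applied to every subject; fitting on the pooled sample is available via
``fit_population="pooled"`` for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COVARIATES = ("age", "sex", "tiv")
META_COLUMNS = ("subject_id", "group", "age", "sex", "tiv")


def region_columns(table: pd.DataFrame) -> list[str]:
    """Regional value columns of a morphometry table (everything after the
    covariate block, in stored order)."""
    return [c for c in table.columns if c not in META_COLUMNS]


def _design_matrix(table: pd.DataFrame) -> np.ndarray:
    sex01 = (table["sex"].astype(str).str.upper() == "M").to_numpy(float)
    X = np.column_stack(
        [
            np.ones(len(table)),
            table["age"].to_numpy(float),
            sex01,
            table["tiv"].to_numpy(float),
        ]
    )
    return X


def _check_full_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # identify the offending covariate for the error message
    names = ["intercept", "age", "sex", "tiv"]
    for j in range(1, X.shape[1]):
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X):
            raise ValueError(
                f"design matrix is rank-deficient: covariate {names[j]!r} is "
                "collinear with the remaining covariates"
            )
    raise ValueError("design matrix is rank-deficient")


@dataclass(frozen=True)
class ConfoundModel:
    """Per-region OLS coefficients for [intercept, age, sex, tiv]."""

    regions: tuple[str, ...]
    coef: np.ndarray  # (n_regions, 4)
    fit_population: str  # e.g. "HC" or "pooled"

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = _design_matrix(table)
        return X @ self.coef.T  # (n_subjects, n_regions)


def fit_confound_model(
    table: pd.DataFrame,
    reference_group: str = "HC",
    fit_population: str = "reference",
) -> ConfoundModel:
    """Fit the per-region confound regression.

    Parameters
    ----------
    table : morphometry table (covariates + regional columns).
    reference_group : group label whose subjects define the fitting
        population when ``fit_population == "reference"``.
    fit_population : "reference" (default) or "pooled".
    """
    if fit_population == "reference":
        fit_tab = table[table["group"] == reference_group]
        pop_label = reference_group
    elif fit_population == "pooled":
        fit_tab = table
        pop_label = "pooled"
    else:
        raise ValueError("fit_population must be 'reference' or 'pooled'")
    if len(fit_tab) == 0:
        raise ValueError(f"no subjects in fitting population {pop_label!r}")
    if len(fit_tab) < 5:
        raise ValueError(
            f"need at least 5 subjects to fit the confound model, got {len(fit_tab)}"
        )
    X = _design_matrix(fit_tab)
    _check_full_rank(X)
    regions = region_columns(table)
    Y = fit_tab[regions].to_numpy(float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return ConfoundModel(regions=tuple(regions), coef=coef.T, fit_population=pop_label)


@dataclass(frozen=True)
class ZScoreTable:
    """Confound-adjusted values standardized against the control group."""

    values: pd.DataFrame  # subjects x regions z-scores, with subject_id index
    control_mean: np.ndarray
    control_sd: np.ndarray
    control_ids: tuple[str, ...]

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)


def residualize_and_zscore(
    table: pd.DataFrame,
    model: ConfoundModel,
    control_ids: list[str] | None = None,
) -> ZScoreTable:
    """Residualize all subjects and z-score against control residuals.

    ``control_ids`` defaults to the subjects of the model's fitting
    population (all subjects if it was pooled).
    """
    regions = region_columns(table)
    if tuple(regions) != model.regions:
        raise ValueError("model regions do not match table regions")
    if control_ids is None:
        if model.fit_population == "pooled":
            control_ids = list(table["subject_id"])
        else:
            control_ids = list(
                table.loc[table["group"] == model.fit_population, "subject_id"]
            )
    if len(control_ids) == 0:
        raise ValueError("control_ids must be non-empty")
    missing = set(control_ids) - set(table["subject_id"])
    if missing:
        raise ValueError(f"control_ids not in table: {sorted(missing)}")

    resid = table[regions].to_numpy(float) - model.predict(table)
    is_ctrl = table["subject_id"].isin(control_ids).to_numpy()
    mu = resid[is_ctrl].mean(axis=0)
    sd = resid[is_ctrl].std(axis=0, ddof=1)
    bad = np.flatnonzero(~(sd > 0))
    if bad.size:
        raise ValueError(
            f"zero control standard deviation in region(s): "
            f"{[regions[i] for i in bad]}"
        )
    z = (resid - mu) / sd
    values = pd.DataFrame(z, columns=regions, index=pd.Index(table["subject_id"], name="subject_id"))
    return ZScoreTable(
        values=values,
        control_mean=mu,
        control_sd=sd,
        control_ids=tuple(control_ids),
    )
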