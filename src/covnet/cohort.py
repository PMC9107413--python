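"""Synthetic morphometric cohorts with designed covariance structure.

Real single-subject covariance studies start from a table of regional
cortical thickness and subcortical volume values per participant.  This
module generates such tables with the statistical features the downstream
pipeline assumes:

* covariate effects (age slope, sex offset, head-size scaling of volumes),
* shared variation through latent factors organized by anatomical lobe,
  so that regions within a lobe co-vary and produce strong joint-variation
  edges,
* group-specific *decoupling*: in a patient-like group, a designated set
  of regions has its share of lobe-factor variance replaced by independent
  noise, weakening that group's within-lobe edges without changing any
  region's marginal variance,
* optional group mean shifts (atrophy-like decreases).

Generation is a pure function of the seed: the same config always yields
the same table.

Per-subject regional value model (region r, subject s in group g):

    x_sr = baseline_r
           + age_slope * (age_s - 60)
           + sex_offset * male_s
           + [volumes only] baseline_r * ((tiv_s / tiv_ref)^kappa - 1)
           + mean_shift_{r,g}
           + loading_r * sqrt(1 - delta_{r,g}) * f_{lobe(r),s}
           + global_loading_r * u_s
           + eps_sr

where f and u are standard-normal latent factors and eps has variance
noise_r^2 + delta_{r,g} * loading_r^2.  The sqrt(1 - delta) attenuation
together with the compensating noise keeps the marginal variance of every
region exactly invariant to delta; delta only moves variance from shared
to private.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .atlas import AtlasDefinition, CORTICAL, make_default_atlas

GROUPS = ("HC", "svPPA", "nfvPPA")

CLINICAL_SCORES = ("MMSE", "CDR", "CDR_SOB", "semantic_fluency", "lexical_fluency", "BNT")

# (lower, upper) bounds of each clinical scale
CLINICAL_BOUNDS = {
    "MMSE": (0.0, 30.0),
    "CDR": (0.0, 3.0),
    "CDR_SOB": (0.0, 18.0),
    "semantic_fluency": (0.0, 60.0),
    "lexical_fluency": (0.0, 60.0),
    "BNT": (0.0, 15.0),
}

# group -> score -> (mean, sd); None means not collected for that group
_CLINICAL_PARAMS: dict[str, dict[str, tuple[float, float] | None]] = {
    "HC": {
        "MMSE": (29.35, 0.77),
        "CDR": None,
        "CDR_SOB": None,
        "semantic_fluency": (24.25, 5.53),
        "lexical_fluency": (16.37, 4.34),
        "BNT": (14.46, 0.78),
    },
    "svPPA": {
        "MMSE": (24.97, 5.10),
        "CDR": (0.63, 0.31),
        "CDR_SOB": (3.40, 1.72),
        "semantic_fluency": (9.03, 4.15),
        "lexical_fluency": (8.97, 4.47),
        "BNT": (5.90, 3.42),
    },
    "nfvPPA": {
        "MMSE": (25.54, 4.04),
        "CDR": (0.48, 0.40),
        "CDR_SOB": (2.15, 2.11),
        "semantic_fluency": (10.72, 6.01),
        "lexical_fluency": (5.53, 3.35),
        "BNT": (12.64, 2.28),
    },
}

_LOBE_BASE_THICKNESS = {
    "frontal": 2.60,
    "temporal": 2.90,
    "parietal": 2.35,
    "occipital": 2.05,
    "limbic": 2.70,
}

_SUBCORTICAL_BASE_VOLUME = {
    "thalamus": 7000.0,
    "caudate": 3500.0,
    "putamen": 4800.0,
    "pallidum": 1600.0,
    "hippocampus": 3900.0,
    "amygdala": 1500.0,
    "accumbens": 550.0,
}


@dataclass(frozen=True)
class SubjectRecord:
    """Covariates and clinical scores for one participant."""

    subject_id: str
    group: str
    age: float
    sex: str  # "M" or "F"
    tiv: float  # ml
    clinical: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.tiv <= 0:
            raise ValueError("tiv must be positive")
        for k, v in self.clinical.items():
            lo, hi = CLINICAL_BOUNDS[k]
            if np.isfinite(v) and not (lo <= v <= hi):
                raise ValueError(f"{k}={v} outside scale bounds [{lo}, {hi}]")


@dataclass(frozen=True)
class RegionSelector:
    """Selects atlas regions by lobe and/or hemisphere, plus explicit names."""

    lobes: tuple[str, ...] | None = None
    hemisphere: str | None = None
    names: tuple[str, ...] | None = None

    def mask(self, atlas: AtlasDefinition) -> np.ndarray:
        return np.asarray(
            atlas.mask(lobes=self.lobes, hemisphere=self.hemisphere, names=self.names)
        )


@dataclass(frozen=True)
class GroupEffect:
    """Designed group-level deviation from the control generative model."""

    decoupling: tuple[tuple[RegionSelector, float], ...] = ()
    # fractional decrease of the regional baseline, e.g. 0.06 = -6%
    mean_shift: tuple[tuple[RegionSelector, float], ...] = ()
    # atrophy is graded, not uniform: per-region severity multipliers span
    # [1 - spread, 1 + spread] linearly across each selected region set
    mean_shift_spread: float = 0.5


def _default_group_effects() -> dict[str, GroupEffect]:
    temporal_limbic = RegionSelector(
        lobes=("temporal", "limbic"),
        names=("lh_hippocampus", "rh_hippocampus", "lh_amygdala", "rh_amygdala"),
    )
    left_frontal = RegionSelector(lobes=("frontal",), hemisphere="L")
    return {
        "HC": GroupEffect(),
        "svPPA": GroupEffect(
            decoupling=((temporal_limbic, 0.8),),
            mean_shift=((temporal_limbic, 0.15),),
            mean_shift_spread=0.3,
        ),
        "nfvPPA": GroupEffect(
            decoupling=((left_frontal, 0.8),),
            mean_shift=((left_frontal, 0.12),),
            mean_shift_spread=0.3,
        ),
    }


@dataclass
class CohortConfig:
    """Generative settings for a synthetic cohort.

    Demographic defaults follow the study population this generator
    emulates: 110 controls and 34 subjects per patient group, controls and
    svPPA around age 63, nfvPPA older on average (68) so that confound
    correction is exercised, and head size (TIV, ml) around 1.5 l.
    """

    n_hc: int = 110
    n_svppa: int = 34
    n_nfvppa: int = 34
    seed: int = 0

    # group -> (mean, sd) of age in years
    age_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "HC": (63.1, 7.5),
            "svPPA": (62.9, 6.3),
            "nfvPPA": (68.3, 7.3),
        }
    )
    # group -> probability of male sex
    sex_p_male: dict[str, float] = field(
        default_factory=lambda: {"HC": 49 / 110, "svPPA": 20 / 34, "nfvPPA": 15 / 34}
    )
    # group -> (mean, sd) of TIV in ml
    tiv_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "HC": (1517.7, 69.0),
            "svPPA": (1535.3, 156.8),
            "nfvPPA": (1471.1, 171.2),
        }
    )

    # covariate effect sizes
    age_slope_cortical: float = -0.004  # mm per year
    age_slope_subcortical: float = -0.002  # fraction of baseline per year
    sex_offset_cortical: float = 0.03  # mm, male minus female
    sex_offset_subcortical: float = 0.04  # fraction of baseline, male minus female
    tiv_exponent: float = 1.0  # volume ~ (tiv/tiv_ref)^exponent
    tiv_ref: float = 1500.0  # ml

    # shared-covariance spec: one latent factor per lobe community plus an
    # optional global factor (off by default: a class-uniform additive
    # factor cancels from pairwise-difference edge weights)
    loading_cortical: float = 0.12  # mm
    loading_subcortical: float = 0.06  # fraction of baseline
    global_loading_scale: float = 0.4  # global loading = scale * lobe loading
    include_global_factor: bool = False

    # independent noise
    noise_cortical: float = 0.06  # mm
    noise_subcortical: float = 0.03  # fraction of baseline

    group_effects: dict[str, GroupEffect] = field(default_factory=_default_group_effects)
    # per-subject disease-severity multiplier on the mean shift (SD of a
    # truncated normal around 1); patients differ in how far atrophy has
    # progressed, which widens their z-score dispersion
    severity_sd: float = 0.4

    generate_clinical: bool = True

    def validate(self) -> None:
        if min(self.n_hc, self.n_svppa, self.n_nfvppa) < 0:
            raise ValueError("group sizes must be non-negative")
        for g, eff in self.group_effects.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r} in group_effects")
            for _, delta in eff.decoupling:
                if not 0.0 <= delta <= 1.0:
                    raise ValueError(f"decoupling strength {delta} outside [0, 1]")
        if self.noise_cortical <= 0 or self.noise_subcortical <= 0:
            raise ValueError("noise SDs must be positive (covariance must be PSD)")
        if self.loading_cortical < 0 or self.loading_subcortical < 0:
            raise ValueError("factor loadings must be non-negative")


def _region_params(atlas: AtlasDefinition, cfg: CohortConfig):
    """Per-region baseline, loading, noise SD, covariate effects (atlas order)."""
    n = len(atlas)
    baseline = np.empty(n)
    loading = np.empty(n)
    noise = np.empty(n)
    age_slope = np.empty(n)
    sex_off = np.empty(n)
    is_vol = np.empty(n, dtype=bool)
    lobe_idx = np.empty(n, dtype=int)
    lobes = sorted({r.lobe for r in atlas})
    within = {lb: 0 for lb in lobes}
    for i, r in enumerate(atlas):
        lobe_idx[i] = lobes.index(r.lobe)
        if r.tissue_class == CORTICAL:
            # small deterministic spread so regions are not identical
            baseline[i] = _LOBE_BASE_THICKNESS[r.lobe] + 0.015 * within[r.lobe]
            loading[i] = cfg.loading_cortical
            noise[i] = cfg.noise_cortical
            age_slope[i] = cfg.age_slope_cortical
            sex_off[i] = cfg.sex_offset_cortical
            is_vol[i] = False
        else:
            base = _SUBCORTICAL_BASE_VOLUME[r.name.split("_", 1)[1]]
            baseline[i] = base
            loading[i] = cfg.loading_subcortical * base
            noise[i] = cfg.noise_subcortical * base
            age_slope[i] = cfg.age_slope_subcortical * base
            sex_off[i] = cfg.sex_offset_subcortical * base
            is_vol[i] = True
        within[r.lobe] += 1
    return baseline, loading, noise, age_slope, sex_off, is_vol, lobe_idx, lobes


def _group_delta_shift(atlas: AtlasDefinition, cfg: CohortConfig, baseline: np.ndarray):
    """Per-group per-region decoupling delta and additive mean shift."""
    n = len(atlas)
    delta = {g: np.zeros(n) for g in GROUPS}
    shift = {g: np.zeros(n) for g in GROUPS}
    for g, eff in cfg.group_effects.items():
        for sel, d in eff.decoupling:
            m = sel.mask(atlas)
            delta[g][m] = np.maximum(delta[g][m], d)
        for sel, frac in eff.mean_shift:
            idx = np.flatnonzero(sel.mask(atlas))
            s = eff.mean_shift_spread
            grades = (
                np.linspace(1.0 - s, 1.0 + s, idx.size) if idx.size > 1 else np.ones(1)
            )
            shift[g][idx] -= frac * baseline[idx] * grades
    return delta, shift


def _draw_clinical(rng: np.random.Generator, group: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for score in CLINICAL_SCORES:
        params = _CLINICAL_PARAMS[group][score]
        if params is None:
            out[score] = math.nan
            continue
        mu, sd = params
        lo, hi = CLINICAL_BOUNDS[score]
        out[score] = float(np.clip(rng.normal(mu, sd), lo, hi))
    return out


def generate_cohort(
    config: CohortConfig | None = None,
    atlas: AtlasDefinition | None = None,
) -> tuple[pd.DataFrame, list[SubjectRecord]]:
    """Generate a morphometry table and subject records.

    Returns
    -------
    table : DataFrame
        One row per subject: subject_id, group, age, sex, tiv, then the 82
        regional values in atlas order.
    records : list of SubjectRecord
        Covariates plus clinical scores (NaN where a scale is not
        collected for a group, as for CDR in controls).
    """
    cfg = config if config is not None else CohortConfig()
    cfg.validate()
    atl = atlas if atlas is not None else make_default_atlas()
    rng = np.random.default_rng(cfg.seed)

    baseline, loading, noise, age_slope, sex_off, is_vol, lobe_idx, lobes = _region_params(
        atl, cfg
    )
    delta, shift = _group_delta_shift(atl, cfg, baseline)
    gload = cfg.global_loading_scale * loading if cfg.include_global_factor else 0.0 * loading

    rows = []
    records: list[SubjectRecord] = []
    counts = {"HC": cfg.n_hc, "svPPA": cfg.n_svppa, "nfvPPA": cfg.n_nfvppa}
    sid = 0
    for group in GROUPS:
        a_mu, a_sd = cfg.age_params[group]
        t_mu, t_sd = cfg.tiv_params[group]
        p_male = cfg.sex_p_male[group]
        dlt = delta[group]
        shared_scale = loading * np.sqrt(1.0 - dlt)
        # decoupling compensates: total marginal variance is delta-invariant
        noise_sd = np.sqrt(noise**2 + dlt * loading**2)
        for _ in range(counts[group]):
            sid += 1
            age = float(max(rng.normal(a_mu, a_sd), 30.0))
            male = rng.random() < p_male
            tiv = float(max(rng.normal(t_mu, t_sd), 1000.0))
            factors = rng.standard_normal(len(lobes))
            gfac = rng.standard_normal()
            eps = rng.standard_normal(len(atl)) * noise_sd
            severity = float(max(rng.normal(1.0, cfg.severity_sd), 0.0))

            x = (
                baseline
                + age_slope * (age - 60.0)
                + (sex_off if male else 0.0)
                + severity * shift[group]
                + shared_scale * factors[lobe_idx]
                + gload * gfac
                + eps
            )
            tiv_term = baseline * ((tiv / cfg.tiv_ref) ** cfg.tiv_exponent - 1.0)
            x = np.where(is_vol, x + tiv_term, x)

            subject_id = f"sub-{sid:04d}"
            clinical = _draw_clinical(rng, group) if cfg.generate_clinical else {}
            records.append(
                SubjectRecord(
                    subject_id=subject_id,
                    group=group,
                    age=age,
                    sex="M" if male else "F",
                    tiv=tiv,
                    clinical=clinical,
                )
            )
            rows.append([subject_id, group, age, "M" if male else "F", tiv, *x])

    cols = ["subject_id", "group", "age", "sex", "tiv", *atl.names]
    table = pd.DataFrame(rows, columns=cols)
    return table, records


def clinical_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Clinical scores as a DataFrame (one row per subject)."""
    rows = [
        {"subject_id": r.subject_id, "group": r.group, **r.clinical} for r in records
    ]
    return pd.DataFrame(rows)


def config_to_dict(cfg: CohortConfig) -> dict:
    """JSON/YAML-serializable echo of a cohort config."""
    d = asdict(cfg)
    d["group_effects"] = {
        g: {
            "decoupling": [
                {"selector": asdict(sel), "delta": dl} for sel, dl in eff.decoupling
            ],
            "mean_shift": [
                {"selector": asdict(sel), "fraction": fr} for sel, fr in eff.mean_shift
            ],
        }
        for g, eff in cfg.group_effects.items()
    }
    return d
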