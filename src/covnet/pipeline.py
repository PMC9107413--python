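"""End-to-end orchestration: cohort -> z-scores -> networks -> metrics -> stats.

A single :class:`PipelineConfig` drives the whole analysis.  All
randomness (cohort generation, null graphs, permutations) derives from
one seed through ``numpy.random.SeedSequence`` spawning, so rerunning the
same config byte-reproduces every numeric output.  The run writes tidy
CSV tables, per-subject weight matrices, BrainNet node files for
significant local effects, and a JSON manifest echoing every parameter.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import make_default_atlas
from .cohort import CohortConfig, clinical_table, config_to_dict, generate_cohort
from .io import (
    read_morphometry_csv,
    write_matrix,
    write_morphometry_csv,
    write_node_file,
)
from .metrics import metric_profiles
from .network import build_network, density_grid
from .preprocess import fit_confound_model, residualize_and_zscore
from .stats import compare_global, compare_local, rank_regions, spearman_metric_clinical

log = logging.getLogger("covnet")

LOCAL_METRICS = ("clustering", "local_efficiency", "degree")
GLOBAL_METRICS = ("gamma", "lambda", "sigma")


@dataclass
class PipelineConfig:
    """Parameters of one full analysis run."""

    # input: either a cohort config to simulate, or a morphometry CSV path
    cohort: CohortConfig | None = None
    morphometry_csv: str | None = None
    clinical_csv: str | None = None

    density_start: float = 0.10
    density_stop: float = 0.40
    density_step: float = 0.01
    n_null: int = 100
    swaps_per_edge: int = 10
    n_perm: int = 5000
    seed: int = 0
    out_dir: str = "covnet-results"

    reference_group: str = "HC"
    fit_population: str = "reference"  # or "pooled"
    path_policy: str = "harmonic"  # or "reachable" / "largest_component"
    nuisance: str | None = "CDR"  # clinical score used for adjusted patient contrasts
    alpha: float = 0.05
    top_k: int = 20
    save_networks: bool = True

    def grid(self) -> np.ndarray:
        return density_grid(self.density_start, self.density_stop, self.density_step)


def _comparison_frame(results) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = make_default_atlas()
    grid = config.grid()
    ss = np.random.SeedSequence(config.seed)
    seed_cohort, seed_metrics, seed_stats = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    collected_warnings: list[str] = []

    # ---- stage 1: obtain the morphometry table -------------------------
    if config.morphometry_csv is not None:
        log.info("loading morphometry table from %s", config.morphometry_csv)
        table = read_morphometry_csv(config.morphometry_csv, atlas)
        clin = (
            pd.read_csv(config.clinical_csv) if config.clinical_csv is not None else None
        )
        cohort_echo = None
    else:
        cohort_cfg = config.cohort if config.cohort is not None else CohortConfig()
        cohort_cfg.seed = seed_cohort
        log.info(
            "simulating cohort: %d HC / %d svPPA / %d nfvPPA",
            cohort_cfg.n_hc, cohort_cfg.n_svppa, cohort_cfg.n_nfvppa,
        )
        table, records = generate_cohort(cohort_cfg, atlas)
        clin = clinical_table(records)
        write_morphometry_csv(out / "cohort.csv", table)
        clin.to_csv(out / "clinical.csv", index=False)
        cohort_echo = config_to_dict(cohort_cfg)

    groups = table.set_index("subject_id")["group"]
    group_labels = [g for g in ("HC", "svPPA", "nfvPPA") if (groups == g).any()]

    # ---- stage 2: preprocessing ---------------------------------------
    log.info("fitting confound model (population=%s)", config.fit_population)
    try:
        model = fit_confound_model(
            table,
            reference_group=config.reference_group,
            fit_population=config.fit_population,
        )
        ztab = residualize_and_zscore(table, model)
    except ValueError as e:
        raise RuntimeError(f"stage preprocessing failed: {e}") from e
    ztab.values.to_csv(out / "zscores.csv")

    # ---- stage 3 + 4: networks and metric profiles --------------------
    subjects = list(ztab.values.index)
    net_dir = out / "networks"
    if config.save_networks:
        net_dir.mkdir(exist_ok=True)
    glob_rows = []
    auc_global_rows = []
    local_auc = {m: np.empty((len(subjects), len(atlas))) for m in LOCAL_METRICS}
    metric_ss = np.random.SeedSequence(seed_metrics).spawn(len(subjects))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for si, sid in enumerate(subjects):
            z = ztab.values.loc[sid].to_numpy()
            try:
                W = build_network(z, region_names=atlas.names)
            except ValueError as e:
                raise RuntimeError(f"stage network failed for subject {sid}: {e}") from e
            if config.save_networks:
                write_matrix(net_dir / f"{sid}.edge", W)
            gp, lp = metric_profiles(
                W, grid,
                n_null=config.n_null,
                seed=np.random.default_rng(metric_ss[si]),
                swaps_per_edge=config.swaps_per_edge,
                path_policy=config.path_policy,
            )
            for t, d in enumerate(grid):
                glob_rows.append(
                    [sid, d, gp.clustering[t], gp.path_length[t], gp.gamma[t], gp.lam[t], gp.sigma[t]]
                )
            aucs = gp.auc
            auc_global_rows.append(
                [sid, groups[sid], aucs["gamma"], aucs["lambda"], aucs["sigma"]]
            )
            lauc = lp.auc
            for m in LOCAL_METRICS:
                local_auc[m][si] = lauc[m]
            if (si + 1) % 25 == 0:
                log.info("metrics: %d/%d subjects done", si + 1, len(subjects))
    collected_warnings += sorted({str(w.message) for w in caught})

    pd.DataFrame(
        glob_rows,
        columns=["subject_id", "density", "clustering", "path_length", "gamma", "lambda", "sigma"],
    ).to_csv(out / "global_profiles.csv", index=False)
    auc_global = pd.DataFrame(
        auc_global_rows, columns=["subject_id", "group", "gamma", "lambda", "sigma"]
    ).set_index("subject_id")
    auc_global.to_csv(out / "auc_global.csv")
    local_auc_df = {
        m: pd.DataFrame(local_auc[m], index=pd.Index(subjects, name="subject_id"), columns=atlas.names)
        for m in LOCAL_METRICS
    }
    for m, df in local_auc_df.items():
        df.to_csv(out / f"auc_local_{m}.csv")

    # ---- stage 5: group statistics ------------------------------------
    log.info("group comparisons (%d permutations)", config.n_perm)
    stats_ss = np.random.SeedSequence(seed_stats)
    pair_list = [
        (a, b) for i, a in enumerate(group_labels) for b in group_labels[i + 1 :]
    ]
    results = []
    pair_seeds = stats_ss.spawn(max(len(pair_list), 1))
    clin_idx = clin.set_index("subject_id") if clin is not None else None
    for (ga, gb), pseed in zip(pair_list, pair_seeds):
        sub_seeds = pseed.spawn(2 + len(LOCAL_METRICS) * 2)
        k = 0
        results += compare_global(
            auc_global[list(GLOBAL_METRICS)], auc_global["group"], ga, gb,
            n_perm=config.n_perm, seed=int(sub_seeds[k].generate_state(1)[0] % 2**31),
        )
        k += 1
        nuis = None
        if config.nuisance is not None and clin_idx is not None and config.nuisance in clin_idx:
            cov = clin_idx[config.nuisance].reindex(auc_global.index)
            in_pair = auc_global["group"].isin([ga, gb])
            if np.all(np.isfinite(cov[in_pair].to_numpy(float))):
                nuis = cov
        if nuis is not None:
            adj = compare_global(
                auc_global[list(GLOBAL_METRICS)], auc_global["group"], ga, gb,
                n_perm=config.n_perm, seed=int(sub_seeds[k].generate_state(1)[0] % 2**31),
                nuisance=nuis,
            )
            results += [
                type(r)(**{**asdict(r), "metric": f"{r.metric}|adj_{config.nuisance}"})
                for r in adj
            ]
        k += 1
        for m in LOCAL_METRICS:
            results += compare_local(
                local_auc_df[m], auc_global["group"], ga, gb, metric=m,
                n_perm=config.n_perm, seed=int(sub_seeds[k].generate_state(1)[0] % 2**31),
            )
            k += 1
            if nuis is not None:
                adj = compare_local(
                    local_auc_df[m], auc_global["group"], ga, gb,
                    metric=f"{m}|adj_{config.nuisance}",
                    n_perm=config.n_perm,
                    seed=int(sub_seeds[k].generate_state(1)[0] % 2**31),
                    nuisance=nuis,
                )
                results += adj
            k += 1
    comp_df = _comparison_frame(results)
    comp_df.to_csv(out / "comparisons.csv", index=False)

    # rankings
    rank_rows = []
    for m in LOCAL_METRICS:
        for g in group_labels:
            sub = local_auc_df[m][(auc_global["group"] == g).to_numpy()]
            rk = rank_regions(sub, metric=m, group=g, k=min(config.top_k, len(atlas)))
            for pos, (reg, val) in enumerate(zip(rk.regions, rk.values), start=1):
                rank_rows.append([m, g, pos, reg, val])
    pd.DataFrame(
        rank_rows, columns=["metric", "group", "rank", "region", "mean_auc"]
    ).to_csv(out / "rankings.csv", index=False)

    # node files: significant local effects, node size ~ |Hedges' g|
    node_dir = out / "nodes"
    node_dir.mkdir(exist_ok=True)
    name_to_idx = {n: i for i, n in enumerate(atlas.names)}
    node_files = []
    for (ga, gb) in pair_list:
        for m in LOCAL_METRICS:
            sig = comp_df[
                (comp_df["metric"] == m)
                & (comp_df["group_a"] == ga)
                & (comp_df["group_b"] == gb)
                & (comp_df["p_bonferroni"] < config.alpha)
            ]
            if len(sig) == 0:
                continue
            size = np.zeros(len(atlas))
            mask = np.zeros(len(atlas), dtype=bool)
            for _, row in sig.iterrows():
                i = name_to_idx[row["scope"]]
                size[i] = abs(row["hedges_g"])
                mask[i] = True
            fname = node_dir / f"{ga}_vs_{gb}_{m}.node"
            write_node_file(fname, atlas, size=size, mask=mask)
            node_files.append(str(fname.relative_to(out)))

    # clinical correlations (patients), Spearman
    corr_rows = []
    if clin_idx is not None:
        score_cols = [c for c in clin_idx.columns if c != "group"]
        for g in group_labels:
            if g == config.reference_group:
                continue
            in_g = (auc_global["group"] == g).to_numpy()
            for metric in GLOBAL_METRICS:
                mv = auc_global.loc[in_g, metric]
                for score in score_cols:
                    cv = clin_idx[score].reindex(mv.index).to_numpy(float)
                    ok = np.isfinite(mv.to_numpy()) & np.isfinite(cv)
                    if ok.sum() < 3:
                        continue
                    rho, p = spearman_metric_clinical(mv.to_numpy(), cv)
                    corr_rows.append([g, metric, score, int(ok.sum()), rho, p])
    pd.DataFrame(
        corr_rows, columns=["group", "metric", "clinical_score", "n", "rho", "p_value"]
    ).to_csv(out / "correlations.csv", index=False)

    # ---- manifest ------------------------------------------------------
    manifest = {
        "covnet_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "stage_seeds": {
            "cohort": seed_cohort,
            "metrics": seed_metrics,
            "stats": seed_stats,
        },
        "parameters": {
            "density_grid": [float(d) for d in grid],
            "n_null": config.n_null,
            "swaps_per_edge": config.swaps_per_edge,
            "n_perm": config.n_perm,
            "reference_group": config.reference_group,
            "fit_population": config.fit_population,
            "path_policy": config.path_policy,
            "nuisance": config.nuisance,
            "alpha": config.alpha,
            "top_k": config.top_k,
        },
        "cohort_config": cohort_echo,
        "inputs": {
            "morphometry_csv": config.morphometry_csv,
            "clinical_csv": config.clinical_csv,
        },
        "n_subjects": len(subjects),
        "groups": {g: int((groups == g).sum()) for g in group_labels},
        "outputs": {
            "zscores": "zscores.csv",
            "global_profiles": "global_profiles.csv",
            "auc_global": "auc_global.csv",
            "auc_local": [f"auc_local_{m}.csv" for m in LOCAL_METRICS],
            "comparisons": "comparisons.csv",
            "rankings": "rankings.csv",
            "correlations": "correlations.csv",
            "node_files": node_files,
        },
        "warnings": collected_warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %s", out)
    return manifest
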