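"""End-to-end orchestration: cohort -> preprocessing & motion QC ->
partial-correlation networks -> metric curves and AUCs over the sparsity
sweep -> covariate-adjusted group statistics and report tables.

Every stage persists its artifacts into the run directory as plain-text
CSV, a manifest records the config hash / seed / versions / exclusions,
and two runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, CohortConfig, GROUPS, generate_cohort, read_cohort, write_cohort
from .inference import (
    DEFAULT_COVARIATES,
    ancova_auc,
    cohort_table,
    correlation_table,
    nodal_ancova_table,
)
from .metrics import (
    GLOBAL_METRIC_NAMES,
    NODAL_METRIC_NAMES,
    NullModelConfig,
    all_metrics,
    auc_over_sweep,
    normalized_metrics,
)
from .network import SparsitySweep, partial_correlation_matrix, sweep_networks
from .preprocess import PreprocessConfig, apply_exclusion, preprocess_series

__all__ = ["RunConfig", "run_pipeline", "repeatability_harness", "ATLAS_SIZES",
           "subject_metric_curves", "cohort_metric_aucs"]

logger = logging.getLogger(__name__)

ATLAS_SIZES = {"aal90": 90, "hoa112": 112, "brainnetome246": 246}

COGNITION_SCORES = ("moca", "tmt_a_seconds", "dst_f", "dst_b", "dst_t")


@dataclass
class RunConfig:
    mode: str = "synthetic"  # "synthetic" | "files"
    data_dir: str | None = None  # input directory for mode="files"
    out_dir: str = "funconn_run"
    atlas: str = "aal90"
    n_regions: int | None = None  # overrides the atlas preset (custom atlas)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sweep: SparsitySweep = field(default_factory=SparsitySweep)
    nulls: NullModelConfig = field(default_factory=NullModelConfig)
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    estimator: str = "auto"  # auto | precision | shrinkage
    compute_normalized: bool = True
    compute_nodal: bool = True
    make_figures: bool = True
    seed: int = 2021

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.atlas not in ATLAS_SIZES and self.n_regions is None:
            raise ValueError(
                f"unknown atlas {self.atlas!r}; pick one of {sorted(ATLAS_SIZES)} "
                "or supply n_regions for a custom parcellation"
            )
        n = self.n_regions or ATLAS_SIZES[self.atlas]
        self.n_regions = n
        # a single seed drives cohort generation and the null ensembles
        self.cohort = dataclasses.replace(self.cohort, n_regions=n, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def subject_metric_curves(
    ts: np.ndarray,
    sweep: SparsitySweep,
    nulls: NullModelConfig | None = None,
    estimator: str = "auto",
    compute_normalized: bool = True,
    compute_nodal: bool = True,
    null_seed: int = 0,
):
    """Metric curves of one preprocessed subject across the sweep.

    Returns ``(global_curves, nodal_curves)``: a dict metric -> values
    per threshold, and a dict metric -> (n_thresholds, N) array (or None
    when nodal metrics are disabled).
    """
    conn = partial_correlation_matrix(ts, estimator=estimator)
    nets = sweep_networks(conn, sweep)
    n_thr = len(nets)
    gcurves = {m: np.full(n_thr, np.nan) for m in GLOBAL_METRIC_NAMES}
    ncurves = (
        {m: np.full((n_thr, conn.n_nodes), np.nan) for m in NODAL_METRIC_NAMES}
        if compute_nodal
        else None
    )
    for k, net in enumerate(nets):
        gm, nm = all_metrics(net)
        if compute_normalized:
            ncfg = NullModelConfig(
                n_nulls=(nulls or NullModelConfig()).n_nulls,
                rewires_per_edge=(nulls or NullModelConfig()).rewires_per_edge,
                seed=(null_seed * 1009 + k) & 0x7FFFFFFF,
            )
            gm.gamma, gm.lam, gm.sigma = normalized_metrics(net, ncfg)
        for name, val in gm.as_dict().items():
            gcurves[name][k] = val
        if compute_nodal:
            for name, vals in nm.as_dict().items():
                ncurves[name][k] = vals
    return gcurves, ncurves


def cohort_metric_aucs(
    series: dict[str, np.ndarray],
    sweep: SparsitySweep,
    nulls: NullModelConfig | None = None,
    estimator: str = "auto",
    compute_normalized: bool = True,
    compute_nodal: bool = True,
    base_seed: int = 0,
):
    """Curves + AUC tables for a whole cohort of preprocessed series.

    Returns ``(curves_df, auc_global_df, nodal_auc)`` where `curves_df`
    is tidy (subject_id, metric, threshold, value), `auc_global_df` is
    subjects x global metrics, and `nodal_auc` maps each nodal metric to
    a subjects x nodes DataFrame.
    """
    thr = sweep.thresholds
    tidy = []
    auc_rows = {}
    nodal_acc: dict[str, dict[str, np.ndarray]] = {m: {} for m in NODAL_METRIC_NAMES}
    for idx, (sid, ts) in enumerate(series.items()):
        gcurves, ncurves = subject_metric_curves(
            ts, sweep, nulls, estimator, compute_normalized, compute_nodal,
            null_seed=base_seed + idx,
        )
        for m, vals in gcurves.items():
            if np.isnan(vals).all():
                continue
            for t, v in zip(thr, vals):
                tidy.append((sid, m, float(t), float(v)))
        auc_rows[sid] = {
            m: auc_over_sweep(thr, vals) if not np.isnan(vals).all() else np.nan
            for m, vals in gcurves.items()
        }
        if compute_nodal:
            for m in NODAL_METRIC_NAMES:
                arr = ncurves[m]
                nodal_acc[m][sid] = np.array(
                    [auc_over_sweep(thr, arr[:, i]) for i in range(arr.shape[1])]
                )
    curves_df = pd.DataFrame(tidy, columns=["subject_id", "metric", "threshold", "value"])
    auc_global = pd.DataFrame.from_dict(auc_rows, orient="index")
    auc_global.index.name = "subject_id"
    nodal_auc = {
        m: pd.DataFrame.from_dict(d, orient="index") for m, d in nodal_acc.items() if d
    }
    for df in nodal_auc.values():
        df.index.name = "subject_id"
    return curves_df, auc_global, nodal_auc


def _global_comparison_table(auc_global: pd.DataFrame, meta: pd.DataFrame, covariates):
    """Table of group mean +/- sd per global metric with ANCOVA p-values."""
    meta_idx = meta.set_index("subject_id").loc[auc_global.index]
    rows = []
    for m in GLOBAL_METRIC_NAMES:
        if m not in auc_global.columns or auc_global[m].isna().all():
            continue
        vals = auc_global[m]
        row = {"metric": m}
        for grp in GROUPS:
            v = vals[(meta_idx["group"] == grp).to_numpy()]
            row[f"{grp}_mean"] = v.mean()
            row[f"{grp}_sd"] = v.std(ddof=1)
        res = ancova_auc(vals.to_numpy(), meta_idx.reset_index(), covariates, metric=m)
        row.update(
            F=res.f_stat, p=res.p_omnibus,
            p1=res.posthoc_p["noCI_vs_HC"], p2=res.posthoc_p["CI_vs_HC"],
            p3=res.posthoc_p["CI_vs_noCI"],
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _correlation_stage(auc_global, nodal_auc, meta, global_table, nodal_tables, covariates):
    """Table-4-style grid: changed parameters vs cognition, patients only."""
    meta_idx = meta.set_index("subject_id").loc[auc_global.index].reset_index()
    patients = (meta_idx["group"] != "HC").to_numpy()
    pmeta = meta_idx[patients]
    if patients.sum() < len(covariates) + 3:
        logger.warning(
            "only %d patients: too few for covariate-adjusted correlation, "
            "table left empty", int(patients.sum()),
        )
        return pd.DataFrame(columns=["block", "parameter", "score", "r", "p", "q", "n"])
    changed = list(global_table.loc[global_table["p"] < 0.05, "metric"])
    if not changed:  # nothing reached significance: report the full global set
        changed = [m for m in global_table["metric"]]
    params = auc_global.loc[patients, changed].reset_index(drop=True).copy()
    blocks = {"global": list(changed)}
    for m, table in nodal_tables.items():
        sig_nodes = list(table.loc[table["significant"], "node"])
        colnames = []
        for node in sig_nodes:
            cname = f"{m}_node{node:03d}"
            params[cname] = nodal_auc[m].loc[patients, node].to_numpy()
            colnames.append(cname)
        if colnames:
            blocks[m] = colnames
    cognition = pmeta[list(COGNITION_SCORES)].reset_index(drop=True)
    covs = pmeta[list(covariates)].reset_index(drop=True)
    return correlation_table(params, cognition, covs, blocks=blocks)


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> Path:
    """Execute every stage and return the populated run directory.

    `cohort` may be supplied directly (e.g. with injected motion
    artifacts); otherwise it is generated (mode="synthetic") or read from
    ``config.data_dir`` (mode="files").
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage 1: cohort -----------------------------------------------------
    if cohort is None:
        if config.mode == "synthetic":
            cohort = generate_cohort(config.cohort)
        else:
            if config.data_dir is None:
                raise ValueError("mode='files' requires data_dir")
            cohort = read_cohort(config.data_dir)
    n_obs = next(iter(cohort.series.values())).shape[1]
    if n_obs != config.n_regions:
        raise ValueError(
            f"atlas {config.atlas!r} expects {config.n_regions} regions, "
            f"time series have {n_obs}"
        )
    cohort.meta.to_csv(out / "participants.csv", index=False)
    logger.info("stage cohort: %d subjects", len(cohort.series))

    # -- stage 2: motion QC + temporal preprocessing -------------------------
    excl_rows = []
    clean: dict[str, np.ndarray] = {}
    for sid in cohort.subject_ids:
        trace = cohort.motion.get(sid)
        if trace is not None:
            dec = apply_exclusion(trace, config.preprocess)
        else:
            dec = None
        if dec is not None:
            excl_rows.append({
                "subject_id": sid,
                "decision": "keep" if dec.keep else "exclude",
                "reasons": ";".join(dec.reasons),
                "max_translation_mm": dec.max_translation_mm,
                "max_rotation_deg": dec.max_rotation_deg,
                "mean_fd": dec.mean_fd,
            })
            if not dec.keep:
                logger.warning("excluding %s: %s", sid, ",".join(dec.reasons))
                continue
        try:
            clean[sid] = preprocess_series(
                cohort.series[sid], trace, cohort.nuisance.get(sid), config.preprocess
            )
        except Exception as err:  # abort with stage + subject, per contract
            raise RuntimeError(f"stage preprocess failed for {sid}: {err}") from err
    exclusions = pd.DataFrame(
        excl_rows,
        columns=["subject_id", "decision", "reasons", "max_translation_mm",
                 "max_rotation_deg", "mean_fd"],
    )
    exclusions.to_csv(out / "exclusions.csv", index=False)
    kept = list(clean)
    meta = cohort.meta[cohort.meta["subject_id"].isin(kept)].reset_index(drop=True)
    logger.info("stage preprocess: kept %d / %d subjects", len(kept), len(cohort.series))

    # -- stage 3+4: networks, metric curves, AUC -----------------------------
    try:
        curves, auc_global, nodal_auc = cohort_metric_aucs(
            clean, config.sweep, config.nulls, config.estimator,
            config.compute_normalized, config.compute_nodal,
            base_seed=config.seed,
        )
    except Exception as err:
        raise RuntimeError(f"stage metrics failed: {err}") from err
    group_of = meta.set_index("subject_id")["group"]
    curves.insert(1, "group", curves["subject_id"].map(group_of))
    curves.to_csv(out / "metric_curves.csv", index=False)
    auc_global.to_csv(out / "auc_global.csv")
    for m, df in nodal_auc.items():
        df.to_csv(out / f"auc_nodal_{m}.csv")

    # -- stage 5: statistics --------------------------------------------------
    table1 = cohort_table(meta)
    table1.to_csv(out / "table1_cohort.csv", index=False)
    table2 = _global_comparison_table(auc_global, meta, config.covariates)
    table2.to_csv(out / "table2_global_ancova.csv", index=False)
    meta_aligned = meta.set_index("subject_id").loc[auc_global.index].reset_index()
    nodal_tables = {}
    for m, df in nodal_auc.items():
        nodal_tables[m] = nodal_ancova_table(df, meta_aligned, metric=m,
                                             covariates=config.covariates)
    if nodal_tables:
        pd.concat(nodal_tables.values(), ignore_index=True).to_csv(
            out / "table3_nodal_ancova.csv", index=False
        )
    table4 = _correlation_stage(
        auc_global, nodal_auc, meta, table2, nodal_tables, config.covariates
    )
    table4.to_csv(out / "table4_correlations.csv", index=False)

    # -- figures ---------------------------------------------------------------
    if config.make_figures:
        from .plotting import plot_metric_curves

        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        plot_metric_curves(curves, figdir)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "funconn": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_subjects": len(cohort.series),
        "n_kept": len(kept),
        "excluded": sorted(set(cohort.subject_ids) - set(kept)),
        "runtime_seconds": None,  # filled below; kept out of the hash
    }
    manifest["runtime_seconds"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def repeatability_harness(
    config: RunConfig, atlases: list[str], out_dir: str | Path | None = None
) -> pd.DataFrame:
    """Cross-atlas concordance of the global group effects.

    Re-runs the pipeline for each atlas preset on cohorts generated from
    the same ground-truth design (same seed, same module structure,
    different region count) and reports, per global metric, the sign of
    the covariate-adjusted HC minus MHD_CI effect under each atlas and
    whether all atlases agree.
    """
    if len(atlases) < 2:
        raise ValueError("need at least 2 atlases to compare")
    base_out = Path(out_dir) if out_dir else Path(config.out_dir) / "repeatability"
    signs: dict[str, dict[str, int]] = {}
    for atlas in atlases:
        acfg = dataclasses.replace(
            config,
            atlas=atlas,
            n_regions=ATLAS_SIZES.get(atlas, config.n_regions),
            out_dir=str(base_out / atlas),
            make_figures=False,
        )
        run_dir = run_pipeline(acfg)
        table2 = pd.read_csv(run_dir / "table2_global_ancova.csv")
        for _, row in table2.iterrows():
            diff = row["HC_mean"] - row["MHD_CI_mean"]
            signs.setdefault(row["metric"], {})[atlas] = int(np.sign(diff))
    rows = []
    for metric, per_atlas in signs.items():
        vals = [per_atlas.get(a, 0) for a in atlases]
        rows.append({
            "metric": metric,
            **{f"sign_{a}": per_atlas.get(a, np.nan) for a in atlases},
            "concordant": len(set(vals)) == 1,
        })
    report = pd.DataFrame(rows)
    base_out.mkdir(parents=True, exist_ok=True)
    report.to_csv(base_out / "concordance.csv", index=False)
    return report
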