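"""End-to-end orchestration: metrics → supercontrollers → group statistics →
clinical correlations → classification → scale prediction.

Every stage writes its tidy table into the output directory so any stage
can be inspected or rerun in isolation; a machine-readable run report
(versions, seed, config echo, counts, warnings) closes the run. Stage
outputs are pure functions of (inputs, config, seed), so a rerun with the
same config and seed reproduces the tables byte for byte.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import default_region_table, read_connectome, read_manifest, read_region_table
from .prediction import classify_cohort, cpm_cohort
from .synthetic import CohortSpec, Effect, ScaleModel, generate_cohort
from .stats import (
    CONTRASTS,
    METRICS,
    Cohort,
    adjusted_group_test,
    build_cohort,
    cohort_partial_spearman,
    metric_intercorrelation,
    omnibus_anova,
)
from .supercontrollers import supercontroller_regions, system_distribution

logger = logging.getLogger("conndyn")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    outdir: str = "conndyn_out"
    manifest: str | None = None  # load a cohort from disk ...
    region_table: str | None = None
    simulate: dict | None = None  # ... or simulate one (CohortSpec overrides)
    alpha: float = 0.05
    bonferroni_m: int | None = None  # defaults to the number of regions
    cv_folds: int = 10
    svm_C: float = 1.0
    seed: int = 0
    contrasts: tuple[str, ...] = CONTRASTS
    scales: tuple[str, ...] | None = None  # defaults to all scale columns
    run_classification: bool = True
    run_prediction: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _spec_from_dict(d: dict, seed: int) -> CohortSpec:
    d = dict(d)
    if "effects" in d:
        d["effects"] = tuple(Effect(**e) if isinstance(e, dict) else e for e in d["effects"])
    if "scale_models" in d:
        d["scale_models"] = tuple(ScaleModel(**s) if isinstance(s, dict) else s for s in d["scale_models"])
    if "group_sizes" in d:
        d["group_sizes"] = tuple((g, int(n)) for g, n in d["group_sizes"])
    d.setdefault("seed", seed)
    return CohortSpec(**d)


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from a subject manifest and its connectome files."""
    manifest_path = Path(manifest_path)
    m = read_manifest(manifest_path)
    base = manifest_path.parent
    connectomes = [
        read_connectome(base / row.connectome_path, subject_id=row.subject_id)
        for row in m.itertuples()
    ]
    return build_cohort(m.drop(columns=["connectome_path"]), connectomes)


def metrics_table(cohort: Cohort) -> pd.DataFrame:
    """Tidy per-subject, per-region metric values."""
    frames = []
    for m in METRICS:
        df = pd.DataFrame(cohort.metrics[m], columns=cohort.region_ids)
        df.insert(0, "subject_id", cohort.subjects["subject_id"])
        long = df.melt(id_vars="subject_id", var_name="region_id", value_name=m)
        frames.append(long.set_index(["subject_id", "region_id"]))
    return pd.concat(frames, axis=1).reset_index().rename(
        columns={"average": "avg_ctrl", "modal": "modal_ctrl", "synchronizability": "sync"}
    )


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns the run report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    report: dict = {
        "conndyn_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
    }

    # --- stage: cohort -----------------------------------------------------
    try:
        if config.manifest:
            cohort = load_cohort(config.manifest)
        elif config.simulate is not None:
            cohort = generate_cohort(_spec_from_dict(config.simulate, config.seed))
        else:
            raise ValueError("config must set either manifest or simulate")
    except Exception as exc:
        raise RuntimeError(f"stage cohort: {exc}") from exc
    n_regions = len(cohort.region_ids)
    report["n_subjects"] = cohort.n_subjects
    report["n_regions"] = n_regions
    report["group_counts"] = cohort.subjects["group"].value_counts().to_dict()
    if config.region_table:
        region_table = read_region_table(config.region_table)
    else:
        region_table = default_region_table(n_regions)
        region_table["region_id"] = cohort.region_ids
    m_bonf = config.bonferroni_m if config.bonferroni_m is not None else n_regions

    # --- stage: metrics ----------------------------------------------------
    metrics_table(cohort).to_csv(out / "metrics.csv", index=False)
    gm = cohort.global_metrics.copy()
    gm.insert(0, "subject_id", cohort.subjects["subject_id"])
    gm.to_csv(out / "global_metrics.csv", index=False)

    # --- stage: supercontrollers -------------------------------------------
    sc_rows, dist_frames = [], []
    groups = [g for g in ("HC", "SZ", "BD") if cohort.group_mask(g).any()]
    for g in groups:
        for m in METRICS:
            vals = cohort.metrics[m][cohort.group_mask(g)]
            group_mean = np.where(np.isfinite(vals).all(axis=0), vals.mean(axis=0), np.nan)
            s = supercontroller_regions(group_mean, cohort.region_ids, metric=m, group=g)
            for r in sorted(s.regions):
                sc_rows.append({"group": g, "metric": m, "region_id": r, "threshold": s.threshold})
            dist = system_distribution(s, region_table)
            dist.insert(0, "metric", m)
            dist.insert(0, "group", g)
            dist_frames.append(dist)
    pd.DataFrame(sc_rows, columns=["group", "metric", "region_id", "threshold"]).to_csv(
        out / "supercontrollers.csv", index=False
    )
    pd.concat(dist_frames).to_csv(out / "supercontroller_systems.csv", index=False)
    report["n_supercontrollers"] = len(sc_rows)

    # --- stage: group statistics -------------------------------------------
    stat_frames = []
    contrasts = [c for c in config.contrasts if all(cohort.group_mask(g).any() for g in c.split("-"))]
    for m in METRICS:
        for level in ("global", "regional"):
            if len(groups) >= 2:
                gc = omnibus_anova(cohort, m, level, bonferroni_m=m_bonf)
                t = gc.table.copy()
                t.insert(0, "contrast", "omnibus")
                t.insert(0, "level", level)
                t.insert(0, "metric", m)
                stat_frames.append(t)
            for contrast in contrasts:
                gc = adjusted_group_test(cohort, m, contrast, level, bonferroni_m=m_bonf)
                t = gc.table.copy()
                t.insert(0, "contrast", contrast)
                t.insert(0, "level", level)
                t.insert(0, "metric", m)
                stat_frames.append(t)
    stats_df = pd.concat(stat_frames, ignore_index=True)
    stats_df.to_csv(out / "group_stats.csv", index=False)
    sig = stats_df[(stats_df["level"] == "regional") & (stats_df["p_corrected"] < config.alpha)]
    report["n_significant_regional"] = int(len(sig))

    # --- stage: clinical correlations --------------------------------------
    corr_rows = []
    scale_names = list(config.scales) if config.scales else cohort.scale_names()
    for scale in scale_names:
        for g in groups:
            y = cohort.subjects.loc[cohort.group_mask(g), scale]
            if y.notna().sum() < 10:
                continue
            for m in METRICS:
                for r in cohort.region_ids:
                    try:
                        rho, p = cohort_partial_spearman(cohort, g, m, r, scale)
                    except ValueError as exc:
                        warnings.append(f"correlate {g}/{m}/{r}/{scale}: {exc}")
                        continue
                    corr_rows.append(
                        {"group": g, "scale": scale, "metric": m, "region_id": r,
                         "rho": rho, "p": p, "p_corrected": min(1.0, p * m_bonf)}
                    )
    pd.DataFrame(corr_rows).to_csv(out / "scale_correlations.csv", index=False)

    inter_frames = []
    for g in groups:
        if cohort.group_mask(g).sum() < 10:
            warnings.append(f"intercorrelation {g}: fewer than 10 subjects, skipped")
            continue
        t = metric_intercorrelation(cohort, g)
        t.insert(0, "group", g)
        inter_frames.append(t)
    if inter_frames:
        pd.concat(inter_frames).to_csv(out / "metric_intercorrelation.csv", index=False)

    # --- stage: classification ----------------------------------------------
    if config.run_classification:
        cls_rows, roc_frames = [], []
        for contrast in contrasts:
            a, b = contrast.split("-")
            n_a = int(cohort.group_mask(a).sum())
            n_b = int(cohort.group_mask(b).sum())
            if min(n_a, n_b) < config.cv_folds:
                warnings.append(f"classify {contrast}: too few subjects for k={config.cv_folds}")
                continue
            res = classify_cohort(
                cohort, contrast, k=config.cv_folds, C=config.svm_C,
                alpha=config.alpha, seed=config.seed,
            )
            cls_rows.append(
                {"contrast": contrast, "k": res.k, "pooled_accuracy": res.pooled_accuracy,
                 "mean_fold_accuracy": res.mean_fold_accuracy, "sensitivity": res.sensitivity,
                 "specificity": res.specificity, "auc": res.auc}
            )
            rp = res.roc_points.copy()
            rp.insert(0, "contrast", contrast)
            roc_frames.append(rp)
        pd.DataFrame(cls_rows).to_csv(out / "classification.csv", index=False)
        if roc_frames:
            pd.concat(roc_frames).to_csv(out / "roc_points.csv", index=False)
        report["classification"] = cls_rows

    # --- stage: scale prediction --------------------------------------------
    if config.run_prediction:
        pred_rows, pred_subject_frames = [], []
        for scale in scale_names:
            for g in groups:
                y = cohort.subjects.loc[cohort.group_mask(g), scale]
                if y.notna().sum() < 10:
                    continue
                res = cpm_cohort(cohort, g, scale, alpha=config.alpha)
                pred_rows.append({"group": g, "scale": scale, "rho": res.rho, "p": res.p,
                                  "n": len(res.y_true)})
                pf = pd.DataFrame({"group": g, "scale": scale,
                                   "y_true": res.y_true, "y_pred": res.y_pred})
                pred_subject_frames.append(pf)
        pd.DataFrame(pred_rows).to_csv(out / "scale_predictions.csv", index=False)
        if pred_subject_frames:
            pd.concat(pred_subject_frames).to_csv(out / "scale_predictions_subjects.csv", index=False)
        report["prediction"] = pred_rows

    report["warnings"] = warnings
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    logger.info("run complete: %s", out)
    return report
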