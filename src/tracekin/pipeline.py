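"""End-to-end analysis driver: preprocessing -> kinematics -> stats ->
classification, with per-stage logging of trial counts.

``analyze_dataset`` consumes a simulated (or schema-compatible recorded)
dataset and emits six artifacts: QC report, trial feature table, mixed-model
reports, follow-up contrast table, Bayes-factor report and the
classification grid.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .classification import (
    build_feature_table,
    contrasts_to_report,
    grid_to_frame,
    run_model_grid,
    select_discriminatory_features,
)
from .cohort import CohortDataset
from .config import RunConfig
from .io import iter_trials
from .kinematics import FEATURE_NAMES, extract_features
from .preprocessing import preprocess_trial
from .shapes import all_task_shapes
from .stats import (
    GROUP_TERM,
    bayes_factor_group,
    build_analysis_table,
    cohort_compare,
    fit_lmm,
    followup_contrasts,
    score_reaction_times,
)

logger = logging.getLogger("tracekin")

__all__ = ["analyze_dataset", "extract_trial_features"]


def extract_trial_features(
    dataset: CohortDataset, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Preprocess every successful trial and compute the nine features.

    Returns (features table, QC table).  Failed attempts and trials
    rejected by the cleaning rules appear in the QC table with reasons.
    """
    shapes_present = tuple(dict.fromkeys(dataset.trajectories["shape"]))
    epsilon_overrides = config.shape_epsilon
    curves = {}
    for name in shapes_present:
        over = {"epsilon": epsilon_overrides[name]} if name in epsilon_overrides else {}
        curves[name] = all_task_shapes([name], **over)[name]
    rows = []
    qc_rows = []
    for traj in iter_trials(dataset.trajectories):
        clean, qc = preprocess_trial(traj, curves[traj.shape], config.preprocess)
        qc_rows.append(
            {**qc.meta, "kept": qc.kept, "reason": qc.reason,
             "traces_completed": qc.traces_completed}
        )
        if clean is None:
            continue
        rec = extract_features(clean, curves[traj.shape], config.kinematics)
        rows.append(rec.to_row())
    features = pd.DataFrame(rows)
    qc = pd.DataFrame(qc_rows)
    kept = int(qc["kept"].sum()) if len(qc) else 0
    logger.info("preprocessing kept %d/%d trials", kept, len(qc))
    return features, qc


def _rt_table(dataset: CohortDataset, k: float) -> pd.DataFrame:
    rt = score_reaction_times(dataset.reaction_times, k=k)
    cov = dataset.covariates.rename(columns={"phq": "depression", "gad": "anxiety"})
    out = rt.merge(
        cov[["participant", "age", "depression", "anxiety"]], on="participant"
    )
    mu, sd = out["reaction_time"].mean(), out["reaction_time"].std(ddof=1)
    out["reaction_time_z"] = (out["reaction_time"] - mu) / sd if sd > 0 else 0.0
    return out


def analyze_dataset(
    dataset: CohortDataset,
    config: RunConfig = RunConfig(),
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Run the full analysis chain; optionally write artifacts to disk."""
    features, qc = extract_trial_features(dataset, config)
    if features.empty:
        raise ValueError("no trial survived preprocessing; nothing to analyse")

    matching = cohort_compare(dataset.covariates)

    tables, prep_report = build_analysis_table(
        features, dataset.covariates, FEATURE_NAMES, config.outlier_k
    )
    single_day = config.single_day or dataset.config.n_days == 1

    lmm_results = {}
    contrast_lists = {}
    bayes = {}
    for feat, table in tables.items():
        try:
            res = fit_lmm(table, feat, "shapes", single_day=single_day)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("LMM for %s failed: %s", feat, exc)
            continue
        lmm_results[feat] = res
        contrast_lists[feat] = followup_contrasts(
            table, feat, res, single_day=single_day
        )
        if res.term_p(GROUP_TERM) >= 0.05:
            try:
                bayes[feat] = bayes_factor_group(table, feat, "shapes")
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("Bayes factor for %s failed: %s", feat, exc)

    # reaction time: group model plus pairwise contrasts
    rt_table = _rt_table(dataset, config.outlier_k)
    rt_contrasts = []
    rt_result = None
    try:
        rt_result = fit_lmm(rt_table, "reaction_time_z", "rt", single_day=single_day)
        if rt_result.term_p(GROUP_TERM) < 0.05:
            groups = ["ASD", "PD", "CTRL"]
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    pair = (groups[i], groups[j])
                    sub = rt_table.loc[rt_table["group"].isin(pair)]
                    if sub["group"].nunique() < 2:
                        continue
                    pres = fit_lmm(sub, "reaction_time_z", "rt", single_day=single_day)
                    fe = pres.fixed_effects
                    row = fe.loc[fe["coef"].str.startswith("C(group, Sum)")].iloc[0]
                    rt_contrasts.append(
                        {
                            "pair": pair,
                            "scope": "rt",
                            "p": pres.term_p(GROUP_TERM),
                            "F": pres.anova.loc[
                                pres.anova["term"] == GROUP_TERM, "F"
                            ].iloc[0],
                            "estimate": float(row["estimate"]),
                            "ci": (float(row["ci_lo"]), float(row["ci_hi"])),
                        }
                    )
    except (ValueError, np.linalg.LinAlgError) as exc:
        logger.warning("reaction-time LMM failed: %s", exc)

    selection_report = contrasts_to_report(lmm_results, contrast_lists, rt_contrasts)
    disc_sets = {
        task: select_discriminatory_features(selection_report, task)
        for task in ("clinical_vs_nonclinical", "ASD_vs_PD")
    }

    rt_scores = score_reaction_times(dataset.reaction_times, k=config.outlier_k)
    feature_table = build_feature_table(
        _mask_outliers(features, config.outlier_k),
        dataset.covariates,
        rt_scores,
    )
    grid = run_model_grid(feature_table, disc_sets, config.split_seed, config.classifier)
    grid_frame = grid_to_frame(grid)

    artifacts = {
        "qc": qc,
        "features": features,
        "matching": matching,
        "preprocessing_report": prep_report,
        "lmm": lmm_results,
        "contrasts": contrast_lists,
        "rt_lmm": rt_result,
        "rt_contrasts": rt_contrasts,
        "bayes": bayes,
        "discriminatory_sets": disc_sets,
        "feature_table": feature_table,
        "classification": grid,
        "classification_grid": grid_frame,
        "config": config,
    }
    if out_dir is not None:
        _write_artifacts(artifacts, Path(out_dir), dataset)
    return artifacts


def _mask_outliers(features: pd.DataFrame, k: float) -> pd.DataFrame:
    """Feature cells beyond k pooled SDs set to NaN (excluded from the
    per-participant averages feeding the classifiers)."""
    out = features.copy()
    for feat in FEATURE_NAMES:
        if feat not in out.columns:
            continue
        v = out[feat]
        mu, sd = v.mean(), v.std(ddof=1)
        if sd > 0:
            out.loc[(v - mu).abs() > k * sd, feat] = np.nan
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, tuple, set)):
        return list(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return str(obj)


def _write_artifacts(artifacts: dict, out: Path, dataset: CohortDataset) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg_echo = {
        "config": artifacts["config"].to_dict(),
        "dataset_seed": dataset.config.seed,
    }
    artifacts["qc"].to_csv(out / "qc_report.csv", index=False)
    artifacts["features"].to_csv(out / "features.csv", index=False)
    lmm_json = {
        feat: {
            "anova": res.anova.to_dict(orient="records"),
            "fixed_effects": res.fixed_effects.to_dict(orient="records"),
            "random_variances": res.random_variances,
            "nobs": res.nobs,
            "converged": res.converged,
        }
        for feat, res in artifacts["lmm"].items()
    }
    if artifacts["rt_lmm"] is not None:
        lmm_json["reaction_time"] = {
            "anova": artifacts["rt_lmm"].anova.to_dict(orient="records"),
            "nobs": artifacts["rt_lmm"].nobs,
            "converged": artifacts["rt_lmm"].converged,
        }
    (out / "lmm_reports.json").write_text(
        json.dumps({**cfg_echo, "models": lmm_json}, indent=2, default=_json_default)
    )
    contrast_rows = []
    for feat, clist in artifacts["contrasts"].items():
        for c in clist:
            contrast_rows.append({"feature": feat, **{k: v for k, v in c.items()}})
    for c in artifacts["rt_contrasts"]:
        contrast_rows.append({"feature": "reaction_time", **c})
    pd.DataFrame(contrast_rows).to_csv(out / "contrasts.csv", index=False)
    (out / "bayes_report.json").write_text(
        json.dumps(
            {**cfg_echo, "bf01": {k: dataclasses.asdict(v) for k, v in artifacts["bayes"].items()}},
            indent=2,
            default=_json_default,
        )
    )
    with open(out / "classification_grid.csv", "w") as fh:
        for task, block in artifacts["classification_grid"].items():
            fh.write(f"# task: {task}\n")
            block.to_csv(fh)
    (out / "matching_report.json").write_text(
        json.dumps({**cfg_echo, "matching": artifacts["matching"]}, indent=2, default=_json_default)
    )
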