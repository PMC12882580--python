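"""Two-stage group classification from per-participant feature tables.

Stage one separates clinical (autism + Parkinson's, coded 1) from
non-clinical (control, coded 0) participants; stage two separates autism
from Parkinson's within the clinical participants.  Three classifiers are
run per feature set — K-nearest neighbours (k tuned on the training
portion), random forest (tree count tuned) and a linear-kernel SVM — on a
stratified 80/20 participant split, with predictors standardised on
training statistics.  Eleven feature sets (kinematic, questionnaire, and
their combinations) give the 2 x 11 model grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .kinematics import FEATURE_NAMES
from .shapes import SHAPE_NAMES
from .stats import LmmResult

__all__ = [
    "ParticipantFeatureTable",
    "FeatureSetSpec",
    "ClassificationResult",
    "ClassifierConfig",
    "build_feature_table",
    "select_discriminatory_features",
    "standard_feature_sets",
    "run_classifiers",
    "run_model_grid",
    "grid_to_frame",
    "kinematic_columns",
]

QUESTIONNAIRE_SETS = {
    "ASD_Q": ("aq_resid", "raads_resid"),
    "PD_Q": ("updrs_resid",),
    "ASDPD_Q": ("aq_resid", "raads_resid", "updrs_resid"),
}

TASKS = ("clinical_vs_nonclinical", "ASD_vs_PD")


def kinematic_columns() -> list[str]:
    """The 37 kinematic predictors: 9 features x 4 shapes + reaction time."""
    cols = [f"{feat}__{shape}" for feat in FEATURE_NAMES for shape in SHAPE_NAMES]
    cols.append("reaction_time")
    return cols


@dataclass
class ParticipantFeatureTable:
    """One row per participant: residualised predictors plus class labels."""

    data: pd.DataFrame
    imputed_cells: list = field(default_factory=list)

    @property
    def kinematic_block(self) -> pd.DataFrame:
        return self.data[kinematic_columns()]


@dataclass(frozen=True)
class FeatureSetSpec:
    name: str
    columns: tuple[str, ...]


@dataclass
class ClassificationResult:
    task: str
    feature_set: str
    accuracy: dict  # method -> test accuracy
    mean_accuracy: float
    split_seed: int
    tuned: dict  # method -> tuned hyperparameters
    n_test: int


@dataclass(frozen=True)
class ClassifierConfig:
    knn_grid: tuple[int, ...] = tuple(range(1, 11))
    rf_grid: tuple[int, ...] = (100, 200, 300, 400, 500)
    svm_c: float = 1.0
    test_fraction: float = 0.2
    cv_folds: int = 5
    max_resplits: int = 20


def _residualize(values: pd.Series, controls: pd.DataFrame) -> np.ndarray:
    X = sm.add_constant(controls.to_numpy(dtype=float))
    return sm.OLS(values.to_numpy(dtype=float), X).fit().resid


def build_feature_table(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    reaction_times: Optional[pd.DataFrame] = None,
) -> ParticipantFeatureTable:
    """Aggregate trials to one row per participant and residualise.

    Per participant x shape x feature, the mean over retained trials and
    days; reaction time averaged across days.  Every predictor column
    (including the questionnaire scores) is then residualised by OLS on
    age, depression and anxiety over the pooled sample.  Cells left empty
    because a participant lost a whole shape are imputed with the pooled
    column mean (logged).
    """
    cov = covariates.rename(columns={"phq": "depression", "gad": "anxiety"}).copy()
    cov = cov.set_index("participant")
    feats = features.rename(columns={"participant_id": "participant"})
    wide = None
    for feat in FEATURE_NAMES:
        if feat not in feats.columns:
            continue
        agg = (
            feats.groupby(["participant", "shape"])[feat].mean().unstack("shape")
        )
        agg.columns = [f"{feat}__{c}" for c in agg.columns]
        wide = agg if wide is None else wide.join(agg, how="outer")
    if wide is None:
        raise ValueError("no kinematic feature columns found")
    if reaction_times is not None:
        rt = reaction_times.groupby("participant")["reaction_time"].mean()
        wide = wide.join(rt.rename("reaction_time"), how="outer")
    wide = wide.reindex(cov.index)

    imputed = []
    for col in wide.columns:
        missing = wide[col].isna()
        if missing.any():
            for pid in wide.index[missing]:
                imputed.append((pid, col))
            wide.loc[missing, col] = wide[col].mean()

    controls = cov[["age", "depression", "anxiety"]]
    out = pd.DataFrame(index=wide.index)
    for col in wide.columns:
        out[col] = _residualize(wide[col], controls)
    for q in ("aq", "raads", "updrs"):
        out[f"{q}_resid"] = _residualize(cov[q], controls)
    out["group"] = cov["group"]
    out["label_clinical"] = (cov["group"] != "CTRL").astype(int)
    out["label_asd_pd"] = cov["group"].map({"ASD": 1, "PD": 0})
    return ParticipantFeatureTable(out.reset_index(), imputed)


def _selection_for_pair(
    reports: Mapping[str, Mapping], pair_key: str, alpha: float = 0.05
) -> set[str]:
    """Columns a single two-group comparison marks discriminatory.

    ``reports`` maps feature name -> {pair_key -> {"main_p", "interaction_p",
    "per_shape_p": {shape: p}}}.  A significant pairwise main effect admits
    the feature on all shapes; an interaction-only effect admits just the
    shapes whose per-shape contrast is significant.
    """
    cols: set[str] = set()
    for feat, pairs in reports.items():
        if feat == "reaction_time" or pair_key not in pairs:
            continue
        rep = pairs[pair_key]
        if rep.get("main_p", 1.0) < alpha:
            cols.update(f"{feat}__{shape}" for shape in SHAPE_NAMES)
        elif rep.get("interaction_p", 1.0) < alpha:
            for shape, p in rep.get("per_shape_p", {}).items():
                if p < alpha:
                    cols.add(f"{feat}__{shape}")
    return cols


def select_discriminatory_features(
    lmm_reports: Mapping[str, Mapping],
    comparison: str,
    alpha: float = 0.05,
) -> FeatureSetSpec:
    """Filter-based feature selection from the mixed-model contrast reports.

    For the ASD-vs-PD task: features significant between ASD and PD.  For
    the clinical-vs-nonclinical task: the union of the ASD-vs-CTRL and
    PD-vs-CTRL selections (ASD-vs-PD-only differences are excluded because
    those groups sit on the same side of the boundary).  Reaction time
    joins a set when its group contrast for the relevant pair(s) is
    significant.
    """
    if comparison == "ASD_vs_PD":
        cols = _selection_for_pair(lmm_reports, "ASD-PD", alpha)
        rt = lmm_reports.get("reaction_time", {}).get("ASD-PD", {})
        if rt.get("main_p", 1.0) < alpha:
            cols.add("reaction_time")
    elif comparison == "clinical_vs_nonclinical":
        cols = _selection_for_pair(lmm_reports, "ASD-CTRL", alpha)
        cols |= _selection_for_pair(lmm_reports, "PD-CTRL", alpha)
        for key in ("ASD-CTRL", "PD-CTRL"):
            rt = lmm_reports.get("reaction_time", {}).get(key, {})
            if rt.get("main_p", 1.0) < alpha:
                cols.add("reaction_time")
    else:
        raise ValueError(f"unknown comparison {comparison!r}")
    ordered = tuple(c for c in kinematic_columns() if c in cols)
    return FeatureSetSpec(name="disc_KF", columns=ordered)


def contrasts_to_report(
    main_results: Mapping[str, LmmResult],
    contrasts: Mapping[str, Sequence[dict]],
    rt_contrasts: Optional[Sequence[dict]] = None,
) -> dict:
    """Reshape fit_lmm/followup_contrasts output into the selection schema."""
    report: dict = {}
    for feat, clist in contrasts.items():
        per_pair: dict = {}
        for c in clist:
            key = "-".join(c["pair"])
            entry = per_pair.setdefault(
                key, {"main_p": 1.0, "interaction_p": 1.0, "per_shape_p": {}}
            )
            if c["scope"] == "all_shapes":
                entry["main_p"] = c["p"]
                entry["interaction_p"] = c["interaction_p"]
            else:
                entry["per_shape_p"][c["scope"]] = c["p"]
        report[feat] = per_pair
    if rt_contrasts is not None:
        per_pair = {}
        for c in rt_contrasts:
            key = "-".join(c["pair"])
            per_pair[key] = {"main_p": c["p"], "interaction_p": 1.0, "per_shape_p": {}}
        report["reaction_time"] = per_pair
    return report


def standard_feature_sets(disc_sets: Mapping[str, FeatureSetSpec]) -> dict[str, list[FeatureSetSpec]]:
    """The eleven feature sets of the classification grid, per task."""
    all_kf = FeatureSetSpec("all_KF", tuple(kinematic_columns()))
    out: dict[str, list[FeatureSetSpec]] = {}
    for task in TASKS:
        disc = disc_sets[task]
        sets = [all_kf, disc]
        for qname, qcols in QUESTIONNAIRE_SETS.items():
            sets.append(FeatureSetSpec(qname, qcols))
        for base in (all_kf, disc):
            for qname, qcols in QUESTIONNAIRE_SETS.items():
                sets.append(
                    FeatureSetSpec(f"{base.name}+{qname}", base.columns + qcols)
                )
        out[task] = sets
    return out


def run_classifiers(
    table: ParticipantFeatureTable,
    feature_set: FeatureSetSpec,
    task: str,
    split_seed: int = 0,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> ClassificationResult:
    """KNN / RF / linear-SVM test accuracies on one stratified 80/20 split."""
    data = table.data
    if task == "clinical_vs_nonclinical":
        y = data["label_clinical"].to_numpy()
        mask = np.ones(len(data), dtype=bool)
    elif task == "ASD_vs_PD":
        mask = data["label_asd_pd"].notna().to_numpy()
        y = data.loc[mask, "label_asd_pd"].to_numpy(dtype=int)
    else:
        raise ValueError(f"unknown task {task!r}")
    if not feature_set.columns:
        raise ValueError(f"feature set {feature_set.name!r} is empty")
    X = data.loc[mask, list(feature_set.columns)].to_numpy(dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 5:
        raise ValueError("need >= 5 participants per class")

    seed = split_seed
    for _ in range(cfg.max_resplits):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=cfg.test_fraction, stratify=y, random_state=seed
        )
        if len(np.unique(y_tr)) == 2 and len(np.unique(y_te)) == 2:
            break
        seed += 1
    folds = int(min(cfg.cv_folds, np.bincount(y_tr).min()))
    folds = max(folds, 2)

    accuracy: dict = {}
    tuned: dict = {}

    max_k = max(1, (len(y_tr) * (folds - 1)) // folds)
    knn = GridSearchCV(
        Pipeline([("scale", StandardScaler()), ("clf", KNeighborsClassifier())]),
        {"clf__n_neighbors": [k for k in cfg.knn_grid if k <= max_k] or [1]},
        cv=folds,
    )
    knn.fit(X_tr, y_tr)
    accuracy["KNN"] = float(knn.score(X_te, y_te))
    tuned["KNN"] = {"n_neighbors": knn.best_params_["clf__n_neighbors"]}

    rf = GridSearchCV(
        RandomForestClassifier(random_state=seed),
        {"n_estimators": list(cfg.rf_grid)},
        cv=folds,
    )
    rf.fit(X_tr, y_tr)
    accuracy["RF"] = float(rf.score(X_te, y_te))
    tuned["RF"] = {"n_estimators": rf.best_params_["n_estimators"]}

    svm = Pipeline(
        [("scale", StandardScaler()), ("clf", SVC(kernel="linear", C=cfg.svm_c))]
    )
    svm.fit(X_tr, y_tr)
    accuracy["SVM"] = float(svm.score(X_te, y_te))
    tuned["SVM"] = {"C": cfg.svm_c}

    return ClassificationResult(
        task=task,
        feature_set=feature_set.name,
        accuracy=accuracy,
        mean_accuracy=float(np.mean(list(accuracy.values()))),
        split_seed=seed,
        tuned=tuned,
        n_test=len(y_te),
    )


def run_model_grid(
    table: ParticipantFeatureTable,
    disc_sets: Mapping[str, FeatureSetSpec],
    split_seed: int = 0,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> list[ClassificationResult]:
    """The full 2 x 11 grid (22 results); empty selections are skipped
    with a placeholder carrying NaN accuracies."""
    results: list[ClassificationResult] = []
    for task, sets in standard_feature_sets(disc_sets).items():
        for fset in sets:
            if not fset.columns:
                results.append(
                    ClassificationResult(
                        task, fset.name,
                        {"KNN": np.nan, "RF": np.nan, "SVM": np.nan},
                        np.nan, split_seed, {}, 0,
                    )
                )
                continue
            results.append(run_classifiers(table, fset, task, split_seed, cfg))
    return results


def grid_to_frame(results: Sequence[ClassificationResult]) -> dict[str, pd.DataFrame]:
    """Heat-map-style tables, one per task: rows KNN/SVM/RF/mean, columns
    feature sets ordered by descending mean accuracy."""
    out: dict[str, pd.DataFrame] = {}
    for task in TASKS:
        sub = [r for r in results if r.task == task]
        sub.sort(key=lambda r: (-(r.mean_accuracy if np.isfinite(r.mean_accuracy) else -1)))
        out[task] = pd.DataFrame(
            {
                r.feature_set: [
                    r.accuracy["KNN"], r.accuracy["SVM"], r.accuracy["RF"],
                    r.mean_accuracy,
                ]
                for r in sub
            },
            index=["KNN", "SVM", "RF", "mean"],
        )
    return out
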