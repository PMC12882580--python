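"""Participant feature tables, discriminatory-feature selection, and the
two-stage classification grid."""

import numpy as np
import pandas as pd
import pytest

from tracekin.classification import (
    ClassifierConfig,
    FeatureSetSpec,
    ParticipantFeatureTable,
    build_feature_table,
    grid_to_frame,
    kinematic_columns,
    run_classifiers,
    run_model_grid,
    select_discriminatory_features,
    standard_feature_sets,
)
from tracekin.kinematics import FEATURE_NAMES
from tracekin.shapes import SHAPE_NAMES

LIGHT = ClassifierConfig(rf_grid=(100, 200), cv_folds=3)


def fabricated_table(rng, n_per_group=15, separation=0.0) -> ParticipantFeatureTable:
    """Feature table built directly (no simulation): standard-normal
    predictors with an optional between-class mean separation."""
    rows = []
    for g in ("ASD", "PD", "CTRL"):
        for i in range(n_per_group):
            row = {"participant": f"{g}{i}", "group": g}
            for col in kinematic_columns():
                shift = separation if g != "CTRL" else 0.0
                if g == "ASD":
                    shift += separation
                row[col] = rng.normal(shift, 1.0)
            for q in ("aq_resid", "raads_resid", "updrs_resid"):
                row[q] = rng.normal(0.0, 1.0)
            rows.append(row)
    df = pd.DataFrame(rows)
    df["label_clinical"] = (df["group"] != "CTRL").astype(int)
    df["label_asd_pd"] = df["group"].map({"ASD": 1, "PD": 0})
    return ParticipantFeatureTable(df)


def trial_features_frame(rng, n_per_group=4, missing_shape_for=None) -> tuple:
    """Synthetic trial-level feature rows plus matching covariates."""
    rows, cov_rows = [], []
    pid = 0
    for g in ("ASD", "PD", "CTRL"):
        for _ in range(n_per_group):
            pid += 1
            name = f"P{pid:02d}"
            age = rng.normal(60, 8)
            cov_rows.append(
                dict(participant=name, group=g, age=age,
                     phq=rng.normal(5, 2), gad=rng.normal(5, 2),
                     aq=rng.normal(20, 5), raads=rng.normal(15, 5),
                     updrs=rng.normal(5, 3), nvr=rng.normal(0.55, 0.1),
                     gender="F")
            )
            for shape in SHAPE_NAMES:
                if missing_shape_for == name and shape == "clover":
                    continue
                for trial in (1, 2):
                    row = dict(participant=name, group=g, shape=shape,
                               day=1, trial=trial)
                    for feat in FEATURE_NAMES:
                        row[feat] = rng.normal(0.1 * age, 1.0)
                    rows.append(row)
    rt = pd.DataFrame(
        {"participant": [r["participant"] for r in cov_rows],
         "reaction_time": rng.normal(0.6, 0.05, len(cov_rows))}
    )
    return pd.DataFrame(rows), pd.DataFrame(cov_rows), rt


class TestBuildFeatureTable:
    def test_kinematic_block_has_37_columns(self):
        rng = np.random.default_rng(0)
        feats, cov, rt = trial_features_frame(rng)
        table = build_feature_table(feats, cov, rt)
        assert table.kinematic_block.shape[1] == 37
        assert table.kinematic_block.notna().all().all()

    def test_residuals_orthogonal_to_age(self):
        rng = np.random.default_rng(1)
        feats, cov, rt = trial_features_frame(rng, n_per_group=10)
        table = build_feature_table(feats, cov, rt)
        merged = table.data.merge(cov[["participant", "age"]], on="participant")
        r = np.corrcoef(merged["speed__clover"], merged["age"])[0, 1]
        assert abs(r) < 1e-9

    def test_hand_averaged_participant_matches(self):
        """Pipeline row equals manual mean + OLS residual for one cell."""
        rng = np.random.default_rng(2)
        feats, cov, rt = trial_features_frame(rng)
        table = build_feature_table(feats, cov, rt)
        pid = "P01"
        manual_means = (
            feats.groupby(["participant", "shape"])["jerk"].mean().unstack("shape")
        )
        controls = cov.set_index("participant")[["age", "phq", "gad"]].to_numpy()
        X = np.column_stack([np.ones(len(controls)), controls])
        ymat = manual_means.loc[cov["participant"]].to_numpy()
        betas = np.linalg.lstsq(X, ymat, rcond=None)[0]
        resid = ymat - X @ betas
        col = list(manual_means.columns).index("petals")
        i = list(cov["participant"]).index(pid)
        got = table.data.set_index("participant").loc[pid, "jerk__petals"]
        assert got == pytest.approx(resid[i, col], abs=1e-9)

    def test_missing_shape_imputed_and_logged(self):
        rng = np.random.default_rng(3)
        feats, cov, rt = trial_features_frame(rng, missing_shape_for="P01")
        table = build_feature_table(feats, cov, rt)
        imputed_cols = {c for _, c in table.imputed_cells}
        assert any(c.endswith("__clover") for c in imputed_cols)
        assert table.kinematic_block.notna().all().all()


class TestFeatureSelection:
    def reported_pattern(self):
        """The discriminatory pattern reported for this task: sub-movement
        main effects, a rounded-square-only speed-modulation interaction,
        and an ASD-PD reaction-time difference."""
        sig = {"main_p": 0.01, "interaction_p": 0.001,
               "per_shape_p": {"rounded_square": 0.02}}
        inter_only = {"main_p": 0.50, "interaction_p": 0.001,
                      "per_shape_p": {"rounded_square": 0.02, "ellipse": 0.60}}
        null = {"main_p": 0.8, "interaction_p": 0.7, "per_shape_p": {}}
        reports = {feat: {"ASD-PD": dict(null), "ASD-CTRL": dict(null),
                          "PD-CTRL": dict(null)} for feat in FEATURE_NAMES}
        reports["submovement_pct"]["ASD-PD"] = dict(sig)
        reports["submovement_pct"]["ASD-CTRL"] = dict(sig)
        reports["speed_modulation"]["ASD-PD"] = dict(inter_only)
        reports["speed_modulation"]["ASD-CTRL"] = dict(inter_only)
        reports["reaction_time"] = {
            "ASD-PD": {"main_p": 0.009}, "ASD-CTRL": {"main_p": 0.6},
            "PD-CTRL": {"main_p": 0.4},
        }
        return reports

    def test_reported_pattern_yields_expected_asd_pd_set(self):
        spec = select_discriminatory_features(self.reported_pattern(), "ASD_vs_PD")
        expected = {f"submovement_pct__{s}" for s in SHAPE_NAMES}
        expected.add("speed_modulation__rounded_square")
        expected.add("reaction_time")
        assert set(spec.columns) == expected

    def test_clinical_set_excludes_asd_pd_only_rt(self):
        spec = select_discriminatory_features(
            self.reported_pattern(), "clinical_vs_nonclinical"
        )
        assert "reaction_time" not in spec.columns
        assert {f"submovement_pct__{s}" for s in SHAPE_NAMES} <= set(spec.columns)

    def test_all_null_report_empty(self):
        null = {"main_p": 0.8, "interaction_p": 0.7, "per_shape_p": {}}
        reports = {feat: {"ASD-PD": dict(null)} for feat in FEATURE_NAMES}
        spec = select_discriminatory_features(reports, "ASD_vs_PD")
        assert spec.columns == ()

    def test_interaction_only_single_column(self):
        null = {"main_p": 0.8, "interaction_p": 0.7, "per_shape_p": {}}
        reports = {feat: {"ASD-PD": dict(null)} for feat in FEATURE_NAMES}
        reports["sparc"]["ASD-PD"] = {
            "main_p": 0.4, "interaction_p": 0.01, "per_shape_p": {"petals": 0.03}
        }
        spec = select_discriminatory_features(reports, "ASD_vs_PD")
        assert spec.columns == ("sparc__petals",)

    def test_pure_function_of_report(self):
        r = self.reported_pattern()
        assert select_discriminatory_features(r, "ASD_vs_PD") == \
            select_discriminatory_features(r, "ASD_vs_PD")


class TestRunClassifiers:
    def test_separable_classes_perfect_accuracy(self):
        rng = np.random.default_rng(4)
        table = fabricated_table(rng, separation=10.0)
        fset = FeatureSetSpec("all_KF", tuple(kinematic_columns()))
        res = run_classifiers(table, fset, "clinical_vs_nonclinical", 0, LIGHT)
        assert all(a == 1.0 for a in res.accuracy.values())
        assert res.mean_accuracy == 1.0

    def test_determinism(self):
        rng = np.random.default_rng(5)
        table = fabricated_table(rng, separation=1.0)
        fset = FeatureSetSpec("all_KF", tuple(kinematic_columns()))
        a = run_classifiers(table, fset, "ASD_vs_PD", 3, LIGHT)
        b = run_classifiers(table, fset, "ASD_vs_PD", 3, LIGHT)
        assert a.accuracy == b.accuracy and a.tuned == b.tuned

    def test_noise_columns_leave_separable_svm_intact(self):
        rng = np.random.default_rng(6)
        table = fabricated_table(rng, separation=10.0)
        clean = FeatureSetSpec("clean", tuple(kinematic_columns()[:5]))
        noisy = FeatureSetSpec("noisy", tuple(kinematic_columns()[:5]) +
                               tuple(kinematic_columns()[20:25]))
        # columns 20..25 carry the same separation here, so instead build
        # true noise columns
        data = table.data.copy()
        for j in range(5):
            data[f"noise_{j}"] = rng.normal(0, 1, len(data))
        noisy = FeatureSetSpec("noisy", clean.columns + tuple(f"noise_{j}" for j in range(5)))
        table2 = ParticipantFeatureTable(data)
        r_clean = run_classifiers(table2, clean, "clinical_vs_nonclinical", 0, LIGHT)
        r_noisy = run_classifiers(table2, noisy, "clinical_vs_nonclinical", 0, LIGHT)
        assert r_noisy.accuracy["SVM"] >= r_clean.accuracy["SVM"] - 0.2

    def test_too_few_participants_rejected(self):
        rng = np.random.default_rng(7)
        table = fabricated_table(rng, n_per_group=4)
        fset = FeatureSetSpec("all_KF", tuple(kinematic_columns()))
        with pytest.raises(ValueError):
            run_classifiers(table, fset, "ASD_vs_PD", 0, LIGHT)


class TestModelGrid:
    def test_eleven_sets_per_task(self):
        disc = FeatureSetSpec("disc_KF", tuple(kinematic_columns()[:3]))
        sets = standard_feature_sets({"clinical_vs_nonclinical": disc, "ASD_vs_PD": disc})
        assert all(len(v) == 11 for v in sets.values())
        names = [s.name for s in sets["ASD_vs_PD"]]
        assert len(set(names)) == 11

    def test_grid_emits_22_results(self):
        rng = np.random.default_rng(8)
        table = fabricated_table(rng, separation=1.0)
        disc = FeatureSetSpec("disc_KF", tuple(kinematic_columns()[:4]))
        results = run_model_grid(
            table, {"clinical_vs_nonclinical": disc, "ASD_vs_PD": disc}, 0, LIGHT
        )
        assert len(results) == 22
        blocks = grid_to_frame(results)
        assert set(blocks) == {"clinical_vs_nonclinical", "ASD_vs_PD"}
        for block in blocks.values():
            assert block.shape == (4, 11)
            vals = block.loc["mean"].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            # columns ordered by descending mean accuracy
            assert (np.diff(finite) <= 1e-12).all()
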