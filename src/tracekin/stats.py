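"""Statistical chain: outlier removal, transforms, group matching, mixed
models with follow-up decomposition, and BIC-approximate Bayes factors.

The primary model for each kinematic dependent variable is an effects-coded
(sum-to-zero) linear mixed model

    DV ~ Group * Shape + Age + Depression + Anxiety
         + (1 | Day) + (1 | Trial) + (1 | Participant)

fit by REML, with per-term F tests (Type III under sum coding).  Reaction
time uses the variant without Shape and the Trial random effect.  Day and
trial random intercepts are modelled as variance components within
participant (a nested approximation to fully crossed effects).

Denominator degrees of freedom use a containment-style rule: effects that
vary only between participants (Group and the covariates) are tested
against participant-level df; within-participant effects (Shape and the
interaction) against observation-level df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .kinematics import FEATURE_NAMES

__all__ = [
    "LmmResult",
    "BayesResult",
    "remove_outliers",
    "transform_features",
    "build_analysis_table",
    "welch_t_from_summary",
    "oneway_f_from_summary",
    "cohort_compare",
    "fit_lmm",
    "followup_contrasts",
    "bayes_factor_group",
    "score_reaction_times",
    "LOG_FEATURES",
    "RECIPROCAL_FEATURES",
]

LOG_FEATURES = ("speed", "acceleration", "jerk")
RECIPROCAL_FEATURES = ("min_speed",)

GROUP_ORDER = ("ASD", "PD", "CTRL")


# ---------------------------------------------------------------------------
# outlier removal and transforms
# ---------------------------------------------------------------------------

def remove_outliers(
    table: pd.DataFrame, feature: str, k: float = 2.0
) -> tuple[pd.DataFrame, float]:
    """Drop rows whose feature lies > k pooled SDs from the pooled mean.

    The mean and SD are computed once over all trials of all participants
    (grand pooling), so the removal fraction is a single per-feature
    quantity.  Returns the retained table and the removed fraction.
    """
    values = table[feature]
    finite = values.notna()
    if finite.sum() < 3:
        raise ValueError("need at least 3 retained values")
    mu = values[finite].mean()
    sd = values[finite].std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return table, 0.0
    out = finite & ((values - mu).abs() > k * sd)
    kept = table.loc[~out]
    return kept, float(out.sum() / finite.sum())


def transform_features(
    table: pd.DataFrame, features: Sequence[str] = FEATURE_NAMES
) -> tuple[pd.DataFrame, dict]:
    """Normalising transforms then z-scoring of every dependent variable.

    Natural log for speed, acceleration and jerk; reciprocal for minimum
    speed.  Rows with non-positive values where a log is required are
    dropped (logged in the returned flags).  Every feature column is then
    z-scored over retained rows.
    """
    table = table.copy()
    flags: dict = {"dropped_nonpositive": {}, "transform_applied": {}}
    for feat in features:
        if feat not in table.columns:
            continue
        if feat in LOG_FEATURES:
            bad = table[feat].notna() & (table[feat] <= 0)
            if bad.any():
                flags["dropped_nonpositive"][feat] = int(bad.sum())
                table = table.loc[~bad]
            table[feat] = np.log(table[feat])
            flags["transform_applied"][feat] = "log"
        elif feat in RECIPROCAL_FEATURES:
            bad = table[feat].notna() & (table[feat] == 0)
            if bad.any():
                flags["dropped_nonpositive"][feat] = int(bad.sum())
                table = table.loc[~bad]
            table[feat] = 1.0 / table[feat]
            flags["transform_applied"][feat] = "reciprocal"
    for feat in features:
        if feat not in table.columns:
            continue
        mu = table[feat].mean()
        sd = table[feat].std(ddof=1)
        if sd > 0:
            table[feat] = (table[feat] - mu) / sd
    return table, flags


def build_analysis_table(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    feature_names: Sequence[str] = FEATURE_NAMES,
    outlier_k: float = 2.0,
) -> tuple[dict, dict]:
    """Per-feature analysis tables: outlier removal, transforms, z-scoring.

    Outliers are feature-specific, so each dependent variable gets its own
    retained table.  Returns ``(tables, report)`` where ``tables`` maps
    feature -> analysis table with covariates joined (columns depression
    and anxiety are the PHQ and GAD scores), and ``report`` records removal
    fractions and transform flags.
    """
    cov = covariates.rename(
        columns={"phq": "depression", "gad": "anxiety", "participant_id": "participant"}
    )
    cov_cols = ["participant", "age", "depression", "anxiety"]
    feats = features.rename(columns={"participant_id": "participant"})
    merged = feats.merge(cov[cov_cols], on="participant", how="left")
    tables: dict = {}
    report: dict = {"removed_fraction": {}, "transforms": {}}
    for feat in feature_names:
        sub = merged.loc[merged[feat].notna()].copy()
        if len(sub) < 3:
            continue
        kept, frac = remove_outliers(sub, feat, outlier_k)
        transformed, flags = transform_features(kept, [feat])
        tables[feat] = transformed
        report["removed_fraction"][feat] = frac
        report["transforms"][feat] = flags["transform_applied"].get(feat, "none")
    return tables, report


def score_reaction_times(
    rt: pd.DataFrame, k: float = 2.0, include_practice: bool = False
) -> pd.DataFrame:
    """Per participant-day mean reaction time after within-participant
    outlier removal (trials > k SD from the participant's mean dropped)."""
    data = rt if include_practice else rt.loc[~rt["practice"]]

    def _participant_clean(g: pd.DataFrame) -> pd.DataFrame:
        mu, sd = g["rt_s"].mean(), g["rt_s"].std(ddof=1)
        if sd > 0:
            g = g.loc[(g["rt_s"] - mu).abs() <= k * sd]
        return g

    cleaned = (
        data.groupby("participant_id", group_keys=False)[data.columns]
        .apply(_participant_clean)
    )
    out = (
        cleaned.groupby(["participant_id", "group", "day"], as_index=False)["rt_s"]
        .mean()
        .rename(columns={"participant_id": "participant", "rt_s": "reaction_time"})
    )
    return out


# ---------------------------------------------------------------------------
# group matching (closed-form from summaries, or from raw columns)
# ---------------------------------------------------------------------------

def welch_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    """Welch's t and Welch-Satterthwaite df from group summaries."""
    se1, se2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(se1 + se2)
    df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    return float(t), float(df)


def oneway_f_from_summary(groups: Sequence[tuple[float, float, int]]) -> tuple[float, int, int]:
    """One-way ANOVA F from (mean, SD, n) summaries."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g[2] for g in groups], dtype=float)
    means = np.array([g[0] for g in groups], dtype=float)
    sds = np.array([g[1] for g in groups], dtype=float)
    grand = float(np.sum(ns * means) / ns.sum())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds**2))
    df1 = len(groups) - 1
    df2 = int(ns.sum()) - len(groups)
    return (ss_between / df1) / (ss_within / df2), df1, df2


def cohort_compare(
    covariates: pd.DataFrame,
    continuous: Sequence[str] = ("age", "nvr", "phq", "gad", "updrs", "raads", "aq"),
    alpha: float = 0.05,
) -> dict:
    """Group-matching report: one-way ANOVA per continuous covariate,
    pairwise Welch t-tests, and a chi-square test of gender counts."""
    groups = [g for g in GROUP_ORDER if g in set(covariates["group"])]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    report: dict = {"anova": {}, "welch": {}, "chi2_gender": None, "excluded": []}
    usable = []
    for g in groups:
        if (covariates["group"] == g).sum() < 2:
            report["excluded"].append(g)
        else:
            usable.append(g)
    for col in continuous:
        if col not in covariates.columns:
            continue
        samples = [
            covariates.loc[covariates["group"] == g, col].dropna().to_numpy()
            for g in usable
        ]
        f, p = sps.f_oneway(*samples)
        df1 = len(usable) - 1
        df2 = sum(len(s) for s in samples) - len(usable)
        report["anova"][col] = {"F": float(f), "df1": df1, "df2": df2, "p": float(p)}
        pairs = {}
        for i in range(len(usable)):
            for j in range(i + 1, len(usable)):
                a, b = samples[i], samples[j]
                t, df = welch_t_from_summary(
                    a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
                )
                p_t = 2.0 * sps.t.sf(abs(t), df)
                pairs[f"{usable[i]}-{usable[j]}"] = {"t": t, "df": df, "p": p_t}
        report["welch"][col] = pairs
    if "gender" in covariates.columns:
        ct = pd.crosstab(covariates["group"], covariates["gender"])
        chi2, p, dof, _ = sps.chi2_contingency(ct)
        report["chi2_gender"] = {"chi2": float(chi2), "df": int(dof), "p": float(p)}
    return report


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

@dataclass
class LmmResult:
    dv: str
    formula: str
    anova: pd.DataFrame  # term, F, df1, df2, p
    fixed_effects: pd.DataFrame  # estimate, ci_lo, ci_hi per coefficient
    random_variances: dict
    nobs: int
    n_participants: int
    converged: bool
    variant: str = "shapes"

    def term_p(self, term: str) -> float:
        row = self.anova.loc[self.anova["term"] == term]
        return float(row["p"].iloc[0]) if len(row) else np.nan


@dataclass
class BayesResult:
    dv: str
    bf01_group: float
    bic_with_group: float
    bic_without_group: float
    method: str = "BIC-approximation"


def _fit_mixedlm(formula: str, data: pd.DataFrame, vc: Optional[dict], reml: bool = True):
    model = MixedLM.from_formula(
        formula, data, groups="participant", re_formula="1", vc_formula=vc or None
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            res = model.fit(reml=reml, method="powell", maxiter=500)
        except (np.linalg.LinAlgError, ValueError):
            res = model.fit(reml=reml, method="lbfgs", maxiter=500)
    return model, res


_BETWEEN_TERMS = {"C(group, Sum)", "age", "depression", "anxiety", "Intercept"}


def fit_lmm(
    table: pd.DataFrame,
    dv: str,
    variant: str = "shapes",
    single_day: bool = False,
) -> LmmResult:
    """Effects-coded mixed model for one dependent variable.

    ``variant="shapes"`` fits ``dv ~ Group*Shape + Age + Depression +
    Anxiety`` with random intercepts for participant, day and trial number;
    ``variant="rt"`` omits Shape and the trial random effect.  With
    ``single_day=True`` the day random effect is dropped (single-day
    sensitivity analysis).
    """
    data = table.rename(columns={dv: "_dv"}).copy()
    data = data.loc[data["_dv"].notna()]
    if variant == "shapes":
        fixed = "_dv ~ C(group, Sum) * C(shape, Sum) + age + depression + anxiety"
        vc = {} if single_day else {"day": "0 + C(day)"}
        if "trial" in data.columns and data["trial"].nunique() > 1:
            vc["trial"] = "0 + C(trial)"
    elif variant == "rt":
        fixed = "_dv ~ C(group, Sum) + age + depression + anxiety"
        vc = {} if single_day else {"day": "0 + C(day)"}
    else:
        raise ValueError(f"unknown variant {variant!r}")
    for factor in ("group",) + (("shape",) if variant == "shapes" else ()):
        if data[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels")
    model, res = _fit_mixedlm(fixed, data, vc, reml=True)

    k_fe = len(res.fe_params)
    beta = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    n_part = data["participant"].nunique()
    nobs = len(data)
    design_info = model.data.design_info
    p_between = sum(
        design_info.term_name_slices[t].stop - design_info.term_name_slices[t].start
        for t in design_info.term_name_slices
        if t in _BETWEEN_TERMS
    )
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(sl.start, sl.stop)
        L = np.zeros((len(idx), k_fe))
        L[np.arange(len(idx)), idx] = 1.0
        lb = L @ beta
        lcov = L @ cov @ L.T
        try:
            w = float(lb @ np.linalg.solve(lcov, lb))
        except np.linalg.LinAlgError:
            w = np.nan
        df1 = len(idx)
        if term in _BETWEEN_TERMS:
            df2 = max(n_part - p_between, 2)
        else:
            df2 = max(nobs - n_part - k_fe, 2)
        f_stat = w / df1
        p = float(sps.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else np.nan
        rows.append({"term": term, "F": f_stat, "df1": df1, "df2": df2, "p": p})
    anova = pd.DataFrame(rows)

    ci = np.asarray(res.conf_int())[:k_fe]
    fixed_effects = pd.DataFrame(
        {
            "coef": model.exog_names,
            "estimate": beta,
            "ci_lo": ci[:, 0],
            "ci_hi": ci[:, 1],
        }
    )
    rv = {"participant": float(np.asarray(res.cov_re).ravel()[0])}
    if res.vcomp is not None and len(res.vcomp):
        for name, v in zip(model.exog_vc.names, res.vcomp):
            rv[name] = float(v)
    return LmmResult(
        dv=dv,
        formula=fixed,
        anova=anova,
        fixed_effects=fixed_effects,
        random_variances=rv,
        nobs=nobs,
        n_participants=n_part,
        converged=bool(res.converged),
        variant=variant,
    )


GROUP_TERM = "C(group, Sum)"
SHAPE_TERM = "C(shape, Sum)"
INTERACTION_TERM = "C(group, Sum):C(shape, Sum)"


def _group_effect_estimate(result: LmmResult) -> tuple[float, float, float]:
    """Sum-coded group coefficient (first level) with its 95% CI."""
    fe = result.fixed_effects
    mask = fe["coef"].str.startswith("C(group, Sum)")
    row = fe.loc[mask].iloc[0]
    return float(row["estimate"]), float(row["ci_lo"]), float(row["ci_hi"])


def followup_contrasts(
    table: pd.DataFrame,
    dv: str,
    main_result: LmmResult,
    alpha: float = 0.05,
    single_day: bool = False,
) -> list[dict]:
    """Decompose a significant group effect or group-by-shape interaction.

    Pairwise two-group models are fitted when the omnibus Group or
    Group x Shape term is significant; where a pairwise interaction is
    significant, per-shape two-group models localise the effect.  Reported
    p-values are uncorrected (alpha = .05), matching the analysis they
    reproduce; multiplicity is a documented limitation.
    """
    contrasts: list[dict] = []
    if not (
        main_result.term_p(GROUP_TERM) < alpha
        or main_result.term_p(INTERACTION_TERM) < alpha
    ):
        return contrasts
    groups = [g for g in GROUP_ORDER if g in set(table["group"])]
    shapes = sorted(set(table["shape"]))
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            pair = (groups[i], groups[j])
            sub = table.loc[table["group"].isin(pair)]
            try:
                pres = fit_lmm(sub, dv, "shapes", single_day=single_day)
            except (ValueError, np.linalg.LinAlgError):
                continue
            est, lo, hi = _group_effect_estimate(pres)
            rec = {
                "pair": pair,
                "scope": "all_shapes",
                "F": pres.anova.loc[pres.anova["term"] == GROUP_TERM, "F"].iloc[0],
                "p": pres.term_p(GROUP_TERM),
                "interaction_p": pres.term_p(INTERACTION_TERM),
                "estimate": est,
                "ci": (lo, hi),
            }
            contrasts.append(rec)
            if rec["interaction_p"] < alpha:
                for shape in shapes:
                    sub_s = sub.loc[sub["shape"] == shape]
                    try:
                        sres = _fit_per_shape(sub_s, dv, single_day)
                    except (ValueError, np.linalg.LinAlgError):
                        continue
                    est_s, lo_s, hi_s = _group_effect_estimate(sres)
                    contrasts.append(
                        {
                            "pair": pair,
                            "scope": shape,
                            "F": sres.anova.loc[
                                sres.anova["term"] == GROUP_TERM, "F"
                            ].iloc[0],
                            "p": sres.term_p(GROUP_TERM),
                            "interaction_p": np.nan,
                            "estimate": est_s,
                            "ci": (lo_s, hi_s),
                        }
                    )
    return contrasts


def _fit_per_shape(sub: pd.DataFrame, dv: str, single_day: bool) -> LmmResult:
    """Two-group single-shape model (no Shape factor)."""
    data = sub.rename(columns={dv: "_dv"}).copy()
    data = data.loc[data["_dv"].notna()]
    if data["group"].nunique() < 2:
        raise ValueError("need both groups")
    vc = {} if single_day else {"day": "0 + C(day)"}
    if "trial" in data.columns and data["trial"].nunique() > 1:
        vc["trial"] = "0 + C(trial)"
    fixed = "_dv ~ C(group, Sum) + age + depression + anxiety"
    model, res = _fit_mixedlm(fixed, data, vc, reml=True)
    k_fe = len(res.fe_params)
    beta = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
    n_part = data["participant"].nunique()
    design_info = model.data.design_info
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(sl.start, sl.stop)
        lb = beta[idx]
        lcov = cov[np.ix_(idx, idx)]
        w = float(lb @ np.linalg.solve(lcov, lb))
        df1 = len(idx)
        df2 = max(n_part - 5, 2)
        f_stat = w / df1
        rows.append(
            {"term": term, "F": f_stat, "df1": df1, "df2": df2,
             "p": float(sps.f.sf(f_stat, df1, df2))}
        )
    ci = np.asarray(res.conf_int())[:k_fe]
    fixed_effects = pd.DataFrame(
        {"coef": model.exog_names, "estimate": beta, "ci_lo": ci[:, 0], "ci_hi": ci[:, 1]}
    )
    return LmmResult(
        dv=dv, formula=fixed, anova=pd.DataFrame(rows), fixed_effects=fixed_effects,
        random_variances={}, nobs=len(data), n_participants=n_part,
        converged=bool(res.converged), variant="per_shape",
    )


def bayes_factor_group(
    table: pd.DataFrame, dv: str, variant: str = "shapes"
) -> BayesResult:
    """BF01 for the group main effect via the BIC approximation.

    The dependent variable is residualised on age, depression and anxiety
    (ordinary least squares), then mixed models with and without the Group
    term are fitted by maximum likelihood;
    ``BF01 = exp((BIC_with_group - BIC_without_group) / 2)``.
    """
    data = table.rename(columns={dv: "_raw"}).copy()
    data = data.loc[data["_raw"].notna()]
    X = sm.add_constant(data[["age", "depression", "anxiety"]])
    data["_dv"] = sm.OLS(data["_raw"], X).fit().resid
    vc = {"day": "0 + C(day)"}
    if variant == "shapes":
        if "trial" in data.columns and data["trial"].nunique() > 1:
            vc["trial"] = "0 + C(trial)"
        with_f = "_dv ~ C(group, Sum) + C(shape, Sum)"
        without_f = "_dv ~ C(shape, Sum)"
    else:
        with_f = "_dv ~ C(group, Sum)"
        without_f = "_dv ~ 1"

    def _bic(formula: str) -> float:
        model, res = _fit_mixedlm(formula, data, vc, reml=False)
        k = len(res.fe_params) + len(np.asarray(res.vcomp)) + 2  # +re var +resid
        return float(-2.0 * res.llf + k * np.log(len(data)))

    bic_with = _bic(with_f)
    bic_without = _bic(without_f)
    bf01 = float(np.exp((bic_with - bic_without) / 2.0))
    return BayesResult(dv, bf01, bic_with, bic_without)
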