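"""Cohort statistics: group ANOVAs with Bonferroni post-hoc tests,
correlation matrices, and transition logistic regression.

The transition models follow the clinical convention for this analysis:
restricted to subjects meeting UHR criteria, source-activity predictors
inverse coded (multiplied by −1 so higher values mean larger deficit),
and all continuous predictors z-transformed on the analysis sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import SeparationError, StatisticsError

UHR_CRITERIA_GROUPS = ("UHR&BS", "UHR")

#: Table-style predictor set of the adjusted transition model
TRANSITION_PREDICTORS = (
    "sex", "age", "rs1_duration", "rs2_duration", "rs3_duration",
    "gaf", "sips_pos", "sips_neg",
)


@dataclass(frozen=True)
class GroupComparisonResult:
    measure: str
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    posthoc: tuple = ()  # (group_a, group_b, adjusted_p, direction)


@dataclass(frozen=True)
class LogisticModelResult:
    label: str
    predictors: tuple
    odds_ratios: dict
    ci_low: dict
    ci_high: dict
    p_values: dict
    n_outcome: tuple  # (n_negative, n_positive)
    converged: bool


def _check_groups(values: np.ndarray, groups: np.ndarray) -> dict[str, np.ndarray]:
    by = {}
    for g in dict.fromkeys(groups):
        v = values[groups == g]
        if len(v) < 2:
            raise StatisticsError(f"group {g!r} has fewer than 2 subjects")
        by[g] = v
    if len(by) < 2:
        raise StatisticsError("at least two groups are required")
    return by


def anova_oneway(values, groups, measure: str = "") -> GroupComparisonResult:
    """Classical one-way fixed-effects ANOVA (between/within decomposition)."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    by = _check_groups(values, groups)
    f, p = sps.f_oneway(*by.values())
    k, n = len(by), len(values)
    return GroupComparisonResult(
        measure=measure,
        f_statistic=float(f),
        df_between=k - 1,
        df_within=n - k,
        p_value=float(p),
    )


def bonferroni_posthoc(values, groups, equal_var: bool = True) -> pd.DataFrame:
    """All unordered pairwise two-sample t tests, Bonferroni adjusted.

    ``adjusted_p = min(1, m * p_raw)`` with m the number of pairs;
    ``direction`` is the sign of mean(a) − mean(b).  Pooled-variance t
    by default; Welch via ``equal_var=False``.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    by = _check_groups(values, groups)
    pairs = list(combinations(by.keys(), 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        delta = float(by[a].mean() - by[b].mean())
        if np.allclose(by[a].std(ddof=1), 0) and np.allclose(by[b].std(ddof=1), 0) \
                and np.isclose(delta, 0):
            p_raw = 1.0
        else:
            _, p_raw = sps.ttest_ind(by[a], by[b], equal_var=equal_var)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "p_raw": float(p_raw),
                "adjusted_p": float(min(1.0, m * p_raw)),
                "direction": int(np.sign(delta)),
                "mean_difference": delta,
            }
        )
    return pd.DataFrame(rows)


def correlation_matrix(table: pd.DataFrame, columns: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r (with two-sided p) over the selected columns.

    Binary sex is encoded 0/1 so its entries are point-biserial
    correlations.  Zero-variance columns yield NaN cells rather than an
    error.  Returns ``(r, p)`` frames, symmetric with unit diagonal.
    """
    data = table[columns].copy()
    if "sex" in data.columns and data["sex"].dtype == object:
        data["sex"] = (data["sex"] == "M").astype(float)
    arr = data.to_numpy(float)
    if arr.shape[0] < 3:
        raise StatisticsError("need at least 3 complete observations")
    if np.isnan(arr).any():
        raise StatisticsError("missing values in correlation columns")
    k = arr.shape[1]
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if arr[:, i].std() == 0 or arr[:, j].std() == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rr, pp = sps.pearsonr(arr[:, i], arr[:, j])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    return (
        pd.DataFrame(r, index=columns, columns=columns),
        pd.DataFrame(p, index=columns, columns=columns),
    )


def select_uhr_subset(table: pd.DataFrame) -> pd.DataFrame:
    """Analysis subset of the transition models: subjects meeting UHR
    criteria (groups UHR and UHR&BS) that passed the acceptance gate."""
    sel = table["group"].isin(UHR_CRITERIA_GROUPS)
    if "gate_included" in table.columns:
        sel &= table["gate_included"]
    return table.loc[sel].copy()


def prepare_regression_predictors(
    table: pd.DataFrame,
    invert: tuple[str, ...] = ("rs1_duration", "rs2_duration", "rs3_duration"),
    predictors: tuple[str, ...] = TRANSITION_PREDICTORS,
) -> pd.DataFrame:
    """Inverse-code source columns and z-transform continuous predictors.

    Inverse coding multiplies the listed source-activity columns by −1;
    all continuous predictors are then standardized to the analysis
    sample's mean/SD (sample SD, ddof 1).  Sex stays binary 0/1.
    """
    out = pd.DataFrame(index=table.index)
    for col in predictors:
        if col == "sex":
            out["sex"] = (table["sex"] == "M").astype(float) \
                if table["sex"].dtype == object else table["sex"].astype(float)
            continue
        x = table[col].to_numpy(float)
        if col in invert:
            x = -x
        sd = x.std(ddof=1)
        if sd == 0:
            raise StatisticsError(f"column {col!r} has zero variance")
        out[col] = (x - x.mean()) / sd
    return out


def fit_logistic(
    outcome,
    predictors: pd.DataFrame,
    mode: str = "unadjusted",
) -> list[LogisticModelResult]:
    """Maximum-likelihood logistic transition models with Wald 95 % CIs.

    ``mode="unadjusted"`` fits one single-predictor model per column;
    ``mode="adjusted"`` fits one joint model over all columns.  Perfect
    separation raises :class:`SeparationError` instead of returning
    runaway estimates.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, float)
    if len(np.unique(y)) < 2:
        raise StatisticsError("outcome must contain both classes")
    if mode not in ("unadjusted", "adjusted"):
        raise StatisticsError(f"unknown mode {mode!r}")
    col_sets = (
        [[c] for c in predictors.columns] if mode == "unadjusted"
        else [list(predictors.columns)]
    )
    results = []
    for cols in col_sets:
        label = "unadjusted:" + cols[0] if mode == "unadjusted" else "adjusted"
        block = predictors[cols].to_numpy(float)
        flat = [c for c, s in zip(cols, block.std(axis=0)) if s == 0]
        if flat:
            raise StatisticsError(
                f"logistic model {label!r}: constant predictor(s) {flat}"
            )
        X = sm.add_constant(block, has_constant="add")
        try:
            import warnings

            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")  # separation raises below
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels PerfectSeparationError etc.
            raise SeparationError(
                f"logistic model {label!r} did not converge: {exc}"
            ) from exc
        params = fit.params[1:]
        bse = fit.bse[1:]
        if not np.isfinite(bse).all() or np.abs(params).max() > 30:
            raise SeparationError(
                f"logistic model {label!r}: separation suspected "
                f"(|beta|max = {np.abs(params).max():.1f})"
            )
        z = 1.959963984540054
        orx = dict(zip(cols, np.exp(params)))
        lo = dict(zip(cols, np.exp(params - z * bse)))
        hi = dict(zip(cols, np.exp(params + z * bse)))
        pv = dict(zip(cols, fit.pvalues[1:]))
        results.append(
            LogisticModelResult(
                label=label,
                predictors=tuple(cols),
                odds_ratios=orx,
                ci_low=lo,
                ci_high=hi,
                p_values=pv,
                n_outcome=(int((y == 0).sum()), int((y == 1).sum())),
                converged=bool(fit.mle_retvals.get("converged", True)),
            )
        )
    return results


@dataclass
class StudyReport:
    """Bundle mirroring the structure of the published result tables."""

    demographics: pd.DataFrame
    measures_by_group: pd.DataFrame
    group_tests: pd.DataFrame
    posthoc: dict = field(default_factory=dict)
    correlations: pd.DataFrame = None
    correlation_p: pd.DataFrame = None
    transition_table: pd.DataFrame = None

    def to_json_dict(self) -> dict:
        out = {
            "demographics": self.demographics.to_dict("records"),
            "measures_by_group": self.measures_by_group.to_dict("records"),
            "group_tests": self.group_tests.to_dict("records"),
            "posthoc": {k: v.to_dict("records") for k, v in self.posthoc.items()},
        }
        if self.correlations is not None:
            out["correlations"] = self.correlations.round(6).to_dict()
        if self.transition_table is not None:
            out["transition_models"] = self.transition_table.to_dict("records")
        return out


def study_report(table: pd.DataFrame) -> StudyReport:
    """Demographics, per-group measure moments with ANOVAs/post-hocs,
    source correlations, and unadjusted/adjusted transition models.

    Gate-excluded subjects are dropped from every analysis block.
    """
    if "gate_included" in table.columns:
        table = table.loc[table["gate_included"]].copy()

    demo_rows = []
    for g, sub in table.groupby("group"):
        demo_rows.append(
            {
                "group": g,
                "n": len(sub),
                "n_male": int((sub["sex"] == "M").sum()),
                "n_transition": int(sub["transition"].sum()),
                "age_mean": sub["age"].mean(),
                "age_sd": sub["age"].std(ddof=1),
            }
        )
    demographics = pd.DataFrame(demo_rows)

    sensor_cols = [c for c in table.columns
                   if c.startswith("amp_") and c.endswith("_duration")]
    source_cols = [c for c in ("rs1_duration", "rs2_duration", "rs3_duration")
                   if c in table.columns]
    measure_cols = sensor_cols + source_cols

    blocks, tests, posthoc = [], [], {}
    groups = table["group"].to_numpy()
    con_vs_all = np.where(groups == "CON", "CON", "at-risk")
    for col in measure_cols:
        vals = table[col].to_numpy(float)
        for g, sub in table.groupby("group"):
            blocks.append(
                {
                    "measure": col,
                    "group": g,
                    "mean": sub[col].mean(),
                    "sd": sub[col].std(ddof=1),
                    "n": len(sub),
                }
            )
        overall = anova_oneway(vals, groups, measure=col)
        convall = anova_oneway(vals, con_vs_all, measure=col)
        tests.append(
            {
                "measure": col,
                "p_across_subgroups": overall.p_value,
                "f_across_subgroups": overall.f_statistic,
                "p_con_vs_risk": convall.p_value,
                "f_con_vs_risk": convall.f_statistic,
            }
        )
        posthoc[col] = bonferroni_posthoc(vals, groups)

    corr_cols = ["sex", "age"] + source_cols + ["gaf"]
    corr, corr_p = correlation_matrix(table, corr_cols)

    uhr = select_uhr_subset(table)
    transition_table = None
    if len(uhr) and uhr["transition"].nunique() == 2:
        prep = prepare_regression_predictors(uhr)
        y = uhr["transition"].astype(int).to_numpy()
        rows = []
        try:
            for res in fit_logistic(y, prep, mode="unadjusted"):
                c = res.predictors[0]
                rows.append(
                    {
                        "predictor": c,
                        "model": "unadjusted",
                        "odds_ratio": res.odds_ratios[c],
                        "ci_low": res.ci_low[c],
                        "ci_high": res.ci_high[c],
                        "p": res.p_values[c],
                    }
                )
            adj = fit_logistic(y, prep, mode="adjusted")[0]
            for c in adj.predictors:
                rows.append(
                    {
                        "predictor": c,
                        "model": "adjusted",
                        "odds_ratio": adj.odds_ratios[c],
                        "ci_low": adj.ci_low[c],
                        "ci_high": adj.ci_high[c],
                        "p": adj.p_values[c],
                    }
                )
        except (SeparationError, StatisticsError) as exc:
            rows.append({"predictor": "—", "model": f"failed: {exc}",
                         "odds_ratio": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan})
        transition_table = pd.DataFrame(rows)

    return StudyReport(
        demographics=demographics,
        measures_by_group=pd.DataFrame(blocks),
        group_tests=pd.DataFrame(tests),
        posthoc=posthoc,
        correlations=corr,
        correlation_p=corr_p,
        transition_table=transition_table,
    )
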