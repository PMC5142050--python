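"""The study's inference layer.

Experiment 1 (behaviour): per-treatment tests of shoal preference against the
no-preference null of 0.5, a clustered binomial model for initial choice, and
a mixed model for activity.  Experiment 2 (physiology): Gaussian mixed models
for MR_min, RMR, ISR and activity with CO2 treatment × testing treatment
fixed effects, body mass as covariate and individual as random intercept;
fixed-effect (GLM) models for MMR and aerobic scope; Tukey-adjusted pairwise
contrasts for the 3-level CO2 factor.

Denominator degrees of freedom for mixed-model F tests use the containment
convention (between-subject terms: n_groups − rank of the between design;
within-subject terms: n_obs − n_groups − rank of the within design); the
convention is recorded in every result.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class InferenceResult:
    """Tidy term-level results plus whatever a downstream contrast needs."""

    table: pd.DataFrame  # term, estimate, se, stat, df_num, df_den, p
    method: str
    notes: list[str] = field(default_factory=list)
    # contrast support (populated by the factorial models)
    level_means: Optional[pd.Series] = None
    level_cov: Optional[pd.DataFrame] = None
    df_den: Optional[float] = None

    def term(self, name: str) -> pd.Series:
        rows = self.table[self.table["term"] == name]
        if rows.empty:
            raise KeyError(f"no term {name!r} in result ({self.method})")
        return rows.iloc[0]


def preference_deviation_test(
    preferences: Sequence[float],
    shoal_ids: Sequence[str],
) -> InferenceResult:
    """Test whether shoal preference deviates from the 0.5 null.

    The response is the signed deviation (familiar share of shoaling time
    minus 0.5) and the model is an intercept-only LMM with a random shoal
    intercept.  For the balanced design used here the F test of the
    intercept with containment df equals the one-sample t-test on shoal
    means, which is exact under the random-intercept model; that statistic
    is reported with df (1, n_shoals − 1).  With one fish per shoal
    everywhere the grouping is singular and the test falls back to a
    one-sample t-test over fish (logged).
    """
    df = pd.DataFrame(
        {"dev": np.asarray(preferences, float) - 0.5, "shoal": list(shoal_ids)}
    ).dropna()
    if df.empty:
        raise ValueError("no informed trials to test")
    counts = df.groupby("shoal").size()
    if (counts == 1).all():
        log.info("singular grouping (1 fish/shoal); one-sample t-test fallback")
        t_stat, p = stats.ttest_1samp(df["dev"], 0.0)
        n = len(df)
        est, se = df["dev"].mean(), df["dev"].std(ddof=1) / np.sqrt(n)
        method = "one-sample t (singular shoal grouping)"
        df_den = n - 1
    else:
        shoal_means = df.groupby("shoal")["dev"].mean()
        n = len(shoal_means)
        if n < 2:
            raise ValueError("need >= 2 shoals per treatment")
        est = float(shoal_means.mean())
        se = float(shoal_means.std(ddof=1) / np.sqrt(n))
        if se == 0.0:
            t_stat = 0.0 if est == 0.0 else np.inf
            p = 1.0 if est == 0.0 else 0.0
        else:
            t_stat = est / se
            p = 2.0 * stats.t.sf(abs(t_stat), n - 1)
        method = "random-intercept LMM, containment F on shoal means"
        df_den = n - 1
    table = pd.DataFrame(
        [
            {
                "term": "deviation_from_0.5",
                "estimate": est,
                "se": se,
                "stat": float(t_stat) ** 2,
                "df_num": 1,
                "df_den": df_den,
                "p": float(p),
            }
        ]
    )
    return InferenceResult(table=table, method=method)


def preference_tests_by_treatment(results_df: pd.DataFrame) -> dict[int, InferenceResult]:
    """One deviation-from-0.5 test per CO2 treatment.

    ``results_df`` needs columns preference, shoal_id, co2_uatm (informed
    trials only).
    """
    out = {}
    for co2, sub in results_df.groupby("co2_uatm"):
        out[int(co2)] = preference_deviation_test(
            sub["preference"].to_numpy(), sub["shoal_id"].tolist()
        )
    return out


def initial_choice_test(choices_df: pd.DataFrame) -> InferenceResult:
    """Clustered binomial model of initial shoal choice.

    ``choices_df`` needs columns chose_familiar (0/1), co2_uatm, shoal_id
    (one informed trial per row).  Fit is a binomial GEE with exchangeable
    within-shoal correlation — the marginal analog of a binomial mixed model
    — and the CO2 effect is a 2-df Wald χ².  Under complete separation (a
    treatment with all-identical outcomes) the model is refit on
    Haldane–Anscombe-corrected cell counts (0.5 pseudo-observations per
    cell), a standard penalized fallback, with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = choices_df.copy()
    df["co2_uatm"] = df["co2_uatm"].astype(int)
    notes: list[str] = []

    cell = df.groupby("co2_uatm")["chose_familiar"].agg(["sum", "count"])
    separated = ((cell["sum"] == 0) | (cell["sum"] == cell["count"])).any()
    method = "binomial GEE (exchangeable, shoal clusters)"
    if separated:
        warnings.warn(
            "complete separation in initial-choice outcomes; refitting with "
            "Haldane–Anscombe cell correction",
            stacklevel=2,
        )
        notes.append("separation: Haldane–Anscombe 0.5 pseudo-counts added")
        method += " + Haldane–Anscombe correction"
        pseudo = []
        for co2 in cell.index:
            for y in (0.0, 1.0):
                pseudo.append(
                    {"chose_familiar": y, "co2_uatm": co2,
                     "shoal_id": f"pseudo_{co2}_{int(y)}", "weight": 0.5}
                )
        df["weight"] = 1.0
        df = pd.concat([df, pd.DataFrame(pseudo)], ignore_index=True)
    else:
        df["weight"] = 1.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.gee(
            "chose_familiar ~ C(co2_uatm)",
            groups="shoal_id",
            data=df,
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
            weights=df["weight"],
        )
        res = model.fit()

    names = list(res.params.index)
    co2_cols = [i for i, nm in enumerate(names) if "co2_uatm" in nm]
    rows = []
    # model-based covariance under the exchangeable working correlation:
    # with ~9 clusters per treatment the sandwich estimator is unstable
    # (and exactly singular on fully balanced fixtures)
    vcov = np.asarray(res.cov_naive)
    params = res.params.to_numpy()
    if co2_cols:
        beta = params[co2_cols]
        vmat = vcov[np.ix_(co2_cols, co2_cols)]
        chi2 = float(beta @ np.linalg.solve(vmat, beta))
        df_num = len(co2_cols)
        p = float(stats.chi2.sf(chi2, df_num))
        rows.append(
            {"term": "co2_treatment", "estimate": np.nan, "se": np.nan,
             "stat": chi2, "df_num": df_num, "df_den": np.nan, "p": p}
        )
    for i, nm in enumerate(names):
        se = float(np.sqrt(max(vcov[i, i], 0.0)))
        z2 = float((params[i] / se) ** 2) if se > 0 else np.nan
        rows.append(
            {"term": nm, "estimate": float(params[i]), "se": se,
             "stat": z2, "df_num": 1, "df_den": np.nan,
             "p": float(stats.chi2.sf(z2, 1)) if np.isfinite(z2) else np.nan}
        )
    return InferenceResult(table=pd.DataFrame(rows), method=method, notes=notes)


def _containment_df(
    data: pd.DataFrame, groups: str, design_cols: pd.DataFrame
) -> dict[str, float]:
    """Containment denominator df: between terms get n_groups − rank(between
    design); within terms get n_obs − n_groups − rank(within design)."""
    g = data[groups]
    n_obs, n_groups = len(data), g.nunique()
    within_cols = [
        c for c in design_cols.columns
        if (design_cols.groupby(g.values)[c].nunique() > 1).any()
    ]
    between_cols = [c for c in design_cols.columns if c not in within_cols]
    rank_b = np.linalg.matrix_rank(design_cols[between_cols].to_numpy()) if between_cols else 0
    rank_w = np.linalg.matrix_rank(design_cols[within_cols].to_numpy()) if within_cols else 0
    return {
        "between": max(n_groups - rank_b, 1),
        "within": max(n_obs - n_groups - rank_w, 1),
        "within_cols": within_cols,
    }


def metabolic_mixed_model(
    summaries: pd.DataFrame,
    endpoint: str,
    include_interaction: bool = True,
) -> InferenceResult:
    """Gaussian mixed model for a within-fish metabolic endpoint.

    ``summaries`` needs one row per fish × testing treatment with columns
    fish_id, co2_uatm, testing, mass_g and the endpoint.  Model: endpoint ~
    CO2 treatment × testing treatment + mass, random intercept per fish
    (REML).  Whole-animal values; marginal F tests per term with containment
    df.  Fish missing either testing treatment are dropped (logged).
    """
    import statsmodels.formula.api as smf

    df = summaries.dropna(subset=[endpoint]).copy()
    paired = df.groupby("fish_id")["testing"].nunique()
    unpaired = paired[paired < 2].index.tolist()
    if unpaired:
        log.info("dropping unpaired fish: %s", unpaired)
        df = df[~df["fish_id"].isin(unpaired)]
    if df.empty:
        raise ValueError("no paired fish remain")
    df["co2_uatm"] = df["co2_uatm"].astype(int)

    rhs = "C(co2_uatm) * C(testing)" if include_interaction else (
        "C(co2_uatm) + C(testing)"
    )
    formula = f"{endpoint} ~ {rhs} + mass_g"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=df, groups=df["fish_id"])
        res = model.fit(reml=True)

    design_info = model.data.design_info
    exog = pd.DataFrame(model.exog, columns=design_info.column_names)
    dfs = _containment_df(df.reset_index(drop=True), "fish_id", exog)

    params = res.fe_params
    cov = res.cov_params().loc[params.index, params.index]
    rows = []
    term_labels = {
        "C(co2_uatm)": "co2_treatment",
        "C(testing)": "testing_treatment",
        "C(co2_uatm):C(testing)": "co2_x_testing",
        "mass_g": "mass",
    }
    for raw_term, label in term_labels.items():
        if raw_term not in design_info.term_name_slices:
            continue
        sl = design_info.term_name_slices[raw_term]
        idx = list(range(*sl.indices(len(params))))
        cols = [design_info.column_names[i] for i in idx]
        is_within = any(c in dfs["within_cols"] for c in cols)
        df_den = dfs["within" if is_within else "between"]
        beta = params[cols].to_numpy()
        vmat = cov.loc[cols, cols].to_numpy()
        try:
            chi2 = float(beta @ np.linalg.solve(vmat, beta))
        except np.linalg.LinAlgError:
            chi2 = float("nan")
        f_stat = chi2 / len(cols)
        p = float(stats.f.sf(f_stat, len(cols), df_den))
        rows.append(
            {"term": label,
             "estimate": float(beta[0]) if len(cols) == 1 else np.nan,
             "se": float(np.sqrt(vmat[0, 0])) if len(cols) == 1 else np.nan,
             "stat": f_stat, "df_num": len(cols), "df_den": df_den, "p": p}
        )

    # estimated marginal means of the CO2 levels (mass at its mean, averaged
    # over testing) for Tukey contrasts
    levels = sorted(df["co2_uatm"].unique())
    lmat = []
    from patsy import build_design_matrices

    for co2 in levels:
        grid = pd.DataFrame(
            {"co2_uatm": [co2, co2], "testing": ["alone", "group"],
             "mass_g": [df["mass_g"].mean()] * 2}
        )
        (dm,) = build_design_matrices([design_info], grid)
        lmat.append(np.asarray(dm).mean(axis=0))
    lmat = np.vstack(lmat)
    means = pd.Series(lmat @ params.to_numpy(), index=levels)
    mcov = pd.DataFrame(
        lmat @ cov.to_numpy() @ lmat.T, index=levels, columns=levels
    )

    result = InferenceResult(
        table=pd.DataFrame(rows),
        method="Gaussian LMM (REML), random fish intercept, containment df",
        notes=[f"unpaired fish dropped: {unpaired}"] if unpaired else [],
        level_means=means,
        level_cov=mcov,
        df_den=dfs["between"],
    )
    return result


def fixed_effect_model(summaries: pd.DataFrame, endpoint: str) -> InferenceResult:
    """Gaussian fixed-effects model (GLM) for a once-per-fish endpoint
    (MMR or aerobic scope): endpoint ~ CO2 treatment + mass."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = summaries.dropna(subset=[endpoint]).copy()
    df = df.drop_duplicates(subset="fish_id")
    df["co2_uatm"] = df["co2_uatm"].astype(int)
    if df[endpoint].nunique() == 1:
        table = pd.DataFrame(
            [{"term": "co2_treatment", "estimate": np.nan, "se": np.nan,
              "stat": 0.0, "df_num": 2, "df_den": np.nan, "p": 1.0}]
        )
        return InferenceResult(
            table=table, method="OLS (degenerate: zero-variance endpoint)",
            notes=["endpoint has zero variance; degenerate fit"],
        )
    res = smf.ols(f"{endpoint} ~ C(co2_uatm) + mass_g", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = anova_lm(res, typ=2)
    df_den = float(res.df_resid)
    rows = []
    for raw, label in (("C(co2_uatm)", "co2_treatment"), ("mass_g", "mass")):
        rows.append(
            {"term": label, "estimate": np.nan, "se": np.nan,
             "stat": float(aov.loc[raw, "F"]),
             "df_num": float(aov.loc[raw, "df"]), "df_den": df_den,
             "p": float(aov.loc[raw, "PR(>F)"])}
        )
    rows.append(
        {"term": "mass_slope", "estimate": float(res.params["mass_g"]),
         "se": float(res.bse["mass_g"]),
         "stat": float(res.tvalues["mass_g"] ** 2),
         "df_num": 1, "df_den": df_den,
         "p": float(res.pvalues["mass_g"])}
    )

    levels = sorted(df["co2_uatm"].unique())
    from patsy import build_design_matrices

    design_info = res.model.data.design_info
    lmat = []
    for co2 in levels:
        grid = pd.DataFrame({"co2_uatm": [co2], "mass_g": [df["mass_g"].mean()]})
        (dm,) = build_design_matrices([design_info], grid)
        lmat.append(np.asarray(dm)[0])
    lmat = np.vstack(lmat)
    means = pd.Series(lmat @ res.params.to_numpy(), index=levels)
    mcov = pd.DataFrame(
        lmat @ res.cov_params().to_numpy() @ lmat.T, index=levels, columns=levels
    )
    return InferenceResult(
        table=pd.DataFrame(rows),
        method="Gaussian GLM (OLS), CO2 + mass",
        level_means=means,
        level_cov=mcov,
        df_den=df_den,
    )


def tukey_contrasts(model: InferenceResult) -> pd.DataFrame:
    """All pairwise contrasts of the 3-level CO2 factor with Tukey
    (studentized-range) family-wise adjustment.

    Requires a fitted factorial result carrying level means and their
    covariance.  Adjusted p ≥ raw p for every contrast.
    """
    if model.level_means is None or model.level_cov is None:
        raise ValueError("model result carries no level means for contrasts")
    levels = list(model.level_means.index)
    if len(levels) < 3:
        raise ValueError(f"need a 3-level factor, got levels {levels}")
    k = len(levels)
    df_den = model.df_den if model.df_den is not None else np.inf
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = float(model.level_means[a] - model.level_means[b])
            var = float(
                model.level_cov.loc[a, a]
                + model.level_cov.loc[b, b]
                - 2.0 * model.level_cov.loc[a, b]
            )
            se = float(np.sqrt(max(var, 0.0)))
            if se == 0.0:
                t_stat, p_raw, p_adj = 0.0, 1.0, 1.0
            else:
                t_stat = diff / se
                p_raw = 2.0 * stats.t.sf(abs(t_stat), df_den)
                p_adj = float(
                    stats.studentized_range.sf(abs(t_stat) * np.sqrt(2.0), k, df_den)
                )
            rows.append(
                {"contrast": f"{a} - {b}", "estimate": diff, "se": se,
                 "stat": t_stat, "df_den": df_den,
                 "p": p_raw, "adj_p": float(min(max(p_adj, p_raw), 1.0))}
            )
    return pd.DataFrame(rows)
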