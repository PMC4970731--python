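"""Cohort-level inference.

Trial-level two-level random-intercept mixed models (child as the random
unit), child-level general linear models for proportion-type outcomes,
age-trend curve estimation, stepwise entry of clinical factors, and small
association helpers (Spearman rho, R-squared change).  Pairwise group
contrasts are Bonferroni-adjusted within a family of the three group
pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

N_PAIRWISE = 3  # contrasts per outcome family (three groups)


class AnalysisError(ValueError):
    """Configuration or data problem that prevents an analysis."""


def bonferroni(p: float, m: int = N_PAIRWISE) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    return min(1.0, m * p)


@dataclass
class EffectsTable:
    """F-type tests per model term plus pairwise group contrasts."""

    terms: pd.DataFrame  # term, F, df_num, df_den, p, eta_sq
    contrasts: pd.DataFrame | None = None  # family, contrast, estimate, se, p, p_adj
    fallback: bool = False  # True when a singular mixed fit fell back to child means
    notes: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        row = self.terms[self.terms["term"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


def _term_tests_mixed(res, trial_df: pd.DataFrame, group_col: str) -> pd.DataFrame:
    """Wald F-tests per fixed-effect term of a fitted MixedLM.

    Denominator df uses a containment-style approximation:
    n_obs - n_children - rank(fixed design) + 1 for within-child terms.
    """
    exog_names = list(res.model.exog_names)
    k_all = len(np.asarray(res.params))  # fixed effects + variance components
    n_obs = res.model.exog.shape[0]
    n_child = trial_df[res.model.groups].nunique() if isinstance(res.model.groups, str) \
        else len(np.unique(res.model.groups))
    k = len(exog_names)
    rows = []
    terms = _design_terms(exog_names)
    for term, cols in terms.items():
        if term == "Intercept":
            continue
        L = np.zeros((len(cols), k_all))
        for i, c in enumerate(cols):
            L[i, c] = 1.0
        wt = res.wald_test(L, use_f=False, scalar=True)
        f = float(np.squeeze(wt.statistic)) / len(cols)  # chi2/q ~ F under H0
        df_num = len(cols)
        between = group_col in term and ":" not in term
        df_den = (n_child - _n_group_params(terms, group_col) - 1) if between \
            else (n_obs - n_child - k + 1)
        df_den = max(df_den, 2)
        p = float(stats.f.sf(f, df_num, df_den))
        rows.append({"term": term, "F": f, "df_num": df_num, "df_den": df_den,
                     "p": p, "eta_sq": np.nan})
    return pd.DataFrame(rows)


def _n_group_params(terms: dict, group_col: str) -> int:
    return sum(len(c) for t, c in terms.items() if group_col in t and ":" not in t)


def _design_terms(exog_names: list[str]) -> dict[str, list[int]]:
    """Group design columns by their model term name."""
    terms: dict[str, list[int]] = {}
    for i, name in enumerate(exog_names):
        if name == "Intercept":
            terms.setdefault("Intercept", []).append(i)
            continue
        parts = name.split(":")
        base = ":".join(p.split("[")[0] for p in parts)
        terms.setdefault(base, []).append(i)
    return terms


def _pairwise_group_contrasts(res, df: pd.DataFrame, outcome: str,
                              by_type: bool) -> pd.DataFrame:
    """Bonferroni-adjusted group differences, within saccade type if present."""
    from patsy import build_design_matrices
    design_info = res.model.data.design_info
    groups = sorted(df["group"].unique())
    stypes = sorted(df["saccade_type"].unique()) if by_type else [None]
    cov = np.asarray(res.cov_params())[:len(res.fe_params), :len(res.fe_params)] \
        if hasattr(res, "fe_params") else np.asarray(res.cov_params())
    beta = np.asarray(res.fe_params if hasattr(res, "fe_params") else res.params)

    rows = []
    for st in stypes:
        for g1, g2 in itertools.combinations(groups, 2):
            cells = pd.DataFrame({"group": [g1, g2]})
            if st is not None:
                cells["saccade_type"] = st
            (X,) = build_design_matrices([design_info], cells)
            L = np.asarray(X)[0] - np.asarray(X)[1]
            est = float(L @ beta)
            se = float(np.sqrt(L @ cov @ L))
            z = est / se if se > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append({"family": st or "overall", "contrast": f"{g1}-{g2}",
                         "estimate": est, "se": se, "p": p,
                         "p_adj": bonferroni(p) if np.isfinite(z) else np.nan})
    return pd.DataFrame(rows)


def mixed_model(trial_df: pd.DataFrame, outcome: str) -> EffectsTable:
    """Two-level random-intercept model on trial-level data.

    Fixed effects: saccade type, group, and their interaction (terms with
    a single observed level are dropped); random intercept per child;
    REML estimation.  A singular or non-converging fit falls back to an
    OLS on child-type means with ``fallback=True``.

    Parameters
    ----------
    trial_df : DataFrame
        Columns ``child_id``, ``group``, ``saccade_type`` and the outcome.
    outcome : str
        One of the trial-level measures (e.g. ``recip_srt``).
    """
    df = trial_df.dropna(subset=[outcome]).copy()
    if df.empty or df[outcome].nunique() <= 1:
        raise AnalysisError(f"outcome {outcome!r} is constant or empty")
    per_group = df.groupby("group")["child_id"].nunique()
    if (per_group < 2).any():
        raise AnalysisError("need >= 2 children per group")

    rhs = []
    if df["saccade_type"].nunique() > 1:
        rhs.append("C(saccade_type)")
    if df["group"].nunique() > 1:
        rhs.append("C(group)")
    if len(rhs) == 2:
        rhs.append("C(saccade_type):C(group)")
    formula = f"{outcome} ~ " + " + ".join(rhs) if rhs else f"{outcome} ~ 1"

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["child_id"])
            res = model.fit(reml=True)
        if not res.converged or not np.isfinite(res.bse_fe).all():
            raise np.linalg.LinAlgError("mixed fit did not converge")
        terms = _term_tests_mixed(res, df, "C(group)")
        contrasts = _pairwise_group_contrasts(
            res, df, outcome, by_type=df["saccade_type"].nunique() > 1)
        return EffectsTable(terms=terms, contrasts=contrasts)
    except (np.linalg.LinAlgError, ValueError) as exc:
        means = (df.groupby(["child_id", "group", "saccade_type"], observed=True)
                 [outcome].mean().reset_index())
        et = proportion_glm(means.rename(columns={outcome: "value"}), "value",
                            predictors=_fallback_predictors(means))
        et.fallback = True
        et.notes.append(f"mixed model fell back to child means: {exc}")
        return et


def _fallback_predictors(means: pd.DataFrame) -> list[str]:
    preds = []
    if means["group"].nunique() > 1:
        preds.append("group")
    if means["saccade_type"].nunique() > 1:
        preds.append("saccade_type")
    return preds or ["group"]


def proportion_glm(child_df: pd.DataFrame, outcome: str,
                   predictors: list[str] = ("group",)) -> EffectsTable:
    """Child-level general linear model for proportion-type outcomes.

    Proportions are analysed untransformed.  Categorical predictors get
    type-II F tests; ``eta_sq`` is the term SS over total SS and
    ``partial_eta_sq`` term SS over (term SS + residual SS).  Pairwise
    Bonferroni group contrasts are attached when ``group`` is a
    predictor.

    Raises
    ------
    AnalysisError
        All-missing outcome, too few children, or a constant predictor
        column (named in the message).
    """
    predictors = list(predictors)
    df = child_df.dropna(subset=[outcome] + predictors).copy()
    if df.empty:
        raise AnalysisError(f"outcome {outcome!r} has no non-missing rows")
    for p in predictors:
        if df[p].nunique() <= 1:
            raise AnalysisError(f"predictor column {p!r} is constant (rank deficient)")
    if "group" in predictors:
        sizes = df.groupby("group")[outcome].count()
        if (sizes < 3).any():
            raise AnalysisError("need outcome for >= 3 children per group")

    def _wrap(p):
        return f"C({p})" if df[p].dtype == object or df[p].dtype.name == "category" else p

    formula = f"{outcome} ~ " + " + ".join(_wrap(p) for p in predictors)
    res = smf.ols(formula, df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        an = anova_lm(res, typ=2)
    ss_res = float(an.loc["Residual", "sum_sq"])
    ss_tot = float(an["sum_sq"].sum())
    rows = []
    for name, row in an.iterrows():
        if name == "Residual":
            continue
        ss = float(row["sum_sq"])
        rows.append({"term": name, "F": float(row["F"]),
                     "df_num": int(row["df"]),
                     "df_den": int(an.loc["Residual", "df"]),
                     "p": float(row["PR(>F)"]),
                     "eta_sq": ss / ss_tot,
                     "partial_eta_sq": ss / (ss + ss_res)})
    terms = pd.DataFrame(rows)

    contrasts = None
    if "group" in predictors:
        rows = []
        groups = sorted(df["group"].unique())
        for g1, g2 in itertools.combinations(groups, 2):
            name = f"C(group)[T.{g1}]" if g1 != groups[0] else None
            b1 = res.params.get(f"C(group)[T.{g1}]", 0.0)
            b2 = res.params.get(f"C(group)[T.{g2}]", 0.0)
            L = pd.Series(0.0, index=res.params.index)
            if f"C(group)[T.{g1}]" in L.index:
                L[f"C(group)[T.{g1}]"] = 1.0
            if f"C(group)[T.{g2}]" in L.index:
                L[f"C(group)[T.{g2}]"] = -1.0
            tt = res.t_test(L.values)
            p = float(np.squeeze(tt.pvalue))
            rows.append({"family": outcome, "contrast": f"{g1}-{g2}",
                         "estimate": float(b1 - b2), "se": float(np.squeeze(tt.sd)),
                         "p": p, "p_adj": bonferroni(p)})
        contrasts = pd.DataFrame(rows)
    return EffectsTable(terms=terms, contrasts=contrasts)


PATIENT_ONLY = ("onset", "duration", "last_seizure")


def age_and_epilepsy_models(cohort: pd.DataFrame, outcome: str,
                            predictors: list[str], form: str = "linear",
                            stepwise: bool = False,
                            covariates: list[str] = ()) -> EffectsTable:
    """Curve estimation for age trends and (stepwise) clinical predictors.

    ``form="quadratic"`` adds a squared term for the first predictor and
    reports the fitted parabola's vertex (``vertex`` column on that
    term's row).  ``stepwise=True`` performs forward entry among
    ``predictors`` by largest F improvement at alpha-to-enter 0.05, on
    top of the covariates.

    Raises
    ------
    AnalysisError
        When a patient-only predictor (onset/duration/last_seizure) is
        requested on a table containing non-patient rows.
    """
    predictors = list(predictors)
    covariates = list(covariates)
    if form not in ("linear", "quadratic"):
        raise AnalysisError(f"unknown form {form!r}")
    uses_patient = [p for p in predictors + covariates if p in PATIENT_ONLY]
    if uses_patient and (cohort["group"] == "HC").any():
        raise AnalysisError(
            f"patient-only predictors {uses_patient} requested on a table with controls")

    need = [outcome] + predictors + [c for c in covariates if c != "group"]
    df = cohort.dropna(subset=[c for c in need if c in cohort.columns]).copy()
    if len(df) < len(predictors) + len(covariates) + 3:
        raise AnalysisError("too few complete rows")

    def _wrap(c):
        return f"C({c})" if df[c].dtype == object else c

    base_terms = [_wrap(c) for c in covariates]

    if stepwise:
        return _forward_stepwise(df, outcome, predictors, base_terms)

    main = predictors[0]
    rhs = base_terms + [main]
    if form == "quadratic":
        rhs.append(f"I({main} ** 2)")
    res = smf.ols(f"{outcome} ~ " + " + ".join(rhs), df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        an = anova_lm(res, typ=2)
    ss_res = float(an.loc["Residual", "sum_sq"])
    rows = []
    for name, row in an.iterrows():
        if name == "Residual":
            continue
        ss = float(row["sum_sq"])
        rows.append({"term": name, "F": float(row["F"]), "df_num": int(row["df"]),
                     "df_den": int(an.loc["Residual", "df"]),
                     "p": float(row["PR(>F)"]), "eta_sq": ss / float(an["sum_sq"].sum()),
                     "partial_eta_sq": ss / (ss + ss_res)})
    terms = pd.DataFrame(rows)
    notes = []
    if form == "quadratic":
        b1 = res.params.get(main, np.nan)
        b2 = res.params.get(f"I({main} ** 2)", np.nan)
        vertex = -b1 / (2.0 * b2) if b2 != 0 else np.nan
        terms["vertex"] = np.nan
        terms.loc[terms["term"] == f"I({main} ** 2)", "vertex"] = vertex
        notes.append(f"quadratic vertex at {main} = {vertex:.3f}")
    et = EffectsTable(terms=terms, notes=notes)
    et.coefs = res.params  # raw coefficients for sign checks
    return et


def _forward_stepwise(df, outcome, candidates, base_terms,
                      alpha_enter: float = 0.05) -> EffectsTable:
    selected: list[str] = []
    base_rhs = base_terms or ["1"]
    rows = []
    while True:
        best = None
        cur = smf.ols(f"{outcome} ~ " + " + ".join(base_rhs + selected), df).fit()
        for cand in candidates:
            if cand in selected:
                continue
            res = smf.ols(f"{outcome} ~ " + " + ".join(base_rhs + selected + [cand]),
                          df).fit()
            df_den = int(res.df_resid)
            f = ((cur.ssr - res.ssr) / 1.0) / (res.ssr / df_den)
            p = float(stats.f.sf(f, 1, df_den))
            if p < alpha_enter and (best is None or f > best[1]):
                best = (cand, f, p, df_den, res)
        if best is None:
            break
        cand, f, p, df_den, res = best
        selected.append(cand)
        rows.append({"term": cand, "F": f, "df_num": 1, "df_den": df_den, "p": p,
                     "eta_sq": np.nan, "coef": float(res.params[cand])})
    terms = pd.DataFrame(rows, columns=["term", "F", "df_num", "df_den", "p",
                                        "eta_sq", "coef"])
    return EffectsTable(terms=terms,
                        notes=[f"stepwise retained: {selected or 'none'}"])


def assoc_stats(x, y, method: str = "spearman", base=None):
    """Bivariate association statistics.

    ``spearman`` returns ``(rho, p)`` with average-rank tie handling.
    ``ols_r2_change`` returns ``(r2_change, p)``: the increase in
    R-squared when ``x`` is added to an OLS of ``y`` on ``base`` (an
    (n, k) array; None for an intercept-only base), with the partial-F
    p-value of the added term.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if base is not None:
        base = np.atleast_2d(np.asarray(base, dtype=float))
        if base.shape[0] != x.size:
            base = base.T
        ok &= np.isfinite(base).all(axis=1)
        base = base[ok]
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise AnalysisError("need at least 4 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("constant input: correlation undefined")

    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    if method == "ols_r2_change":
        X0 = sm.add_constant(base if base is not None else np.empty((x.size, 0)))
        X1 = np.column_stack([X0, x])
        f0 = sm.OLS(y, X0).fit()
        f1 = sm.OLS(y, X1).fit()
        r2_change = float(f1.rsquared - f0.rsquared)
        df_den = int(f1.df_resid)
        f = ((f0.ssr - f1.ssr) / 1.0) / (f1.ssr / df_den) if f1.ssr > 0 else np.inf
        p = float(stats.f.sf(f, 1, df_den))
        return r2_change, p
    raise AnalysisError(f"unknown method {method!r}")
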