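"""Group-contrast and stage-association statistics with FDR control.

Longitudinal contrasts use linear mixed-effects models
``feature ~ 1 + Dx + dt + Dx:dt (+ Age_bl + Sex) + (1 | subject)`` —
the Dx:dt interaction carries the group difference in rate of change;
imaging (w-score) responses omit Age_bl/Sex because w-scoring already
adjusted for them.  Baseline variables dispatch on type: OLS for
continuous, logistic for binary, proportional-odds ordinal logistic for
ordered categories.  Stage associations model
``feature ~ stage + dt (+ covariates) + (1 | subject)``.  Benjamini-
Hochberg FDR is applied within declared families: two families (clinical,
imaging) for group comparisons and one global family for stage
associations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "StatModelSpec",
    "benjamini_hochberg",
    "fdr_correct",
    "fit_group_lme",
    "fit_baseline_model",
    "fit_stage_association",
]


@dataclass
class StatModelSpec:
    """Declarative model description for a group contrast."""

    response: str
    predictor: str = "Dx"                      # grouping / stage column
    covariates: tuple[str, ...] = ()           # extra fixed effects
    family: str = "lme"                        # lme | ols | logistic | ordinal
    group_var: str | None = "subject_id"       # random-intercept grouping
    family_label: str = "clinical"             # FDR family

    def __post_init__(self) -> None:
        if self.family == "lme" and not self.group_var:
            raise ValueError("linear mixed model requires a grouping variable")


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted q-values (monotone, q >= p, q <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def fdr_correct(results: pd.DataFrame, family_col: str = "family",
                p_col: str = "p") -> pd.DataFrame:
    """Add a BH ``q`` column, correcting independently within each family.

    Rows flagged non-converged (``converged == False``) are excluded from
    the correction (their q is NaN) with a warning.  An empty family is a
    no-op."""
    out = results.copy()
    out["q"] = np.nan
    if not len(out):
        return out
    ok = out["converged"] if "converged" in out.columns else pd.Series(True, index=out.index)
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} non-converged fits excluded from FDR",
                      stacklevel=2)
    for _, idx in out[ok].groupby(family_col).groups.items():
        out.loc[idx, "q"] = benjamini_hochberg(out.loc[idx, p_col].to_numpy())
    return out


def _fit_mixedlm(formula: str, data: pd.DataFrame, groups):
    """MixedLM fit with optimizer fallback (lbfgs can hit singular steps)."""
    last_exc = None
    for method in ("lbfgs", "bfgs", "cg", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm(formula, data, groups=groups)
                res = md.fit(reml=True, method=method, maxiter=200)
            if np.all(np.isfinite(res.params)) and np.all(np.isfinite(res.bse)):
                return res
        except Exception as exc:  # singular V, non-finite steps, ...
            last_exc = exc
    raise RuntimeError(f"mixed model failed for {formula!r}") from last_exc


def _result_rows(params, bse, tvalues, pvalues, terms, *, family_label, model,
                 n_obs, n_subjects, converged=True) -> list[dict]:
    rows = []
    for term in terms:
        rows.append({
            "term": term,
            "estimate": float(params[term]),
            "se": float(bse[term]),
            "stat": float(tvalues[term]),
            "p": float(pvalues[term]),
            "family": family_label,
            "model": model,
            "n_obs": int(n_obs),
            "n_subjects": int(n_subjects),
            "converged": bool(converged),
        })
    return rows


def _flag_failure(response: str, terms, family_label, model, n_obs, n_subjects):
    return [{"term": t, "estimate": np.nan, "se": np.nan, "stat": np.nan,
             "p": np.nan, "family": family_label, "model": model,
             "n_obs": int(n_obs), "n_subjects": int(n_subjects),
             "converged": False} for t in terms]


def fit_group_lme(spec: StatModelSpec, data: pd.DataFrame,
                  dx_col: str = "Dx", time_col: str = "delta_months") -> pd.DataFrame:
    """Mixed-effects group contrast; returns Dx and Dx:time term rows.

    When every subject contributes a single observation the random
    intercept is degenerate and the fit falls back to OLS (flagged in the
    ``model`` column)."""
    cols = [spec.response, dx_col, time_col, spec.group_var, *spec.covariates]
    d = data[cols].dropna().copy()
    n_subj = d[spec.group_var].nunique()
    cov = "".join(f" + {c}" for c in spec.covariates)
    formula = f"{spec.response} ~ C({dx_col}) * {time_col}{cov}"
    single_visit = (d.groupby(spec.group_var).size() <= 1).all()
    try:
        if single_visit:
            res = smf.ols(formula, d).fit()
            model_name = "ols_single_visit"
            converged = True
        else:
            res = _fit_mixedlm(formula, d, d[spec.group_var])
            model_name = "lme"
            converged = bool(res.converged)
        terms = [t for t in res.params.index
                 if t.startswith(f"C({dx_col})") or (f"C({dx_col})" in t and time_col in t)]
        return pd.DataFrame(_result_rows(
            res.params, res.bse, res.tvalues, res.pvalues, terms,
            family_label=spec.family_label, model=model_name,
            n_obs=len(d), n_subjects=n_subj, converged=converged))
    except Exception:
        return pd.DataFrame(_flag_failure(
            spec.response, [f"C({dx_col})", f"C({dx_col}):{time_col}"],
            spec.family_label, "lme", len(d), n_subj))


def fit_baseline_model(data: pd.DataFrame, response: str, var_type: str,
                       group_col: str = "Dx", covariates: tuple[str, ...] = (),
                       family_label: str = "clinical") -> pd.DataFrame:
    """Baseline (one row per subject) group regression dispatched on type.

    continuous -> OLS; binary -> logistic; ordinal -> proportional-odds
    logistic.  Returns group-term statistics; quasi-separated logistic
    fits are flagged non-converged."""
    if var_type not in ("continuous", "binary", "ordinal"):
        raise ValueError(f"unknown variable type {var_type!r}")
    cols = [response, group_col, *covariates]
    d = data[cols].dropna().copy()
    n = len(d)
    cov = "".join(f" + {c}" for c in covariates)
    try:
        if var_type == "continuous":
            res = smf.ols(f"{response} ~ C({group_col}){cov}", d).fit()
            model_name = "ols"
        elif var_type == "binary":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.logit(f"{response} ~ C({group_col}){cov}", d).fit(disp=0)
            model_name = "logistic"
            if not res.mle_retvals.get("converged", True) or np.any(res.bse > 1e3):
                raise RuntimeError("separation or non-convergence in logistic fit")
        elif var_type == "ordinal":
            exog = pd.get_dummies(d[group_col], prefix=f"C({group_col})",
                                  drop_first=True, dtype=float)
            for c in covariates:
                exog[c] = d[c].to_numpy(dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = OrderedModel(d[response].astype(float), exog,
                                   distr="logit").fit(method="bfgs", disp=0)
            model_name = "ordinal_logit"
        terms = [t for t in res.params.index if f"C({group_col})" in t]
        return pd.DataFrame(_result_rows(
            res.params, res.bse, res.tvalues, res.pvalues, terms,
            family_label=family_label, model=model_name,
            n_obs=n, n_subjects=n))
    except Exception:  # separation, singular Hessian, non-convergence
        return pd.DataFrame(_flag_failure(
            response, [f"C({group_col})"], family_label, var_type, n, n))


def fit_stage_association(data: pd.DataFrame, feature: str, longitudinal: bool = True,
                          stage_col: str = "stage", time_col: str = "delta_months",
                          covariates: tuple[str, ...] = (),
                          group_var: str = "subject_id",
                          family_label: str = "clinical") -> pd.DataFrame:
    """Association of a feature with inferred stage, adjusting elapsed time.

    Longitudinal features use a mixed model ``feature ~ stage + dt
    (+ covariates) + (1 | subject)``; baseline features use OLS on stage.
    Subgroups where stage takes a single value are flagged not evaluable."""
    cols = [feature, stage_col, group_var, *covariates] + ([time_col] if longitudinal else [])
    d = data[cols].dropna().copy()
    n_subj = d[group_var].nunique()
    if d[stage_col].nunique() < 2:
        return pd.DataFrame([{"term": stage_col, "estimate": np.nan, "se": np.nan,
                              "stat": np.nan, "p": np.nan, "family": family_label,
                              "model": "not evaluable", "n_obs": len(d),
                              "n_subjects": n_subj, "converged": False}])
    cov = "".join(f" + {c}" for c in covariates)
    try:
        if longitudinal:
            formula = f"{feature} ~ {stage_col} + {time_col}{cov}"
            if (d.groupby(group_var).size() <= 1).all():
                res = smf.ols(formula, d).fit()
                model_name = "ols_single_visit"
                converged = True
            else:
                res = _fit_mixedlm(formula, d, d[group_var])
                model_name = "lme"
                converged = bool(res.converged)
        else:
            res = smf.ols(f"{feature} ~ {stage_col}{cov}", d).fit()
            model_name = "ols"
            converged = True
        return pd.DataFrame(_result_rows(
            res.params, res.bse, res.tvalues, res.pvalues, [stage_col],
            family_label=family_label, model=model_name,
            n_obs=len(d), n_subjects=n_subj, converged=converged))
    except Exception:
        return pd.DataFrame(_flag_failure(
            feature, [stage_col], family_label, "lme", len(d), n_subj))
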