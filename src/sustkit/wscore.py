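"""Healthy-control reference models and w-score computation.

Per ROI, the reference is a linear mixed-effects model
``value ~ 1 + age + sex`` with random intercepts for imaging site and for
subject (repeated HC visits), fitted to all HC visits.  The w-score of
any observation is ``(observed - predicted) / residual_sd`` where the
prediction uses the fixed effects plus the (BLUP) site offset — zero for
sites unseen at fit time — and the residual SD is the within-subject
residual variance component.  Negative w means more atrophy than the
HC-expected level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = ["ReferenceModel", "fit_reference", "compute_wscores"]

_REQUIRED = ("age", "sex", "site", "subject_id")


@dataclass
class ReferenceModel:
    """Per-ROI reference coefficients.

    ``params[roi]`` holds intercept, age_coef, sex_coef,
    site_offsets (site -> offset), residual_sd, n_obs and the fitting
    method ("mixed" or "fixed" for the fallback)."""

    params: dict = field(default_factory=dict)

    @property
    def rois(self) -> list[str]:
        return list(self.params)

    def predict(self, roi: str, age, sex, site) -> np.ndarray:
        if roi not in self.params:
            raise KeyError(f"ROI {roi!r} not in reference model")
        p = self.params[roi]
        offs = np.array([p["site_offsets"].get(str(s), 0.0) for s in np.asarray(site)])
        return (p["intercept"] + p["age_coef"] * np.asarray(age, dtype=float)
                + p["sex_coef"] * np.asarray(sex, dtype=float) + offs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.params, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ReferenceModel":
        with open(Path(path)) as fh:
            return cls(params=json.load(fh))


def _fit_mixed(data: pd.DataFrame, multi_site: bool):
    """Site + subject random-intercept fit; returns params or raises."""
    vc = {"subject": "0 + C(subject_id)"}
    res = None
    for method in ("lbfgs", "bfgs", "powell"):
        md = smf.mixedlm("value ~ age + sex", data, groups="site",
                         re_formula="1", vc_formula=vc)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = md.fit(reml=True, method=method, maxiter=200)
        except Exception:
            res = None
            continue
        if res.converged and np.isfinite(res.scale) and res.scale > 0:
            break
    if res is None or not res.converged or not np.isfinite(res.scale) or res.scale <= 0:
        raise RuntimeError("mixed fit did not converge")
    fe = res.params
    offsets = {str(g): float(re["site"]) for g, re in res.random_effects.items()}
    return {
        "intercept": float(fe["Intercept"]),
        "age_coef": float(fe["age"]),
        "sex_coef": float(fe["sex"]),
        "site_offsets": offsets if multi_site else {k: 0.0 for k in offsets},
        "residual_sd": float(np.sqrt(res.scale)),
        "site_var": float(res.cov_re.iloc[0, 0]),
        "subject_var": float(res.vcomp[0]) if res.vcomp.size else 0.0,
        "method": "mixed",
    }


def _fit_fixed(data: pd.DataFrame, multi_site: bool):
    """Fallback: fixed sum-coded site effects, OLS, residual SD from MSE."""
    formula = "value ~ age + sex" + (" + C(site, Sum)" if multi_site else "")
    res = smf.ols(formula, data).fit()
    fe = res.params
    offsets = {}
    if multi_site:
        sites = sorted(data["site"].unique(), key=str)
        acc = 0.0
        for s in sites[:-1]:
            key = f"C(site, Sum)[S.{s}]"
            offsets[str(s)] = float(fe[key])
            acc += float(fe[key])
        offsets[str(sites[-1])] = -acc  # sum-to-zero: last level is the negated sum
    else:
        offsets = {str(s): 0.0 for s in data["site"].unique()}
    resid_sd = float(np.sqrt(res.mse_resid))
    if not np.isfinite(resid_sd) or resid_sd <= 0:
        raise RuntimeError("singular fixed-effects fit")
    return {
        "intercept": float(fe["Intercept"]),
        "age_coef": float(fe["age"]),
        "sex_coef": float(fe["sex"]),
        "site_offsets": offsets,
        "residual_sd": resid_sd,
        "site_var": float("nan"),
        "subject_var": float("nan"),
        "method": "fixed",
    }


def fit_reference(hc_table: pd.DataFrame, roi_names: list[str]) -> ReferenceModel:
    """Fit the HC reference model for every ROI in ``roi_names``.

    Requires age/sex/site/subject_id columns and at least 20 HC
    observations.  Falls back to fixed site effects when the variance
    components are degenerate; a single site reduces to the fixed fit
    with all-zero site offsets."""
    missing = [c for c in _REQUIRED if c not in hc_table.columns]
    if missing:
        raise ValueError(f"HC table lacks covariate columns: {missing}")
    if len(hc_table) < 20:
        raise ValueError(f"need >= 20 HC observations, got {len(hc_table)}")
    multi_site = hc_table["site"].nunique() >= 2
    if not multi_site:
        warnings.warn("single-site HC data: reducing to the fixed-effects fit",
                      stacklevel=2)
    model = ReferenceModel()
    for roi in roi_names:
        if roi not in hc_table.columns:
            raise ValueError(f"ROI column {roi!r} missing from HC table")
        data = hc_table[["age", "sex", "site", "subject_id", roi]].rename(
            columns={roi: "value"}).dropna()
        params = None
        if multi_site:
            try:
                params = _fit_mixed(data, multi_site)
            except Exception:
                params = None
        if params is None:
            try:
                params = _fit_fixed(data, multi_site)
            except Exception as exc:
                raise RuntimeError(f"reference fit failed for ROI {roi!r}") from exc
            if multi_site:
                params["method"] = "fixed_fallback"
        params["n_obs"] = int(len(data))
        model.params[roi] = params
    return model


def compute_wscores(table: pd.DataFrame, model: ReferenceModel,
                    rois: list[str] | None = None) -> pd.DataFrame:
    """w = (observed - predicted) / residual_sd for every modelled ROI.

    Works for any subject group at any visit; unseen sites get a zero
    site offset.  Identifier/covariate columns present in ``table`` are
    carried through."""
    rois = model.rois if rois is None else list(rois)
    for roi in rois:
        if roi not in model.params:
            raise KeyError(f"ROI {roi!r} absent from reference model")
        if roi not in table.columns:
            raise KeyError(f"ROI column {roi!r} missing from input table")
    keep = [c for c in ("subject_id", "visit", "delta_months", "site", "age_bl",
                        "age", "sex", "group") if c in table.columns]
    out = table[keep].copy()
    for roi in rois:
        pred = model.predict(roi, table["age"], table["sex"], table["site"])
        out[roi] = (table[roi].to_numpy(dtype=float) - pred) / model.params[roi]["residual_sd"]
    return out
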