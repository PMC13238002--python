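"""Composite-endpoint survival analysis: record construction, Kaplan-Meier
curves with medians, and log-rank group contrasts.

The endpoint is composite (death, tracheostomy, or >=22 h/day assisted
ventilation); subjects alive at 60 months, lost to follow-up, or opting
for assisted dying are censored, and subjects without any post-baseline
follow-up are excluded from the analysis set.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test

from .association import benjamini_hochberg

__all__ = ["build_survival_records", "kaplan_meier", "logrank_test"]


def build_survival_records(raw: pd.DataFrame, final_subtypes: pd.DataFrame | pd.Series | None = None,
                           followup_subjects=None,
                           admin_censor_months: float = 60.0) -> pd.DataFrame:
    """Apply censoring rules and attach group labels.

    ``raw`` needs subject_id, time_months, event_flag and optionally a
    ``maid_months`` column (assisted-dying date -> censored there).
    ``followup_subjects``, when given, restricts the analysis set to
    subjects with post-baseline follow-up.  Times beyond the
    administrative horizon are truncated to it and censored.
    """
    d = raw.copy()
    if (d["time_months"] <= 0).any():
        raise ValueError("survival times must be positive")
    if "maid_months" in d.columns:
        maid = d["maid_months"].notna() & (d["maid_months"] <= d["time_months"])
        d.loc[maid, "time_months"] = d.loc[maid, "maid_months"]
        d.loc[maid, "event_flag"] = 0
    over = d["time_months"] >= admin_censor_months
    d.loc[over, "time_months"] = admin_censor_months
    d.loc[over, "event_flag"] = 0
    if followup_subjects is not None:
        d = d[d["subject_id"].isin(set(followup_subjects))].copy()
    if final_subtypes is not None:
        if isinstance(final_subtypes, pd.DataFrame):
            mapping = final_subtypes.set_index("subject_id")["final_subtype"]
        else:
            mapping = final_subtypes
        d["group"] = d["subject_id"].map(mapping)
        d = d[d["group"].notna()].copy()
    cols = ["subject_id", "time_months", "event_flag"] + (["group"] if "group" in d else [])
    return d[cols].reset_index(drop=True)


def kaplan_meier(records: pd.DataFrame):
    """Product-limit curve and median survival.

    Returns ``(table, median)`` where the table has columns time,
    n_at_risk, n_events, n_censored, survival, and the median is the
    earliest time with S(t) <= 0.5 (NaN when never reached)."""
    if not len(records):
        raise ValueError("no survival records")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time_months"], records["event_flag"])
    ev = kmf.event_table.reset_index().rename(columns={"event_at": "time"})
    table = pd.DataFrame({
        "time": ev["time"],
        "n_at_risk": ev["at_risk"].astype(int),
        "n_events": ev["observed"].astype(int),
        "n_censored": ev["censored"].astype(int),
        "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
    })
    med = kmf.median_survival_time_
    return table, (float("nan") if np.isinf(med) else float(med))


def logrank_test(records: pd.DataFrame, group_col: str = "group",
                 pairwise: bool = False, fdr: bool = False) -> pd.DataFrame:
    """Log-rank contrast of survival distributions between groups.

    Omnibus mode (default) runs one k-group test; ``pairwise`` runs every
    group pair and reports raw p-values (BH-adjusted q added when
    ``fdr``).  With no events at all the result is flagged not
    evaluable."""
    groups = sorted(records[group_col].dropna().unique(), key=str)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if records["event_flag"].sum() == 0:
        return pd.DataFrame([{"comparison": "all", "statistic": np.nan,
                              "p": np.nan, "evaluable": False}])
    rows = []
    if pairwise:
        for ga, gb in itertools.combinations(groups, 2):
            a = records[records[group_col] == ga]
            b = records[records[group_col] == gb]
            res = _ll_logrank(a["time_months"], b["time_months"],
                              a["event_flag"], b["event_flag"])
            rows.append({"comparison": f"{ga} vs {gb}",
                         "statistic": float(res.test_statistic),
                         "p": float(res.p_value), "evaluable": True})
        out = pd.DataFrame(rows)
        if fdr:
            out["q"] = benjamini_hochberg(out["p"].to_numpy())
        return out
    res = multivariate_logrank_test(records["time_months"], records[group_col],
                                    records["event_flag"])
    return pd.DataFrame([{"comparison": "omnibus", "statistic": float(res.test_statistic),
                          "p": float(res.p_value), "evaluable": True}])
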