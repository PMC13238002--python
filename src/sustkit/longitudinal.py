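"""Longitudinal application of a baseline-trained model.

Follow-up visits are staged with the frozen baseline fit (no refitting).
Between-visit transitions are classified as consistent or inconsistent:
a subtype pair is consistent when the subtype is unchanged or the earlier
visit is Normal Appearing (S0); a stage pair is consistent when the later
stage is not lower.  Assignment confidence at the earliest visit of each
pair is compared between consistent and inconsistent cases, and each
subject is resolved to a single most-confident non-S0 subtype while all
per-visit stages are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sustain import SustainFit, assign_subjects

__all__ = [
    "stage_followups",
    "classify_consistency",
    "compare_confidence",
    "resolve_final_subtype",
    "ConsistencyReport",
]

_PAIRS = ((1, 2), (2, 3), (1, 3))


@dataclass
class ConsistencyReport:
    """Per visit-pair consistency percentages, transition counts and cases."""

    pairs: dict = field(default_factory=dict)   # "V1->V2" -> summary dict
    cases: pd.DataFrame | None = None           # one row per evaluable pair
    confidence_tests: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {"pairs": self.pairs}
        if self.confidence_tests is not None:
            out["confidence_tests"] = self.confidence_tests.to_dict(orient="records")
        return out


def stage_followups(fit: SustainFit, wscores: pd.DataFrame,
                    sigma: float = 1.0) -> pd.DataFrame:
    """Assign (subtype, stage) to every visit row of a w-score table.

    The model must have been trained on baseline data only; this never
    refits.  Returns one row per (subject, visit) with assignment labels
    and probabilities, ordered by subject and elapsed time.
    """
    required = {"subject_id", "visit", "delta_months"}
    if not required.issubset(wscores.columns):
        raise ValueError(f"w-score table must contain columns {sorted(required)}")
    if wscores.duplicated(["subject_id", "visit"]).any():
        raise ValueError("duplicate (subject_id, visit) rows in w-score table")
    X = fit.event_set.to_model_scale(wscores)
    asg = assign_subjects(X, fit, sigma=sigma)
    out = wscores[["subject_id", "visit", "delta_months"]].copy().reset_index(drop=True)
    out["ml_subtype"] = [a.ml_subtype for a in asg]
    out["ml_stage"] = [a.ml_stage for a in asg]
    out["label"] = [a.label for a in asg]
    out["subtype_prob"] = [a.subtype_prob for a in asg]
    out["stage_prob"] = [a.stage_prob for a in asg]
    out["s0_flag"] = [a.s0_flag for a in asg]
    return out.sort_values(["subject_id", "delta_months"], kind="mergesort").reset_index(drop=True)


def classify_consistency(assignments: pd.DataFrame) -> ConsistencyReport:
    """Classify V1->V2, V2->V3 and V1->V3 transitions.

    V1->V3 pairs are evaluated whenever both visits exist, independently
    of whether V2 does.
    """
    if not (assignments.groupby("subject_id").size() >= 2).any():
        raise ValueError("need at least one subject with two visits")
    by_visit = {
        (sid, int(v)): row
        for (sid, v), row in assignments.set_index(["subject_id", "visit"]).iterrows()
    }
    rows = []
    for va, vb in _PAIRS:
        pair = f"V{va}->V{vb}"
        for sid in assignments["subject_id"].unique():
            a, b = by_visit.get((sid, va)), by_visit.get((sid, vb))
            if a is None or b is None:
                continue
            subtype_ok = (a["label"] == b["label"]) or a["label"] == "S0"
            stage_ok = b["ml_stage"] >= a["ml_stage"]
            rows.append({
                "pair": pair, "subject_id": sid,
                "from_label": a["label"], "to_label": b["label"],
                "from_stage": int(a["ml_stage"]), "to_stage": int(b["ml_stage"]),
                "subtype_consistent": bool(subtype_ok),
                "stage_consistent": bool(stage_ok),
                "early_subtype_prob": float(a["subtype_prob"]),
                "early_stage_prob": float(a["stage_prob"]),
            })
    cases = pd.DataFrame(rows)
    pairs = {}
    for va, vb in _PAIRS:
        pair = f"V{va}->V{vb}"
        sub = cases[cases["pair"] == pair] if len(cases) else cases
        n = len(sub)
        trans = (sub.groupby(["from_label", "to_label"]).size().to_dict() if n else {})
        pairs[pair] = {
            "n_pairs": n,
            "subtype_consistency_pct": 100.0 * sub["subtype_consistent"].mean() if n else float("nan"),
            "stage_consistency_pct": 100.0 * sub["stage_consistent"].mean() if n else float("nan"),
            "transitions": {f"{a}->{b}": int(c) for (a, b), c in trans.items()},
        }
    return ConsistencyReport(pairs=pairs, cases=cases)


def _two_group_test(cons: np.ndarray, incons: np.ndarray) -> dict:
    """Student's t when both groups pass Shapiro-Wilk at alpha=0.05,
    Mann-Whitney U otherwise.  Tiny groups (< 3) cannot be tested for
    normality and fall through to Mann-Whitney."""
    if len(cons) == 0 or len(incons) == 0:
        return {"test": "not evaluable", "statistic": float("nan"), "p": float("nan"),
                "n_consistent": len(cons), "n_inconsistent": len(incons)}
    normal = True
    for g in (cons, incons):
        if len(g) < 3 or np.ptp(g) == 0:
            normal = False
            break
        if stats.shapiro(g).pvalue < 0.05:
            normal = False
            break
    if normal:
        res = stats.ttest_ind(cons, incons)
        name = "t"
    else:
        res = stats.mannwhitneyu(cons, incons, alternative="two-sided")
        name = "mannwhitney"
    return {"test": name, "statistic": float(res.statistic), "p": float(res.pvalue),
            "n_consistent": len(cons), "n_inconsistent": len(incons)}


def compare_confidence(report: ConsistencyReport,
                       assignments: pd.DataFrame | None = None) -> pd.DataFrame:
    """Earliest-visit assignment probability, consistent vs inconsistent.

    Runs per visit pair and per metric (subtype / stage).  The subtype
    metric uses the stage-marginalized posterior probability of the
    assigned subtype; the stage metric the posterior probability of the
    ML stage given the subtype."""
    cases = report.cases
    rows = []
    for va, vb in _PAIRS:
        pair = f"V{va}->V{vb}"
        sub = cases[cases["pair"] == pair] if cases is not None and len(cases) else None
        for metric, flag_col, prob_col in (
                ("subtype", "subtype_consistent", "early_subtype_prob"),
                ("stage", "stage_consistent", "early_stage_prob")):
            if sub is None or not len(sub):
                res = _two_group_test(np.array([]), np.array([]))
            else:
                res = _two_group_test(
                    sub.loc[sub[flag_col], prob_col].to_numpy(),
                    sub.loc[~sub[flag_col], prob_col].to_numpy())
            rows.append({"pair": pair, "metric": metric, **res})
    out = pd.DataFrame(rows)
    report.confidence_tests = out
    return out


def resolve_final_subtype(assignments: pd.DataFrame) -> pd.DataFrame:
    """One representative subtype per subject; stages are never altered.

    Subjects with any non-S0 visit take the non-S0 subtype with the
    highest stage-marginalized assignment probability across visits (ties
    break toward the earlier visit, then the lower subtype index);
    subjects S0 at every visit stay S0.  Returns per-visit rows with a
    ``final_subtype`` column added."""
    out = assignments.copy()
    finals = {}
    for sid, grp in assignments.groupby("subject_id"):
        grp = grp.sort_values("delta_months", kind="mergesort")
        nz = grp[~grp["s0_flag"]]
        if not len(nz):
            finals[sid] = "S0"
            continue
        best = None
        for _, row in nz.iterrows():
            key = (-row["subtype_prob"], row["delta_months"], row["ml_subtype"])
            if best is None or key < best[0]:
                best = (key, row["label"])
        finals[sid] = best[1]
    out["final_subtype"] = out["subject_id"].map(finals)
    return out
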