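"""Synthetic multi-site longitudinal cohort generator.

Stands in for restricted consortium data: generates healthy-control and
patient tables on a pseudo-DBM scale (HC mean surface plus a planted
atrophy shift of -z * residual_sd), so that downstream w-scoring recovers
the planted z magnitudes with the atrophy-negative sign convention.
Patients carry planted subtype-specific event orderings, stage-linked
clinical decline and subtype-linked survival hazards.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .events import EventSet, trajectory_matrix

__all__ = [
    "MODEL_ROIS",
    "GeneratorConfig",
    "GroundTruth",
    "kendall_distance",
    "plant_subtype_sequences",
    "generate_cohort",
    "simulate_survival",
    "write_cohort",
]

# The 14 modelled regions: early motor system, frontal, striatal, medial
# temporal, and parietal representatives (bilateral means).
MODEL_ROIS = [
    "precentral",
    "paracentral",
    "corticospinal_tract",
    "brainstem",
    "superior_frontal",
    "rostral_middle_frontal",
    "caudate",
    "putamen",
    "hippocampus",
    "entorhinal",
    "parahippocampal",
    "amygdala",
    "superior_parietal",
    "inferior_parietal",
]

# stage-linked clinical generation: value = base + slope * true_stage + N(0, sd)
_CLINICAL_EFFECTS = {
    "alsfrs_total": {"base": 44.0, "slope": -0.9, "sd": 2.0, "lo": 0.0, "hi": 48.0},
    "fvc": {"base": 95.0, "slope": -1.5, "sd": 5.0, "lo": 20.0, "hi": 130.0},
    "umn_burden": {"base": 4.0, "slope": 0.20, "sd": 1.5, "lo": 0.0, "hi": 16.0},
    "lmn_burden": {"base": 3.0, "slope": 0.25, "sd": 1.5, "lo": 0.0, "hi": 12.0},
    "finger_tapping": {"base": 50.0, "slope": -0.8, "sd": 6.0, "lo": 0.0, "hi": 90.0},
    "foot_tapping": {"base": 35.0, "slope": -0.6, "sd": 6.0, "lo": 0.0, "hi": 80.0},
    "ecas_total": {"base": 110.0, "slope": -0.5, "sd": 6.0, "lo": 40.0, "hi": 136.0},
}


@dataclass
class GeneratorConfig:
    """Knobs for the cohort generator.

    ``noise_sd`` is the patient biomarker noise in w-score units; the HC
    noise is fixed at one w-score unit because it *defines* the unit the
    reference model estimates.  ``survival_hazard_by_subtype`` is indexed
    by true subtype label 0..n_subtypes_true (0 = normal-appearing-like).
    """

    n_hc: int = 144
    n_patients: int = 198
    n_sites: int = 7
    n_subtypes_true: int = 3
    visit_months: tuple[float, ...] = (0.0, 4.0, 8.0)
    noise_sd: float = 1.0
    stage_advance_per_month: float = 0.25
    attrition_prob: float = 0.15
    survival_hazard_by_subtype: tuple[float, ...] = (0.016, 0.023, 0.026, 0.029)
    seed: int = 0
    # secondary knobs
    frac_stage0: float = 0.2
    subtype_fractions: tuple[float, ...] | None = None
    stage_jitter_sd: float = 0.2
    visit_month_jitter_sd: float = 0.3
    male_frac_hc: float = 0.45
    male_frac_patients: float = 0.65
    ltfu_hazard: float = 0.006
    admin_censor_months: float = 60.0
    min_sequence_separation: float = 0.3
    # baseline-stage range for non-stage-0 patients, as fractions of N.
    # Trajectories of different subtypes converge at both ends of the
    # stage axis, so recovery experiments plant stages in the middle.
    stage_min_frac: float = 0.02
    stage_max_frac: float = 0.75
    # Patient noise decomposition (all in w-units; total per-biomarker,
    # per-visit SD stays noise_sd).  visit_noise_frac is the share of
    # noise_sd that is fresh measurement noise at each visit; the rest is
    # a persistent per-subject anatomical deviation, which is what makes
    # repeated stagings of one subject agree.  global_noise_sd adds a
    # scan-session component shared across all biomarkers of a visit
    # (registration / global scaling nuisance).
    visit_noise_frac: float = 0.3
    global_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_patients, self.n_sites, self.n_subtypes_true) <= 0:
            raise ValueError("all counts must be > 0")
        vm = tuple(float(v) for v in self.visit_months)
        if vm[0] != 0.0 or any(b <= a for a, b in zip(vm, vm[1:])):
            raise ValueError("visit_months must be strictly increasing and start at 0")
        self.visit_months = vm
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if any(h < 0 for h in self.survival_hazard_by_subtype):
            raise ValueError("hazards must be >= 0")
        if len(self.survival_hazard_by_subtype) < self.n_subtypes_true + 1:
            raise ValueError(
                "survival_hazard_by_subtype must cover labels 0..n_subtypes_true")
        if self.subtype_fractions is not None:
            sf = np.asarray(self.subtype_fractions, dtype=float)
            if sf.size != self.n_subtypes_true or not np.isclose(sf.sum(), 1.0):
                raise ValueError("subtype_fractions must sum to 1 over n_subtypes_true")


@dataclass
class GroundTruth:
    """Planted generative state; the oracle for recovery experiments."""

    sequences: list[np.ndarray]          # per-subtype event orderings
    subject_subtype: pd.Series           # patient -> 0 (normal-appearing-like) or 1..K
    subject_sequence: pd.Series          # patient -> 1..K sequence used for progression
    subject_stage: pd.DataFrame          # subject_id, visit, true_stage (real-valued)
    effects: dict = field(default_factory=dict)  # per-ROI generation coefficients

    def to_dict(self) -> dict:
        return {
            "sequences": [s.tolist() for s in self.sequences],
            "subject_subtype": {k: int(v) for k, v in self.subject_subtype.items()},
            "subject_sequence": {k: int(v) for k, v in self.subject_sequence.items()},
            "subject_stage": self.subject_stage.to_dict(orient="list"),
            "effects": self.effects,
        }


def kendall_distance(seq_a, seq_b) -> float:
    """Normalized Kendall-tau distance between two event orderings in [0, 1]."""
    a = np.asarray(seq_a)
    b = np.asarray(seq_b)
    n = a.size
    if n < 2:
        return 0.0
    pos_a = np.empty(n)
    pos_b = np.empty(n)
    pos_a[a] = np.arange(n)
    pos_b[b] = np.arange(n)
    tau = kendalltau(pos_a, pos_b).statistic
    return float((1.0 - tau) / 2.0)


def _blocked_sequence(event_set: EventSet, rotation: int, n_groups: int,
                      group_of: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One valid ordering in which biomarker groups complete in rotated order.

    Group ``rotation`` runs through all its thresholds first, then the
    next group, and so on — mimicking subtypes with distinct onset
    systems.  Within a group the biomarker order is shuffled."""
    order = []
    for g in range(n_groups):
        grp = np.flatnonzero(group_of == (g + rotation) % n_groups)
        grp = rng.permutation(grp)
        levels = max(len(event_set.thresholds[event_set.biomarkers[b]]) for b in grp)
        for lev in range(levels):
            for b in grp:
                ev_ids = np.flatnonzero(event_set.event_biomarker == b)
                if lev < ev_ids.size:
                    order.append(ev_ids[lev])
    return np.asarray(order, dtype=np.intp)


def plant_subtype_sequences(event_set: EventSet, n_subtypes: int, seed=None,
                            min_distance: float = 0.3, style: str = "blocked",
                            max_tries: int = 2000) -> list[np.ndarray]:
    """Draw ``n_subtypes`` well-separated valid event orderings.

    ``style="blocked"`` (default) partitions the biomarkers into
    ``n_subtypes`` groups and gives each subtype a rotated group order, so
    subtypes differ in which anatomical system degenerates first — this
    is what makes them recoverable at realistic noise.  ``style="random"``
    draws unstructured valid permutations.  Either way the draw is
    repeated until every pair is at normalized Kendall-tau distance
    >= ``min_distance``; if the event set is too small for that
    separation the best attempt is returned with a warning.
    """
    if n_subtypes < 1:
        raise ValueError("n_subtypes must be >= 1")
    from .events import random_valid_sequence

    rng = np.random.default_rng(seed)
    n = event_set.n_events
    if n_subtypes == 1:
        return [random_valid_sequence(event_set, rng)]
    n_groups = min(n_subtypes, event_set.n_biomarkers)
    best, best_sep = None, -1.0
    for _ in range(max_tries):
        if style == "blocked":
            group_of = rng.permutation(event_set.n_biomarkers) % n_groups
            seqs = [_blocked_sequence(event_set, c % n_groups, n_groups, group_of, rng)
                    for c in range(n_subtypes)]
        elif style == "random":
            seqs = [random_valid_sequence(event_set, rng) for _ in range(n_subtypes)]
        else:
            raise ValueError(f"unknown style {style!r}")
        sep = min(
            kendall_distance(seqs[i], seqs[j])
            for i in range(n_subtypes) for j in range(i + 1, n_subtypes)
        )
        if sep > best_sep:
            best, best_sep = seqs, sep
        if sep >= min_distance:
            return seqs
    warnings.warn(
        f"could not separate {n_subtypes} sequences of {n} events at "
        f"distance {min_distance}; best achieved {best_sep:.3f}", stacklevel=2)
    return best


def _roi_effects(rois: list[str], rng: np.random.Generator, n_sites: int) -> dict:
    eff = {}
    for r in rois:
        sd = float(rng.uniform(0.03, 0.08))  # pseudo-DBM residual scale
        eff[r] = {
            "intercept": float(rng.normal(1.0, 0.05)),
            "age_slope": float(rng.normal(-0.3, 0.15)) * sd / 20.0,  # per year
            "sex_effect": float(rng.normal(0.0, 0.3)) * sd,
            "site_effects": (rng.normal(0.0, 0.5, size=n_sites) * sd).tolist(),
            "residual_sd": sd,
        }
    return eff


def _visit_schedule(cfg: GeneratorConfig, rng: np.random.Generator) -> list[float]:
    """Attended visit delta-months for one subject (attrition applied)."""
    months = [0.0]
    for m in cfg.visit_months[1:]:
        if rng.uniform() < cfg.attrition_prob:
            break
        months.append(float(max(m + rng.normal(0.0, cfg.visit_month_jitter_sd), months[-1] + 0.5)))
    return months


def generate_cohort(config: GeneratorConfig, event_set: EventSet,
                    sequences: list[np.ndarray] | None = None):
    """Generate (HC table, patient table, GroundTruth).

    HC biomarker values follow ``intercept + site + age_slope*age +
    sex_effect*sex + noise``; patients are additionally shifted by
    ``-mu_b(floor(stage)) * residual_sd`` under their true subtype's
    sequence, so w-scoring recovers the planted z magnitudes.
    """
    if config.n_patients <= 0:
        raise ValueError("need at least one patient")
    if config.n_sites < 2:
        warnings.warn("fewer than 2 sites: site effects are degenerate", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    rois = event_set.biomarkers
    if not rois:
        raise ValueError("event set has no biomarkers")
    n_events = event_set.n_events

    if sequences is None:
        sequences = plant_subtype_sequences(
            event_set, config.n_subtypes_true, seed=rng.integers(2**31),
            min_distance=config.min_sequence_separation)
    trajectories = [trajectory_matrix(s, event_set) for s in sequences]
    effects = _roi_effects(rois, rng, config.n_sites)

    def hc_mean(roi, site, age, sex):
        e = effects[roi]
        return (e["intercept"] + e["site_effects"][site]
                + e["age_slope"] * (age - 60.0) + e["sex_effect"] * sex)

    rows_hc = []
    for i in range(config.n_hc):
        sid = f"HC{i:04d}"
        site = int(rng.integers(config.n_sites))
        age_bl = float(rng.uniform(40.0, 78.0))
        sex = int(rng.uniform() < config.male_frac_hc)
        edu = int(rng.integers(8, 21))
        for v, dm in enumerate(_visit_schedule(config, rng), start=1):
            age = age_bl + dm / 12.0
            row = {"subject_id": sid, "visit": v, "delta_months": dm, "site": site,
                   "age_bl": age_bl, "age": age, "sex": sex, "education_years": edu,
                   "group": "HC"}
            for name, p in _CLINICAL_EFFECTS.items():
                base = 48.0 if name == "alsfrs_total" else p["base"]
                row[name] = float(np.clip(base + rng.normal(0.0, p["sd"] / 2), p["lo"], p["hi"]))
            for r in rois:
                row[r] = hc_mean(r, site, age, sex) + rng.normal(0.0, effects[r]["residual_sd"])
            rows_hc.append(row)

    sf = (np.full(config.n_subtypes_true, 1.0 / config.n_subtypes_true)
          if config.subtype_fractions is None else np.asarray(config.subtype_fractions))

    rows_pt, stage_rows = [], []
    subtype_lbl, seq_lbl = {}, {}
    for i in range(config.n_patients):
        sid = f"PT{i:04d}"
        site = int(rng.integers(config.n_sites))
        age_bl = float(rng.uniform(40.0, 82.0))
        sex = int(rng.uniform() < config.male_frac_patients)
        edu = int(rng.integers(8, 21))
        seq_c = int(rng.choice(config.n_subtypes_true, p=sf)) + 1
        at_zero = rng.uniform() < config.frac_stage0
        stage_bl = 0.0 if at_zero else float(rng.uniform(
            config.stage_min_frac * n_events,
            max(config.stage_max_frac * n_events, config.stage_min_frac * n_events + 1.0)))
        subtype_lbl[sid] = 0 if at_zero else seq_c
        seq_lbl[sid] = seq_c
        onset_bulbar = int(rng.uniform() < 0.25)
        sympt_dur = float(rng.uniform(6.0, 60.0))
        months = _visit_schedule(config, rng)
        vf = float(np.clip(config.visit_noise_frac, 0.0, 1.0))
        subj_sd = config.noise_sd * np.sqrt(max(1.0 - vf * vf, 0.0))
        visit_sd = config.noise_sd * vf
        subj_dev = rng.normal(0.0, subj_sd, size=len(rois))  # persistent anatomy
        prev_stage = 0.0
        for v, dm in enumerate(months, start=1):
            stage = stage_bl + config.stage_advance_per_month * dm
            if v > 1 and config.stage_jitter_sd > 0:
                stage += rng.normal(0.0, config.stage_jitter_sd)
            stage = float(np.clip(stage, prev_stage, n_events))  # non-decreasing
            prev_stage = stage
            stage_int = int(np.clip(np.floor(stage), 0, n_events))
            age = age_bl + dm / 12.0
            row = {"subject_id": sid, "visit": v, "delta_months": dm, "site": site,
                   "age_bl": age_bl, "age": age, "sex": sex, "education_years": edu,
                   "group": "ALS", "onset_bulbar": onset_bulbar,
                   "symptom_duration_months": sympt_dur}
            for name, p in _CLINICAL_EFFECTS.items():
                row[name] = float(np.clip(
                    p["base"] + p["slope"] * stage + rng.normal(0.0, p["sd"]),
                    p["lo"], p["hi"]))
            row["ecas_abnormal"] = int(row["ecas_total"] < 100.0)
            mu = trajectories[seq_c - 1][stage_int]
            session = rng.normal(0.0, config.global_noise_sd) if config.global_noise_sd > 0 else 0.0
            for b, r in enumerate(rois):
                sd = effects[r]["residual_sd"]
                w_noise = subj_dev[b] + session + rng.normal(0.0, visit_sd)
                row[r] = hc_mean(r, site, age, sex) + (-mu[b] + w_noise) * sd
            rows_pt.append(row)
            stage_rows.append({"subject_id": sid, "visit": v, "delta_months": dm,
                               "true_stage": stage})

    hc = pd.DataFrame(rows_hc)
    patients = pd.DataFrame(rows_pt)
    truth = GroundTruth(
        sequences=[np.asarray(s, dtype=np.intp) for s in sequences],
        subject_subtype=pd.Series(subtype_lbl, name="true_subtype"),
        subject_sequence=pd.Series(seq_lbl, name="true_sequence"),
        subject_stage=pd.DataFrame(stage_rows),
        effects=effects,
    )
    return hc, patients, truth


def simulate_survival(ground_truth: GroundTruth, config: GeneratorConfig,
                      seed=None) -> pd.DataFrame:
    """Exponential event times with subtype-specific monthly hazards.

    Censoring: administrative at ``admin_censor_months``, plus random
    loss-to-follow-up with hazard ``ltfu_hazard``.  Returns columns
    subject_id, time_months, event_flag, true_subtype.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rows = []
    for sid, lbl in ground_truth.subject_subtype.items():
        h = config.survival_hazard_by_subtype[int(lbl)]
        t_event = rng.exponential(1.0 / h) if h > 0 else np.inf
        t_ltfu = (rng.exponential(1.0 / config.ltfu_hazard)
                  if config.ltfu_hazard > 0 else np.inf)
        t = min(t_event, t_ltfu, config.admin_censor_months)
        rows.append({"subject_id": sid, "time_months": float(max(t, 1e-6)),
                     "event_flag": int(t_event <= min(t_ltfu, config.admin_censor_months)),
                     "true_subtype": int(lbl)})
    return pd.DataFrame(rows)


def write_cohort(outdir, hc: pd.DataFrame, patients: pd.DataFrame,
                 survival: pd.DataFrame | None, truth: GroundTruth) -> dict:
    """Write hc.csv / patients.csv / survival.csv / truth.json; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"hc": outdir / "hc.csv", "patients": outdir / "patients.csv",
             "truth": outdir / "truth.json"}
    hc.to_csv(paths["hc"], index=False)
    patients.to_csv(paths["patients"], index=False)
    if survival is not None:
        paths["survival"] = outdir / "survival.csv"
        survival.to_csv(paths["survival"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
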