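"""Shared fixtures.

Heavy artefacts (the standard recovery cohort and its fitted model) are
session-scoped so the recovery/consistency assertions and the acceptance
checks reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sustkit.events import build_events, trajectory_matrix
from sustkit.synthetic import (MODEL_ROIS, GeneratorConfig, generate_cohort,
                               plant_subtype_sequences, simulate_survival)
from sustkit.sustain import fit_sustain
from sustkit.wscore import compute_wscores, fit_reference


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def es6():
    """Tiny event set: 3 biomarkers x thresholds (1, 2), N = 6."""
    return build_events(["a", "b", "c"], (1.0, 2.0), zmax_rule=3.0)


@pytest.fixture(scope="session")
def es28():
    """Full-size event set: 14 ROIs x thresholds (1, 2), N = 28."""
    return build_events(MODEL_ROIS, (1.0, 2.0), zmax_rule=3.0)


def make_subtype_data(event_set, n, n_subtypes, noise_sd, seed,
                      stage_lo_frac=0.15, stage_hi_frac=0.85):
    """Model-scale data matrix with planted subtypes and stages."""
    rng = np.random.default_rng(seed)
    seqs = plant_subtype_sequences(event_set, n_subtypes, seed=rng.integers(2**31))
    mus = [trajectory_matrix(s, event_set) for s in seqs]
    n_ev = event_set.n_events
    lbl = rng.integers(0, n_subtypes, size=n)
    stages = rng.integers(int(stage_lo_frac * n_ev), int(stage_hi_frac * n_ev) + 1, size=n)
    X = np.stack([mus[lbl[i]][stages[i]] for i in range(n)])
    X = X + rng.normal(0.0, noise_sd, size=X.shape)
    return X, lbl, stages, seqs


@pytest.fixture(scope="session")
def recovery_data(es28):
    """The standard recovery configuration: 3 subtypes, n=200, noise SD 1."""
    return make_subtype_data(es28, n=200, n_subtypes=3, noise_sd=1.0, seed=42)


@pytest.fixture(scope="session")
def recovery_fit(es28, recovery_data):
    X, _, _, _ = recovery_data
    fits = fit_sustain(X, es28, max_subtypes=3, n_startpoints=5, mcmc_iters=2000,
                       seed=7, n_split_restarts=3, split_startpoints=2)
    return fits[-1]


@pytest.fixture(scope="session")
def hc_selfscore_calibration(es28):
    """Per-ROI mean and SD of w-scores when the HC training set scores
    itself (n = 500 simulated HCs, subset of ROIs to keep the mixed fits
    affordable)."""
    rois = MODEL_ROIS[:6]
    cfg = GeneratorConfig(n_hc=500, n_patients=5, seed=21)
    hc, _, _ = generate_cohort(cfg, es28)
    model = fit_reference(hc, rois)
    w = compute_wscores(hc, model)
    return w[rois].mean().to_numpy(), w[rois].std().to_numpy()


@pytest.fixture(scope="session")
def lme_type1_rate():
    """Rejection rate of the Dx:time interaction at alpha=0.05 over 500
    null longitudinal replicates (no group difference planted)."""
    from sustkit.association import StatModelSpec, fit_group_lme

    rng = np.random.default_rng(4)
    rejections = 0
    n_rep = 500
    for _ in range(n_rep):
        rows = []
        for i in range(24):
            b = rng.normal()
            for v in range(2):
                dm = 4.0 * v
                rows.append({"subject_id": f"s{i}", "Dx": i % 2,
                             "delta_months": dm,
                             "y": b + 0.1 * dm + rng.normal()})
        res = fit_group_lme(StatModelSpec(response="y"), pd.DataFrame(rows))
        inter = res[res["term"].str.contains("delta_months")].iloc[0]
        rejections += bool(inter["p"] < 0.05)
    return rejections / n_rep


@pytest.fixture(scope="session")
def logrank_null_rate():
    """Log-rank rejection rate at alpha=0.05 over 500 equal-hazard
    replicates."""
    from sustkit.survival import logrank_test

    rng = np.random.default_rng(2)
    rejections = 0
    n_rep = 500
    for _ in range(n_rep):
        d = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(60)],
            "time_months": rng.exponential(25, size=60),
            "event_flag": 1, "group": np.repeat(["a", "b"], 30)})
        rejections += bool(logrank_test(d).iloc[0]["p"] < 0.05)
    return rejections / n_rep


@pytest.fixture(scope="session")
def greedy_oracle_hitrate(es6):
    """Fraction of 50 seeded replicates where greedy attains the
    exhaustive valid-permutation maximum within 1e-6 (N = 6 events)."""
    from sustkit.events import random_valid_sequence
    from sustkit.sustain import optimize_sequence_greedy
    from tests.test_sustain import exhaustive_best

    hits = 0
    for seed in range(50):
        r = np.random.default_rng(seed)
        true = random_valid_sequence(es6, r)
        mu = trajectory_matrix(true, es6)
        X = mu[r.integers(0, 7, size=40)] + r.normal(0, 1.0, size=(40, 3))
        _, greedy_ll = optimize_sequence_greedy(X, es6, n_startpoints=5, seed=seed)
        _, exh_ll = exhaustive_best(X, es6)
        hits += greedy_ll >= exh_ll - 1e-6
    return hits / 50


@pytest.fixture(scope="session")
def longitudinal_cohort(es28):
    """Noisy longitudinal synthetic cohort staged by a baseline-only fit."""
    cfg = GeneratorConfig(n_hc=120, n_patients=150, seed=3,
                          stage_advance_per_month=0.4,
                          frac_stage0=0.15, stage_max_frac=0.7)
    hc, patients, truth = generate_cohort(cfg, es28)
    ref = fit_reference(hc, MODEL_ROIS)
    w_pt = compute_wscores(patients, ref)
    w_bl = w_pt[w_pt["visit"] == 1]
    es = build_events(MODEL_ROIS, (1.0, 2.0), zmax_rule="auto", patient_wscores=w_bl)
    fits = fit_sustain(es.to_model_scale(w_bl), es, max_subtypes=3,
                       n_startpoints=5, mcmc_iters=800, seed=11,
                       n_split_restarts=2, split_startpoints=2, em_tol=1e-3)
    return {"config": cfg, "hc": hc, "patients": patients, "truth": truth,
            "wscores": w_pt, "event_set": es, "fit": fits[-1]}
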