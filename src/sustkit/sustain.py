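"""z-score event-based subtype-and-stage model.

Fits mixtures of event orderings to cross-sectional biomarker data on the
atrophy-positive model scale (d = -w).  Each subtype c is a total ordering
S_c of all N events; a subject at stage k under S_c is modelled as
independent Gaussians around the piecewise-linear trajectory values
mu_i(k) with unit SD (w-scores are HC-standardized).  Stage carries a
uniform prior over 0..N.

Fitting is hierarchical: the single-subtype solution is found by greedy
ascent from random starts; k+1 subtypes are seeded by 2-way splits of each
existing cluster, refined by EM, and uncertainty is estimated by a
Metropolis sampler over sequences and mixture fractions.  Model order is
selected by the cross-validation information criterion
CVIC(k) = -2 * sum of held-out log mean mixture likelihoods (lower is
better).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .events import EventSet, is_valid_sequence, random_valid_sequence, trajectory_matrix

__all__ = [
    "SustainFit",
    "CvicResult",
    "SubjectAssignment",
    "stage_conditional_loglik",
    "subject_marginal_loglik",
    "optimize_sequence_greedy",
    "fit_sustain",
    "mcmc_sample",
    "positional_variance",
    "cross_validate_cvic",
    "assign_subject",
    "assign_subjects",
]

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# likelihood kernels
# ---------------------------------------------------------------------------

def _stage_loglik_matrix(X: np.ndarray, mu: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """(n, N+1) matrix of sum_b log Normal(x_sb; mu_kb, sigma)."""
    nb = X.shape[1]
    quad = (X @ mu.T - 0.5 * (X * X).sum(axis=1)[:, None] - 0.5 * (mu * mu).sum(axis=1)[None, :])
    return quad / (sigma * sigma) - nb * (0.5 * _LOG2PI + np.log(sigma))


def _marginal_loglik_vector(X: np.ndarray, seq: np.ndarray, event_set: EventSet,
                            sigma: float = 1.0) -> np.ndarray:
    """Per-subject stage-marginalized log-likelihood under one sequence."""
    mu = trajectory_matrix(seq, event_set)
    ll = _stage_loglik_matrix(X, mu, sigma)
    return logsumexp(ll, axis=1) - np.log(event_set.n_events + 1)


def stage_conditional_loglik(x, sequence, stage: int, event_set: EventSet,
                             sigma: float = 1.0) -> float:
    """log P(x | sequence, stage) = sum_i log Normal(x_i; mu_i(stage), sigma)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("biomarker vector contains non-finite values")
    mu = trajectory_matrix(np.asarray(sequence), event_set)
    if not 0 <= int(stage) <= event_set.n_events:
        raise ValueError(f"stage must lie in [0, {event_set.n_events}]")
    return float(_stage_loglik_matrix(x[None, :], mu[[int(stage)], :], sigma)[0, 0])


def subject_marginal_loglik(x, sequence, event_set: EventSet, sigma: float = 1.0) -> float:
    """log [ (1/(N+1)) sum_k exp(stage_conditional_loglik(x, seq, k)) ]."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("biomarker vector contains non-finite values")
    return float(_marginal_loglik_vector(x[None, :], np.asarray(sequence), event_set, sigma)[0])


def _mixture_loglik(L: np.ndarray, fractions: np.ndarray) -> float:
    """Total log-likelihood from the (n, k) per-subtype marginal matrix."""
    with np.errstate(divide="ignore"):
        return float(logsumexp(L + np.log(fractions)[None, :], axis=1).sum())


# ---------------------------------------------------------------------------
# greedy sequence optimization
# ---------------------------------------------------------------------------

def _weighted_score(X, weights, seq, event_set, sigma) -> float:
    return float(weights @ _marginal_loglik_vector(X, seq, event_set, sigma))


def _relocation_scores(X, sx, weights, seq, event, event_set, sigma):
    """Weighted marginal loglik of relocating ``event`` to every position.

    Returns a length-N vector: entry j scores the sequence obtained by
    removing ``event`` from ``seq`` and re-inserting it at index j;
    insertions that would break the ascending-threshold order of the
    event's same-biomarker siblings score -inf.  Batched over the valid
    insertion window (``sx`` is the precomputed per-subject 0.5*||x||^2
    vector).
    """
    n = event_set.n_events
    nb = event_set.n_biomarkers
    rest = seq[seq != event]
    lo, hi = _valid_insertion_range(rest, event, event_set)
    J = np.arange(lo, hi + 1)
    C = J.size
    m_idx = np.arange(n - 1)
    # stage (1-based) of each event id under candidate c
    event_stage = np.empty((C, n))
    event_stage[:, rest] = m_idx[None, :] + 1 + (m_idx[None, :] >= J[:, None])
    event_stage[:, event] = J + 1

    stages = np.arange(n + 1, dtype=float)
    mu = np.empty((C, n + 1, nb))
    zmax = event_set.zmax_array()
    for b in range(nb):
        ev_ids = np.flatnonzero(event_set.event_biomarker == b)
        # valid candidates keep sibling order, so stages come out ascending
        xs = event_stage[:, ev_ids]                              # (C, m)
        xs_full = np.concatenate(
            [np.zeros((C, 1)), xs, np.full((C, 1), n + 1.0)], axis=1)
        ys_full = np.concatenate(
            ([0.0], event_set.event_threshold[ev_ids], [zmax[b]]))
        idx = (stages[None, :, None] >= xs_full[:, None, 1:-1]).sum(axis=2)
        x0 = np.take_along_axis(xs_full, idx, axis=1)
        x1 = np.take_along_axis(xs_full, idx + 1, axis=1)
        y0 = ys_full[idx]
        y1 = ys_full[idx + 1]
        mu[:, :, b] = y0 + (stages[None, :] - x0) * (y1 - y0) / (x1 - x0)

    quad = (np.matmul(X[None, :, :], mu.transpose(0, 2, 1))
            - sx[None, :, None] - 0.5 * (mu * mu).sum(axis=2)[:, None, :])
    ll = quad / (sigma * sigma) - nb * (0.5 * _LOG2PI + np.log(sigma))
    mx = ll.max(axis=2)
    marg = mx + np.log(np.exp(ll - mx[:, :, None]).sum(axis=2)) - np.log(n + 1)
    scores = np.full(n, -np.inf)
    scores[J] = marg @ weights
    return scores


def _valid_insertion_range(rest, event, event_set):
    """[lo, hi] inclusive range of valid insertion indices into ``rest``."""
    b = event_set.event_biomarker[event]
    siblings = np.flatnonzero(event_set.event_biomarker == b)
    lo, hi = 0, rest.size
    rest_pos = {e: i for i, e in enumerate(rest)}
    for s in siblings:
        if s == event:
            continue
        m = rest_pos[s]
        if event_set.event_threshold[s] < event_set.event_threshold[event]:
            lo = max(lo, m + 1)
        else:
            hi = min(hi, m)
    return lo, hi


def _greedy_ascend(X, weights, seq, event_set, sigma, max_sweeps: int = 1000):
    """Single-event relocation hill climb on the weighted marginal loglik."""
    n = event_set.n_events
    seq = np.asarray(seq, dtype=np.intp).copy()
    sx = 0.5 * (X * X).sum(axis=1)
    best = _weighted_score(X, weights, seq, event_set, sigma)
    for _ in range(max_sweeps):
        improved = False
        for event in range(n):
            scores = _relocation_scores(X, sx, weights, seq, event, event_set, sigma)
            j = int(np.argmax(scores))
            if scores[j] > best + 1e-9:
                rest = seq[seq != event]
                seq = np.insert(rest, j, event)
                best = float(scores[j])
                improved = True
        if not improved:
            break
    return seq, best


def optimize_sequence_greedy(X, event_set: EventSet, weights=None, n_startpoints: int = 25,
                             seed=None, init_sequences=None, sigma: float = 1.0):
    """Best sequence over random restarts of greedy single-event relocation.

    ``init_sequences`` (optional list of permutations) are used as
    additional deterministic start points, tried before the random ones.
    Returns (sequence, weighted marginal log-likelihood).
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0 or X.shape[0] == 0:
        raise ValueError("empty data matrix")
    n = event_set.n_events
    if weights is None:
        weights = np.ones(X.shape[0])
    weights = np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    starts = [np.asarray(s, dtype=np.intp) for s in (init_sequences or [])]
    starts += [random_valid_sequence(event_set, rng) for _ in range(n_startpoints)]
    best_seq, best_score = None, -np.inf
    for s0 in starts:
        seq, score = _greedy_ascend(X, weights, s0, event_set, sigma)
        if score > best_score:
            best_seq, best_score = seq, score
    return best_seq, best_score


# ---------------------------------------------------------------------------
# EM for the mixture of sequences
# ---------------------------------------------------------------------------

def _em_refine(X, event_set, sequences, fractions, sigma, em_tol, max_iter=10):
    """Alternate responsibilities / (fractions + weighted greedy) updates."""
    k = len(sequences)
    seqs = [np.asarray(s, dtype=np.intp) for s in sequences]
    fracs = np.asarray(fractions, dtype=float)
    L = np.column_stack([_marginal_loglik_vector(X, s, event_set, sigma) for s in seqs])
    total = _mixture_loglik(L, fracs)
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            logr = L + np.log(fracs)[None, :]
        R = np.exp(logr - logsumexp(logr, axis=1, keepdims=True))
        fracs = R.mean(axis=0)
        fracs = np.maximum(fracs, 1e-12)
        fracs /= fracs.sum()
        for c in range(k):
            seqs[c], _ = _greedy_ascend(X, R[:, c], seqs[c], event_set, sigma,
                                        max_sweeps=3)
            L[:, c] = _marginal_loglik_vector(X, seqs[c], event_set, sigma)
        new_total = _mixture_loglik(L, fracs)
        if new_total - total < em_tol:
            total = max(new_total, total)
            break
        total = new_total
    return seqs, fracs, total, L


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

def mcmc_sample(X, event_set: EventSet, sequences, fractions, n_iters: int = 10000,
                seed=None, sigma: float = 1.0, burn_frac: float = 0.1,
                sample_fractions: bool = True, fraction_step: float = 0.05):
    """Metropolis sampler over (sequences, fractions) from an EM optimum.

    Proposals alternate between relocating one uniformly chosen event of a
    uniformly chosen subtype to a uniform new position, and a Gaussian
    perturbation of the fractions on the softmax scale.  Acceptance is
    min(1, exp(delta total loglik)) under uniform priors.  Iterations
    after the burn-in fraction are recorded (every iteration).

    Returns (sequence_samples (M,k,N), fraction_samples (M,k),
    loglik_samples (M,), acceptance_rate).
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    k = len(sequences)
    n = event_set.n_events
    seqs = np.stack([np.asarray(s, dtype=np.intp) for s in sequences])
    eta = np.log(np.maximum(np.asarray(fractions, dtype=float), 1e-12))
    fracs = np.exp(eta - logsumexp(eta))
    L = np.column_stack([_marginal_loglik_vector(X, s, event_set, sigma) for s in seqs])
    total = _mixture_loglik(L, fracs)

    burn = int(np.floor(burn_frac * n_iters))
    seq_samples = np.empty((n_iters - burn, k, n), dtype=np.intp)
    frac_samples = np.empty((n_iters - burn, k))
    ll_samples = np.empty(n_iters - burn)
    n_accept = 0
    do_frac = sample_fractions and k > 1

    for it in range(n_iters):
        move_fracs = do_frac and it % 2 == 1
        if move_fracs:
            eta_new = eta + rng.normal(0.0, fraction_step, size=k)
            fr_new = np.exp(eta_new - logsumexp(eta_new))
            new_total = _mixture_loglik(L, fr_new)
            if np.log(rng.uniform()) < new_total - total:
                eta, fracs, total = eta_new, fr_new, new_total
                n_accept += 1
        else:
            c = int(rng.integers(k))
            pos = int(rng.integers(n))
            newpos = int(rng.integers(n))
            cand = np.delete(seqs[c], pos)
            cand = np.insert(cand, newpos, seqs[c][pos])
            if not is_valid_sequence(cand, event_set):
                # invalid orderings carry zero prior mass: auto-reject
                if it >= burn:
                    seq_samples[it - burn] = seqs
                    frac_samples[it - burn] = fracs
                    ll_samples[it - burn] = total
                continue
            Lc = _marginal_loglik_vector(X, cand, event_set, sigma)
            L_new = L.copy()
            L_new[:, c] = Lc
            new_total = _mixture_loglik(L_new, fracs)
            if np.log(rng.uniform()) < new_total - total:
                seqs = seqs.copy()
                seqs[c] = cand
                L, total = L_new, new_total
                n_accept += 1
        if it >= burn:
            seq_samples[it - burn] = seqs
            frac_samples[it - burn] = fracs
            ll_samples[it - burn] = total
    return seq_samples, frac_samples, ll_samples, n_accept / max(n_iters, 1)


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------

@dataclass
class SustainFit:
    """Fitted k-subtype model with MCMC uncertainty samples."""

    event_set: EventSet
    k: int
    ml_sequences: np.ndarray          # (k, N)
    ml_fractions: np.ndarray          # (k,)
    log_likelihood: float             # training mixture loglik at the ML point
    mcmc_sequence_samples: np.ndarray  # (M, k, N)
    mcmc_fraction_samples: np.ndarray  # (M, k)
    mcmc_loglik_samples: np.ndarray    # (M,)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        has_samples = self.mcmc_sequence_samples.shape[0] > 0
        pvd = positional_variance(self) if has_samples else []
        return {
            "k": self.k,
            "event_set": self.event_set.to_dict(),
            "ml_sequences": self.ml_sequences.tolist(),
            "ml_fractions": self.ml_fractions.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_mcmc_samples": int(self.mcmc_sequence_samples.shape[0]),
            "mean_fractions": (self.mcmc_fraction_samples.mean(axis=0).tolist()
                               if has_samples else self.ml_fractions.tolist()),
            "positional_variance": [m.tolist() for m in pvd],
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SustainFit":
        """Rebuild a point-estimate fit (ML sequences/fractions only; the
        MCMC samples are not serialized)."""
        es = EventSet.from_dict(d["event_set"])
        k = int(d["k"])
        n = es.n_events
        return cls(
            event_set=es, k=k,
            ml_sequences=np.asarray(d["ml_sequences"], dtype=np.intp),
            ml_fractions=np.asarray(d["ml_fractions"], dtype=float),
            log_likelihood=float(d["log_likelihood"]),
            mcmc_sequence_samples=np.zeros((0, k, n), dtype=np.intp),
            mcmc_fraction_samples=np.zeros((0, k)),
            mcmc_loglik_samples=np.zeros(0),
            config=d.get("config", {}),
        )


@dataclass
class CvicResult:
    """CVIC(k) = -2 * sum over all held-out subjects of the log of the
    MCMC-sample-averaged mixture likelihood; ``fold_gibbs`` additionally
    records the sample-average of the log likelihood (<= the predictive
    version by Jensen; the gap reflects posterior spread)."""

    cvic: dict                      # k -> CVIC value
    fold_loglik: dict               # k -> list of per-fold out-of-sample logliks
    selected_k: int
    fold_assignment: np.ndarray     # per-subject fold index
    fold_gibbs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cvic": {int(k): float(v) for k, v in self.cvic.items()},
            "fold_loglik": {int(k): [float(x) for x in v] for k, v in self.fold_loglik.items()},
            "selected_k": int(self.selected_k),
        }


@dataclass
class SubjectAssignment:
    """Posterior over (subtype, stage) for one observation."""

    posterior: np.ndarray   # (k, N+1), sums to 1
    ml_subtype: int         # 0-based subtype index
    ml_stage: int
    subtype_prob: float     # stage-marginalized posterior of ml_subtype
    stage_prob: float       # posterior of ml_stage given ml_subtype

    @property
    def s0_flag(self) -> bool:
        return self.ml_stage == 0

    @property
    def label(self) -> str:
        return "S0" if self.s0_flag else f"S{self.ml_subtype + 1}"


# ---------------------------------------------------------------------------
# hierarchical fitting
# ---------------------------------------------------------------------------

def fit_sustain(X, event_set: EventSet, max_subtypes: int = 3, n_startpoints: int = 25,
                em_tol: float = 1e-6, mcmc_iters: int = 10000, seed=None,
                sigma: float = 1.0, n_split_restarts: int = 5,
                split_startpoints: int = 3, n_runs: int = 1) -> list[SustainFit]:
    """Fit models for k = 1..max_subtypes hierarchically.

    k = 1 is fitted by greedy ascent from ``n_startpoints`` random starts.
    Each k -> k+1 step tries 2-way splits of every existing cluster's
    ML-assigned members (``n_split_restarts`` random halvings plus a
    2-means halving, each half refitted by greedy), keeps the EM-refined
    candidate with the highest total likelihood, then refines uncertainty
    by MCMC.  The ML point of each fit is the best state visited by EM or
    MCMC.  ``n_runs`` > 1 repeats the whole hierarchy from independent
    seeds and keeps, per k, the run with the higher training likelihood —
    a guard against hierarchies stuck in a poor basin.
    """
    if n_runs > 1:
        run_seeds = np.random.SeedSequence(seed).spawn(n_runs)
        best: dict[int, SustainFit] = {}
        for rs in run_seeds:
            fits = fit_sustain(X, event_set, max_subtypes=max_subtypes,
                               n_startpoints=n_startpoints, em_tol=em_tol,
                               mcmc_iters=mcmc_iters,
                               seed=int(rs.generate_state(1)[0]), sigma=sigma,
                               n_split_restarts=n_split_restarts,
                               split_startpoints=split_startpoints, n_runs=1)
            for f in fits:
                if f.k not in best or f.log_likelihood > best[f.k].log_likelihood:
                    best[f.k] = f
        return [best[k] for k in sorted(best)]
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 subjects to fit")
    if not np.all(np.isfinite(X)):
        raise ValueError("data matrix contains non-finite values")
    rng = np.random.default_rng(seed)
    fits: list[SustainFit] = []

    seq1, _ = optimize_sequence_greedy(
        X, event_set, n_startpoints=n_startpoints,
        seed=rng.integers(2**31), sigma=sigma)
    seqs = [seq1]
    fracs = np.array([1.0])
    seqs, fracs, total, L = _em_refine(X, event_set, seqs, fracs, sigma, em_tol)

    for k in range(1, max_subtypes + 1):
        if k > 1:
            seqs, fracs, total, L = _split_step(
                X, event_set, seqs, fracs, L, sigma, em_tol, rng,
                n_split_restarts, split_startpoints)
            if seqs is None:
                break
            # global restart guard: a k-means(k) initialization sometimes
            # escapes basins the hierarchical split cannot
            alt = _kmeans_candidate(X, event_set, k, sigma, em_tol, rng,
                                    split_startpoints)
            if alt is not None and alt[2] > total:
                seqs, fracs, total, L = alt
        seq_s, frac_s, ll_s, _ = mcmc_sample(
            X, event_set, seqs, fracs, n_iters=mcmc_iters,
            seed=rng.integers(2**31), sigma=sigma)
        # ML point: best of EM optimum and MCMC samples; when MCMC found a
        # better basin, polish it with a short EM restart
        best_idx = int(np.argmax(ll_s))
        if ll_s[best_idx] > total:
            p_seqs, p_fracs, p_total, _ = _em_refine(
                X, event_set, list(seq_s[best_idx]), frac_s[best_idx],
                sigma, em_tol, max_iter=5)
            if p_total >= ll_s[best_idx]:
                ml_seqs = np.stack(p_seqs)
                ml_fracs = np.asarray(p_fracs)
                ml_total = float(p_total)
            else:
                ml_seqs = seq_s[best_idx].copy()
                ml_fracs = frac_s[best_idx].copy()
                ml_total = float(ll_s[best_idx])
        else:
            ml_seqs = np.stack(seqs)
            ml_fracs = np.asarray(fracs)
            ml_total = float(total)
        fits.append(SustainFit(
            event_set=event_set, k=k,
            ml_sequences=ml_seqs, ml_fractions=ml_fracs, log_likelihood=ml_total,
            mcmc_sequence_samples=seq_s, mcmc_fraction_samples=frac_s,
            mcmc_loglik_samples=ll_s,
            config={"n_startpoints": n_startpoints, "em_tol": em_tol,
                    "mcmc_iters": mcmc_iters, "sigma": sigma, "seed": seed},
        ))
        seqs = [s.copy() for s in ml_seqs]
        fracs = ml_fracs.copy()
        L = np.column_stack([_marginal_loglik_vector(X, s, event_set, sigma) for s in seqs])
        total = ml_total
    return fits


def _kmeans_candidate(X, event_set, k, sigma, em_tol, rng, split_startpoints):
    """EM-refined model seeded from a k-means partition of the subjects."""
    try:
        from sklearn.cluster import KMeans
        # cluster on row-normalized profiles: raw distances are dominated
        # by overall severity (stage), the direction carries the subtype
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        Xn = X / np.maximum(norms, 1.0)
        km = KMeans(n_clusters=k, n_init=3,
                    random_state=int(rng.integers(2**31))).fit(Xn)
    except Exception:
        return None
    seqs, fracs = [], []
    for c in range(k):
        members = np.flatnonzero(km.labels_ == c)
        if members.size < 2:
            return None
        s, _ = optimize_sequence_greedy(
            X[members], event_set, n_startpoints=split_startpoints,
            seed=rng.integers(2**31), sigma=sigma)
        seqs.append(s)
        fracs.append(members.size / X.shape[0])
    return _em_refine(X, event_set, seqs, np.asarray(fracs), sigma, em_tol)


def _split_step(X, event_set, seqs, fracs, L, sigma, em_tol, rng,
                n_split_restarts, split_startpoints):
    """Best k+1 model obtained by splitting one of the current clusters."""
    k = len(seqs)
    with np.errstate(divide="ignore"):
        logr = L + np.log(fracs)[None, :]
    hard = np.argmax(logr, axis=1)
    best = (None, None, -np.inf, None)
    for c in range(k):
        members = np.flatnonzero(hard == c)
        if members.size < 4:
            warnings.warn(f"cluster {c} has {members.size} members; split skipped",
                          stacklevel=2)
            continue
        halvings = []
        for _ in range(n_split_restarts):
            perm = rng.permutation(members)
            halvings.append((perm[: members.size // 2], perm[members.size // 2:]))
        # one data-driven halving: 2-means on the members' biomarker rows
        # rescues splits where two merged subtypes defeat random halving
        try:
            from sklearn.cluster import KMeans
            km = KMeans(n_clusters=2, n_init=3,
                        random_state=int(rng.integers(2**31))).fit(X[members])
            h1 = members[km.labels_ == 0]
            h2 = members[km.labels_ == 1]
            if min(h1.size, h2.size) >= 2:
                halvings.append((h1, h2))
        except Exception:
            pass
        for half1, half2 in halvings:
            new_seqs = []
            for half in (half1, half2):
                s, _ = optimize_sequence_greedy(
                    X[half], event_set, n_startpoints=split_startpoints,
                    seed=rng.integers(2**31), init_sequences=[seqs[c]], sigma=sigma)
                new_seqs.append(s)
            cand_seqs = [s for i, s in enumerate(seqs) if i != c] + new_seqs
            cand_fracs = np.array(
                [fracs[i] for i in range(k) if i != c] + [fracs[c] / 2] * 2)
            # cheap screening EM; the winner is refined fully below
            cand = _em_refine(X, event_set, cand_seqs, cand_fracs, sigma, em_tol,
                              max_iter=2)
            if cand[2] > best[2]:
                best = cand
    if best[0] is None:
        warnings.warn("no cluster could be split; stopping hierarchy early", stacklevel=2)
        return None, None, None, None
    return _em_refine(X, event_set, best[0], best[1], sigma, em_tol)


# ---------------------------------------------------------------------------
# diagnostics, model selection, assignment
# ---------------------------------------------------------------------------

def positional_variance(fit: SustainFit) -> list[np.ndarray]:
    """Per subtype, the (N events x N positions) matrix of empirical
    frequencies of each event's sequence position across MCMC samples.
    Rows sum to 1."""
    samples = fit.mcmc_sequence_samples
    if samples.shape[0] == 0:
        raise ValueError("fit has no MCMC samples")
    n = fit.event_set.n_events
    out = []
    for c in range(fit.k):
        mat = np.zeros((n, n))
        # samples[:, c, pos] = event id at that position
        pos_of_event = np.empty_like(samples[:, c, :])
        m = samples.shape[0]
        rows = np.arange(m)[:, None]
        pos_of_event[rows, samples[:, c, :]] = np.arange(n)[None, :]
        for e in range(n):
            mat[e] = np.bincount(pos_of_event[:, e], minlength=n) / m
        out.append(mat)
    return out


def cross_validate_cvic(X, event_set: EventSet, max_subtypes: int = 3, n_folds: int = 8,
                        seed=None, n_startpoints: int = 25, em_tol: float = 1e-6,
                        mcmc_iters: int = 10000, sigma: float = 1.0,
                        n_split_restarts: int = 5, split_startpoints: int = 3,
                        max_eval_samples: int = 100, n_runs: int = 1) -> CvicResult:
    """8-fold (by default) cross-validated information criterion per k.

    Subjects are partitioned into folds once (seeded, unstratified).  For
    each fold and k the model is fitted on the training subjects and each
    held-out subject contributes the log of its average — over (thinned)
    MCMC samples, sequences and fractions jointly — mixture likelihood.
    CVIC(k) = -2 * sum over all held-out subjects; selected k = argmin.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < n_folds:
        raise ValueError("need at least as many subjects as folds")
    rng = np.random.default_rng(seed)
    fold = np.tile(np.arange(n_folds), n // n_folds + 1)[:n]
    fold = fold[rng.permutation(n)]
    if min(np.bincount(fold, minlength=n_folds)) < 2:
        raise ValueError("a fold has fewer than 2 subjects")

    fold_ll: dict[int, list[float]] = {k: [] for k in range(1, max_subtypes + 1)}
    fold_gibbs: dict[int, list[float]] = {k: [] for k in range(1, max_subtypes + 1)}
    for f in range(n_folds):
        train, test = X[fold != f], X[fold == f]
        fits = fit_sustain(train, event_set, max_subtypes=max_subtypes,
                           n_startpoints=n_startpoints, em_tol=em_tol,
                           mcmc_iters=mcmc_iters, seed=rng.integers(2**31),
                           sigma=sigma, n_split_restarts=n_split_restarts,
                           split_startpoints=split_startpoints, n_runs=n_runs)
        for fit in fits:
            predictive, gibbs = _out_of_sample_loglik(test, fit, sigma, max_eval_samples)
            fold_ll[fit.k].append(predictive)
            fold_gibbs[fit.k].append(gibbs)
    cvic = {k: -2.0 * float(np.sum(v)) for k, v in fold_ll.items() if v}
    ks = sorted(cvic)
    selected = ks[int(np.argmin([cvic[k] for k in ks]))]
    return CvicResult(cvic=cvic, fold_loglik=fold_ll, selected_k=selected,
                      fold_assignment=fold, fold_gibbs=fold_gibbs)


def _out_of_sample_loglik(X, fit: SustainFit, sigma: float, max_eval_samples: int):
    """Held-out scores under (thinned) MCMC samples.

    Returns ``(predictive, gibbs)``: ``predictive`` sums over subjects the
    log of the sample-averaged mixture likelihood; ``gibbs`` averages over
    samples the summed log mixture likelihood (always <= predictive by
    Jensen; the gap grows with posterior spread)."""
    m = fit.mcmc_sequence_samples.shape[0]
    idx = np.unique(np.linspace(0, m - 1, min(m, max_eval_samples)).astype(int))
    per_sample = np.empty((X.shape[0], idx.size))
    for j, i in enumerate(idx):
        fr = fit.mcmc_fraction_samples[i]
        terms = np.empty((X.shape[0], fit.k))
        for c in range(fit.k):
            L = _marginal_loglik_vector(X, fit.mcmc_sequence_samples[i, c],
                                        fit.event_set, sigma)
            with np.errstate(divide="ignore"):
                terms[:, c] = L + np.log(max(fr[c], 1e-300))
        per_sample[:, j] = logsumexp(terms, axis=1)
    predictive = float((logsumexp(per_sample, axis=1) - np.log(idx.size)).sum())
    gibbs = float(per_sample.sum(axis=0).mean())
    return predictive, gibbs


def assign_subject(x, fit: SustainFit, sigma: float = 1.0) -> SubjectAssignment:
    """MAP (subtype, stage) assignment with the stage-0 -> S0 rule."""
    return assign_subjects(np.asarray(x, dtype=float)[None, :], fit, sigma)[0]


def assign_subjects(X, fit: SustainFit, sigma: float = 1.0) -> list[SubjectAssignment]:
    """Vectorized assignment of each row of ``X``.

    Joint posterior P(c, k | x) ∝ f_c * (1/(N+1)) * exp(conditional
    loglik under S_c at stage k).  ml_subtype maximizes the
    stage-marginalized posterior; ml_stage maximizes P(k | x, ml_subtype).
    Argmax ties break toward the lower index.  ml_stage = 0 flags the
    observation as Normal Appearing (S0).
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("data matrix contains non-finite values")
    n1 = fit.event_set.n_events + 1
    logpost = np.empty((X.shape[0], fit.k, n1))
    for c in range(fit.k):
        mu = trajectory_matrix(fit.ml_sequences[c], fit.event_set)
        with np.errstate(divide="ignore"):
            logpost[:, c, :] = (_stage_loglik_matrix(X, mu, sigma)
                                + np.log(max(fit.ml_fractions[c], 1e-300)) - np.log(n1))
    out = []
    for s in range(X.shape[0]):
        lp = logpost[s]
        post = np.exp(lp - logsumexp(lp))
        post /= post.sum()
        subtype_marg = post.sum(axis=1)
        c_ml = int(np.argmax(subtype_marg))
        stage_given = post[c_ml] / subtype_marg[c_ml]
        k_ml = int(np.argmax(stage_given))
        out.append(SubjectAssignment(
            posterior=post, ml_subtype=c_ml, ml_stage=k_ml,
            subtype_prob=float(subtype_marg[c_ml]),
            stage_prob=float(stage_given[k_ml]),
        ))
    return out
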