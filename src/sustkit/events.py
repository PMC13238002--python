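"""Event catalogue for the z-score event-based subtype/stage model.

An *event* is a (biomarker, threshold) pair: the point along the disease
course at which a biomarker's abnormality crosses a given z level.  The
model operates on the atrophy-positive scale ``d = -w`` so that the
thresholds (typically 1 and 2) are positive numbers, while w-scores keep
the atrophy-negative sign convention everywhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Event",
    "EventSet",
    "build_events",
    "expected_biomarker_value",
    "trajectory_matrix",
    "is_valid_sequence",
    "random_valid_sequence",
]


@dataclass(frozen=True)
class Event:
    biomarker: str
    threshold: float


@dataclass
class EventSet:
    """Ordered catalogue of (biomarker, threshold) events.

    Events are enumerated biomarker-major, then threshold-ascending, so
    for biomarkers ``[a, b]`` with thresholds ``(1, 2)`` the catalogue is
    ``[(a,1), (a,2), (b,1), (b,2)]``.

    Parameters
    ----------
    biomarkers
        Ordered biomarker (ROI) names.
    thresholds
        Per-biomarker strictly increasing z thresholds.
    z_max
        Per-biomarker terminal severity; must be >= the largest threshold.
    """

    biomarkers: list[str]
    thresholds: dict[str, tuple[float, ...]]
    z_max: dict[str, float]
    events: list[Event] = field(init=False)
    # per-event biomarker index, parallel to ``events``
    event_biomarker: np.ndarray = field(init=False, repr=False)
    event_threshold: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for b in self.biomarkers:
            th = tuple(self.thresholds[b])
            if len(th) == 0:
                raise ValueError(f"biomarker {b!r} has no thresholds")
            if any(t2 <= t1 for t1, t2 in zip(th, th[1:])):
                raise ValueError(f"thresholds for {b!r} must be strictly increasing: {th}")
            if th[-1] > self.z_max[b]:
                raise ValueError(
                    f"threshold {th[-1]} exceeds z_max {self.z_max[b]} for biomarker {b!r}"
                )
        self.events = [
            Event(b, float(t)) for b in self.biomarkers for t in self.thresholds[b]
        ]
        bidx = {b: i for i, b in enumerate(self.biomarkers)}
        self.event_biomarker = np.array([bidx[e.biomarker] for e in self.events], dtype=np.intp)
        self.event_threshold = np.array([e.threshold for e in self.events], dtype=float)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarkers)

    def zmax_array(self) -> np.ndarray:
        return np.array([self.z_max[b] for b in self.biomarkers], dtype=float)

    def to_model_scale(self, wscores: pd.DataFrame) -> np.ndarray:
        """Map a w-score table to the atrophy-positive model scale (d = -w)."""
        missing = [b for b in self.biomarkers if b not in wscores.columns]
        if missing:
            raise KeyError(f"w-score table lacks modelled biomarkers: {missing}")
        return -wscores[self.biomarkers].to_numpy(dtype=float)

    def to_dict(self) -> dict:
        return {
            "biomarkers": list(self.biomarkers),
            "thresholds": {b: list(self.thresholds[b]) for b in self.biomarkers},
            "z_max": {b: float(self.z_max[b]) for b in self.biomarkers},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventSet":
        return cls(
            biomarkers=list(d["biomarkers"]),
            thresholds={b: tuple(v) for b, v in d["thresholds"].items()},
            z_max={b: float(v) for b, v in d["z_max"].items()},
        )


def build_events(
    roi_names: list[str],
    thresholds=(1.0, 2.0),
    zmax_rule="auto",
    patient_wscores: pd.DataFrame | None = None,
    *,
    zmax_exceed_level: float = 2.0,
    zmax_exceed_frac: float = 0.05,
) -> EventSet:
    """Construct the event set for a list of ROIs.

    Parameters
    ----------
    roi_names
        Modelled ROI names, in catalogue order.
    thresholds
        Either a single increasing tuple applied to every ROI, or a
        mapping ROI -> tuple.
    zmax_rule
        ``"auto"``: z_max is 3 when at least ``zmax_exceed_frac`` of the
        patients' atrophy-direction w-scores (d = -w) for that ROI exceed
        ``zmax_exceed_level``, else 2 (requires ``patient_wscores``).
        A number: fixed z_max for every ROI.  A mapping: per-ROI z_max.
    patient_wscores
        Baseline patient w-score table, needed only for ``"auto"``.
    """
    roi_names = list(roi_names)
    if isinstance(thresholds, dict):
        th_map = {r: tuple(float(t) for t in thresholds[r]) for r in roi_names}
    else:
        th = tuple(float(t) for t in thresholds)
        th_map = {r: th for r in roi_names}

    if isinstance(zmax_rule, dict):
        zmax = {r: float(zmax_rule[r]) for r in roi_names}
    elif isinstance(zmax_rule, (int, float)):
        zmax = {r: float(zmax_rule) for r in roi_names}
    elif zmax_rule == "auto":
        if patient_wscores is None:
            raise ValueError("zmax_rule='auto' requires patient_wscores")
        zmax = {}
        for r in roi_names:
            d = -patient_wscores[r].to_numpy(dtype=float)
            d = d[np.isfinite(d)]
            frac = float(np.mean(d > zmax_exceed_level)) if d.size else 0.0
            zmax[r] = 3.0 if frac >= zmax_exceed_frac else 2.0
    else:
        raise ValueError(f"unrecognized zmax_rule: {zmax_rule!r}")

    for r in roi_names:
        if th_map[r] and th_map[r][-1] > zmax[r]:
            raise ValueError(
                f"largest threshold {th_map[r][-1]} exceeds resolved z_max {zmax[r]} for {r!r}"
            )
    if not roi_names:
        warnings.warn("empty ROI list: event set has N=0", stacklevel=2)
    return EventSet(biomarkers=roi_names, thresholds=th_map, z_max=zmax)


def is_valid_sequence(sequence: np.ndarray, event_set: EventSet) -> bool:
    """True iff each biomarker's events appear in ascending-threshold order.

    The z-score event model requires a biomarker to cross its lower
    threshold before a higher one; only such permutations yield monotone
    trajectories."""
    seq = np.asarray(sequence, dtype=np.intp)
    n = event_set.n_events
    if seq.shape != (n,) or not np.array_equal(np.sort(seq), np.arange(n)):
        return False
    pos = np.empty(n, dtype=np.intp)
    pos[seq] = np.arange(n)
    for b in range(event_set.n_biomarkers):
        ev_ids = np.flatnonzero(event_set.event_biomarker == b)  # threshold-ascending
        if np.any(np.diff(pos[ev_ids]) <= 0):
            return False
    return True


def random_valid_sequence(event_set: EventSet, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation with same-biomarker events reordered
    ascending, so the result is always a valid sequence."""
    n = event_set.n_events
    seq = rng.permutation(n)
    pos = np.empty(n, dtype=np.intp)
    pos[seq] = np.arange(n)
    for b in range(event_set.n_biomarkers):
        ev_ids = np.flatnonzero(event_set.event_biomarker == b)
        slots = np.sort(pos[ev_ids])
        seq[slots] = ev_ids  # ev_ids are threshold-ascending by construction
    return seq


def trajectory_matrix(sequence: np.ndarray, event_set: EventSet) -> np.ndarray:
    """Expected biomarker values mu[k, b] for stages k = 0..N.

    Piecewise-linear through the anchors (0, 0), (position of each of the
    biomarker's events in ``sequence``, its threshold) and (N + 1, z_max),
    where an event at sequence index i occurs at stage i + 1.  The
    terminal anchor sits at N + 1 so a last-position event never collides
    with it; mu stays <= z_max over the valid stage range.
    """
    seq = np.asarray(sequence, dtype=np.intp)
    n = event_set.n_events
    if not is_valid_sequence(seq, event_set):
        raise ValueError(
            "sequence must be a permutation of all events with ascending "
            "thresholds per biomarker")
    nb = event_set.n_biomarkers
    mu = np.zeros((n + 1, nb))
    stages = np.arange(n + 1, dtype=float)
    # stage at which each event occurs, indexed by event id
    event_stage = np.empty(n, dtype=float)
    event_stage[seq] = np.arange(1, n + 1, dtype=float)
    for b in range(nb):
        ev_ids = np.flatnonzero(event_set.event_biomarker == b)
        xs = event_stage[ev_ids]
        order = np.argsort(xs)
        xp = np.concatenate(([0.0], xs[order], [n + 1.0]))
        fp = np.concatenate(
            ([0.0], event_set.event_threshold[ev_ids][order], [event_set.z_max[event_set.biomarkers[b]]])
        )
        mu[:, b] = np.interp(stages, xp, fp)
    return mu


def expected_biomarker_value(
    sequence: np.ndarray, stage: int, event_set: EventSet, biomarker: str
) -> float:
    """mu_biomarker(stage) for a single biomarker under ``sequence``."""
    if not 0 <= stage <= event_set.n_events:
        raise ValueError(f"stage must lie in [0, {event_set.n_events}]")
    b = event_set.biomarkers.index(biomarker)
    return float(trajectory_matrix(sequence, event_set)[int(stage), b])
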