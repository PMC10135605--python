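"""Transition kinetics and transition-state-theory energetics.

From Viterbi-segmented traces, every adjacent pair of dwell segments yields
a transition event characterized by the mean observed step before and after
the switch and the dwell time in the departing state. Events populate a
transition density plot (TDP); clusters in the TDP correspond to ordered
state pairs and are recovered with k-means followed by a 2D Gaussian
mixture. Dwell times in each cluster are exponential, giving per-pair rates
k_ij, which transition-state theory converts into activation energies

    Ea = -R*T*ln(h*k_ij / (kB*T))

and relative free-energy differences between adjacent states

    dG = -R*T*ln(k_ij / k_ji),

both in kJ/mol at T = 298 K by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.constants import R as GAS_CONSTANT  # J/(mol K)
from scipy.constants import h as PLANCK  # J s
from scipy.constants import k as BOLTZMANN  # J/K
from scipy.optimize import curve_fit
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from sptstates.states import SegmentedTrace

logger = logging.getLogger(__name__)

DEFAULT_TEMPERATURE_K = 298.0


@dataclass
class TransitionEvent:
    particle_id: int
    mean_step_before: float  # um
    mean_step_after: float  # um
    dwell_before: float  # s
    state_before: int
    state_after: int


def extract_transitions(
    segmented_traces: list[SegmentedTrace],
) -> tuple[list[TransitionEvent], list[tuple[int, float]]]:
    """Transition events plus right-censored terminal dwells.

    One event per adjacent segment pair; ``dwell_before`` is the duration of
    the segment being left. The final segment of every trace ends by track
    termination (photobleaching), not by a transition, so it is returned
    separately as a censored (state, duration) observation.
    """
    events: list[TransitionEvent] = []
    censored: list[tuple[int, float]] = []
    for seg_trace in segmented_traces:
        segs = seg_trace.segments
        r = seg_trace.r
        for a, b in zip(segs[:-1], segs[1:]):
            events.append(
                TransitionEvent(
                    particle_id=seg_trace.particle_id,
                    mean_step_before=float(
                        r[a.start_step : a.start_step + a.n_steps].mean()
                    ),
                    mean_step_after=float(
                        r[b.start_step : b.start_step + b.n_steps].mean()
                    ),
                    dwell_before=a.duration,
                    state_before=a.state,
                    state_after=b.state,
                )
            )
        if segs:
            censored.append((segs[-1].state, segs[-1].duration))
    return events, censored


def events_to_frame(events: list[TransitionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "particle_id": [e.particle_id for e in events],
            "mean_step_before": [e.mean_step_before for e in events],
            "mean_step_after": [e.mean_step_after for e in events],
            "dwell_before": [e.dwell_before for e in events],
            "state_before": [e.state_before for e in events],
            "state_after": [e.state_after for e in events],
        }
    )


def cluster_tdp(
    events: list[TransitionEvent],
    n_states: int,
    state_means: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Assign each TDP event to an ordered state pair by clustering.

    K-means with k = n_states*(n_states-1) on (mean_step_before,
    mean_step_after) initializes a 2D Gaussian mixture; events take the
    cluster of maximum responsibility, and clusters are mapped to ordered
    state pairs by proximity of their centres to (state_mean_i,
    state_mean_j).

    Returns an (n_events, 2) integer array of (state_before, state_after)
    assignments.
    """
    n_clusters = n_states * (n_states - 1)
    if len(events) < n_clusters:
        raise ValueError(f"need >= {n_clusters} events for {n_states} states")
    X = np.array([[e.mean_step_before, e.mean_step_after] for e in events])
    state_means = np.asarray(state_means, dtype=float)
    init_pairs = np.array(
        [
            [state_means[i], state_means[j]]
            for i in range(n_states)
            for j in range(n_states)
            if i != j
        ]
    )
    # anchor k-means at the ordered-pair coordinates so each cluster starts
    # on its own off-diagonal TDP blob
    km = KMeans(n_clusters=n_clusters, init=init_pairs, n_init=1,
                random_state=seed).fit(X)
    centers = km.cluster_centers_
    try:
        gmm = GaussianMixture(
            n_components=n_clusters,
            means_init=centers,
            covariance_type="full",
            random_state=seed,
            reg_covar=1e-8,
        ).fit(X)
        labels = gmm.predict(X)
        centers = gmm.means_
    except Exception:
        logger.warning("cluster_tdp: GMM refinement failed; using k-means labels")
        labels = km.labels_

    occupied = np.unique(labels)
    if len(occupied) < n_clusters:
        logger.warning(
            "cluster_tdp: %d of %d clusters empty; remaining clusters absorb them",
            n_clusters - len(occupied), n_clusters,
        )
    pairs = [
        (i, j) for i in range(n_states) for j in range(n_states) if i != j
    ]
    pair_coords = np.array([[state_means[i], state_means[j]] for i, j in pairs])
    # one-to-one cluster <-> ordered-pair mapping by minimum total distance,
    # so no pair loses its cluster to a denser neighbouring blob
    from scipy.optimize import linear_sum_assignment

    dist = np.linalg.norm(centers[:, None, :] - pair_coords[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(dist)
    cluster_pair = {int(c): pairs[int(p)] for c, p in zip(rows, cols)}
    return np.array([cluster_pair[int(c)] for c in labels])


def _binned_decay_rate(dwells: np.ndarray, frame_interval: float | None) -> float:
    """Literal single-exponential decay fit to a dwell-time histogram."""
    width = frame_interval if frame_interval else max(dwells.min(), 1e-3)
    edges = np.arange(0.0, dwells.max() + 2 * width, width)
    counts, edges = np.histogram(dwells, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    p0 = [counts.max(), 1.0 / max(dwells.mean(), 1e-6)]
    popt, _ = curve_fit(
        lambda t, A, k: A * np.exp(-k * t), centers[keep], counts[keep],
        p0=p0, maxfev=10000,
    )
    return float(popt[1])


def fit_rates(
    events: list[TransitionEvent],
    assignments: np.ndarray | None = None,
    censored_dwells: list[tuple[int, float]] | None = None,
    n_states: int | None = None,
    min_events: int = 10,
    method: str = "mle",
    frame_interval: float | None = None,
    min_dwell: float = 0.0,
) -> np.ndarray:
    """Transition-rate matrix k_ij (1/s) from clustered dwell times.

    ``method="mle"`` (default) is the censoring-aware competing-risks
    estimator: the exit rate of state i is (number of observed exits from
    i) / (total time spent in i, censored terminal dwells included), and
    k_ij splits it by the observed branching fractions — equivalently
    ``k_ij = N_ij / T_i``. On a single uncensored cluster this reduces to
    1/mean(dwell). ``method="binned"`` instead fits a single exponential
    decay to each cluster's dwell-time histogram and reports its decay
    constant for that pair (no censoring correction).

    Pairs with fewer than ``min_events`` events get ``k = nan`` and a log
    message. ``min_dwell`` (s) is a sensitivity flag that drops events with
    shorter dwells (e.g. single-frame dwells at the resolution limit);
    the default keeps everything down to one frame.
    """
    if assignments is None:
        assignments = np.array([[e.state_before, e.state_after] for e in events])
    assignments = np.asarray(assignments)
    if min_dwell > 0:
        keep = np.array([e.dwell_before >= min_dwell for e in events])
        events = [e for e, k_ in zip(events, keep) if k_]
        assignments = assignments[keep]
    if n_states is None:
        n_states = int(assignments.max()) + 1
    K = n_states
    dwells = np.array([e.dwell_before for e in events])
    k = np.full((K, K), np.nan)
    np.fill_diagonal(k, 0.0)

    if method == "binned":
        for i in range(K):
            for j in range(K):
                if i == j:
                    continue
                sel = (assignments[:, 0] == i) & (assignments[:, 1] == j)
                if sel.sum() < min_events:
                    logger.info("fit_rates: %d->%d has %d < %d events; omitted",
                                i, j, int(sel.sum()), min_events)
                    continue
                k[i, j] = _binned_decay_rate(dwells[sel], frame_interval)
        return k

    if method != "mle":
        raise ValueError(f"unknown method {method!r}")

    for i in range(K):
        out_i = assignments[:, 0] == i
        n_exit = int(out_i.sum())
        total_time = float(dwells[out_i].sum())
        if censored_dwells:
            total_time += sum(d for s, d in censored_dwells if s == i)
        for j in range(K):
            if i == j:
                continue
            n_ij = int((out_i & (assignments[:, 1] == j)).sum())
            if n_ij < min_events:
                logger.info("fit_rates: %d->%d has %d < %d events; omitted",
                            i, j, n_ij, min_events)
                continue
            if total_time <= 0:
                continue
            k[i, j] = n_ij / total_time
    return k


def energy_barrier(k_ij: float, T: float = DEFAULT_TEMPERATURE_K) -> float:
    """Eyring activation energy (kJ/mol) of a transition with rate ``k_ij``.

    ``Ea = -R*T*ln(h*k_ij/(kB*T))``; positive whenever the rate is below
    the attempt frequency kB*T/h (~6.2e12 1/s at 298 K).
    """
    if not k_ij > 0:
        raise ValueError("rate must be > 0")
    return float(-GAS_CONSTANT * T * np.log(PLANCK * k_ij / (BOLTZMANN * T)) / 1000.0)


def free_energy_difference(
    k_ij: float, k_ji: float, T: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Relative free-energy difference (kJ/mol): ``dG = -R*T*ln(k_ij/k_ji)``.

    Antisymmetric in its rate arguments; zero for a symmetric exchange.
    """
    if not (k_ij > 0 and k_ji > 0):
        raise ValueError("both rates must be > 0")
    return float(-GAS_CONSTANT * T * np.log(k_ij / k_ji) / 1000.0)


@dataclass
class KineticModel:
    """Assembled state diagram: occupancies, rates, and energetics."""

    occupancies: np.ndarray
    k: np.ndarray  # 1/s
    Ea: np.ndarray  # kJ/mol, nan where rate missing
    dG: np.ndarray  # kJ/mol, antisymmetric
    temperature: float
    cycle_dG: float | None = None  # dG_01 + dG_12 + dG_20 for 3 states
    hmm_implied_k: np.ndarray | None = None
    missing_pairs: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "occupancies": self.occupancies.tolist(),
            "rates_per_s": self.k.tolist(),
            "Ea_kJ_mol": self.Ea.tolist(),
            "dG_kJ_mol": self.dG.tolist(),
            "temperature_K": self.temperature,
            "cycle_dG_kJ_mol": self.cycle_dG,
            "missing_pairs": [list(p) for p in self.missing_pairs],
        }
        if self.hmm_implied_k is not None:
            d["hmm_implied_rates_per_s"] = self.hmm_implied_k.tolist()
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, allow_nan=True))


def rates_from_transition_matrix(A: np.ndarray, frame_interval: float) -> np.ndarray:
    """Continuous-time rates implied by a per-frame transition matrix.

    Uses the matrix logarithm ``Q = logm(A)/t``; falls back to the
    first-order approximation ``k_ij = A_ij/t`` if the principal logarithm
    has negative off-diagonal entries.
    """
    from scipy.linalg import logm

    A = np.asarray(A, dtype=float)
    try:
        Q = np.real(logm(A)) / frame_interval
        off = Q[~np.eye(len(A), dtype=bool)]
        if np.any(off < -1e-9):
            raise ValueError
        Q = np.clip(Q, 0.0, None)
    except Exception:
        Q = A / frame_interval
    k = Q.copy()
    np.fill_diagonal(k, 0.0)
    return k


def build_state_diagram(
    occupancies: np.ndarray,
    k: np.ndarray,
    T: float = DEFAULT_TEMPERATURE_K,
    hmm_transition_matrix: np.ndarray | None = None,
    frame_interval: float | None = None,
) -> KineticModel:
    """Assemble the quantitative state diagram from rates and occupancies.

    Computes Ea for every available rate and dG for every ordered pair with
    both rates available; missing rates leave gaps, flagged in
    ``missing_pairs``. For a 3-state model the round-trip dG over the cycle
    0->1->2->0 is reported (zero iff the rates satisfy detailed balance).
    """
    occupancies = np.asarray(occupancies, dtype=float)
    k = np.asarray(k, dtype=float)
    K = len(occupancies)
    Ea = np.full((K, K), np.nan)
    dG = np.full((K, K), np.nan)
    missing = []
    for i in range(K):
        for j in range(K):
            if i == j:
                continue
            if np.isfinite(k[i, j]) and k[i, j] > 0:
                Ea[i, j] = energy_barrier(k[i, j], T)
            else:
                missing.append((i, j))
            if (np.isfinite(k[i, j]) and k[i, j] > 0
                    and np.isfinite(k[j, i]) and k[j, i] > 0):
                dG[i, j] = free_energy_difference(k[i, j], k[j, i], T)
    cycle = None
    if K == 3 and np.isfinite([dG[0, 1], dG[1, 2], dG[2, 0]]).all():
        cycle = float(dG[0, 1] + dG[1, 2] + dG[2, 0])
    hmm_k = None
    if hmm_transition_matrix is not None and frame_interval:
        hmm_k = rates_from_transition_matrix(hmm_transition_matrix, frame_interval)
    if missing:
        logger.warning("build_state_diagram: missing rates for pairs %s", missing)
    return KineticModel(
        occupancies=occupancies, k=k, Ea=Ea, dG=dG, temperature=T,
        cycle_dG=cycle, hmm_implied_k=hmm_k, missing_pairs=missing,
    )


def stationary_from_rates(k: np.ndarray) -> np.ndarray:
    """Stationary distribution of the continuous-time chain with rates k."""
    k = np.asarray(k, dtype=float)
    q = np.where(np.isfinite(k), k, 0.0).copy()
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    w, v = np.linalg.eig(q.T)
    i = int(np.argmin(np.abs(w)))
    pi = np.abs(np.real(v[:, i]))
    return pi / pi.sum()
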