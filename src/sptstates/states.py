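"""Hidden Markov modelling of step-length traces with gamma emissions.

One model is shared across all traces of a condition: a per-frame Markov
chain over K mobility states, each emitting the observed step length from
its own gamma distribution. Training is Baum-Welch (EM with scaled
forward-backward over every trace jointly), model order is chosen by BIC
over 1-4 states, and traces are segmented with the Viterbi decoder so that
dwell segments are contiguous.

States are always sorted by increasing mean step (shape*scale), which makes
the labels identifiable across runs: for a 3-state model state 0 is the
immobile state, state 1 the slow and state 2 the fast state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import gamma as gamma_dist

from sptstates._gamma import weighted_gamma_mle
from sptstates.linking import StepTrace

logger = logging.getLogger(__name__)

#: Steps of exactly zero are floored to this value (um) so the gamma
#: density stays finite; well below any physical localization error.
STEP_FLOOR_UM = 1e-4


@dataclass
class GammaEmission:
    shape: float
    scale: float  # um

    @property
    def mean(self) -> float:
        return self.shape * self.scale


@dataclass
class HMMModel:
    n_states: int
    initial_probs: np.ndarray
    transition_matrix: np.ndarray  # per-frame probabilities, rows sum to 1
    emissions: list[GammaEmission]
    log_likelihood: float
    n_params: int
    bic: float
    n_observations: int
    converged: bool
    ll_history: np.ndarray = field(repr=False, default=None)

    @property
    def state_means(self) -> np.ndarray:
        return np.array([e.mean for e in self.emissions])

    def to_json(self, path: str | Path) -> None:
        d = {
            "n_states": self.n_states,
            "initial_probs": self.initial_probs.tolist(),
            "transition_matrix": self.transition_matrix.tolist(),
            "emissions": [asdict(e) for e in self.emissions],
            "log_likelihood": self.log_likelihood,
            "n_params": self.n_params,
            "bic": self.bic,
            "n_observations": self.n_observations,
            "converged": self.converged,
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "HMMModel":
        d = json.loads(Path(path).read_text())
        return cls(
            n_states=d["n_states"],
            initial_probs=np.asarray(d["initial_probs"]),
            transition_matrix=np.asarray(d["transition_matrix"]),
            emissions=[GammaEmission(**e) for e in d["emissions"]],
            log_likelihood=d["log_likelihood"],
            n_params=d["n_params"],
            bic=d["bic"],
            n_observations=d["n_observations"],
            converged=d["converged"],
        )


@dataclass
class Segment:
    state: int
    start_step: int
    n_steps: int
    duration: float  # s


@dataclass
class SegmentedTrace:
    particle_id: int
    states: np.ndarray  # Viterbi state per step
    segments: list[Segment]
    idealized_r: np.ndarray  # state mean step per step, um
    r: np.ndarray  # observed steps, um
    t: float  # frame interval, s


def _pack(step_traces: list[StepTrace]) -> tuple[np.ndarray, np.ndarray]:
    lens = np.array([len(tr.r) for tr in step_traces])
    R = np.full((len(step_traces), int(lens.max())), np.nan)
    for i, tr in enumerate(step_traces):
        R[i, : lens[i]] = np.maximum(tr.r, STEP_FLOOR_UM)
    return R, lens


def _log_emissions(R: np.ndarray, shapes: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """(N, T, K) log gamma densities; padded cells are 0 (emit nothing)."""
    N, T = R.shape
    K = len(shapes)
    logB = np.zeros((N, T, K))
    valid = ~np.isnan(R)
    rv = R[valid]
    for k in range(K):
        col = np.zeros((N, T))
        col[valid] = gamma_dist.logpdf(rv, shapes[k], scale=scales[k])
        logB[:, :, k] = col
    return logB


def _forward_backward(R, lens, pi, A, shapes, scales):
    """Scaled forward-backward over all traces jointly.

    Returns (log_likelihood, posteriors (N,T,K), xi_sum (K,K),
    initial posterior (N,K)).
    """
    N, T = R.shape
    K = len(pi)
    logB = _log_emissions(R, shapes, scales)
    # scale emissions per (n, t) for numerical range, fold into c
    bmax = logB.max(axis=2, keepdims=True)
    B = np.exp(logB - bmax)
    bmax = bmax[:, :, 0]

    alphas = np.empty((N, T, K))
    logc = np.zeros((N, T))
    a = pi[None, :] * B[:, 0, :]
    c = a.sum(axis=1)
    a /= c[:, None]
    alphas[:, 0] = a
    logc[:, 0] = np.log(c) + bmax[:, 0]
    for t in range(1, T):
        active = lens > t
        if not active.any():
            break
        a_new = (alphas[active, t - 1] @ A) * B[active, t, :]
        c = a_new.sum(axis=1)
        a_new /= c[:, None]
        alphas[active, t] = a_new
        logc[active, t] = np.log(c) + bmax[active, t]
    ll = float(logc.sum())

    xi_sum = np.zeros((K, K))
    last = lens - 1
    # scaled beta; each trace's final step has beta = 1
    beta_full = np.zeros((N, T, K))
    beta_full[np.arange(N), last, :] = 1.0
    for t in range(T - 2, -1, -1):
        active = lens > t + 1
        if not active.any():
            continue
        bb = B[active, t + 1, :] * beta_full[active, t + 1, :]
        # xi contribution at transition t -> t+1
        al = alphas[active, t]
        ctp = np.exp(logc[active, t + 1] - bmax[active, t + 1])  # scaled-c
        xi = (al[:, :, None] * A[None, :, :] * bb[:, None, :]) / ctp[:, None, None]
        xi_sum += xi.sum(axis=0)
        beta_t = (bb / ctp[:, None]) @ A.T
        beta_full[active, t, :] = beta_t
    post = alphas * beta_full
    # zero out padding
    valid = ~np.isnan(R)
    post[~valid] = 0.0
    gamma0 = post[:, 0, :]
    return ll, post, xi_sum, gamma0


def _init_params(R: np.ndarray, K: int, rng: np.random.Generator, jitter: float = 0.0):
    """Quantile-split method-of-moments initialization on pooled steps."""
    x = np.sort(R[~np.isnan(R)])
    blocks = np.array_split(x, K)
    shapes = np.empty(K)
    scales = np.empty(K)
    for k, b in enumerate(blocks):
        m, v = b.mean(), max(b.var(), 1e-12)
        shapes[k] = np.clip(m**2 / v, 0.05, 1e6)
        scales[k] = max(v / m, 1e-9)
    if jitter > 0:
        shapes *= np.exp(rng.normal(0, jitter, K))
        scales *= np.exp(rng.normal(0, jitter, K))
    pi = np.full(K, 1.0 / K)
    A = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(A, 0.9)
    if K == 1:
        A = np.ones((1, 1))
    return pi, A, shapes, scales


def fit_hmm(
    step_traces: list[StepTrace],
    n_states: int,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> HMMModel:
    """Baum-Welch fit of a shared gamma-emission HMM over many traces.

    The log-likelihood is non-decreasing over iterations (available in
    ``ll_history``); convergence is a relative change below ``tol``. If an
    emission collapses (scale -> 0), training restarts with jittered
    initialization, up to 5 times.
    """
    if not 1 <= n_states <= 4:
        raise ValueError("n_states must be in 1..4")
    if len(step_traces) < 1:
        raise ValueError("need at least one step trace")
    R, lens = _pack(step_traces)
    n_obs = int(lens.sum())
    K = n_states
    rng = np.random.default_rng(seed)

    last_err = None
    for attempt in range(6):
        pi, A, shapes, scales = _init_params(R, K, rng, jitter=0.0 if attempt == 0 else 0.2)
        ll_history = []
        converged = False
        failed = False
        for _ in range(max_iter):
            ll, post, xi_sum, gamma0 = _forward_backward(R, lens, pi, A, shapes, scales)
            if not np.isfinite(ll):
                failed = True
                last_err = "non-finite log-likelihood"
                break
            if ll_history and ll - ll_history[-1] < tol * abs(ll_history[-1]):
                ll_history.append(ll)
                converged = True
                break
            ll_history.append(ll)
            # M-step
            pi = gamma0.mean(axis=0)
            pi = np.clip(pi, 1e-12, None)
            pi /= pi.sum()
            if K > 1:
                rows = xi_sum.sum(axis=1, keepdims=True)
                A = xi_sum / np.clip(rows, 1e-300, None)
                A = np.clip(A, 1e-12, None)
                A /= A.sum(axis=1, keepdims=True)
            valid = ~np.isnan(R)
            rv = R[valid]
            w = post[valid]  # (n_obs, K)
            for k in range(K):
                wk = w[:, k]
                if wk.sum() < 1e-6:
                    failed = True
                    last_err = f"state {k} lost all weight"
                    break
                shapes[k], scales[k] = weighted_gamma_mle(rv, wk)
                if scales[k] < 1e-10 or not np.isfinite(shapes[k]):
                    failed = True
                    last_err = f"emission collapse in state {k}"
                    break
            if failed:
                break
        if not failed:
            break
    else:
        raise RuntimeError(f"HMM fit failed after restarts: {last_err}")

    # identifiability: sort states by mean step ascending
    order = np.argsort(shapes * scales)
    pi = pi[order]
    A = A[np.ix_(order, order)]
    shapes, scales = shapes[order], scales[order]

    n_params = 2 * K + K * (K - 1) + (K - 1)
    ll = ll_history[-1]
    bic = -2.0 * ll + n_params * np.log(n_obs)
    return HMMModel(
        n_states=K,
        initial_probs=pi,
        transition_matrix=A,
        emissions=[GammaEmission(float(a), float(s)) for a, s in zip(shapes, scales)],
        log_likelihood=float(ll),
        n_params=n_params,
        bic=float(bic),
        n_observations=n_obs,
        converged=converged,
        ll_history=np.asarray(ll_history),
    )


def fit_hmm_per_trace(
    step_traces: list[StepTrace],
    n_states: int,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> list[HMMModel]:
    """Independent per-trace HMM fits (one parameter set per trace).

    The shared fit (:func:`fit_hmm`) is the default analysis; per-trace
    fitting trades statistical power for per-molecule heterogeneity and is
    only meaningful for long traces.
    """
    return [
        fit_hmm([tr], n_states, tol=tol, max_iter=max_iter, seed=seed)
        for tr in step_traces
    ]


def select_n_states(
    step_traces: list[StepTrace],
    candidates: tuple[int, ...] = (1, 2, 3, 4),
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> tuple[HMMModel, list[dict]]:
    """Fit every candidate state count and pick the minimum-BIC model.

    Ties (within 1e-9 relative) go to the smaller model. Returns the chosen
    model and the full BIC table.
    """
    table = []
    best = None
    for K in candidates:
        model = fit_hmm(step_traces, K, tol=tol, max_iter=max_iter, seed=seed)
        table.append(
            {
                "n_states": K,
                "bic": model.bic,
                "log_likelihood": model.log_likelihood,
                "converged": model.converged,
            }
        )
        if best is None or model.bic < best.bic - 1e-9 * max(1.0, abs(best.bic)):
            best = model
    return best, table


def viterbi(model: HMMModel, step_trace: StepTrace) -> SegmentedTrace:
    """Most probable state path of one trace, with dwell segments.

    The idealized step of each decoded step is the mean step of its state.
    """
    r = np.maximum(np.asarray(step_trace.r, dtype=float), STEP_FLOOR_UM)
    n = len(r)
    if n == 0:
        raise ValueError("empty step trace")
    K = model.n_states
    logA = np.log(np.clip(model.transition_matrix, 1e-300, None))
    logpi = np.log(np.clip(model.initial_probs, 1e-300, None))
    logB = np.stack(
        [gamma_dist.logpdf(r, e.shape, scale=e.scale) for e in model.emissions], axis=1
    )
    delta = logpi + logB[0]
    back = np.zeros((n, K), dtype=np.int64)
    for t in range(1, n):
        cand = delta[:, None] + logA
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]

    means = model.state_means
    segments = []
    start = 0
    for i in range(1, n + 1):
        if i == n or path[i] != path[start]:
            segments.append(
                Segment(
                    state=int(path[start]),
                    start_step=start,
                    n_steps=i - start,
                    duration=(i - start) * step_trace.t,
                )
            )
            start = i
    return SegmentedTrace(
        particle_id=step_trace.particle_id,
        states=path,
        segments=segments,
        idealized_r=means[path],
        r=np.asarray(step_trace.r, dtype=float),
        t=step_trace.t,
    )


def segment_all(model: HMMModel, step_traces: list[StepTrace]) -> list[SegmentedTrace]:
    return [viterbi(model, tr) for tr in step_traces if len(tr.r)]


def occupancy(segmented_traces: list[SegmentedTrace], n_states: int | None = None) -> np.ndarray:
    """Fraction of all decoded steps spent in each state; sums to 1."""
    if not segmented_traces:
        raise ValueError("no segmented traces")
    if n_states is None:
        n_states = max(int(s.states.max()) for s in segmented_traces) + 1
    counts = np.zeros(n_states)
    for seg in segmented_traces:
        counts += np.bincount(seg.states, minlength=n_states)
    return counts / counts.sum()


@dataclass
class IdealizedStepHistogram:
    density: np.ndarray
    edges: np.ndarray
    gauss_means: np.ndarray | None
    gauss_sigmas: np.ndarray | None
    gauss_weights: np.ndarray | None
    fit_ok: bool


def _three_gauss(x, w1, m1, s1, w2, m2, s2, w3, m3, s3):
    out = 0.0
    for w, m, s in ((w1, m1, s1), (w2, m2, s2), (w3, m3, s3)):
        out = out + w / (np.sqrt(2 * np.pi) * s) * np.exp(-0.5 * ((x - m) / s) ** 2)
    return out


def idealized_step_histogram(
    segmented_traces: list[SegmentedTrace], bins: int = 60
) -> IdealizedStepHistogram:
    """Pooled histogram of idealized steps with a three-Gaussian fit.

    With a shared model the idealized steps concentrate at the K state
    means, so the Gaussian components recover those means. Inputs with
    fewer than three distinct states flag the fit as degenerate but still
    return the histogram.
    """
    pooled = np.concatenate([s.idealized_r for s in segmented_traces])
    density, edges = np.histogram(pooled, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    distinct = np.unique(np.round(pooled, 12))
    if len(distinct) < 3:
        logger.warning("idealized_step_histogram: < 3 distinct state means; fit degenerate")
        return IdealizedStepHistogram(density, edges, None, None, None, False)
    binw = edges[1] - edges[0]
    means0 = np.quantile(distinct, [0.1, 0.5, 0.9]) if len(distinct) > 3 else distinct[:3]
    p0 = []
    for m in means0:
        frac = np.mean(np.abs(pooled - m) < binw)
        p0 += [max(frac, 0.05), m, binw / 2]
    lower = [0, edges[0] - binw, binw / 20] * 3
    upper = [1.5, edges[-1] + binw, edges[-1] - edges[0]] * 3
    p0 = np.clip(p0, lower, upper)
    try:
        popt, _ = curve_fit(
            _three_gauss, centers, density, p0=p0, bounds=(lower, upper),
            maxfev=20000,
        )
        w = popt[0::3]
        m = popt[1::3]
        s = popt[2::3]
        order = np.argsort(m)
        return IdealizedStepHistogram(
            density, edges, m[order], s[order], w[order] / w.sum() * w.sum(), True
        )
    except Exception:
        logger.warning("idealized_step_histogram: three-Gaussian fit failed")
        return IdealizedStepHistogram(density, edges, None, None, None, False)
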