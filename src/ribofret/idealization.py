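"""FRET trajectory computation and hidden-Markov-model idealization.

Traces are reduced to frame-wise FRET efficiency E = I_A / (I_A + I_D) over
their pre-bleach segment, then idealized with a three-state Gaussian-emission
HMM in which transitions between all states are allowed.  Emission means/SDs
default to the published per-species state values and are held fixed (only
the transition matrix and initial distribution are estimated); a free-fit
mode re-estimates the emission parameters as well.

Implementation notes
--------------------
* All recursions (forward, backward, Viterbi) run in log space and are
  vectorized across a padded (n_traces, n_frames) batch; padding frames and
  masked (NaN) frames contribute unit emission likelihood, which leaves the
  per-trace likelihood untouched because transition rows sum to one.
* Baum-Welch accumulates transition statistics only over real time steps of
  each trace and emission statistics only over unmasked frames.
* A variance floor (1e-4) prevents state collapse; hitting it sets
  ``GaussianHMM.variance_floored``.
* Viterbi ties break toward the lowest state index (first argmax).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .synthetic_data import ConformationalModel, Trace
from . import trace_qc

__all__ = [
    "HMMSpec",
    "GaussianHMM",
    "IdealizedPath",
    "compute_fret",
    "fit_hmm",
    "log_likelihood",
    "idealize",
]

_LOG2PI = float(np.log(2.0 * np.pi))
VARIANCE_FLOOR = 1e-4


# ---------------------------------------------------------------------------
# FRET computation
# ---------------------------------------------------------------------------

def compute_fret(
    trace: Trace,
    bleach_frame: int | None | str = "auto",
    intensity_floor_fraction: float = 0.25,
) -> np.ndarray:
    """Frame-wise FRET efficiency over the pre-bleach segment.

    E_t = acceptor_t / (acceptor_t + donor_t).  Frames whose total intensity
    falls below ``intensity_floor_fraction`` of the median pre-bleach total
    (blinks, near-zero totals) are masked as NaN.

    ``bleach_frame="auto"`` takes the simulated ground truth when present and
    otherwise runs photobleach detection; pass an int to override, or None to
    use the full trace.
    """
    if bleach_frame == "auto":
        if trace.truth is not None:
            bleach_frame = trace.truth.bleach_frame
        else:
            bleach_frame, _ = trace_qc.detect_photobleach(trace)
    end = len(trace) if bleach_frame is None else int(bleach_frame)
    if end == 0:
        return np.empty(0)
    donor = np.asarray(trace.donor, dtype=float)[:end]
    acceptor = np.asarray(trace.acceptor, dtype=float)[:end]
    total = donor + acceptor
    floor = intensity_floor_fraction * np.median(total)
    valid = total > max(floor, 1e-12)
    E = np.full(end, np.nan)
    np.divide(acceptor, total, out=E, where=valid)
    return E


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HMMSpec:
    """Configuration of the idealization model and of Baum-Welch."""

    init_means: tuple[float, ...]
    init_sds: tuple[float, ...]
    n_states: int = 3
    transition_init: np.ndarray | None = None
    startprob_init: np.ndarray | None = None
    fix_means: bool = True          # hold emission means AND sds fixed
    max_iterations: int = 50
    tolerance: float = 1e-3

    def __post_init__(self) -> None:
        if len(self.init_means) != self.n_states or len(self.init_sds) != self.n_states:
            raise ValueError("init_means/init_sds must have n_states entries")
        if len(set(self.init_means)) != self.n_states:
            raise ValueError("initial means must be distinct")
        if any(s <= 0 for s in self.init_sds):
            raise ValueError("initial sds must be positive")
        if self.transition_init is not None:
            A = np.asarray(self.transition_init)
            if A.shape != (self.n_states, self.n_states) or not np.allclose(
                    A.sum(axis=1), 1.0):
                raise ValueError("transition_init must be row-stochastic")

    @classmethod
    def for_model(cls, model: ConformationalModel, dark_state: bool = False,
                  **kwargs) -> "HMMSpec":
        """Spec initialized at (and by default fixed to) a species' states.

        ``dark_state=True`` appends a zero-FRET fourth state (for datasets
        where blink-heavy traces were not removed upstream).
        """
        means = tuple(model.means)
        sds = tuple(model.sds)
        if dark_state:
            means = means + (0.02,)
            sds = sds + (0.06,)
            kwargs.setdefault("n_states", 4)
        return cls(init_means=means, init_sds=sds, **kwargs)


@dataclass
class GaussianHMM:
    """A fitted Gaussian-emission HMM."""

    means: np.ndarray
    sds: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    ll_history: list = field(default_factory=list)
    converged: bool = False
    variance_floored: bool = False

    @property
    def n_states(self) -> int:
        return len(self.means)

    def emission_loglik(self, obs: np.ndarray) -> np.ndarray:
        """log N(obs | mean_s, sd_s) with masked (NaN) frames -> 0 for all s."""
        obs = np.asarray(obs, dtype=float)
        x = obs[..., None]
        z = (x - self.means) / self.sds
        logb = -0.5 * z**2 - np.log(self.sds) - 0.5 * _LOG2PI
        return np.where(np.isnan(x), 0.0, logb)


@dataclass(frozen=True)
class IdealizedPath:
    """Per-frame Viterbi assignment of one FRET series."""

    states: np.ndarray
    dwell_segments: tuple[tuple[int, int, int], ...]  # (state, start, length)
    log_likelihood: float  # joint log P(path, observations)

    def __post_init__(self) -> None:
        covered = sum(seg[2] for seg in self.dwell_segments)
        if covered != len(self.states):
            raise ValueError("dwell segments must exactly tile the frame range")


def _segments(states: np.ndarray) -> tuple[tuple[int, int, int], ...]:
    if len(states) == 0:
        return ()
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(states)]])
    return tuple((int(states[a]), int(a), int(b - a)) for a, b in zip(starts, stops))


# ---------------------------------------------------------------------------
# Batched log-space recursions
# ---------------------------------------------------------------------------

def _pad_batch(series_list: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([len(s) for s in series_list])
    T = int(lengths.max())
    obs = np.full((len(series_list), T), np.nan)
    for i, s in enumerate(series_list):
        obs[i, :len(s)] = s
    return obs, lengths


def _forward(logb: np.ndarray, log_a: np.ndarray, log_pi: np.ndarray) -> np.ndarray:
    """alpha[n, t, s] = log P(obs[n, :t+1], state_t = s)."""
    N, T, S = logb.shape
    alpha = np.empty((N, T, S))
    alpha[:, 0] = log_pi + logb[:, 0]
    for t in range(1, T):
        alpha[:, t] = logb[:, t] + logsumexp(
            alpha[:, t - 1, :, None] + log_a[None], axis=1)
    return alpha


def _backward(logb: np.ndarray, log_a: np.ndarray) -> np.ndarray:
    N, T, S = logb.shape
    beta = np.zeros((N, T, S))
    for t in range(T - 2, -1, -1):
        beta[:, t] = logsumexp(
            log_a[None] + (logb[:, t + 1] + beta[:, t + 1])[:, None, :], axis=2)
    return beta


def log_likelihood(fret_series: np.ndarray, hmm: GaussianHMM) -> float:
    """Log observation likelihood via the forward recursion in log space.

    Masked (NaN) frames are marginalized out of the emission model.
    """
    series = np.asarray(fret_series, dtype=float)
    if series.ndim != 1 or len(series) == 0:
        raise ValueError("fret_series must be a non-empty 1-D array")
    logb = hmm.emission_loglik(series)[None]
    alpha = _forward(logb, np.log(hmm.transmat), np.log(hmm.startprob))
    return float(logsumexp(alpha[0, -1]))


# ---------------------------------------------------------------------------
# Baum-Welch
# ---------------------------------------------------------------------------

def fit_hmm(
    fret_series_collection: list[np.ndarray], spec: HMMSpec
) -> GaussianHMM:
    """Fit the HMM to a collection of FRET series by expectation-maximization.

    The transition matrix and initial distribution are shared across all
    series; emission parameters are re-estimated only when
    ``spec.fix_means=False``.  The per-iteration total log-likelihood is
    recorded in ``ll_history`` and is non-decreasing (EM guarantee).
    """
    series_list = [np.asarray(s, dtype=float) for s in fret_series_collection]
    if not series_list:
        raise ValueError("need at least one FRET series")
    if any(len(s) < 2 * spec.n_states for s in series_list):
        raise ValueError(f"every series needs >= {2 * spec.n_states} frames")

    S = spec.n_states
    obs, lengths = _pad_batch(series_list)
    N, T = obs.shape
    # real[n, t]: frame t exists in trace n; unmasked additionally not NaN
    real = np.arange(T)[None, :] < lengths[:, None]
    unmasked = real & ~np.isnan(obs)
    obs0 = np.where(unmasked, obs, 0.0)
    # valid_step[n, t]: the transition t -> t+1 is a real step of trace n
    valid_step = np.arange(T - 1)[None, :] < (lengths - 1)[:, None]

    if spec.transition_init is not None:
        A = np.array(spec.transition_init, dtype=float)
    else:
        A = np.full((S, S), 0.1 / (S - 1))
        np.fill_diagonal(A, 0.9)
    pi = (np.array(spec.startprob_init, dtype=float)
          if spec.startprob_init is not None else np.full(S, 1.0 / S))

    hmm = GaussianHMM(means=np.array(spec.init_means, dtype=float),
                      sds=np.array(spec.init_sds, dtype=float),
                      transmat=A, startprob=pi)

    # EM with scaled (normalized linear-domain) forward-backward: the scaling
    # constants c[n, t] reproduce the log-likelihood as sum(log c), and the
    # sufficient statistics are accumulated on the fly to keep memory at
    # O(N * T * S).
    prev_ll = -np.inf
    for _ in range(spec.max_iterations):
        B = np.where(unmasked[..., None],
                     np.exp(hmm.emission_loglik(obs)), 1.0)
        A = hmm.transmat

        alpha = np.empty((N, T, S))
        c = np.empty((N, T))
        a = hmm.startprob * B[:, 0]
        c[:, 0] = np.maximum(a.sum(axis=1), 1e-300)
        alpha[:, 0] = a / c[:, 0, None]
        for t in range(1, T):
            a = (alpha[:, t - 1] @ A) * B[:, t]
            c[:, t] = np.maximum(a.sum(axis=1), 1e-300)
            alpha[:, t] = a / c[:, t, None]

        logc = np.log(c)
        logc[~real] = 0.0
        ll = float(logc.sum())
        hmm.ll_history.append(ll)

        # backward pass, accumulating xi / gamma statistics
        beta = np.ones((N, S))
        xi_sum = np.zeros((S, S))
        gamma_last = alpha[np.arange(N), lengths - 1] * beta  # beta = 1 there
        wsum = np.zeros(S)
        wx = np.zeros(S)
        wxx = np.zeros(S)
        gamma0 = gamma_last
        for t in range(T - 2, -1, -1):
            bb = B[:, t + 1] * beta / c[:, t + 1, None]
            sel = valid_step[:, t]
            if np.any(sel):
                xi_sum += A * (alpha[sel, t].T @ bb[sel])
            beta = bb @ A.T
            gamma = alpha[:, t] * beta
            if t == 0:
                gamma0 = gamma
            if not spec.fix_means:
                w = np.where(unmasked[:, t, None], gamma, 0.0)
                wsum += w.sum(axis=0)
                wx += w.T @ obs0[:, t]
                wxx += w.T @ obs0[:, t] ** 2
        if not spec.fix_means:
            w = np.where(unmasked[:, -1, None], gamma_last, 0.0)
            wsum += w.sum(axis=0)
            wx += w.T @ obs0[:, -1]
            wxx += w.T @ obs0[:, -1] ** 2

        new_pi = gamma0.sum(axis=0)
        hmm.startprob = new_pi / new_pi.sum()
        hmm.transmat = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True),
                                           1e-300)

        if not spec.fix_means:
            denom = np.maximum(wsum, 1e-300)
            means = wx / denom
            var = wxx / denom - means**2
            if np.any(var < VARIANCE_FLOOR):
                hmm.variance_floored = True
                var = np.maximum(var, VARIANCE_FLOOR)
            hmm.means = means
            hmm.sds = np.sqrt(var)

        if ll - prev_ll < spec.tolerance and np.isfinite(prev_ll):
            hmm.converged = True
            break
        prev_ll = ll
    return hmm


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------

def _viterbi_batch(
    obs: np.ndarray, lengths: np.ndarray, hmm: GaussianHMM
) -> tuple[list[np.ndarray], np.ndarray]:
    """Most-probable state paths for a padded batch.

    Returns per-trace state arrays (trimmed to each trace's length) and the
    joint log-likelihood of each path with its observations.  Ties break to
    the lowest state index.
    """
    N, T = obs.shape
    S = hmm.n_states
    real = np.arange(T)[None, :] < lengths[:, None]
    logb = hmm.emission_loglik(obs)
    logb[~real] = 0.0
    log_a = np.log(hmm.transmat)

    delta = np.empty((N, T, S))
    psi = np.empty((N, T, S), dtype=np.int8)
    delta[:, 0] = np.log(hmm.startprob) + logb[:, 0]
    psi[:, 0] = 0
    for t in range(1, T):
        cand = delta[:, t - 1, :, None] + log_a[None]  # (N, from, to)
        psi[:, t] = np.argmax(cand, axis=1)
        delta[:, t] = np.take_along_axis(
            cand, psi[:, t][:, None, :], axis=1)[:, 0, :] + logb[:, t]

    paths, lls = [], np.empty(N)
    for n in range(N):
        L = int(lengths[n])
        states = np.empty(L, dtype=int)
        states[-1] = int(np.argmax(delta[n, L - 1]))
        lls[n] = float(delta[n, L - 1, states[-1]])
        for t in range(L - 2, -1, -1):
            states[t] = psi[n, t + 1, states[t + 1]]
        paths.append(states)
    return paths, lls


def idealize(fret_series: np.ndarray, hmm: GaussianHMM) -> IdealizedPath:
    """Viterbi idealization of one FRET series under a fitted HMM."""
    series = np.asarray(fret_series, dtype=float)
    if series.ndim != 1 or len(series) == 0:
        raise ValueError("fret_series must be a non-empty 1-D array")
    paths, lls = _viterbi_batch(series[None], np.array([len(series)]), hmm)
    states = paths[0]
    return IdealizedPath(states=states, dwell_segments=_segments(states),
                         log_likelihood=float(lls[0]))


def idealize_many(
    fret_series_collection: list[np.ndarray], hmm: GaussianHMM
) -> list[IdealizedPath]:
    """Batched idealization of many series (same result as per-series calls)."""
    series_list = [np.asarray(s, dtype=float) for s in fret_series_collection]
    obs, lengths = _pad_batch(series_list)
    paths, lls = _viterbi_batch(obs, lengths, hmm)
    return [IdealizedPath(states=s, dwell_segments=_segments(s),
                          log_likelihood=float(ll))
            for s, ll in zip(paths, lls)]
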