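"""Hidden-Markov segmentation of intensity traces and dwell-event extraction.

Each background-subtracted trace is fit with Gaussian-emission HMMs of one
to four states by expectation-maximization (numba-accelerated scaled
forward-backward), and the model order is chosen by Bayesian model
selection using the BIC-penalized likelihood as the evidence score.  Only
traces best fit by the two-state model — state 1 dark, state 2 fluorescent
— represent clean single-molecule recordings: one state means no binding
event, three or more usually mean overlapping molecules.

From each accepted two-state fit, every maximal run of the fluorescent
state becomes a dwell event.  Events are then filtered by the rules the
lifetime analysis requires: traces whose two state means differ by less
than 60 counts are discarded entirely; events overlapping the start or end
of the trace (censored — true duration unknowable) are dropped; dwell
times shorter than 2 s are dropped; and traces with more than two events
are excluded outright.

States are decoded by posterior mode (most probable state per frame), and
events are defined on the higher-mean state, so relabeling never changes
the extracted events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass
class HmmFit:
    """A fitted Gaussian-emission HMM for one trace.

    ``evidence`` is the model-selection score: the maximized log-likelihood
    minus the BIC complexity penalty ``0.5 * p * ln(T)`` with
    ``p = K^2 + 2K - 1`` free parameters.  ``state_means`` are sorted
    ascending and ``state_path`` uses the sorted labels.
    """

    n_states: int
    state_means: np.ndarray
    state_sds: np.ndarray
    transition_matrix: np.ndarray
    startprob: np.ndarray
    state_path: np.ndarray
    log_likelihood: float
    evidence: float
    converged: bool
    collapsed: bool = False  # a state lost all responsibility or sds hit floor


@dataclass(frozen=True)
class DwellEvent:
    """One contiguous fluorescent-state interval, ``[start, end)`` frames."""

    start_frame: int
    end_frame: int
    duration_s: float
    left_censored: bool
    right_censored: bool
    trace_id: int = 0

    @property
    def censored(self) -> bool:
        return self.left_censored or self.right_censored


@numba.njit(cache=True)
def _em_fit(x, means, variances, pi, A, n_iter, tol, var_floor):  # pragma: no cover
    T = x.shape[0]
    K = means.shape[0]
    B = np.empty((T, K))
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    gamma = np.empty((T, K))
    c = np.empty(T)
    loglik = -1e300
    converged = False
    for _ in range(n_iter):
        # emission probabilities, per-frame max-scaled for stability
        logB_shift = 0.0
        for t in range(T):
            m = -1e300
            for k in range(K):
                lb = -0.5 * (x[t] - means[k]) ** 2 / variances[k] - 0.5 * np.log(
                    2.0 * np.pi * variances[k]
                )
                B[t, k] = lb
                if lb > m:
                    m = lb
            for k in range(K):
                B[t, k] = np.exp(B[t, k] - m)
            logB_shift += m
        # forward
        s = 0.0
        for k in range(K):
            alpha[0, k] = pi[k] * B[0, k]
            s += alpha[0, k]
        c[0] = s if s > 0 else 1e-300
        for k in range(K):
            alpha[0, k] /= c[0]
        for t in range(1, T):
            s = 0.0
            for j in range(K):
                a = 0.0
                for i in range(K):
                    a += alpha[t - 1, i] * A[i, j]
                alpha[t, j] = a * B[t, j]
                s += alpha[t, j]
            c[t] = s if s > 0 else 1e-300
            for j in range(K):
                alpha[t, j] /= c[t]
        # backward
        for k in range(K):
            beta[T - 1, k] = 1.0
        for t in range(T - 2, -1, -1):
            for i in range(K):
                b = 0.0
                for j in range(K):
                    b += A[i, j] * B[t + 1, j] * beta[t + 1, j]
            # scale by c[t+1]
                beta[t, i] = b / c[t + 1]
        new_ll = logB_shift
        for t in range(T):
            new_ll += np.log(c[t])
        # posteriors
        for t in range(T):
            s = 0.0
            for k in range(K):
                gamma[t, k] = alpha[t, k] * beta[t, k]
                s += gamma[t, k]
            if s > 0:
                for k in range(K):
                    gamma[t, k] /= s
        # transition expected counts
        xi = np.zeros((K, K))
        for t in range(T - 1):
            s = 0.0
            for i in range(K):
                for j in range(K):
                    s += alpha[t, i] * A[i, j] * B[t + 1, j] * beta[t + 1, j]
            if s <= 0:
                continue
            for i in range(K):
                for j in range(K):
                    xi[i, j] += alpha[t, i] * A[i, j] * B[t + 1, j] * beta[t + 1, j] / s
        # M step
        for k in range(K):
            pi[k] = gamma[0, k]
        for i in range(K):
            rs = 0.0
            for j in range(K):
                rs += xi[i, j]
            if rs > 0:
                for j in range(K):
                    A[i, j] = xi[i, j] / rs
        for k in range(K):
            w = 0.0
            mx = 0.0
            for t in range(T):
                w += gamma[t, k]
                mx += gamma[t, k] * x[t]
            if w > 1e-10:
                means[k] = mx / w
                v = 0.0
                for t in range(T):
                    v += gamma[t, k] * (x[t] - means[k]) ** 2
                variances[k] = max(v / w, var_floor)
        if new_ll - loglik < tol and new_ll >= loglik:
            loglik = new_ll
            converged = True
            break
        loglik = new_ll
    # final posteriors at the last parameter values are in gamma
    return means, variances, pi, A, gamma, loglik, converged


def _initial_params(x: np.ndarray, n_states: int, rng: np.random.Generator | None):
    if rng is None:
        # min-to-max quantiles so rare extreme levels get a component
        means = np.quantile(x, np.linspace(0.0, 1.0, n_states)) if n_states > 1 else np.array(
            [x.mean()]
        )
        means = means.astype(float).copy()
    else:
        # restarts: random data points as means (k-means style seeding)
        means = np.sort(rng.choice(x, size=n_states, replace=False).astype(float))
        means = means + rng.normal(0.0, max(x.std(), 1.0) * 0.05, size=n_states)
    spread = max(x.var() / max(n_states, 1), 1e-6)
    variances = np.full(n_states, spread)
    pi = np.full(n_states, 1.0 / n_states)
    if n_states == 1:
        A = np.ones((1, 1))
    else:
        off = 0.1 / (n_states - 1)
        A = np.full((n_states, n_states), off)
        np.fill_diagonal(A, 0.9)
    return means, variances, pi, A


def _n_params(K: int) -> int:
    # (K-1) start + K(K-1) transitions + K means + K variances
    return K * K + 2 * K - 1


def fit_hmm(
    trace,
    n_states: int,
    n_restarts: int = 5,
    n_iter: int = 300,
    tol: float = 1e-5,
    seed: int = 0,
    sd_floor: float = 1e-3,
) -> HmmFit:
    """Fit a Gaussian-emission HMM with ``n_states`` states to one trace.

    Runs EM from a deterministic quantile-based initialization plus
    ``n_restarts - 1`` seeded perturbations and keeps the best likelihood.
    A constant trace with ``n_states > 1`` still returns a fit, flagged
    ``collapsed``.
    """
    x = np.asarray(getattr(trace, "values", trace), dtype=float)
    if x.ndim != 1:
        raise ValueError("trace must be 1-D")
    if len(x) < 2 * n_states:
        raise ValueError("trace too short for the requested number of states")
    var_floor = sd_floor**2
    if n_states == 1:
        n_restarts = 1  # single-state EM is deterministic (closed form)
    best = None
    for r in range(max(n_restarts, 1)):
        rng = None if r == 0 else np.random.default_rng((seed, r))
        means, variances, pi, A = _initial_params(x, n_states, rng)
        means, variances, pi, A, gamma, ll, conv = _em_fit(
            x, means, variances, pi.copy(), A.copy(), n_iter, tol, var_floor
        )
        if best is None or ll > best[5]:
            best = (means, variances, pi, A, gamma, ll, conv)
    means, variances, pi, A, gamma, ll, conv = best
    order = np.argsort(means)
    means = means[order]
    sds = np.sqrt(variances[order])
    pi = pi[order]
    A = A[np.ix_(order, order)]
    gamma = gamma[:, order]
    path = np.argmax(gamma, axis=1).astype(np.int8)
    occupancy = gamma.sum(axis=0)
    collapsed = bool(
        n_states > 1
        and (occupancy.min() < 1.0 or np.min(np.diff(means)) < 10 * sd_floor)
    )
    evidence = float(ll - 0.5 * _n_params(n_states) * np.log(len(x)))
    return HmmFit(
        n_states=n_states,
        state_means=means,
        state_sds=sds,
        transition_matrix=A,
        startprob=pi,
        state_path=path,
        log_likelihood=float(ll),
        evidence=evidence,
        converged=bool(conv),
        collapsed=collapsed,
    )


def select_model(
    trace,
    orders=(1, 2, 3, 4),
    n_restarts: int = 5,
    seed: int = 0,
) -> tuple[HmmFit, dict[int, float]]:
    """Fit HMMs of each candidate order and return the best by evidence.

    Downstream analysis keeps only traces whose winner has two states.
    """
    fits = {k: fit_hmm(trace, k, n_restarts=n_restarts, seed=seed) for k in orders}
    evidences = {k: f.evidence for k, f in fits.items()}
    best_k = max(orders, key=lambda k: evidences[k])
    return fits[best_k], evidences


def extract_events(
    fit: HmmFit,
    frame_interval_s: float,
    min_state_sep_counts: float = 60.0,
    trace_id: int = 0,
) -> list[DwellEvent]:
    """Turn the fluorescent-state runs of a two-state fit into dwell events.

    If the two state means differ by less than ``min_state_sep_counts`` the
    whole trace is discarded (returns no events): the putative fluorescent
    state is indistinguishable from background.  Censoring flags mark
    events touching the first or last frame.
    """
    if fit.n_states != 2:
        raise ValueError("extract_events requires a two-state fit")
    if fit.state_means[1] - fit.state_means[0] < min_state_sep_counts:
        return []
    path = fit.state_path
    T = len(path)
    events = []
    t = 0
    while t < T:
        if path[t] == 1:
            start = t
            while t < T and path[t] == 1:
                t += 1
            events.append(
                DwellEvent(
                    start_frame=start,
                    end_frame=t,
                    duration_s=(t - start) * frame_interval_s,
                    left_censored=start == 0,
                    right_censored=t == T,
                    trace_id=trace_id,
                )
            )
        else:
            t += 1
    return events


def filter_events(
    events_per_trace: dict[int, list[DwellEvent]],
    min_dwell_s: float = 2.0,
    max_events_per_trace: int = 2,
) -> tuple[list[DwellEvent], dict[str, int]]:
    """Apply the event-level acceptance rules; return accepted events + tally.

    Per trace, the event count compared against ``max_events_per_trace`` is
    the number of uncensored events (before the duration cut); a trace over
    the limit loses all its events.  Otherwise censored events are dropped,
    then events shorter than ``min_dwell_s`` (strictly) are dropped — an
    event of exactly ``min_dwell_s`` is kept.
    """
    accepted: list[DwellEvent] = []
    tally = {
        "traces": len(events_per_trace),
        "events_total": 0,
        "dropped_too_many_events": 0,
        "dropped_censored": 0,
        "dropped_short": 0,
        "accepted": 0,
    }
    for _tid, events in sorted(events_per_trace.items()):
        tally["events_total"] += len(events)
        uncensored = [e for e in events if not e.censored]
        if len(uncensored) > max_events_per_trace:
            tally["dropped_too_many_events"] += len(events)
            continue
        tally["dropped_censored"] += len(events) - len(uncensored)
        for e in uncensored:
            if e.duration_s < min_dwell_s:
                tally["dropped_short"] += 1
            else:
                accepted.append(e)
                tally["accepted"] += 1
    return accepted, tally


def events_to_frame(events_per_trace: dict[int, list[DwellEvent]], accepted) -> pd.DataFrame:
    accepted_set = {(e.trace_id, e.start_frame, e.end_frame) for e in accepted}
    rows = []
    for tid, events in sorted(events_per_trace.items()):
        uncensored = [e for e in events if not e.censored]
        too_many = len(uncensored) > 2
        for e in events:
            key = (e.trace_id, e.start_frame, e.end_frame)
            if key in accepted_set:
                reason = ""
            elif too_many:
                reason = "too_many_events"
            elif e.censored:
                reason = "censored"
            else:
                reason = "short"
            rows.append(
                {
                    "trace_id": tid,
                    "start_frame": e.start_frame,
                    "end_frame": e.end_frame,
                    "duration_s": e.duration_s,
                    "censored": e.censored,
                    "accepted": reason == "",
                    "reject_reason": reason,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "trace_id",
            "start_frame",
            "end_frame",
            "duration_s",
            "censored",
            "accepted",
            "reject_reason",
        ],
    )
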