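"""Gaussian hidden Markov baseline for normalized gaze-speed series.

Fitting uses Baum-Welch EM (via hmmlearn's scaled forward-backward routines)
with package-controlled initialization: emission means at evenly spaced
sample quantiles, pooled-variance emissions, uniform transitions perturbed by
seed-controlled noise, several restarts with the best final log-likelihood
kept, and a relative-change stopping rule.  The forward log-likelihood used
for scoring is implemented here directly (log-space recursion) so it can be
validated independently of the fitting library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM
from scipy.special import logsumexp

from .errors import InsufficientDataError
from .evaluation import sample_js_divergence

VARIANCE_FLOOR = 1e-10


@dataclass
class HMMModel:
    n_states: int
    initial_probs: np.ndarray
    transition: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True

    def __post_init__(self):
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.means = np.asarray(self.means, dtype=float).ravel()
        self.variances = np.asarray(self.variances, dtype=float).ravel()
        self.loglik_trace = np.asarray(self.loglik_trace, dtype=float)
        K = self.n_states
        if self.initial_probs.shape != (K,) or self.transition.shape != (K, K):
            raise ValueError("parameter shapes inconsistent with n_states")
        if abs(self.initial_probs.sum() - 1.0) > 1e-9:
            raise ValueError("initial probabilities must sum to 1")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("emission variances must be positive")

    def to_dict(self) -> dict:
        return {"n_states": self.n_states,
                "initial_probs": self.initial_probs.tolist(),
                "transition": self.transition.tolist(),
                "means": self.means.tolist(),
                "variances": self.variances.tolist(),
                "loglik_trace": self.loglik_trace.tolist(),
                "converged": bool(self.converged)}

    @classmethod
    def from_dict(cls, d: dict) -> "HMMModel":
        return cls(d["n_states"], np.array(d["initial_probs"]),
                   np.array(d["transition"]), np.array(d["means"]),
                   np.array(d["variances"]), np.array(d["loglik_trace"]),
                   d.get("converged", True))


class _TraceMonitor(ConvergenceMonitor):
    """Records every per-iteration log-likelihood and stops on relative
    change (hmmlearn's stock monitor keeps only the last two values and uses
    an absolute threshold)."""

    def __init__(self, tol: float, n_iter: int):
        super().__init__(tol, n_iter, verbose=False)
        self.trace: list[float] = []

    def report(self, log_prob: float) -> None:
        self.trace.append(float(log_prob))
        self.history.append(log_prob)
        self.iter += 1

    @property
    def converged(self) -> bool:
        if self.iter >= self.n_iter:
            return True
        if len(self.trace) < 2:
            return False
        prev, cur = self.trace[-2], self.trace[-1]
        return abs(cur - prev) <= self.tol * max(abs(prev), 1.0)


def fit_baum_welch(y, n_states: int, seed: int = 0, tol: float = 1e-4,
                   max_iter: int = 500, n_restarts: int = 5) -> HMMModel:
    """Fit a Gaussian HMM to a normalized speed series by EM.

    The log-likelihood trace of the best restart is attached to the returned
    model; states with collapsed variance are floored (with a warning) rather
    than allowed to degenerate.
    """
    y = np.asarray(y, dtype=float).ravel()
    K = int(n_states)
    if K < 1:
        raise ValueError("n_states must be >= 1")
    if len(y) < 10 * K:
        raise InsufficientDataError(
            f"need at least {10 * K} observations for {K} states, got {len(y)}")
    X = y[:, None]
    q_means = np.quantile(y, (np.arange(K) + 0.5) / K)
    pooled_var = max(float(y.var()), VARIANCE_FLOOR)

    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        model = GaussianHMM(n_components=K, covariance_type="diag",
                            init_params="", params="stmc", n_iter=max_iter,
                            tol=tol, covars_prior=0.0, covars_weight=0.0,
                            min_covar=VARIANCE_FLOOR)
        model.startprob_ = np.full(K, 1.0 / K)
        A = np.full((K, K), 1.0 / K) + rng.uniform(0.0, 0.1, size=(K, K))
        model.transmat_ = A / A.sum(axis=1, keepdims=True)
        model.means_ = (q_means + rng.normal(0.0, 0.01 * np.sqrt(pooled_var), K))[:, None]
        model.covars_ = np.full((K, 1), pooled_var)
        model.monitor_ = _TraceMonitor(tol, max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X)
        ll = model.monitor_.trace[-1]
        if best is None or ll > best[0]:
            best = (ll, model)

    model = best[1]
    variances = np.array(model.covars_).reshape(K, -1)[:, 0].astype(float)
    if np.any(variances < VARIANCE_FLOOR):
        warnings.warn("emission variance collapsed; applying variance floor")
        variances = np.maximum(variances, VARIANCE_FLOOR)
    monitor = model.monitor_
    return HMMModel(K, model.startprob_, model.transmat_, model.means_.ravel(),
                    variances, np.array(monitor.trace),
                    converged=bool(monitor.converged))


def log_likelihood(model: HMMModel, y) -> float:
    """Exact forward-algorithm log-likelihood (log-space recursion)."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty series")
    var = model.variances
    log_b = (-0.5 * (y[:, None] - model.means) ** 2 / var
             - 0.5 * np.log(2.0 * np.pi * var))
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.initial_probs)
        log_a = np.log(model.transition)
    alpha = log_pi + log_b[0]
    for t in range(1, len(y)):
        alpha = logsumexp(alpha[:, None] + log_a, axis=0) + log_b[t]
    return float(logsumexp(alpha))


def sample_hmm(model: HMMModel, length: int, seed: int = 0,
               max_redraws: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Sample (observations, state path); emissions are per-state Gaussians
    truncated to [0, 1] by resampling (the normalized-speed scale)."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    K = model.n_states
    states = np.empty(length, dtype=int)
    # draw the state path via inverse-CDF lookups
    cum_pi = np.cumsum(model.initial_probs)
    cum_a = np.cumsum(model.transition, axis=1)
    u = rng.random(length)
    states[0] = np.searchsorted(cum_pi, u[0])
    for t in range(1, length):
        states[t] = np.searchsorted(cum_a[states[t - 1]], u[t])
    sd = np.sqrt(model.variances)
    obs = rng.normal(model.means[states], sd[states])
    for _ in range(max_redraws):
        bad = (obs < 0.0) | (obs > 1.0)
        if not bad.any():
            break
        obs[bad] = rng.normal(model.means[states[bad]], sd[states[bad]])
    np.clip(obs, 0.0, 1.0, out=obs)
    return obs, states


def select_state_count(y, candidates=(2, 3, 4, 5), seed: int = 0,
                       sample_length: int | None = None, n_bins: int = 100,
                       **fit_kwargs) -> tuple[pd.DataFrame, int]:
    """For each candidate state count: fit, sample, and score the histogram
    D_JS against the input series.  Returns the table (in candidate order)
    and the divergence-minimizing state count."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    y = np.asarray(y, dtype=float).ravel()
    if sample_length is None:
        sample_length = len(y)
    rows = []
    for k in candidates:
        sub = np.random.SeedSequence(seed, spawn_key=(k,)).generate_state(2) >> 1
        model = fit_baum_welch(y, k, seed=int(sub[0]), **fit_kwargs)
        sample, _ = sample_hmm(model, sample_length, seed=int(sub[1]))
        rows.append({"n_states": k,
                     "D_JS": sample_js_divergence(y, sample, n_bins),
                     "loglik": model.loglik_trace[-1],
                     "converged": model.converged})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["D_JS"].idxmin(), "n_states"])
    return table, best
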