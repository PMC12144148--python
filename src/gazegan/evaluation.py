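"""Comparison metrics and experiment harnesses.

Provides the histogram Jensen-Shannon divergence (base-2 logs, so the value
is bounded by [0, 1]), the autocorrelation function, distribution moment
summaries, the spectral score (mean squared log-magnitude-spectrum error),
epoch-integral efficiency scores, and the lambda sweep harness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DegenerateRangeError
from .losses import spectral_loss

DEFAULT_N_BINS = 100


@dataclass(frozen=True)
class HistogramPair:
    bin_edges: np.ndarray
    P: np.ndarray
    Q: np.ndarray

    def __post_init__(self):
        if len(self.P) != len(self.Q):
            raise ValueError("P and Q must have equal lengths")
        for name, v in (("P", self.P), ("Q", self.Q)):
            if np.any(np.asarray(v) < 0) or abs(np.sum(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector")


def histogram_probs(a, b, n_bins: int = DEFAULT_N_BINS) -> HistogramPair:
    """Equal-width histograms of two sample sets on shared edges spanning the
    pooled range."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both sample sets must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        raise DegenerateRangeError("pooled samples span a zero range")
    edges = np.linspace(lo, hi, n_bins + 1)
    P, _ = np.histogram(a, bins=edges)
    Q, _ = np.histogram(b, bins=edges)
    return HistogramPair(edges, P / a.size, Q / b.size)


def _kl_bits(p: np.ndarray, m: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / m[mask])))


def js_divergence(pair: HistogramPair) -> float:
    """0.5 KL(P||M) + 0.5 KL(Q||M), M = (P+Q)/2, base-2 logs; in [0, 1],
    0 iff P = Q, 1 for disjoint supports (0 log 0 = 0 convention)."""
    P, Q = np.asarray(pair.P, dtype=float), np.asarray(pair.Q, dtype=float)
    M = 0.5 * (P + Q)
    return 0.5 * _kl_bits(P, M) + 0.5 * _kl_bits(Q, M)


def sample_js_divergence(a, b, n_bins: int = DEFAULT_N_BINS) -> float:
    """Convenience wrapper: histogram two pooled sample sets, then D_JS."""
    return js_divergence(histogram_probs(a, b, n_bins))


def acf(x, max_lag: int) -> np.ndarray:
    """ACF(h) = sum_{t<=T-h} (X_t - Xbar)(X_{t+h} - Xbar) / sum_t (X_t - Xbar)^2
    for h = 0..max_lag; ACF(0) = 1 and all values lie in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    T = len(x)
    if T <= max_lag:
        raise ValueError(f"series of length {T} cannot support lag {max_lag}")
    xc = x - x.mean()
    denom = float(np.sum(xc ** 2))
    if denom == 0.0:
        raise DegenerateRangeError("constant series has no autocorrelation")
    return np.array([np.sum(xc[:T - h] * xc[h:]) / denom
                     for h in range(max_lag + 1)])


@dataclass(frozen=True)
class MomentSummary:
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    kurtosis_convention: str = "excess"  # {"excess", "pearson"}


def moment_summary(samples, convention: str = "excess") -> MomentSummary:
    """Population moments (divisor n): mean, SD, skewness m3/m2^1.5 and
    kurtosis m4/m2^2 (- 3 under the default excess convention)."""
    if convention not in ("excess", "pearson"):
        raise ValueError(f"unknown kurtosis convention {convention!r}")
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    sd = float(np.std(x))
    if sd == 0.0:
        raise DegenerateRangeError("constant samples have undefined shape moments")
    return MomentSummary(
        mean=float(np.mean(x)),
        sd=sd,
        skewness=float(scipy.stats.skew(x, bias=True)),
        kurtosis=float(scipy.stats.kurtosis(x, fisher=(convention == "excess"),
                                            bias=True)),
        kurtosis_convention=convention,
    )


def spectral_score(real, fake) -> float:
    """Mean over frequencies of squared log-magnitude-spectrum differences of
    the batch-mean spectra (the spectral loss divided by sequence length)."""
    real = np.atleast_2d(np.asarray(real, dtype=float))
    return spectral_loss(real, fake) / real.shape[1]


@dataclass(frozen=True)
class EfficiencyScore:
    integral_L_spectral: float
    integral_D_JS: float
    mean_epoch_time: float

    @property
    def volume(self) -> float:
        return self.integral_L_spectral * self.integral_D_JS * self.mean_epoch_time


def integral_scores(history, start: int = 100, end: int = 500) -> EfficiencyScore:
    """Trapezoidal integrals of the spectral-loss and D_JS curves over the
    epoch window [start, end], plus the mean wall time per epoch there."""
    records = history.records if hasattr(history, "records") else list(history)
    in_window = [r for r in records if start <= r.epoch <= end]
    epochs = np.array([r.epoch for r in in_window], dtype=float)
    if len(epochs) < 2 or epochs.min() > start or epochs.max() < end:
        raise ValueError(f"history does not cover epochs [{start}, {end}]")
    l_spec = np.array([r.L_spectral for r in in_window])
    d_js = np.array([r.D_JS for r in in_window])
    times = np.array([r.wall_time for r in in_window])
    return EfficiencyScore(
        integral_L_spectral=float(np.trapezoid(l_spec, epochs)),
        integral_D_JS=float(np.trapezoid(d_js, epochs)),
        mean_epoch_time=float(times.mean()),
    )


def lambda_sweep(data, spec, hp_base, lambdas=(0.0, 0.01, 0.05, 0.1, 0.5, 1.0),
                 lrs=(0.0002, 0.0005, 0.001), checkpoints=(100, 250, 500),
                 seeds=(0, 1, 2), holdout=None) -> pd.DataFrame:
    """One training run per (lambda, lr, seed); D_JS recorded at each
    checkpoint epoch.  Returns a tidy table with one row per
    (lambda, lr, seed, checkpoint)."""
    from dataclasses import replace

    from .training import train_gan

    rows = []
    checkpoints = sorted(checkpoints)
    for lam in lambdas:
        for lr in lrs:
            for seed in seeds:
                hp = replace(hp_base, lam=lam, learning_rate=lr,
                             epochs=max(checkpoints), seed=seed)
                history = train_gan(data, spec, hp, holdout)
                by_epoch = {r.epoch: r for r in history.records}
                for ck in checkpoints:
                    rows.append({"lambda": lam, "lr": lr, "seed": seed,
                                 "checkpoint": ck, "D_JS": by_epoch[ck].D_JS,
                                 "L_G": by_epoch[ck].L_G,
                                 "L_final": by_epoch[ck].L_final})
    return pd.DataFrame(rows)


def moment_report(named_samples: dict, convention: str = "excess",
                  reference: str | None = None,
                  n_bins: int = DEFAULT_N_BINS) -> pd.DataFrame:
    """Moment-summary table (one row per sample set) with an optional D_JS
    column against a designated reference set."""
    rows = []
    for name, samples in named_samples.items():
        m = moment_summary(samples, convention)
        row = {"name": name, "mean": m.mean, "sd": m.sd,
               "skewness": m.skewness, "kurtosis": m.kurtosis}
        if reference is not None and name != reference:
            row["D_JS"] = sample_js_divergence(named_samples[reference],
                                               samples, n_bins)
        rows.append(row)
    return pd.DataFrame(rows)
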