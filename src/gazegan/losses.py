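"""Adversarial and spectral training objectives.

The spectral loss compares the batch-mean DFT magnitude spectra of real and
generated sequences on a log scale,

    L_spectral = sum_k [ log(m_real[k] + eps) - log(m_fake[k] + eps) ]^2,

where m[k] is the batch mean of |F(x)_k| and F is the plain (unnormalized)
discrete Fourier transform.  Real and generated mini-batches carry no pairing,
so the comparison is between the two population spectra rather than per-pair.
Logs are natural; a different base only rescales the loss, which the weight
lambda absorbs.

All losses accept either numpy arrays (returning floats, for evaluation) or
autodiff Tensors (returning Tensors, for training); both routes share one
code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .nn import Tensor, as_tensor, clip, log, sqrt

PROB_EPS = 1e-7  # discriminator outputs are clamped to [PROB_EPS, 1 - PROB_EPS]
MAG_TINY = 1e-24  # inside the magnitude sqrt; keeps gradients finite at |F|=0


def dft_magnitudes(x) -> np.ndarray:
    """|F(x)_k| for k = 0..N-1 of a real sequence (unnormalized DFT)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("input must be a non-empty 1-D sequence")
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite values")
    return np.abs(np.fft.fft(x))


@lru_cache(maxsize=8)
def _dft_mats(n: int):
    k = np.arange(n)
    ang = 2.0 * np.pi * np.outer(k, k) / n
    return np.cos(ang), -np.sin(ang)


def _batch(x) -> Tensor:
    t = as_tensor(x)
    if t.ndim == 1:
        t = t.reshape(1, t.shape[0])
    if t.ndim != 2:
        raise ValueError("expected a (batch, seq_len) array")
    return t


def _mean_magnitudes(batch: Tensor) -> Tensor:
    """Batch-mean DFT magnitude spectrum, differentiable."""
    n = batch.shape[1]
    cos_m, sin_m = _dft_mats(n)
    re = batch @ cos_m
    im = batch @ sin_m
    return sqrt(re ** 2 + im ** 2 + MAG_TINY).mean(axis=0)


def _maybe_float(result: Tensor, *inputs):
    if any(isinstance(x, Tensor) and x.requires_grad for x in inputs):
        return result
    return float(result.data)


def spectral_loss(real, fake, eps: float = 1e-8):
    """Sum over frequencies of squared log-magnitude-spectrum differences.

    Batches may differ in size but must share the sequence length; the value
    is 0 exactly when the two batch-mean magnitude spectra coincide.
    """
    r, f = _batch(real), _batch(fake)
    if r.shape[1] != f.shape[1]:
        raise ValueError(f"sequence length mismatch: {r.shape[1]} vs {f.shape[1]}")
    diff = log(_mean_magnitudes(r) + eps) - log(_mean_magnitudes(f) + eps)
    return _maybe_float((diff ** 2).sum(), real, fake)


def generator_adversarial_loss(d_fake):
    """Non-saturating generator objective -mean(log D(G(z)))."""
    d = as_tensor(d_fake)
    if d.data.size == 0:
        raise ValueError("empty probability batch")
    out = -log(clip(d, PROB_EPS, 1.0)).mean()
    return _maybe_float(out, d_fake)


def discriminator_adversarial_loss(d_real, d_fake):
    """Negated discriminator objective, to be minimized:
    -mean(log D(x)) - mean(log(1 - D(G(z)))); real and fake batches may
    differ in size (the two means are independent)."""
    dr, df = as_tensor(d_real), as_tensor(d_fake)
    if dr.data.size == 0 or df.data.size == 0:
        raise ValueError("empty probability batch")
    term_real = -log(clip(dr, PROB_EPS, 1.0)).mean()
    term_fake = -log(clip(1.0 - df, PROB_EPS, 1.0)).mean()
    return _maybe_float(term_real + term_fake, d_real, d_fake)


@dataclass(frozen=True)
class LossBreakdown:
    L_G: float
    L_D: float
    L_spectral: float
    L_final: float
    lam: float


def combined_generator_loss(L_G, L_spec, lam: float, L_D: float = float("nan")):
    """L_final = L_G + lambda * L_spectral; lambda = 0 recovers pure
    adversarial training.  Tensor inputs yield a Tensor L_final; float inputs
    yield a LossBreakdown record."""
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    if isinstance(L_G, Tensor) or isinstance(L_spec, Tensor):
        return as_tensor(L_G) + lam * as_tensor(L_spec)
    return LossBreakdown(L_G=float(L_G), L_D=float(L_D), L_spectral=float(L_spec),
                         L_final=float(L_G) + lam * float(L_spec), lam=float(lam))
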