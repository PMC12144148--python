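"""Alternating adversarial training with spectral regularization.

Each mini-batch performs one discriminator step (minimizing the negated
discriminator objective) followed by one generator step (minimizing
L_G + lambda * L_spectral, with the spectral term computed against the same
real mini-batch).  The spectral term used in training (and logged as
L_spectral) is normalized by the number of frequencies -- the mean squared
log-magnitude-spectrum error -- so that the regularization strength selected
by lambda does not grow with sequence length; the un-normalized sum is
available as ``losses.spectral_loss``.  Epoch-level metrics (D_JS and the spectral score) are
computed on a fixed holdout against a fresh generated sample of equal size,
with normalization layers in inference mode.  All randomness -- weight
initialization, batch shuffling, noise -- derives from the single seed in the
hyperparameters, so runs are bit-reproducible in single-threaded mode.
"""

from __future__ import annotations

import csv
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import losses
from .errors import ConfigError, DivergenceError, InsufficientDataError
from .evaluation import sample_js_divergence, spectral_score
from .gan import ArchitectureSpec, build_discriminator, build_generator, sample_noise
from .nn import Adam, Tensor


@dataclass(frozen=True)
class Hyperparameters:
    """Training settings; the defaults are the full-scale configuration
    (sequence length 200, batch 128, Adam(2e-4, 0.5, 0.999), 256-dim noise,
    500 epochs, lambda = 0.1)."""

    seq_len: int = 200
    batch_size: int = 128
    learning_rate: float = 0.0002
    optimizer: str = "adam"
    beta1: float = 0.5
    beta2: float = 0.999
    noise_dim: int = 256
    epochs: int = 500
    lam: float = 0.1
    seed: int = 0
    eval_every: int = 1

    def __post_init__(self):
        if min(self.seq_len, self.batch_size, self.epochs, self.eval_every) < 1:
            raise ConfigError("seq_len, batch_size, epochs, eval_every must be >= 1")
        if self.learning_rate <= 0 or self.noise_dim < 1:
            raise ConfigError("learning_rate must be > 0 and noise_dim >= 1")
        if self.lam < 0:
            raise ConfigError("lambda must be non-negative")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ConfigError("Adam betas must lie in (0, 1)")
        if self.optimizer.lower() != "adam":
            raise ConfigError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class EpochRecord:
    epoch: int
    L_G: float
    L_D: float
    L_spectral: float
    L_final: float
    D_JS: float
    spectral_score: float
    wall_time: float


@dataclass
class TrainingHistory:
    spec: ArchitectureSpec
    hp: Hyperparameters
    records: list = field(default_factory=list)
    generator: object = None
    discriminator: object = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])


def evaluate_epoch(generator, holdout, n_gen: int, seed: int,
                   n_bins: int = 100) -> tuple[float, float]:
    """(D_JS, spectral score) between pooled holdout values and a freshly
    generated sample of `n_gen` sequences."""
    if n_gen < 1:
        raise ValueError(f"n_gen must be >= 1, got {n_gen}")
    real = holdout.sequences if hasattr(holdout, "sequences") else np.asarray(holdout)
    fake = generator.generate(n_gen, seed=seed)
    d_js = sample_js_divergence(real.ravel(), fake.ravel(), n_bins)
    return d_js, spectral_score(real, fake)


def _as_matrix(data) -> np.ndarray:
    return data.sequences if hasattr(data, "sequences") else np.asarray(data, dtype=float)


def train_gan(data, spec: ArchitectureSpec, hp: Hyperparameters, holdout,
              history_path=None, verbose: bool = False) -> TrainingHistory:
    """Train one GAN variant; returns the per-epoch history with the trained
    generator/discriminator attached.

    `data` and `holdout` are SequenceDatasets (or plain (n, seq_len)
    matrices); the holdout drives per-epoch metrics and never enters the
    gradient updates.  If `history_path` is given, each epoch record is
    appended to a CSV as soon as it exists, so an interrupted run keeps its
    completed epochs.
    """
    X = _as_matrix(data)
    if X.shape[0] < hp.batch_size:
        raise InsufficientDataError(
            f"{X.shape[0]} sequences cannot fill one batch of {hp.batch_size}")
    if X.shape[1] != spec.seq_len or spec.seq_len != hp.seq_len:
        raise ConfigError("data, spec and hyperparameter sequence lengths disagree")
    Xhold = _as_matrix(holdout)
    if Xhold.shape[0] < 1:
        raise InsufficientDataError("holdout must be non-empty")

    root = np.random.SeedSequence(hp.seed)
    g_seed, d_seed, shuffle_seed, noise_seed, eval_seed = root.generate_state(5) >> 1
    G = build_generator(spec, seed=int(g_seed))
    D = build_discriminator(spec, seed=int(d_seed))
    opt_g = Adam(G.parameters(), hp.learning_rate, hp.beta1, hp.beta2)
    opt_d = Adam(D.parameters(), hp.learning_rate, hp.beta1, hp.beta2)
    shuffle_rng = np.random.default_rng(int(shuffle_seed))
    noise_rng = np.random.default_rng(int(noise_seed))

    history = TrainingHistory(spec=spec, hp=hp, generator=G, discriminator=D)
    writer = None
    if history_path is not None:
        fh = open(history_path, "w", newline="")
        writer = (fh, csv.DictWriter(fh, fieldnames=list(
            EpochRecord.__dataclass_fields__)))
        writer[1].writeheader()

    n_batches = X.shape[0] // hp.batch_size
    m = hp.batch_size
    try:
        for epoch in range(1, hp.epochs + 1):
            t0 = time.perf_counter()
            perm = shuffle_rng.permutation(X.shape[0])
            ep_lg = ep_ld = ep_ls = 0.0
            for b in range(n_batches):
                real = X[perm[b * m:(b + 1) * m]]

                # discriminator step on detached generator output
                fake = Tensor(G(Tensor(sample_noise(m, spec, rng=noise_rng))).data)
                d_loss = losses.discriminator_adversarial_loss(
                    D(Tensor(real)), D(fake))
                if not np.isfinite(d_loss.data):
                    raise DivergenceError(epoch, b, "discriminator")
                opt_d.zero_grad()
                d_loss.backward()
                opt_d.step()

                # generator step: adversarial + spectral against this batch
                z = Tensor(sample_noise(m, spec, rng=noise_rng))
                fake2 = G(z)
                g_loss = losses.generator_adversarial_loss(D(fake2))
                # per-frequency mean form of the spectral loss (sum / seq_len)
                s_loss = losses.spectral_loss(Tensor(real), fake2) * (1.0 / spec.seq_len)
                final = losses.combined_generator_loss(g_loss, s_loss, hp.lam)
                if not np.isfinite(final.data):
                    raise DivergenceError(epoch, b, "generator")
                opt_g.zero_grad()
                opt_d.zero_grad()  # D grads from the G step are discarded
                final.backward()
                opt_g.step()

                ep_lg += g_loss.item()
                ep_ld += d_loss.item()
                ep_ls += s_loss.item()

            G.eval()
            D.eval()
            d_js, sc = evaluate_epoch(G, Xhold, n_gen=Xhold.shape[0],
                                      seed=int(eval_seed) + epoch)
            G.train()
            D.train()

            lg, ld, ls = ep_lg / n_batches, ep_ld / n_batches, ep_ls / n_batches
            rec = EpochRecord(epoch=epoch, L_G=lg, L_D=ld, L_spectral=ls,
                              L_final=lg + hp.lam * ls, D_JS=d_js,
                              spectral_score=sc,
                              wall_time=time.perf_counter() - t0)
            history.records.append(rec)
            if writer is not None:
                writer[1].writerow(asdict(rec))
                writer[0].flush()
            if verbose:
                print(f"epoch {epoch:4d}  L_G {lg:.4f}  L_D {ld:.4f}  "
                      f"L_spec {ls:.4f}  D_JS {d_js:.4f}")
    finally:
        if writer is not None:
            writer[0].close()

    G.eval()
    D.eval()
    return history
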