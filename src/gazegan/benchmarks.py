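"""Scaled-down end-to-end benchmark used by the acceptance harness.

The full-scale configuration (200-point sequences, 500 epochs, batch 128)
is far larger than needed to demonstrate the directional claims of interest,
so this benchmark trains the LSTM-CNN variant on 2,000 simulated sequences of
length 64 for 50 epochs with batch 64, once with the spectral regularizer
(lambda = 0.1) and once without (lambda = 0), across several seeds.  Noise
dimensionality is scaled to 64 alongside the sequence length.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gan import ArchitectureSpec
from .hmm import HMMModel, sample_hmm, select_state_count
from .preprocess import (SequenceDataset, apply_normalization, minmax_normalize,
                         segment_sequences)
from .simulate import ScanpathConfig, simulate_velocity_series
from .training import Hyperparameters, train_gan

SCALED_SPEC = ArchitectureSpec(generator_kind="LSTM", discriminator_kind="CNN",
                               seq_len=64, noise_dim=64)


def benchmark_dataset(seed: int, n_train: int = 2000, n_holdout: int = 256,
                      seq_len: int = 64) -> tuple[SequenceDataset, SequenceDataset]:
    """Simulate one long gaze-speed series and split it into train/holdout
    segment sets; min-max parameters are fitted on the training portion only
    and reused (with clipping) for the holdout."""
    total = (n_train + n_holdout) * seq_len + 2 * seq_len
    cfg = ScanpathConfig(total_duration=total, seed=seed)
    v = simulate_velocity_series(cfg).values
    split = n_train * seq_len
    norm_train, params = minmax_normalize(v[:split])
    norm_hold = apply_normalization(v[split:], params)
    train = segment_sequences(norm_train, seq_len, provenance=params)
    hold = segment_sequences(norm_hold, seq_len, provenance=params)
    hold = SequenceDataset(hold.sequences[:n_holdout], seq_len, provenance=params)
    return train, hold


#: Ground truth for the state-count selection experiment: four well-separated
#: speed regimes with sticky transitions.
SELECTION_TRUTH = HMMModel(
    4, [0.25, 0.25, 0.25, 0.25],
    [[0.90, 0.04, 0.03, 0.03],
     [0.05, 0.85, 0.05, 0.05],
     [0.03, 0.07, 0.85, 0.05],
     [0.04, 0.03, 0.03, 0.90]],
    [0.10, 0.35, 0.60, 0.85], [0.03 ** 2] * 4)


def state_selection_benchmark(seed: int, n_seeds: int = 3, series_length: int = 20_000,
                              sample_length: int = 200_000,
                              candidates=(2, 3, 4, 5)) -> pd.DataFrame:
    """Self-consistency check of the state-count selection harness: draw data
    from the known four-state model and record which candidate count minimizes
    the histogram divergence, per seed."""
    rows = []
    for i in range(n_seeds):
        sub = np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(2) >> 1
        y, _ = sample_hmm(SELECTION_TRUTH, series_length, seed=int(sub[0]))
        table, best = select_state_count(y, candidates, seed=int(sub[1]),
                                         sample_length=sample_length)
        rows.append({"seed_index": i, "best_n_states": best,
                     **{f"djs_{k}": d for k, d in zip(table["n_states"],
                                                      table["D_JS"])}})
    return pd.DataFrame(rows)


def scaled_gan_benchmark(seed: int, lambdas=(0.0, 0.1), n_seeds: int = 3,
                         epochs: int = 50, batch_size: int = 64,
                         verbose: bool = False) -> pd.DataFrame:
    """Train the scaled LSTM-CNN benchmark for each (seed, lambda) pair.

    Returns one row per run with the first- and final-epoch D_JS and
    spectral score.
    """
    rows = []
    for i in range(n_seeds):
        run_seed = int(np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0] >> 1)
        train, hold = benchmark_dataset(run_seed)
        for lam in lambdas:
            hp = Hyperparameters(seq_len=SCALED_SPEC.seq_len, batch_size=batch_size,
                                 noise_dim=SCALED_SPEC.noise_dim, epochs=epochs,
                                 lam=lam, seed=run_seed)
            history = train_gan(train, SCALED_SPEC, hp, hold, verbose=verbose)
            first, last = history.records[0], history.records[-1]
            rows.append({"seed_index": i, "lambda": lam,
                         "djs_first": first.D_JS, "djs_final": last.D_JS,
                         "spectral_first": first.spectral_score,
                         "spectral_final": last.spectral_score,
                         "L_final_last": last.L_final})
    return pd.DataFrame(rows)
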