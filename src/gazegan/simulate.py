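"""Synthetic gaze scanpaths with alternating fixations and saccades.

The simulator produces speed series (and matching 2-D scanpaths) at 1 ms
resolution with the qualitative statistics of visual-search eye tracking:
long low-speed fixation epochs, short saccades with a smooth bell-shaped
speed profile, and a log-normal spread of saccade peak speeds that yields a
strongly heavy-tailed marginal speed distribution after min-max scaling
(skewness of a few, excess kurtosis in the tens).

Epoch durations are gamma-distributed.  Every epoch draws from its own
seed-derived substream (keyed by the epoch index), so extending the total
duration never perturbs earlier epochs, and the speed and direction draws use
separate substreams so the speed series is identical whether or not a 2-D
scanpath is materialized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .preprocess import GazeRecording, VelocitySeries


@dataclass
class ScanpathConfig:
    fixation_duration_mean: float = 250.0  # ms
    fixation_duration_shape: float = 4.0
    saccade_duration_mean: float = 30.0  # ms
    saccade_duration_shape: float = 8.0
    fixation_speed_scale: float = 0.02  # px/ms
    saccade_peak_median: float = 2.0  # px/ms, log-normal location exp(mu)
    saccade_peak_sigma: float = 0.45  # log-normal spread
    noise_scale: float = 0.005  # px/ms additive positive noise
    total_duration: int = 100_000  # ms
    seed: int = 0

    def __post_init__(self):
        positive = {
            "fixation_duration_mean": self.fixation_duration_mean,
            "fixation_duration_shape": self.fixation_duration_shape,
            "saccade_duration_mean": self.saccade_duration_mean,
            "saccade_duration_shape": self.saccade_duration_shape,
            "saccade_peak_median": self.saccade_peak_median,
        }
        for name, val in positive.items():
            if not val > 0:
                raise ConfigError(f"{name} must be > 0, got {val}")
        for name, val in (("fixation_speed_scale", self.fixation_speed_scale),
                          ("saccade_peak_sigma", self.saccade_peak_sigma),
                          ("noise_scale", self.noise_scale)):
            if val < 0:
                raise ConfigError(f"{name} must be >= 0, got {val}")
        if self.total_duration < 2:
            raise ConfigError("total_duration must be at least 2 ms")


def _epoch_rng(seed: int, index: int, channel: int) -> np.random.Generator:
    """Independent substream for (epoch, channel); channel 0 drives durations
    and speeds, channel 1 drives movement directions."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index, channel)))


def _gamma_duration(rng, mean: float, shape: float) -> int:
    return max(2, int(round(rng.gamma(shape, mean / shape))))


def _generate_epochs(cfg: ScanpathConfig):
    """Yield (index, kind, speeds) epochs until total_duration is covered."""
    total = 0
    index = 0
    epochs = []
    while total < cfg.total_duration:
        rng = _epoch_rng(cfg.seed, index, 0)
        if index % 2 == 0:  # fixation
            d = _gamma_duration(rng, cfg.fixation_duration_mean,
                                cfg.fixation_duration_shape)
            speeds = np.abs(rng.normal(0.0, 1.0, d)) * cfg.fixation_speed_scale
            kind = "fixation"
        else:  # saccade
            d = _gamma_duration(rng, cfg.saccade_duration_mean,
                                cfg.saccade_duration_shape)
            peak = cfg.saccade_peak_median * np.exp(
                cfg.saccade_peak_sigma * rng.standard_normal())
            bell = np.sin(np.pi * (np.arange(d) + 0.5) / d)
            speeds = peak * bell + np.abs(rng.normal(0.0, 1.0, d)) * cfg.noise_scale
            kind = "saccade"
        if total + d > cfg.total_duration:
            speeds = speeds[:cfg.total_duration - total]
        epochs.append((index, kind, speeds))
        total += len(speeds)
        index += 1
    return epochs


def saccade_bell(duration: int) -> np.ndarray:
    """The deterministic unit-peak within-saccade speed template."""
    return np.sin(np.pi * (np.arange(duration) + 0.5) / duration)


def fixation_time_fraction(cfg: ScanpathConfig) -> float:
    """Long-run expected fraction of time spent in fixation epochs."""
    return cfg.fixation_duration_mean / (cfg.fixation_duration_mean
                                         + cfg.saccade_duration_mean)


def simulate_velocity_series(cfg: ScanpathConfig) -> VelocitySeries:
    """Simulate a 1 ms-resolution gaze speed series (px/ms)."""
    speeds = np.concatenate([s for _, _, s in _generate_epochs(cfg)])
    return VelocitySeries(speeds, dt=1.0)


def simulate_scanpath(cfg: ScanpathConfig,
                      start: tuple[float, float] = (512.0, 384.0)) -> GazeRecording:
    """Simulate a 2-D scanpath whose speed series equals
    :func:`simulate_velocity_series` under the same config.

    Saccades move along one direction drawn uniformly on the circle;
    fixation samples jitter in a fresh random direction every millisecond.
    """
    disps = []
    for index, kind, speeds in _generate_epochs(cfg):
        rng = _epoch_rng(cfg.seed, index, 1)
        if kind == "saccade":
            theta = np.full(len(speeds), rng.uniform(0.0, 2.0 * np.pi))
        else:
            theta = rng.uniform(0.0, 2.0 * np.pi, len(speeds))
        disps.append(np.column_stack([speeds * np.cos(theta),
                                      speeds * np.sin(theta)]))
    disp = np.vstack(disps)
    pos = np.vstack([[start], disp]).cumsum(axis=0)
    time = np.arange(len(pos), dtype=float)
    return GazeRecording(time, pos[:, 0], pos[:, 1], eye="unspecified")
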