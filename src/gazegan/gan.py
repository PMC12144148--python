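"""Generator/discriminator architectures for gaze-speed sequence GANs.

Four variants are supported, crossing {CNN, LSTM} generators with
{CNN, LSTM} discriminators:

* LSTM generator: an independent uniform noise vector per time step feeds a
  16-unit LSTM; a dense layer maps each hidden state to per-step horizontal
  and vertical displacements (tanh), whose Euclidean norm (divided by sqrt 2
  so it lands in [0, 1]) is the emitted speed.
* CNN generator: a noise vector is densely projected to (channels x L/8) and
  grown by three fractional-strided convolutions (kernel 4, stride 2, pad 1;
  batch-norm + ReLU), ending in a tanh layer.  tanh outputs in [-1, 1] are
  mapped to the [0, 1] data range.
* LSTM discriminator: per-step dense sigmoid scores on LSTM hidden states,
  averaged over the sequence.
* CNN discriminator: three strided convolutions (batch-norm + LeakyReLU after
  all but the first), flattened into a dense sigmoid score.

The channel schedule (generator 64-32-16, discriminator mirrored) and kernel
geometry follow the common deep-convolutional GAN convention; they are
package choices, as is the displacement-norm output head (a direct 1-channel
speed head is available via ``output_head="speed1d"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import SpecError
from .nn import Tensor


@dataclass(frozen=True)
class ArchitectureSpec:
    generator_kind: str = "LSTM"  # {"CNN", "LSTM"}
    discriminator_kind: str = "CNN"  # {"CNN", "LSTM"}
    lstm_hidden: int = 16
    noise_dim: int = 256
    seq_len: int = 200
    cnn_channels: tuple = (64, 32, 16)  # generator schedule; discriminator mirrors it
    output_head: str = "displacement2d"  # {"displacement2d", "speed1d"}

    def __post_init__(self):
        if self.generator_kind not in ("CNN", "LSTM"):
            raise SpecError(f"unknown generator kind {self.generator_kind!r}")
        if self.discriminator_kind not in ("CNN", "LSTM"):
            raise SpecError(f"unknown discriminator kind {self.discriminator_kind!r}")
        if self.output_head not in ("displacement2d", "speed1d"):
            raise SpecError(f"unknown output head {self.output_head!r}")
        if self.lstm_hidden < 1 or self.noise_dim < 1:
            raise SpecError("lstm_hidden and noise_dim must be >= 1")
        n_stages = len(self.cnn_channels)
        if self.seq_len % (2 ** n_stages) != 0 or self.seq_len < 2 ** n_stages:
            raise SpecError(
                f"seq_len {self.seq_len} is not divisible by 2^{n_stages} "
                f"(one halving per convolution stage)")

    @property
    def name(self) -> str:
        return f"{self.generator_kind}-{self.discriminator_kind}"


def sample_noise(batch: int, spec: ArchitectureSpec, seed: int | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform[0, 1) noise: (batch, noise_dim) for CNN generators, a fresh
    noise vector per time step, (batch, seq_len, noise_dim), for LSTM ones."""
    if batch < 1:
        raise ValueError(f"batch must be >= 1, got {batch}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if spec.generator_kind == "LSTM":
        return rng.random((batch, spec.seq_len, spec.noise_dim))
    return rng.random((batch, spec.noise_dim))


def _speed_from_displacements(dx: Tensor, dy: Tensor) -> Tensor:
    # norm of two tanh components <= sqrt(2); dividing keeps speeds in [0, 1]
    return nn.sqrt(dx ** 2 + dy ** 2 + 1e-24) * (1.0 / np.sqrt(2.0))


class LSTMGenerator(nn.Module):
    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        out_ch = 2 if spec.output_head == "displacement2d" else 1
        self.lstm = nn.LSTM(spec.noise_dim, spec.lstm_hidden, rng)
        self.head = nn.Dense(spec.lstm_hidden, out_ch, rng)

    def forward(self, z: Tensor) -> Tensor:
        z = nn.as_tensor(z)
        B, T, _ = z.shape
        h = self.lstm(z)  # (B, T, H)
        out = nn.tanh(self.head(h.reshape(B * T, self.spec.lstm_hidden)))
        if self.spec.output_head == "displacement2d":
            speed = _speed_from_displacements(out[:, 0], out[:, 1])
        else:
            speed = (out[:, 0] + 1.0) * 0.5
        return speed.reshape(B, T)

    def generate(self, n: int, seed: int | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
        was_training = self.training
        self.eval()
        out = self.forward(Tensor(sample_noise(n, self.spec, seed=seed, rng=rng))).data
        if was_training:
            self.train()
        return out


class CNNGenerator(nn.Module):
    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        ch = spec.cnn_channels
        self.l0 = spec.seq_len // (2 ** len(ch))
        out_ch = 2 if spec.output_head == "displacement2d" else 1
        self.proj = nn.Dense(spec.noise_dim, ch[0] * self.l0, rng)
        self.bn0 = nn.BatchNorm1d(ch[0])
        self.ups = [nn.ConvTranspose1d(ch[i], ch[i + 1], rng) for i in range(len(ch) - 1)]
        self.bns = [nn.BatchNorm1d(c) for c in ch[1:]]
        self.out = nn.ConvTranspose1d(ch[-1], out_ch, rng)

    def forward(self, z: Tensor) -> Tensor:
        z = nn.as_tensor(z)
        B = z.shape[0]
        x = self.proj(z).reshape(B, self.spec.cnn_channels[0], self.l0)
        x = nn.relu(self.bn0(x))
        for up, bn in zip(self.ups, self.bns):
            x = nn.relu(bn(up(x)))
        y = nn.tanh(self.out(x))  # (B, out_ch, seq_len), values in [-1, 1]
        if self.spec.output_head == "displacement2d":
            speed = _speed_from_displacements(y[:, 0, :], y[:, 1, :])
        else:
            speed = (y[:, 0, :] + 1.0) * 0.5
        return speed

    generate = LSTMGenerator.generate

    def stage_lengths(self) -> list[int]:
        """Internal length schedule, e.g. 25 -> 50 -> 100 -> 200."""
        n = len(self.spec.cnn_channels)
        return [self.spec.seq_len // (2 ** (n - i)) for i in range(n + 1)]


class LSTMDiscriminator(nn.Module):
    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.lstm = nn.LSTM(1, spec.lstm_hidden, rng)
        self.head = nn.Dense(spec.lstm_hidden, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = nn.as_tensor(x)
        self._check_len(x)
        B, T = x.shape
        h = self.lstm(x.reshape(B, T, 1))
        p = nn.sigmoid(self.head(h.reshape(B * T, self.spec.lstm_hidden)))
        return p.reshape(B, T).mean(axis=1)  # mean per-step plausibility

    def _check_len(self, x):
        if x.ndim != 2 or x.shape[1] != self.spec.seq_len:
            raise ValueError(f"expected (batch, {self.spec.seq_len}) input, "
                             f"got {x.shape}")


class CNNDiscriminator(nn.Module):
    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        ch = tuple(reversed(spec.cnn_channels))  # e.g. 16 -> 32 -> 64
        convs, bns = [], []
        c_prev = 1
        for i, c in enumerate(ch):
            convs.append(nn.Conv1d(c_prev, c, rng))
            bns.append(nn.BatchNorm1d(c) if i > 0 else None)
            c_prev = c
        self.convs = convs
        self._bn_map = bns  # None for the first stage (no batch-norm there)
        latent = ch[-1] * (spec.seq_len // (2 ** len(ch)))
        self.head = nn.Dense(latent, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = nn.as_tensor(x)
        if x.ndim != 2 or x.shape[1] != self.spec.seq_len:
            raise ValueError(f"expected (batch, {self.spec.seq_len}) input, "
                             f"got {x.shape}")
        B = x.shape[0]
        h = x.reshape(B, 1, self.spec.seq_len)
        for conv, bn in zip(self.convs, self._bn_map):
            h = conv(h)
            if bn is not None:
                h = bn(h)
            h = nn.leaky_relu(h, 0.2)
        flat = h.reshape(B, h.shape[1] * h.shape[2])
        return nn.sigmoid(self.head(flat)).reshape(B)


def save_generator(generator: nn.Module, path) -> None:
    """Checkpoint a generator as JSON: the architecture spec plus the flat
    parameter list (ordered by the module's deterministic traversal)."""
    import dataclasses
    import json

    spec = generator.spec
    payload = {"spec": {**dataclasses.asdict(spec),
                        "cnn_channels": list(spec.cnn_channels)},
               "params": [p.data.tolist() for p in generator.parameters()]}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_generator(path) -> nn.Module:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    spec_d = payload["spec"]
    spec_d["cnn_channels"] = tuple(spec_d["cnn_channels"])
    spec = ArchitectureSpec(**spec_d)
    gen = build_generator(spec)
    for p, stored in zip(gen.parameters(), payload["params"], strict=True):
        arr = np.asarray(stored, dtype=float)
        if arr.shape != p.data.shape:
            raise ValueError("checkpoint does not match the architecture")
        p.data = arr
    gen.eval()
    return gen


def build_generator(spec: ArchitectureSpec, seed: int = 0) -> nn.Module:
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    cls = LSTMGenerator if spec.generator_kind == "LSTM" else CNNGenerator
    return cls(spec, rng)


def build_discriminator(spec: ArchitectureSpec, seed: int = 0) -> nn.Module:
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    cls = LSTMDiscriminator if spec.discriminator_kind == "LSTM" else CNNDiscriminator
    return cls(spec, rng)
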