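# gazegan

Generative models of eye-gaze **velocity trajectories**: adversarially
trained sequence generators with a spectral (log-Fourier-magnitude)
regularizer, a Gaussian hidden-Markov baseline, and the evaluation metrics to
compare them — plus a calibrated fixation/saccade simulator so the whole
pipeline runs end-to-end without access to private eye-tracking recordings.

## Who this is for

Researchers in oculomotor modeling, human–computer interaction and
eye-tracking tooling who need realistic synthetic gaze-speed data — for
simulation environments, augmentation, or benchmarking — and a reproducible
harness for comparing generative models of heavy-tailed physiological time
series.

## The models

Gaze position sampled at 1000 Hz is reduced to a per-millisecond speed
series `v_i = ||p_{i+1} − p_i|| / Δt` (px/ms), min-max scaled to [0, 1] and
segmented into length-200 sequences.  A generator `G` maps noise
`z ~ U[0,1)` to such sequences and a discriminator `D` scores their realism;
training minimizes the non-saturating adversarial losses

    L_G = −(1/m) Σ_i log D(G(z_i)),
    L_D = −(1/m) Σ_i [ log D(x_i) + log(1 − D(G(z_i))) ],

with the generator objective augmented by a spectral regularizer built from
the DFT `F(x)_k = Σ_n x_n e^{−2πikn/N}`:

    L_spectral = Σ_k [ log(mean_batch|F(x)_k| + ε) − log(mean_batch|F(x̂)_k| + ε) ]²,
    L_final    = L_G + λ · L_spectral / N        (λ = 0.1 by default).

Four architectures cross {CNN, LSTM} generators with {CNN, LSTM}
discriminators (16-unit LSTMs with per-step noise and a displacement head;
DCGAN-style fractional-strided 1-D convolutions).  The baseline is a
Gaussian HMM fitted by Baum–Welch with quantile initialization and restarts,
with state-count selection by histogram Jensen–Shannon divergence
(base-2, bounded in [0, 1]).  Temporal fidelity is checked with the
autocorrelation function `ACF(h)`.  See `docs/methods.md` for the full
model account and design rationale.

## Worked example

```python
from gazegan import ScanpathConfig, simulate_velocity_series, minmax_normalize
from gazegan.evaluation import moment_summary, sample_js_divergence
from gazegan.hmm import fit_baum_welch, sample_hmm

cfg = ScanpathConfig(total_duration=200_000, seed=7)   # 200 s of gaze at 1 kHz
y, params = minmax_normalize(simulate_velocity_series(cfg))
m = moment_summary(y)
print(f"normalized speed: mean={m.mean:.4f}  sd={m.sd:.4f}  "
      f"skewness={m.skewness:.2f}  excess kurtosis={m.kurtosis:.1f}")

model = fit_baum_welch(y, n_states=4, seed=0)
sample, _ = sample_hmm(model, len(y), seed=1)
print(f"4-state HMM, D_JS against the data: {sample_js_divergence(y, sample):.4f}")
```

prints

```
normalized speed: mean=0.0200  sd=0.0657  skewness=4.76  excess kurtosis=28.3
4-state HMM, D_JS against the data: 0.0035
```

The simulated speed distribution is strongly heavy-tailed (skewness ≈ 4.8,
excess kurtosis ≈ 28 — the regime of visual-search gaze data), and a 4-state
HMM reproduces its marginal to a divergence of a few 1e-3 bits.  Training a
spectrally regularized GAN on the same data and comparing architectures:

```bash
gazegan simulate --config run.yaml          # scanpath.csv + manifest
gazegan preprocess runs/scanpath.csv        # sequences.txt, normalization.json
gazegan train --config run.yaml --lambda 0.1
gazegan generate runs --n 64                # sample the trained generator
gazegan eval runs                           # integral efficiency scores, plots
gazegan hmm select                          # state-count selection table
gazegan report runs                         # moment/D_JS summary table
```

Every command writes a JSON manifest (resolved config, seed, versions) next
to its artifacts; reruns with the same manifest reproduce identical metrics.

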