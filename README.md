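# ecgcast

Hybrid one-step-ahead forecasting of ECG and other quasi-periodic
physiological time series.

Forecasting a raw ECG one sample ahead is hard because the signal is
nonstationary and broadband: sharp QRS complexes, slow baseline drift and
beat-to-beat variability all live in one channel. `ecgcast` tackles this
by *decompose-then-forecast*:

1. **Variational mode decomposition (VMD).** The series x(n) is split
   into K band-limited modes u_k(n) with center frequencies ω_k by
   minimizing the summed mode bandwidths subject to (soft)
   reconstruction, via alternating spectral Wiener-filter updates and
   dual ascent (ADMM). The number of modes is chosen from the residual
   ratio R_res = Σ|x − Σ_k u_k| / Σ|x|: the smallest K with R_res below
   1% and no significant further decrease.
2. **Phase-space reconstruction (PSR).** Each mode is delay-embedded
   into vectors (u(i), u(i+τ), …, u(i+(m−1)τ)). The delay τ can be taken
   at the first local minimum of the lagged mutual information and the
   dimension m from the false-nearest-neighbor (FNN) criterion; by
   default τ = 1 for every mode, which minimizes one-step error.
3. **Exact-interpolation RBF networks.** One Gaussian radial-basis-
   function network per mode, with a hidden unit centered on every
   training vector and output weights solved linearly, predicts that
   mode one step ahead: ŷ(x) = Σ_j w_j exp(−‖x − C_j‖²/2σ²). The shared
   width σ derives from a user-facing `spread` (activation 0.5 at
   distance `spread`).
4. **Summation.** The K per-mode one-step predictions are summed to give
   the forecast x̂(n); forecasting is open-loop (true history up to n−1
   feeds every prediction). Errors are reported as RMSE, MAE and MSE
   over a chronological train/test split (first 2/3 train).

The package is aimed at researchers working on biosignal prediction —
e.g. for transmission-suppression schemes in body-area sensor networks,
where a sensor sends a sample only when the receiver's forecast would
miss it — and ships seeded generators (synthetic ECG, tone mixtures,
Lorenz-63) so everything can be built and tested without data downloads.

## Worked example

```python
from ecgcast import (SynthEcgSpec, synth_ecg, HybridConfig, VmdConfig,
                     fit, evaluate_model)

signal = synth_ecg(SynthEcgSpec(duration_s=8.0, fs=360.0, seed=42))
model = fit(signal, HybridConfig(vmd=VmdConfig(K=10)))
report = evaluate_model(model)
print(f"K = {model.K} modes, split at sample {model.split_index}")
print(f"center frequencies (cycles/sample): {model.vmd_result.omega.round(3)}")
print(f"one-step test RMSE = {report.rmse:.4f} mV")
print(f"one-step test MAE  = {report.mae:.4f} mV")
print(f"one-step test MSE  = {report.mse:.3e} mV^2")
```

prints

```
K = 10 modes, split at sample 1920
center frequencies (cycles/sample): [0.    0.011 0.021 0.03  0.041 0.055 0.238 0.305 0.383 0.437]
one-step test RMSE = 0.0099 mV
one-step test MAE  = 0.0069 mV
one-step test MSE  = 9.716e-05 mV^2
```

The ten modes separate into a trend (ω ≈ 0), five low-frequency
beat-morphology bands and four high-frequency QRS bands. The one-step
RMSE of ~0.01 mV is about 6% of the test segment's standard deviation;
a single RBF network trained on the raw, undecomposed series under the
identical embedding policy is several times worse, which is the point
of decomposing first.

The same pipeline is scriptable from the shell — `ecgcast synth`,
`decompose`, `select-k`, `embed-params`, `fit`, `predict`, `evaluate`,
`sweep-spread` — and reads either CSV signals or WFDB format-212
records (`.hea` + `.dat`, the MIT-BIH layout), e.g.
`ecgcast fit --input 100.hea --channel 0 --count 2768 --k 10 --out model.json`.

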