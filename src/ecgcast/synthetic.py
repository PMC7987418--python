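"""Seeded fixture generators.

Three families cover the statistical structure each pipeline stage
assumes: a quasi-periodic ECG-like waveform (Gaussian P/Q/R/S/T bumps on
beats with jittered RR intervals plus white noise), pure-tone mixtures
for decomposition oracles, and the Lorenz-63 chaotic series for
embedding-selection oracles.  All generators are pure functions of
their arguments: identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal import InvalidInputError, Signal

__all__ = ["SynthEcgSpec", "synth_ecg", "tone_mixture", "lorenz63"]

# (amplitude mV, width s, offset s from the R peak) for P, Q, R, S, T;
# amplitudes and timings in the normal-sinus range for a limb lead
DEFAULT_WAVES: tuple[tuple[float, float, float], ...] = (
    (0.15, 0.025, -0.20),   # P
    (-0.10, 0.010, -0.030), # Q
    (1.00, 0.012, 0.0),     # R
    (-0.20, 0.010, 0.030),  # S
    (0.30, 0.045, 0.26),    # T
)


@dataclass
class SynthEcgSpec:
    """Parameters of the synthetic ECG generator.

    duration_s/fs give the sample count; mean_hr_bpm and hr_sd_bpm set
    the beat rate and its beat-to-beat variability; wave_params holds
    the five (amplitude mV, width s, offset s) Gaussian bumps for the
    P, Q, R, S and T waves; noise_sd is the white-noise level in mV.
    """

    duration_s: float = 8.0
    fs: float = 360.0
    mean_hr_bpm: float = 72.0
    hr_sd_bpm: float = 3.0
    wave_params: tuple[tuple[float, float, float], ...] = DEFAULT_WAVES
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise InvalidInputError("fs and duration_s must be positive")
        if self.mean_hr_bpm <= 0:
            raise InvalidInputError("mean_hr_bpm must be positive")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be non-negative")
        if len(self.wave_params) != 5 or any(w[1] <= 0 for w in self.wave_params):
            raise InvalidInputError("wave_params must be 5 triples with widths > 0")


def synth_ecg(spec: SynthEcgSpec) -> Signal:
    """Generate a quasi-periodic ECG-like signal.

    Beat onsets follow RR intervals drawn from Normal(60/mean_hr, sd)
    truncated positive, with the RR standard deviation obtained from
    hr_sd_bpm by the local linearization sd_RR = hr_sd * 60 / hr^2.
    Each beat is the sum of the five Gaussian bumps at their offsets;
    white Gaussian noise of sd ``noise_sd`` is added on top.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs

    mean_rr = 60.0 / spec.mean_hr_bpm
    sd_rr = spec.hr_sd_bpm * 60.0 / spec.mean_hr_bpm**2

    # draw beats until past the end (plus margin so edge beats contribute)
    r_times = []
    t_beat = 0.10  # first R peak shortly after the start
    while t_beat < spec.duration_s + mean_rr:
        r_times.append(t_beat)
        rr = rng.normal(mean_rr, sd_rr) if sd_rr > 0 else mean_rr
        while rr <= 0:
            rr = rng.normal(mean_rr, sd_rr)
        t_beat += rr

    x = np.zeros(n)
    for t_r in r_times:
        for amp, width, offset in spec.wave_params:
            x += amp * np.exp(-0.5 * ((t - t_r - offset) / width) ** 2)
    if spec.noise_sd > 0:
        x += rng.normal(0.0, spec.noise_sd, size=n)
    return Signal(samples=x, fs=spec.fs, name=f"synth_ecg(seed={spec.seed})")


def tone_mixture(
    freqs: list[float],
    amps: list[float],
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Signal:
    """Sum of cosines at the given frequencies (cycles/sample) plus noise."""
    freqs = list(freqs)
    amps = list(amps)
    if not freqs:
        raise InvalidInputError("freqs must be non-empty")
    if len(freqs) != len(amps):
        raise InvalidInputError("freqs and amps must have equal length")
    if any(not (0.0 < f < 0.5) for f in freqs):
        raise InvalidInputError("frequencies must lie in (0, 0.5) cycles/sample")
    t = np.arange(n, dtype=float)
    x = np.zeros(n)
    for f, a in zip(freqs, amps):
        x += a * np.cos(2.0 * np.pi * f * t)
    if noise_sd > 0:
        x += np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return Signal(samples=x, name="tone_mixture")


def lorenz63(
    n: int,
    dt: float = 0.01,
    initial: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_transient: int = 1000,
) -> np.ndarray:
    """x-component of the Lorenz-63 system (sigma=10, rho=28, beta=8/3).

    Fixed-step 4th-order Runge-Kutta integration; the first
    ``n_transient`` steps are discarded so the trajectory sits on the
    attractor.  Deterministic given ``initial``.
    """
    if n < 100:
        raise InvalidInputError("n must be >= 100")
    if not (0.0 < dt <= 0.05):
        raise InvalidInputError("dt must lie in (0, 0.05]")
    sigma, rho, beta = 10.0, 28.0, 8.0 / 3.0

    def deriv(s: np.ndarray) -> np.ndarray:
        x, y, z = s
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

    state = np.array(initial, dtype=float)
    out = np.empty(n)
    for i in range(n_transient + n):
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * dt * k1)
        k3 = deriv(state + 0.5 * dt * k2)
        k4 = deriv(state + dt * k3)
        state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if i >= n_transient:
            out[i - n_transient] = state[0]
    return out
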