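"""Hybrid one-step-ahead forecaster: VMD -> per-mode delay embedding ->
per-mode exact-interpolation RBF network -> summed forecast.

The signal is decomposed once over its full length, split
chronologically (first ``split_fraction`` of samples for training), and
one RBF network is trained per mode on that mode's delay-embedded
training pairs.  Test-time prediction is open-loop one-step-ahead: the
forecast of sample n uses each mode's true decomposed samples up to
n-1, and the per-mode predictions are summed.

Decomposing the full series before splitting lets the decomposition see
the test interval (a mild form of leakage); a strict-causal alternative
(decompose the training segment only) is available via
``causal_decomposition`` but is not the default, since the default
matches how such hybrid forecasters are customarily evaluated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import rbf
from .embedding import EmbeddingParams, embed, select_delay, select_embedding_dim
from .signal import ConfigurationError, InvalidInputError, Signal
from .vmd import VmdConfig, VmdResult, vmd_decompose

__all__ = [
    "HybridConfig",
    "ImfRecord",
    "HybridModel",
    "EvalReport",
    "split_series",
    "fit",
    "predict_test",
    "evaluate",
    "spread_sweep",
]


@dataclass
class HybridConfig:
    """Pipeline settings.

    delay_policy "fixed_one" uses tau = 1 for every mode (the setting
    that minimizes one-step error in practice); "mi_selected" takes each
    mode's first mutual-information minimum, falling back to 1 when the
    profile has none.  dims_policy picks each mode's embedding dimension
    by the FNN criterion or from an explicit per-mode list.  ``spread``
    is the shared RBF width parameter; ``split_fraction`` the train
    share of the chronological split.
    """

    vmd: VmdConfig = field(default_factory=VmdConfig)
    delay_policy: str = "fixed_one"
    dims_policy: str = "fnn_selected"
    fixed_dims: list[int] | None = None
    fixed_taus: list[int] | None = None
    spread: float = 0.5
    split_fraction: float = 2.0 / 3.0
    normalize: bool = False
    causal_decomposition: bool = False
    mi_max_lag: int = 40
    mi_bins: int = 16
    fnn_m_max: int = 8
    fnn_r_threshold: float = 15.0

    def __post_init__(self) -> None:
        if self.delay_policy not in ("fixed_one", "mi_selected", "fixed_list"):
            raise ConfigurationError(f"unknown delay_policy {self.delay_policy!r}")
        if self.dims_policy not in ("fnn_selected", "fixed_list"):
            raise ConfigurationError(f"unknown dims_policy {self.dims_policy!r}")
        if not (0.0 < self.split_fraction < 1.0):
            raise ConfigurationError("split_fraction must lie in (0, 1)")
        if self.spread <= 0:
            raise ConfigurationError("spread must be positive")
        if self.dims_policy == "fixed_list":
            if self.fixed_dims is None or len(self.fixed_dims) != self.vmd.K:
                raise ConfigurationError(
                    "fixed_dims must list one m per mode (length K)"
                )
        if self.delay_policy == "fixed_list":
            if self.fixed_taus is None or len(self.fixed_taus) != self.vmd.K:
                raise ConfigurationError(
                    "fixed_taus must list one tau per mode (length K)"
                )


@dataclass
class ImfRecord:
    """Per-mode fit artifacts: embedding parameters, trained network,
    optional min-max scaling, and a degeneracy flag for (near-)constant
    modes, which are forecast by their constant value."""

    params: EmbeddingParams
    model: rbf.RbfModel | None
    degenerate: bool = False
    constant_value: float = 0.0
    scale_min: float = 0.0
    scale_range: float = 1.0


@dataclass
class HybridModel:
    per_imf: list[ImfRecord]
    vmd_result: VmdResult
    split_index: int
    config: HybridConfig
    signal: Signal

    @property
    def K(self) -> int:
        return len(self.per_imf)


@dataclass
class EvalReport:
    """One-step forecast errors: RMSE, MAE, MSE (rmse = sqrt(mse)), plus
    per-mode RMSEs when per-mode prediction/target pairs are supplied."""

    rmse: float
    mae: float
    mse: float
    per_imf_rmse: np.ndarray | None
    n_test: int


def split_series(n_total: int, split_fraction: float) -> tuple[int, int]:
    """Chronological split: first floor(split_fraction*n) samples train."""
    if not (0.0 < split_fraction < 1.0):
        raise InvalidInputError("split_fraction must lie in (0, 1)")
    if n_total < 3:
        raise InvalidInputError("n_total must be >= 3")
    n_train = int(np.floor(split_fraction * n_total))
    return n_train, n_total - n_train

def _choose_params(
    train: np.ndarray, k: int, config: HybridConfig
) -> EmbeddingParams:
    if config.delay_policy == "fixed_one":
        tau = 1
    elif config.delay_policy == "fixed_list":
        tau = int(config.fixed_taus[k])
    else:
        profile = select_delay(train, config.mi_max_lag, config.mi_bins)
        tau = profile.selected if profile.selected is not None else 1
    if config.dims_policy == "fixed_list":
        m = int(config.fixed_dims[k])
    else:
        m = select_embedding_dim(
            train,
            tau,
            m_max=config.fnn_m_max,
            r_threshold=config.fnn_r_threshold,
        ).selected
    return EmbeddingParams(m=m, tau=tau)


_DEGENERATE_PTP = 1e-12


def _decompose_for_fit(
    signal: Signal, config: HybridConfig, n_train: int
) -> VmdResult:
    """Default: decompose the full series once, then split per mode.

    With ``causal_decomposition`` the center frequencies are learned on
    the training segment only and the full series is then separated by
    fixed Wiener filters at those frozen frequencies (one sweep, no
    further frequency adaptation), so no test-interval information
    shapes the filter bank.  The filtering itself remains a whole-record
    spectral operation.
    """
    if not config.causal_decomposition:
        return vmd_decompose(signal, config.vmd)
    train_res = vmd_decompose(
        Signal(signal.samples[:n_train], fs=signal.fs, name=signal.name),
        config.vmd,
    )
    return _fixed_omega_sweep(signal, config.vmd, train_res.omega)


def _fixed_omega_sweep(
    signal: Signal, base: VmdConfig, omega: np.ndarray
) -> VmdResult:
    x = signal.samples
    N = x.size
    if base.mirror_boundary:
        half = N // 2
        xe = np.concatenate([x[:half][::-1], x, x[N - half:][::-1]])
    else:
        xe = x
    T = xe.size
    freqs = np.fft.rfftfreq(T)
    f_hat = np.fft.rfft(xe)
    K = omega.size
    u_hat = np.zeros((K, freqs.size), dtype=complex)
    sum_u = u_hat.sum(axis=0)
    for k in range(K):
        sum_u -= u_hat[k]
        u_hat[k] = (f_hat - sum_u) / (
            1.0 + 2.0 * base.alpha * (freqs - omega[k]) ** 2
        )
        sum_u += u_hat[k]
    modes_ext = np.fft.irfft(u_hat, n=T, axis=1)
    if base.mirror_boundary:
        half = N // 2
        modes = modes_ext[:, half: half + N]
    else:
        modes = modes_ext
    order = np.argsort(omega, kind="stable")
    return VmdResult(
        modes=np.ascontiguousarray(modes[order]),
        omega=np.asarray(omega)[order],
        iterations=1,
        converged=True,
        final_increment=0.0,
    )


def fit(signal: Signal, config: HybridConfig) -> HybridModel:
    """Fit the full hybrid model.

    Decomposes the series, splits chronologically, then per mode:
    selects (m, tau) from the training segment only, builds the
    delay-embedding training pairs, and trains an exact-interpolation
    RBF network with the configured spread.  A (near-)constant mode gets
    no network and is forecast by its constant.
    """
    x = signal.samples
    n_train, _ = split_series(x.size, config.split_fraction)

    vmd_res = _decompose_for_fit(signal, config, n_train)

    records: list[ImfRecord] = []
    for k in range(vmd_res.K):
        mode = vmd_res.modes[k]
        train = mode[:n_train]
        if np.ptp(train) < _DEGENERATE_PTP:
            records.append(
                ImfRecord(
                    params=EmbeddingParams(m=1, tau=1),
                    model=None,
                    degenerate=True,
                    constant_value=float(train.mean()),
                )
            )
            continue
        params = _choose_params(train, k, config)
        if train.size <= (params.m - 1) * params.tau + 1:
            raise InvalidInputError(
                f"training segment too short for mode {k} embedding {params}"
            )
        scale_min, scale_range = 0.0, 1.0
        series = train
        if config.normalize:
            scale_min = float(train.min())
            scale_range = float(np.ptp(train))
            series = (train - scale_min) / scale_range
        emb = embed(series, params)
        model = rbf.train_exact(emb.X[: emb.M_usable], emb.Y, config.spread)
        records.append(
            ImfRecord(
                params=params,
                model=model,
                scale_min=scale_min,
                scale_range=scale_range,
            )
        )
    return HybridModel(
        per_imf=records,
        vmd_result=vmd_res,
        split_index=n_train,
        config=config,
        signal=signal,
    )


def _imf_test_queries(
    mode: np.ndarray, params: EmbeddingParams, split: int, n_test: int
) -> np.ndarray:
    """Delay vectors ending at n-1 for each test index n = split..N-1."""
    m, tau = params.m, params.tau
    start = split - 1 - (m - 1) * tau
    if start < 0:
        raise InvalidInputError("training history too short for test queries")
    rows = np.arange(n_test)[:, None] + start + tau * np.arange(m)[None, :]
    return mode[rows]


def predict_per_imf(model: HybridModel) -> np.ndarray:
    """K x n_test matrix of per-mode one-step forecasts (open loop)."""
    split = model.split_index
    n = len(model.signal)
    n_test = n - split
    out = np.empty((model.K, n_test))
    for k, rec in enumerate(model.per_imf):
        mode = model.vmd_result.modes[k]
        if rec.degenerate:
            out[k] = rec.constant_value
            continue
        series = mode
        if model.config.normalize:
            series = (mode - rec.scale_min) / rec.scale_range
        queries = _imf_test_queries(series, rec.params, split, n_test)
        pred = rbf.predict(rec.model, queries)
        if model.config.normalize:
            pred = pred * rec.scale_range + rec.scale_min
        out[k] = pred
    return out


def predict_test(model: HybridModel) -> tuple[np.ndarray, np.ndarray]:
    """Open-loop one-step forecasts over the test segment.

    Returns (predictions, actual), both of length n_test; predictions
    are the per-mode forecasts summed, actual the original samples.
    """
    per_imf = predict_per_imf(model)
    predictions = per_imf.sum(axis=0)
    actual = model.signal.samples[model.split_index:]
    return predictions, actual


def evaluate(
    predictions: np.ndarray,
    actual: np.ndarray,
    per_imf: tuple[np.ndarray, np.ndarray] | None = None,
) -> EvalReport:
    """RMSE / MAE / MSE of a forecast.

    ``per_imf``, when given, is a (K x n, K x n) pair of per-mode
    predictions and true mode samples from which per-mode RMSEs are
    computed.
    """
    p = np.asarray(predictions, dtype=float).ravel()
    a = np.asarray(actual, dtype=float).ravel()
    if p.size != a.size:
        raise InvalidInputError(f"length mismatch: {p.size} vs {a.size}")
    if p.size < 1:
        raise InvalidInputError("need at least one sample")
    err = a - p
    mse = float(np.mean(err**2))
    report = EvalReport(
        rmse=float(np.sqrt(mse)),
        mae=float(np.mean(np.abs(err))),
        mse=mse,
        per_imf_rmse=None,
        n_test=p.size,
    )
    if per_imf is not None:
        pk, ak = (np.atleast_2d(np.asarray(v, dtype=float)) for v in per_imf)
        if pk.shape != ak.shape:
            raise InvalidInputError("per-mode shapes differ")
        report.per_imf_rmse = np.sqrt(np.mean((ak - pk) ** 2, axis=1))
    return report


def evaluate_model(model: HybridModel) -> EvalReport:
    """Fit-level convenience: predict the test segment and score it,
    including per-mode RMSEs against the true decomposed modes."""
    per_imf_pred = predict_per_imf(model)
    predictions = per_imf_pred.sum(axis=0)
    actual = model.signal.samples[model.split_index:]
    true_modes = model.vmd_result.modes[:, model.split_index:]
    return evaluate(predictions, actual, per_imf=(per_imf_pred, true_modes))


def spread_sweep(
    signal: Signal,
    config: HybridConfig,
    spreads: list[float],
) -> tuple[list[tuple[float, float, float]], float]:
    """Re-train only the RBF stage per spread and score the test segment.

    The decomposition and per-mode embedding parameters are computed
    once and reused.  Returns the (spread, rmse, mae) table and the
    error-minimizing spread.
    """
    if not spreads:
        raise InvalidInputError("spreads must be non-empty")
    if any(s <= 0 for s in spreads):
        raise InvalidInputError("all spreads must be positive")
    base = fit(signal, config)
    table: list[tuple[float, float, float]] = []
    for s in spreads:
        model = _refit_spread(base, float(s))
        pred, actual = predict_test(model)
        rep = evaluate(pred, actual)
        table.append((float(s), rep.rmse, rep.mae))
    best = min(table, key=lambda row: row[1])[0]
    return table, best


def _refit_spread(base: HybridModel, spread: float) -> HybridModel:
    cfg = replace(base.config, spread=spread)
    records: list[ImfRecord] = []
    n_train = base.split_index
    for k, rec in enumerate(base.per_imf):
        if rec.degenerate:
            records.append(rec)
            continue
        mode = base.vmd_result.modes[k]
        train = mode[:n_train]
        series = train
        if cfg.normalize:
            series = (train - rec.scale_min) / rec.scale_range
        emb = embed(series, rec.params)
        model = rbf.train_exact(emb.X[: emb.M_usable], emb.Y, spread)
        records.append(
            ImfRecord(
                params=rec.params,
                model=model,
                scale_min=rec.scale_min,
                scale_range=rec.scale_range,
            )
        )
    return HybridModel(
        per_imf=records,
        vmd_result=base.vmd_result,
        split_index=base.split_index,
        config=cfg,
        signal=base.signal,
    )
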