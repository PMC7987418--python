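"""Phase-space reconstruction (delay embedding) and its parameter selection.

A scalar series x_1..x_N is embedded as delay vectors
X_i = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau}), i = 1..M with
M = N - (m-1)*tau.  For one-step forecasting the target paired with X_i
is the sample following its last coordinate, so M-1 supervised pairs
exist and the final row of X is the query whose target is the next,
unobserved sample.

Delay tau is chosen at the first local minimum of the lagged mutual
information (histogram estimator, bits); embedding dimension m by the
false-nearest-neighbor (FNN) criterion: a neighbor pair at dimension m
is "false" when its distance blows up at dimension m+1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .signal import InvalidInputError

__all__ = [
    "EmbeddingParams",
    "DelayEmbedding",
    "MiProfile",
    "FnnProfile",
    "embed",
    "mutual_information",
    "select_delay",
    "fnn_fraction",
    "select_embedding_dim",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Embedding dimension m and delay tau (in samples)."""

    m: int
    tau: int

    def __post_init__(self) -> None:
        if self.m < 1:
            raise InvalidInputError("embedding dimension m must be >= 1")
        if self.tau < 1:
            raise InvalidInputError("delay tau must be >= 1")


@dataclass
class DelayEmbedding:
    """Delay-vector matrix X (M x m) and one-step targets Y (M-1,).

    Y[i] is the sample that follows X[i]'s last coordinate; the final
    row of X has no observed target and serves as the forecast query.
    """

    X: np.ndarray
    Y: np.ndarray
    M: int

    @property
    def M_usable(self) -> int:
        return self.M - 1


@dataclass
class MiProfile:
    """Lagged mutual information I(tau) in bits, lags 1..L.

    ``selected`` is the smallest lag that is a strict local minimum of
    the profile (with I(0) = H(series) as left boundary), or None when
    the profile has no interior minimum.
    """

    lags: np.ndarray
    mi_bits: np.ndarray
    selected: int | None


@dataclass
class FnnProfile:
    """False-nearest-neighbor fraction per embedding dimension 1..m_max."""

    dims: np.ndarray
    fractions: np.ndarray
    selected: int
    warned: bool = False


def embed(series: np.ndarray, params: EmbeddingParams) -> DelayEmbedding:
    """Build the delay-embedding matrix and one-step targets.

    With 1-based series indexing, row i of X is
    (x_i, x_{i+tau}, ..., x_{i+(m-1)tau}) and Y_i = x_{i+1+(m-1)tau};
    storage here is 0-based.
    """
    x = np.asarray(series, dtype=float).ravel()
    m, tau = params.m, params.tau
    N = x.size
    M = N - (m - 1) * tau
    if M < 2:
        raise InvalidInputError(
            f"series of length {N} too short for m={m}, tau={tau}"
        )
    idx = np.arange(M)[:, None] + tau * np.arange(m)[None, :]
    X = x[idx]
    Y = x[(m - 1) * tau + 1:]
    return DelayEmbedding(X=X, Y=Y, M=M)


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information(series: np.ndarray, lag: int, n_bins: int = 16) -> float:
    """Histogram mutual information (bits) between x_t and x_{t+lag}.

    Marginal and joint probabilities come from equal-width histograms
    with ``n_bins`` bins per axis over each variable's observed range;
    I = H(S) + H(Q) - H(S, Q) in base-2 logs.  A constant series carries
    no information and returns 0.
    """
    x = np.asarray(series, dtype=float).ravel()
    if lag < 1:
        raise InvalidInputError("lag must be >= 1")
    if x.size - lag < 10:
        raise InvalidInputError("need at least 10 lagged pairs")
    s, q = x[:-lag], x[lag:]
    if np.ptp(s) == 0 or np.ptp(q) == 0:
        warnings.warn(
            "degenerate (constant) series: mutual information is 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    joint, _, _ = np.histogram2d(s, q, bins=n_bins)
    h_s = _entropy_bits(joint.sum(axis=1))
    h_q = _entropy_bits(joint.sum(axis=0))
    h_sq = _entropy_bits(joint.ravel())
    return max(h_s + h_q - h_sq, 0.0)


def select_delay(
    series: np.ndarray, max_lag: int, n_bins: int = 16
) -> MiProfile:
    """Delay selection at the first local minimum of lagged MI.

    Scans lags 1..max_lag; the selected lag L satisfies
    I(L) < I(L-1) and I(L) < I(L+1), with I(0) taken as the marginal
    entropy H(series) under the same binning.  A candidate must also
    have decayed at least 5% below that lag-0 entropy: histogram edge
    effects wiggle an otherwise flat profile (e.g. a monotone ramp,
    whose lagged copies stay fully dependent) at the 1e-4 level and
    would otherwise fake a minimum.  Returns None for ``selected`` when
    no such minimum exists (callers fall back to tau = 1).
    """
    x = np.asarray(series, dtype=float).ravel()
    if max_lag >= x.size / 2:
        raise InvalidInputError("max_lag must be < N/2")
    lags = np.arange(1, max_lag + 1)
    mi = np.array([mutual_information(x, int(l), n_bins) for l in lags])

    if np.ptp(x) > 0:
        counts, _ = np.histogram(x, bins=n_bins)
        mi0 = _entropy_bits(counts)
    else:
        mi0 = 0.0
    padded = np.concatenate([[mi0], mi])
    ceiling = 0.95 * mi0
    selected = None
    for i in range(1, len(padded) - 1):
        if (
            padded[i] < padded[i - 1]
            and padded[i] < padded[i + 1]
            and padded[i] < ceiling
        ):
            selected = int(i)
            break
    return MiProfile(lags=lags, mi_bits=mi, selected=selected)


def fnn_fraction(
    series: np.ndarray,
    m: int,
    tau: int,
    r_threshold: float = 15.0,
    theiler: int | None = None,
) -> float:
    """Fraction of false nearest neighbors at embedding dimension m.

    Each m-dimensional delay vector is paired with its Euclidean nearest
    neighbor among points more than ``theiler`` samples away in time;
    the pair is false when the relative distance growth
    (d_{m+1} - d_m) / d_m of their (m+1)-dimensional extensions reaches
    ``r_threshold``.  Pairs at (numerically) zero distance -- exact or
    round-off-level duplicates, as arise in exactly periodic series --
    are excluded entirely, since their distance ratio is noise.
    """
    x = np.asarray(series, dtype=float).ravel()
    if theiler is None:
        theiler = tau
    emb_hi = embed(x, EmbeddingParams(m=m + 1, tau=tau))
    n_pts = emb_hi.M  # points usable at both m and m+1
    if n_pts < 2:
        raise InvalidInputError("too few points to embed at dimension m+1")
    X_lo = emb_hi.X[:, :m]
    X_hi = emb_hi.X

    d_lo = cdist(X_lo, X_lo)
    ii = np.arange(n_pts)
    band = np.abs(ii[:, None] - ii[None, :]) <= theiler
    d_lo[band] = np.inf
    nn = np.argmin(d_lo, axis=1)
    d_m = d_lo[ii, nn]

    floor = 1e-9 * max(float(np.ptp(x)), np.finfo(float).tiny)
    valid = np.isfinite(d_m) & (d_m > floor)
    if not np.any(valid):
        return 0.0
    d_m1 = np.linalg.norm(X_hi[ii[valid]] - X_hi[nn[valid]], axis=1)
    ratio = (d_m1 - d_m[valid]) / d_m[valid]
    return float(np.mean(ratio >= r_threshold))


def select_embedding_dim(
    series: np.ndarray,
    tau: int,
    m_max: int = 8,
    frac_threshold: float = 0.05,
    plateau_abs: float = 0.01,
    r_threshold: float = 15.0,
    theiler: int | None = None,
) -> FnnProfile:
    """Embedding-dimension selection by the FNN curve.

    Evaluates the FNN fraction for m = 1..m_max and selects the smallest
    m whose fraction falls below ``frac_threshold``; failing that, the
    smallest m where the curve has flattened (|f(m) - f(m+1)| <
    ``plateau_abs``); failing that, m_max with a warning.
    """
    if m_max < 2:
        raise InvalidInputError("m_max must be >= 2")
    dims = np.arange(1, m_max + 1)
    fracs = np.array(
        [fnn_fraction(series, int(m), tau, r_threshold, theiler) for m in dims]
    )
    below = np.nonzero(fracs < frac_threshold)[0]
    if below.size:
        return FnnProfile(dims=dims, fractions=fracs, selected=int(dims[below[0]]))
    flat = np.nonzero(np.abs(np.diff(fracs)) < plateau_abs)[0]
    if flat.size:
        return FnnProfile(dims=dims, fractions=fracs, selected=int(dims[flat[0]]))
    warnings.warn(
        "FNN curve neither small nor flat within m_max; returning m_max",
        RuntimeWarning,
        stacklevel=2,
    )
    return FnnProfile(dims=dims, fractions=fracs, selected=int(m_max), warned=True)
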