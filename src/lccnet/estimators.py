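"""Connectivity estimators: lagged cross-correlation (LCC), linear
differential covariance (DDC), their combination, cut/thresholded variants,
and the correlation, partial-correlation and naive-transfer-entropy
baselines.

Lag-sign convention (used throughout): the cross-correlation between the
pair (first, second) is

    R(tau) = sum_t first(t) * second(t + tau) / norm,

so ``tau_max > 0`` means the second series lags the first, i.e. the first
node leads and is inferred to drive the second; ``tau_max < 0`` infers the
reverse; ``tau_max == 0`` with high zero-lag correlation is read as a
bidirectional connection.  Swapping the two series mirrors the lag axis
exactly, so a single computation per unordered pair determines both
directions.

All estimators return an :class:`EstimatedConnectivity` whose ``weights``
follow the package-wide orientation ``weights[i, j]`` = strength of j -> i,
with a zero diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft
from sklearn.covariance import GraphicalLasso
from sklearn.exceptions import ConvergenceWarning

from .errors import DegenerateSignalError
from .hopf_sim import TimeSeriesEnsemble

__all__ = [
    "EstimatedConnectivity",
    "LagResult",
    "xcorr_fft",
    "lcc_estimate",
    "threshold_matrix",
    "cut_series",
    "ddc_matrix",
    "ddc_linear",
    "combine_lcc_ddc",
    "correlation_estimate",
    "partial_correlation",
    "naive_transfer_entropy",
    "estimate_with",
    "METHOD_NAMES",
]

#: default binarization/clamping threshold used across LCC/DDC variants
DEFAULT_THRESHOLD = 0.1
#: default subsampling stride of the "cut" variants
DEFAULT_STRIDE = 15
#: default maximum |lag| in samples considered by the LCC scan, twice the
#: largest possible delay of the default Hopf setup (10 ms at dt = 0.1 ms)
DEFAULT_MAX_LAG = 200


@dataclass
class EstimatedConnectivity:
    """A directed weighted N x N estimate tagged with method and parameters."""

    weights: np.ndarray
    method: str
    params: dict

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be square")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


@dataclass
class LagResult:
    """Normalized cross-correlation over symmetric lags.

    ``corr_sequence[k]`` is R(lags[k]); normalization is such that the
    autocorrelation of any series at lag 0 equals 1, hence the value at lag
    0 is the plain Pearson coefficient of the pair.
    """

    corr_sequence: np.ndarray
    lags: np.ndarray
    tau_max: int
    r_max: float

    @property
    def r_zero_lag(self) -> float:
        return float(self.corr_sequence[len(self.corr_sequence) // 2])


def xcorr_fft(x: np.ndarray, y: np.ndarray, max_lag: int | None = None) -> LagResult:
    """FFT-based normalized cross-correlation of two equal-length series.

    Both series are demeaned; the cross-spectrum conj(F(x)) * F(y) is
    inverted after zero-padding to at least 2T - 1 points, which removes the
    circular wrap-around, and the result is normalized by the product of
    the series' standard deviations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be 1-D and of equal length")
    T = x.size
    if T < 2:
        raise ValueError("need at least 2 samples")
    L = T - 1 if max_lag is None else int(max_lag)
    if not 1 <= L <= T - 1:
        raise ValueError(f"max_lag must lie in [1, {T - 1}], got {max_lag!r}")

    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(xd @ xd)
    sy = np.sqrt(yd @ yd)
    if sx == 0.0 or sy == 0.0:
        raise DegenerateSignalError("zero-variance input to cross-correlation")

    nfft = next_fast_len(2 * T - 1)
    c = irfft(np.conj(rfft(xd, nfft)) * rfft(yd, nfft), nfft)
    # c[m] = sum_t x(t) y(t + m); negative lags wrap to the tail
    corr = np.concatenate([c[nfft - L:], c[: L + 1]]) / (sx * sy)
    lags = np.arange(-L, L + 1)
    k = int(np.argmax(corr))
    return LagResult(corr, lags, int(lags[k]), float(corr[k]))


def lcc_estimate(
    ts: TimeSeriesEnsemble,
    max_lag: int | None = None,
    bidir_floor: float = DEFAULT_THRESHOLD,
    value: str = "lagged",
) -> EstimatedConnectivity:
    """Lagged-cross-correlation connectivity estimate.

    For every unordered pair the lag of maximal cross-correlation within
    ``|lag| <= max_lag`` determines the direction (see the module docstring
    for the sign convention); the selected entry is filled with the
    maximal correlation value, i.e. the Pearson coefficient of the
    lag-aligned pair (``value='lagged'``, the default), or with the plain
    zero-lag Pearson coefficient (``value='pearson'``).  The lag-aligned
    fill is the faithful strength readout for delayed oscillatory
    dynamics, where the zero-lag coefficient is suppressed by the phase
    offset ``cos(2 pi tau / period)`` of each delayed connection.  A zero-lag
    maximum is read as bidirectional when the Pearson coefficient is at
    least ``bidir_floor`` in magnitude; otherwise neither direction is
    assigned.

    Degenerate (constant) node series produce a warning and an all-zero
    row and column for that node.
    """
    if value not in ("pearson", "lagged"):
        raise ValueError(f"unknown value mode {value!r}")
    series = ts.x
    n, T = series.shape
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if max_lag is None:
        max_lag = min(DEFAULT_MAX_LAG, T // 2 - 1)
    if not max_lag < T / 2:
        raise ValueError(f"max_lag={max_lag} must be < T/2 = {T / 2}")

    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                res = xcorr_fft(series[i], series[j], max_lag=max_lag)
            except DegenerateSignalError:
                warnings.warn(
                    f"degenerate series for node pair ({i}, {j}); "
                    "leaving entries at zero",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            r0 = res.r_zero_lag
            val = r0 if value == "pearson" else res.r_max
            if res.tau_max > 0:  # i leads -> i drives j
                W[j, i] = val
            elif res.tau_max < 0:  # j leads -> j drives i
                W[i, j] = val
            elif abs(r0) >= bidir_floor:
                W[i, j] = W[j, i] = val
    return EstimatedConnectivity(
        W, "lcc",
        {"max_lag": int(max_lag), "bidir_floor": bidir_floor, "value": value},
    )


def threshold_matrix(m: np.ndarray, thr: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Clamp every entry lower than ``thr`` to zero; entries >= thr are kept.

    The rule applies to raw signed values, so negative entries are always
    clamped.  Idempotent by construction.
    """
    if thr < 0:
        raise ValueError(f"thr must be >= 0, got {thr!r}")
    m = np.asarray(m, dtype=float)
    return np.where(m < thr, 0.0, m)


def cut_series(ts: TimeSeriesEnsemble, stride: int = DEFAULT_STRIDE) -> TimeSeriesEnsemble:
    """Keep every ``stride``-th sample (a naive smoothing/subsampling).

    The sampling step is scaled accordingly; spectral content above the new
    Nyquist frequency aliases.
    """
    stride = int(stride)
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride!r}")
    if stride >= ts.n_samples:
        raise ValueError(f"stride {stride} >= series length {ts.n_samples}")
    return replace(
        ts,
        x=ts.x[:, ::stride].copy(),
        y=None if ts.y is None else ts.y[:, ::stride].copy(),
        dt=ts.dt * stride,
    )


def ddc_matrix(X: np.ndarray, dt: float, scheme: str = "forward") -> np.ndarray:
    """Raw linear differential-covariance estimate, diagonal included.

    Chat = Cov(dX/dt, X) @ Cov(X, X)^{-1}.  The derivative scheme matters:

    - ``'forward'`` (default): ``(X_{t+1} - X_t) / dt`` paired with ``X_t``.
      This is the consistent least-squares estimator for stochastic
      (SDE-generated) trajectories: ``E[(X_{t+1} - X_t) X_t^T] / dt`` tends
      to ``C Sigma`` for ``dX = C X dt + dW``.
    - ``'central'``: ``(X_{t+1} - X_{t-1}) / (2 dt)`` paired with ``X_t``,
      second-order accurate for smooth (noiseless) trajectories.  On
      noise-driven data it converges to the *antisymmetrized* drift
      ``(C Sigma - Sigma C^T) / 2`` and is therefore not used by default.

    A near-singular covariance is ridge-regularized (1e-6 * trace/N on the
    diagonal) with a warning.
    """
    X = np.asarray(X, dtype=float)
    n, T = X.shape
    if T < 3:
        raise ValueError("need at least 3 samples for finite differences")
    if scheme not in ("forward", "central"):
        raise ValueError(f"unknown derivative scheme {scheme!r}")
    if scheme == "forward":
        dX = (X[:, 1:] - X[:, :-1]) / dt
        Xc = X[:, :-1]
    else:
        dX = (X[:, 2:] - X[:, :-2]) / (2.0 * dt)
        Xc = X[:, 1:-1]
    Xm = Xc - Xc.mean(axis=1, keepdims=True)
    Dm = dX - dX.mean(axis=1, keepdims=True)
    m = Xm.shape[1] - 1
    cov_xx = (Xm @ Xm.T) / m
    cov_dx = (Dm @ Xm.T) / m
    if np.linalg.cond(cov_xx) > 1e12:
        warnings.warn(
            "near-singular covariance in DDC; applying ridge regularization",
            RuntimeWarning,
            stacklevel=2,
        )
        cov_xx = cov_xx + (1e-6 * np.trace(cov_xx) / n) * np.eye(n)
    return np.linalg.solve(cov_xx.T, cov_dx.T).T


def ddc_linear(
    ts: TimeSeriesEnsemble, dt: float | None = None, scheme: str = "forward"
) -> EstimatedConnectivity:
    """Linear DDC estimate with the diagonal (intrinsic decay) zeroed."""
    dt = ts.dt if dt is None else dt
    full = ddc_matrix(ts.x, dt, scheme=scheme)
    W = full.copy()
    np.fill_diagonal(W, 0.0)
    return EstimatedConnectivity(
        W, "ddc", {"dt": dt, "diagonal": np.diag(full).tolist()}
    )


def combine_lcc_ddc(
    lcc: EstimatedConnectivity,
    ddc: EstimatedConnectivity,
    thr: float = DEFAULT_THRESHOLD,
) -> EstimatedConnectivity:
    """Keep entries exceeding ``thr`` in *both* estimates; values from LCC."""
    if lcc.weights.shape != ddc.weights.shape:
        raise ValueError("shape mismatch between LCC and DDC estimates")
    mask = (lcc.weights > thr) & (ddc.weights > thr)
    return EstimatedConnectivity(
        np.where(mask, lcc.weights, 0.0), "lcc_plus_ddc", {"thr": thr}
    )


def correlation_estimate(ts: TimeSeriesEnsemble) -> EstimatedConnectivity:
    """Zero-lag Pearson correlation matrix, diagonal zeroed (symmetric)."""
    if ts.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    stds = ts.x.std(axis=1)
    degenerate = stds == 0
    if degenerate.any():
        warnings.warn(
            f"degenerate node series {np.nonzero(degenerate)[0].tolist()}; "
            "their rows/columns are zeroed",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.corrcoef(ts.x)
    W[~np.isfinite(W)] = 0.0
    W[degenerate, :] = 0.0
    W[:, degenerate] = 0.0
    np.fill_diagonal(W, 0.0)
    return EstimatedConnectivity(W, "correlation", {})


def partial_correlation(
    ts: TimeSeriesEnsemble, l1_penalty: float = 0.01
) -> EstimatedConnectivity:
    """Partial correlation from an L1-penalized (sparse) precision matrix.

    Entries are -P_ij / sqrt(P_ii P_jj) from the GraphicalLasso precision P;
    symmetric with zero diagonal.  On non-convergence the unpenalized
    precision (pseudo-inverse of the sample covariance) is used instead,
    with a warning.
    """
    n, T = ts.x.shape
    if T <= n:
        raise ValueError("need more samples than nodes")
    data = ts.x.T
    data = (data - data.mean(axis=0)) / data.std(axis=0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            model = GraphicalLasso(alpha=l1_penalty, assume_centered=True)
            model.fit(data)
        precision = model.precision_
    except (ConvergenceWarning, FloatingPointError, ValueError):
        warnings.warn(
            "GraphicalLasso did not converge; falling back to the "
            "unpenalized precision matrix",
            RuntimeWarning,
            stacklevel=2,
        )
        precision = np.linalg.pinv(np.cov(ts.x))
    d = np.sqrt(np.abs(np.diag(precision)))
    W = -precision / np.outer(d, d)
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return EstimatedConnectivity(W, "partial_correlation", {"l1_penalty": l1_penalty})


def naive_transfer_entropy(
    ts: TimeSeriesEnsemble, n_bins: int = 8, history: int = 1
) -> EstimatedConnectivity:
    """Pairwise naive transfer entropy on equal-width-binned series.

    TE(j -> i) = sum p(x_{t+1}, x_t, y_t) log[ p(x_{t+1} | x_t, y_t) /
    p(x_{t+1} | x_t) ] with natural logarithms, one-step history, and no
    conditioning on third nodes (hence "naive").  Non-negative and
    asymmetric in general; ``weights[i, j]`` holds TE(j -> i).
    """
    if history != 1:
        raise NotImplementedError("only one-step history is implemented")
    n_bins = int(n_bins)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n, T = ts.x.shape
    if T < 10 * n_bins**2:
        warnings.warn(
            "few samples per bin; transfer-entropy estimates are "
            "low-confidence",
            RuntimeWarning,
            stacklevel=2,
        )
    codes = np.empty((n, T), dtype=np.int64)
    for i in range(n):
        v = ts.x[i]
        lo, hi = v.min(), v.max()
        if hi == lo:
            codes[i] = 0
        else:
            codes[i] = np.clip(((v - lo) / (hi - lo) * n_bins).astype(np.int64), 0, n_bins - 1)

    W = np.zeros((n, n))
    B = n_bins
    for i in range(n):  # target
        a = codes[i, 1:]       # x_{t+1}
        b = codes[i, :-1]      # x_t
        n_ab = np.bincount(a * B + b, minlength=B * B).astype(float)
        n_b = n_ab.reshape(B, B).sum(axis=0)
        for j in range(n):  # source
            if i == j:
                continue
            c = codes[j, :-1]  # y_t
            n_abc = np.bincount((a * B + b) * B + c, minlength=B**3).astype(float)
            n_bc = n_abc.reshape(B, B, B).sum(axis=0).ravel()
            idx = np.nonzero(n_abc)[0]
            ab = idx // B
            bc = (ab % B) * B + idx % B
            ratio = (n_abc[idx] * n_b[ab % B]) / (n_bc[bc] * n_ab[ab])
            W[i, j] = float(np.sum(n_abc[idx] * np.log(ratio)) / (T - 1))
    W[W < 0] = 0.0  # clip tiny negatives from finite-sample round-off
    return EstimatedConnectivity(W, "nte", {"n_bins": n_bins, "history": history})


#: Fig.-2-style method registry: row label -> estimator on an ensemble
METHOD_NAMES = (
    "correlation",
    "correlation_cut",
    "partial_correlation",
    "lcc",
    "lcc_thresholded",
    "lcc_cut",
    "lcc_plus_ddc",
    "ddc",
    "ddc_thresholded",
    "nte",
)


def estimate_with(method: str, ts: TimeSeriesEnsemble, **kwargs) -> EstimatedConnectivity:
    """Dispatch a named estimation method (the Fig.-2 row labels).

    ``kwargs`` forwards method parameters (``thr``, ``stride``,
    ``max_lag``, ``n_bins``, ``l1_penalty``).
    """
    thr = kwargs.pop("thr", DEFAULT_THRESHOLD)
    stride = kwargs.pop("stride", DEFAULT_STRIDE)
    if method == "correlation":
        return correlation_estimate(ts)
    if method == "correlation_cut":
        est = correlation_estimate(cut_series(ts, stride))
        return replace(est, method=method, params={"stride": stride})
    if method == "partial_correlation":
        return partial_correlation(ts, **kwargs)
    if method == "lcc":
        return lcc_estimate(ts, **kwargs)
    if method == "lcc_thresholded":
        est = lcc_estimate(ts, **kwargs)
        return EstimatedConnectivity(
            threshold_matrix(est.weights, thr), method, {**est.params, "thr": thr}
        )
    if method == "lcc_cut":
        cut = cut_series(ts, stride)
        max_lag = kwargs.pop("max_lag", None)
        if max_lag is None:
            max_lag = min(max(DEFAULT_MAX_LAG // stride, 1), cut.n_samples // 2 - 1)
        est = lcc_estimate(cut, max_lag=max_lag, **kwargs)
        return replace(est, method=method, params={**est.params, "stride": stride})
    if method == "lcc_plus_ddc":
        return combine_lcc_ddc(lcc_estimate(ts, **kwargs), ddc_linear(ts), thr)
    if method == "ddc":
        return ddc_linear(ts, **kwargs)
    if method == "ddc_thresholded":
        est = ddc_linear(ts, **kwargs)
        return EstimatedConnectivity(
            threshold_matrix(est.weights, thr), method, {**est.params, "thr": thr}
        )
    if method == "nte":
        return naive_transfer_entropy(ts, **kwargs)
    raise ValueError(f"unknown method {method!r}; known: {METHOD_NAMES}")
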