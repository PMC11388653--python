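"""Signal-transform dimensionality reduction for expression vectors.

Each sample's gene vector is treated as a pseudo-time series (gene file
order is the axis — the only ordering the data carries) and reduced to a
fixed number of features by one of three transforms:

* **HT** — discrete Hilbert transform; the feature is the mean analytic-signal
  envelope over each contiguous gene window.
* **DFA** — detrended fluctuation analysis; the feature is the RMS of the
  linearly detrended integrated profile within each window (a per-window
  fluctuation; a scaling exponent is ill-posed on ~10 points).
* **LSLR** — least-squares linear regression; the feature is the RMS residual
  of a straight-line fit to the raw intensities within each window.

All three methods share the same window map: ``target_dim`` contiguous
half-open gene ranges of equal width, the final window absorbing the
remainder (12,533 genes -> 1,253 windows of width 10, the last of width 13).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal

from .errors import ConfigError, DegenerateFluctuationError, InputError, SingularDesignError
from .io_formats import ExpressionMatrix

_METHODS = ("HT", "DFA", "LSLR")


@dataclass
class ReducedFeatureMatrix:
    """samples x target_dim feature matrix produced by one DR method."""

    values: np.ndarray                       # (n_samples, target_dim)
    method: str
    window_map: list[tuple[int, int]]        # half-open gene ranges, in order
    labels: list[str]
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def target_dim(self) -> int:
        return self.values.shape[1]


@dataclass
class DfaProfile:
    """Everything DFA computes for one series."""

    integrated: np.ndarray                   # y(i), cumulative sum of the centred series
    residuals: np.ndarray                    # pooled detrended residuals r(i)
    scales: np.ndarray                       # segment lengths s, strictly increasing
    fluctuation: np.ndarray                  # F(s) per scale
    alpha: float                             # slope of log F(s) on log s


@dataclass
class LslrFit:
    coefficients: np.ndarray                 # beta_0 .. beta_p (intercept first)
    sse: float
    residuals: np.ndarray


def hilbert_analytic(signal) -> tuple[np.ndarray, np.ndarray]:
    """Discrete Hilbert transform and analytic-signal envelope.

    Returns ``(transform, envelope)`` where ``transform`` is the Hilbert
    transform of the input (frequency-domain construction) and ``envelope``
    the magnitude of the analytic signal, pointwise >= |signal|.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise InputError("hilbert_analytic needs a 1-D signal of length >= 4")
    if not np.all(np.isfinite(x)):
        raise InputError("hilbert_analytic: non-finite values in signal")
    analytic = scipy.signal.hilbert(x)
    return analytic.imag.copy(), np.abs(analytic)


def dfa(series, scales, detrend_order: int = 1) -> DfaProfile:
    """Detrended fluctuation analysis of a 1-D series.

    The series is mean-centred and integrated; within each non-overlapping
    segment of length ``s`` a least-squares polynomial of ``detrend_order``
    is removed; ``F(s)`` is the RMS of the residuals pooled over all points
    of all segments, and ``alpha`` is the least-squares slope of
    ``log F(s)`` on ``log s``.
    """
    x = np.asarray(series, dtype=float)
    scales = np.asarray(sorted(int(s) for s in scales), dtype=int)
    if scales.size < 2:
        raise InputError("dfa needs at least two scales")
    if np.any(np.diff(scales) == 0):
        raise InputError("dfa scales must be distinct")
    if np.any(scales < detrend_order + 2):
        raise InputError(f"every scale must be >= detrend_order + 2 = {detrend_order + 2}")
    if x.size < 4 * scales.min():
        raise InputError("series too short: need length >= 4 x min(scales)")
    if scales.max() > x.size:
        raise InputError("scale exceeds series length")

    y = np.cumsum(x - x.mean())
    fluct = np.empty(scales.size)
    pooled = []
    for k, s in enumerate(scales):
        n_seg = y.size // s
        segs = y[: n_seg * s].reshape(n_seg, s)
        t = np.arange(s, dtype=float)
        # per-segment polynomial detrend, all segments at once
        coeffs = np.polynomial.polynomial.polyfit(t, segs.T, detrend_order)
        trend = np.polynomial.polynomial.polyval(t, coeffs)
        r = segs - trend
        pooled.append(r.ravel())
        fluct[k] = np.sqrt(np.mean(r * r))

    positive = fluct > 0
    if positive.sum() < 2:
        raise DegenerateFluctuationError(
            "detrended residuals vanish at (nearly) all scales; alpha is undefined"
        )
    slope = np.polynomial.polynomial.polyfit(
        np.log(scales[positive]), np.log(fluct[positive]), 1
    )[1]
    return DfaProfile(
        integrated=y,
        residuals=np.concatenate(pooled),
        scales=scales,
        fluctuation=fluct,
        alpha=float(slope),
    )


def lslr_fit(x, y) -> LslrFit:
    """Ordinary least squares with intercept, solved by the normal equations.

    ``x`` is (N, p); the returned coefficient vector is
    ``[beta_0, beta_1, ..., beta_p]`` and ``sse`` the sum of squared errors
    at the solution.
    """
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    yv = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if yv.size != n:
        raise InputError("x and y have incompatible lengths")
    if n <= p:
        raise InputError(f"need N > p observations (got N={n}, p={p})")
    A = np.hstack([np.ones((n, 1)), X])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name the offending columns via pivoted QR
        _, _, piv = scipy.linalg.qr(A, pivoting=True, mode="economic")
        dropped = sorted(int(c) - 1 for c in piv[rank:])  # -1: report in x-column index
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {A.shape[1]}); "
            f"dependent columns: {dropped}",
            columns=dropped,
        )
    beta = np.linalg.solve(A.T @ A, A.T @ yv)
    resid = yv - A @ beta
    return LslrFit(coefficients=beta, sse=float(resid @ resid), residuals=resid)


# ---------------------------------------------------------------------------
# windowed reduction


def window_partition(n_genes: int, target_dim: int) -> list[tuple[int, int]]:
    """target_dim contiguous half-open windows covering all genes exactly once.

    All windows share width ``n_genes // target_dim``; the final window
    absorbs the remainder.
    """
    if target_dim > n_genes:
        raise ConfigError(f"target_dim {target_dim} exceeds n_genes {n_genes}")
    width = n_genes // target_dim
    bounds = [i * width for i in range(target_dim)] + [n_genes]
    return [(bounds[i], bounds[i + 1]) for i in range(target_dim)]


def _line_residual_maker(width: int) -> np.ndarray:
    """Annihilator matrix M with M @ v = residuals of an order-1 LS fit to v."""
    if width <= 2:
        # a line interpolates <= 2 points exactly: residuals are identically zero
        return np.zeros((width, width))
    t = np.arange(width, dtype=float)
    A = np.column_stack([np.ones(width), t])
    H = A @ np.linalg.solve(A.T @ A, A.T)
    return np.eye(width) - H


def _windowed_rms_residuals(rows: np.ndarray, window_map) -> np.ndarray:
    """RMS of per-window linear-detrend residuals for every row of ``rows``."""
    widths = [stop - start for start, stop in window_map]
    out = np.empty((rows.shape[0], len(window_map)))
    # group windows by width so the detrend is a single batched matmul per width
    by_width: dict[int, list[int]] = {}
    for j, w in enumerate(widths):
        by_width.setdefault(w, []).append(j)
    for w, idxs in by_width.items():
        M = _line_residual_maker(w)
        starts = np.array([window_map[j][0] for j in idxs])
        # (n_rows, n_windows_of_this_width, w)
        segs = rows[:, starts[:, None] + np.arange(w)]
        resid = segs @ M.T
        out[:, idxs] = np.sqrt(np.mean(resid * resid, axis=-1))
    return out


def reduce_dimensions(
    matrix: ExpressionMatrix, method: str, target_dim: int = 1253
) -> ReducedFeatureMatrix:
    """Reduce every sample's gene vector to ``target_dim`` windowed features.

    The full-length vector is transformed first, then summarized over the
    shared contiguous window map; output shape is (n_samples, target_dim)
    for every method.  Deterministic and independent of sample order.
    """
    if method not in _METHODS:
        raise ConfigError(f"unknown DR method {method!r}; expected one of {_METHODS}")
    wmap = window_partition(matrix.n_genes, target_dim)
    X = matrix.values.T  # (n_samples, n_genes), gene order preserved

    if method == "HT":
        analytic = scipy.signal.hilbert(X, axis=1)
        env = np.abs(analytic)
        feats = np.column_stack([env[:, a:b].mean(axis=1) for a, b in wmap])
    elif method == "DFA":
        profiles = np.cumsum(X - X.mean(axis=1, keepdims=True), axis=1)
        feats = _windowed_rms_residuals(profiles, wmap)
    else:  # LSLR
        feats = _windowed_rms_residuals(X, wmap)

    return ReducedFeatureMatrix(
        values=feats,
        method=method,
        window_map=wmap,
        labels=list(matrix.labels),
        sample_ids=list(matrix.sample_ids),
    )
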