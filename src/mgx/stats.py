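"""Per-class statistical battery and plot-ready diagnostics for reduced features.

Covers the descriptive moments (mean, population variance, Fisher skewness,
Pearson kurtosis), within-class mean pairwise Pearson correlation,
between-class variance-ratio and t tests, the first canonical correlation
between class feature blocks, and the arrays behind histogram /
normal-probability / scatter diagnostics.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .errors import ConfigError, InputError, InsufficientDataError
from .dimred import ReducedFeatureMatrix

logger = logging.getLogger("mgx")


@dataclass
class ClassMoments:
    mean: float
    variance: float        # population convention (divide by N)
    skewness: float        # Fisher; 0 by convention for constant data
    kurtosis: float        # Pearson (normal = 3); NaN + flag when degenerate
    degenerate: bool = False


@dataclass
class ClassStatsReport:
    """One DR method's Table-1-style battery for the two classes."""

    method: str
    adeno: ClassMoments
    meso: ClassMoments
    pcc_adeno: float
    pcc_meso: float
    f_stat: float
    f_p: float
    t_stat: float
    t_p: float
    cca: float


def _class_rows(features: ReducedFeatureMatrix, label: str) -> np.ndarray:
    idx = np.flatnonzero(np.asarray(features.labels) == label)
    if idx.size < 2:
        raise InsufficientDataError(f"class {label!r} has {idx.size} sample(s); need >= 2")
    return features.values[idx]


def describe_class(features: ReducedFeatureMatrix, label: str) -> ClassMoments:
    """Four moments of each sample's feature vector, averaged over the class."""
    rows = _class_rows(features, label)
    means = rows.mean(axis=1)
    variances = rows.var(axis=1)  # population convention
    degenerate = bool(np.any(variances == 0))
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant rows
        skews = np.where(variances == 0, 0.0, scipy.stats.skew(rows, axis=1))
        kurts = scipy.stats.kurtosis(rows, axis=1, fisher=False)
    return ClassMoments(
        mean=float(means.mean()),
        variance=float(variances.mean()),
        skewness=float(np.mean(skews)),
        kurtosis=float(np.mean(kurts)) if not degenerate else math.nan,
        degenerate=degenerate,
    )


def mean_pairwise_correlation(rows: np.ndarray) -> float:
    """Mean Pearson correlation between all pairs of sample feature vectors."""
    if rows.shape[0] < 2:
        raise InsufficientDataError("need >= 2 samples for pairwise correlation")
    c = np.corrcoef(rows)
    iu = np.triu_indices_from(c, k=1)
    return float(np.nanmean(c[iu]))


def canonical_correlation_first(x_block, y_block, ridge: float = 1e-6) -> float:
    """Largest canonical correlation between two observation-aligned blocks.

    Rank-deficient blocks are handled by a small ridge on the block
    covariances (with a logged warning), as wide expression blocks are
    singular by construction.
    """
    X = np.asarray(x_block, dtype=float)
    Y = np.asarray(y_block, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise InputError("blocks must be 2-D with the same number of observations")
    if X.shape[1] < 2 or Y.shape[1] < 2:
        raise InputError("each block needs >= 2 columns")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    n = X.shape[0]
    Sxx = Xc.T @ Xc / n
    Syy = Yc.T @ Yc / n
    Sxy = Xc.T @ Yc / n
    if (np.linalg.matrix_rank(Sxx) < Sxx.shape[0]
            or np.linalg.matrix_rank(Syy) < Syy.shape[0]):
        logger.warning("canonical_correlation_first: rank-deficient block; applying ridge %g", ridge)
    Sxx = Sxx + ridge * np.eye(Sxx.shape[0])
    Syy = Syy + ridge * np.eye(Syy.shape[0])
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    eigvals = np.linalg.eigvals(M).real
    rho = math.sqrt(max(float(eigvals.max()), 0.0))
    return min(rho, 1.0)


def variance_ratio_test(a, b) -> tuple[float, float]:
    """Two-sample F test for equal variances (two-sided p)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0 or va == 0:
        raise InputError("variance-ratio test undefined for zero-variance sample")
    f = va / vb
    dfa_, dfb = a.size - 1, b.size - 1
    cdf = scipy.stats.f.cdf(f, dfa_, dfb)
    return float(f), float(2 * min(cdf, 1 - cdf))


def class_stats_report(features: ReducedFeatureMatrix) -> ClassStatsReport:
    """Assemble the full battery for one reduced-feature matrix.

    The canonical correlation aligns the two class blocks on the feature
    axis (observations = features, variables = samples), which is the only
    alignment available when the classes have different sample counts.
    """
    ad = _class_rows(features, "Adeno")
    me = _class_rows(features, "Meso")
    f_stat, f_p = variance_ratio_test(ad.ravel(), me.ravel())
    t_stat, t_p = scipy.stats.ttest_ind(ad.ravel(), me.ravel(), equal_var=False)
    cca = canonical_correlation_first(ad.T, me.T)
    return ClassStatsReport(
        method=features.method,
        adeno=describe_class(features, "Adeno"),
        meso=describe_class(features, "Meso"),
        pcc_adeno=mean_pairwise_correlation(ad),
        pcc_meso=mean_pairwise_correlation(me),
        f_stat=float(f_stat),
        f_p=float(f_p),
        t_stat=float(t_stat),
        t_p=float(t_p),
        cca=cca,
    )


def histogram_npp_scatter_data(
    features: ReducedFeatureMatrix, bins: int = 20, scatter_pair: tuple[int, int] = (0, 1)
) -> dict:
    """Plot-ready arrays: histogram counts, normal-probability quantile pairs,
    and class-tagged scatter pairs.

    Histogram counts always sum to the number of pooled feature values.
    NPP pairs are (theoretical normal quantile, ordered sample value) using
    Blom plotting positions.
    """
    if bins < 2:
        raise ConfigError("need at least 2 histogram bins")
    vals = features.values.ravel()
    if vals.size == 0:
        raise InputError("empty feature set")
    counts, edges = np.histogram(vals, bins=bins)
    ordered = np.sort(vals)
    n = ordered.size
    pp = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    theo = scipy.stats.norm.ppf(pp)
    i, j = scatter_pair
    labels = np.asarray(features.labels)
    scatter = {
        lab: np.column_stack([features.values[labels == lab, i],
                              features.values[labels == lab, j]])
        for lab in ("Adeno", "Meso")
    }
    return {
        "hist_counts": counts,
        "hist_edges": edges,
        "npp_theoretical": theo,
        "npp_sample": ordered,
        "scatter": scatter,
    }
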