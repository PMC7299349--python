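"""Shared statistical machinery.

Bias-corrected and accelerated (BCa) bootstrap confidence intervals with
optional replicate-level weights, a two-tailed Fisher exact test, the
Mann-Whitney U test, the Pearson correlation test, and the seeded-RNG
contract used by every stochastic routine in the package.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "BootstrapConfig",
    "ContingencyTable2x2",
    "bca_interval",
    "fisher_exact_two_tailed",
    "mann_whitney_two_tailed",
    "pearson_test",
    "rng_for",
]


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from a top-level seed.

    Streams for distinct labels are statistically independent; the same
    (seed, label) pair always yields the same stream.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(label.encode())])
    )


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling settings: number of bootstrap replicates, coverage level, seed."""

    n_boot: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; rows are treatments, columns with/without a feature."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def _weighted_mean(values: np.ndarray, weights: Optional[np.ndarray]) -> float:
    if weights is None:
        return float(np.mean(values))
    return float(np.sum(values * weights) / np.sum(weights))


def _bca_levels(z0: float, accel: float, alpha: float) -> tuple[float, float]:
    """Adjusted quantile levels for the BCa interval endpoints.

    With z0 = 0 and accel = 0 this reduces exactly to the percentile
    method's (alpha/2, 1 - alpha/2).
    """
    z_lo, z_hi = sps.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
    levels = []
    for z in (z_lo, z_hi):
        adj = z0 + (z0 + z) / (1.0 - accel * (z0 + z))
        levels.append(float(sps.norm.cdf(adj)))
    return levels[0], levels[1]


def bca_interval(
    values: Sequence[float],
    config: BootstrapConfig,
    weights: Optional[Sequence[float]] = None,
    statistic: Optional[Callable[[np.ndarray, Optional[np.ndarray]], float]] = None,
) -> tuple[float, float]:
    """BCa bootstrap confidence interval over replicate-level values.

    Replicate indices are resampled uniformly with replacement; the
    statistic (default: weighted mean) is recomputed per resample, with
    weights travelling alongside their replicates. The bias correction
    z0 comes from the fraction of bootstrap statistics below the point
    estimate; the acceleration from the jackknife third/second moment
    ratio. Reproducible for a given ``config.seed``.

    Parameters
    ----------
    values:
        Replicate-level statistics (one per biological replicate).
    config:
        Number of resamples, coverage level and seed.
    weights:
        Optional positive per-replicate weights (e.g. cells counted per
        replicate culture).
    statistic:
        Callable ``f(values, weights) -> float`` applied to each
        resample. Defaults to the (weighted) mean.

    Returns
    -------
    (lower, upper):
        Interval endpoints. Degenerate data (all values identical)
        yields the degenerate interval ``(v, v)``.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1:
        raise ValueError("values must be one-dimensional")
    n = vals.size
    if n < 2:
        raise ValueError("BCa interval requires at least 2 replicates")
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != vals.shape:
            raise ValueError("weights must align with values")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    stat = statistic if statistic is not None else _weighted_mean

    if np.all(vals == vals[0]):
        v = stat(vals, w)
        return (v, v)

    theta_hat = stat(vals, w)
    rng = rng_for(config.seed, "bca")

    idx = rng.integers(0, n, size=(config.n_boot, n))
    if statistic is None and w is None:
        boot = vals[idx].mean(axis=1)
    else:
        boot = np.empty(config.n_boot)
        for b in range(config.n_boot):
            take = idx[b]
            boot[b] = stat(vals[take], None if w is None else w[take])

    # Bias correction: fraction of bootstrap statistics below the estimate,
    # clipped away from {0, 1} so the normal quantile stays finite.
    prop = np.mean(boot < theta_hat)
    prop = min(max(prop, 1.0 / (config.n_boot + 1)), config.n_boot / (config.n_boot + 1))
    z0 = float(sps.norm.ppf(prop))

    # Acceleration from the jackknife.
    jack = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        jack[i] = stat(vals[keep], None if w is None else w[keep])
    d = jack.mean() - jack
    denom = np.sum(d**2) ** 1.5
    accel = 0.0 if denom == 0 else float(np.sum(d**3) / (6.0 * denom))

    lo_level, hi_level = _bca_levels(z0, accel, config.alpha)
    lower, upper = np.quantile(boot, [lo_level, hi_level])
    return float(lower), float(upper)


def fisher_exact_two_tailed(table: ContingencyTable2x2) -> float:
    """Two-tailed Fisher exact p-value for a 2x2 table.

    Uses the method of small p-values: with all margins fixed, sum the
    hypergeometric probabilities of every table no more probable than
    the observed one. A zero margin carries no information and returns
    p = 1 by convention.
    """
    arr = table.as_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        return 1.0
    return float(sps.fisher_exact(arr, alternative="two-sided").pvalue)


def _mw_exact_two_tailed(x: np.ndarray, y: np.ndarray) -> float:
    """Exact Mann-Whitney p by enumerating all label assignments.

    Handles ties via midranks. Two-tailed p is the null probability of a
    U statistic at least as far from its mean as the observed one.
    """
    pooled = np.concatenate([x, y])
    n1, n_total = x.size, pooled.size
    ranks = sps.rankdata(pooled)
    center = n1 * (n_total - n1) / 2.0
    obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    obs_dev = abs(obs_u - center)
    hits = total = 0
    for combo in itertools.combinations(range(n_total), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - center) >= obs_dev - 1e-12:
            hits += 1
    return hits / total


def mann_whitney_two_tailed(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-tailed Mann-Whitney U test.

    Exact enumeration of all label assignments when the combined sample
    size is at most 12; otherwise the normal approximation with tie
    correction and continuity correction. Completely tied data returns
    p = 1.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([xa, ya])
    if np.all(pooled == pooled[0]):
        return 1.0
    if pooled.size <= 12:
        return float(_mw_exact_two_tailed(xa, ya))
    return float(
        sps.mannwhitneyu(xa, ya, alternative="two-sided", method="asymptotic").pvalue
    )


def pearson_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Pearson correlation with its two-tailed t-based p-value.

    Returns ``(r, df, p)`` with ``df = n - 2``. Requires equal lengths,
    at least 3 points and non-zero variance in each variable.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(xa) == 0 or np.var(ya) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(xa, ya)
    return float(res.statistic), xa.size - 2, float(res.pvalue)
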