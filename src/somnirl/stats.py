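"""Normality testing, two-sample comparison, effect sizes, significance masks.

Feature distributions across sleep states are typically non-normal, so the
workflow is: Kolmogorov-Smirnov normality check, then Mann-Whitney U tests
between states with an eta-squared effect size (``z^2 / n``), and a
significance mask (optionally Bonferroni-corrected) over channels / bands /
features.

The Mann-Whitney test uses the exact permutation distribution of the
midrank U statistic whenever ``n1 + n2 <= exact_threshold`` (ties handled by
midranks inside the enumeration); larger samples use the normal
approximation with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str
    effect_size_eta2: float | None = None
    z: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def ks_normality(sample: np.ndarray) -> TestResult:
    """One-sample KS test against a normal with the sample's mean and s.d.

    Parameters are estimated from the data, which makes the test
    conservative (Lilliefors effect); it is labeled accordingly.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample; normality test undefined")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return TestResult(statistic=float(stat), p_value=float(p),
                      n1=x.size, n2=0,
                      method="ks_one_sample_estimated_params")


def _u_statistic(ranks_a: np.ndarray, n1: int) -> float:
    return float(ranks_a.sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(a: np.ndarray, b: np.ndarray,
                   exact_threshold: int = 20) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    Exact permutation p-value (full enumeration of the C(n, n1) group
    assignments, two-sided by distance of U from its null mean n1*n2/2) when
    ``n1 + n2 <= exact_threshold``; otherwise the normal approximation with
    tie and continuity corrections.  The returned statistic is U for the
    first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n1], n1)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    if n <= exact_threshold:
        dev = abs(u_obs - mu)
        hits = 0
        for idx in combinations(range(n), n1):
            u = _u_statistic(ranks[list(idx)], n1)
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        p = hits / comb(n, n1)
        z = None
        method = "mann_whitney_exact"
    else:
        # normal approximation, tie-corrected variance, continuity correction
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        sigma = np.sqrt(sigma2)
        if sigma == 0:
            p, z = 1.0, 0.0
        else:
            z = (u_obs - mu - 0.5 * np.sign(u_obs - mu)) / sigma
            p = float(2 * sps.norm.sf(abs(z)))
        method = "mann_whitney_normal_approx"
    eta2 = None if z is None else eta_squared(z, n)
    return TestResult(statistic=u_obs, p_value=min(p, 1.0), n1=n1, n2=n2,
                      method=method, effect_size_eta2=eta2, z=z)


def eta_squared(z: float, n_total: int) -> float:
    """Effect size eta^2 = z^2 / n for a rank test, clipped to [0, 1]."""
    if n_total < 2:
        raise ValueError("need n_total >= 2")
    return float(min(z**2 / n_total, 1.0))


def significance_mask(p_values, alpha: float = 0.05,
                      correction: str = "none"):
    """Boolean mask of p < threshold (threshold alpha, or alpha/m).

    Accepts a mapping (returns a mapping) or a sequence (returns an array).
    """
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    if isinstance(p_values, dict):
        keys = list(p_values)
        ps = np.array([p_values[k] for k in keys], dtype=float)
    else:
        keys = None
        ps = np.asarray(list(p_values), dtype=float)
    if ps.size and (ps.min() < 0 or ps.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = ps.size
    threshold = alpha if correction == "none" or m == 0 else alpha / m
    mask = ps < threshold
    if keys is not None:
        return {k: bool(v) for k, v in zip(keys, mask)}
    return mask
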