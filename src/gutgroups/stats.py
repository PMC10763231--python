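"""Shared rank/correlation statistics used across the analysis modules.

All Spearman correlations in the package (co-occurrence edges, virome
coupling, taxon-phage heatmaps) go through :func:`spearman` so that ties are
handled identically everywhere (midranks) and the p-value convention (t
approximation, exact permutation enumeration for very small n) is uniform.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps

__all__ = [
    "spearman",
    "spearman_matrix",
    "pearson",
    "mann_whitney",
    "bh_adjust",
    "significance_tier",
]


def _t_sf_two_sided(r: float, n: int) -> float:
    """Two-sided p for a correlation r on n pairs via the t distribution."""
    if n < 3:
        return 1.0
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def spearman(x, y, exact: bool | None = None) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    Parameters
    ----------
    x, y : array-like, same length n >= 3
    exact : if True, the two-sided p-value is computed by full enumeration of
        the n! rank permutations (only feasible for n <= 8); if None, the t
        approximation is used for n >= 10 and exact enumeration below that
        when n <= 8 (n = 9 falls back to the t approximation).

    Returns
    -------
    (rho, p_two_sided)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("spearman requires two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact is None:
        exact = n <= 8
    if exact and n <= 8:
        p = _exact_perm_p(rx, ry, rho)
    else:
        p = _t_sf_two_sided(rho, n)
    return rho, p


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p by enumerating all orderings of one vector."""
    n = rx.size
    rxc = rx - rx.mean()
    denom_x = math.sqrt(float(rxc @ rxc))
    ryc = ry - ry.mean()
    denom_y = math.sqrt(float(ryc @ ryc))
    count = 0
    total = 0
    thresh = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = float(rxc @ ryc[list(perm)]) / (denom_x * denom_y)
        if abs(r) >= thresh:
            count += 1
        total += 1
    return count / total


def spearman_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided t-approximation p over columns of X.

    Columns with zero variance yield NaN rho/p against every partner.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    ranks = np.apply_along_axis(sps.rankdata, 0, X)
    const = np.ptp(X, axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.atleast_2d(rho)
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.clip(1.0 - rho**2, 1e-300, None))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, 0.0)
    return rho, p


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with the standard two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("pearson requires two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, _t_sf_two_sided(r, n)


def mann_whitney(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    mode 'exact' enumerates the null distribution (no ties allowed by the
    exact method); 'approx' uses the normal approximation with tie and
    continuity corrections; 'auto' chooses exact when both samples have
    n <= 8 and the pooled data carry no ties, otherwise the approximation.

    Returns (U of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    if x.size < 2 or y.size < 2:
        raise ValueError("mann_whitney requires n >= 2 per sample")
    if mode not in ("exact", "approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def significance_tier(p: float) -> str:
    """Marker tiers used in association heatmaps ($ p<0.1 ... *** p<0.001)."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "$"
    return ""
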