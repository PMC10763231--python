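"""Virome-bacteriome coupling: alpha-diversity correlation, Mantel tests on
Bray-Curtis matrices, and taxon-by-phage correlation heatmap values.

All rank correlations reuse the package-wide Spearman routine, so midrank
tie handling and p-value conventions match the co-occurrence analysis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import FeatureProfile, GutgroupsError
from .ecology import DistanceMatrix
from .stats import bh_adjust, spearman

__all__ = ["alpha_coupling", "mantel", "MantelResult", "taxon_phage_correlations"]


def alpha_coupling(alpha_viral: pd.DataFrame, alpha_bacterial: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation between viral and bacterial alpha diversity.

    Correlates each shared index column (e.g. chao1, shannon) across matched
    samples; returns a frame of rho and p per index.
    """
    if not alpha_viral.index.equals(alpha_bacterial.index):
        raise GutgroupsError("alpha tables must cover the same samples in the same order")
    if len(alpha_viral) < 5:
        raise GutgroupsError("alpha coupling needs at least 5 samples")
    indices = [c for c in alpha_viral.columns if c in alpha_bacterial.columns]
    rows = {}
    for col in indices:
        rho, p = spearman(alpha_viral[col], alpha_bacterial[col], exact=False)
        rows[col] = {"rho": rho, "p": p}
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclasses.dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    method: str


def mantel(
    dist_a: DistanceMatrix,
    dist_b: DistanceMatrix,
    permutations: int = 999,
    method: str = "spearman",
    seed: int | None = 0,
) -> MantelResult:
    """Mantel test of association between two distance matrices.

    Correlates the n(n-1)/2 off-diagonal pairs (Spearman by default,
    Pearson optionally) and permutes the sample order of the second matrix;
    the p-value is one-sided (greater), on the (b + 1)/(B + 1) lattice.
    """
    if method not in ("spearman", "pearson"):
        raise GutgroupsError(f"unknown method {method!r}")
    if not np.array_equal(dist_a.sample_ids, dist_b.sample_ids):
        raise GutgroupsError("distance matrices must cover the same samples in the same order")
    A = dist_a.values()
    B = dist_b.values()
    n = A.shape[0]
    if n < 5:
        raise GutgroupsError("mantel needs at least 5 samples")
    iu = np.triu_indices(n, k=1)
    a = A[iu]
    if method == "spearman":
        a = sps.rankdata(a)

    def corr_with(Bm: np.ndarray) -> float:
        b = Bm[iu]
        if method == "spearman":
            b = sps.rankdata(b)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise GutgroupsError("constant distance matrix in mantel test")
        return float(np.corrcoef(a, b)[0, 1])

    observed = corr_with(B)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        if corr_with(B[np.ix_(perm, perm)]) >= observed:
            count += 1
    p = (count + 1) / (permutations + 1)
    return MantelResult(r=observed, p_value=float(p), n_permutations=permutations, method=method)


def taxon_phage_correlations(
    bact_profile: FeatureProfile,
    viral_profile: FeatureProfile,
    bh_correct: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman correlations between bacterial and viral taxa.

    Returns (rho, p) frames with bacterial taxa as rows and viral taxa as
    columns.  Constant features have undefined rank correlations and are
    reported as missing.  Benjamini-Hochberg adjustment of the p-values is
    available behind ``bh_correct`` (off by default).
    """
    if not bact_profile.sample_ids.equals(viral_profile.sample_ids):
        raise GutgroupsError("profiles must cover the same samples in the same order")
    Xb = bact_profile.frame.to_numpy(dtype=float)
    Xv = viral_profile.frame.to_numpy(dtype=float)
    n = Xb.shape[0]
    rb = np.apply_along_axis(sps.rankdata, 0, Xb)
    rv = np.apply_along_axis(sps.rankdata, 0, Xv)
    const_b = np.ptp(Xb, axis=0) == 0
    const_v = np.ptp(Xv, axis=0) == 0
    zb = (rb - rb.mean(axis=0)) / np.where(rb.std(axis=0) > 0, rb.std(axis=0), 1.0)
    zv = (rv - rv.mean(axis=0)) / np.where(rv.std(axis=0) > 0, rv.std(axis=0), 1.0)
    rho = zb.T @ zv / n
    rho[const_b, :] = np.nan
    rho[:, const_v] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.clip(1.0 - rho**2, 1e-300, None))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    p[np.isnan(rho)] = np.nan
    if bh_correct:
        flat = p.ravel()
        ok = ~np.isnan(flat)
        flat[ok] = bh_adjust(flat[ok])
        p = flat.reshape(p.shape)
    rows = bact_profile.feature_ids
    cols = viral_profile.feature_ids
    return (
        pd.DataFrame(rho, index=rows, columns=cols),
        pd.DataFrame(p, index=rows, columns=cols),
    )
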