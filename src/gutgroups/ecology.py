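"""Community ecology: alpha diversity, rarefaction, Bray-Curtis, PCoA and
permutation tests (PERMANOVA / ANOSIM).

Alpha diversity follows the classic estimators: Shannon entropy with natural
log, Gini-Simpson (1 - sum p_i^2), bias-corrected Chao1
(S_obs + F1(F1-1)/(2(F2+1))) and ACE with the conventional rare-species
cutoff of 10.  The rarefaction curve is the analytic hypergeometric
expectation rather than resampling.  Both permutation tests use the
(b + 1) / (B + 1) p-value rule and draw their label permutations from a
caller-supplied seed so runs are reproducible.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy import stats as sps

from .datatypes import FeatureProfile, GutgroupsError

__all__ = [
    "alpha_diversity",
    "alpha_diversity_table",
    "rarefaction_curve",
    "bray_curtis",
    "DistanceMatrix",
    "pcoa",
    "PcoaResult",
    "permanova",
    "anosim",
    "PermutationTestResult",
    "multi_group_comparison",
]


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def alpha_diversity(counts) -> dict[str, float]:
    """Ace, Chao1, Shannon and Simpson indices of one sample's counts.

    Shannon and Simpson use relative abundances and tolerate real-valued
    input; the richness estimators (ACE, Chao1) need integer counts and
    round real input with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or (counts < 0).any():
        raise GutgroupsError("counts must be non-negative")
    counts = counts[counts > 0]
    if counts.size == 0:
        raise GutgroupsError("all-zero sample has no diversity")

    p = counts / counts.sum()
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p**2).sum())

    ints = np.rint(counts)
    if not np.allclose(counts, ints):
        warnings.warn("ACE/Chao1 require integer counts; rounding", stacklevel=2)
    ints = ints[ints > 0].astype(int)
    s_obs = ints.size
    f1 = int((ints == 1).sum())
    f2 = int((ints == 2).sum())
    chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return {
        "ace": _ace(ints),
        "chao1": float(chao1),
        "shannon": shannon,
        "simpson": simpson,
        "observed": float(s_obs),
    }


def _ace(counts: np.ndarray, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator (ACE) with the standard cutoff."""
    rare = counts[counts <= rare_cutoff]
    abund = counts[counts > rare_cutoff]
    s_rare, s_abund = rare.size, abund.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    if f1 == n_rare:
        # every rare species a singleton: sample coverage is zero and ACE is
        # undefined; report the bias-corrected Chao1 value instead
        f2 = 0
        return float(s_abund + s_rare + f1 * (f1 - 1) / (2.0 * (f2 + 1)))
    c_ace = 1.0 - f1 / n_rare
    top = sum(i * (i - 1) * int((rare == i).sum()) for i in range(1, rare_cutoff + 1))
    gamma2 = max(s_rare / c_ace * top / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    return float(s_abund + s_rare / c_ace + f1 / c_ace * gamma2)


def alpha_diversity_table(profile: FeatureProfile) -> pd.DataFrame:
    """Per-sample alpha diversity of a raw count profile."""
    rows = {sid: alpha_diversity(row.to_numpy()) for sid, row in profile.frame.iterrows()}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def rarefaction_curve(counts, depths) -> pd.Series:
    """Expected richness at each subsampling depth (analytic, hypergeometric).

    E[S(d)] = sum_i [1 - C(N - n_i, d) / C(N, d)] for total N = sum n_i.
    """
    counts = np.asarray(counts)
    if not np.allclose(counts, np.rint(counts)) or (counts < 0).any():
        raise GutgroupsError("rarefaction requires non-negative integer counts")
    counts = np.rint(counts).astype(np.int64)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise GutgroupsError("all-zero sample cannot be rarefied")
    total = int(counts.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=np.int64))
    if (depths < 0).any() or (depths > total).any():
        raise GutgroupsError(f"depths must lie in [0, {total}]")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    expected = []
    for d in depths:
        # P(taxon i absent from a subsample of size d) = C(N - n_i, d) / C(N, d)
        keep = counts <= total - d
        p_absent = np.zeros(counts.size)
        if keep.any():
            p_absent[keep] = np.exp(log_choose(total - counts[keep], d) - log_choose(total, d))
        expected.append(float((1.0 - p_absent).sum()))
    return pd.Series(expected, index=depths, name="expected_richness")


# ---------------------------------------------------------------------------
# Distances and ordination
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric sample-by-sample distances with zero diagonal."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy(dtype=float)
        if vals.shape[0] != vals.shape[1]:
            raise GutgroupsError("distance matrix must be square")
        if not np.array_equal(self.frame.index, self.frame.columns):
            raise GutgroupsError("distance matrix rows/columns must agree")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise GutgroupsError("distance matrix must be symmetric")
        if not np.allclose(np.diag(vals), 0.0):
            raise GutgroupsError("distance matrix diagonal must be zero")
        if (vals < -1e-12).any():
            raise GutgroupsError("distances must be non-negative")

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


def bray_curtis(profile: FeatureProfile) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: d(x, y) = sum|x_i - y_i| / sum(x_i + y_i)."""
    X = profile.frame.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise GutgroupsError("bray_curtis needs at least two samples")
    sums = X.sum(axis=1)
    if (sums == 0).sum() >= 2:
        raise GutgroupsError("two all-zero samples have undefined Bray-Curtis distance")
    diff = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    tot = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(pd.DataFrame(d, index=profile.sample_ids, columns=profile.sample_ids))


@dataclasses.dataclass(frozen=True)
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes (positive eigenvalues only)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per positive axis, over positive sum


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Principal coordinate analysis by Gower double-centering.

    Axes are ordered by eigenvalue; negative eigenvalues (possible for
    non-Euclidean dissimilarities such as Bray-Curtis) are reported but
    excluded from the proportion-explained denominator.
    """
    D = dist.values()
    n = D.shape[0]
    if n < 3:
        raise GutgroupsError("pcoa needs at least three samples")
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    evals, evecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    prop = evals[pos] / evals[pos].sum()
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=dist.sample_ids, columns=axes),
        eigenvalues=evals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    method: str


def _check_groups(labels: np.ndarray) -> list[np.ndarray]:
    groups = [np.flatnonzero(labels == g) for g in pd.unique(labels)]
    if len(groups) < 2:
        raise GutgroupsError("permutation tests need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise GutgroupsError("every group needs at least two samples")
    return groups


def permanova(
    dist: DistanceMatrix, labels, permutations: int = 999, seed: int | None = None
) -> PermutationTestResult:
    """One-way PERMANOVA pseudo-F with a free label-permutation p-value.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within = sum over groups of the
    within-group pairwise d^2 divided by the group size; pseudo-F =
    (SS_between / (a - 1)) / (SS_within / (n - a)).
    """
    labels = np.asarray(labels)
    D2 = dist.values() ** 2
    n = D2.shape[0]
    if labels.size != n:
        raise GutgroupsError("labels must match the distance matrix")
    groups = _check_groups(labels)
    a = len(groups)
    ss_total = D2.sum() / (2.0 * n)

    def pseudo_f(lab: np.ndarray) -> float:
        ss_within = 0.0
        for g in pd.unique(lab):
            ix = np.flatnonzero(lab == g)
            ss_within += D2[np.ix_(ix, ix)].sum() / (2.0 * len(ix))
        return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))

    observed = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(permutations):
        if pseudo_f(rng.permutation(labels)) >= observed:
            b += 1
    p = (b + 1) / (permutations + 1)
    return PermutationTestResult(float(observed), float(p), permutations, "permanova")


def anosim(
    dist: DistanceMatrix, labels, permutations: int = 999, seed: int | None = None
) -> PermutationTestResult:
    """ANOSIM R with midranks on tied distances and free label permutation.

    R = (mean between-group rank - mean within-group rank) / (M / 2) with
    M = n(n-1)/2 ranks over all pairwise distances.
    """
    labels = np.asarray(labels)
    D = dist.values()
    n = D.shape[0]
    if labels.size != n:
        raise GutgroupsError("labels must match the distance matrix")
    _check_groups(labels)
    iu = np.triu_indices(n, k=1)
    ranks = sps.rankdata(D[iu])
    m = ranks.size
    denom = m / 2.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    observed = r_stat(labels)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(permutations):
        if r_stat(rng.permutation(labels)) >= observed:
            b += 1
    p = (b + 1) / (permutations + 1)
    return PermutationTestResult(float(observed), float(p), permutations, "anosim")


# ---------------------------------------------------------------------------
# Parametric multi-group utility
# ---------------------------------------------------------------------------


def multi_group_comparison(values, groups) -> pd.DataFrame:
    """One-way ANOVA plus Tukey HSD pairwise comparisons.

    A thin convenience over the standard procedures for comparing ratios or
    diversity indices across three or more diet groups.  Returns a tidy frame
    of pairwise comparisons with the overall ANOVA F and p attached.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = list(pd.unique(groups))
    if len(uniq) < 2:
        raise GutgroupsError("multi_group_comparison needs >= 2 groups")
    samples = [values[groups == g] for g in uniq]
    f_stat, f_p = sps.f_oneway(*samples)
    tukey = sps.tukey_hsd(*samples)
    rows = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            rows.append(
                {
                    "group_a": uniq[i],
                    "group_b": uniq[j],
                    "mean_diff": float(np.mean(samples[i]) - np.mean(samples[j])),
                    "tukey_p": float(tukey.pvalue[i, j]),
                    "anova_F": float(f_stat),
                    "anova_p": float(f_p),
                }
            )
    return pd.DataFrame(rows)
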